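"""Time-frequency phase extraction and phase-locking-value maps.

Phase is estimated by convolving the *continuous* (re-referenced,
notched) signal with fixed-cycle complex Morlet wavelets at 1 Hz
spacing and taking the argument; epoching happens afterwards, so no
edge artifacts from the wavelet support fall inside the epoch window.
With the default five cycles the 4 Hz wavelet spans about 1.6 s --
longer than the 800 ms epoch -- which is why convolution must run on
the continuous recording.

The phase-locking value between a seed and a target channel at one
(frequency, time) bin is the mean resultant length of the across-trial
phase differences; its significance is the Rayleigh test of uniformity,
FDR-corrected over all bins of one seed x target x condition map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.fft import fft, ifft, next_fast_len

from .bundle import EventTable, RecordingBundle
from .circstats import (
    bh_fdr,
    rayleigh_p_from_resultant,
    resultant_length_rows,
    wrap_angle,
)
from .config import AnalysisConfig
from .errors import ConfigError

logger = logging.getLogger(__name__)

__all__ = [
    "TFPhaseSet",
    "PlvMap",
    "morlet_kernel",
    "tf_phase",
    "tf_valid_events",
    "pairwise_plv",
    "seed_channels",
]

#: Gaussian support truncation, in standard deviations of the envelope.
_SUPPORT_SD = 4.0


@dataclass
class TFPhaseSet:
    """Per-trial instantaneous phase of one channel.

    ``phase`` is trials x frequencies x times (radians in (-pi, pi]),
    sampled on the decimated epoch time grid.  ``event_index`` maps
    trials to rows of the source event table.
    """

    channel_id: str
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    phase: np.ndarray
    conditions: np.ndarray
    event_index: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.phase.shape[0]

    def restrict(self, event_indices: np.ndarray) -> "TFPhaseSet":
        """Keep only trials whose source event is in ``event_indices``
        (order preserved)."""
        sel = np.isin(self.event_index, event_indices)
        return replace(
            self,
            phase=self.phase[sel],
            conditions=self.conditions[sel],
            event_index=self.event_index[sel],
        )

    def condition_phase(self, condition: str) -> np.ndarray:
        return self.phase[self.conditions == condition]


@dataclass
class PlvMap:
    """Seed-to-target PLV over the frequency x time grid for one
    condition, with Rayleigh significance and its FDR mask."""

    seed_id: str
    target_id: str
    condition: str
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    plv: np.ndarray
    rayleigh_p: np.ndarray
    significant: np.ndarray
    n_trials: int

    def to_frame(self) -> pd.DataFrame:
        ff, tt = np.meshgrid(self.freqs_hz, self.times_ms, indexing="ij")
        return pd.DataFrame(
            {
                "seed": self.seed_id,
                "target": self.target_id,
                "condition": self.condition,
                "freq_hz": ff.ravel(),
                "time_ms": tt.ravel(),
                "plv": self.plv.ravel(),
                "p": self.rayleigh_p.ravel(),
                "significant": self.significant.ravel(),
            }
        )

    def band_time_course(self, lo_hz: float, hi_hz: float) -> np.ndarray:
        """PLV averaged over the half-open band [lo, hi)."""
        sel = (self.freqs_hz >= lo_hz) & (self.freqs_hz < hi_hz)
        return self.plv[sel].mean(axis=0)


def morlet_kernel(freq_hz: float, fs: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet wavelet, L2-normalized, truncated at 4 envelope SDs.

    The envelope SD is ``n_cycles / (2 pi f)`` seconds, i.e. the wavelet
    holds ``n_cycles`` cycles within one SD-pair of its Gaussian window.
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq_hz)
    half = int(np.ceil(_SUPPORT_SD * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(
        2j * np.pi * freq_hz * t
    )
    return kernel / np.linalg.norm(kernel)


def _grid(
    config: AnalysisConfig, fs: float
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """(freqs, times_ms, start offset in samples, step in samples)."""
    freqs = config.freqs_hz()
    step = config.time_step_ms * fs / 1000.0
    if abs(step - round(step)) > 1e-9 or round(step) < 1:
        raise ConfigError(
            f"time step {config.time_step_ms} ms is not a whole number of "
            f"samples at {fs} Hz"
        )
    step = int(round(step))
    w0, w1 = config.epoch_window_ms
    n_steps = int(np.floor((w1 - w0) / config.time_step_ms))
    times = w0 + config.time_step_ms * np.arange(n_steps)
    start_off = int(round(w0 * fs / 1000.0))
    return freqs, times, start_off, step


def tf_valid_events(
    bundle: RecordingBundle, events: EventTable, config: AnalysisConfig
) -> np.ndarray:
    """Boolean mask of events whose epoch stays clear of the wavelet
    edge region (half the support of the lowest-frequency kernel) at
    both ends of the recording."""
    fs = bundle.fs
    freqs, times, start_off, step = _grid(config, fs)
    half = (morlet_kernel(freqs.min(), fs, config.n_cycles).size - 1) // 2
    onset_idx = np.round(events.onsets_ms * fs / 1000.0).astype(int)
    first = onset_idx + start_off
    last = onset_idx + start_off + (len(times) - 1) * step
    return (first >= half) & (last < bundle.n_samples - half)


def tf_phase(
    bundle: RecordingBundle,
    events: EventTable,
    channel_id: str,
    config: AnalysisConfig,
) -> TFPhaseSet:
    """Instantaneous phase of one channel on the trial x freq x time grid.

    Morlet convolution runs over the whole continuous signal per
    frequency (single FFT of the channel, one inverse FFT per
    frequency); phases are then cut into epochs on the decimated time
    grid.  Events too close to the recording edges for the widest
    wavelet are dropped with a warning.
    """
    fs = bundle.fs
    freqs, times, start_off, step = _grid(config, fs)
    x = bundle.signals[bundle.channel_index(channel_id)].astype(np.float64)
    n = x.size

    kernels = [morlet_kernel(f, fs, config.n_cycles) for f in freqs]
    l_max = max(k.size for k in kernels)
    nfft = next_fast_len(n + l_max - 1)
    X = fft(x, nfft)

    valid = tf_valid_events(bundle, events, config)
    n_dropped = int(np.sum(~valid))
    if n_dropped:
        logger.warning(
            "tf_phase(%s): dropped %d of %d events too close to the "
            "recording edge for the %.0f Hz wavelet",
            channel_id, n_dropped, len(events), freqs.min(),
        )
    idx = np.flatnonzero(valid)
    onset_idx = np.round(events.onsets_ms[idx] * fs / 1000.0).astype(int)
    # trials x times sample index matrix
    sample_idx = (
        onset_idx[:, None] + start_off + step * np.arange(len(times))[None, :]
    )

    phase = np.empty((idx.size, freqs.size, len(times)), dtype=np.float32)
    for fi, kernel in enumerate(kernels):
        half = (kernel.size - 1) // 2
        y = ifft(X * fft(kernel, nfft))
        y = y[half: half + n]  # 'same' alignment: y[t] centred on x[t]
        phase[:, fi, :] = np.angle(y[sample_idx])
    return TFPhaseSet(
        channel_id=channel_id,
        freqs_hz=freqs,
        times_ms=times,
        phase=phase,
        conditions=events.kinds[idx].copy(),
        event_index=idx,
    )


def pairwise_plv(
    seed: TFPhaseSet,
    target: TFPhaseSet,
    condition: str,
    alpha: float = 0.05,
) -> PlvMap:
    """PLV map between a seed and a target phase set for one condition.

    Requires identical trial sets and grids (equate conditions
    upstream).  Significance: Rayleigh test per bin, BH-FDR over all
    frequency x time bins of the map at ``alpha``.
    """
    if not np.array_equal(seed.event_index, target.event_index):
        raise ValueError("seed and target phase sets cover different trials")
    if not (
        np.array_equal(seed.freqs_hz, target.freqs_hz)
        and np.array_equal(seed.times_ms, target.times_ms)
    ):
        raise ValueError("seed and target grids differ")
    dphi = wrap_angle(
        seed.condition_phase(condition).astype(np.float64)
        - target.condition_phase(condition).astype(np.float64)
    )
    n = dphi.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 trials, got {n}")
    plv = resultant_length_rows(dphi, axis=0)
    p = rayleigh_p_from_resultant(plv, n)
    mask = bh_fdr(p.ravel(), alpha).reshape(p.shape)
    return PlvMap(
        seed_id=seed.channel_id,
        target_id=target.channel_id,
        condition=condition,
        freqs_hz=seed.freqs_hz,
        times_ms=seed.times_ms,
        plv=plv,
        rayleigh_p=p,
        significant=mask,
        n_trials=n,
    )


def seed_channels(bundle: RecordingBundle) -> list[str]:
    """Channels flagged as connectivity seeds in the montage metadata."""
    seeds = bundle.seed_channel_ids()
    if not seeds:
        raise ValueError("bundle flags no seed channels")
    return seeds
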