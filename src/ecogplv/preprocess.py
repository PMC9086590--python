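"""Deterministic signal conditioning and epoching.

Two preprocessing paths feed the analyses:

* ERP path: zero-phase 1-30 Hz Butterworth band-pass on the continuous
  signal, then epoching, artifact rejection and trial-count equating.
* PLV path: connector-group re-referencing and a 48-52 Hz zero-phase
  notch on the continuous signal; the 1-30 Hz band-pass is *not*
  applied, since phase is later extracted per frequency by wavelet
  convolution.

All filters are 4th-order Butterworth applied forward-backward
(``sosfiltfilt``), so they are linear and introduce no group delay --
the peak latencies the ERP statistics depend on are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .bundle import EventTable, RecordingBundle
from .errors import ConfigError

logger = logging.getLogger(__name__)

__all__ = [
    "EpochSet",
    "bandpass",
    "notch",
    "rereference_connector",
    "epoch",
    "reject_artifacts",
    "equate_trials",
]

_FILTER_ORDER = 4


@dataclass
class EpochSet:
    """Event-locked trials cut from a continuous recording.

    ``data`` is trials x channels x samples (microvolts) over the
    half-open window ``window_ms`` relative to each event onset.
    ``kept`` marks trials surviving artifact rejection / equating;
    rejection and equating only ever touch this mask, never the data.
    ``event_index`` maps each trial back to its row in the source event
    table (events whose window fell outside the recording are absent).
    """

    data: np.ndarray
    window_ms: tuple[float, float]
    fs: float
    conditions: np.ndarray  # per-trial "tone" | "omission"
    kept: np.ndarray  # bool per trial
    event_index: np.ndarray  # int per trial
    channel_ids: list[str]

    def __post_init__(self) -> None:
        n_trials = self.data.shape[0]
        if not (
            len(self.conditions) == len(self.kept) == len(self.event_index) == n_trials
        ):
            raise ValueError("per-trial metadata length mismatch")
        span = self.window_ms[1] - self.window_ms[0]
        expected = int(round(span * self.fs / 1000.0))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"window {self.window_ms} at {self.fs} Hz implies "
                f"{expected} samples, data has {self.data.shape[2]}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times_ms(self) -> np.ndarray:
        """Sample times (ms, relative to onset) of the epoch grid."""
        step = 1000.0 / self.fs
        return self.window_ms[0] + step * np.arange(self.n_samples)

    def kept_indices(self, condition: str | None = None) -> np.ndarray:
        mask = self.kept.copy()
        if condition is not None:
            mask &= self.conditions == condition
        return np.flatnonzero(mask)


def _sos(lo_hz: float, hi_hz: float, fs: float, btype: str) -> np.ndarray:
    nyq = fs / 2.0
    if not (0.0 < lo_hz < hi_hz < nyq):
        raise ConfigError(
            f"filter band ({lo_hz}, {hi_hz}) Hz must lie inside (0, {nyq}) Hz"
        )
    return sps.butter(_FILTER_ORDER, [lo_hz, hi_hz], btype=btype, fs=fs, output="sos")


def _filt_bundle(bundle: RecordingBundle, sos: np.ndarray) -> RecordingBundle:
    out = sps.sosfiltfilt(sos, bundle.signals.astype(np.float64), axis=1)
    return bundle.with_signals(out)


def bandpass(bundle: RecordingBundle, lo_hz: float, hi_hz: float) -> RecordingBundle:
    """Zero-phase Butterworth band-pass, per channel."""
    return _filt_bundle(bundle, _sos(lo_hz, hi_hz, bundle.fs, "bandpass"))


def notch(
    bundle: RecordingBundle, lo_hz: float = 48.0, hi_hz: float = 52.0
) -> RecordingBundle:
    """Zero-phase Butterworth band-stop removing line noise."""
    return _filt_bundle(bundle, _sos(lo_hz, hi_hz, bundle.fs, "bandstop"))


def rereference_connector(bundle: RecordingBundle) -> RecordingBundle:
    """Subtract, at every sample, the mean across each connector group.

    Removes noise shared within a headstage connector; afterwards the
    per-group channel mean is exactly zero, which also makes the
    operation idempotent.
    """
    out = bundle.signals.astype(np.float64)
    groups = np.array([c.connector_group for c in bundle.channels])
    for g in np.unique(groups):
        rows = groups == g
        out[rows, :] -= out[rows, :].mean(axis=0, keepdims=True)
    return bundle.with_signals(out)


def epoch(
    bundle: RecordingBundle,
    events: EventTable,
    window_ms: tuple[float, float] = (-200.0, 600.0),
) -> EpochSet:
    """Cut one trial per event over the half-open window ``window_ms``.

    The sample at trial time 0 equals the raw sample at the event onset.
    Events whose window exceeds the recording bounds are dropped with a
    logged warning rather than zero-padded.
    """
    fs = bundle.fs
    w0, w1 = window_ms
    n_win = int(round((w1 - w0) * fs / 1000.0))
    start_off = int(round(w0 * fs / 1000.0))
    onset_idx = np.round(events.onsets_ms * fs / 1000.0).astype(int)
    starts = onset_idx + start_off
    ok = (starts >= 0) & (starts + n_win <= bundle.n_samples)
    n_dropped = int(np.sum(~ok))
    if n_dropped:
        logger.warning(
            "epoch: dropped %d of %d events whose window %s ms exceeds the "
            "recording bounds", n_dropped, len(events), window_ms,
        )
    idx = np.flatnonzero(ok)
    data = np.empty((idx.size, bundle.n_channels, n_win), dtype=np.float32)
    for t, ev in enumerate(idx):
        s = starts[ev]
        data[t] = bundle.signals[:, s: s + n_win]
    return EpochSet(
        data=data,
        window_ms=(float(w0), float(w1)),
        fs=fs,
        conditions=events.kinds[idx].copy(),
        kept=np.ones(idx.size, dtype=bool),
        event_index=idx,
        channel_ids=bundle.channel_ids,
    )


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 1000.0) -> EpochSet:
    """Mark trials containing any sample strictly exceeding the
    threshold magnitude as rejected.  Samples at exactly the threshold
    are kept (strict inequality).  Data values are untouched."""
    peak = np.max(np.abs(epochs.data), axis=(1, 2))
    kept = epochs.kept & ~(peak > threshold_uv)
    return replace(epochs, kept=kept)


def equate_trials(epochs: EpochSet, rng: np.random.Generator) -> EpochSet:
    """Randomly subsample kept tone trials down to the kept omission
    count, so both conditions enter the statistics with equal n.

    Deterministic under a fixed generator; omission trials are never
    touched.  Raises if there are fewer kept tone than omission trials.
    """
    tone_idx = epochs.kept_indices("tone")
    n_omit = epochs.kept_indices("omission").size
    if tone_idx.size < n_omit:
        raise ValueError(
            f"cannot equate: {tone_idx.size} kept tone trials < "
            f"{n_omit} kept omission trials"
        )
    keep_tone = rng.choice(tone_idx, size=n_omit, replace=False)
    kept = epochs.kept.copy()
    kept[tone_idx] = False
    kept[keep_tone] = True
    return replace(epochs, kept=kept)


def save_epochs(epochs: EpochSet, path) -> None:
    """Write an epoch set as ``epochs.f32`` (raw float32, trials x
    channels x samples) plus ``epochs.json`` metadata."""
    import json
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.ascontiguousarray(epochs.data, dtype="<f4").tofile(path / "epochs.f32")
    meta = {
        "shape": list(epochs.data.shape),
        "window_ms": list(epochs.window_ms),
        "fs": epochs.fs,
        "conditions": list(epochs.conditions),
        "kept": epochs.kept.tolist(),
        "event_index": epochs.event_index.tolist(),
        "channel_ids": epochs.channel_ids,
    }
    with open(path / "epochs.json", "w") as fh:
        json.dump(meta, fh)
        fh.write("\n")


def load_epochs(path) -> EpochSet:
    """Read an epoch set written by :func:`save_epochs`."""
    import json
    from pathlib import Path

    path = Path(path)
    with open(path / "epochs.json") as fh:
        meta = json.load(fh)
    data = np.fromfile(path / "epochs.f32", dtype="<f4")
    shape = tuple(meta["shape"])
    if data.size != int(np.prod(shape)):
        raise ValueError(
            f"epochs.f32 holds {data.size} values, metadata declares {shape}"
        )
    return EpochSet(
        data=data.reshape(shape),
        window_ms=tuple(meta["window_ms"]),
        fs=meta["fs"],
        conditions=np.array(meta["conditions"], dtype=object),
        kept=np.array(meta["kept"], dtype=bool),
        event_index=np.array(meta["event_index"], dtype=int),
        channel_ids=list(meta["channel_ids"]),
    )
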