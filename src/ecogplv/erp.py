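"""Region-averaged event-related potentials with pointwise statistics.

For each cortical region and condition, trials are first averaged
across the region's electrodes (one trace per trial), then across
trials to give the ERP.  A one-sample t test against zero is run at
every time point over trials, and the Benjamini-Hochberg procedure
controls the false discovery rate across the time points of one
(region, condition) trace.

The exchangeable unit is the trial: with several sessions, pooling is
a plain concatenation of trials.  No baseline correction is applied;
the 1 Hz high-pass edge of the ERP filter serves that role.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bundle import EVENT_KINDS, REGIONS, EventTable, RecordingBundle
from .circstats import bh_fdr
from .config import AnalysisConfig
from .preprocess import EpochSet, bandpass, epoch, equate_trials, reject_artifacts

__all__ = [
    "ErpTrace",
    "ErpResult",
    "region_trial_traces",
    "erp_mean",
    "erp_pointwise_test",
    "run_erp",
]


@dataclass
class ErpTrace:
    """ERP of one (region, condition): mean waveform plus pointwise
    one-sample t statistics and the FDR rejection mask."""

    region: str
    condition: str
    times_ms: np.ndarray
    mean_uv: np.ndarray
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    n_trials: int

    def peak_latency_ms(self, t_from: float | None = None,
                        t_to: float | None = None) -> float:
        """Latency of the largest |mean| deflection, optionally within
        a time window."""
        sel = np.ones_like(self.times_ms, dtype=bool)
        if t_from is not None:
            sel &= self.times_ms >= t_from
        if t_to is not None:
            sel &= self.times_ms < t_to
        idx = np.flatnonzero(sel)
        return float(self.times_ms[idx[np.argmax(np.abs(self.mean_uv[idx]))]])


@dataclass
class ErpResult:
    """All (region, condition) ERP traces of one session."""

    traces: list[ErpTrace]

    def get(self, region: str, condition: str) -> ErpTrace:
        for tr in self.traces:
            if tr.region == region and tr.condition == condition:
                return tr
        raise KeyError(f"no ERP trace for ({region}, {condition})")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.traces:
            rows.append(
                pd.DataFrame(
                    {
                        "region": tr.region,
                        "condition": tr.condition,
                        "time_ms": tr.times_ms,
                        "mean_uv": tr.mean_uv,
                        "t": tr.t,
                        "p": tr.p,
                        "significant": tr.significant,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def region_trial_traces(
    epochs: EpochSet, region_channel_ids: list[str], condition: str | None = None
) -> np.ndarray:
    """Per-trial traces averaged over a region's channels.

    Only kept trials (optionally of one condition) are used; returns a
    trials x samples matrix.
    """
    if not region_channel_ids:
        raise ValueError("region has no channels")
    rows = [epochs.channel_ids.index(c) for c in region_channel_ids]
    trials = epochs.kept_indices(condition)
    return epochs.data[np.ix_(trials, rows)].mean(axis=1)


def erp_mean(traces: np.ndarray) -> np.ndarray:
    """Pointwise mean across trials."""
    traces = np.asarray(traces)
    if traces.shape[0] < 1:
        raise ValueError("need at least one trial")
    return traces.mean(axis=0)


def erp_pointwise_test(
    traces: np.ndarray, alpha: float, fdr: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-sample t test against zero at each time point, across trials.

    Returns ``(t, p, mask)``.  Two-sided p with ``df = n - 1``; the mask
    is the BH-FDR rejection mask over the time points at level
    ``alpha`` (or a plain ``p < alpha`` threshold when ``fdr=False``).
    Zero-variance time points are reported as ``t = 0, p = 1`` so
    degenerate synthetic inputs do not propagate NaNs.
    """
    traces = np.asarray(traces, dtype=float)
    n = traces.shape[0]
    if n < 3:
        raise ValueError("pointwise t test needs at least 3 trials")
    mean = traces.mean(axis=0)
    sd = traces.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, 0.0, mean / (sd / np.sqrt(n)))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(zero_var, 1.0, p)
    mask = bh_fdr(p, alpha) if fdr else p < alpha
    return t, p, mask


def run_erp(
    bundle: RecordingBundle,
    events: EventTable,
    config: AnalysisConfig,
    rng: np.random.Generator | None = None,
    equate: bool = True,
) -> ErpResult:
    """Full ERP pipeline on one session.

    Band-pass -> epoch -> artifact rejection -> (optional) trial
    equating -> region-averaged ERPs with pointwise statistics for
    every (region, condition) present in the montage.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    filt = bandpass(bundle, *config.erp_bandpass_hz)
    ep = epoch(filt, events, config.epoch_window_ms)
    ep = reject_artifacts(ep, config.artifact_uv)
    if equate:
        ep = equate_trials(ep, rng)
    return erp_from_epochs(ep, bundle, config)


def erp_from_epochs(
    ep: EpochSet, bundle: RecordingBundle, config: AnalysisConfig
) -> ErpResult:
    """Region/condition ERP statistics from an already-prepared epoch set."""
    times = ep.times_ms()
    traces_out: list[ErpTrace] = []
    for region in REGIONS:
        chan_ids = bundle.region_channels(region)
        if not chan_ids:
            continue
        for condition in EVENT_KINDS:
            trials = region_trial_traces(ep, chan_ids, condition)
            if trials.shape[0] < 3:
                continue
            t, p, mask = erp_pointwise_test(trials, config.alpha_erp)
            traces_out.append(
                ErpTrace(
                    region=region,
                    condition=condition,
                    times_ms=times,
                    mean_uv=erp_mean(trials),
                    t=t,
                    p=p,
                    significant=mask,
                    n_trials=trials.shape[0],
                )
            )
    return ErpResult(traces_out)
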