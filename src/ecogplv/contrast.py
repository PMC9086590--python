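"""Presentation-vs-omission PLV contrasts.

Per (seed, target) pair and (frequency, time) bin, the two conditions'
across-trial phase-difference samples are compared with the circular
common-median test; a bin gets a sign (+1: omission PLV larger, -1:
presentation larger) when the uncorrected p falls below the contrast
level.  Three summaries follow:

* the *band rule*: a frequency band is called significant at a time
  point when more than a fixed fraction (default 20%) of its frequency
  bins carry a significant contrast, with the majority direction;
* the signed significance-ratio map over many electrode pairs;
* region time courses: the signed proportion of significant electrodes
  per band, averaged over 10 ms windows.

Swapping the condition labels flips every sign and negates the ratio
maps and proportion time courses exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circstats import common_median_test_rows, resultant_length_rows, wrap_angle
from .config import AnalysisConfig
from .errors import ConfigError
from .plv import TFPhaseSet

__all__ = [
    "BinContrast",
    "BandCall",
    "bin_condition_test",
    "band_rule",
    "significance_ratio_map",
    "proportion_timecourse",
]


@dataclass
class BinContrast:
    """Signed per-bin condition contrast for one seed-target pair.

    ``sign`` is +1 where omission PLV exceeds presentation PLV and the
    common-median test is significant at ``alpha`` (uncorrected), -1 in
    the opposite direction, 0 otherwise.
    """

    seed_id: str
    target_id: str
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    p: np.ndarray  # freq x time
    sign: np.ndarray  # int8 freq x time
    plv_tone: np.ndarray
    plv_omission: np.ndarray
    alpha: float
    n_trials_per_condition: int

    def to_frame(self) -> pd.DataFrame:
        ff, tt = np.meshgrid(self.freqs_hz, self.times_ms, indexing="ij")
        return pd.DataFrame(
            {
                "seed": self.seed_id,
                "target": self.target_id,
                "freq_hz": ff.ravel(),
                "time_ms": tt.ravel(),
                "p": self.p.ravel(),
                "sign": self.sign.ravel(),
            }
        )


@dataclass
class BandCall:
    """Band-level significance time course for one pair and band."""

    seed_id: str
    target_id: str
    band: str
    times_ms: np.ndarray
    significant: np.ndarray  # bool per time point
    direction: np.ndarray  # int8 per time point; 0 when not significant

    @property
    def signed(self) -> np.ndarray:
        """Signed indicator: direction where significant, else 0."""
        return np.where(self.significant, self.direction, 0).astype(np.int8)


def bin_condition_test(
    seed: TFPhaseSet, target: TFPhaseSet, alpha: float = 0.05
) -> BinContrast:
    """Common-median test of the two conditions' phase differences at
    every (frequency, time) bin, with PLV-difference signs.

    Trial counts must be equated between conditions upstream.  P values
    are uncorrected, matching a per-bin contrast-map convention.
    """
    if not np.array_equal(seed.event_index, target.event_index):
        raise ValueError("seed and target phase sets cover different trials")
    dphi = {
        cond: wrap_angle(
            seed.condition_phase(cond).astype(np.float64)
            - target.condition_phase(cond).astype(np.float64)
        )
        for cond in ("tone", "omission")
    }
    n_tone = dphi["tone"].shape[0]
    n_omis = dphi["omission"].shape[0]
    if n_tone != n_omis:
        raise ValueError(
            f"conditions not equated: {n_tone} tone vs {n_omis} omission trials"
        )
    F, T = seed.freqs_hz.size, seed.times_ms.size

    def rows(x: np.ndarray) -> np.ndarray:
        # trials x F x T  ->  (F*T) x trials
        return np.ascontiguousarray(
            x.transpose(1, 2, 0).reshape(F * T, x.shape[0])
        )

    _, p = common_median_test_rows(rows(dphi["tone"]), rows(dphi["omission"]))
    p = p.reshape(F, T)
    plv_tone = resultant_length_rows(dphi["tone"], axis=0)
    plv_omis = resultant_length_rows(dphi["omission"], axis=0)
    sign = np.sign(plv_omis - plv_tone).astype(np.int8)
    sign[p >= alpha] = 0
    return BinContrast(
        seed_id=seed.channel_id,
        target_id=target.channel_id,
        freqs_hz=seed.freqs_hz,
        times_ms=seed.times_ms,
        p=p,
        sign=sign,
        plv_tone=plv_tone,
        plv_omission=plv_omis,
        alpha=alpha,
        n_trials_per_condition=n_tone,
    )


def band_rule(
    contrast: BinContrast,
    band: str,
    config: AnalysisConfig,
    fraction: float | None = None,
) -> BandCall:
    """Band-level call: at each time point the band is significant when
    *more than* ``fraction`` of its frequency bins carry a significant
    contrast; the direction is the majority sign among those bins, and
    an exact tie withdraws the call."""
    if fraction is None:
        fraction = config.band_rule_fraction
    sel = config.band_mask(band, contrast.freqs_hz)
    n_bins = int(sel.sum())
    if n_bins == 0:
        raise ConfigError(f"band {band!r} covers no frequency bins")
    signs = contrast.sign[sel]  # bins x time
    n_pos = np.sum(signs > 0, axis=0)
    n_neg = np.sum(signs < 0, axis=0)
    n_sig = n_pos + n_neg
    significant = n_sig / n_bins > fraction
    direction = np.sign(n_pos.astype(int) - n_neg.astype(int)).astype(np.int8)
    significant &= direction != 0  # tied directions are not called
    direction = np.where(significant, direction, 0).astype(np.int8)
    return BandCall(
        seed_id=contrast.seed_id,
        target_id=contrast.target_id,
        band=band,
        times_ms=contrast.times_ms,
        significant=significant,
        direction=direction,
    )


def significance_ratio_map(contrasts: Sequence[BinContrast]) -> np.ndarray:
    """Signed ratio (count of +1 minus count of -1, over the number of
    contrasts) per (frequency, time) bin, pooled over electrode pairs."""
    if not contrasts:
        raise ValueError("need at least one contrast")
    signs = np.stack([c.sign for c in contrasts])
    return (np.sum(signs > 0, axis=0) - np.sum(signs < 0, axis=0)) / len(contrasts)


def proportion_timecourse(
    band_calls: Sequence[BandCall],
    target_regions: Mapping[str, str],
    window_ms: float = 10.0,
) -> pd.DataFrame:
    """Signed proportion of significant electrodes per (region, band),
    averaged within half-open time windows of ``window_ms``.

    ``target_regions`` maps target channel id to its region.  Each
    electrode contributes its signed indicator (+1/-1/0) at every time
    point; the value is the mean over the region's electrodes and the
    window's time points, so it lies in [-1, 1].
    """
    if not band_calls:
        raise ValueError("need at least one band call")
    times = band_calls[0].times_ms
    t0 = times[0]
    win_of = ((times - t0) // window_ms).astype(int)
    win_starts = t0 + window_ms * np.unique(win_of)

    rows = []
    keys = sorted({(target_regions[bc.target_id], bc.band) for bc in band_calls})
    for region, band in keys:
        members = [
            bc.signed
            for bc in band_calls
            if bc.band == band and target_regions[bc.target_id] == region
        ]
        stack = np.stack(members).astype(float)  # electrodes x time
        per_time = stack.mean(axis=0)
        for w, start in zip(np.unique(win_of), win_starts):
            rows.append(
                {
                    "region": region,
                    "band": band,
                    "window_start_ms": float(start),
                    "value": float(per_time[win_of == w].mean()),
                }
            )
    return pd.DataFrame(rows)
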