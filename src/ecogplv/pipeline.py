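"""Session-level orchestration: ERP, PLV and contrast runs with file output.

The functions here chain the stage modules in the documented order:

* ERP path: band-pass -> epoch -> artifact rejection -> trial equating
  -> region ERPs with pointwise statistics.
* PLV path: connector re-referencing -> notch -> wavelet phase on the
  continuous signal -> epoch-aligned phase sets for the equated trial
  set -> seed-to-frontal PLV maps, per-bin condition contrasts, band
  calls, ratio maps and region proportion time courses.

Both paths share one artifact-rejection / equating decision per path;
the PLV path additionally restricts trials to events far enough from
the recording edges for the widest wavelet before equating, so tone and
omission always enter the contrast with exactly equal counts.

``run_all`` writes the result tables (TSV + JSON config sidecars) the
way the command-line interface exposes them.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .bundle import (
    FRONTAL_REGIONS,
    EventTable,
    RecordingBundle,
    write_bundle,
    write_table,
)
from .config import AnalysisConfig
from .contrast import (
    BandCall,
    BinContrast,
    band_rule,
    bin_condition_test,
    proportion_timecourse,
    significance_ratio_map,
)
from .erp import run_erp
from .plv import PlvMap, pairwise_plv, seed_channels, tf_phase, tf_valid_events
from .preprocess import (
    EpochSet,
    epoch,
    equate_trials,
    notch,
    reject_artifacts,
    rereference_connector,
)
from .simulate import SessionConfig, simulate_session

logger = logging.getLogger(__name__)

__all__ = [
    "PlvSessionResult",
    "prepare_plv_trials",
    "run_plv",
    "run_all",
]


@dataclass
class PlvSessionResult:
    """All PLV-path outputs of one session."""

    freqs_hz: np.ndarray
    times_ms: np.ndarray
    maps: list[PlvMap]
    contrasts: list[BinContrast]
    band_calls: list[BandCall]
    ratio_maps: dict[str, np.ndarray]  # per seed
    proportions: dict[str, pd.DataFrame]  # per seed
    n_trials_per_condition: int

    def maps_for(self, seed: str, target: str) -> dict[str, PlvMap]:
        return {
            m.condition: m
            for m in self.maps
            if m.seed_id == seed and m.target_id == target
        }

    def contrast_for(self, seed: str, target: str) -> BinContrast:
        for c in self.contrasts:
            if c.seed_id == seed and c.target_id == target:
                return c
        raise KeyError(f"no contrast for ({seed}, {target})")

    def ratio_frame(self) -> pd.DataFrame:
        rows = []
        for seed, ratio in self.ratio_maps.items():
            ff, tt = np.meshgrid(self.freqs_hz, self.times_ms, indexing="ij")
            rows.append(
                pd.DataFrame(
                    {
                        "seed": seed,
                        "freq_hz": ff.ravel(),
                        "time_ms": tt.ravel(),
                        "ratio": ratio.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def prepare_plv_trials(
    bundle: RecordingBundle,
    events: EventTable,
    config: AnalysisConfig,
    rng: np.random.Generator,
) -> tuple[RecordingBundle, EpochSet]:
    """PLV-path conditioning and trial selection.

    Returns the re-referenced + notched continuous bundle and an epoch
    set whose kept mask encodes artifact rejection, wavelet edge
    exclusion, and tone/omission equating.
    """
    conditioned = notch(rereference_connector(bundle), *config.notch_hz)
    ep = epoch(conditioned, events, config.epoch_window_ms)
    ep = reject_artifacts(ep, config.artifact_uv)
    valid = tf_valid_events(bundle, events, config)
    ep = replace(ep, kept=ep.kept & valid[ep.event_index])
    ep = equate_trials(ep, rng)
    return conditioned, ep


def run_plv(
    bundle: RecordingBundle,
    events: EventTable,
    config: AnalysisConfig,
    rng: np.random.Generator | None = None,
    seeds: list[str] | None = None,
    targets: list[str] | None = None,
    with_contrast: bool = True,
) -> PlvSessionResult:
    """Seed-to-target PLV maps and (optionally) condition contrasts.

    Defaults: seeds are the montage's flagged seed electrodes; targets
    are all channels in the frontal regions.  Target phase sets are
    computed one channel at a time to bound memory.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if seeds is None:
        seeds = seed_channels(bundle)
    if targets is None:
        targets = [
            c.channel_id for c in bundle.channels if c.region in FRONTAL_REGIONS
        ]
    if not targets:
        raise ValueError("no target channels")

    conditioned, ep = prepare_plv_trials(bundle, events, config, rng)
    kept_events = ep.event_index[ep.kept]
    n_per = kept_events.size // 2

    seed_phases = {
        s: tf_phase(conditioned, events, s, config).restrict(kept_events)
        for s in seeds
    }
    target_regions = {
        c.channel_id: c.region for c in bundle.channels if c.channel_id in targets
    }

    maps: list[PlvMap] = []
    contrasts: list[BinContrast] = []
    band_calls: list[BandCall] = []
    freqs = config.freqs_hz()
    for target in targets:
        tp = tf_phase(conditioned, events, target, config).restrict(kept_events)
        for seed_id, sp in seed_phases.items():
            if seed_id == target:
                continue
            for condition in ("tone", "omission"):
                maps.append(pairwise_plv(sp, tp, condition, config.alpha_plv))
            if with_contrast:
                c = bin_condition_test(sp, tp, config.alpha_plv)
                contrasts.append(c)
                for band in config.bands:
                    band_calls.append(band_rule(c, band, config))

    ratio_maps: dict[str, np.ndarray] = {}
    proportions: dict[str, pd.DataFrame] = {}
    if with_contrast:
        for seed_id in seed_phases:
            own = [c for c in contrasts if c.seed_id == seed_id]
            ratio_maps[seed_id] = significance_ratio_map(own)
            own_calls = [bc for bc in band_calls if bc.seed_id == seed_id]
            proportions[seed_id] = proportion_timecourse(
                own_calls, target_regions, config.window_ms
            )
    times = maps[0].times_ms if maps else np.array([])
    return PlvSessionResult(
        freqs_hz=freqs,
        times_ms=times,
        maps=maps,
        contrasts=contrasts,
        band_calls=band_calls,
        ratio_maps=ratio_maps,
        proportions=proportions,
        n_trials_per_condition=n_per,
    )


# ---------------------------------------------------------------------------
# full session run with file output

def run_all(
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    session_config: SessionConfig | None = None,
    bundle: RecordingBundle | None = None,
    events: EventTable | None = None,
    seed: int = 0,
    full_maps: bool = False,
) -> dict:
    """Simulate (unless a bundle is given), run the ERP and PLV/contrast
    pipelines, and write all result tables under ``out_dir``.

    By default the large per-pair PLV maps are summarized as band-mean
    time courses (full maps are written for one representative target
    per frontal region); pass ``full_maps=True`` to write every bin of
    every pair.  Returns a dictionary with the in-memory results and
    elapsed seconds per stage.
    """
    t_start = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or AnalysisConfig(rng_seed=seed)
    sidecar = {"seed": int(seed), "config": config.to_dict()}

    timings: dict[str, float] = {}
    if bundle is None:
        from .simulate import default_session_config

        session_config = session_config or default_session_config()
        t0 = time.perf_counter()
        bundle, events, truth = simulate_session(session_config, seed)
        timings["simulate"] = time.perf_counter() - t0
        write_bundle(bundle, out / "bundle")
        truth.to_json(out / "truth.json")
        logger.info("simulated session %s: %d channels, %d events",
                    bundle.session_id, bundle.n_channels, len(events))
    elif events is None:
        if bundle.events is None:
            raise ValueError("bundle has no events and none were given")
        events = bundle.events

    t0 = time.perf_counter()
    erp_result = run_erp(bundle, events, config,
                         np.random.default_rng([seed, 1]))
    timings["erp"] = time.perf_counter() - t0
    write_table(erp_result.to_frame(), out / "erp_result.tsv", sidecar)

    t0 = time.perf_counter()
    plv_result = run_plv(bundle, events, config,
                         np.random.default_rng([seed, 2]))
    timings["plv"] = time.perf_counter() - t0

    _write_plv_tables(plv_result, bundle, out, sidecar, full_maps)
    timings["total"] = time.perf_counter() - t_start
    with open(out / "timings.json", "w") as fh:
        json.dump(timings, fh, indent=1)
        fh.write("\n")
    logger.info("run_all finished in %.1f s", timings["total"])
    return {"erp": erp_result, "plv": plv_result, "timings": timings,
            "bundle": bundle, "events": events}


def _write_plv_tables(
    result: PlvSessionResult,
    bundle: RecordingBundle,
    out: Path,
    sidecar: dict,
    full_maps: bool,
) -> None:
    # representative full maps: first target of each frontal region per seed
    rep_targets = []
    for region in FRONTAL_REGIONS:
        ids = bundle.region_channels(region)
        if ids:
            rep_targets.append(ids[0])
    frames = []
    for m in result.maps:
        if full_maps or m.target_id in rep_targets:
            frames.append(m.to_frame())
    if frames:
        write_table(pd.concat(frames, ignore_index=True),
                    out / "plv_map.tsv", sidecar)

    # compact per-pair summaries: mean PLV and significant-bin counts
    # over frequency, per time point (band slices are available from the
    # full maps via PlvMap.band_time_course)
    summary = []
    for m in result.maps:
        summary.append(
            pd.DataFrame(
                {
                    "seed": m.seed_id,
                    "target": m.target_id,
                    "condition": m.condition,
                    "time_ms": m.times_ms,
                    "plv_mean": m.plv.mean(axis=0),
                    "n_significant_bins": m.significant.sum(axis=0),
                }
            )
        )
    write_table(pd.concat(summary, ignore_index=True),
                out / "plv_summary.tsv", sidecar)

    if result.contrasts:
        contrast_frames = [c.to_frame() for c in result.contrasts]
        write_table(pd.concat(contrast_frames, ignore_index=True),
                    out / "contrast_bins.tsv", sidecar)
        calls = []
        for bc in result.band_calls:
            calls.append(
                pd.DataFrame(
                    {
                        "seed": bc.seed_id,
                        "target": bc.target_id,
                        "band": bc.band,
                        "time_ms": bc.times_ms,
                        "significant": bc.significant,
                        "direction": bc.direction,
                    }
                )
            )
        write_table(pd.concat(calls, ignore_index=True),
                    out / "band_calls.tsv", sidecar)
        write_table(result.ratio_frame(), out / "ratio_map.tsv", sidecar)
        props = pd.concat(
            [df.assign(seed=seed) for seed, df in result.proportions.items()],
            ignore_index=True,
        )
        write_table(props, out / "proportions.tsv", sidecar)
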