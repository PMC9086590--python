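"""Analysis configuration.

All tunable analysis parameters live in one dataclass so that every
result file can carry the exact configuration that produced it.
Defaults follow common intracranial-EEG practice for an auditory
omission paradigm: 1-30 Hz ERP band-pass, -200..600 ms epochs,
+-1000 uV artifact threshold, 48-52 Hz line-noise notch, and five
canonical frequency bands from theta to gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

from .errors import ConfigError

__all__ = ["AnalysisConfig", "DEFAULT_BANDS"]

#: Canonical frequency bands (Hz); half-open [low, high) when mapped
#: onto the integer frequency grid so adjacent bands never share a bin.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "low_beta": (12.0, 25.0),
    "high_beta": (25.0, 35.0),
    "gamma": (35.0, 60.0),
}


@dataclass
class AnalysisConfig:
    """Parameters of the ERP / PLV / contrast analysis chain.

    Attributes
    ----------
    bands
        Named frequency bands in Hz, treated half-open ``[low, high)``.
    epoch_window_ms
        Half-open epoch window relative to event onset.
    erp_bandpass_hz
        Zero-phase Butterworth band-pass applied on the ERP path.
    notch_hz
        Band-stop edges removing line noise on the PLV path.
    artifact_uv
        Trials with any sample strictly exceeding this magnitude are
        rejected.
    alpha_erp
        Pointwise one-sample t-test level for ERP deviation from zero
        (FDR-adjusted over time points).
    alpha_plv
        Level for Rayleigh significance of PLV maps (FDR-adjusted over
        map bins) and for per-bin condition contrasts (uncorrected).
    band_rule_fraction
        A band/time point is called significant when *more than* this
        fraction of the band's frequency bins carry a significant
        contrast.
    window_ms
        Width of the time windows over which electrode proportions are
        averaged in the region time courses.
    freq_lo_hz, freq_hi_hz, freq_step_hz
        Inclusive frequency grid for time-frequency phase maps.
    n_cycles
        Morlet wavelet width (cycles), constant across frequency.
    time_step_ms
        Decimation step of the time-frequency maps.
    rng_seed
        Seed for every stochastic stage (trial equating, simulation).
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    epoch_window_ms: tuple[float, float] = (-200.0, 600.0)
    erp_bandpass_hz: tuple[float, float] = (1.0, 30.0)
    notch_hz: tuple[float, float] = (48.0, 52.0)
    artifact_uv: float = 1000.0
    alpha_erp: float = 1e-6
    alpha_plv: float = 0.05
    band_rule_fraction: float = 0.20
    window_ms: float = 10.0
    freq_lo_hz: float = 4.0
    freq_hi_hz: float = 60.0
    freq_step_hz: float = 1.0
    n_cycles: float = 5.0
    time_step_ms: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not (0 < lo < hi):
                raise ConfigError(
                    f"band {name!r}: edges must be positive and increasing, "
                    f"got ({lo}, {hi})"
                )
        if self.epoch_window_ms[0] >= self.epoch_window_ms[1]:
            raise ConfigError("epoch window must be increasing")
        for nm in ("erp_bandpass_hz", "notch_hz"):
            lo, hi = getattr(self, nm)
            if not (0 < lo < hi):
                raise ConfigError(f"{nm}: edges must be positive and increasing")
        if not (0 < self.band_rule_fraction < 1):
            raise ConfigError("band_rule_fraction must be in (0, 1)")
        if self.artifact_uv <= 0:
            raise ConfigError("artifact threshold must be positive")
        if not (0 < self.freq_lo_hz < self.freq_hi_hz):
            raise ConfigError("frequency grid edges must be increasing")
        if self.freq_step_hz <= 0 or self.time_step_ms <= 0:
            raise ConfigError("grid steps must be positive")
        if self.n_cycles <= 0:
            raise ConfigError("n_cycles must be positive")
        for nm in ("alpha_erp", "alpha_plv"):
            a = getattr(self, nm)
            if not (0 < a < 1):
                raise ConfigError(f"{nm} must be in (0, 1)")

    # -- frequency grid -----------------------------------------------------
    def freqs_hz(self) -> "np.ndarray":
        import numpy as np

        return np.arange(
            self.freq_lo_hz, self.freq_hi_hz + 0.5 * self.freq_step_hz,
            self.freq_step_hz,
        )

    def band_mask(self, band: str, freqs: "np.ndarray") -> "np.ndarray":
        """Boolean mask of grid frequencies in half-open band [lo, hi)."""
        lo, hi = self.bands[band]
        return (freqs >= lo) & (freqs < hi)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = {k: tuple(v) for k, v in d["bands"].items()}
        for key in ("epoch_window_ms", "erp_bandpass_hz", "notch_hz"):
            if key in d:
                d[key] = tuple(d[key])
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
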