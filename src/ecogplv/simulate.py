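"""Synthetic ECoG session generator.

Builds recording bundles with the statistical structure the downstream
analysis assumes, so that every stage of the pipeline can be verified
against known injected effects:

* a tone schedule at a fixed stimulus-onset asynchrony with a fraction
  of slots replaced by omissions (exact-count or Bernoulli placement);
* per-channel 1/f background noise with a mains-line sinusoid;
* region- and condition-specific event-related potential templates
  (sums of Gaussian bumps);
* event-locked inter-channel phase coupling: a raised-cosine tone burst
  with a common random phase per event added to a seed channel and, with
  von Mises phase jitter, to one or more target channels.

The coupling concentration ``kappa`` is defined on the *seed-target
phase difference*: the seed carries the event's reference phase and each
target is jittered by an independent vonMises(0, kappa) draw, so the
population phase-locking value at the injected bin is I1(kappa)/I0(kappa).

Everything is deterministic given ``(seed, session_id)``, and a
:class:`SimulationTruth` record is sufficient to regenerate a session
exactly.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .bundle import (
    REGIONS,
    ChannelInfo,
    EventTable,
    RecordingBundle,
)
from .circstats import KAPPA_INF
from .errors import ConfigError

__all__ = [
    "ScheduleSpec",
    "NoiseSpec",
    "ErpTemplateSpec",
    "CouplingSpec",
    "SessionConfig",
    "SimulationTruth",
    "make_schedule",
    "gen_background",
    "inject_erp",
    "inject_coupling",
    "simulate_session",
    "default_session_config",
    "reduced_session_config",
]


# ---------------------------------------------------------------------------
# specs

@dataclass
class ScheduleSpec:
    """Tone/omission slot schedule.

    ``exact_count`` places ``round(n_slots * p_omit)`` omissions
    uniformly at random without adjacency constraints; ``bernoulli``
    draws each slot independently.
    """

    n_slots: int = 1000
    soa_ms: float = 500.0
    p_omit: float = 0.10
    mode: str = "exact_count"

    def __post_init__(self) -> None:
        if self.n_slots < 1:
            raise ConfigError("n_slots must be >= 1")
        if not (0.0 <= self.p_omit <= 1.0):
            raise ConfigError("p_omit must be a probability")
        if self.mode not in ("exact_count", "bernoulli"):
            raise ConfigError(f"unknown schedule mode {self.mode!r}")
        if self.soa_ms <= 0:
            raise ConfigError("soa_ms must be positive")


@dataclass
class NoiseSpec:
    """Background noise: 1/f^exponent spectrum scaled to a target rms,
    plus a mains-line sinusoid."""

    one_over_f_exponent: float = 1.0
    rms_uv: float = 20.0
    line_hz: float = 50.0
    line_amp_uv: float = 2.0

    def __post_init__(self) -> None:
        if self.one_over_f_exponent < 0:
            raise ConfigError("1/f exponent must be >= 0")
        if not np.isfinite(self.rms_uv) or self.rms_uv <= 0:
            raise ConfigError("rms_uv must be positive and finite")
        if self.line_amp_uv < 0:
            raise ConfigError("line_amp_uv must be >= 0")


@dataclass
class ErpTemplateSpec:
    """Evoked-response template: Gaussian bumps added to every channel
    of one region at matching events.

    ``components`` is a list of ``(latency_ms, width_ms, amplitude_uv)``;
    each contributes ``amp * exp(-(t - latency)^2 / (2 width^2))``.
    """

    region: str
    condition: str  # tone | omission | both
    components: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ConfigError(f"unknown region {self.region!r}")
        if self.condition not in ("tone", "omission", "both"):
            raise ConfigError(f"unknown condition {self.condition!r}")
        for lat, width, amp in self.components:
            if width <= 0:
                raise ConfigError("component widths must be positive")


@dataclass
class CouplingSpec:
    """Event-locked phase coupling between a seed and a target channel.

    At each matching event a common phase ``phi ~ U(0, 2pi)`` is drawn
    and a raised-cosine (Hann) windowed tone burst
    ``amplitude * w(t) * cos(2 pi f (t - t_a) + phi [+ delta])``
    is added to the seed (``delta = 0``) and to the target
    (``delta ~ vonMises(0, kappa)`` independently per event).
    ``kappa >= 1e6`` encodes perfect locking (``delta = 0``).
    """

    seed_channel: str
    target_channel: str
    condition: str  # tone | omission | both
    center_freq_hz: float
    window_ms: tuple[float, float]
    kappa: float
    amplitude_uv: float
    n_cycles: float | None = None  # informational: cycles within the window

    def __post_init__(self) -> None:
        if self.condition not in ("tone", "omission", "both"):
            raise ConfigError(f"unknown condition {self.condition!r}")
        if not (4.0 <= self.center_freq_hz <= 60.0):
            raise ConfigError("center frequency must lie within [4, 60] Hz")
        a, b = self.window_ms
        if not (a < b):
            raise ConfigError("coupling window must be increasing")
        if self.kappa < 0:
            raise ConfigError("kappa must be >= 0")
        if self.amplitude_uv < 0:
            raise ConfigError("amplitude must be >= 0")
        if self.n_cycles is None:
            self.n_cycles = self.center_freq_hz * (b - a) / 1000.0

    def _group_key(self) -> tuple:
        return (
            self.seed_channel,
            self.condition,
            self.center_freq_hz,
            self.window_ms,
            self.amplitude_uv,
        )


@dataclass
class SessionConfig:
    """Full description of one synthetic session."""

    fs_hz: float = 1000.0
    channels_per_region: int = 16
    regions: tuple[str, ...] = (
        "posterior_temporal",
        "anterior_temporal",
        "frontal_pole",
        "vlpfc",
        "ofc",
    )
    seed_channels: tuple[str, ...] = ("at08", "pt08")
    schedule: ScheduleSpec = field(default_factory=ScheduleSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    templates: list[ErpTemplateSpec] = field(default_factory=list)
    couplings: list[CouplingSpec] = field(default_factory=list)
    lead_pad_ms: float = 1000.0
    tail_pad_ms: float = 1100.0
    session_id: str = "sim"
    epoch_window_ms: tuple[float, float] = (-200.0, 600.0)
    connector_size: int = 32

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ConfigError("fs_hz must be positive")
        if self.channels_per_region < 1:
            raise ConfigError("channels_per_region must be >= 1")
        if not (1 <= self.connector_size <= 32):
            raise ConfigError("connector_size must be in [1, 32]")
        for c in self.couplings:
            a, b = c.window_ms
            w0, w1 = self.epoch_window_ms
            if not (w0 <= a and b <= w1):
                raise ConfigError(
                    f"coupling window {c.window_ms} outside epoch window "
                    f"{self.epoch_window_ms}"
                )
        if self.lead_pad_ms < -min(0.0, self.epoch_window_ms[0]):
            raise ConfigError("lead padding shorter than the pre-event window")

    # -- montage ------------------------------------------------------------
    _REGION_CODES = {
        "posterior_temporal": "pt",
        "anterior_temporal": "at",
        "frontal_pole": "fp",
        "vlpfc": "vl",
        "ofc": "of",
        "other": "ox",
    }

    def montage(self) -> list[ChannelInfo]:
        """Channels in region order; 32-channel connector groups assembled
        in channel order; seed flags from ``seed_channels``."""
        chans: list[ChannelInfo] = []
        idx = 0
        for region in self.regions:
            code = self._REGION_CODES[region]
            for k in range(self.channels_per_region):
                cid = f"{code}{k:02d}"
                chans.append(
                    ChannelInfo(
                        channel_id=cid,
                        region=region,
                        connector_group=idx // self.connector_size,
                        is_seed=cid in self.seed_channels,
                    )
                )
                idx += 1
        return chans

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        d["schedule"] = ScheduleSpec(**d.get("schedule", {}))
        d["noise"] = NoiseSpec(**d.get("noise", {}))
        d["templates"] = [
            ErpTemplateSpec(
                region=t["region"],
                condition=t["condition"],
                components=[tuple(c) for c in t["components"]],
            )
            for t in d.get("templates", [])
        ]
        d["couplings"] = [
            CouplingSpec(
                seed_channel=c["seed_channel"],
                target_channel=c["target_channel"],
                condition=c["condition"],
                center_freq_hz=c["center_freq_hz"],
                window_ms=tuple(c["window_ms"]),
                kappa=c["kappa"],
                amplitude_uv=c["amplitude_uv"],
                n_cycles=c.get("n_cycles"),
            )
            for c in d.get("couplings", [])
        ]
        for key in ("regions", "seed_channels", "epoch_window_ms"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimulationTruth:
    """Ground-truth record sufficient to regenerate a session exactly."""

    config: SessionConfig
    rng_seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"rng_seed": self.rng_seed, "config": self.config.to_dict()},
                fh,
                indent=1,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(config=SessionConfig.from_dict(d["config"]), rng_seed=d["rng_seed"])

    def replay(self) -> tuple[RecordingBundle, EventTable, "SimulationTruth"]:
        return simulate_session(self.config, self.rng_seed)


# ---------------------------------------------------------------------------
# operations

def make_schedule(spec: ScheduleSpec, rng: np.random.Generator) -> EventTable:
    """Slot schedule: onsets at ``k * soa_ms`` with tone/omission labels."""
    onsets = np.arange(spec.n_slots, dtype=float) * spec.soa_ms
    kinds = np.full(spec.n_slots, "tone", dtype=object)
    if spec.mode == "exact_count":
        n_omit = int(round(spec.n_slots * spec.p_omit))
        pos = rng.choice(spec.n_slots, size=n_omit, replace=False)
        kinds[pos] = "omission"
    else:  # bernoulli
        kinds[rng.random(spec.n_slots) < spec.p_omit] = "omission"
    return EventTable(onsets, kinds)


def gen_background(
    n_channels: int,
    n_samples: int,
    fs: float,
    spec: NoiseSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independent per-channel 1/f^exponent noise at the target rms,
    plus a mains-line sinusoid of the given amplitude (random phase
    per channel).  Spectral-shaping construction: white Gaussian noise
    filtered in the frequency domain by ``f**(-exponent/2)``."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    white = rng.standard_normal((n_channels, n_samples))
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-spec.one_over_f_exponent / 2.0)
    x = np.fft.irfft(spectrum * shaping, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x * x, axis=1, keepdims=True))
    x *= spec.rms_uv / rms
    if spec.line_amp_uv > 0:
        t = np.arange(n_samples) / fs
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_channels, 1))
        x += spec.line_amp_uv * np.cos(
            2.0 * np.pi * spec.line_hz * t[None, :] + phases
        )
    return x


def _template_kernel(
    template: ErpTemplateSpec, fs: float
) -> tuple[int, np.ndarray]:
    """Sampled sum of Gaussian bumps; returns (offset_samples, kernel)
    where offset is relative to the event-onset sample."""
    lo = min(lat - 5.0 * w for lat, w, _ in template.components)
    hi = max(lat + 5.0 * w for lat, w, _ in template.components)
    s0 = int(np.floor(lo * fs / 1000.0))
    s1 = int(np.ceil(hi * fs / 1000.0))
    t_ms = np.arange(s0, s1 + 1) * 1000.0 / fs
    kernel = np.zeros_like(t_ms)
    for lat, width, amp in template.components:
        kernel += amp * np.exp(-((t_ms - lat) ** 2) / (2.0 * width**2))
    return s0, kernel


def _matching_events(events: EventTable, condition: str) -> np.ndarray:
    if condition == "both":
        return np.arange(len(events))
    return np.flatnonzero(events.kinds == condition)


def inject_erp(
    signals: np.ndarray,
    fs: float,
    events: EventTable,
    templates: Sequence[ErpTemplateSpec],
    channel_regions: Sequence[str],
) -> np.ndarray:
    """Add evoked-response templates to ``signals`` in place (returned
    for convenience).  For every event whose kind matches a template's
    condition the template kernel is added, linearly, to all channels of
    the template's region."""
    channel_regions = list(channel_regions)
    n_samples = signals.shape[1]
    for template in templates:
        rows = [i for i, r in enumerate(channel_regions) if r == template.region]
        if not rows:
            raise ConfigError(
                f"template region {template.region!r} has no channels"
            )
        if not template.components:
            continue
        s0, kernel = _template_kernel(template, fs)
        onset_idx = np.round(
            events.onsets_ms[_matching_events(events, template.condition)]
            * fs / 1000.0
        ).astype(int)
        trace = np.zeros(n_samples)
        for oi in onset_idx:
            a = oi + s0
            b = a + kernel.size
            ka, kb = max(0, -a), kernel.size - max(0, b - n_samples)
            if ka < kb:
                trace[max(0, a): min(b, n_samples)] += kernel[ka:kb]
        signals[rows, :] += trace[None, :]
    return signals


def inject_coupling(
    signals: np.ndarray,
    fs: float,
    events: EventTable,
    specs: CouplingSpec | Sequence[CouplingSpec],
    rng: np.random.Generator,
    channel_ids: Sequence[str],
    phase_log: list | None = None,
) -> np.ndarray:
    """Add event-locked phase coupling in place (returned for
    convenience).

    A single spec couples one seed-target pair.  A *list* of specs that
    share seed, condition, frequency, window and amplitude couples one
    seed to several targets with a common per-event phase: the seed
    receives each event's burst once and every target receives a copy
    jittered by its own vonMises(0, kappa) draw.  (Passing unrelated
    specs in one call is an error; call once per spec instead.)
    """
    if isinstance(specs, CouplingSpec):
        specs = [specs]
    specs = list(specs)
    if not specs:
        return signals
    key = specs[0]._group_key()
    if any(s._group_key() != key for s in specs):
        raise ConfigError(
            "grouped coupling specs must share seed, condition, frequency, "
            "window and amplitude"
        )
    ids = list(channel_ids)
    try:
        seed_row = ids.index(specs[0].seed_channel)
        target_rows = [ids.index(s.target_channel) for s in specs]
    except ValueError as exc:
        raise ConfigError(f"coupling channel not in bundle: {exc}") from exc

    a_ms, b_ms = specs[0].window_ms
    f = specs[0].center_freq_hz
    amp = specs[0].amplitude_uv
    s0 = int(round(a_ms * fs / 1000.0))
    n_win = int(round((b_ms - a_ms) * fs / 1000.0))
    if n_win < 1:
        raise ConfigError("coupling window shorter than one sample")
    tt = np.arange(n_win) / fs  # time from window start, seconds
    envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * (np.arange(n_win) + 0.5) / n_win))
    carrier = 2.0 * np.pi * f * tt

    onset_idx = np.round(
        events.onsets_ms[_matching_events(events, specs[0].condition)]
        * fs / 1000.0
    ).astype(int)
    n_samples = signals.shape[1]
    for oi in onset_idx:
        phi = rng.uniform(0.0, 2.0 * np.pi)
        a = oi + s0
        b = a + n_win
        if a < 0 or b > n_samples:
            continue  # burst would fall off the recording
        signals[seed_row, a:b] += amp * envelope * np.cos(carrier + phi)
        deltas = {}
        for s, row in zip(specs, target_rows):
            delta = 0.0 if s.kappa >= KAPPA_INF else rng.vonmises(0.0, s.kappa)
            signals[row, a:b] += amp * envelope * np.cos(carrier + phi + delta)
            deltas[s.target_channel] = float(delta)
        if phase_log is not None:
            phase_log.append(
                {"onset_idx": int(oi), "phi": float(phi), "deltas": deltas}
            )
    return signals


def _session_rng(seed: int, session_id: str) -> np.random.Generator:
    """One stream per session, keyed by (seed, session_id)."""
    return np.random.default_rng([int(seed), zlib.crc32(session_id.encode())])


def simulate_session(
    config: SessionConfig, seed: int
) -> tuple[RecordingBundle, EventTable, SimulationTruth]:
    """Generate a full synthetic session.

    Returns the recording bundle (events attached), the event table
    (onsets shifted by the lead padding so every epoch fits inside the
    recording), and the ground-truth record.
    """
    rng = _session_rng(seed, config.session_id)
    fs = config.fs_hz
    schedule = make_schedule(config.schedule, rng)
    events = EventTable(schedule.onsets_ms + config.lead_pad_ms, schedule.kinds)

    total_ms = (
        config.lead_pad_ms
        + config.schedule.n_slots * config.schedule.soa_ms
        + config.tail_pad_ms
    )
    n_samples = int(round(total_ms * fs / 1000.0))
    channels = config.montage()
    signals = gen_background(len(channels), n_samples, fs, config.noise, rng)

    regions = [c.region for c in channels]
    inject_erp(signals, fs, events, config.templates, regions)

    ids = [c.channel_id for c in channels]
    for group in _group_couplings(config.couplings):
        inject_coupling(signals, fs, events, group, rng, ids)

    bundle = RecordingBundle(
        signals=signals.astype(np.float32),
        fs=fs,
        channels=channels,
        session_id=config.session_id,
        events=events,
    )
    return bundle, events, SimulationTruth(config=config, rng_seed=int(seed))


def _group_couplings(
    couplings: Sequence[CouplingSpec],
) -> list[list[CouplingSpec]]:
    """Group specs sharing (seed, condition, freq, window, amplitude) so
    their targets share the per-event reference phase, preserving the
    listed order of first appearance."""
    groups: dict[tuple, list[CouplingSpec]] = {}
    for spec in couplings:
        groups.setdefault(spec._group_key(), []).append(spec)
    return list(groups.values())


# ---------------------------------------------------------------------------
# default configurations

def default_session_config(session_id: str = "sim") -> SessionConfig:
    """The default session: 80 channels (5 regions x 16), 1000 slots at
    500 ms SOA with 10% omissions, 1 kHz sampling.

    Evoked templates follow the qualitative shapes seen in auditory
    omission paradigms: sharp early tone deflections in the temporal
    cortex echoed (smaller) frontally, an early broad positive omission
    deflection in the anterior temporal cortex / frontal pole / OFC, and
    a late gradual rise in the temporal regions.  Couplings: tone-locked
    theta-to-low-beta bursts between the anterior temporal seed and the
    frontal-pole electrodes around 100 ms, and an omission-only low-beta
    burst near 200 ms; a posterior-seed omission theta burst to the
    VLPFC.  Amplitudes and noise levels are simulator conventions.
    """
    tone_early = [(20.0, 6.0, -15.0), (50.0, 10.0, 20.0), (90.0, 12.0, -12.0),
                  (250.0, 50.0, 8.0)]
    tone_frontal = [(lat, w, 0.7 * a) for lat, w, a in tone_early]
    templates = [
        ErpTemplateSpec("posterior_temporal", "tone", tone_early),
        ErpTemplateSpec("anterior_temporal", "tone", tone_frontal),
        ErpTemplateSpec("frontal_pole", "tone", tone_frontal),
        ErpTemplateSpec("vlpfc", "tone", tone_frontal),
        ErpTemplateSpec("ofc", "tone", tone_frontal),
        # early omission deflection: anterior temporal first, then frontal
        ErpTemplateSpec("anterior_temporal", "omission", [(60.0, 25.0, 8.0)]),
        ErpTemplateSpec("frontal_pole", "omission", [(80.0, 25.0, 6.0)]),
        ErpTemplateSpec("ofc", "omission", [(90.0, 25.0, 6.0)]),
        # late gradual rise in the temporal cortex
        ErpTemplateSpec("anterior_temporal", "omission", [(380.0, 90.0, 8.0)]),
        ErpTemplateSpec("posterior_temporal", "omission", [(380.0, 90.0, 8.0)]),
    ]
    fp = [f"fp{k:02d}" for k in range(16)]
    vl = [f"vl{k:02d}" for k in range(16)]
    couplings = []
    for f_hz in (6.0, 10.0, 18.0):
        couplings += [
            CouplingSpec("at08", t, "tone", f_hz, (40.0, 160.0), 4.0, 12.0)
            for t in fp
        ]
    couplings += [
        CouplingSpec("at08", t, "omission", 18.0, (180.0, 220.0), 5.0, 15.0)
        for t in fp
    ]
    couplings += [
        CouplingSpec("pt08", t, "omission", 6.0, (100.0, 200.0), 4.0, 12.0)
        for t in vl
    ]
    return SessionConfig(
        templates=templates, couplings=couplings, session_id=session_id
    )


def reduced_session_config(
    session_id: str = "mini",
    n_slots: int = 1000,
    fs_hz: float = 200.0,
    channels_per_region: int = 4,
    couplings: list[CouplingSpec] | None = None,
    templates: list[ErpTemplateSpec] | None = None,
    noise: NoiseSpec | None = None,
) -> SessionConfig:
    """Desk-scale session for Monte-Carlo studies: two regions
    (anterior temporal seed + frontal pole targets), a lower sampling
    rate, and no injected effects unless given.  The 5 ms map time step
    is one sample at 200 Hz, so time-frequency grids are unchanged."""
    return SessionConfig(
        fs_hz=fs_hz,
        channels_per_region=channels_per_region,
        regions=("anterior_temporal", "frontal_pole"),
        seed_channels=("at00",),
        schedule=ScheduleSpec(n_slots=n_slots),
        noise=noise or NoiseSpec(),
        templates=templates or [],
        couplings=couplings or [],
        session_id=session_id,
        connector_size=channels_per_region,
    )
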