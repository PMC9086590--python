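"""Recording-bundle container and on-disk format.

A *recording bundle* is the package's exchange format for a continuous
multichannel electrophysiology session: a channels x samples float32
signal matrix in microvolts, the sampling rate, per-channel montage
metadata (cortical region, headstage connector group, seed flag), and an
optional event table.  On disk a bundle is a directory holding

* ``signals.f32`` -- raw little-endian float32, row-major channels x samples
* ``meta.json``   -- sampling rate, shape declaration, channel metadata
* ``events.tsv``  -- tab-separated ``onset_ms``/``kind`` table (optional)

The format is deliberately minimal so that a round trip through
:func:`write_bundle` / :func:`read_bundle` is bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

__all__ = [
    "REGIONS",
    "EVENT_KINDS",
    "ChannelInfo",
    "RecordingBundle",
    "EventTable",
    "read_bundle",
    "write_bundle",
    "read_events",
    "write_events",
]

#: Closed set of montage region labels.
REGIONS = (
    "posterior_temporal",
    "anterior_temporal",
    "frontal_pole",
    "vlpfc",
    "ofc",
    "other",
)

#: Regions counted as "frontal" targets for seed-to-frontal connectivity.
FRONTAL_REGIONS = ("frontal_pole", "vlpfc", "ofc")

EVENT_KINDS = ("tone", "omission")

#: Maximum number of channels sharing one headstage connector.
MAX_CONNECTOR_SIZE = 32


@dataclass(frozen=True)
class ChannelInfo:
    """Montage metadata for one electrode."""

    channel_id: str
    region: str
    connector_group: int
    is_seed: bool = False

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise IntegrityError(
                f"unknown region {self.region!r}; expected one of {REGIONS}"
            )
        if self.connector_group < 0:
            raise IntegrityError("connector_group must be >= 0")


@dataclass
class EventTable:
    """Ordered event onsets with condition labels.

    Onsets are in milliseconds from the start of the recording and must
    be strictly increasing; each kind is ``"tone"`` or ``"omission"``.
    """

    onsets_ms: np.ndarray
    kinds: np.ndarray

    def __post_init__(self) -> None:
        self.onsets_ms = np.asarray(self.onsets_ms, dtype=float)
        self.kinds = np.asarray(self.kinds, dtype=object)
        if self.onsets_ms.shape != self.kinds.shape:
            raise IntegrityError("onsets and kinds must have equal length")
        if self.onsets_ms.size and self.onsets_ms.min() < 0:
            raise IntegrityError("event onsets must be non-negative")
        if np.any(np.diff(self.onsets_ms) <= 0):
            raise IntegrityError("event onsets must be strictly increasing")
        bad = set(self.kinds) - set(EVENT_KINDS)
        if bad:
            raise FormatError(f"unknown event kind(s): {sorted(bad)}")

    def __len__(self) -> int:
        return self.onsets_ms.size

    def counts(self) -> dict[str, int]:
        return {k: int(np.sum(self.kinds == k)) for k in EVENT_KINDS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"onset_ms": self.onsets_ms, "kind": self.kinds})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventTable":
        return cls(df["onset_ms"].to_numpy(float), df["kind"].to_numpy(object))


@dataclass
class RecordingBundle:
    """Continuous multichannel recording plus montage metadata.

    ``signals`` is channels x samples in microvolts (float32); ``fs`` is
    the sampling rate in Hz.
    """

    signals: np.ndarray
    fs: float
    channels: Sequence[ChannelInfo]
    session_id: str = "session"
    events: EventTable | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float32)
        if self.signals.ndim != 2:
            raise IntegrityError("signals must be a 2-D channels x samples array")
        if self.fs <= 0:
            raise IntegrityError("sampling rate must be positive")
        if len(self.channels) != self.signals.shape[0]:
            raise IntegrityError(
                f"{len(self.channels)} channel records for "
                f"{self.signals.shape[0]} signal rows"
            )
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise IntegrityError("channel ids must be unique")
        groups: dict[int, int] = {}
        for c in self.channels:
            groups[c.connector_group] = groups.get(c.connector_group, 0) + 1
        too_big = {g: n for g, n in groups.items() if n > MAX_CONNECTOR_SIZE}
        if too_big:
            raise IntegrityError(
                f"connector groups exceed {MAX_CONNECTOR_SIZE} members: {too_big}"
            )

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    def channel_index(self, channel_id: str) -> int:
        try:
            return self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"no channel {channel_id!r} in bundle") from None

    def region_channels(self, region: str) -> list[str]:
        return [c.channel_id for c in self.channels if c.region == region]

    def seed_channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels if c.is_seed]

    def with_signals(self, signals: np.ndarray) -> "RecordingBundle":
        """Copy of the bundle with the signal matrix replaced."""
        return replace(self, signals=np.asarray(signals, dtype=np.float32))


# ---------------------------------------------------------------------------
# on-disk format

_SIGNALS = "signals.f32"
_META = "meta.json"
_EVENTS = "events.tsv"


def write_bundle(bundle: RecordingBundle, path: str | Path) -> None:
    """Write a bundle directory (``signals.f32`` + ``meta.json`` [+ events])."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sig = np.ascontiguousarray(bundle.signals, dtype="<f4")
    sig.tofile(path / _SIGNALS)
    meta = {
        "fs_hz": bundle.fs,
        "n_channels": bundle.n_channels,
        "n_samples": bundle.n_samples,
        "session_id": bundle.session_id,
        "channels": [
            {
                "channel_id": c.channel_id,
                "region": c.region,
                "connector_group": c.connector_group,
                "is_seed": c.is_seed,
            }
            for c in bundle.channels
        ],
    }
    with open(path / _META, "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")
    if bundle.events is not None:
        write_events(bundle.events, path / _EVENTS)


def read_bundle(path: str | Path) -> RecordingBundle:
    """Read a bundle directory written by :func:`write_bundle`."""
    path = Path(path)
    meta_path = path / _META
    sig_path = path / _SIGNALS
    for p in (meta_path, sig_path):
        if not p.exists():
            raise FormatError(f"missing bundle file: {p}")
    with open(meta_path) as fh:
        try:
            meta = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"invalid meta.json: {exc}") from exc
    try:
        n_ch, n_s = int(meta["n_channels"]), int(meta["n_samples"])
        fs = float(meta["fs_hz"])
        channels = [
            ChannelInfo(
                channel_id=str(c["channel_id"]),
                region=str(c["region"]),
                connector_group=int(c["connector_group"]),
                is_seed=bool(c.get("is_seed", False)),
            )
            for c in meta["channels"]
        ]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"meta.json missing required key: {exc}") from exc
    raw = np.fromfile(sig_path, dtype="<f4")
    if raw.size != n_ch * n_s:
        raise IntegrityError(
            f"signals.f32 holds {raw.size} values but meta.json declares "
            f"{n_ch} x {n_s} = {n_ch * n_s}"
        )
    events = None
    if (path / _EVENTS).exists():
        events = read_events(path / _EVENTS)
    return RecordingBundle(
        signals=raw.reshape(n_ch, n_s),
        fs=fs,
        channels=channels,
        session_id=str(meta.get("session_id", path.name)),
        events=events,
    )


def write_events(events: EventTable, path: str | Path) -> None:
    events.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_events(path: str | Path) -> EventTable:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing events file: {path}")
    df = pd.read_csv(path, sep="\t")
    if not {"onset_ms", "kind"} <= set(df.columns):
        raise FormatError("events.tsv must have columns onset_ms and kind")
    return EventTable.from_frame(df)


def write_table(df: pd.DataFrame, path: str | Path, sidecar: dict | None = None) -> None:
    """Write a long-format result TSV with an optional JSON config sidecar.

    The sidecar (same stem, ``.json`` suffix) records the configuration and
    seed that produced the table so every result file is reproducible.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    if sidecar is not None:
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1, default=_json_default)
            fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
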