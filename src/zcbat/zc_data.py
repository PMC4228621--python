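"""Data model and I/O for zero-crossing bat recordings.

Zero-crossing (frequency-division) bat detectors emit one time-frequency
point ("dot") per N cycles of the incoming signal and record no amplitude.
A run of dots produced by a single emission of ultrasonic sound is a pulse;
a series of pulses with interpulse intervals below one second is a pulse
sequence, the unit at which species labels are attached.

This module defines the dot/pulse/sequence/library containers, the ZC-CSV
interchange format (``file_id,time_us,freq_hz``), the JSON library manifest,
dot-to-pulse segmentation, and sequence assembly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES_CODES",
    "ZC_COLUMNS",
    "ZcParseError",
    "SegmentationConfig",
    "Pulse",
    "PulseSequence",
    "CallLibrary",
    "read_zc_csv",
    "write_zc_csv",
    "segment_pulses",
    "assemble_sequences",
    "load_manifest",
    "save_manifest",
]

#: Four-letter codes of the eleven eastern North American species in scope,
#: in fixed order (used for deterministic tie-breaking downstream).
SPECIES_CODES: tuple[str, ...] = (
    "EPFU", "LABO", "LACI", "LANO", "MYGR", "MYLE",
    "MYLU", "MYSE", "MYSO", "NYHU", "PESU",
)

ZC_COLUMNS: tuple[str, str, str] = ("file_id", "time_us", "freq_hz")

#: Default interpulse-interval bound (seconds) defining a pulse sequence.
MAX_INTERPULSE_S: float = 1.0


class ZcParseError(ValueError):
    """Raised for malformed ZC-CSV content, naming the offending line."""


@dataclass(frozen=True)
class SegmentationConfig:
    """How raw dots are grouped into pulses.

    Parameters
    ----------
    max_dot_gap_us
        Inter-dot gap (microseconds) above which a dot run is split into
        fragments.  1000 us is at least five times the inter-dot period of a
        40 kHz signal at division ratio 8, robust for the species in scope.
    join_fragments_us
        Fragments whose gap to the next fragment is below this are merged
        (applied before ``ignore_fragments_us``).  ``None`` disables.
    ignore_fragments_us
        Fragments shorter than this duration are discarded.  ``None``
        disables.
    """

    max_dot_gap_us: int = 1000
    join_fragments_us: int | None = None
    ignore_fragments_us: int | None = None

    def __post_init__(self) -> None:
        if self.max_dot_gap_us <= 0:
            raise ValueError("max_dot_gap_us must be positive")
        for name in ("join_fragments_us", "ignore_fragments_us"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive if given")


@dataclass(frozen=True)
class Pulse:
    """One emission of ultrasonic sound: an ordered run of >=2 dots."""

    file_id: str
    t_us: np.ndarray  # int64, strictly increasing
    f_hz: np.ndarray  # positive floats

    def __post_init__(self) -> None:
        t = np.asarray(self.t_us, dtype=np.int64)
        f = np.asarray(self.f_hz, dtype=float)
        object.__setattr__(self, "t_us", t)
        object.__setattr__(self, "f_hz", f)
        if t.size < 2:
            raise ValueError("a pulse requires at least two dots")
        if t.size != f.size:
            raise ValueError("time and frequency arrays differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("dot times must be strictly increasing")
        if np.any(f <= 0):
            raise ValueError("dot frequencies must be positive")

    @property
    def n_dots(self) -> int:
        return int(self.t_us.size)

    @property
    def start_us(self) -> int:
        return int(self.t_us[0])

    @property
    def end_us(self) -> int:
        return int(self.t_us[-1])

    @property
    def duration_us(self) -> int:
        return self.end_us - self.start_us

    @property
    def key(self) -> tuple[str, int, int]:
        """Identity used for cross-filter pulse comparison."""
        return (self.file_id, self.start_us, self.end_us)


@dataclass(frozen=True)
class PulseSequence:
    """Time-ordered pulses from one file with interpulse gaps < 1 s."""

    pulses: tuple[Pulse, ...]
    file_id: str
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.pulses:
            raise ValueError("a pulse sequence requires at least one pulse")
        for a, b in zip(self.pulses, self.pulses[1:]):
            if b.start_us < a.end_us:
                raise ValueError("pulses overlap in time")

    @property
    def n_pulses(self) -> int:
        return len(self.pulses)

    @property
    def start_us(self) -> int:
        return self.pulses[0].start_us


@dataclass
class CallLibrary:
    """A named collection of recording files with optional species labels.

    The library is raw-dot backed: each file maps to its full dot record so
    that filters can re-segment it with their own join/ignore settings.  A
    noise library carries no species labels (all ``None``).
    """

    name: str
    files: dict[str, tuple[np.ndarray, np.ndarray]]  # file_id -> (t_us, f_hz)
    labels: dict[str, str | None] = field(default_factory=dict)
    species_set: tuple[str, ...] = SPECIES_CODES

    def __post_init__(self) -> None:
        for fid, sp in self.labels.items():
            if sp is not None and sp not in self.species_set:
                raise ValueError(f"label {sp!r} for {fid!r} not in species_set")

    @property
    def file_ids(self) -> list[str]:
        return list(self.files)

    def label(self, file_id: str) -> str | None:
        return self.labels.get(file_id)

    @property
    def is_noise(self) -> bool:
        return all(v is None for v in self.labels.values())

    def segmented(self, cfg: SegmentationConfig | None = None) -> dict[str, list[Pulse]]:
        cfg = cfg or SegmentationConfig()
        return {
            fid: segment_pulses(t, f, cfg, file_id=fid)
            for fid, (t, f) in self.files.items()
        }

    def sequences(
        self,
        cfg: SegmentationConfig | None = None,
        max_interpulse_s: float = MAX_INTERPULSE_S,
    ) -> list[PulseSequence]:
        out: list[PulseSequence] = []
        for fid, pulses in self.segmented(cfg).items():
            for seq in assemble_sequences(pulses, max_interpulse_s):
                out.append(replace(seq, species=self.label(fid)))
        return out

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for fid, (t, f) in self.files.items():
            parts.append(pd.DataFrame({"file_id": fid, "time_us": t, "freq_hz": f}))
        if not parts:
            return pd.DataFrame(columns=list(ZC_COLUMNS))
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_frame(
        cls,
        dots: pd.DataFrame,
        labels: Mapping[str, str | None] | None = None,
        name: str = "library",
        species_set: Sequence[str] = SPECIES_CODES,
    ) -> "CallLibrary":
        files: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for fid, grp in dots.groupby("file_id", sort=False):
            order = np.argsort(grp["time_us"].to_numpy(), kind="stable")
            files[str(fid)] = (
                grp["time_us"].to_numpy(dtype=np.int64)[order],
                grp["freq_hz"].to_numpy(dtype=float)[order],
            )
        lab = {fid: (labels or {}).get(fid) for fid in files}
        return cls(name=name, files=files, labels=lab, species_set=tuple(species_set))


# ---------------------------------------------------------------------------
# ZC-CSV I/O
# ---------------------------------------------------------------------------

def read_zc_csv(path: str | Path) -> pd.DataFrame:
    """Read a ZC-CSV dot table.

    The format is UTF-8 comma-separated text with header
    ``file_id,time_us,freq_hz`` and one dot per row.  Rows are returned
    grouped by ``file_id`` (order of first appearance) and sorted by time
    within each file.  A header-only file yields an empty table.

    Raises
    ------
    ZcParseError
        For a missing/incorrect header or a malformed row (non-numeric time
        or frequency, or frequency <= 0), naming the 1-based line number.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skip_blank_lines=False)
    if tuple(raw.columns) != ZC_COLUMNS:
        raise ZcParseError(
            f"{path}: expected header {','.join(ZC_COLUMNS)!r}, "
            f"got {','.join(map(str, raw.columns))!r}"
        )
    if raw.empty:
        return pd.DataFrame({c: pd.Series(dtype=d) for c, d in
                             zip(ZC_COLUMNS, (str, np.int64, float))})
    t = pd.to_numeric(raw["time_us"], errors="coerce")
    f = pd.to_numeric(raw["freq_hz"], errors="coerce")
    bad = t.isna() | f.isna() | (f <= 0)
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ZcParseError(f"{path}: malformed row at line {line}")
    out = pd.DataFrame({
        "file_id": raw["file_id"].astype(str),
        "time_us": t.astype(np.int64),
        "freq_hz": f.astype(float),
    })
    out = out.sort_values(["time_us"], kind="stable")
    order = {fid: i for i, fid in enumerate(dict.fromkeys(raw["file_id"]))}
    out["_ord"] = out["file_id"].map(order)
    out = out.sort_values(["_ord"], kind="stable").drop(columns="_ord")
    return out.reset_index(drop=True)


def write_zc_csv(dots: pd.DataFrame, path: str | Path) -> None:
    """Write a dot table to ZC-CSV (inverse of :func:`read_zc_csv`)."""
    dots.loc[:, list(ZC_COLUMNS)].to_csv(path, index=False)


def save_manifest(library: CallLibrary, path: str | Path) -> None:
    """Write the JSON manifest: library name plus file_id -> species label."""
    payload = {"name": library.name, "labels": dict(library.labels),
               "species_set": list(library.species_set)}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_manifest(path: str | Path) -> tuple[str, dict[str, str | None], tuple[str, ...]]:
    payload = json.loads(Path(path).read_text())
    return (
        payload.get("name", "library"),
        {k: v for k, v in payload.get("labels", {}).items()},
        tuple(payload.get("species_set", SPECIES_CODES)),
    )


def load_library(csv_path: str | Path, manifest_path: str | Path | None = None) -> CallLibrary:
    """Read a ZC-CSV dot table plus optional manifest into a CallLibrary."""
    dots = read_zc_csv(csv_path)
    if manifest_path is None:
        return CallLibrary.from_frame(dots, name=Path(csv_path).stem)
    name, labels, species_set = load_manifest(manifest_path)
    return CallLibrary.from_frame(dots, labels=labels, name=name, species_set=species_set)


# ---------------------------------------------------------------------------
# Segmentation and sequence assembly
# ---------------------------------------------------------------------------

def segment_pulses(
    t_us: np.ndarray,
    f_hz: np.ndarray,
    cfg: SegmentationConfig | None = None,
    file_id: str = "",
) -> list[Pulse]:
    """Group a file's time-sorted dots into pulses.

    Dot runs are split wherever the inter-dot gap exceeds
    ``cfg.max_dot_gap_us``, yielding fragments.  Fragments whose gap to the
    next fragment is below ``cfg.join_fragments_us`` are then merged (join is
    applied before ignore, so fragments that together form a valid pulse are
    not discarded piecemeal), and remaining fragments shorter than
    ``cfg.ignore_fragments_us`` are dropped.  Fragments reduced to a single
    dot carry no duration or frequency-change information and are always
    dropped.

    Raises ``ValueError`` on unsorted input; empty input yields ``[]``.
    """
    cfg = cfg or SegmentationConfig()
    t = np.asarray(t_us, dtype=np.int64)
    f = np.asarray(f_hz, dtype=float)
    if t.size == 0:
        return []
    if np.any(np.diff(t) < 0):
        raise ValueError("dots must be time-sorted within a file")

    gaps = np.diff(t)
    cut = np.flatnonzero(gaps > cfg.max_dot_gap_us) + 1
    bounds = [(int(a), int(b)) for a, b in
              zip(np.r_[0, cut], np.r_[cut, t.size])]  # half-open dot spans

    if cfg.join_fragments_us is not None:
        merged: list[tuple[int, int]] = []
        for span in bounds:
            if merged and t[span[0]] - t[merged[-1][1] - 1] < cfg.join_fragments_us:
                merged[-1] = (merged[-1][0], span[1])
            else:
                merged.append(span)
        bounds = merged

    pulses: list[Pulse] = []
    for a, b in bounds:
        if b - a < 2:
            continue
        dur = int(t[b - 1] - t[a])
        if cfg.ignore_fragments_us is not None and dur < cfg.ignore_fragments_us:
            continue
        pulses.append(Pulse(file_id=file_id, t_us=t[a:b], f_hz=f[a:b]))
    return pulses


def assemble_sequences(
    pulses: Iterable[Pulse],
    max_interpulse_s: float = MAX_INTERPULSE_S,
) -> list[PulseSequence]:
    """Partition time-ordered pulses into sequences.

    Consecutive pulses whose start-to-start gap is below ``max_interpulse_s``
    belong to the same sequence; a gap at or above the bound starts a new
    one.  The interpulse interval is measured between pulse onsets, the
    conventional definition of pulse period.
    """
    pulses = list(pulses)
    if not pulses:
        return []
    max_gap_us = max_interpulse_s * 1e6
    groups: list[list[Pulse]] = [[pulses[0]]]
    for prev, cur in zip(pulses, pulses[1:]):
        if cur.start_us - prev.start_us < max_gap_us:
            groups[-1].append(cur)
        else:
            groups.append([cur])
    return [
        PulseSequence(pulses=tuple(g), file_id=g[0].file_id) for g in groups
    ]
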