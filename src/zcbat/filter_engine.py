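"""Rule-based acoustic filters for zero-crossing pulse selection.

A filter is a set of selection rules applied to a recording: pulse-level
rules (smoothness, high start, per-dot frequency-change bounds, parameter
ranges, synthetic lines) decide which pulses are acceptable, and
sequence-level rules (minimum number of calls within a time window, minimum
spacing between calls, rejection of call pairs separated by tiny gaps)
decide whether the recording is retained at all.  Four presets mirror
published and working filters (BM, BCID, WEST1, WEST2); arbitrary filters
can be loaded from YAML.

Every rule is optional: an absent setting is simply not applied, so adding
any rule to a specification can only shrink the retained set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import pulse_metrics as pm
from .zc_data import (
    MAX_INTERPULSE_S,
    CallLibrary,
    Pulse,
    SegmentationConfig,
    assemble_sequences,
    segment_pulses,
)

__all__ = [
    "Range",
    "SyntheticLineSpec",
    "FilterSpec",
    "FilterResult",
    "PRESET_NAMES",
    "load_preset",
    "load_filter_spec",
    "synthetic_line_value",
    "pulse_passes",
    "sequence_postfilter",
    "apply_filter",
    "consensus",
]

PRESET_NAMES = ("BM", "BCID", "WEST1", "WEST2")

#: Tolerance (kHz) on "the first dot attains Fmax" for the high-start rule,
#: absorbing zero-crossing quantization jitter.
HIGH_START_TOL_KHZ = 2.0


@dataclass(frozen=True)
class Range:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"range low {self.lo} exceeds high {self.hi}")

    def contains(self, x: float) -> bool:
        return self.lo <= x <= self.hi


@dataclass(frozen=True)
class SyntheticLineSpec:
    """A linear guard in a 2-D feature plane.

    The rule evaluates the vertical distance of a pulse's (x, y) feature
    point from the line through ``p1`` and ``p2`` and passes iff that
    distance lies in ``[min, max]``.
    """

    x_var: str
    y_var: str
    p1: tuple[float, float]
    p2: tuple[float, float]
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.p1[0] == self.p2[0]:
            raise ValueError("synthetic line anchors share an x coordinate")
        if self.min > self.max:
            raise ValueError("synthetic line min exceeds max")


@dataclass(frozen=True)
class FilterSpec:
    """One filter: every selection rule, all optional except Body Over."""

    name: str = "custom"
    body_over_us: float = 1000.0
    smoothness_max_pct: float | None = None
    high_start: bool = False
    max_change_up_khz: float | None = None
    max_change_down_khz: float | None = None
    ignore_fragments_us: float | None = None
    join_fragments_us: float | None = None
    reject_gap_ms: float | None = None
    fc_khz: Range | None = None
    fmax_khz: Range | None = None
    fmin_khz: Range | None = None
    sc_oct_s: Range | None = None
    s1_oct_s: Range | None = None
    sweep_khz: Range | None = None
    duration_ms: Range | None = None
    pmc_pct: Range | None = None
    min_calls: int | None = None
    time_for_calls_s: float | None = None
    min_time_between_calls_ms: float | None = None
    synthetic_lines: tuple[SyntheticLineSpec, ...] = ()
    max_dot_gap_us: int = 1000

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            max_dot_gap_us=self.max_dot_gap_us,
            join_fragments_us=(
                int(self.join_fragments_us) if self.join_fragments_us else None
            ),
            ignore_fragments_us=(
                int(self.ignore_fragments_us) if self.ignore_fragments_us else None
            ),
        )


_RANGE_FIELDS = (
    "fc_khz", "fmax_khz", "fmin_khz", "sc_oct_s", "s1_oct_s",
    "sweep_khz", "duration_ms", "pmc_pct",
)


def _spec_from_mapping(doc: Mapping) -> FilterSpec:
    kw: dict = {}
    for key, value in doc.items():
        if key in _RANGE_FIELDS:
            kw[key] = Range(float(value[0]), float(value[1]))
        elif key == "max_change_khz":
            kw["max_change_up_khz"] = float(value[0])
            kw["max_change_down_khz"] = float(value[1])
        elif key == "synthetic_lines":
            kw["synthetic_lines"] = tuple(
                SyntheticLineSpec(
                    x_var=d["x_var"], y_var=d["y_var"],
                    p1=(float(d["p1"][0]), float(d["p1"][1])),
                    p2=(float(d["p2"][0]), float(d["p2"][1])),
                    min=float(d["min"]), max=float(d["max"]),
                )
                for d in value
            )
        else:
            kw[key] = value
    return FilterSpec(**kw)


def load_filter_spec(path: str | Path) -> FilterSpec:
    """Load a filter specification from a YAML key-value file."""
    doc = yaml.safe_load(Path(path).read_text())
    return _spec_from_mapping(doc or {})


def load_preset(name: str) -> FilterSpec:
    """Return one of the packaged presets: BM, BCID, WEST1 or WEST2."""
    key = name.upper().replace(" ", "")
    if key not in PRESET_NAMES:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    text = resources.files("zcbat.presets").joinpath(f"{key.lower()}.yaml").read_text()
    return _spec_from_mapping(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Rule evaluation
# ---------------------------------------------------------------------------

def synthetic_line_value(features: Mapping[str, float], line: SyntheticLineSpec) -> float:
    """Vertical distance of the feature point from the synthetic line."""
    x = float(features[line.x_var])
    y = float(features[line.y_var])
    (x1, y1), (x2, y2) = line.p1, line.p2
    y_hat = y1 + (y2 - y1) * (x - x1) / (x2 - x1)
    return y - y_hat


def pulse_passes(
    pulse: Pulse,
    features: pm.PulseFeatures,
    spec: FilterSpec,
) -> tuple[bool, list[str]]:
    """Apply every present pulse-level rule; return (pass, violated names)."""
    violated: list[str] = []
    fd = features.as_dict()

    if spec.smoothness_max_pct is not None and features.smooth_pct > spec.smoothness_max_pct:
        violated.append("smoothness")
    if spec.high_start and pulse.f_hz[0] / 1e3 < features.fmax_khz - HIGH_START_TOL_KHZ:
        violated.append("high_start")
    if spec.max_change_up_khz is not None or spec.max_change_down_khz is not None:
        df_khz = np.diff(pulse.f_hz) / 1e3  # positive = frequency increase
        up = spec.max_change_up_khz if spec.max_change_up_khz is not None else np.inf
        down = spec.max_change_down_khz if spec.max_change_down_khz is not None else np.inf
        if np.any(df_khz > up) or np.any(df_khz < -down):
            violated.append("max_change")

    range_rules = {
        "fc": (spec.fc_khz, features.fc_khz),
        "fmax": (spec.fmax_khz, features.fmax_khz),
        "fmin": (spec.fmin_khz, features.fmin_khz),
        "sc": (spec.sc_oct_s, features.sc_oct_s),
        "s1": (spec.s1_oct_s, features.s1_oct_s),
        "sweep": (spec.sweep_khz, features.sweep_khz),
        "duration": (spec.duration_ms, features.dur_ms),
        "pmc": (spec.pmc_pct, features.pmc_pct),
    }
    for rule, (rng, value) in range_rules.items():
        if rng is not None and not rng.contains(value):
            violated.append(rule)

    for idx, line in enumerate(spec.synthetic_lines, start=1):
        v = synthetic_line_value(fd, line)
        if not (line.min <= v <= line.max):
            violated.append(f"synthetic_line_{idx}")

    return (not violated, violated)


def sequence_postfilter(
    passing_pulses: Sequence[Pulse],
    spec: FilterSpec,
) -> tuple[Pulse, ...]:
    """Apply sequence-level rules; return retained pulses (empty = reject).

    Steps, in order:

    1. ``reject_gap``: any two consecutive passing pulses separated
       (end-to-start) by less than the gap are *both* removed.
    2. Countable pulses: the greedy-from-earliest subset whose onsets are
       pairwise at least ``min_time_between_calls_ms`` apart.
    3. The sequence is retained iff some sliding window of
       ``time_for_calls_s`` seconds contains at least ``min_calls``
       countable pulses.  Retained sequences keep the surviving (post step
       1) pulses; rejected sequences contribute none.
    """
    pulses = list(passing_pulses)
    if not pulses:
        return ()

    if spec.reject_gap_ms is not None and len(pulses) > 1:
        gap_us = spec.reject_gap_ms * 1e3
        drop = set()
        for k in range(len(pulses) - 1):
            if pulses[k + 1].start_us - pulses[k].end_us < gap_us:
                drop.update((k, k + 1))
        pulses = [p for k, p in enumerate(pulses) if k not in drop]
        if not pulses:
            return ()

    countable = pulses
    if spec.min_time_between_calls_ms is not None:
        spacing_us = spec.min_time_between_calls_ms * 1e3
        countable = [pulses[0]]
        for p in pulses[1:]:
            if p.start_us - countable[-1].start_us >= spacing_us:
                countable.append(p)

    if spec.min_calls is not None:
        starts = np.array([p.start_us for p in countable], dtype=float)
        if spec.time_for_calls_s is not None:
            window_us = spec.time_for_calls_s * 1e6
            # max countable pulses inside any window of that length
            best = 0
            for i in range(starts.size):
                j = np.searchsorted(starts, starts[i] + window_us, side="right")
                best = max(best, j - i)
            if best < spec.min_calls:
                return ()
        elif starts.size < spec.min_calls:
            return ()

    return tuple(pulses)


# ---------------------------------------------------------------------------
# Library-level application
# ---------------------------------------------------------------------------

@dataclass
class FilterResult:
    """Pulses and sequences a filter retained from one library."""

    library_name: str
    spec_name: str
    #: file_id -> list of retained pulse tuples, one per retained sequence
    retained: dict[str, list[tuple[Pulse, ...]]]
    #: species label per file (None for noise files)
    labels: dict[str, str | None]
    #: feature table of retained pulses (columns as pulse_metrics tables)
    features: pd.DataFrame

    @property
    def n_sequences(self) -> int:
        return sum(len(v) for v in self.retained.values())

    @property
    def n_pulses(self) -> int:
        return sum(len(seq) for v in self.retained.values() for seq in v)

    def pulse_keys(self) -> set[tuple[str, int, int]]:
        return {
            p.key for v in self.retained.values() for seq in v for p in seq
        }

    def counts(self) -> pd.DataFrame:
        """Sequences and pulses retained, by species (noise under ``None``)."""
        rows: dict[str | None, dict[str, int]] = {}
        for fid, seqs in self.retained.items():
            sp = self.labels.get(fid)
            entry = rows.setdefault(sp, {"sequences": 0, "pulses": 0})
            entry["sequences"] += len(seqs)
            entry["pulses"] += sum(len(s) for s in seqs)
        df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("species")
        return df.sort_index(key=lambda idx: idx.map(lambda v: (v is None, v)))

    def noise_counts(self) -> dict[str, int]:
        noise = [
            (fid, seqs) for fid, seqs in self.retained.items()
            if self.labels.get(fid) is None
        ]
        return {
            "sequences": sum(len(s) for _, s in noise),
            "pulses": sum(len(seq) for _, s in noise for seq in s),
        }


def apply_filter(library: CallLibrary, spec: FilterSpec) -> FilterResult:
    """Run one filter over a library, end to end.

    Each file is re-segmented with the filter's own join/ignore settings,
    assembled into sequences, measured at the filter's Body Over, and then
    passed through the pulse- and sequence-level rules.  The filter output
    is accepted in toto: no manual vetting stage exists.
    """
    seg_cfg = spec.segmentation()
    retained: dict[str, list[tuple[Pulse, ...]]] = {}
    feat_rows: list[dict] = []
    seq_counter = 0
    for fid, (t, f) in library.files.items():
        pulses = segment_pulses(t, f, seg_cfg, file_id=fid)
        for seq in assemble_sequences(pulses):
            passing = []
            feats_map = {}
            for p in seq.pulses:
                feats = pm.extract_features(p, spec.body_over_us)
                ok, _ = pulse_passes(p, feats, spec)
                if ok:
                    passing.append(p)
                    feats_map[p.key] = feats
            kept = sequence_postfilter(passing, spec)
            if kept:
                retained.setdefault(fid, []).append(kept)
                for p_idx, p in enumerate(kept):
                    feat_rows.append({
                        "file_id": fid,
                        "seq_id": seq_counter,
                        "pulse_id": p_idx,
                        "species": library.label(fid),
                        **feats_map[p.key].as_dict(),
                    })
                seq_counter += 1
    cols = ["file_id", "seq_id", "pulse_id", "species", *pm.FEATURE_COLUMNS]
    return FilterResult(
        library_name=library.name,
        spec_name=spec.name,
        retained=retained,
        labels={fid: library.label(fid) for fid in library.files},
        features=pd.DataFrame(feat_rows, columns=cols),
    )


def consensus(results: Iterable[FilterResult]) -> FilterResult:
    """Intersect filter results: keep pulses every filter retained.

    Pulse identity is (file_id, first-dot time, last-dot time): filters with
    different join settings may delimit pulses differently, and only
    identically-delimited pulses count as the same pulse.  A file's
    sequences survive only if every filter retained the file; surviving
    consensus pulses are re-grouped into sequences by the standard
    interpulse rule.  The consensus feature table re-measures nothing: it
    keeps the rows of the first result restricted to consensus pulses (use
    per-filter re-measurement for measurement comparisons).
    """
    results = list(results)
    if not results:
        raise ValueError("consensus requires at least one result")
    names = {r.library_name for r in results}
    if len(names) != 1:
        raise ValueError(f"results come from different libraries: {sorted(names)}")

    keys = set.intersection(*(r.pulse_keys() for r in results))
    files_all = set.intersection(*({fid for fid in r.retained} for r in results))

    first = results[0]
    retained: dict[str, list[tuple[Pulse, ...]]] = {}
    for fid in first.retained:
        if fid not in files_all:
            continue
        pulses = [
            p for seq in first.retained[fid] for p in seq if p.key in keys
        ]
        pulses.sort(key=lambda p: p.start_us)
        seqs = assemble_sequences(pulses, MAX_INTERPULSE_S)
        if seqs:
            retained[fid] = [s.pulses for s in seqs]

    feat = first.features
    if not feat.empty:
        key_col = list(zip(feat["file_id"], *_pulse_spans(first)))
        keep = [k in keys for k in key_col]
        feat = feat.loc[keep].reset_index(drop=True)
    return FilterResult(
        library_name=first.library_name,
        spec_name="CONSENSUS",
        retained=retained,
        labels=dict(first.labels),
        features=feat,
    )


def _pulse_spans(result: FilterResult) -> tuple[list[int], list[int]]:
    starts: list[int] = []
    ends: list[int] = []
    for seqs in result.retained.values():
        for seq in seqs:
            for p in seq:
                starts.append(p.start_us)
                ends.append(p.end_us)
    return starts, ends
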