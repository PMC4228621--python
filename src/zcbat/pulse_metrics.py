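"""Pulse parameter measurement for zero-crossing bat pulses.

The central construct is the pulse *body*: the flattest contiguous portion
of the pulse, searched at a granularity set by the ``Body Over`` time
increment.  Frequency at the end of the body (Fc, kHz) and slope of the body
(Sc, octaves/s, positive for downward sweeps) are typically the most
diagnostic parameters for species identification, and both depend on the
Body Over setting used to find the body.

Measured parameters
-------------------
Dur     pulse duration (ms)
Sweep   total pulse bandwidth, Fmax - Fmin (kHz)
Fc      frequency at the end of the body (kHz)
Sc      slope of the body, bandwidth(octaves)/duration(s) between its
        endpoints (octaves/s)
Tail    duration of the pulse after the body (ms)
Fmax, Fmin  extreme dot frequencies (kHz)
S1      initial slope, measured over roughly the first quarter of the pulse
        (octaves/s)
Pmc     body duration as a percentage of pulse duration (%)
smooth  roughness score: the largest relative deviation (%) of any dot from
        a two-dot linear extrapolation of its predecessors

S1, Pmc and the smoothness score are operational stand-ins: the tools that
originated these rule names do not publish their algorithms, so each is a
documented, swappable predicate (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .zc_data import CallLibrary, Pulse, SegmentationConfig

__all__ = [
    "BodySegment",
    "PulseFeatures",
    "FEATURE_COLUMNS",
    "CLASSIFIER_FEATURES",
    "slope_octaves_per_s",
    "find_body",
    "extract_features",
    "initial_slope_s1",
    "smoothness_pct",
    "pmc_pct",
    "features_table",
]

#: Column order of the exported feature table.
FEATURE_COLUMNS = [
    "dur_ms", "sweep_khz", "fc_khz", "sc_oct_s", "tail_ms",
    "fmax_khz", "fmin_khz", "s1_oct_s", "pmc_pct", "smooth_pct",
]

#: The five uncorrelated parameters used as classifier covariates.
CLASSIFIER_FEATURES = ["dur_ms", "fc_khz", "sc_oct_s", "sweep_khz", "tail_ms"]

#: Relative tolerance for treating two candidate-body slopes as tied.
_SLOPE_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class BodySegment:
    """The flattest portion of a pulse, as inclusive dot indices."""

    start: int
    end: int
    t_b_s: float     # body duration (s)
    f_b_oct: float   # body bandwidth between endpoints (octaves, >=0 down)
    sc_oct_s: float  # endpoint slope (octaves/s)


@dataclass(frozen=True)
class PulseFeatures:
    dur_ms: float
    sweep_khz: float
    fc_khz: float
    sc_oct_s: float
    tail_ms: float
    fmax_khz: float
    fmin_khz: float
    s1_oct_s: float
    pmc_pct: float
    smooth_pct: float
    body: BodySegment

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in FEATURE_COLUMNS}


def slope_octaves_per_s(f_start_hz: float, f_end_hz: float, dt_s: float) -> float:
    """Endpoint slope in octaves per second.

    Positive for downward sweeps (``f_start > f_end``), matching the sign
    convention under which body slopes of typical bat pulses are positive.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    if f_start_hz <= 0 or f_end_hz <= 0:
        raise ValueError("frequencies must be positive")
    return float((np.log2(f_start_hz) - np.log2(f_end_hz)) / dt_s)


def find_body(pulse: Pulse, body_over_us: float) -> BodySegment:
    """Locate the flattest portion of a pulse.

    Among all contiguous dot segments whose duration is at least
    ``body_over_us``, returns the one minimizing the absolute endpoint slope
    (octaves/s).  Ties are broken by longer duration, then earlier start,
    which deterministically favours a single maximal flat body.  If the
    whole pulse is shorter than ``body_over_us`` the body is the whole
    pulse, so that a long Body Over can still be applied to short pulses.
    """
    t = pulse.t_us
    f = pulse.f_hz
    n = t.size
    if n < 2:
        raise ValueError("find_body requires a pulse with at least two dots")

    L = np.log2(f)
    ts = t.astype(float) / 1e6

    if t[-1] - t[0] < body_over_us:
        return _segment(0, n - 1, ts, L)

    dt = ts[None, :] - ts[:, None]            # dt[i, j] = t_j - t_i
    valid = (t[None, :] - t[:, None]) >= body_over_us
    valid &= np.tri(n, n, -1, dtype=bool).T   # j > i
    ii, jj = np.nonzero(valid)
    seg_dt = dt[ii, jj]
    score = np.abs((L[ii] - L[jj]) / seg_dt)

    best = score.min()
    tol = _SLOPE_TIE_RTOL * max(1.0, best)
    tied = np.flatnonzero(score <= best + tol)
    # longest duration first, then earliest start
    order = np.lexsort((ii[tied], -seg_dt[tied]))
    k = tied[order[0]]
    return _segment(int(ii[k]), int(jj[k]), ts, L)


def _segment(i: int, j: int, ts: np.ndarray, L: np.ndarray) -> BodySegment:
    t_b = float(ts[j] - ts[i])
    f_b = float(L[i] - L[j])
    sc = f_b / t_b if t_b > 0 else 0.0
    return BodySegment(start=i, end=j, t_b_s=t_b, f_b_oct=f_b, sc_oct_s=sc)


def initial_slope_s1(pulse: Pulse) -> float:
    """Slope over roughly the first quarter of the pulse (octaves/s).

    Measured between the first dot and the dot nearest to 25% of pulse
    duration, never earlier than the second dot.
    """
    t = pulse.t_us
    if t.size < 2:
        raise ValueError("S1 requires at least two dots")
    target = t[0] + 0.25 * (t[-1] - t[0])
    k = int(np.argmin(np.abs(t.astype(float) - target)))
    k = max(k, 1)
    return slope_octaves_per_s(pulse.f_hz[0], pulse.f_hz[k], (t[k] - t[0]) / 1e6)


def smoothness_pct(pulse: Pulse) -> float:
    """Largest relative deviation (%) from two-dot linear extrapolation.

    For each dot from the third onward, the expected frequency is the linear
    (time-aware) extrapolation of the previous two dots; the score is the
    maximum of ``100 * |f - f_hat| / f_hat``.  A pulse passes a filter's
    smoothness rule ``s`` iff its score is at most ``s``.  Pulses with fewer
    than three dots carry no interior evidence and score 0.
    """
    t = pulse.t_us.astype(float)
    f = pulse.f_hz
    if t.size < 3:
        return 0.0
    rate = (f[1:-1] - f[:-2]) / (t[1:-1] - t[:-2])
    f_hat = f[1:-1] + rate * (t[2:] - t[1:-1])
    f_hat = np.maximum(f_hat, 1e-6)
    return float(np.max(np.abs(f[2:] - f_hat) / f_hat) * 100.0)


def pmc_pct(pulse: Pulse, body: BodySegment) -> float:
    """Percentage of pulse duration occupied by the body."""
    dur_s = pulse.duration_us / 1e6
    if dur_s <= 0:
        return 100.0
    return float(100.0 * body.t_b_s / dur_s)


def extract_features(pulse: Pulse, body_over_us: float) -> PulseFeatures:
    """Measure all pulse parameters at the given Body Over increment."""
    body = find_body(pulse, body_over_us)
    t = pulse.t_us
    f = pulse.f_hz
    dur_ms = pulse.duration_us / 1e3
    fmax = float(f.max()) / 1e3
    fmin = float(f.min()) / 1e3
    fc = float(f[body.end]) / 1e3
    tail_ms = float(t[-1] - t[body.end]) / 1e3
    return PulseFeatures(
        dur_ms=dur_ms,
        sweep_khz=fmax - fmin,
        fc_khz=fc,
        sc_oct_s=body.sc_oct_s,
        tail_ms=tail_ms,
        fmax_khz=fmax,
        fmin_khz=fmin,
        s1_oct_s=initial_slope_s1(pulse),
        pmc_pct=pmc_pct(pulse, body),
        smooth_pct=smoothness_pct(pulse),
        body=body,
    )


def features_table(
    library: CallLibrary,
    body_over_us: float,
    seg_cfg: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Measure every segmentable pulse of a library (no selection rules).

    Returns one row per pulse with identification columns
    ``file_id, seq_id, pulse_id, species`` followed by the feature columns.
    ``seq_id`` is globally unique across files.
    """
    rows: list[dict] = []
    seq_counter = 0
    for seq in library.sequences(seg_cfg):
        for p_idx, pulse in enumerate(seq.pulses):
            feats = extract_features(pulse, body_over_us)
            rows.append({
                "file_id": seq.file_id,
                "seq_id": seq_counter,
                "pulse_id": p_idx,
                "species": seq.species,
                **feats.as_dict(),
            })
        seq_counter += 1
    cols = ["file_id", "seq_id", "pulse_id", "species", *FEATURE_COLUMNS]
    return pd.DataFrame(rows, columns=cols)
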