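"""Model validation: cross-validation, bootstrap intervals, comparisons.

Classification performance is summarized per species i as three rates over
its N_i labelled sequences: n_i/N_i correct, n_j/N_i incorrect (assigned to
some other species), and (N_i - n_i - n_j)/N_i unknown (no strict majority
of pulse votes).  Overall rates are the unweighted arithmetic mean across
species, so rare species count as much as common ones.

Internal validation is leave-one-out at the sequence level: all pulses of
one sequence are withheld, the model is refit, and the held-out sequence is
classified.  External validation fits on one library and classifies a
second, independently collected one.  Confidence intervals come from a
nonparametric bootstrap that resamples pulse sequences with replacement and
repeats the whole evaluation; the 5th and 95th quantiles of the replicate
rates form a 90% interval, and intervals that do not overlap are treated as
significant differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classifier import (
    UNKNOWN,
    FeatureMatrix,
    classify_sequence,
    fit_qdfa,
)

__all__ = [
    "RateTable",
    "BootstrapConfig",
    "ComparisonReport",
    "confusion_rates",
    "loocv",
    "external_validate",
    "bootstrap_rates",
    "compare_filter_parameters",
]

RATE_COLUMNS = ["N", "n_correct", "n_incorrect", "correct", "incorrect", "unknown"]


@dataclass
class RateTable:
    """Per-species and overall classification rates, optionally with CIs.

    ``per_species`` has one row per species (columns ``N, n_correct,
    n_incorrect, correct, incorrect, unknown``); ``overall`` is the
    unweighted mean of the per-species rates.  ``ci`` maps rate name ->
    DataFrame with ``lo``/``hi`` columns indexed like ``per_species`` plus
    an ``overall`` row.
    """

    per_species: pd.DataFrame
    overall: pd.Series
    ci: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return list(self.per_species.index)

    def rate(self, which: str = "correct") -> float:
        return float(self.overall[which])

    def to_json_dict(self) -> dict:
        out = {
            "per_species": self.per_species.to_dict(orient="index"),
            "overall": self.overall.to_dict(),
        }
        if self.ci:
            out["ci"] = {k: v.to_dict(orient="index") for k, v in self.ci.items()}
        return out


def confusion_rates(
    truth: Mapping[int, str] | Sequence[str],
    predictions: Mapping[int, str] | Sequence[str],
    species_set: Sequence[str],
) -> RateTable:
    """Tabulate correct / incorrect / unknown rates from sequence labels.

    ``truth`` and ``predictions`` are parallel (dict keyed by sequence id,
    or plain sequences).  Predictions may be species codes or ``UNKNOWN``.
    A truth label outside ``species_set`` is an error.
    """
    if isinstance(truth, Mapping):
        keys = list(truth)
        t = [truth[k] for k in keys]
        p = [predictions[k] for k in keys]
    else:
        t = list(truth)
        p = list(predictions)
    if len(t) != len(p):
        raise ValueError("truth and predictions differ in length")
    bad = sorted(set(t) - set(species_set))
    if bad:
        raise ValueError(f"truth labels not in species set: {bad}")

    rows = {}
    for sp in species_set:
        idx = [i for i, x in enumerate(t) if x == sp]
        N = len(idx)
        if N == 0:
            continue
        n_corr = sum(1 for i in idx if p[i] == sp)
        n_inc = sum(1 for i in idx if p[i] != sp and p[i] != UNKNOWN)
        rows[sp] = {
            "N": N, "n_correct": n_corr, "n_incorrect": n_inc,
            "correct": n_corr / N, "incorrect": n_inc / N,
            "unknown": (N - n_corr - n_inc) / N,
        }
    per = pd.DataFrame.from_dict(rows, orient="index")[RATE_COLUMNS]
    per.index.name = "species"
    overall = per[["correct", "incorrect", "unknown"]].mean(axis=0)
    overall["N"] = per["N"].sum()
    return RateTable(per_species=per, overall=overall)


def _sequence_views(fm: FeatureMatrix) -> tuple[list[int], dict[int, np.ndarray], dict[int, str]]:
    idx = fm.sequence_index()
    labels = fm.sequence_labels()
    return list(idx), idx, labels


def loocv(fm: FeatureMatrix) -> RateTable:
    """Sequence-level leave-one-out cross-validation.

    For each labelled sequence, all of its pulses are removed, the model is
    refit on the remainder, and the held-out pulses are classified as a
    sequence.  Every species needs at least two sequences so each fold can
    still be fit; a fold whose training set violates the fit preconditions
    raises an error naming the withheld sequence.
    """
    seq_order, seq_idx, seq_truth = _sequence_views(fm)
    species_counts = pd.Series(list(seq_truth.values())).value_counts()
    few = species_counts[species_counts < 2]
    if not few.empty:
        raise ValueError(
            f"species with a single sequence cannot be cross-validated: "
            f"{sorted(few.index)}"
        )
    preds: dict[int, str] = {}
    mask = np.ones(fm.n_pulses, dtype=bool)
    for s in seq_order:
        rows = seq_idx[s]
        mask[rows] = False
        try:
            model = fit_qdfa(fm.subset(mask))
        except ValueError as exc:
            raise ValueError(f"fold holding out sequence {s} failed: {exc}") from exc
        finally:
            mask[rows] = True
        preds[s] = classify_sequence(model, fm.X[rows]).label
    present = [sp for sp in fm.species if sp in set(seq_truth.values())]
    return confusion_rates(seq_truth, preds, present)


def resubstitution(fm: FeatureMatrix) -> RateTable:
    """Fit on everything, classify everything (optimistic reference)."""
    model = fit_qdfa(fm)
    _, seq_idx, seq_truth = _sequence_views(fm)
    preds = {s: classify_sequence(model, fm.X[rows]).label for s, rows in seq_idx.items()}
    present = [sp for sp in fm.species if sp in set(seq_truth.values())]
    return confusion_rates(seq_truth, preds, present)


def external_validate(train: FeatureMatrix, test: FeatureMatrix) -> RateTable:
    """Fit on the whole training library; classify the whole test library."""
    train_species = {train.species[k] for k in np.unique(train.y)}
    test_species = {test.species[k] for k in np.unique(test.y)}
    missing = sorted(test_species - train_species)
    if missing:
        raise ValueError(f"test species unseen in training: {missing}")
    model = fit_qdfa(train)
    _, seq_idx, seq_truth = _sequence_views(test)
    preds = {s: classify_sequence(model, test.X[rows]).label for s, rows in seq_idx.items()}
    present = [sp for sp in test.species if sp in test_species]
    return confusion_rates(seq_truth, preds, present)


@dataclass(frozen=True)
class BootstrapConfig:
    B: int = 1000
    quantiles: tuple[float, float] = (0.05, 0.95)
    seed: int | None = None
    #: Fraction of replicates allowed to fail (degenerate resamples).
    max_skip_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        lo, hi = self.quantiles
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("quantiles must satisfy 0 < lo < hi < 1")


def _resample_sequences(fm: FeatureMatrix, rng: np.random.Generator) -> FeatureMatrix:
    seq_order, seq_idx, _ = _sequence_views(fm)
    picks = rng.integers(0, len(seq_order), size=len(seq_order))
    rows = []
    new_seq = []
    for new_id, pick in enumerate(picks):
        r = seq_idx[seq_order[int(pick)]]
        rows.append(r)
        new_seq.append(np.full(r.size, new_id, dtype=np.int64))
    rows = np.concatenate(rows)
    return FeatureMatrix(
        X=fm.X[rows], y=fm.y[rows], seq_ids=np.concatenate(new_seq),
        species=fm.species, features=fm.features,
    )


def bootstrap_rates(
    fm: FeatureMatrix,
    cfg: BootstrapConfig,
    evaluator: Callable[[FeatureMatrix], RateTable] = loocv,
) -> RateTable:
    """Bootstrap confidence intervals around an evaluator's rates.

    Each replicate draws pulse sequences with replacement to the original
    number of sequences and re-runs the evaluator; the configured quantiles
    of the replicate rates form the interval.  The point estimate comes
    from the unresampled data.  Replicates in which the evaluator fails
    (e.g. a species stratum vanished under resampling) are skipped and
    counted; more than ``max_skip_frac`` skipped is an error.
    """
    point = evaluator(fm)
    rng = np.random.default_rng(cfg.seed)
    per_rates: list[pd.DataFrame] = []
    overall_rates: list[pd.Series] = []
    skipped = 0
    for _ in range(cfg.B):
        try:
            rt = evaluator(_resample_sequences(fm, rng))
        except ValueError:
            skipped += 1
            continue
        per_rates.append(rt.per_species[["correct", "incorrect", "unknown"]])
        overall_rates.append(rt.overall[["correct", "incorrect", "unknown"]])
    if skipped > cfg.max_skip_frac * cfg.B:
        raise RuntimeError(
            f"{skipped}/{cfg.B} bootstrap replicates failed "
            f"(> {cfg.max_skip_frac:.0%} allowed)"
        )
    lo_q, hi_q = cfg.quantiles
    ci: dict[str, pd.DataFrame] = {}
    for rate in ("correct", "incorrect", "unknown"):
        reps = pd.concat(
            [df[rate] for df in per_rates], axis=1
        )
        ov = np.array([s[rate] for s in overall_rates])
        tab = pd.DataFrame({
            "lo": reps.quantile(lo_q, axis=1),
            "hi": reps.quantile(hi_q, axis=1),
        })
        tab.loc["overall"] = [np.quantile(ov, lo_q), np.quantile(ov, hi_q)]
        ci[rate] = tab
    return RateTable(per_species=point.per_species, overall=point.overall, ci=ci)


# ---------------------------------------------------------------------------
# Filter parameter comparisons
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Nonparametric comparison of parameter measurements across filters.

    For each parameter: a Kruskal-Wallis test across filters; if it is
    significant, all pairwise two-sided Wilcoxon rank-sum tests with a Holm
    adjustment; and compact letters such that two filters share a letter
    iff their adjusted p-value is at or above alpha.
    """

    alpha: float
    kruskal: pd.DataFrame                       # parameter x (statistic, p)
    pairwise: dict[str, pd.DataFrame]           # parameter -> p-matrix (Holm)
    letters: dict[str, dict[str, str]]          # parameter -> filter -> letters


def _letter_groups(groups: list[str], ns_pairs: set[frozenset[str]]) -> dict[str, str]:
    """Compact letter display: letters = maximal cliques of non-significance."""
    adj = {g: {g} for g in groups}
    for pair in ns_pairs:
        a, b = tuple(pair)
        adj[a].add(b)
        adj[b].add(a)
    cliques: list[set[str]] = []
    # full clique search is overkill for a handful of filters: enumerate
    # subsets from largest to smallest, keeping maximal ones
    n = len(groups)
    for size in range(n, 0, -1):
        for cand in combinations(groups, size):
            s = set(cand)
            if all(b in adj[a] for a, b in combinations(cand, 2)):
                if not any(s <= c for c in cliques):
                    cliques.append(s)
    cliques.sort(key=lambda c: sorted(groups.index(g) for g in c)[0])
    letters = {g: "" for g in groups}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for g in clique:
            letters[g] += ch
    return letters


def compare_filter_parameters(
    samples: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
) -> ComparisonReport:
    """Compare each parameter's measurements across filters.

    ``samples`` maps filter name -> DataFrame of parameter measurements
    (shared columns).  Needs at least two filters with at least two
    measurements each per parameter.
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least two filters to compare")
    params = list(samples[names[0]].columns)
    for nm in names:
        if samples[nm].empty:
            raise ValueError(f"filter {nm!r} has no measurements")

    kw_rows = {}
    pairwise: dict[str, pd.DataFrame] = {}
    letters: dict[str, dict[str, str]] = {}
    for param in params:
        arrays = [samples[nm][param].dropna().to_numpy() for nm in names]
        if any(a.size < 2 for a in arrays):
            raise ValueError(f"parameter {param!r} has a group with <2 values")
        if np.ptp(np.concatenate(arrays)) == 0:
            stat, p = 0.0, 1.0  # identical samples: no evidence of difference
        else:
            stat, p = stats.kruskal(*arrays)
        kw_rows[param] = {"statistic": float(stat), "p": float(p)}

        pmat = pd.DataFrame(np.nan, index=names, columns=names)
        ns_pairs: set[frozenset[str]] = set()
        if p < alpha:
            pairs = list(combinations(range(len(names)), 2))
            raw = []
            for i, j in pairs:
                if np.ptp(np.concatenate([arrays[i], arrays[j]])) == 0:
                    raw.append(1.0)
                else:
                    raw.append(float(stats.mannwhitneyu(
                        arrays[i], arrays[j], alternative="two-sided",
                        method="asymptotic",
                    ).pvalue))
            adj = multipletests(raw, method="holm")[1]
            for (i, j), pv in zip(pairs, adj):
                pmat.iloc[i, j] = pmat.iloc[j, i] = pv
                if pv >= alpha:
                    ns_pairs.add(frozenset((names[i], names[j])))
        else:
            # omnibus not significant: no pair differs
            ns_pairs = {frozenset(p) for p in combinations(names, 2)}
            pmat.loc[:, :] = 1.0
            np.fill_diagonal(pmat.values, np.nan)
        pairwise[param] = pmat
        letters[param] = _letter_groups(names, ns_pairs)

    return ComparisonReport(
        alpha=alpha,
        kruskal=pd.DataFrame.from_dict(kw_rows, orient="index"),
        pairwise=pairwise,
        letters=letters,
    )
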