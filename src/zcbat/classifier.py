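"""Quadratic discriminant classification of pulses and sequences.

Each species is modelled as a multivariate Gaussian over the selected pulse
parameters with its own covariance matrix (class covariances differ too
much for a common pooled matrix to be tenable), and prior probabilities of
group membership are equalized.  Individual pulses are classified to the
species with the highest posterior probability; a pulse sequence is
assigned to a species only if that species wins a strict majority (>50%) of
its pulses' votes, and is labelled ``UNKNOWN`` otherwise — plurality is not
sufficient.

Covariate screening drops parameters until no pair is correlated at
Pearson R^2 >= 0.5, so a single covariate set can feed models trained on
differently filtered data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

__all__ = [
    "UNKNOWN",
    "FeatureMatrix",
    "QdfaModel",
    "screen_features",
    "fit_qdfa",
    "log_posteriors",
    "classify_pulse",
    "classify_pulses",
    "classify_sequence",
    "SequencePrediction",
]

UNKNOWN = "UNKNOWN"

#: Minimum pulses per sequence for sequence-level work.
MIN_PULSES_PER_SEQUENCE = 5


@dataclass
class FeatureMatrix:
    """Pulse-level feature matrix with species labels and sequence ids."""

    X: np.ndarray                 # (n_pulses, n_features)
    y: np.ndarray                 # (n_pulses,) species indices into `species`
    seq_ids: np.ndarray           # (n_pulses,) sequence membership
    species: tuple[str, ...]      # fixed species order (tie-break order)
    features: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.seq_ids = np.asarray(self.seq_ids, dtype=np.int64)
        n = self.X.shape[0]
        if self.y.shape != (n,) or self.seq_ids.shape != (n,):
            raise ValueError("X, y and seq_ids disagree in length")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains missing or non-finite values")

    @property
    def n_pulses(self) -> int:
        return int(self.X.shape[0])

    def sequence_index(self) -> dict[int, np.ndarray]:
        """Map seq_id -> row indices, in order of first appearance."""
        out: dict[int, list[int]] = {}
        for i, s in enumerate(self.seq_ids):
            out.setdefault(int(s), []).append(i)
        return {k: np.asarray(v) for k, v in out.items()}

    def sequence_labels(self) -> dict[int, str]:
        idx = self.sequence_index()
        return {s: self.species[int(self.y[rows[0]])] for s, rows in idx.items()}

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X[mask], y=self.y[mask], seq_ids=self.seq_ids[mask],
            species=self.species, features=self.features,
        )

    def validate_sequences(self, min_pulses: int = MIN_PULSES_PER_SEQUENCE) -> None:
        counts = pd.Series(self.seq_ids).value_counts()
        if (counts < min_pulses).any():
            bad = counts[counts < min_pulses].index.tolist()
            raise ValueError(f"sequences with fewer than {min_pulses} pulses: {bad}")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        features: Sequence[str],
        species_order: Sequence[str] | None = None,
        label_col: str = "species",
        seq_col: str = "seq_id",
    ) -> "FeatureMatrix":
        labels = df[label_col].astype(str)
        if species_order is None:
            species_order = tuple(sorted(labels.unique()))
        lut = {sp: k for k, sp in enumerate(species_order)}
        unknown = set(labels.unique()) - set(species_order)
        if unknown:
            raise ValueError(f"labels not in species order: {sorted(unknown)}")
        return cls(
            X=df[list(features)].to_numpy(dtype=float),
            y=labels.map(lut).to_numpy(),
            seq_ids=df[seq_col].to_numpy(dtype=np.int64),
            species=tuple(species_order),
            features=tuple(features),
        )


def screen_features(df: pd.DataFrame, r2_max: float = 0.5) -> list[str]:
    """Drop covariates until all pairwise Pearson R^2 fall below ``r2_max``.

    Correlations are computed over pulses pooled across species.  While any
    pair reaches the threshold, the member of the worst (highest R^2) pair
    with the larger number of correlated partners is dropped; ties drop the
    later column.  Raises on constant columns (undefined correlation).
    """
    cols = list(df.columns)
    if len(cols) < 2 or len(df) < 3:
        raise ValueError("screening requires at least two features and three rows")
    sd = df.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant columns have undefined correlation: {constant}")

    keep = list(cols)
    while True:
        r2 = df[keep].corr() ** 2
        np.fill_diagonal(r2.values, 0.0)
        worst = float(r2.values.max())
        if worst < r2_max:
            return keep
        i, j = np.unravel_index(int(np.argmax(r2.values)), r2.shape)
        a, b = keep[i], keep[j]
        partners = (r2 >= r2_max).sum()
        if partners[a] > partners[b]:
            drop = a
        elif partners[b] > partners[a]:
            drop = b
        else:  # tie: drop the later column
            drop = b if keep.index(b) > keep.index(a) else a
        keep.remove(drop)


@dataclass
class QdfaModel:
    """Per-species Gaussian densities with equal priors."""

    species: tuple[str, ...]
    features: tuple[str, ...]
    means: np.ndarray        # (K, d)
    covs: np.ndarray         # (K, d, d), symmetric positive-definite
    priors: np.ndarray       # (K,), equal, sum to 1
    _chol: np.ndarray = field(init=False, repr=False)
    _logdet: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        K, d = self.means.shape
        chol = np.empty_like(self.covs)
        logdet = np.empty(K)
        for k in range(K):
            try:
                chol[k] = np.linalg.cholesky(self.covs[k])
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"covariance for species {self.species[k]!r} is singular"
                ) from exc
            logdet[k] = 2.0 * np.sum(np.log(np.diag(chol[k])))
        self._chol = chol
        self._logdet = logdet

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "species": list(self.species),
            "features": list(self.features),
            "means": self.means.tolist(),
            "covs": self.covs.tolist(),
            "priors": self.priors.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "QdfaModel":
        p = Path(source)
        payload = json.loads(p.read_text() if p.exists() else str(source))
        return cls(
            species=tuple(payload["species"]),
            features=tuple(payload["features"]),
            means=np.asarray(payload["means"], dtype=float),
            covs=np.asarray(payload["covs"], dtype=float),
            priors=np.asarray(payload["priors"], dtype=float),
        )


def fit_qdfa(fm: FeatureMatrix) -> QdfaModel:
    """Fit per-species means and unbiased covariances; equalize priors.

    Every class must contribute more pulses than features + 1 so its
    covariance is full rank; a singular class covariance raises an error
    naming the species.
    """
    present = np.unique(fm.y)
    species = tuple(fm.species[int(k)] for k in present)
    d = fm.X.shape[1]
    K = len(species)
    means = np.empty((K, d))
    covs = np.empty((K, d, d))
    for idx, k in enumerate(present):
        Xk = fm.X[fm.y == k]
        if Xk.shape[0] <= d + 1:
            raise ValueError(
                f"species {fm.species[int(k)]!r} has only {Xk.shape[0]} pulses "
                f"for {d} features (needs more than {d + 1})"
            )
        means[idx] = Xk.mean(axis=0)
        covs[idx] = np.cov(Xk, rowvar=False, ddof=1)
    priors = np.full(K, 1.0 / K)
    return QdfaModel(
        species=species, features=fm.features,
        means=means, covs=covs, priors=priors,
    )


def log_posteriors(model: QdfaModel, X: np.ndarray) -> np.ndarray:
    """Unnormalized Gaussian log posteriors, shape (n, K)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    n = X.shape[0]
    K = len(model.species)
    out = np.empty((n, K))
    for k in range(K):
        diff = (X - model.means[k]).T
        z = solve_triangular(model._chol[k], diff, lower=True)
        maha = np.sum(z * z, axis=0)
        out[:, k] = (
            np.log(model.priors[k]) - 0.5 * model._logdet[k] - 0.5 * maha
        )
    return out


def _normalize(logp: np.ndarray) -> np.ndarray:
    m = logp.max(axis=1, keepdims=True)
    p = np.exp(logp - m)
    return p / p.sum(axis=1, keepdims=True)


def classify_pulses(model: QdfaModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels (indices into model.species) and posteriors for many pulses.

    The argmax is taken in fixed species order, so exact posterior ties
    resolve to the earlier species deterministically.
    """
    logp = log_posteriors(model, X)
    post = _normalize(logp)
    labels = np.argmax(post, axis=1)
    return labels, post


def classify_pulse(model: QdfaModel, x: np.ndarray) -> tuple[str, np.ndarray]:
    """Species label and posterior vector for one pulse."""
    labels, post = classify_pulses(model, np.atleast_2d(x))
    return model.species[int(labels[0])], post[0]


@dataclass(frozen=True)
class SequencePrediction:
    label: str                    # species code or UNKNOWN
    votes: dict[str, float]       # vote fraction per species
    pulse_labels: tuple[str, ...]
    posteriors: np.ndarray        # (n_pulses, K)


def classify_sequence(model: QdfaModel, X: np.ndarray) -> SequencePrediction:
    """Majority-vote sequence label with a reject option.

    Each pulse votes for its highest-posterior species; the sequence is
    assigned to a species only if it holds strictly more than half the
    votes, otherwise it is labelled ``UNKNOWN``.
    """
    X = np.atleast_2d(X)
    if X.shape[0] < 1:
        raise ValueError("classify_sequence requires at least one pulse")
    labels, post = classify_pulses(model, X)
    n = labels.size
    counts = np.bincount(labels, minlength=len(model.species))
    votes = {sp: counts[k] / n for k, sp in enumerate(model.species)}
    winner = int(np.argmax(counts))
    label = model.species[winner] if counts[winner] * 2 > n else UNKNOWN
    return SequencePrediction(
        label=label,
        votes=votes,
        pulse_labels=tuple(model.species[int(k)] for k in labels),
        posteriors=post,
    )
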