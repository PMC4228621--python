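"""Glue between libraries, filters and the classifier.

Small conveniences for the common end-to-end paths: measure a library's
pulses into a classifier-ready feature matrix, either without selection
rules (plain extraction at a chosen Body Over) or through a filter.
"""

from __future__ import annotations

import pandas as pd

from . import pulse_metrics as pm
from .classifier import FeatureMatrix
from .filter_engine import FilterResult, FilterSpec, apply_filter
from .zc_data import CallLibrary, SegmentationConfig

__all__ = ["feature_matrix_from_library", "feature_matrix_from_result"]


def _to_matrix(df: pd.DataFrame, features, species_order, min_pulses: int,
               min_seqs_per_species: int = 0) -> FeatureMatrix:
    df = df[df["species"].notna()]
    if min_pulses:
        counts = df.groupby("seq_id")["pulse_id"].size()
        df = df[df["seq_id"].map(counts) >= min_pulses]
    if min_seqs_per_species:
        # a species needs enough retained sequences to be fit and refit
        seq_counts = df.drop_duplicates("seq_id").groupby("species")["seq_id"].size()
        ok = seq_counts[seq_counts >= min_seqs_per_species].index
        df = df[df["species"].isin(ok)]
    if species_order is None:
        species_order = tuple(sorted(df["species"].unique()))
    return FeatureMatrix.from_dataframe(df, features=features, species_order=species_order)


def feature_matrix_from_library(
    library: CallLibrary,
    body_over_us: float = 2000.0,
    features=tuple(pm.CLASSIFIER_FEATURES),
    species_order: tuple[str, ...] | None = None,
    seg_cfg: SegmentationConfig | None = None,
    min_pulses: int = 5,
    min_seqs_per_species: int = 0,
) -> FeatureMatrix:
    """Measure every labelled pulse of a library (no selection rules).

    Sequences with fewer than ``min_pulses`` pulses are dropped so the
    sequence-level invariant holds; species left with fewer than
    ``min_seqs_per_species`` sequences can optionally be dropped too.
    """
    df = pm.features_table(library, body_over_us, seg_cfg)
    return _to_matrix(df, features, species_order, min_pulses, min_seqs_per_species)


def feature_matrix_from_result(
    result: FilterResult,
    features=tuple(pm.CLASSIFIER_FEATURES),
    species_order: tuple[str, ...] | None = None,
    min_pulses: int = 5,
    min_seqs_per_species: int = 0,
) -> FeatureMatrix:
    """Classifier matrix from the retained pulses of a filter run."""
    return _to_matrix(result.features, features, species_order, min_pulses,
                      min_seqs_per_species)


def filter_and_features(
    library: CallLibrary,
    spec: FilterSpec,
    **kwargs,
) -> tuple[FilterResult, FeatureMatrix]:
    res = apply_filter(library, spec)
    return res, feature_matrix_from_result(res, **kwargs)
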