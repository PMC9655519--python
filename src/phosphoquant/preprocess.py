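"""Normalization, noise-floor imputation and quantifiability filtering.

The estimator classes follow the scikit-learn convention: ``X`` is a
(n_samples, n_features) array with NaN marking missing values, ``y`` (where
needed) is the per-sample condition label.  The module-level functions are
thin wrappers that apply the estimators to an :class:`~phosphoquant.io.
IntensityTable` (stored features x samples) together with a
:class:`~phosphoquant.io.SampleDesign`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import DataError, IntensityTable, SampleDesign, PROTEIN_GROUP


@dataclass(frozen=True)
class NormalizationReport:
    """Per-sample medians, the reference value and the scale factors applied."""

    sample_medians: dict[str, float]
    reference: float
    scale_factors: dict[str, float]


@dataclass(frozen=True)
class NoiseFloor:
    """The constant imputation value for one condition."""

    condition: str
    level: float
    value: float


def _as_array(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DataError("expected a 2-D intensity matrix")
    if np.nanmin(X, initial=0.0) < 0:
        raise DataError("negative intensities are not allowed")
    return X


class MedianOfMediansNormalizer(TransformerMixin, BaseEstimator):
    """Scale each sample so observed medians meet at the median of medians.

    For sample ``s`` with observed median ``m_s``, the reference is
    ``M = median(m_s)`` and the factor ``k_s = M / m_s`` multiplies every
    observed value of that sample; missing entries are untouched.  With
    ``reference="conditions"`` the reference is instead the median of the
    per-condition medians (each condition median being the median of its
    samples' medians), which requires ``y``.

    Attributes
    ----------
    sample_medians_ : ndarray of shape (n_samples,)
    reference_ : float
    scale_factors_ : ndarray of shape (n_samples,)
    """

    def __init__(self, reference: str = "samples"):
        self.reference = reference

    def fit(self, X, y=None):
        X = _as_array(X)
        if self.reference not in ("samples", "conditions"):
            raise DataError(f"unknown normalization reference {self.reference!r}")
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            medians = np.nanmedian(X, axis=1)
        if np.isnan(medians).any():
            bad = int(np.flatnonzero(np.isnan(medians))[0])
            raise DataError(f"sample at row {bad} has no observed values")
        if self.reference == "samples":
            ref = float(np.median(medians))
        else:
            if y is None:
                raise DataError("reference='conditions' requires condition labels y")
            y = np.asarray(y)
            cond_medians = [
                float(np.median(medians[y == c])) for c in dict.fromkeys(y)
            ]
            ref = float(np.median(cond_medians))
        self.sample_medians_ = medians
        self.reference_ = ref
        self.scale_factors_ = ref / medians
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_factors_")
        X = _as_array(X)
        if X.shape[0] != self.scale_factors_.shape[0]:
            raise DataError("sample count differs from fit")
        return X * self.scale_factors_[:, None]


class NoiseFloorImputer(TransformerMixin, BaseEstimator):
    """Replace missing intensities by a low quantile of the observed values.

    For each condition ``c`` (labels in ``y``), the floor is the ``level``
    quantile — linear interpolation between order statistics by default,
    ``method="nearest-rank"`` for the nearest-rank definition — of *all*
    observed values pooled across that condition's samples and features.
    Every missing cell in condition ``c`` is set to that single constant,
    which is why imputed rows of an exported table repeat one identical
    value per condition.

    Attributes
    ----------
    floors_ : dict mapping condition label to its noise floor
    """

    def __init__(self, level: float = 0.01, method: str = "linear"):
        self.level = level
        self.method = method

    def fit(self, X, y=None):
        X = _as_array(X)
        if y is None:
            raise DataError("condition labels y are required")
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise DataError("y length differs from the number of samples")
        if not 0 <= self.level <= 1:
            raise DataError("quantile level must lie in [0, 1]")
        interp = {"linear": "linear", "nearest-rank": "inverted_cdf"}.get(self.method)
        if interp is None:
            raise DataError(f"unknown quantile method {self.method!r}")
        floors: dict = {}
        for cond in dict.fromkeys(y):
            vals = X[y == cond]
            obs = vals[~np.isnan(vals)]
            if obs.size == 0:
                raise DataError(f"condition {cond!r} has no observed values")
            floors[str(cond)] = float(np.quantile(obs, self.level, method=interp))
        self.floors_ = floors
        self.conditions_ = y.copy()
        return self

    def transform(self, X):
        check_is_fitted(self, "floors_")
        X = _as_array(X).copy()
        if X.shape[0] != self.conditions_.shape[0]:
            raise DataError("sample count differs from fit")
        for i, cond in enumerate(self.conditions_):
            row = X[i]
            row[np.isnan(row)] = self.floors_[cond]
        return X


class QuantifiabilityFilter(TransformerMixin, BaseEstimator):
    """Keep features observed often enough in at least one condition.

    A feature is quantifiable when it has at least ``min_values`` observed
    (pre-imputation) intensities in condition A *or* in condition B; protein
    groups additionally require ``peptide_counts >= min_peptides``.  The
    decision uses raw missingness only, never imputed values.
    """

    def __init__(
        self,
        min_values: int = 3,
        min_peptides: int = 2,
        peptide_counts=None,
    ):
        self.min_values = min_values
        self.min_peptides = min_peptides
        self.peptide_counts = peptide_counts

    def fit(self, X, y=None):
        X = _as_array(X)
        if y is None:
            raise DataError("condition labels y are required")
        y = np.asarray(y)
        conds = list(dict.fromkeys(y))
        if len(conds) != 2:
            raise DataError(f"expected exactly two conditions, got {conds}")
        n_a = int((y == conds[0]).sum())
        n_b = int((y == conds[1]).sum())
        if self.min_values > max(n_a, n_b):
            raise DataError(
                f"min_values={self.min_values} exceeds the sample count of both "
                f"conditions ({n_a}, {n_b})"
            )
        obs = ~np.isnan(X)
        count_a = obs[y == conds[0]].sum(axis=0)
        count_b = obs[y == conds[1]].sum(axis=0)
        support = (count_a >= self.min_values) | (count_b >= self.min_values)
        if self.peptide_counts is not None:
            pc = np.asarray(self.peptide_counts)
            if pc.shape[0] != X.shape[1]:
                raise DataError("peptide_counts length differs from feature count")
            support &= pc >= self.min_peptides
        self.support_ = support
        self.n_identified_ = int(X.shape[1])
        self.n_quantified_ = int(support.sum())
        return self

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = _as_array(X)
        return X[:, self.support_]


# ---------------------------------------------------------------------------
# IntensityTable wrappers


def normalize_median_of_medians(
    table: IntensityTable, reference: str = "samples", design: SampleDesign | None = None
) -> tuple[IntensityTable, NormalizationReport]:
    """Normalize a table so every sample's observed median equals the
    median of the per-sample medians."""
    if table.normalized:
        raise DataError("table is already normalized")
    est = MedianOfMediansNormalizer(reference=reference)
    y = None
    if reference == "conditions":
        if design is None:
            raise DataError("reference='conditions' requires a sample design")
        y = [design.condition_of(s) for s in table.sample_ids]
    X = table.values.to_numpy(dtype=float).T
    try:
        scaled = est.fit(X, y).transform(X)
    except DataError as exc:
        if "has no observed values" in str(exc):
            row = int(str(exc).split("row ")[1].split(" ")[0])
            raise DataError(
                f"sample {table.sample_ids[row]!r} has no observed values"
            ) from exc
        raise
    values = pd.DataFrame(scaled.T, index=table.values.index, columns=table.values.columns)
    report = NormalizationReport(
        sample_medians=dict(zip(table.sample_ids, map(float, est.sample_medians_))),
        reference=est.reference_,
        scale_factors=dict(zip(table.sample_ids, map(float, est.scale_factors_))),
    )
    out = IntensityTable(
        values=values, metadata=table.metadata.copy(), kind=table.kind,
        normalized=True, imputed=None if table.imputed is None else table.imputed.copy(),
    )
    return out, report


def impute_noise_percentile(
    table: IntensityTable,
    design: SampleDesign,
    level: float = 0.01,
    method: str = "linear",
) -> tuple[IntensityTable, list[NoiseFloor]]:
    """Fill missing cells with each condition's noise floor (the ``level``
    quantile of that condition's pooled observed values)."""
    if not table.normalized:
        raise DataError("impute after normalization, not before")
    sids = table.sample_ids
    y = np.array([design.condition_of(s) for s in sids])
    X = table.values.to_numpy(dtype=float).T
    est = NoiseFloorImputer(level=level, method=method)
    filled = est.fit(X, y).transform(X)
    values = pd.DataFrame(filled.T, index=table.values.index, columns=table.values.columns)
    newly = table.values.isna()
    imputed = newly if table.imputed is None else (table.imputed | newly)
    floors = [NoiseFloor(condition=c, level=level, value=v) for c, v in est.floors_.items()]
    out = IntensityTable(
        values=values, metadata=table.metadata.copy(), kind=table.kind,
        normalized=True, imputed=imputed,
    )
    return out, floors


@dataclass(frozen=True)
class FilterReport:
    n_identified: int
    n_quantified: int
    n_failed_support: int
    n_failed_peptides: int


def filter_quantifiable(
    table: IntensityTable,
    design: SampleDesign,
    pair: tuple[str, str],
    min_values: int = 3,
    min_peptides: int = 2,
) -> tuple[IntensityTable, FilterReport]:
    """Apply the quantifiability rule for one pairwise comparison.

    Uses pre-imputation missingness (observed cells only).  Protein-group
    tables additionally enforce the peptide-count minimum.
    """
    cond_a, cond_b = pair
    samples = design.samples_for(cond_a) + design.samples_for(cond_b)
    y = np.array([cond_a] * len(design.samples_for(cond_a)) +
                 [cond_b] * len(design.samples_for(cond_b)))
    obs = table.observed_mask()[samples]
    X = obs.to_numpy().astype(float)
    X[X == 0] = np.nan  # filter estimator counts non-NaN cells
    pc = None
    if table.kind == PROTEIN_GROUP:
        pc = table.metadata["peptide_count"].to_numpy()
    est = QuantifiabilityFilter(
        min_values=min_values, min_peptides=min_peptides, peptide_counts=pc
    )
    est.fit(X.T, y)
    support = est.support_
    # decompose failures for the report
    count_ok = (
        (obs[design.samples_for(cond_a)].sum(axis=1) >= min_values)
        | (obs[design.samples_for(cond_b)].sum(axis=1) >= min_values)
    ).to_numpy()
    pep_ok = np.ones_like(count_ok) if pc is None else (pc >= min_peptides)
    report = FilterReport(
        n_identified=len(table.values),
        n_quantified=int(support.sum()),
        n_failed_support=int((~count_ok).sum()),
        n_failed_peptides=int((count_ok & ~pep_ok).sum()),
    )
    kept = table.values.index[support]
    return table.subset_features(kept), report
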