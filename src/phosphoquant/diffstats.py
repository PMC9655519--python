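"""Differential-abundance statistics: empirical-Bayes moderated t, BH FDR,
log2-fold-change z-scores and the volcano / variant classifications.

The moderated t-test shrinks each feature's sample variance toward a prior
``s0^2`` with ``d0`` prior degrees of freedom, estimated across all features
by moment-matching the log sample variances against a scaled-F model.  With
``d0 = 0`` the statistic reduces to the classical pooled two-sample t; as
``d0 -> inf`` it approaches a known-variance z-test with variance ``s0^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import DataError


@dataclass(frozen=True)
class VariancePrior:
    """Empirical-Bayes variance prior: ``s_g^2 ~ s0_sq * d0 / chi2(d0)``."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise DataError("prior degrees of freedom must be >= 0")
        if not (self.s0_sq > 0 and math.isfinite(self.s0_sq)):
            raise DataError("prior variance must be positive and finite")


@dataclass(frozen=True)
class Thresholds:
    """Significance cutoffs; defaults are the workflow's standard values."""

    q_max: float = 0.05
    z_abs: float = 1.96
    volcano_log2fc: float = 1.17
    volcano_p: float = 0.05

    def __post_init__(self) -> None:
        for name in ("q_max", "z_abs", "volcano_log2fc", "volcano_p"):
            if getattr(self, name) <= 0:
                raise DataError(f"threshold {name} must be positive")


UP, DOWN, NS = "up", "down", "not_significant"


def log2_fold_change(mean_a: float, mean_b: float) -> tuple[float, float]:
    """Ratio B/A and its log2, from post-imputation condition means.

    Returns ``(ratio, log2fc)``; the direction-resolved fold is
    ``max(ratio, 1/ratio)``.
    """
    if mean_a <= 0 or mean_b <= 0:
        raise DataError("condition means must be positive after imputation")
    ratio = mean_b / mean_a
    return ratio, math.log2(ratio)


def _trigamma(x):
    return special.polygamma(1, x)


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Uses the asymptotic bounds 1/x < y < 1/x + 1 to start; converges in a
    handful of iterations for any positive x.
    """
    if x <= 0:
        raise DataError("trigamma inverse requires a positive argument")
    if x > 1e7:  # trigamma(y) ~ 1/y near 0
        return 1.0 / math.sqrt(x)
    if x < 1e-6:  # trigamma(y) ~ 1/y for large y
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(_trigamma(y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return y


def fit_variance_prior(sample_variances, residual_df: int) -> VariancePrior:
    """Estimate (d0, s0^2) by moment-matching log sample variances.

    Each variance is modelled as ``s_g^2 ~ s0^2 * F(d_g, d0)``; on the log
    scale the excess spread of ``log s_g^2`` beyond ``trigamma(d_g/2)``
    identifies ``d0`` through the trigamma inverse, and the mean identifies
    ``s0^2`` through digamma corrections.  A non-positive excess yields
    ``d0 = +inf`` with ``s0^2`` the bias-corrected geometric mean.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    if residual_df < 1:
        raise DataError("residual degrees of freedom must be >= 1")
    if np.all(s2 <= 0):
        raise DataError("all sample variances are zero; nothing to moderate")
    s2 = s2[s2 > 0]
    if s2.size < 2:
        # a single informative variance: no spread to match, infinite shrinkage
        return VariancePrior(d0=math.inf, s0_sq=float(s2[0]))
    d = float(residual_df)
    z = np.log(s2)
    e = z - float(special.digamma(d / 2.0)) + math.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(_trigamma(d / 2.0))
    if excess > 0:
        half_d0 = _trigamma_inverse(excess)
        d0 = 2.0 * half_d0
        s0_sq = math.exp(e_mean + float(special.digamma(half_d0)) - math.log(half_d0))
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def _group_stats(X: np.ndarray, y: np.ndarray, pair: tuple[str, str]):
    cond_a, cond_b = pair
    A = X[y == cond_a]
    B = X[y == cond_b]
    n_a, n_b = A.shape[0], B.shape[0]
    if n_a < 2 or n_b < 2:
        raise DataError(
            f"both conditions need >= 2 samples (got {n_a} for {cond_a!r}, "
            f"{n_b} for {cond_b!r}); per-feature variance is undefined otherwise"
        )
    mean_a = A.mean(axis=0)
    mean_b = B.mean(axis=0)
    var_a = A.var(axis=0, ddof=1)
    var_b = B.var(axis=0, ddof=1)
    df = n_a + n_b - 2
    pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
    return mean_a, mean_b, pooled, df, n_a, n_b


def moderated_t_test(
    X,
    y,
    pair: tuple[str, str],
    prior: VariancePrior,
):
    """Per-feature moderated t on a log2 (samples x features) matrix.

    Posterior variance ``(d0*s0^2 + d_g*s_g^2) / (d0 + d_g)``; two-sided p
    from Student's t with ``d0 + d_g`` degrees of freedom (standard normal
    when ``d0`` is infinite).  Returns ``(t_mod, p, df_total)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    mean_a, mean_b, s2, df, n_a, n_b = _group_stats(X, y, pair)
    se_scale = math.sqrt(1.0 / n_a + 1.0 / n_b)
    if math.isinf(prior.d0):
        s_post = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    else:
        s_post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_b - mean_a) / (np.sqrt(s_post) * se_scale)
    t = np.where((mean_b - mean_a) == 0, 0.0, t)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p, df_total


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Stable sort on (p, position) so ties are handled deterministically;
    monotonicity is enforced by the running minimum from the largest p down.
    ``q >= p`` elementwise.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise DataError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DataError("p-values must be finite and in [0, 1]")
    n = p.size
    order = np.lexsort((np.arange(n), p))  # stable in p, then position
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def zscore_logfc(log2fc, robust: bool = False) -> np.ndarray:
    """Standardize log2 fold changes across the comparison's features.

    ``z = (L - center) / scale`` with mean/SD by default, or median and
    1.4826*MAD with ``robust=True``.
    """
    L = np.asarray(log2fc, dtype=float)
    if L.size < 2:
        raise DataError("z-scores need at least two features")
    if robust:
        center = float(np.median(L))
        scale = 1.4826 * float(np.median(np.abs(L - center)))
    else:
        center = float(np.mean(L))
        scale = float(np.std(L))
    if scale <= 0:
        raise DataError(
            "log2 fold changes have zero spread; z-scores are undefined on "
            "this degenerate input"
        )
    return (L - center) / scale


def call_variants(q, z, thresholds: Thresholds = Thresholds()) -> np.ndarray:
    """Dual criterion: significant if ``q < q_max`` and ``|z| >= z_abs``."""
    q = np.asarray(q, dtype=float)
    z = np.asarray(z, dtype=float)
    if q.shape != z.shape:
        raise DataError("q and z are not aligned")
    labels = np.full(q.shape, NS, dtype=object)
    sig = q < thresholds.q_max
    labels[sig & (z >= thresholds.z_abs)] = UP
    labels[sig & (z <= -thresholds.z_abs)] = DOWN
    return labels


def classify_volcano(log2fc, p, thresholds: Thresholds = Thresholds()) -> np.ndarray:
    """Volcano classification: ``|log2fc| >= volcano_log2fc`` and ``p < volcano_p``."""
    L = np.asarray(log2fc, dtype=float)
    p = np.asarray(p, dtype=float)
    if L.shape != p.shape:
        raise DataError("log2fc and p are not aligned")
    labels = np.full(L.shape, NS, dtype=object)
    sig = p < thresholds.volcano_p
    labels[sig & (L >= thresholds.volcano_log2fc)] = UP
    labels[sig & (L <= -thresholds.volcano_log2fc)] = DOWN
    return labels


def heatmap_matrix(values, variant_ids, log2fc_by_id):
    """Log10 intensity matrix of variant features, rows ordered by
    descending log2 fold change.

    Parameters
    ----------
    values : pandas.DataFrame
        Post-imputation intensities, features x samples.
    variant_ids : sequence of feature ids
    log2fc_by_id : mapping feature id -> log2fc (ordering key)
    """
    import pandas as pd
    import warnings

    ids = list(variant_ids)
    if not ids:
        warnings.warn("empty variant set: returning an empty heatmap matrix")
        return pd.DataFrame(columns=values.columns)
    ordered = sorted(ids, key=lambda f: -log2fc_by_id[f])
    sub = values.loc[ordered]
    if (sub.to_numpy() <= 0).any():
        raise DataError("heatmap requires positive (post-imputation) intensities")
    return np.log10(sub)


class ModeratedTTest(BaseEstimator):
    """Two-group empirical-Bayes moderated t-test as a sklearn estimator.

    ``fit(X, y)`` takes a log2-scale (n_samples, n_features) matrix and a
    condition label per sample; exactly two distinct labels are expected and
    the pair order (reference, treatment) follows first appearance unless
    ``pair`` is given.  With ``d0``/``s0_sq`` left ``None``, the variance
    prior is estimated from the data by moment matching.

    Attributes
    ----------
    prior_ : VariancePrior
    mean_a_, mean_b_ : ndarray, per-feature group means (log2 scale)
    t_, p_, q_ : ndarray, moderated t, two-sided p, BH-adjusted q
    df_total_ : float, posterior degrees of freedom
    """

    def __init__(self, pair=None, d0=None, s0_sq=None):
        self.pair = pair
        self.d0 = d0
        self.s0_sq = s0_sq

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        labels = list(dict.fromkeys(y))
        if len(labels) != 2:
            raise DataError(f"expected exactly two conditions, got {labels}")
        pair = tuple(self.pair) if self.pair is not None else tuple(labels)
        mean_a, mean_b, s2, df, _, _ = _group_stats(X, y, pair)
        if (self.d0 is None) != (self.s0_sq is None):
            raise DataError("fix both d0 and s0_sq or neither")
        if self.d0 is not None:
            prior = VariancePrior(d0=float(self.d0), s0_sq=float(self.s0_sq))
        else:
            prior = fit_variance_prior(s2, residual_df=df)
        t, p, df_total = moderated_t_test(X, y, pair, prior)
        self.pair_ = pair
        self.prior_ = prior
        self.mean_a_ = mean_a
        self.mean_b_ = mean_b
        self.residual_df_ = df
        self.df_total_ = df_total
        self.t_ = t
        self.p_ = p
        self.q_ = bh_adjust(p)
        return self

    def score(self, X=None, y=None):
        """Fraction of features significant at q < 0.05 (descriptive)."""
        check_is_fitted(self, "q_")
        return float(np.mean(self.q_ < 0.05))
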