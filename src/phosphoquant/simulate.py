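"""Synthetic MaxQuant-style intensity data with the statistical structure
the analysis assumes.

The generator emulates label-free MS1 quantification of a three-condition
treatment design: log-normal feature intensities around a baseline, inverse-
chi-square per-feature variances matching the empirical-Bayes prior of the
moderated t-test, a planted fraction of differential features with known
log2 effects, and intensity-dependent (left-censored) missingness through a
logistic detection model — low-abundance measurements are the ones that drop
out, the regime the noise-floor imputation targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import DataError, IntensityTable, SampleDesign, MOD_PEPTIDE, PROTEIN_GROUP
from .phospho import PhosphoFeature, PHOSPHO_RESIDUES


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one synthetic dataset.

    Defaults model the study design this workflow targets: three conditions
    (control, stimulated, stimulated+inhibited) measured in three independent
    experiments, baseline log2 intensity ~ N(21, 2^2) (ion counts around
    2e6, the scale of typical LFQ tables), per-feature variances drawn from
    ``s0_sq * d0 / chi2(d0)`` with (d0, s0_sq) = (4, 0.05), and a logistic
    detection curve with midpoint ``baseline_mean - 4`` and scale 1.5
    yielding ~10% missing cells concentrated at low abundance.
    """

    n_features: int = 1000
    conditions: tuple[str, ...] = ("DMSO", "Fsk", "Fsk+AICAR")
    n_experiments: int = 3
    n_replicates: int = 1
    baseline_mean: float = 21.0
    baseline_sd: float = 2.0
    d0: float = 4.0
    s0_sq: float = 0.05
    diff_fraction: float = 0.05
    effect_log2_mean: float = 0.0
    effect_log2_sd: float = 1.5
    effect_log2_fixed: float | None = None
    missing_midpoint: float | None = None  # default baseline_mean - 4
    missing_scale: float = 1.5
    mcar_rate: float | None = None  # switch: uniform missingness instead of MNAR
    kind: str = MOD_PEPTIDE
    peptide_count_mean: float = 4.0  # protein-group tables only
    serine_fraction: float = 0.85
    threonine_fraction: float = 0.13
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise DataError("n_features must be positive")
        if len(self.conditions) < 1:
            raise DataError("at least one condition is required")
        if self.n_experiments * self.n_replicates < 2:
            raise DataError("need >= 2 replicates per condition")
        if not 0 <= self.diff_fraction <= 1:
            raise DataError("diff_fraction must lie in [0, 1]")
        if not 0 <= self.serine_fraction + self.threonine_fraction <= 1:
            raise DataError("S/T/Y fractions must sum to at most 1")
        if self.d0 <= 0 or self.s0_sq <= 0:
            raise DataError("variance prior parameters must be positive")
        if self.mcar_rate is not None and not 0 <= self.mcar_rate <= 1:
            raise DataError("mcar_rate must lie in [0, 1]")
        if self.seed is None:
            raise DataError("a seed is mandatory for reproducibility")

    @property
    def midpoint(self) -> float:
        return (
            self.baseline_mean - 4.0
            if self.missing_midpoint is None
            else self.missing_midpoint
        )

    @property
    def n_per_condition(self) -> int:
        return self.n_experiments * self.n_replicates


def _make_design(config: SyntheticConfig) -> SampleDesign:
    rows = []
    for cond in config.conditions:
        tag = cond.replace("+", "").replace(" ", "")
        for exp in range(1, config.n_experiments + 1):
            for rep in range(1, config.n_replicates + 1):
                sid = f"{tag}_e{exp}r{rep}"
                rows.append((sid, cond, exp, rep))
    return SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "condition", "experiment", "replicate"])
    )


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[IntensityTable, SampleDesign, pd.DataFrame]:
    """Generate an intensity table, its design and the ground-truth table.

    The truth table records, per feature, the baseline log2 intensity, the
    true residual variance, differential status and the planted log2 effect
    (applied to every non-control condition).  Identical seeds give
    identical output.
    """
    rng = np.random.default_rng(config.seed)
    design = _make_design(config)
    n = config.n_features
    feature_ids = [f"F{i:05d}" for i in range(n)]

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    # scaled inverse chi-square: s0_sq * d0 / chi2(d0)
    sigma2 = config.s0_sq * config.d0 / rng.chisquare(config.d0, size=n)
    n_diff = int(round(config.diff_fraction * n))
    diff_idx = rng.choice(n, size=n_diff, replace=False)
    is_diff = np.zeros(n, dtype=bool)
    is_diff[diff_idx] = True
    if config.effect_log2_fixed is not None:
        effects = np.where(is_diff, config.effect_log2_fixed, 0.0)
    else:
        drawn = rng.normal(config.effect_log2_mean, config.effect_log2_sd, size=n)
        effects = np.where(is_diff, drawn, 0.0)

    control = config.conditions[0]
    latent = {}
    for cond in config.conditions:
        shift = 0.0 if cond == control else effects
        for sid in design.samples_for(cond):
            latent[sid] = baseline + shift + rng.normal(0.0, np.sqrt(sigma2), size=n)
    latent_mat = pd.DataFrame(latent, index=pd.Index(feature_ids, name="feature_id"))

    if config.mcar_rate is not None:
        detected = rng.random(latent_mat.shape) >= config.mcar_rate
    else:
        p_detect = expit((latent_mat.to_numpy() - config.midpoint) / config.missing_scale)
        detected = rng.random(latent_mat.shape) < p_detect

    values = np.power(2.0, latent_mat.to_numpy())
    values[~detected] = np.nan
    values = pd.DataFrame(values, index=latent_mat.index, columns=latent_mat.columns)

    meta = pd.DataFrame(index=latent_mat.index)
    meta["accession"] = [f"P{i:05d}" for i in range(n)]
    meta["gene"] = [f"Gene{i}" for i in range(n)]
    meta["protein"] = [f"Protein {i}" for i in range(n)]
    if config.kind == PROTEIN_GROUP:
        meta["peptide_count"] = 1 + rng.poisson(config.peptide_count_mean - 1, size=n)
    else:
        meta["sequence"] = ""
        meta["modifications"] = "Phospho (STY)"

    truth = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "baseline_log2": baseline,
            "sigma2": sigma2,
            "is_differential": is_diff,
            "log2_effect": effects,
        }
    ).set_index("feature_id")

    table = IntensityTable(values=values, metadata=meta, kind=config.kind)
    return table, design, truth


_NON_TERMINAL = tuple(sorted(set("ACDEFGHILMNPQVW")))  # no K/R/S/T/Y


def _random_peptide(rng: np.random.Generator, config: SyntheticConfig) -> tuple[str, int]:
    """Tryptic-like peptide (K/R C-terminus, length 7-35) with a phosphosite.

    The site residue is S with probability ``serine_fraction``, T with
    ``threonine_fraction``, else Y; extra S/T/Y may appear elsewhere.
    """
    length = int(rng.integers(7, 36))
    body = rng.choice(_NON_TERMINAL, size=length - 1)
    # sprinkle additional S/T/Y so secondary candidate sites exist
    n_extra = int(rng.integers(0, max(2, length // 6)))
    for pos in rng.integers(0, length - 1, size=n_extra):
        body[pos] = rng.choice(("S", "T", "Y"))
    u = rng.random()
    if u < config.serine_fraction:
        site_res = "S"
    elif u < config.serine_fraction + config.threonine_fraction:
        site_res = "T"
    else:
        site_res = "Y"
    site = int(rng.integers(0, length - 1))
    body[site] = site_res
    terminal = "K" if rng.random() < 0.5 else "R"
    return "".join(body) + terminal, site


def generate_phospho_metadata(
    table: IntensityTable, config: SyntheticConfig
) -> tuple[IntensityTable, list[PhosphoFeature]]:
    """Attach random tryptic peptide sequences and site probabilities.

    The intended site gets a dominant localization probability (0.75-1);
    any other S/T/Y shares the remainder.  Returns a copy of the table with
    sequences filled into the metadata plus the PhosphoFeature list.
    """
    if table.kind != MOD_PEPTIDE:
        raise DataError("phospho metadata applies to mod-peptide tables")
    rng = np.random.default_rng(config.seed + 1)
    features = []
    sequences = []
    for fid, acc, gene in zip(
        table.feature_ids, table.metadata["accession"], table.metadata["gene"]
    ):
        seq, site = _random_peptide(rng, config)
        top = float(rng.uniform(0.75, 1.0))
        others = [
            i for i, aa in enumerate(seq[:-1])
            if aa in PHOSPHO_RESIDUES and i != site
        ]
        probs = {site: top}
        if others:
            rest = (1.0 - top) * rng.dirichlet(np.ones(len(others)))
            for pos, pr in zip(others, rest):
                probs[pos] = float(pr)
        features.append(
            PhosphoFeature(
                feature_id=fid, sequence=seq, site_probs=probs,
                accession=acc, gene=gene,
            )
        )
        sequences.append(seq)
    out = IntensityTable(
        values=table.values.copy(),
        metadata=table.metadata.assign(sequence=sequences),
        kind=table.kind,
        normalized=table.normalized,
        imputed=None if table.imputed is None else table.imputed.copy(),
    )
    return out, features


def expected_missing_fraction(config: SyntheticConfig, n_mc: int = 200_000,
                              seed: int = 12345) -> float:
    """Monte-Carlo expectation of the missing-cell fraction under the
    logistic detection model (marginalizing baseline, variance and effects)."""
    if config.mcar_rate is not None:
        return config.mcar_rate
    rng = np.random.default_rng(seed)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_mc)
    sigma2 = config.s0_sq * config.d0 / rng.chisquare(config.d0, size=n_mc)
    noise = rng.normal(0.0, np.sqrt(sigma2))
    # effects shift only non-control conditions; weight accordingly
    n_cond = len(config.conditions)
    x0 = baseline + noise
    p_missing_ctl = 1.0 - expit((x0 - config.midpoint) / config.missing_scale)
    if n_cond == 1:
        return float(np.mean(p_missing_ctl))
    if config.effect_log2_fixed is not None:
        eff = np.full(n_mc, config.effect_log2_fixed)
    else:
        eff = rng.normal(config.effect_log2_mean, config.effect_log2_sd, size=n_mc)
    eff = np.where(rng.random(n_mc) < config.diff_fraction, eff, 0.0)
    p_missing_trt = 1.0 - expit((x0 + eff - config.midpoint) / config.missing_scale)
    w_ctl = 1.0 / n_cond
    return float(w_ctl * np.mean(p_missing_ctl) + (1 - w_ctl) * np.mean(p_missing_trt))
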