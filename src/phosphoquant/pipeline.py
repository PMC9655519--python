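"""End-to-end orchestration of the pairwise differential-abundance analysis.

For each condition pair the pipeline runs: read -> normalize -> filter
(on raw missingness) -> impute -> log2 -> variance-prior fit -> moderated t
-> BH -> z-score -> variant call -> volcano class -> heatmap matrix ->
export, and records every parameter and count in a run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__ as _version
from .diffstats import (
    ModeratedTTest,
    Thresholds,
    call_variants,
    classify_volcano,
    heatmap_matrix,
    log2_fold_change,
    zscore_logfc,
)
from .io import (
    ComparisonResult,
    DataError,
    IntensityTable,
    SampleDesign,
    write_results_tsv,
)
from .preprocess import (
    FilterReport,
    NoiseFloor,
    NormalizationReport,
    filter_quantifiable,
    impute_noise_percentile,
    normalize_median_of_medians,
)

logger = logging.getLogger(__name__)

DEFAULT_COMPARISONS = (
    ("DMSO", "Fsk"),
    ("Fsk", "Fsk+AICAR"),
    ("DMSO", "Fsk+AICAR"),
)


@dataclass
class RunConfig:
    """Parameters of a full analysis run; defaults are the workflow's
    standard values."""

    comparisons: tuple = DEFAULT_COMPARISONS
    normalization_reference: str = "samples"
    impute_level: float = 0.01
    quantile_method: str = "linear"
    min_values: int = 3
    min_peptides: int = 2
    thresholds: Thresholds = field(default_factory=Thresholds)
    robust_z: bool = False
    d0: float | None = None
    s0_sq: float | None = None
    seed: int | None = None

    def validate(self, design: SampleDesign) -> None:
        known = set(design.conditions)
        for a, b in self.comparisons:
            if a not in known or b not in known:
                raise DataError(
                    f"comparison ({a!r}, {b!r}) references a condition absent "
                    f"from the design {sorted(known)}"
                )


@dataclass
class PairwiseOutput:
    pair: tuple[str, str]
    results: list[ComparisonResult]
    table: IntensityTable  # post-imputation, quantifiable features only
    normalization: NormalizationReport
    floors: list[NoiseFloor]
    filter_report: FilterReport
    heatmap: pd.DataFrame
    prior_d0: float
    prior_s0_sq: float

    def results_frame(self) -> pd.DataFrame:
        from .io import RESULT_COLUMNS

        return pd.DataFrame(
            [{c: getattr(r, c) for c in RESULT_COLUMNS} for r in self.results]
        )


def run_pairwise(
    table: IntensityTable,
    design: SampleDesign,
    pair: tuple[str, str],
    config: RunConfig | None = None,
) -> PairwiseOutput:
    """Run one pairwise comparison on a raw (unnormalized) intensity table.

    Normalization and imputation are computed on the two conditions of the
    pair only, so each comparison is self-contained.
    """
    config = config or RunConfig()
    cond_a, cond_b = pair
    sub_design = design.subset([cond_a, cond_b])
    sub = table.subset_samples(sub_design.sample_ids)

    stage = "normalize"
    try:
        normed, norm_report = normalize_median_of_medians(
            sub, reference=config.normalization_reference, design=sub_design
        )
        stage = "filter"
        filtered, filt_report = filter_quantifiable(
            normed, sub_design, pair,
            min_values=config.min_values,
            min_peptides=config.min_peptides if sub.kind == "protein_group" else 0,
        )
        stage = "impute"
        # floors come from the full normalized table; filling happens for
        # survivors and non-survivors alike, then survivors are carried on
        imputed_full, floors = impute_noise_percentile(
            normed, sub_design, level=config.impute_level,
            method=config.quantile_method,
        )
        imputed = imputed_full.subset_features(filtered.feature_ids)
        stage = "test"
        samples_a = sub_design.samples_for(cond_a)
        samples_b = sub_design.samples_for(cond_b)
        ordered = samples_a + samples_b
        y = np.array([cond_a] * len(samples_a) + [cond_b] * len(samples_b))
        raw = imputed.values[ordered]
        X_log2 = np.log2(raw.to_numpy(dtype=float)).T
        test = ModeratedTTest(pair=pair, d0=config.d0, s0_sq=config.s0_sq)
        test.fit(X_log2, y)

        stage = "classify"
        mean_a = raw[samples_a].mean(axis=1).to_numpy()
        mean_b = raw[samples_b].mean(axis=1).to_numpy()
        ratio_log2 = [log2_fold_change(a, b) for a, b in zip(mean_a, mean_b)]
        ratios = np.array([r for r, _ in ratio_log2])
        log2fc = np.array([l for _, l in ratio_log2])
        z = zscore_logfc(log2fc, robust=config.robust_z)
        variants = call_variants(test.q_, z, config.thresholds)
        volcano = classify_volcano(log2fc, test.p_, config.thresholds)

        ids = list(imputed.feature_ids)
        meta = imputed.metadata
        results = [
            ComparisonResult(
                feature_id=fid, condition_a=cond_a, condition_b=cond_b,
                mean_a=float(ma), mean_b=float(mb), ratio=float(r),
                log2fc=float(l), t_mod=float(t), p=float(p), q=float(q),
                z=float(zz), variant=str(v), volcano_class=str(vc),
                gene=str(meta.at[fid, "gene"]), protein=str(meta.at[fid, "protein"]),
            )
            for fid, ma, mb, r, l, t, p, q, zz, v, vc in zip(
                ids, mean_a, mean_b, ratios, log2fc, test.t_, test.p_,
                test.q_, z, variants, volcano,
            )
        ]

        stage = "heatmap"
        variant_ids = [r.feature_id for r in results if r.variant != "not_significant"]
        hm = heatmap_matrix(
            imputed.values[ordered], variant_ids,
            {r.feature_id: r.log2fc for r in results},
        )
    except DataError as exc:
        raise DataError(f"[stage {stage}] {exc}") from exc

    logger.info(
        "%s vs %s: %d identified, %d quantified, %d variants",
        cond_a, cond_b, filt_report.n_identified, filt_report.n_quantified,
        len(variant_ids),
    )
    return PairwiseOutput(
        pair=pair, results=results, table=imputed,
        normalization=norm_report, floors=floors, filter_report=filt_report,
        heatmap=hm, prior_d0=test.prior_.d0, prior_s0_sq=test.prior_.s0_sq,
    )


def run_analysis(
    table: IntensityTable,
    design: SampleDesign,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run every configured comparison; optionally export results + manifest.

    Returns a manifest dict (also written as ``manifest.json`` when *out_dir*
    is given) sufficient to reproduce the run: parameters, software version
    and per-comparison identified/quantified/significant counts.
    """
    config = config or RunConfig()
    config.validate(design)
    outputs: dict[tuple[str, str], PairwiseOutput] = {}
    manifest: dict = {
        "software": {"name": "phosphoquant", "version": _version},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": {
            "comparisons": [list(p) for p in config.comparisons],
            "normalization_reference": config.normalization_reference,
            "impute_level": config.impute_level,
            "quantile_method": config.quantile_method,
            "min_values": config.min_values,
            "min_peptides": config.min_peptides,
            "thresholds": asdict(config.thresholds),
            "robust_z": config.robust_z,
            "d0": config.d0,
            "s0_sq": config.s0_sq,
            "seed": config.seed,
        },
        "comparisons": {},
    }
    for pair in config.comparisons:
        out = run_pairwise(table, design, tuple(pair), config)
        outputs[tuple(pair)] = out
        n_sig = sum(r.variant != "not_significant" for r in out.results)
        n_up = sum(r.variant == "up" for r in out.results)
        n_down = sum(r.variant == "down" for r in out.results)
        key = f"{pair[0]}_vs_{pair[1]}"
        manifest["comparisons"][key] = {
            "n_identified": out.filter_report.n_identified,
            "n_quantified": out.filter_report.n_quantified,
            "n_variants": n_sig,
            "n_up": n_up,
            "n_down": n_down,
            "noise_floors": {f.condition: f.value for f in out.floors},
            "prior_d0": out.prior_d0 if np.isfinite(out.prior_d0) else "inf",
            "prior_s0_sq": out.prior_s0_sq,
        }
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            write_results_tsv(out.results, out_dir / f"results_{_slug(key)}.tsv")
            if not out.heatmap.empty:
                out.heatmap.to_csv(
                    out_dir / f"heatmap_{_slug(key)}.tsv", sep="\t",
                    index_label="feature_id",
                )
    if out_dir is not None:
        with open(Path(out_dir) / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    manifest["_outputs"] = outputs
    return manifest


def _slug(name: str) -> str:
    return name.replace("+", "").replace(" ", "").replace("/", "-")
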