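"""Phosphopeptide post-processing: site selection, consensus motifs,
unique-protein accounting and phospho-vs-total trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DataError, SampleDesign

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"
ALPHABET = AMINO_ACIDS + (GAP,)
PHOSPHO_RESIDUES = frozenset("STY")


@dataclass(frozen=True)
class PhosphoFeature:
    """A phosphopeptide with per-residue site localization probabilities.

    ``site_probs`` maps 0-based positions within the peptide to localization
    probabilities; only S/T/Y positions may carry probability.
    """

    feature_id: str
    sequence: str
    site_probs: dict[int, float]
    accession: str
    gene: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError("empty peptide sequence")
        for pos, prob in self.site_probs.items():
            if not 0 <= pos < len(self.sequence):
                raise DataError(f"site position {pos} outside peptide")
            if self.sequence[pos] not in PHOSPHO_RESIDUES:
                raise DataError(
                    f"position {pos} ({self.sequence[pos]}) is not S/T/Y"
                )
            if not 0 <= prob <= 1:
                raise DataError("localization probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class MotifMatrix:
    """Position-frequency matrix of peptides aligned on the phosphosite.

    Columns run over offsets -w..+w relative to the site; rows over the 20
    amino acids plus the gap symbol (positions beyond a peptide's ends).
    Every column sums to 1.
    """

    w: int
    frequencies: pd.DataFrame  # rows = ALPHABET, columns = offsets
    n_peptides: int

    def center_distribution(self) -> dict[str, float]:
        """Residue distribution at the phosphosite (offset 0)."""
        col = self.frequencies[0]
        return {aa: float(col[aa]) for aa in ("S", "T", "Y") if col[aa] > 0}


def pick_top_site(feature: PhosphoFeature) -> int:
    """Most probable phosphosite; ties broken by the lowest position."""
    candidates = [(pos, p) for pos, p in feature.site_probs.items() if p > 0]
    if not candidates:
        raise DataError(
            f"peptide {feature.sequence} has no S/T/Y with positive probability"
        )
    best = max(candidates, key=lambda item: (item[1], -item[0]))
    return best[0]


def build_motif_pfm(features, w: int = 7) -> MotifMatrix:
    """Align peptides on their top phosphosite and tally residues per offset.

    Offsets outside the peptide contribute the gap symbol, kept as its own
    category so short peptides do not inflate edge frequencies.
    """
    features = list(features)
    if not features:
        raise DataError("cannot build a motif from zero peptides")
    offsets = list(range(-w, w + 1))
    counts = pd.DataFrame(0.0, index=list(ALPHABET), columns=offsets)
    for feat in features:
        site = pick_top_site(feat)
        for off in offsets:
            pos = site + off
            if 0 <= pos < len(feat.sequence):
                counts.loc[feat.sequence[pos], off] += 1
            else:
                counts.loc[GAP, off] += 1
    freqs = counts / len(features)
    return MotifMatrix(w=w, frequencies=freqs, n_peptides=len(features))


@dataclass(frozen=True)
class MultiSiteProtein:
    accession: str
    peptide_ids: tuple[str, ...]
    directions: tuple[str, ...]
    divergent: bool


def count_unique_proteins(peptides) -> tuple[int, int, list[MultiSiteProtein]]:
    """Distinct-protein accounting over significant phosphopeptides.

    Parameters
    ----------
    peptides : iterable of (feature_id, accession, direction) triples or
        objects with those attributes.

    Returns ``(n_peptides, n_proteins, multi_site)`` where *multi_site* lists
    proteins with more than one significant phosphopeptide, flagging those
    whose peptides move in opposite directions.
    """
    rows = []
    for item in peptides:
        if isinstance(item, tuple):
            fid, acc, direction = item
        else:
            fid, acc, direction = item.feature_id, item.accession, item.variant
        rows.append((fid, acc, direction))
    by_protein: dict[str, list[tuple[str, str]]] = {}
    for fid, acc, direction in rows:
        by_protein.setdefault(acc, []).append((fid, direction))
    multi = []
    for acc, members in by_protein.items():
        if len(members) > 1:
            directions = tuple(d for _, d in members)
            real = {d for d in directions if d in ("up", "down")}
            multi.append(
                MultiSiteProtein(
                    accession=acc,
                    peptide_ids=tuple(f for f, _ in members),
                    directions=directions,
                    divergent=real == {"up", "down"},
                )
            )
    return len(rows), len(by_protein), multi


@dataclass(frozen=True)
class TrajectoryPoint:
    """Fold change of one feature in one condition relative to control."""

    condition: str
    phospho_fold: float
    phospho_sem: float
    total_fold: float
    total_sem: float


def _condition_folds(
    values: pd.Series, design: SampleDesign, condition: str, control_mean: float
) -> tuple[float, float]:
    """Overall fold for a condition plus the SEM over experiment-level folds."""
    samples = design.samples_for(condition)
    fold = float(values[samples].mean()) / control_mean
    per_exp = []
    for _, sids in sorted(design.experiments_for(condition).items()):
        per_exp.append(float(values[sids].mean()) / control_mean)
    if len(per_exp) > 1:
        sem = float(np.std(per_exp, ddof=1) / np.sqrt(len(per_exp)))
    else:
        sem = 0.0
    return fold, sem


def trajectory(
    phospho_values: pd.Series,
    protein_values: pd.Series,
    design: SampleDesign,
    control_condition: str,
) -> list[TrajectoryPoint]:
    """Per-condition fold changes of a phosphopeptide and its parent protein.

    Both series are post-imputation intensities indexed by sample id.  Every
    condition's mean is divided by the control condition's mean; the SEM is
    taken over experiment-level fold values.  The control's fold is 1 by
    construction.
    """
    for name, vals in (("phospho", phospho_values), ("protein", protein_values)):
        if vals[design.sample_ids].isna().any():
            raise DataError(f"{name} feature is not quantified in every sample")
    ctl_samples = design.samples_for(control_condition)
    ctl_phos = float(phospho_values[ctl_samples].mean())
    ctl_prot = float(protein_values[ctl_samples].mean())
    if ctl_phos <= 0 or ctl_prot <= 0:
        raise DataError("control condition mean must be positive")
    points = []
    for cond in design.conditions:
        pf, ps = _condition_folds(phospho_values, design, cond, ctl_phos)
        tf, ts = _condition_folds(protein_values, design, cond, ctl_prot)
        points.append(
            TrajectoryPoint(
                condition=cond, phospho_fold=pf, phospho_sem=ps,
                total_fold=tf, total_sem=ts,
            )
        )
    return points


def motif_to_tsv(motif: MotifMatrix, path) -> None:
    motif.frequencies.to_csv(path, sep="\t", index_label="residue")


def trajectories_to_tsv(named_points: dict[str, list[TrajectoryPoint]], path) -> None:
    """Tidy export: one row per (feature, condition, layer)."""
    rows = []
    for feature, points in named_points.items():
        for pt in points:
            rows.append((feature, pt.condition, "phospho", pt.phospho_fold, pt.phospho_sem))
            rows.append((feature, pt.condition, "total", pt.total_fold, pt.total_sem))
    frame = pd.DataFrame(rows, columns=["feature", "condition", "layer", "fold", "sem"])
    frame.to_csv(path, sep="\t", index=False)
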