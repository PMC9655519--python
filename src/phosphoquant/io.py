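"""Core data containers and tabular IO in the MaxQuant output dialect.

Intensity matrices are stored features x samples with ``NaN`` marking a
missing (non-detected) value.  MaxQuant writes ``0`` for non-detection, so
zeros and NaN in input files both map to missing on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROTEIN_GROUP = "protein_group"
MOD_PEPTIDE = "mod_peptide"
FEATURE_KINDS = (PROTEIN_GROUP, MOD_PEPTIDE)


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class SampleDesign:
    """Maps intensity columns to conditions and replicate structure.

    Parameters
    ----------
    frame : pandas.DataFrame
        One row per sample with columns ``sample_id``, ``condition``,
        ``experiment`` (integer batch index) and ``replicate``
        (within-experiment index).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "experiment", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DataError(f"sample design missing columns: {sorted(missing)}")
        ids = self.frame["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise DataError(f"duplicate sample_ids in design: {dupes}")
        if self.frame.empty:
            raise DataError("sample design is empty")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def conditions(self) -> list[str]:
        # preserve first-appearance order
        return list(dict.fromkeys(self.frame["condition"]))

    def samples_for(self, condition: str) -> list[str]:
        sel = self.frame["condition"] == condition
        out = list(self.frame.loc[sel, "sample_id"])
        if not out:
            raise DataError(f"condition {condition!r} not present in design")
        return out

    def condition_of(self, sample_id: str) -> str:
        sel = self.frame["sample_id"] == sample_id
        if not sel.any():
            raise DataError(f"sample {sample_id!r} not present in design")
        return self.frame.loc[sel, "condition"].iloc[0]

    def experiments_for(self, condition: str) -> dict[int, list[str]]:
        """Sample ids per experiment (batch) within one condition."""
        sel = self.frame[self.frame["condition"] == condition]
        out: dict[int, list[str]] = {}
        for exp, grp in sel.groupby("experiment"):
            out[int(exp)] = list(grp["sample_id"])
        return out

    def subset(self, conditions: Sequence[str]) -> "SampleDesign":
        sel = self.frame["condition"].isin(conditions)
        return SampleDesign(self.frame.loc[sel].reset_index(drop=True))


@dataclass
class IntensityTable:
    """Features x samples intensity matrix plus feature metadata.

    ``values`` holds nonnegative intensities with NaN for missing; ``imputed``
    (same shape, boolean) flags cells filled by noise-floor imputation.
    ``metadata`` is indexed by feature_id and carries accession, gene,
    protein name, ``peptide_count`` (protein groups) and ``sequence`` /
    ``modifications`` (mod-peptides) where applicable.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    kind: str
    normalized: bool = False
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise DataError(f"unknown feature kind {self.kind!r}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()][:5]
            raise DataError(f"duplicate feature_ids: {list(dupes)}")
        if not self.values.index.equals(self.metadata.index):
            raise DataError("values and metadata indexes differ")
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise DataError("negative intensities are not allowed")
        if self.imputed is not None and self.imputed.shape != self.values.shape:
            raise DataError("imputed mask shape mismatch")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def observed_mask(self) -> pd.DataFrame:
        """True where a value was actually measured (not missing, not imputed)."""
        obs = self.values.notna()
        if self.imputed is not None:
            obs &= ~self.imputed
        return obs

    def subset_samples(self, sample_ids: Sequence[str]) -> "IntensityTable":
        return IntensityTable(
            values=self.values[list(sample_ids)].copy(),
            metadata=self.metadata.copy(),
            kind=self.kind,
            normalized=self.normalized,
            imputed=None if self.imputed is None else self.imputed[list(sample_ids)].copy(),
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "IntensityTable":
        idx = pd.Index(feature_ids)
        return IntensityTable(
            values=self.values.loc[idx].copy(),
            metadata=self.metadata.loc[idx].copy(),
            kind=self.kind,
            normalized=self.normalized,
            imputed=None if self.imputed is None else self.imputed.loc[idx].copy(),
        )


@dataclass(frozen=True)
class ComparisonResult:
    """Differential statistics for one feature in one pairwise comparison."""

    feature_id: str
    condition_a: str
    condition_b: str
    mean_a: float
    mean_b: float
    ratio: float
    log2fc: float
    t_mod: float
    p: float
    q: float
    z: float
    variant: str
    volcano_class: str
    gene: str = ""
    protein: str = ""


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT-style) for over-representation analysis."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# readers / writers

_INTENSITY_PREFIX = "Intensity "
# MaxQuant decoy / contaminant conventions
_FLAG_COLUMNS = ("Reverse", "Potential contaminant", "Contaminant")
_ID_PREFIXES = ("REV__", "CON__")


def read_sample_design(path: str | Path) -> SampleDesign:
    """Read a sample design table (TSV or CSV by extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep)
    return SampleDesign(frame)


def _feature_ids(meta: pd.DataFrame, kind: str) -> pd.Index:
    if kind == PROTEIN_GROUP:
        # leading accession of the (possibly ;-separated) protein group
        ids = meta["accession"].str.split(";").str[0]
    else:
        acc = meta["accession"].str.split(";").str[0]
        mods = meta.get("modifications", pd.Series("", index=meta.index)).fillna("")
        ids = acc + "|" + meta["sequence"] + "|" + mods
    return pd.Index(ids, name="feature_id")


def read_intensity_table(
    path: str | Path,
    design: SampleDesign,
    kind: str,
    intensity_prefix: str = _INTENSITY_PREFIX,
    drop_decoys: bool = True,
) -> IntensityTable:
    """Read a MaxQuant-style TSV (proteinGroups or modificationSpecificPeptides).

    Intensity columns must be named ``"<prefix><sample_id>"`` for every sample
    in *design*; zeros and empty cells become the missing marker.  Reverse
    decoys and contaminants (``+`` flags or ``REV__``/``CON__`` id prefixes)
    are dropped by default and counted in the log.
    """
    if kind not in FEATURE_KINDS:
        raise DataError(f"unknown feature kind {kind!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    cols = {}
    for sid in design.sample_ids:
        col = f"{intensity_prefix}{sid}"
        if col not in raw.columns:
            raise DataError(f"intensity column {col!r} not found in {path}")
        cols[sid] = col

    n_raw = len(raw)
    if drop_decoys:
        keep = pd.Series(True, index=raw.index)
        for flag in _FLAG_COLUMNS:
            if flag in raw.columns:
                keep &= raw[flag].str.strip() != "+"
        id_col = _accession_column(raw, kind)
        keep &= ~raw[id_col].str.startswith(_ID_PREFIXES)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropped %d decoy/contaminant rows from %s", n_dropped, path)
        raw = raw.loc[keep]
    else:
        n_dropped = 0

    meta = _build_metadata(raw, kind)
    meta.index = _feature_ids(meta, kind)

    values = pd.DataFrame(index=meta.index)
    for sid, col in cols.items():
        ser = raw[col].str.strip().replace("", "0")
        try:
            # float() is correctly rounded; pandas' fast parser can be off
            # by one ulp, which would break bit-exact round trips
            num = ser.map(float)
        except (ValueError, TypeError) as exc:
            bad = ser[pd.to_numeric(ser, errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise DataError(
                f"non-numeric intensity in column {col!r}, file row {row}: "
                f"{bad.iloc[0]!r}" if len(bad) else f"non-numeric intensity in {col!r}"
            ) from exc
        num = num.astype(float)
        num[num == 0.0] = np.nan
        values[sid] = num.to_numpy()

    table = IntensityTable(values=values, metadata=meta, kind=kind)
    logger.info(
        "read %d features (%d raw rows, %d excluded) from %s",
        len(table.values), n_raw, n_dropped, path,
    )
    return table


def _accession_column(raw: pd.DataFrame, kind: str) -> str:
    if kind == PROTEIN_GROUP:
        for cand in ("Majority protein IDs", "Protein IDs"):
            if cand in raw.columns:
                return cand
        raise DataError("no protein accession column (Protein IDs) found")
    for cand in ("Proteins", "Protein"):
        if cand in raw.columns:
            return cand
    raise DataError("no protein accession column (Proteins) found")


def _build_metadata(raw: pd.DataFrame, kind: str) -> pd.DataFrame:
    acc = raw[_accession_column(raw, kind)]
    meta = pd.DataFrame({"accession": acc.to_numpy()}, index=raw.index)
    meta["gene"] = raw.get("Gene names", pd.Series("", index=raw.index)).to_numpy()
    meta["protein"] = raw.get("Protein names", pd.Series("", index=raw.index)).to_numpy()
    if kind == PROTEIN_GROUP:
        if "Peptides" not in raw.columns:
            raise DataError("protein-group table lacks a 'Peptides' count column")
        meta["peptide_count"] = pd.to_numeric(raw["Peptides"]).astype(int).to_numpy()
    else:
        if "Sequence" not in raw.columns:
            raise DataError("mod-peptide table lacks a 'Sequence' column")
        meta["sequence"] = raw["Sequence"].to_numpy()
        meta["modifications"] = raw.get(
            "Modifications", pd.Series("", index=raw.index)
        ).to_numpy()
    return meta.reset_index(drop=True)


def write_intensity_table(table: IntensityTable, path: str | Path) -> None:
    """Write *table* back to the MaxQuant dialect read by read_intensity_table.

    Missing values are written as 0 (the MaxQuant convention); intensities at
    full ``repr`` precision so a round trip is bit-exact.
    """
    out = pd.DataFrame(index=table.values.index)
    if table.kind == PROTEIN_GROUP:
        out["Protein IDs"] = table.metadata["accession"].to_numpy()
        out["Gene names"] = table.metadata["gene"].to_numpy()
        out["Protein names"] = table.metadata["protein"].to_numpy()
        out["Peptides"] = table.metadata["peptide_count"].to_numpy()
    else:
        out["Proteins"] = table.metadata["accession"].to_numpy()
        out["Sequence"] = table.metadata["sequence"].to_numpy()
        out["Modifications"] = table.metadata.get(
            "modifications", pd.Series("", index=table.metadata.index)
        ).to_numpy()
        out["Gene names"] = table.metadata["gene"].to_numpy()
        out["Protein names"] = table.metadata["protein"].to_numpy()
    for sid in table.sample_ids:
        col = table.values[sid].map(lambda v: "0" if pd.isna(v) else repr(float(v)))
        out[f"{_INTENSITY_PREFIX}{sid}"] = col.to_numpy()
    out.to_csv(path, sep="\t", index=False)


RESULT_COLUMNS = [
    "feature_id", "gene", "protein", "condition_a", "condition_b",
    "mean_a", "mean_b", "ratio", "log2fc", "t_mod", "p", "q", "z",
    "variant", "volcano_class",
]


def write_results_tsv(results: Sequence[ComparisonResult], path: str | Path) -> None:
    """Write comparison results as a TSV with a deterministic column order."""
    if not results:
        raise DataError("refusing to write an empty results table")
    rows = [
        {c: getattr(r, c) for c in RESULT_COLUMNS}
        for r in results
    ]
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results_tsv(path: str | Path) -> list[ComparisonResult]:
    frame = pd.read_csv(path, sep="\t")
    out = []
    for rec in frame.to_dict("records"):
        rec = {k: ("" if pd.isna(v) else v) if k in ("gene", "protein") else v
               for k, v in rec.items()}
        out.append(ComparisonResult(**rec))
    return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Duplicate members within a set are de-duplicated.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = parts
            if name in sets:
                raise DataError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(m for m in members if m)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
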