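import numpy as np
import pandas as pd
import pytest

from phosphoquant import IntensityTable, SampleDesign


def make_design(conditions=("DMSO", "Fsk"), n_per=3, n_experiments=None):
    """Design with n_per samples per condition; experiments default 1..n_per."""
    rows = []
    for cond in conditions:
        tag = cond.replace("+", "").replace(" ", "")
        for i in range(1, n_per + 1):
            exp = i if n_experiments is None else ((i - 1) % n_experiments) + 1
            rows.append((f"{tag}{i}", cond, exp, i))
    return SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "condition", "experiment", "replicate"])
    )


def make_table(values: dict, kind="mod_peptide", peptide_counts=None, normalized=False):
    """Build an IntensityTable from {feature_id: {sample_id: value-or-None}}."""
    frame = pd.DataFrame(values).T.astype(float)
    frame.index.name = "feature_id"
    meta = pd.DataFrame(index=frame.index)
    meta["accession"] = [f"ACC{i}" for i in range(len(frame))]
    meta["gene"] = [f"G{i}" for i in range(len(frame))]
    meta["protein"] = [f"Prot {i}" for i in range(len(frame))]
    if kind == "protein_group":
        meta["peptide_count"] = (
            peptide_counts if peptide_counts is not None else [3] * len(frame)
        )
    else:
        meta["sequence"] = ["SAMPLEK"] * len(frame)
        meta["modifications"] = ["Phospho (STY)"] * len(frame)
    return IntensityTable(values=frame, metadata=meta, kind=kind, normalized=normalized)


@pytest.fixture
def two_condition_design():
    return make_design()


@pytest.fixture
def three_condition_design():
    return make_design(("DMSO", "Fsk", "Fsk+AICAR"))
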