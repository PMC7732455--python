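import numpy as np
import pandas as pd
import pytest

from neoplasma.io import ProteinQuantMatrix, RECORD_COLUMNS
from neoplasma.simulate import SimConfig, generate_cohort


def make_records(ids, **overrides):
    rec = pd.DataFrame(
        {
            "protein_group_id": ids,
            "gene_name": overrides.get("gene_name", [""] * len(ids)),
            "is_reverse": overrides.get("is_reverse", False),
            "is_contaminant": overrides.get("is_contaminant", False),
            "only_modified_site": overrides.get("only_modified_site", False),
            "unique_peptides": overrides.get("unique_peptides", 1),
        }
    )[RECORD_COLUMNS]
    rec.index = pd.Index(rec["protein_group_id"], name="protein_group_id")
    return rec


def make_matrix(values, sample_ids=None, ids=None, ibaq=None, **rec_overrides):
    """Small hand-built ProteinQuantMatrix from a 2-D array (NaN = missing)."""
    values = np.asarray(values, float)
    ids = ids or [f"P{i + 1:03d}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j + 1}" for j in range(values.shape[1])]
    rec = make_records(ids, **rec_overrides)
    lfq = pd.DataFrame(values, index=rec.index, columns=sample_ids)
    ib = None
    if ibaq is not None:
        ib = pd.DataFrame(np.asarray(ibaq, float), index=rec.index, columns=sample_ids)
    return ProteinQuantMatrix(records=rec, lfq=lfq, ibaq=ib)


def make_paired_meta(n_per_day=(2, 2, 2), batch_cycle=("b1",), sexes=None):
    """Valid paired-design metadata: DOL0 + one follow-up per participant."""
    rows = []
    pid = 0
    for day, count in zip((1, 3, 7), n_per_day):
        for _ in range(count):
            pid += 1
            participant = f"P{pid:02d}"
            sex = (sexes or ["F", "M"])[pid % 2]
            batch = batch_cycle[pid % len(batch_cycle)]
            for dol in (0, day):
                rows.append(
                    {
                        "sample_id": f"{participant}_D{dol}",
                        "participant_id": participant,
                        "dol": dol,
                        "sex": sex,
                        "batch": batch,
                        "cohort": "test",
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    return generate_cohort(SimConfig(seed=42))


@pytest.fixture(scope="session")
def clean_cohort():
    """Cohort without censoring or batch effects: complete matrix."""
    cfg = SimConfig(
        seed=43,
        censor_quantile=0.0,
        batch_effects={"b": (0.0, 1.0)},
    )
    return generate_cohort(cfg)
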