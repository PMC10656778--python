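import numpy as np
import pandas as pd
import pytest

from refstab import CtMatrix


def make_ct(values, gene_ids=None, groups=None, conditions=None, bio_reps=None, tech_reps=None,
            sample_ids=None) -> CtMatrix:
    """Build a CtMatrix from a 2-d array with minimal boilerplate."""
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    gene_ids = gene_ids or [f"G{i + 1}" for i in range(g)]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(s)]
    groups = groups or ["grp"] * s
    conditions = conditions or ["control"] * s
    bio_reps = bio_reps or list(range(1, s + 1))
    tech_reps = tech_reps or [1] * s
    data = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {"group": groups, "condition": conditions, "bio_rep": bio_reps, "tech_rep": tech_reps},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CtMatrix(data, meta)


@pytest.fixture
def worked_ct() -> CtMatrix:
    """The 3-gene x 3-sample worked fixture: G1 = G2 = (20,21,22), G3 = (20,20,20)."""
    return make_ct([[20, 21, 22], [20, 21, 22], [20, 20, 20]])
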