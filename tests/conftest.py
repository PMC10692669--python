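import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from crosstalk.phospho import FragmentTable


def make_fragment_table(values: dict, peptides: dict) -> FragmentTable:
    """Build a FragmentTable from {(pep, frag): {(sample, cond, rep): v}}."""
    idx = pd.MultiIndex.from_tuples(sorted(values), names=["peptide", "fragment"])
    cols = sorted({c for row in values.values() for c in row})
    columns = pd.MultiIndex.from_tuples(cols, names=["sample", "condition", "replicate"])
    mat = pd.DataFrame(np.nan, index=idx, columns=columns)
    for rk, row in values.items():
        for ck, v in row.items():
            mat.loc[rk, ck] = v
    meta = pd.DataFrame.from_dict(peptides, orient="index")
    meta.index.name = "peptide"
    return FragmentTable(mat, meta)


@pytest.fixture
def simple_table():
    """One peptide, three fragments, control + one treatment, 3 reps."""
    cols = [("S1", c, r) for c in ("control", "drug") for r in (1, 2, 3)]
    values = {
        ("pep1", f"f{i}"): {c: 10000.0 * (i + 1) * (2 if c[1] == "drug" else 1) for c in cols}
        for i in range(3)
    }
    peptides = {"pep1": {"protein": "P1", "sequence": "SPSLK", "offsets": (1,)}}
    return make_fragment_table(values, peptides)


@pytest.fixture
def small_net():
    from crosstalk import synth

    return synth.gen_prior_network(6, 8, 0.3, seed=11)
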