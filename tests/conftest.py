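import numpy as np
import pandas as pd
import pytest

from ramamap import core


def make_table(records):
    """Build an ensemble table from (model, chain, resid, resname, phi, psi)
    tuples, deriving R and Rsigned the same way structure_io does."""
    df = pd.DataFrame(
        records, columns=["model", "chain", "resid", "resname", "phi", "psi"]
    )
    df["R"] = core.ramachandran_number(df["phi"].to_numpy(), df["psi"].to_numpy())
    df["Rsigned"] = core.signed_ramachandran_number(
        df["phi"].to_numpy(), df["psi"].to_numpy()
    )
    return df


@pytest.fixture
def helix_table():
    """3 models x 4 residues of one chain, all alpha-helical."""
    rows = []
    for m in (1, 2, 3):
        for r in (1, 2, 3, 4):
            rows.append((m, "A", r, "ALA", -57.0, -47.0))
    return make_table(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
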