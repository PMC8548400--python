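import numpy as np
import pandas as pd
import pytest

import degradomics as dg
from degradomics.core_io import PEPTIDE_COLUMNS


@pytest.fixture(scope="session")
def cyclin():
    return dg.cyclin_b1_nt()


@pytest.fixture(scope="session")
def cyclin_k64():
    return dg.cyclin_b1_nt_k64()


@pytest.fixture(scope="session")
def ub():
    return dg.ubiquitin()


@pytest.fixture
def toy_substrate():
    return dg.SubstrateRecord(id="toy", sequence="MKTAYIAKQR")


def make_table(rows):
    """rows: (sample, condition, replicate, sequence, psm[, branch_pos, remnant])."""
    full = [tuple(r) + (np.nan, None)[len(r) - 5:] for r in rows]
    frame = pd.DataFrame(full, columns=PEPTIDE_COLUMNS)
    return dg.PeptideTable(frame)


@pytest.fixture
def two_condition_table(toy_substrate):
    """Hand-built table on MKTAYIAKQR: two conditions, three replicates."""
    rows = []
    for rep in (1, 2, 3):
        rows.append((f"a{rep}", "20S", rep, "TAYI", 10))
        rows.append((f"a{rep}", "20S", rep, "MKTA", 5))
        rows.append((f"b{rep}", "26S", rep, "TAYI", 4))
    rows.append(("b1", "26S", 1, "AKQR", 7))  # single replicate: filtered at 2-of-3
    return make_table(rows)


@pytest.fixture(scope="session")
def random_substrate():
    rng = np.random.default_rng(2024)
    seq = "".join(rng.choice(list(dg.core_io.CANONICAL_AA), size=51))
    return dg.SubstrateRecord(id="sim51", sequence=seq)
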