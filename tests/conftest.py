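import numpy as np
import pytest

from nhejoin import builtin_assay


@pytest.fixture(scope="session")
def partial_assay():
    return builtin_assay("partial")


@pytest.fixture(scope="session")
def noncomp_assay():
    return builtin_assay("noncomp")


@pytest.fixture(scope="session")
def cis_assay():
    return builtin_assay("cis")


@pytest.fixture()
def rng():
    return np.random.default_rng(20130718)


def random_junction(assay, rng):
    """A junction built by concatenating trimmed ends plus a random insertion.

    Draws (left trim, right trim, insertion) uniformly inside the assay
    bounds; the result is a valid anchored junction by construction.
    """
    lt, rt = assay.left_top, assay.right_top
    t1 = int(rng.integers(0, assay.max_deletion + 1))
    t2 = int(rng.integers(0, assay.max_deletion + 1))
    g = int(rng.integers(0, assay.max_insertion + 1))
    ins = "".join(rng.choice(list("ACGT"), size=g))
    return lt[: len(lt) - t1] + ins + rt[t2:]
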