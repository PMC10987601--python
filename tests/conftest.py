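"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

import cosmotherm as ct
from cosmotherm.core_io import InputNode, InputNodeSet, OmicsMatrix, PKN


@pytest.fixture(scope="session")
def truth():
    return ct.synthetic_data.generate_pkn(seed=0)


@pytest.fixture(scope="session")
def omics(truth):
    return ct.synthetic_data.simulate_omics(truth, seed=1)


@pytest.fixture(scope="session")
def tpp_profiles(truth):
    return ct.synthetic_data.simulate_tpp(truth, seed=2)


@pytest.fixture
def chain_pkn():
    """K -> X -> TF activating chain."""
    return PKN.from_edges([("K", 1, "X"), ("X", 1, "TF")])


@pytest.fixture
def kinase_input():
    return InputNodeSet.build([InputNode("K", "kinase", 1, 1.0)])


@pytest.fixture
def tf_input():
    return InputNodeSet.build([InputNode("TF", "tf", 1, 1.0)])


def make_matrix(values, kind="phospho_log2", features=None, n_t=None):
    """Small OmicsMatrix helper: first half of columns treatment."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    n_t = n_samp // 2 if n_t is None else n_t
    features = features or [f"F{i+1}" for i in range(n_feat)]
    samples = [f"T{i+1}" for i in range(n_t)] + \
              [f"C{i+1}" for i in range(n_samp - n_t)]
    cond = {s: ("treatment" if s.startswith("T") else "control")
            for s in samples}
    return OmicsMatrix(values=pd.DataFrame(values, index=features,
                                           columns=samples),
                       sample_condition=cond, kind=kind)
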