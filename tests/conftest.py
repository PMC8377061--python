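"""Shared fixtures: small synthetic studies reused across test modules."""

import numpy as np
import pytest

import gsemkit as gk


@pytest.fixture(scope="session")
def small_study():
    """Genotype-derived GRM + complete 3-trait phenotypes (n=300).

    Truth: one common genetic factor (shares 0.3/0.4/0.2) plus moderate
    residual correlation; used wherever a realistic-but-cheap dataset is
    needed.
    """
    traits = ["t1", "t2", "t3"]
    La = np.zeros((3, 4))
    La[:, 0] = np.sqrt([0.3, 0.4, 0.2])
    La[np.arange(3), np.arange(1, 4)] = np.sqrt([0.05, 0.0, 0.1])
    h2 = np.sum(La**2, axis=1)
    R = np.array([[1.0, 0.4, 0.3], [0.4, 1.0, 0.35], [0.3, 0.35, 1.0]])
    v = 1.0 - h2
    Le = np.linalg.cholesky(np.sqrt(np.outer(v, v)) * R)
    scen = gk.Scenario(trait_names=traits, lambda_a=La, lambda_e=Le,
                       n=300, m=1200, seed=42, name="small")
    grm, pheno = gk.simulate_study(scen, route="genotype")
    ds = gk.align(pheno, grm, mode="complete", require_transformed=False)
    return scen, grm, pheno, ds


@pytest.fixture(scope="session")
def toy_grm():
    """Hand-made 4x4 GRM with one related pair."""
    values = np.eye(4)
    values[0, 1] = values[1, 0] = 0.3
    values[2, 3] = values[3, 2] = 0.02
    ids = [("F0", "I0"), ("F1", "I1"), ("F2", "I2"), ("F3", "I3")]
    return gk.GRMatrix(ids=ids, values=values)
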