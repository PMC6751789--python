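"""Shared fixtures: synthetic benchmark scenarios and matching helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from consensusica.ica import match_components
from consensusica.simulate import SyntheticScenario, simulate_mixture


def matched_abs_corr(S_true: np.ndarray | pd.DataFrame,
                     S_est: np.ndarray | pd.DataFrame) -> np.ndarray:
    """|Pearson r| between each true source and its greedily matched
    estimated metagene (resolves permutation and sign)."""
    A = np.asarray(S_true, dtype=float)
    B = np.asarray(S_est, dtype=float)
    perm, signs = match_components(A, B)
    An = A - A.mean(axis=0)
    An /= np.linalg.norm(An, axis=0)
    Bn = B[:, perm] * signs
    Bn = Bn - Bn.mean(axis=0)
    Bn /= np.linalg.norm(Bn, axis=0)
    return np.abs(np.sum(An * Bn, axis=0))


def mean_pairwise_metagene_corr(res_a, res_b) -> float:
    """Mean |r| between matched metagenes of two decompositions."""
    return float(matched_abs_corr(res_a.metagenes.to_numpy(),
                                  res_b.metagenes.to_numpy()).mean())


@pytest.fixture(scope="session")
def bench5():
    """Reference benchmark: 5 Laplace sources, n=2000, m=100, noise sd 0.1."""
    scn = SyntheticScenario(seed=11)
    E, S_true, M_true, batches = simulate_mixture(scn)
    return {"scenario": scn, "E": E, "S_true": S_true, "M_true": M_true,
            "batches": batches}


@pytest.fixture(scope="session")
def bench5_fit(bench5):
    """Consensus decomposition of the reference benchmark (k=5, nt=20)."""
    from consensusica.ica import consensus_decompose
    return consensus_decompose(bench5["E"], k=5, nt=20, seed=42)
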