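"""Ranking-score projection of new samples onto a discovery cohort.

ICA weights are neither centred nor scaled, so a raw weight value of a new
sample is hard to read.  The ranking score re-expresses it as the sample's
quantile position within the discovery cohort's weights for that
component: 0 when below every discovery weight, 1 when above all of them,
about 0.5 when near the discovery median.  Only the discovery cohort
defines the ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ica import ConsensusICAResults

__all__ = ["ranking_score", "rank_profile"]


def ranking_score(discovery_weights, w_new: float) -> float:
    """Quantile position of ``w_new`` within the discovery weights.

    Fraction of discovery weights strictly below ``w_new``, with ties
    counted as half (mid-rank convention); values outside the discovery
    range clamp to exactly 0 or 1.
    """
    w = np.asarray(discovery_weights, dtype=float)
    if w.size < 2:
        raise ValueError("need at least 2 discovery weights")
    if w_new < w.min():
        return 0.0
    if w_new > w.max():
        return 1.0
    below = float((w < w_new).sum())
    ties = float((w == w_new).sum())
    return (below + 0.5 * ties) / w.size


def rank_profile(results: ConsensusICAResults,
                 M_new: pd.DataFrame) -> pd.DataFrame:
    """Ranking scores of new samples for every component.

    ``M_new`` is a component x sample weight matrix (e.g. from
    ``results.project``); the discovery ranking comes from the fitted
    weights.  Returns samples x components scores in [0, 1].
    """
    missing = [c for c in results.component_ids if c not in M_new.index]
    if missing:
        raise ValueError(f"weight matrix lacks components: {missing[:5]}")
    out = {}
    for cid in results.component_ids:
        disc = results.weights.loc[cid].to_numpy(dtype=float)
        out[cid] = [ranking_score(disc, w)
                    for w in M_new.loc[cid].to_numpy(dtype=float)]
    return pd.DataFrame(out, index=list(M_new.columns))
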