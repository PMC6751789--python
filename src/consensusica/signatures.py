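"""Component interpretation: top-contributing features, orientation, and
annotation against gene sets and reference signature matrices.

Metagenes extracted by ICA are non-Gaussian by construction: most features
sit in a roughly normal bulk while a small set of features carries extreme
loadings — those are the component's markers.  Significance of each
feature is assessed against a normal background whose centre and scale are
estimated robustly (median and MAD, so the heavy tails do not inflate the
variance), followed by Benjamini–Hochberg adjustment across the
component's features.  Features at adjusted p below the threshold are
split into positively and negatively contributing lists.

Because ICA fixes component signs only up to convention, components are
reoriented so that the biologically dominant tail is positive: by gene-set
enrichment when sets are available, by the heavier significant tail
otherwise.  miRNA components, which lack useful set annotation, are
instead oriented by their correlation with mRNA components.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ica import ConsensusICAResults

__all__ = ["ComponentSignature", "GeneSetCollection", "top_contributors",
           "benjamini_hochberg", "orient_components", "orient_mirna_by_link",
           "hypergeometric_enrichment", "enrich_signature",
           "best_signature_match", "read_gmt", "component_signatures",
           "signatures_to_frame"]

#: MAD -> sd consistency factor for the normal distribution
MAD_SCALE = 1.4826


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComponentSignature:
    """Significantly contributing features of one component, split by sign."""

    component_id: str
    positive_features: list[tuple[str, float]]  # (feature_id, adjusted p)
    negative_features: list[tuple[str, float]]
    alpha: float

    @property
    def n_positive(self) -> int:
        return len(self.positive_features)

    @property
    def n_negative(self) -> int:
        return len(self.negative_features)

    def feature_ids(self, side: str = "both") -> list[str]:
        if side == "positive":
            return [f for f, _ in self.positive_features]
        if side == "negative":
            return [f for f, _ in self.negative_features]
        return [f for f, _ in self.positive_features + self.negative_features]


def top_contributors(s: pd.Series, alpha: float = 0.01,
                     component_id: str = "IC") -> ComponentSignature:
    """Flag features whose loading deviates from the normal background.

    z = (s - median) / (1.4826 * MAD); two-sided normal p-values; BH across
    the component's features; adjusted p < alpha reported, split by z sign.
    """
    s = pd.Series(s)
    if len(s) < 10:
        raise ValueError("metagene too short for background estimation")
    x = s.to_numpy(dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ValueError(f"degenerate metagene {component_id}: MAD is zero")
    z = (x - med) / (MAD_SCALE * mad)
    p = 2.0 * stats.norm.sf(np.abs(z))
    adj = benjamini_hochberg(p)
    sig = adj < alpha
    order = np.argsort(adj, kind="stable")
    pos, neg = [], []
    for i in order:
        if not sig[i]:
            continue
        (pos if z[i] > 0 else neg).append((str(s.index[i]), float(adj[i])))
    return ComponentSignature(component_id=component_id,
                              positive_features=pos, negative_features=neg,
                              alpha=alpha)


def component_signatures(results: ConsensusICAResults, alpha: float = 0.01
                         ) -> dict[str, ComponentSignature]:
    """Top contributors for every component of a fitted decomposition."""
    return {cid: top_contributors(results.metagenes[cid], alpha=alpha,
                                  component_id=cid)
            for cid in results.component_ids}


def signatures_to_frame(sigs: dict[str, ComponentSignature]) -> pd.DataFrame:
    """Long-format table (component, feature, side, adj_p) for TSV export."""
    rows = []
    for cid, sig in sigs.items():
        rows += [(cid, f, "positive", p) for f, p in sig.positive_features]
        rows += [(cid, f, "negative", p) for f, p in sig.negative_features]
    return pd.DataFrame(rows, columns=["component", "feature", "side", "adj_p"])


# ---------------------------------------------------------------------------
# gene sets and enrichment
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named feature sets plus the background universe they are tested in."""

    sets: dict[str, list[str]]
    background: list[str]

    def __post_init__(self) -> None:
        bg = set(self.background)
        # restrict every set to the background universe
        self.sets = {name: [f for f in members if f in bg]
                     for name, members in self.sets.items()}


def read_gmt(path, background: list[str]) -> GeneSetCollection:
    """Read a standard GMT file (name <tab> description <tab> members...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = parts[2:]
    return GeneSetCollection(sets=sets, background=background)


def hypergeometric_enrichment(signature: list[str], gene_set: list[str],
                              background: list[str]) -> float:
    """Upper-tail hypergeometric p-value for the signature/set overlap.

    Probability of drawing at least the observed overlap when
    ``len(signature)`` features are drawn without replacement from the
    background containing ``len(gene_set)`` set members.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    sig = set(signature) & bg
    gs = set(gene_set) & bg
    overlap = len(sig & gs)
    # P(X >= overlap), X ~ Hypergeom(N=len(bg), K=len(gs), n=len(sig))
    return float(stats.hypergeom.sf(overlap - 1, len(bg), len(gs), len(sig)))


def enrich_signature(sig: ComponentSignature, collection: GeneSetCollection,
                     side: str = "both") -> pd.DataFrame:
    """Hypergeometric enrichment of one signature against every set.

    BH adjustment is applied across the collection's sets.  Returns a
    DataFrame (set, overlap, set_size, p, adj_p) sorted by p.
    """
    features = sig.feature_ids(side)
    rows = []
    for name, members in collection.sets.items():
        p = hypergeometric_enrichment(features, members, collection.background)
        overlap = len(set(features) & set(members))
        rows.append((name, overlap, len(members), p))
    df = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"])
    df["adj_p"] = benjamini_hochberg(df["p"].to_numpy()) if len(df) else []
    return df.sort_values("p", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def orient_components(results: ConsensusICAResults,
                      gene_sets: GeneSetCollection | None = None,
                      alpha: float = 0.01) -> ConsensusICAResults:
    """Fix each component's sign so its dominant biology is positive.

    With gene sets: flip when the best enrichment p-value among the
    negative-side top contributors beats the best among the positive side.
    Without gene sets: flip when the negative tail has more significant
    contributors than the positive tail.  Idempotent; ``S @ M`` unchanged.
    """
    to_flip = []
    for cid in results.component_ids:
        sig = top_contributors(results.metagenes[cid], alpha=alpha,
                               component_id=cid)
        if gene_sets is not None and gene_sets.sets:
            best_pos = _best_enrichment_p(sig, gene_sets, "positive")
            best_neg = _best_enrichment_p(sig, gene_sets, "negative")
            if best_neg < best_pos:
                to_flip.append(cid)
        else:
            if sig.n_negative > sig.n_positive:
                to_flip.append(cid)
    return results.flip(to_flip) if to_flip else results


def _best_enrichment_p(sig: ComponentSignature, gene_sets: GeneSetCollection,
                       side: str) -> float:
    if not sig.feature_ids(side):
        return 1.0
    return float(enrich_signature(sig, gene_sets, side=side)["p"].min())


def orient_mirna_by_link(results_mirna: ConsensusICAResults,
                         results_mrna: ConsensusICAResults,
                         threshold: float = 0.5) -> ConsensusICAResults:
    """Orient miRNA components by their strongest-correlated mRNA component.

    For each miRNA component, find the mRNA component with the highest
    absolute Pearson correlation of weight rows over shared samples; flip
    the miRNA component only when that correlation is strongly negative
    (r < -threshold).
    """
    shared = [s for s in results_mirna.sample_ids
              if s in set(results_mrna.sample_ids)]
    if len(shared) < 3:
        raise ValueError("no (or too few) shared samples between layers")
    Wm = results_mirna.weights[shared].to_numpy()
    Wr = results_mrna.weights[shared].to_numpy()
    to_flip = []
    for i, cid in enumerate(results_mirna.component_ids):
        r = np.array([np.corrcoef(Wm[i], Wr[j])[0, 1]
                      for j in range(Wr.shape[0])])
        best = r[np.argmax(np.abs(r))]
        if best < -threshold:
            to_flip.append(cid)
    return results_mirna.flip(to_flip) if to_flip else results_mirna


# ---------------------------------------------------------------------------
# reference signature matrices
# ---------------------------------------------------------------------------

def best_signature_match(results: ConsensusICAResults,
                         reference: pd.DataFrame) -> pd.DataFrame:
    """Associate each component with the best-matching reference profile.

    ``reference`` is a features x cell-type matrix (LM22-style).  For each
    metagene, the reference column with the highest absolute Pearson
    correlation over shared features is reported with its signed r.
    """
    if reference.columns.has_duplicates:
        raise ValueError("duplicate cell-type names in reference matrix")
    shared = [f for f in results.feature_ids if f in set(reference.index)]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared features with the reference")
    S = results.metagenes.loc[shared]
    R = reference.loc[shared]
    rows = []
    for cid in results.component_ids:
        r = R.apply(lambda col: np.corrcoef(S[cid], col)[0, 1], axis=0)
        best = r.abs().idxmax()
        rows.append((cid, best, float(r[best])))
    return pd.DataFrame(rows, columns=["component", "cell_type", "r"]
                        ).set_index("component")
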