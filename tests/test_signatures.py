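"""Top-contributor calling, multiple-testing adjustment, enrichment,
orientation and reference-signature matching."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from consensusica.ica import ConsensusICAResults
from consensusica.signatures import (GeneSetCollection, benjamini_hochberg,
                                     best_signature_match,
                                     hypergeometric_enrichment,
                                     orient_components, orient_mirna_by_link,
                                     read_gmt, top_contributors)


def bh_oracle(p):
    """Literal step-up definition: adj_i = min over j >= rank(i) of m*p(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


def hypergeom_oracle(signature, gene_set, background):
    """Enumerate every possible draw of |signature| items from the
    background and count draws with overlap >= observed."""
    bg = list(background)
    gs = set(gene_set)
    n_draw = len(signature)
    observed = len(set(signature) & gs)
    hits = total = 0
    for draw in itertools.combinations(bg, n_draw):
        total += 1
        if len(set(draw) & gs) >= observed:
            hits += 1
    return hits / total


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2]), [0.2])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(benjamini_hochberg(p), bh_oracle(p),
                                       atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestTopContributors:
    def test_null_normal_metagene_rarely_flags(self):
        flagged = []
        for seed in range(100):
            s = pd.Series(np.random.default_rng(seed).normal(size=5000))
            sig = top_contributors(s, alpha=0.01)
            flagged.append(sig.n_positive + sig.n_negative)
        assert np.mean(flagged) <= 0.5

    def test_injected_outliers_are_flagged_with_sign(self):
        rng = np.random.default_rng(1)
        s = pd.Series(np.concatenate([rng.normal(size=1000), [10.0, -12.0]]),
                      index=[f"g{i}" for i in range(1002)])
        sig = top_contributors(s, alpha=0.01)
        assert "g1000" in [f for f, _ in sig.positive_features]
        assert "g1001" in [f for f, _ in sig.negative_features]
        assert all(p < 0.01 for _, p in
                   sig.positive_features + sig.negative_features)

    def test_constant_metagene_rejected(self):
        with pytest.raises(ValueError, match="MAD"):
            top_contributors(pd.Series(np.ones(100)))

    def test_invariant_to_positive_rescaling(self):
        s = pd.Series(np.random.default_rng(2).standard_t(3, size=2000))
        a = top_contributors(s, alpha=0.05)
        b = top_contributors(10.0 * s, alpha=0.05)
        assert a.feature_ids("positive") == b.feature_ids("positive")
        assert a.feature_ids("negative") == b.feature_ids("negative")


class TestHypergeometric:
    def test_full_overlap_of_everything_is_certain(self):
        universe = [f"g{i}" for i in range(10)]
        assert hypergeometric_enrichment(universe, universe, universe) == 1.0

    def test_closed_form_perfect_overlap(self):
        bg = [f"g{i}" for i in range(20)]
        sig = bg[:5]
        p = hypergeometric_enrichment(sig, sig, bg)
        assert p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_matches_enumeration_oracle_small_universes(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            N = int(rng.integers(4, 13))
            bg = [f"g{i}" for i in range(N)]
            gs = list(rng.choice(bg, size=rng.integers(1, N), replace=False))
            sig = list(rng.choice(bg, size=rng.integers(1, N), replace=False))
            p = hypergeometric_enrichment(sig, gs, bg)
            assert p == pytest.approx(hypergeom_oracle(sig, gs, bg), rel=1e-9)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            hypergeometric_enrichment(["a"], ["a"], [])


def _toy_results(S, M=None, stability=None):
    S = pd.DataFrame(S)
    S.index = [f"g{i}" for i in range(S.shape[0])]
    S.columns = [f"IC{i + 1}" for i in range(S.shape[1])]
    k = S.shape[1]
    if M is None:
        M = pd.DataFrame(np.random.default_rng(0).normal(size=(k, 20)),
                         index=S.columns,
                         columns=[f"s{j}" for j in range(20)])
    else:
        M = pd.DataFrame(M, index=S.columns)
        M.columns = [f"s{j}" for j in range(M.shape[1])]
    stab = pd.Series(1.0 if stability is None else stability, index=S.columns)
    offsets = pd.Series(0.0, index=S.index)
    return ConsensusICAResults(S, M, stab, offsets, k, 2, 0, 2)


class TestOrientation:
    def _skewed_results(self, negative_heavy=True):
        rng = np.random.default_rng(4)
        s = rng.normal(size=2000)
        tail = -np.abs(rng.normal(8, 1, size=40))
        if not negative_heavy:
            tail = -tail
        s = np.concatenate([s, tail, np.abs(rng.normal(8, 1, size=5))
                            if negative_heavy else
                            -np.abs(rng.normal(8, 1, size=5))])
        return _toy_results(s[:, None])

    def test_negative_heavy_component_is_flipped(self):
        res = self._skewed_results(negative_heavy=True)
        oriented = orient_components(res)
        assert (oriented.metagenes["IC1"] == -res.metagenes["IC1"]).all()
        assert (oriented.weights.loc["IC1"] == -res.weights.loc["IC1"]).all()

    def test_idempotent_and_reconstruction_preserving(self):
        res = self._skewed_results(negative_heavy=True)
        once = orient_components(res)
        twice = orient_components(once)
        pd.testing.assert_frame_equal(once.metagenes, twice.metagenes)
        np.testing.assert_allclose(
            once.metagenes.to_numpy() @ once.weights.to_numpy(),
            res.metagenes.to_numpy() @ res.weights.to_numpy(), atol=1e-12)

    def test_positive_heavy_component_untouched(self):
        res = self._skewed_results(negative_heavy=False)
        oriented = orient_components(res)
        pd.testing.assert_frame_equal(oriented.metagenes, res.metagenes)

    def test_gene_set_orientation_overrides_tail_counts(self):
        # negative side carries the enriched set -> flip even though the
        # positive tail is heavier
        rng = np.random.default_rng(5)
        s = rng.normal(size=500)
        pos_idx = np.arange(460, 480)   # 20 positive outliers
        neg_idx = np.arange(480, 490)   # 10 negative outliers
        s[pos_idx] = rng.normal(10, 0.5, size=20)
        s[neg_idx] = rng.normal(-10, 0.5, size=10)
        res = _toy_results(s[:, None])
        features = list(res.metagenes.index)
        sets = GeneSetCollection(
            sets={"negset": [features[i] for i in neg_idx]},
            background=features)
        oriented = orient_components(res, sets)
        assert (oriented.metagenes["IC1"] == -res.metagenes["IC1"]).all()


class TestMirnaOrientation:
    def _pair(self, r_sign, m=200, seed=6):
        rng = np.random.default_rng(seed)
        W_rna = rng.normal(size=(2, m))
        W_mi = np.vstack([r_sign * W_rna[0] + rng.normal(0, 0.05, m),
                          rng.normal(size=m)])
        S = rng.laplace(size=(100, 2))
        res_rna = _toy_results(S, M=W_rna)
        res_mi = _toy_results(S, M=W_mi)
        return res_rna, res_mi

    def test_strong_negative_correlation_flips(self):
        res_rna, res_mi = self._pair(-1.0)
        out = orient_mirna_by_link(res_mi, res_rna, threshold=0.5)
        r = np.corrcoef(out.weights.loc["IC1"],
                        res_rna.weights.loc["IC1"])[0, 1]
        assert r > 0.99

    def test_weak_negative_correlation_untouched(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(1, 300))
        W_mi = -0.3 * base + rng.normal(0, 1.0, size=(1, 300))
        r = np.corrcoef(W_mi[0], base[0])[0, 1]
        assert -0.5 < r < 0       # construction sanity
        res_rna = _toy_results(rng.laplace(size=(50, 1)), M=base)
        res_mi = _toy_results(rng.laplace(size=(50, 1)), M=W_mi)
        out = orient_mirna_by_link(res_mi, res_rna, threshold=0.5)
        pd.testing.assert_frame_equal(out.metagenes, res_mi.metagenes)

    def test_independent_weights_rarely_flip(self):
        flips = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            res_rna = _toy_results(rng.laplace(size=(30, 2)),
                                   M=rng.normal(size=(2, 200)))
            res_mi = _toy_results(rng.laplace(size=(30, 2)),
                                  M=rng.normal(size=(2, 200)))
            out = orient_mirna_by_link(res_mi, res_rna, threshold=0.5)
            if not out.metagenes.equals(res_mi.metagenes):
                flips += 1
        assert flips <= 5

    def test_disjoint_samples_rejected(self):
        res_rna, res_mi = self._pair(-1.0)
        res_mi.weights.columns = [f"x{j}" for j in
                                  range(res_mi.weights.shape[1])]
        with pytest.raises(ValueError, match="shared samples"):
            orient_mirna_by_link(res_mi, res_rna)


class TestSignatureMatch:
    def test_self_and_negated_profiles(self):
        rng = np.random.default_rng(8)
        res = _toy_results(rng.laplace(size=(200, 2)))
        ref = pd.DataFrame({
            "own": res.metagenes["IC1"],
            "neg": -res.metagenes["IC2"],
            "noise": rng.normal(size=200)}, index=res.metagenes.index)
        out = best_signature_match(res, ref)
        assert out.loc["IC1", "cell_type"] == "own"
        assert out.loc["IC1", "r"] == pytest.approx(1.0)
        assert out.loc["IC2", "cell_type"] == "neg"
        assert out.loc["IC2", "r"] == pytest.approx(-1.0)

    def test_noisy_profile_recovered(self):
        rng = np.random.default_rng(9)
        profiles = np.linalg.qr(rng.normal(size=(300, 5)))[0]
        metagene = profiles[:, 3] + rng.normal(0, 0.1, 300)
        res = _toy_results(metagene[:, None])
        ref = pd.DataFrame(profiles, index=res.metagenes.index,
                           columns=[f"ct{i}" for i in range(5)])
        out = best_signature_match(res, ref)
        assert out.loc["IC1", "cell_type"] == "ct3"


class TestGMT:
    def test_read_gmt_restricts_to_background(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("setA\tdesc\tg1\tg2\tg99\nsetB\tdesc\tg3\n")
        coll = read_gmt(path, background=["g1", "g2", "g3", "g4"])
        assert coll.sets["setA"] == ["g1", "g2"]   # g99 outside background
        assert coll.sets["setB"] == ["g3"]

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_name\n")
        with pytest.raises(ValueError, match="malformed"):
            read_gmt(path, background=["g1"])
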