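"""Entropy/JSD identities, triplet comparisons, ANOVA and similarity checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from suitbiome import diversity as div


class TestShannonEntropy:
    def test_uniform_is_log_k(self):
        for k in (2, 5, 100):
            assert div.shannon_entropy(np.ones(k)) == pytest.approx(np.log(k))

    def test_single_taxon_zero(self):
        assert div.shannon_entropy([42]) == 0.0

    def test_closed_form_three_one(self):
        # H(0.75, 0.25) = -(0.75 ln 0.75 + 0.25 ln 0.25)
        assert div.shannon_entropy([3, 1]) == pytest.approx(0.5623, abs=1e-4)

    def test_all_zero_error(self):
        with pytest.raises(ValueError):
            div.shannon_entropy([0, 0])


class TestJsd:
    def test_identity(self):
        p = np.array([0.2, 0.3, 0.5])
        assert div.jsd(p, p) == 0.0

    def test_disjoint_supports_ln2(self):
        assert div.jsd([1, 0], [0, 1]) == pytest.approx(np.log(2))

    def test_half_overlap_value(self):
        # JSD((1,0),(.5,.5)) = H(.75,.25) - H(.5,.5)/2
        expected = (-(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
                    - 0.5 * np.log(2))
        assert div.jsd([1, 0], [0.5, 0.5]) == pytest.approx(expected)

    def test_negative_entries_error(self):
        with pytest.raises(ValueError):
            div.jsd([-0.1, 1.1], [0.5, 0.5])

    def test_kl_decomposition_oracle(self):
        # JSD = (KL(p||m) + KL(q||m)) / 2 — independent route via scipy
        rng = np.random.default_rng(1)
        for _ in range(1000):
            k = rng.integers(2, 12)
            p = rng.dirichlet(np.ones(k))
            q = rng.dirichlet(np.ones(k))
            m = 0.5 * (p + q)
            oracle = 0.5 * (stats.entropy(p, m) + stats.entropy(q, m))
            assert div.jsd(p, q) == pytest.approx(oracle, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_divergence_properties_and_sqrt_triangle(self, seed):
        rng = np.random.default_rng(seed)
        p, q, r = rng.dirichlet(np.ones(6), size=3)
        dpq, dqr, dpr = div.jsd(p, q), div.jsd(q, r), div.jsd(p, r)
        assert 0 <= dpq <= np.log(2) + 1e-12
        assert dpq == pytest.approx(div.jsd(q, p))
        assert np.sqrt(dpr) <= np.sqrt(dpq) + np.sqrt(dqr) + 1e-9


class TestJsdMatrix:
    def test_duplicate_sample_zero_offdiagonal(self):
        m = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        dm = div.jsd_matrix(m)
        assert dm.values[0, 1] == 0.0

    def test_matches_pairwise_calls(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.integers(1, 50, (3, 5)), index=list("abc"))
        dm = div.jsd_matrix(m)
        for i, a in enumerate("abc"):
            for j, b in enumerate("abc"):
                pair = div.jsd(m.loc[a].to_numpy(), m.loc[b].to_numpy())
                assert dm.values[i, j] == pytest.approx(pair, abs=1e-12)

    def test_invariants(self):
        rng = np.random.default_rng(3)
        dm = div.jsd_matrix(rng.integers(1, 50, (6, 8)))
        assert np.allclose(dm.values, dm.values.T)
        assert (np.diag(dm.values) == 0).all()


class TestTriplets:
    def test_full_design_count(self, default_dataset):
        meta = default_dataset.metadata
        pma = meta[(meta.component != "CONTROL") & meta.pma]
        assert len(div.build_triplets(pma)) == 14  # 7 sets x 2 sides

    def test_missing_component_drops_pair(self, default_dataset):
        meta = default_dataset.metadata
        pma = meta[(meta.component != "CONTROL") & meta.pma]
        assert div.build_triplets(pma[pma.component != "OG"]) == []
        one = pma[(pma.set_id == "SET-1") & (pma.side == "L")]
        assert len(div.build_triplets(one)) == 1


class TestWithinBetween:
    def _dmat(self, values, labels):
        return div.DistanceMatrix(labels=labels, values=values)

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(0)
        # two triplets internally tight, far apart
        pts = np.array([0.0, 0.001, 0.002, 1.0, 1.001, 1.002])
        vals = np.abs(pts[:, None] - pts[None, :])
        labels = [f"s{i}" for i in range(6)]
        trips = [div.Triplet("SET-1", "L", "s0", "s1", "s2"),
                 div.Triplet("SET-2", "L", "s3", "s4", "s5")]
        cmp = div.within_between_comparison(self._dmat(vals, labels), trips)
        assert cmp.mean_within < cmp.mean_between
        assert cmp.p_value < 1e-6

    def test_welch_identical_groups(self):
        t, dof, p = div.welch_ttest([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_welch_p_uniform_on_independent_identical_distributions(self):
        # calibration oracle: with independent iid groups, p ~ U(0,1)
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(200):
            a, b = rng.normal(size=20), rng.normal(size=60)
            ps.append(div.welch_ttest(a, b)[2])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_requires_two_triplets(self):
        with pytest.raises(ValueError):
            div.within_between_comparison(
                self._dmat(np.zeros((3, 3)), ["a", "b", "c"]),
                [div.Triplet("SET-1", "L", "a", "b", "c")])


class TestControlComparison:
    def test_identical_controls_same_set_mean_zero(self):
        labels = ["c1", "p1", "p2", "c2", "p3", "p4"]
        meta = pd.DataFrame({
            "sample_id": labels,
            "component": ["CONTROL", "WJ", "IG", "CONTROL", "WJ", "IG"],
            "set_id": ["SET-1", "SET-1", "SET-1", "SET-2", "SET-2", "SET-2"],
        }).set_index("sample_id")
        # controls identical to own-set components, sets far apart
        pos = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        vals = np.abs(pos[:, None] - pos[None, :])
        out = div.control_distance_comparison(
            div.DistanceMatrix(labels=labels, values=vals), meta)
        assert out["control_same_vs_other"].mean_within == 0.0
        assert out["control_same_vs_other"].mean_between == 1.0

    def test_no_controls_error(self):
        meta = pd.DataFrame({"sample_id": ["a", "b"], "component": ["WJ", "IG"],
                             "set_id": ["SET-1", "SET-1"]}).set_index("sample_id")
        dm = div.DistanceMatrix(labels=["a", "b"], values=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            div.control_distance_comparison(dm, meta)


class TestEmbed:
    def test_deterministic_and_block_separation(self):
        # two tight distance blocks; embedded between-block distance larger
        n = 10
        vals = np.full((n, n), 0.05)
        vals[:5, :5] = 0.001
        vals[5:, 5:] = 0.001
        np.fill_diagonal(vals, 0)
        dm = div.DistanceMatrix(labels=[f"s{i}" for i in range(n)], values=vals)
        a = div.embed(dm, seed=7, n_neighbors=4)
        b = div.embed(dm, seed=7, n_neighbors=4)
        pd.testing.assert_frame_equal(a, b)
        assert np.isfinite(a.to_numpy()).all()
        c = a.to_numpy()
        within = np.linalg.norm(c[:5] - c[:5].mean(0), axis=1).mean()
        between = np.linalg.norm(c[:5].mean(0) - c[5:].mean(0))
        assert between > within

    def test_too_few_samples_error(self):
        dm = div.DistanceMatrix(labels=list("abc"), values=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            div.embed(dm, seed=0)


class TestBodySiteSimilarity:
    def _refs(self):
        return pd.DataFrame([[1.0, 0, 0], [0, 1.0, 0]],
                            index=["skin", "oral"], columns=list("xyz"))

    def test_exact_match_ranks_first(self):
        out = div.body_site_similarity(pd.Series({"x": 1.0}), self._refs())
        assert out.iloc[0]["site"] == "skin"
        assert out.iloc[0]["cosine"] == pytest.approx(1.0)

    def test_orthogonal_zero(self):
        out = div.body_site_similarity(pd.Series({"z": 1.0}), self._refs())
        assert (out["cosine"] == 0).all()

    def test_hand_arithmetic_half(self):
        refs = pd.DataFrame([[0.5, 0, 0.5]], index=["skin"], columns=list("xyz"))
        out = div.body_site_similarity(pd.Series({"x": 0.5, "y": 0.5}), refs)
        assert out.iloc[0]["cosine"] == pytest.approx(0.5)

    def test_scale_invariance(self):
        refs = self._refs()
        p = pd.Series({"x": 0.3, "y": 0.7})
        a = div.body_site_similarity(p, refs)
        b = div.body_site_similarity(p * 1000, refs * 5)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_norm_error(self):
        with pytest.raises(ValueError):
            div.body_site_similarity(pd.Series({"x": 0.0}), self._refs())


class TestRichnessAnova:
    def test_hand_computed_f(self):
        # groups {1,2,3} vs {4,5,6}: MSB=13.5, MSW=1 -> F=13.5
        f, p = div.richness_anova({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert f == pytest.approx(13.5)

    def test_constant_groups_convention(self):
        f, p = div.richness_anova({"a": [5, 5], "b": [5, 5]})
        assert (f, p) == (0.0, 1.0)

    def test_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(8)
        groups = {g: rng.normal(size=n) for g, n in
                  zip("abc", (5, 7, 8))}
        f, p = div.richness_anova(groups)
        allv = np.concatenate(list(groups.values()))
        gm = allv.mean()
        ssb = sum(len(v) * (v.mean() - gm) ** 2 for v in groups.values())
        ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        k, n = len(groups), len(allv)
        f_hand = (ssb / (k - 1)) / (ssw / (n - k))
        assert f == pytest.approx(f_hand)
        assert p == pytest.approx(stats.f.sf(f_hand, k - 1, n - k))

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            div.richness_anova({"a": [1], "b": [2, 3]})
        with pytest.raises(ValueError):
            div.richness_anova({"a": [1, 2]})
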