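import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import snptag as st
from snptag.mi import effective_entropy, entropy_from_pmf

from _oracles import deboor_basis, plugin_entropy, plugin_mi

TRILEVEL = np.array([0, 0, 1, 1, 2, 2], dtype=float)


class TestBinWeightProfile:
    def test_order1_is_indicator_binning(self, order1):
        prof = st.bin_weight_profile(TRILEVEL, order1)
        assert np.allclose(prof.sum(axis=1), 1.0)
        assert set(np.unique(prof)) == {0.0, 1.0}
        # distinct genotype values land in distinct bins
        bins = prof.argmax(axis=1)
        assert len({b for v, b in zip(TRILEVEL, bins)}) == 3

    def test_constant_vector_maps_all_samples_identically(self, cfg):
        prof = st.bin_weight_profile(np.ones(4), cfg)
        assert np.allclose(prof, prof[0])
        assert np.allclose(prof.sum(axis=1), 1.0)

    def test_order2_matches_de_boor_recursion(self, cfg):
        x = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        prof = st.bin_weight_profile(x, cfg)
        knots = cfg.knots()
        scaled = (x - x.min()) / (x.max() - x.min()) * cfg.domain_max
        expected = np.array(
            [
                [deboor_basis(v, knots, cfg.spline_order - 1, i) for i in range(4)]
                for v in scaled
            ]
        )
        np.testing.assert_allclose(prof, expected, atol=1e-12)

    def test_rows_sum_to_one_and_entries_in_unit_interval(self, cfg):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        prof = st.bin_weight_profile(x, cfg)
        assert np.allclose(prof.sum(axis=1), 1.0, atol=1e-9)
        assert prof.min() >= 0 and prof.max() <= 1

    def test_empty_vector_rejected(self, cfg):
        with pytest.raises(st.InvalidInputError):
            st.bin_weight_profile(np.array([]), cfg)


class TestEntropy:
    def test_point_mass_has_zero_entropy(self, cfg):
        prof = np.tile([1.0, 0, 0, 0], (6, 1))
        assert st.entropy(prof, cfg) == 0.0

    def test_uniform_four_bins_gives_two_bits(self, cfg):
        prof = np.eye(4)[[0, 1, 2, 3]]
        assert st.entropy(prof, cfg) == pytest.approx(2.0)

    def test_order1_profile_entropy_equals_histogram_plugin(self, order1):
        prof = st.bin_weight_profile(TRILEVEL, order1)
        assert st.entropy(prof, order1) == pytest.approx(
            plugin_entropy(tuple(TRILEVEL)), abs=1e-12
        )

    def test_entropy_bounded_by_log_bins(self, cfg):
        rng = np.random.default_rng(11)
        for _ in range(20):
            prof = st.bin_weight_profile(rng.normal(size=30), cfg)
            assert 0.0 <= st.entropy(prof, cfg) <= 2.0 + 1e-12


class TestMutualInformation:
    def test_self_information_identity_order1(self, order1):
        prof = st.bin_weight_profile(TRILEVEL, order1)
        assert st.mutual_information(TRILEVEL, TRILEVEL, order1) == pytest.approx(
            st.entropy(prof, order1), abs=1e-12
        )

    def test_self_information_equals_effective_entropy_order2(self, cfg):
        prof = st.bin_weight_profile(TRILEVEL, cfg)
        assert st.mutual_information(TRILEVEL, TRILEVEL, cfg) == pytest.approx(
            effective_entropy(prof, cfg.log_base), abs=1e-12
        )

    @pytest.mark.parametrize("order", [1, 2])
    def test_discrete_pairs_match_contingency_plugin(self, order):
        # at order 2, tri-level genotype pairs occupy disjoint bin supports,
        # so the soft-binned estimate reduces to the plug-in value too
        cfg = st.SimilarityConfig(spline_order=order)
        rng = np.random.default_rng(99)
        for _ in range(100):
            x = rng.integers(0, 3, 8).astype(float)
            y = rng.integers(0, 3, 8).astype(float)
            assert st.mutual_information(x, y, cfg) == pytest.approx(
                plugin_mi(tuple(x), tuple(y)), abs=1e-9
            )

    def test_independent_vectors_have_near_zero_mi(self, cfg):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 3, 5000).astype(float)
        y = rng.permutation(x)
        assert st.mutual_information(x, y, cfg) < 0.01

    def test_length_mismatch_rejected(self, cfg):
        with pytest.raises(st.InvalidInputError):
            st.mutual_information(np.zeros(3), np.zeros(4), cfg)

    def test_missing_entries_use_pairwise_complete_subset(self, cfg):
        x = np.array([0, 0, 1, 1, 2, 2, np.nan])
        y = np.array([0, 0, 1, 1, 2, 2, 1.0])
        complete = st.mutual_information(x[:6], y[:6], cfg)
        assert st.mutual_information(x, y, cfg) == pytest.approx(complete)


class TestNormalizedMI:
    def test_self_similarity_is_one(self, cfg):
        assert st.normalized_mi(TRILEVEL, TRILEVEL, cfg) == pytest.approx(1.0)

    def test_bijective_recoding_preserves_similarity(self, cfg):
        assert st.normalized_mi(TRILEVEL, 2 - TRILEVEL, cfg) == pytest.approx(1.0)

    def test_constant_argument_gives_zero(self, cfg):
        assert st.normalized_mi(TRILEVEL, np.ones(6), cfg) == 0.0
        assert st.normalized_mi(np.ones(6), TRILEVEL, cfg) == 0.0

    def test_sqrt_normalization_switch(self):
        cfg = st.SimilarityConfig(normalization="sqrt")
        assert st.normalized_mi(TRILEVEL, TRILEVEL, cfg) == pytest.approx(1.0)
        x = np.array([0, 0, 0, 1, 2, 2], dtype=float)
        assert 0.0 <= st.normalized_mi(TRILEVEL, x, cfg) <= 1.0

    def test_permutation_null_decreases_with_sample_size(self, cfg):
        means = []
        for p, seed in ((50, 1), (500, 2)):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 3, p).astype(float)
            vals = [
                st.normalized_mi(x, rng.permutation(x), cfg) for _ in range(30)
            ]
            means.append(np.mean(vals))
        assert means[1] < means[0]
        assert means[1] < 0.05

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        hst.lists(hst.integers(0, 2), min_size=4, max_size=12),
        hst.lists(hst.integers(0, 2), min_size=4, max_size=12),
    )
    def test_symmetry_and_range(self, xs, ys):
        n = min(len(xs), len(ys))
        x = np.array(xs[:n], dtype=float)
        y = np.array(ys[:n], dtype=float)
        cfg = st.SimilarityConfig()
        a = st.normalized_mi(x, y, cfg)
        b = st.normalized_mi(y, x, cfg)
        assert abs(a - b) < 1e-9
        assert 0.0 <= a <= 1.0


class TestSimilarity:
    def test_perfect_association_any_alpha(self):
        for alpha in (0.5, 2.0, 5.0):
            cfg = st.SimilarityConfig(alpha=alpha)
            assert st.similarity(TRILEVEL, TRILEVEL, cfg) == pytest.approx(1.0)

    def test_alpha_exponent_applied(self):
        # J = I**alpha: verified against the separately computed I
        cfg5 = st.SimilarityConfig(alpha=5.0)
        x = np.array([0, 1, 2, 0, 1, 2, 0, 0], dtype=float)
        y = np.array([0, 1, 1, 0, 2, 2, 1, 0], dtype=float)
        i_val = st.normalized_mi(x, y, cfg5)
        assert st.similarity(x, y, cfg5) == pytest.approx(i_val**5)
        assert 0.5**5 == 0.03125  # the shape the exponent imposes

    def test_sharper_alpha_never_increases_similarity(self):
        rng = np.random.default_rng(3)
        cfg2 = st.SimilarityConfig(alpha=2.0)
        cfg5 = st.SimilarityConfig(alpha=5.0)
        for _ in range(20):
            x = rng.integers(0, 3, 10).astype(float)
            y = rng.integers(0, 3, 10).astype(float)
            assert st.similarity(x, y, cfg5) <= st.similarity(x, y, cfg2) + 1e-12


def test_config_invariants_enforced():
    with pytest.raises(st.InvalidInputError):
        st.SimilarityConfig(alpha=-1)
    with pytest.raises(st.InvalidInputError):
        st.SimilarityConfig(num_bins=1, spline_order=2)
    with pytest.raises(st.InvalidInputError):
        st.SimilarityConfig(normalization="max")


def test_entropy_from_pmf_matches_closed_form():
    assert entropy_from_pmf(np.array([0.5, 0.5]), 2.0) == pytest.approx(1.0)
    assert entropy_from_pmf(np.array([1.0, 0.0]), 2.0) == 0.0
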