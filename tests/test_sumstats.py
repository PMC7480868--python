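import itertools
from collections import Counter

import numpy as np
import pytest

from wavesweep import (
    FixtureSpec,
    build_layout,
    featurize,
    filter_minor_allele_count,
    fit_standardization,
    generate_haplotypes,
    h_statistics,
    haplotype_spectrum,
    pi_hat,
    r2_moments,
    r2_pair,
    read_feature_table,
    standardize,
    write_feature_table,
)
from wavesweep.sumstats import ContractError, FeatureCurves, N_STATS


# ---------------------------------------------------------------------------
# independent brute-force oracles


def pi_oracle(w):
    n = w.shape[0]
    total = sum(
        int(np.sum(w[i] != w[j])) for i, j in itertools.combinations(range(n), 2)
    )
    return total / (n * (n - 1) / 2)


def spectrum_oracle(w):
    counts = Counter("".join(map(str, row)) for row in w)
    return sorted((c / w.shape[0] for c in counts.values()), reverse=True)


def r2_oracle(a, b):
    pa = a.mean()
    pb = b.mean()
    pab = np.mean(a * b)
    d = pab - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


def moments_oracle(vals):
    vals = np.asarray(vals, dtype=float)
    mean = vals.mean()
    m2 = ((vals - mean) ** 2).mean()
    if m2 < 1e-14:
        return mean, 0.0, 0.0, 0.0
    m3 = ((vals - mean) ** 3).mean()
    m4 = ((vals - mean) ** 4).mean()
    return mean, m2, m3 / m2**1.5, m4 / m2**2


def random_window(rng, n=20, w=10):
    """Random polymorphic window."""
    while True:
        mat = (rng.random((n, w)) < rng.uniform(0.1, 0.9, w)).astype(np.uint8)
        sums = mat.sum(axis=0)
        if np.all((sums > 0) & (sums < n)):
            return mat


class TestPiHat:
    def test_identical_haplotypes_give_zero(self):
        assert pi_hat(np.ones((5, 10), dtype=np.uint8)) == 0

    def test_single_pair_counts_differences(self):
        w = np.zeros((2, 10), dtype=np.uint8)
        w[1, :3] = 1
        assert pi_hat(w) == 3

    def test_four_haplotype_enumeration(self):
        w = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        # all 6 pairs: 4 pairs differ at 1 site? no: enumerate -> total 8
        assert pi_hat(w) == pytest.approx(8 / 6)
        assert pi_hat(w) == pytest.approx(pi_oracle(w))

    def test_requires_two_haplotypes(self):
        with pytest.raises(ValueError):
            pi_hat(np.array([[0, 1]]))


class TestSpectrum:
    def test_all_distinct_and_counting(self):
        w = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        assert haplotype_spectrum(w).tolist() == [0.25] * 4
        w2 = np.repeat(np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
                       [4, 3, 2, 1], axis=0)
        assert haplotype_spectrum(w2).tolist() == [0.4, 0.3, 0.2, 0.1]

    def test_matches_string_count_oracle(self):
        rng = np.random.default_rng(3)
        w = random_window(rng)
        np.testing.assert_allclose(haplotype_spectrum(w), spectrum_oracle(w))


class TestHStatistics:
    @pytest.mark.parametrize(
        "spectrum, expected",
        [
            ([1.0], (1.0, 1.0, 0.0)),
            ([0.4, 0.3, 0.2, 0.1], (0.30, 0.54, 0.4667)),
            ([0.5, 0.5], (0.5, 1.0, 0.5)),
        ],
    )
    def test_hand_evaluations(self, spectrum, expected):
        h1, h12, h2h1 = h_statistics(np.array(spectrum))
        assert (h1, h12, h2h1) == pytest.approx(expected, abs=1e-4)

    def test_rejects_unsorted_or_unnormalized(self):
        with pytest.raises(ContractError):
            h_statistics(np.array([0.3, 0.7]))
        with pytest.raises(ContractError):
            h_statistics(np.array([0.5, 0.4]))

    def test_ordering_invariant_h12_ge_h1_ge_h2(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            k = rng.integers(1, 10)
            s = np.sort(rng.dirichlet(np.ones(k)))[::-1]
            h1, h12, h2h1 = h_statistics(s)
            h2 = h1 - s[0] ** 2
            assert 0 <= h2 <= h1 <= h12 <= 1 + 1e-12


class TestR2:
    def test_identical_sites_give_one(self):
        a = np.array([1, 1, 0, 0, 1, 0])
        assert r2_pair(a, a) == pytest.approx(1.0)

    def test_independent_composition_gives_zero(self):
        a = np.array([1, 1, 0, 0])
        b = np.array([1, 0, 1, 0])
        assert r2_pair(a, b) == pytest.approx(0.0)

    def test_hand_computed_two_locus_table(self):
        # haplotype counts AB, Ab, aB, ab = 3, 1, 1, 3 over n = 8:
        # D = 3/8 - 1/2 * 1/2 = 1/8; r2 = (1/64) / (1/16) = 1/4
        a = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        b = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        assert r2_pair(a, b) == pytest.approx(0.25)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            r2_pair(np.zeros(6), np.array([1, 0, 1, 0, 1, 0]))

    def test_symmetric_and_relabeling_invariant(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            a = random_window(rng, n=16, w=1)[:, 0]
            b = random_window(rng, n=16, w=1)[:, 0]
            assert r2_pair(a, b) == pytest.approx(r2_pair(b, a))
            assert r2_pair(1 - a, b) == pytest.approx(r2_pair(a, b))

    def test_matches_d_based_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            a = random_window(rng, n=24, w=1)[:, 0]
            b = random_window(rng, n=24, w=1)[:, 0]
            assert r2_pair(a, b) == pytest.approx(r2_oracle(a, b), abs=1e-12)


class TestR2Moments:
    def test_cross_window_pair_count_and_oracle(self):
        rng = np.random.default_rng(14)
        wa = random_window(rng)
        wb = random_window(rng)
        vals = [r2_pair(wa[:, i], wb[:, j]) for i in range(10) for j in range(10)]
        assert len(vals) == 100
        got = r2_moments(wa, wb)
        assert got == pytest.approx(moments_oracle(vals), abs=1e-10)

    def test_self_pair_uses_distinct_pairs(self):
        rng = np.random.default_rng(15)
        w = random_window(rng)
        vals = [
            r2_pair(w[:, i], w[:, j]) for i, j in itertools.combinations(range(10), 2)
        ]
        assert len(vals) == 45
        assert r2_moments(w) == pytest.approx(moments_oracle(vals), abs=1e-10)

    def test_degenerate_distribution_rule(self):
        w = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.uint8)
        mean, var, skew, kurt = r2_moments(w)
        assert (mean, var, skew, kurt) == (1.0, 0.0, 0.0, 0.0)


class TestFeaturize:
    def test_shape_contract(self, trough_region, default_layout):
        fc = featurize(trough_region, default_layout)
        assert fc.curves.shape == (9, 128)
        assert fc.twod_blocks is None

    def test_trough_region_has_central_pi_minimum(self, trough_region, default_layout):
        fc = featurize(trough_region, default_layout)
        assert abs(int(fc.curves[0].argmin()) - 63.5) < 8
        assert abs(int(fc.curves[2].argmax()) - 63.5) < 8  # H12 maximum

    def test_2d_blocks_symmetric_and_bounded(self):
        h = filter_minor_allele_count(
            generate_haplotypes(FixtureSpec(pattern="trough", n_snps=60, seed=5))
        )
        layout = build_layout(p=8)
        fc = featurize(h, layout, include_2d=True)
        for name, block in fc.twod_blocks.items():
            assert block.shape == (4, 4)
            np.testing.assert_array_equal(block, block.T)
        assert np.all(fc.twod_blocks["r2_mean"] >= 0)
        assert np.all(fc.twod_blocks["r2_mean"] <= 1)
        assert np.all(fc.twod_blocks["r2_var"] >= 0)

    def test_anchor_beyond_region_rejected(self, trough_region, default_layout):
        with pytest.raises(ValueError):
            featurize(trough_region, default_layout,
                      anchor_offset=trough_region.n_sites)

    def test_statistic_range_invariants(self, trough_region, default_layout):
        fc = featurize(trough_region, default_layout)
        h1, h12 = fc.curves[1], fc.curves[2]
        assert np.all((h1 > 0) & (h1 <= 1))
        assert np.all(h12 >= h1 - 1e-12)
        hf = fc.curves[4:9]
        assert np.all(np.diff(hf, axis=0) <= 1e-12)  # descending top-5
        assert np.all((hf >= 0) & (hf <= 1))


class TestStandardization:
    def _toy(self, values):
        out = []
        for i, v in enumerate(values):
            curves = np.full((N_STATS, 4), float(v))
            out.append(FeatureCurves(obs_id=str(i), curves=curves))
        return out

    def test_identical_observations_guarded_to_unit_sd(self):
        train = self._toy([2.0, 2.0, 2.0])
        sp = fit_standardization(train)
        z = standardize(train[0], sp)
        assert np.all(sp.sds == 1.0)
        np.testing.assert_allclose(z.curves, 0.0)

    def test_two_point_population_z_scores(self):
        train = self._toy([1.0, 3.0])
        sp = fit_standardization(train)
        assert standardize(train[0], sp).curves[0, 0] == pytest.approx(-1.0)
        assert standardize(train[1], sp).curves[0, 0] == pytest.approx(1.0)

    def test_training_set_recentered(self, separable_train):
        feats, _ = separable_train
        sp = fit_standardization(feats)
        z = np.stack([standardize(fc, sp).curves for fc in feats])
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)

    def test_double_standardization_rejected(self):
        train = self._toy([1.0, 2.0])
        sp = fit_standardization(train)
        z = standardize(train[0], sp)
        with pytest.raises(ContractError):
            standardize(z, sp)


class TestFeatureTable:
    def test_round_trip_with_2d_blocks(self, tmp_path):
        h = filter_minor_allele_count(
            generate_haplotypes(FixtureSpec(pattern="trough", n_snps=60, seed=5))
        )
        layout = build_layout(p=8)
        fc = featurize(h, layout, include_2d=True, obs_id="rt")
        path = tmp_path / "f.tsv"
        write_feature_table([fc], str(path))
        (back,) = read_feature_table(str(path))
        assert back.obs_id == "rt"
        np.testing.assert_allclose(back.curves, fc.curves)
        for name in fc.twod_blocks:
            np.testing.assert_allclose(back.twod_blocks[name],
                                       fc.twod_blocks[name])
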