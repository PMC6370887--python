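"""Standardization, the π/4 rotation and its identities, COMET histograms,
quadrant occupancy and distribution moments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from comet.energetics import (
    DegenerateMapError, StandardizedPair, comet_histogram, distribution_moments,
    power_cost_pipeline, quadrant_occupancy, rotate_power_cost,
    rotate_power_cost_polar, standardize, verify_pca_equivalence,
)

from conftest import scalar_map

SQRT2 = np.sqrt(2.0)


def make_pair(x, y):
    return StandardizedPair(
        standardize(scalar_map(x, tag="log_lFCD")),
        standardize(scalar_map(y, tag="CMRglc")),
    )


def correlated_pair(rng, r, n):
    a = rng.normal(size=n)
    b = r * a + np.sqrt(1 - r * r) * rng.normal(size=n)
    return make_pair(a, b)


class TestStandardize:
    def test_hand_case_divisor_n(self):
        out = standardize(scalar_map([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.values, [-1.22474487, 0.0, 1.22474487],
                                   atol=1e-8)

    def test_idempotent(self, rng):
        z = standardize(scalar_map(rng.normal(size=500)))
        z2 = standardize(z)
        np.testing.assert_allclose(z2.values, z.values, atol=1e-10)

    def test_constant_map_degenerate(self):
        with pytest.raises(DegenerateMapError):
            standardize(scalar_map(np.full(10, 3.3)))

    def test_output_moments_exact(self, rng):
        z = standardize(scalar_map(rng.exponential(size=1000)))
        assert abs(z.values.mean()) < 1e-10
        assert abs(z.values.var() - 1.0) < 1e-10


class TestRotation:
    @pytest.mark.parametrize("za, zs, rpwr, rcst", [
        (1.0, 1.0, SQRT2, 0.0),
        (0.0, 1.0, 1 / SQRT2, 1 / SQRT2),
        (1.0, 0.0, 1 / SQRT2, -1 / SQRT2),
    ])
    def test_single_voxel_values(self, rng, za, zs, rpwr, rcst):
        # embed the target voxel in a standardized cloud, then check its image
        n = 2000
        a = np.concatenate([[za], rng.normal(size=n)])
        s = np.concatenate([[zs], rng.normal(size=n)])
        pair = make_pair(a, s)
        pc = rotate_power_cost(pair)
        za_std = pair.z_activity.values[0]
        zs_std = pair.z_supply.values[0]
        assert pc.rpwr.values[0] == pytest.approx((za_std + zs_std) / SQRT2)
        assert pc.rcst.values[0] == pytest.approx((zs_std - za_std) / SQRT2)

    def test_zero_means_always(self, rng):
        pair = correlated_pair(rng, 0.44, 5000)
        pc = rotate_power_cost(pair)
        assert abs(pc.rpwr.values.mean()) < 1e-10
        assert abs(pc.rcst.values.mean()) < 1e-10

    def test_per_voxel_isometry(self, rng):
        pair = correlated_pair(rng, 0.3, 3000)
        pc = rotate_power_cost(pair)
        lhs = pc.rpwr.values ** 2 + pc.rcst.values ** 2
        rhs = pair.z_activity.values ** 2 + pair.z_supply.values ** 2
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_variance_split_and_orthogonality(self, rng):
        pair = correlated_pair(rng, 0.44, 10000)
        r = pair.correlation
        pc = rotate_power_cost(pair)
        vp, vc = pc.variance_split
        assert vp == pytest.approx(1 + r, abs=1e-10)
        assert vc == pytest.approx(1 - r, abs=1e-10)
        cov = np.mean(pc.rpwr.values * pc.rcst.values)
        assert abs(cov) < 1e-10

    def test_polar_and_cartesian_forms_agree(self, rng):
        pair = correlated_pair(rng, 0.44, 5000)
        pc = rotate_power_cost(pair)
        rpwr_p, rcst_p = rotate_power_cost_polar(pair)
        np.testing.assert_allclose(pc.rpwr.values, rpwr_p, atol=1e-10)
        np.testing.assert_allclose(pc.rcst.values, rcst_p, atol=1e-10)

    def test_swap_antisymmetry(self, rng):
        a, s = rng.normal(size=300), rng.normal(size=300)
        pc = rotate_power_cost(make_pair(a, s))
        pc_swapped = rotate_power_cost(make_pair(s, a))
        np.testing.assert_allclose(pc_swapped.rpwr.values, pc.rpwr.values,
                                   atol=1e-12)
        np.testing.assert_allclose(pc_swapped.rcst.values, -pc.rcst.values,
                                   atol=1e-12)

    def test_supply_increase_raises_both_outputs(self, rng):
        # among voxels with identical activity, both outputs are strictly
        # ordered by supply (positive supply weight in both rotation rows)
        a = np.repeat(rng.normal(size=50), 2)
        s = rng.normal(size=100)
        pair = make_pair(a, s)
        pc = rotate_power_cost(pair)
        zs = pair.z_supply.values
        for i in range(0, 100, 2):
            lo, hi = (i, i + 1) if zs[i] < zs[i + 1] else (i + 1, i)
            assert pc.rpwr.values[hi] > pc.rpwr.values[lo]
            assert pc.rcst.values[hi] > pc.rcst.values[lo]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(hnp.arrays(np.float64, st.tuples(st.just(2), st.integers(8, 60)),
                      elements=st.floats(-50, 50, allow_nan=False)))
    def test_rotation_identities_hold_for_arbitrary_maps(self, xy):
        xs, ys = xy
        if np.std(xs) < 1e-6 or np.std(ys) < 1e-6:
            return
        pc = rotate_power_cost(make_pair(xs, ys))
        assert abs(pc.rpwr.values.mean()) < 1e-9
        assert abs(pc.rcst.values.mean()) < 1e-9
        vp, vc = pc.variance_split
        assert vp + vc == pytest.approx(2.0, abs=1e-8)


class TestPcaEquivalence:
    @pytest.mark.parametrize("r", [0.44, 0.9, 0.1])
    def test_first_axis_is_the_diagonal(self, rng, r):
        pair = correlated_pair(rng, r, 4000)
        assert verify_pca_equivalence(pair) < 1e-8

    def test_nonpositive_correlation_warns(self, rng):
        a = rng.normal(size=2000)
        b = -0.5 * a + np.sqrt(0.75) * rng.normal(size=2000)
        with pytest.warns(UserWarning, match="does not apply"):
            verify_pca_equivalence(make_pair(a, b))


class TestCometHistogram:
    def test_identical_pairs_single_bin(self):
        x = scalar_map(np.full(50, 2.0))
        h = comet_histogram(x, x, n_bins=8)
        assert h.total == 50
        assert h.counts.max() == 50
        assert np.isnan(h.pearson_r)

    def test_counts_conserved_and_r_reported(self, rng):
        n = 139269 // 10
        a = rng.normal(size=n)
        b = 0.44 * a + np.sqrt(1 - 0.44 ** 2) * rng.normal(size=n)
        h = comet_histogram(scalar_map(a), scalar_map(b))
        assert h.total == n
        assert h.pearson_r == pytest.approx(0.44, abs=0.03)


class TestQuadrants:
    def test_single_voxel_at_one_one(self):
        from comet.energetics import PowerCostMap
        m = scalar_map([1.0], tag="rPWR")
        pc = PowerCostMap(m, m.with_values(np.array([1.0]), "rCST"))
        occ = quadrant_occupancy(pc)
        assert occ.totals == {"hiP_hiC": 1, "hiP_loC": 0,
                              "loP_hiC": 0, "loP_loC": 0}

    def test_circular_symmetry_gives_quarter_shares(self, rng):
        pc = rotate_power_cost(correlated_pair(rng, 0.0, 10000))
        occ = quadrant_occupancy(pc)
        for q, share in occ.shares.items():
            assert share == pytest.approx(25.0, abs=2.0), q

    def test_positive_coupling_favors_power_quadrants_of_source_plane(self, rng):
        # under positive coupling, most voxels have concordant activity and
        # supply, i.e. land in the high-/low-power quadrants of the source
        # plane (|rPWR| > |rCST|); orthant probability 1/2 + arcsin(r)/pi
        from comet.energetics import power_dominant_share
        pc = rotate_power_cost(correlated_pair(rng, 0.44, 20000))
        share = power_dominant_share(pc)
        expected = 100 * (0.5 + np.arcsin(0.44) / np.pi)
        assert share > 50.0
        assert share == pytest.approx(expected, abs=2.0)
        # in the rotated plane itself the two axes are uncorrelated, so the
        # diagonal quadrants hold no comparable excess
        occ = quadrant_occupancy(pc)
        diag = occ.shares["hiP_hiC"] + occ.shares["loP_loC"]
        assert diag == pytest.approx(50.0, abs=2.0)

    def test_bin_geometry_and_overflow_partition(self, rng):
        pc = rotate_power_cost(correlated_pair(rng, 0.44, 5000))
        occ = quadrant_occupancy(pc, range_limit=1.0)  # force overflow
        for q in occ.totals:
            assert occ.bins[q].shape == (5, 5)
            assert occ.bins[q].sum() + occ.overflow[q] == occ.totals[q]
        assert sum(occ.overflow.values()) > 0


class TestMoments:
    def test_symmetric_values_zero_skew(self):
        skew, _ = distribution_moments(scalar_map([-2.0, -1.0, 0.0, 1.0, 2.0]))
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_normal_kurtosis_is_three(self, rng):
        _, kurt = distribution_moments(scalar_map(rng.normal(size=100000)))
        assert kurt == pytest.approx(3.0, abs=0.1)

    def test_exponential_skewness_is_two(self, rng):
        skew, _ = distribution_moments(scalar_map(rng.exponential(size=100000)))
        assert skew == pytest.approx(2.0, abs=0.1)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateMapError):
            distribution_moments(scalar_map(np.ones(10)))


class TestPipelineGeneralization:
    def test_supply_equal_activity_zero_cost(self, rng):
        m = scalar_map(rng.normal(size=400), tag="fALFF")
        pc = power_cost_pipeline(m, m.with_values(m.values, "CBF"))
        assert np.abs(pc.rcst.values).max() < 1e-10
        assert pc.source_tags == ("fALFF", "CBF")

    def test_supply_equal_negated_activity_zero_power(self, rng):
        m = scalar_map(rng.normal(size=400), tag="log_lFCD")
        pc = power_cost_pipeline(m, m.with_values(-m.values, "CMRglc"))
        assert np.abs(pc.rpwr.values).max() < 1e-10

    def test_alternative_modalities_share_latent_power(self, rng):
        # two (activity, supply) pairs built from one latent field: their
        # rPWR maps should agree strongly, mirroring the generalization to
        # CBF/fALFF
        n = 5000
        latent = rng.normal(size=n)
        pc1 = power_cost_pipeline(
            scalar_map(latent + 0.3 * rng.normal(size=n), tag="log_lFCD"),
            scalar_map(latent + 0.3 * rng.normal(size=n), tag="CMRglc"))
        pc2 = power_cost_pipeline(
            scalar_map(latent + 0.3 * rng.normal(size=n), tag="fALFF"),
            scalar_map(latent + 0.3 * rng.normal(size=n), tag="CBF"))
        r = np.corrcoef(pc1.rpwr.values, pc2.rpwr.values)[0, 1]
        assert r > 0.9
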