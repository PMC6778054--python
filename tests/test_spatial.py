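"""Spatial point statistics: minimum separations, densities, group tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fibgold.morphometry import ShellDecomposition, shell_decompose
from fibgold.spatial import (
    compare_groups,
    fold_change,
    invagination_association,
    nn_min_distances,
    peripheral_central_ratio,
    region_conditional_nn,
    region_density,
)


def table(points, compartment="nuclear", region="central"):
    points = np.atleast_2d(points)
    return pd.DataFrame(
        {
            "z_nm": points[:, 0],
            "y_nm": points[:, 1],
            "x_nm": points[:, 2],
            "compartment": compartment,
            "region": region,
        }
    )


def brute_force_nn(points):
    points = np.asarray(points, float)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


class TestNNMinDistances:
    def test_two_points_share_their_distance(self):
        res = nn_min_distances(table([[0, 0, 0], [0, 0, 500]]))
        np.testing.assert_allclose(res.distances_nm, [500.0, 500.0])

    def test_collinear_micron_points(self):
        res = nn_min_distances(table([[0, 0, 0], [0, 0, 1000], [0, 0, 3000]]))
        np.testing.assert_allclose(res.distances_nm, [1000.0, 1000.0, 2000.0])

    def test_index_matches_exhaustive_oracle_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pts = rng.uniform(0, 3000, (500, 3))
            res = nn_min_distances(table(pts))
            np.testing.assert_allclose(res.distances_nm, brute_force_nn(pts), rtol=1e-12)

    def test_fewer_than_two_points_rejected_with_scope(self):
        with pytest.raises(ValueError, match="peripheral"):
            nn_min_distances(table([[0, 0, 0]]), scope="peripheral")

    def test_histogram_covers_all_minima(self):
        rng = np.random.default_rng(1)
        res = nn_min_distances(table(rng.uniform(0, 2000, (50, 3))))
        assert res.hist_counts.sum() == 50


class TestRegionConditionalNN:
    def test_single_region_equals_unrestricted(self):
        rng = np.random.default_rng(2)
        t = table(rng.uniform(0, 2000, (40, 3)), region="peripheral")
        np.testing.assert_allclose(
            region_conditional_nn(t, "peripheral").distances_nm,
            nn_min_distances(t).distances_nm,
        )

    def test_two_by_two_split_matches_enumeration(self):
        pts = np.array([[0, 0, 0], [0, 0, 300], [0, 2000, 0], [0, 2000, 400]], float)
        t = table(pts)
        t["region"] = ["peripheral", "peripheral", "central", "central"]
        per = region_conditional_nn(t, "peripheral")
        cen = region_conditional_nn(t, "central")
        np.testing.assert_allclose(per.distances_nm, [300.0, 300.0])
        np.testing.assert_allclose(cen.distances_nm, [400.0, 400.0])

    def test_single_particle_region_rejected(self):
        t = table([[0, 0, 0], [0, 0, 500]])
        t["region"] = ["peripheral", "central"]
        with pytest.raises(ValueError):
            region_conditional_nn(t, "peripheral")


def _shell_from_volumes(p_um3, c_um3):
    # synthetic decomposition with prescribed region volumes: 1 µm cubes
    n_p = int(round(p_um3))
    n_c = int(round(c_um3))
    peripheral = np.zeros((max(n_p + n_c, 1), 1, 1), bool)
    central = np.zeros_like(peripheral)
    peripheral[:n_p] = True
    central[n_p : n_p + n_c] = True
    return ShellDecomposition(peripheral, central, 150.0, (1000.0, 1000.0, 1000.0))


class TestRegionDensity:
    def test_ten_particles_in_unit_volume(self):
        shell = _shell_from_volumes(1.0, 1.0)
        pts = table(np.zeros((10, 3)), region="peripheral")
        dens = region_density(pts, shell)
        assert dens["peripheral"].density_per_um3 == pytest.approx(10.0)
        assert dens["peripheral"].count == 10

    def test_empty_region_has_zero_density(self):
        shell = _shell_from_volumes(1.0, 2.0)
        pts = table(np.zeros((4, 3)), region="peripheral")
        dens = region_density(pts, shell)
        assert dens["central"].count == 0
        assert dens["central"].density_per_um3 == 0.0

    def test_counts_conserved_across_partition(self, invagination_analysis):
        result, _ = invagination_analysis
        rep = result["report"]
        assert (
            rep["n_labels_peripheral"] + rep["n_labels_central"]
            == rep["n_labels_nuclear"]
        )


class TestPeripheralCentralRatio:
    def test_planted_count_ratio(self):
        shell = _shell_from_volumes(1.0, 1.0)
        pts = table(np.zeros((40, 3)))
        pts["region"] = ["peripheral"] * 16 + ["central"] * 24
        dens = region_density(pts, shell)
        assert peripheral_central_ratio(dens) == pytest.approx(16 / 24)

    def test_equal_counts_give_unity(self):
        shell = _shell_from_volumes(1.0, 1.0)
        pts = table(np.zeros((20, 3)))
        pts["region"] = ["peripheral"] * 10 + ["central"] * 10
        assert peripheral_central_ratio(region_density(pts, shell)) == pytest.approx(1.0)

    def test_empty_centre_is_absent_not_zero(self):
        shell = _shell_from_volumes(1.0, 1.0)
        pts = table(np.zeros((5, 3)), region="peripheral")
        with pytest.warns(UserWarning):
            assert peripheral_central_ratio(region_density(pts, shell)) is None


class TestDensityInvariances:
    @given(
        shift=st.tuples(*[st.floats(-1e4, 1e4) for _ in range(3)]),
    )
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_nn_distances_invariant_under_rigid_translation(self, shift):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 2000, (30, 3))
        base = nn_min_distances(table(pts)).distances_nm
        moved = nn_min_distances(table(pts + np.asarray(shift))).distances_nm
        np.testing.assert_allclose(moved, base, rtol=1e-9, atol=1e-6)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_nn_distances_scale_linearly(self, scale):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 2000, (30, 3))
        base = nn_min_distances(table(pts)).distances_nm
        scaled = nn_min_distances(table(pts * scale)).distances_nm
        np.testing.assert_allclose(scaled, base * scale, rtol=1e-9)


class TestInvaginationAssociation:
    def test_particles_inside_invaginations_are_fully_associated(
        self, invagination_phantom
    ):
        from fibgold.morphometry import InvaginationSet

        _, gt = invagination_phantom
        inv = InvaginationSet(
            labels=gt.invagination_mask,
            table=pd.DataFrame(),
            per_slice_counts=pd.Series(dtype=int),
            spacing=gt.spec.spacing,
        )
        centers = np.array(np.nonzero(gt.invagination_mask)).T[:50] * np.array(
            gt.spec.spacing
        )
        pts = table(centers)
        assert invagination_association(pts, inv, max_dist_nm=0.0) == 100.0

    def test_no_invaginations_gives_zero_percent(self, small_phantom):
        from fibgold.morphometry import InvaginationSet

        _, gt = small_phantom
        inv = InvaginationSet(
            labels=np.zeros_like(gt.nucleus_mask, dtype=int),
            table=pd.DataFrame(),
            per_slice_counts=pd.Series(dtype=int),
            spacing=gt.spec.spacing,
        )
        pts = table([[0, 0, 0], [90, 50, 50]])
        assert invagination_association(pts, inv) == 0.0

    def test_zero_nuclear_particles_gives_absent(self, small_phantom):
        from fibgold.morphometry import InvaginationSet

        _, gt = small_phantom
        inv = InvaginationSet(
            labels=np.zeros_like(gt.nucleus_mask, dtype=int),
            table=pd.DataFrame(),
            per_slice_counts=pd.Series(dtype=int),
            spacing=gt.spec.spacing,
        )
        pts = table([[0, 0, 0]], compartment="cytosolic")
        assert invagination_association(pts, inv) is None


class TestFoldChange:
    def test_paper_style_ratio(self):
        assert fold_change(70, 50) == pytest.approx(1.4)

    def test_equal_counts(self):
        assert fold_change(5, 5) == 1.0

    def test_zero_numerator(self):
        assert fold_change(0, 50) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_change(10, 0)


class TestCompareGroups:
    def test_mann_whitney_exact_small_sample(self):
        res = compare_groups([1, 2, 3], [4, 5, 6], test="mann-whitney")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_exact_p_matches_enumeration_oracle(self):
        # enumerate all 20 assignments of ranks {1..6} into two triples
        a, b = (1, 2, 3), (4, 5, 6)
        pooled = a + b
        observed_u = sum(x < y for x in a for y in b)  # = 9 -> U_a = 0
        count_extreme = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in combo]
            gb = [pooled[i] for i in range(6) if i not in combo]
            u = sum(x > y for x in ga for y in gb)
            total += 1
            if min(u, 9 - u) <= min(observed_u, 9 - observed_u):
                count_extreme += 1
        assert count_extreme / total == pytest.approx(0.1)
        res = compare_groups(a, b)
        assert res.p_value == pytest.approx(count_extreme / total)

    def test_identical_groups_give_p_one(self):
        res = compare_groups([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value == pytest.approx(1.0)

    def test_wilcoxon_paired_requires_equal_sizes(self):
        with pytest.raises(ValueError, match="equal"):
            compare_groups([1, 2, 3, 4], [1, 2, 3], test="wilcoxon-paired")

    def test_minimum_sample_size_enforced(self):
        with pytest.raises(ValueError, match="at least 3"):
            compare_groups([1, 2], [3, 4, 5])

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError, match="unknown test"):
            compare_groups([1, 2, 3], [4, 5, 6], test="kruskal")
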