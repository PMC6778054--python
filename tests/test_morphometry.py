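"""Nuclear morphometry: segmentation, scalar measures, shell, invaginations."""

import numpy as np
import pytest
from scipy import ndimage

from fibgold.io import VoxelGrid
from fibgold.morphometry import (
    compute_sphericity,
    compute_surface_area,
    compute_volume,
    detect_invaginations,
    invaginations_per_section,
    segment_nucleus,
    shell_decompose,
)
from fibgold.synthetic import PhantomSpec, generate_phantom, make_nucleus


def ball_mask(radius_nm, spacing, margin=5):
    shape = tuple(int(2 * radius_nm / d) + 2 * margin + 1 for d in spacing)
    ax = [(np.arange(s) - (s - 1) / 2) * d for s, d in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*ax, indexing="ij")
    return zz**2 + yy**2 + xx**2 <= radius_nm**2


class TestVolume:
    def test_ball_volume_within_one_percent(self):
        mask = ball_mask(450.0, (10.0, 10.0, 10.0))
        assert compute_volume(mask, (10, 10, 10)) == pytest.approx(0.38179, rel=0.01)

    def test_empty_mask_has_zero_volume(self):
        assert compute_volume(np.zeros((4, 4, 4), bool), (90, 10, 10)) == 0.0

    def test_single_anisotropic_voxel(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        assert compute_volume(mask, (90, 10, 10)) == pytest.approx(9e-6)


class TestSurfaceArea:
    def test_ball_area_within_two_percent_at_fine_spacing(self):
        r = 300.0
        mask = ball_mask(r, (5.0, 5.0, 5.0))
        area = compute_surface_area(mask, (5, 5, 5))
        assert area == pytest.approx(4 * np.pi * r**2 / 1e6, rel=0.02)

    def test_box_area_within_five_percent(self):
        a, b, c = 400.0, 300.0, 200.0  # nm
        mask = np.zeros((60, 90, 110), bool)
        mask[10 : 10 + int(c / 5), 10 : 10 + int(b / 5), 10 : 10 + int(a / 5)] = True
        area = compute_surface_area(mask, (5, 5, 5))
        analytic = 2 * (a * b + b * c + a * c) / 1e6
        assert area == pytest.approx(analytic, rel=0.05)

    def test_refinement_reduces_error(self):
        r = 300.0
        analytic = 4 * np.pi * r**2 / 1e6
        coarse = abs(compute_surface_area(ball_mask(r, (10, 10, 10)), (10, 10, 10)) - analytic)
        fine = abs(compute_surface_area(ball_mask(r, (5, 5, 5)), (5, 5, 5)) - analytic)
        assert fine < coarse

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_surface_area(np.zeros((3, 3, 3), bool), (10, 10, 10))


class TestSphericity:
    def test_exact_sphere_is_one(self):
        r = 1.0
        assert compute_sphericity(4 / 3 * np.pi * r**3, 4 * np.pi * r**2) == pytest.approx(1.0)

    def test_cube_closed_form(self):
        assert compute_sphericity(1.0, 6.0) == pytest.approx((np.pi / 6) ** (1 / 3), rel=1e-6)

    def test_prolate_ellipsoid_against_numeric_oracle(self):
        # semi-axes (1, 1, 5) µm; V analytic, A by brute-force surface
        # integration in spherical parametrisation
        a, b, c = 1.0, 1.0, 5.0
        V = 4 / 3 * np.pi * a * b * c
        th = np.linspace(0, np.pi, 2001)
        ph = np.linspace(0, 2 * np.pi, 2001)
        T, P = np.meshgrid(th, ph, indexing="ij")
        # surface element of an ellipsoid parametrised by angles
        x = a * np.sin(T) * np.cos(P)
        y = b * np.sin(T) * np.sin(P)
        z = c * np.cos(T)
        xt = a * np.cos(T) * np.cos(P); yt = b * np.cos(T) * np.sin(P); zt = -c * np.sin(T)
        xp = -a * np.sin(T) * np.sin(P); yp = b * np.sin(T) * np.cos(P); zp = 0 * T
        cross = np.stack([yt * zp - zt * yp, zt * xp - xt * zp, xt * yp - yt * xp])
        dA = np.sqrt((cross**2).sum(axis=0))
        A = np.trapezoid(np.trapezoid(dA, ph, axis=1), th)
        expected = np.pi ** (1 / 3) * (6 * V) ** (2 / 3) / A
        # voxelized estimate
        spacing = (25.0, 25.0, 25.0)  # nm at 1 µm = 1000 nm axes scale
        mask = np.zeros((420, 100, 100), bool)
        ax0 = (np.arange(420) - 209.5) * 25
        ax1 = (np.arange(100) - 49.5) * 25
        zz, yy, xx = np.meshgrid(ax0, ax1, ax1, indexing="ij")
        mask = (zz / 5000) ** 2 + (yy / 1000) ** 2 + (xx / 1000) ** 2 <= 1
        s = compute_sphericity(
            compute_volume(mask, spacing), compute_surface_area(mask, spacing)
        )
        assert s == pytest.approx(expected, rel=0.03)

    def test_sphericity_decreases_with_elongation(self):
        values = []
        for aspect in [1, 2, 4, 8]:
            a = 200.0
            c = a * aspect
            mask_shape = (int(2 * c / 10) + 8, 52, 52)
            ax0 = (np.arange(mask_shape[0]) - (mask_shape[0] - 1) / 2) * 10
            ax1 = (np.arange(52) - 25.5) * 10
            zz, yy, xx = np.meshgrid(ax0, ax1, ax1, indexing="ij")
            mask = (zz / c) ** 2 + (yy / a) ** 2 + (xx / a) ** 2 <= 1
            values.append(
                compute_sphericity(
                    compute_volume(mask, (10, 10, 10)),
                    compute_surface_area(mask, (10, 10, 10)),
                )
            )
        assert values[0] <= 1.05
        assert all(v1 > v2 for v1, v2 in zip(values, values[1:]))

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_sphericity(0.0, 1.0)
        with pytest.raises(ValueError):
            compute_sphericity(1.0, -1.0)


class TestShellDecompose:
    def test_zero_thickness_makes_everything_central(self, small_phantom):
        _, gt = small_phantom
        shell = shell_decompose(gt.nucleus_mask, gt.spec.spacing, 0.0)
        assert not shell.peripheral_mask.any()
        assert (shell.central_mask == gt.nucleus_mask).all()

    def test_thickness_beyond_inradius_makes_everything_peripheral(self, small_phantom):
        _, gt = small_phantom
        shell = shell_decompose(gt.nucleus_mask, gt.spec.spacing, 10_000.0)
        assert not shell.central_mask.any()
        assert (shell.peripheral_mask == gt.nucleus_mask).all()

    def test_sphere_shell_fraction_matches_analytic(self):
        mask = ball_mask(500.0, (10.0, 10.0, 10.0))
        shell = shell_decompose(mask, (10, 10, 10), 150.0)
        frac = shell.peripheral_mask.sum() / mask.sum()
        assert frac == pytest.approx(1 - (350 / 500) ** 3, rel=0.02)

    def test_partition_is_exact(self, small_phantom):
        _, gt = small_phantom
        shell = shell_decompose(gt.nucleus_mask, gt.spec.spacing, 150.0)
        assert (
            shell.peripheral_mask.sum() + shell.central_mask.sum()
            == gt.nucleus_mask.sum()
        )

    def test_negative_thickness_rejected(self, small_phantom):
        _, gt = small_phantom
        with pytest.raises(ValueError):
            shell_decompose(gt.nucleus_mask, gt.spec.spacing, -1.0)


class TestSegmentNucleus:
    def test_phantom_segmentation_overlaps_truth(self, small_phantom):
        grid, gt = small_phantom
        mask = segment_nucleus(grid)
        dice = 2 * (mask & gt.nucleus_mask).sum() / (mask.sum() + gt.nucleus_mask.sum())
        assert dice >= 0.95

    def test_blank_volume_rejected(self):
        with pytest.raises(ValueError, match="contrast"):
            segment_nucleus(VoxelGrid(np.zeros((8, 64, 64)), (90, 10, 10)))

    def test_clean_binary_mask_passes_through(self, small_spec):
        # a {0,1} volume comes back essentially unchanged: only the
        # surface regularisation touches it, rounding the voxel staircase
        mask, _ = make_nucleus(small_spec)
        grid = VoxelGrid(mask.astype(np.float32), small_spec.spacing)
        out = segment_nucleus(grid, threshold=0.5, boundary_erode_nm=0.0)
        dice = 2 * (out & mask).sum() / (out.sum() + mask.sum())
        assert dice >= 0.97
        assert out.sum() == pytest.approx(mask.sum(), rel=0.05)


class TestInvaginations:
    def test_convex_body_has_no_invaginations(self, small_spec):
        mask, _ = make_nucleus(small_spec)
        inv = detect_invaginations(mask, small_spec.spacing)
        assert len(inv) == 0
        assert invaginations_per_section(inv) == 0.0

    def test_planted_tubes_detected_one_to_one(self, invagination_phantom):
        _, gt = invagination_phantom
        inv = detect_invaginations(gt.nucleus_mask, gt.spec.spacing)
        assert len(inv) == 5
        assert invaginations_per_section(inv) == pytest.approx(
            gt.invaginations_per_section
        )

    def test_shallow_dimple_excluded_by_depth_filter(self, small_spec):
        mask, _ = make_nucleus(small_spec)
        # carve a 100 nm-deep lateral notch: below the 200 nm depth default
        spec = PhantomSpec(
            **{
                **small_spec.__dict__,
                "n_invaginations": 1,
                "invagination_depth": 100.0,
                "invagination_radius": 120.0,
            }
        )
        from fibgold.synthetic import carve_invaginations

        carved, labels, _ = carve_invaginations(mask, spec, np.random.default_rng(2))
        inv = detect_invaginations(carved, spec.spacing, min_depth_nm=200.0)
        assert len(inv) == 0

    def test_single_tube_crossing_every_slice_counts_one(self):
        # synthetic mask: a slab with one lateral groove through all slices
        mask = np.ones((6, 120, 120), bool)
        mask[:, :, :20] = False
        mask[:, 55:66, 20:60] = False  # groove entering from the x face
        inv = detect_invaginations(mask, (90, 10, 10), min_depth_nm=200.0)
        assert invaginations_per_section(inv) == 1.0
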