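"""Synthetic FIB-SEM phantom generator with exhaustive ground truth.

Emulates the imaging situation of an immunogold slice-and-view
experiment: a superellipsoidal nucleus (elongated for grooved-substrate
cells, rounder for flat substrates) with membrane contrast and chromatin
texture; tubular inward invaginations of the nuclear envelope
(type II nucleoplasmic reticulum); gold labels enhanced to 20–30 nm
rendered as bright in-plane Gaussian spots with a hard-core exclusion
distance; per-slice translational stage drift; and Poisson–Gaussian
shot/readout noise.  Every stochastic element is seeded and every
planted feature is recorded, so each downstream stage (registration,
detection, segmentation, shell decomposition, invagination detection,
spatial statistics) can be scored against an exact truth.

All geometry is computed in physical nm on the anisotropic voxel grid:
the physical centre of voxel ``(i, j, k)`` is ``(i*dz, j*dy, k*dx)``.
Because label diameters (20–30 nm) are well below the ~90 nm section
spacing, each particle appears in exactly one section.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .io import VoxelGrid, write_stack

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PackingError",
    "make_nucleus",
    "carve_invaginations",
    "place_particles",
    "render_stack",
    "generate_phantom",
    "write_ground_truth",
]


class PackingError(RuntimeError):
    """Requested particle count is infeasible under the hard-core radius."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic nucleus volume.

    Distances are nm, shapes are voxels in ``(z, y, x)`` order.  Defaults
    describe the standard phantom: 10 nm in-plane / 90 nm section
    spacing, gold enhanced to 20–30 nm, a 150 nm peripheral shell, and a
    50 nm hard-core exclusion between label centres.
    """

    grid_shape: tuple[int, int, int] = (48, 320, 320)
    spacing: tuple[float, float, float] = (90.0, 10.0, 10.0)
    nucleus_axes: tuple[float, float, float] = (1620.0, 1400.0, 1200.0)
    nucleus_center: tuple[float, float, float] | None = None  # default: grid centre
    nucleus_exponent: float = 2.0  # 2 = ellipsoid; >2 boxier
    n_invaginations: int = 0
    invagination_depth: float = 600.0
    invagination_radius: float = 150.0
    n_particles: int = 300
    particle_diameter_range: tuple[float, float] = (20.0, 30.0)
    hardcore_radius: float = 50.0
    peripheral_fraction: float = 0.4
    shell_thickness: float = 150.0
    cytosolic_fraction: float = 0.1
    invagination_fraction: float = 0.0  # share of nuclear labels planted at invaginations
    association_dist_nm: float = 100.0
    drift_sigma: float = 0.0  # px per slice (incremental random walk)
    integer_drift: bool = True
    noise: tuple[float, float] = (0.08, 200.0)  # (gaussian_sigma, poisson_scale)
    particle_intensity: float = 1.0
    membrane_intensity: float = 0.7
    nucleus_intensity: float = 0.35
    cytosol_intensity: float = 0.2
    membrane_halfwidth_nm: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all voxel spacings must be positive")
        for name in ("peripheral_fraction", "cytosolic_fraction", "invagination_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.hardcore_radius < 0:
            raise ValueError("hardcore_radius must be >= 0")
        dmin, dmax = self.particle_diameter_range
        in_plane_extent = min(
            self.grid_shape[1] * self.spacing[1], self.grid_shape[2] * self.spacing[2]
        )
        if not 0 < dmin <= dmax < in_plane_extent:
            raise ValueError(
                f"particle_diameter_range {self.particle_diameter_range} must lie in "
                f"(0, {in_plane_extent})"
            )
        if self.nucleus_center is None:
            self.nucleus_center = tuple(
                (n - 1) / 2.0 * d for n, d in zip(self.grid_shape, self.spacing)
            )

    def expected_snr(self) -> float:
        """Planted spot peak over the background fluctuation s.d.

        The background of the nuclear interior fluctuates through
        readout noise, shot noise and chromatin texture (amplitude 0.15
        in the renderer); all three count, since all three compete with
        the spots.
        """
        gauss, pscale = self.noise
        shot_var = self.nucleus_intensity / pscale if pscale > 0 else 0.0
        chromatin_var = 0.15**2
        return self.particle_intensity / float(np.sqrt(gauss**2 + shot_var + chromatin_var))


@dataclass
class GroundTruth:
    """Everything the generator planted, in analysis-ready form."""

    spec: PhantomSpec
    nucleus_mask: np.ndarray
    peripheral_mask: np.ndarray
    central_mask: np.ndarray
    invagination_mask: np.ndarray  # int labels, 0 = background
    invagination_table: pd.DataFrame
    particles: pd.DataFrame
    slice_shifts: np.ndarray  # (nz, 2) per-slice (dy, dx) px relative to slice 0
    analytic_volume_nm3: float | None = None
    analytic_area_nm2: float | None = None
    analytic_area_exact: bool = False

    @property
    def invaginations_per_section(self) -> float:
        """Mean per-slice 2D invagination cross-section count over nucleus slices."""
        return _per_section_mean(self.invagination_mask > 0, self.nucleus_mask)


def _per_section_mean(feature_mask: np.ndarray, nucleus_mask: np.ndarray) -> float:
    slices = np.flatnonzero(nucleus_mask.any(axis=(1, 2)))
    if slices.size == 0:
        raise ValueError("nucleus mask intersects no slices")
    counts = [ndimage.label(feature_mask[z])[1] for z in slices]
    return float(np.mean(counts))


def _coord_axes(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return tuple(
        np.arange(n, dtype=np.float64) * d for n, d in zip(spec.grid_shape, spec.spacing)
    )


# ---------------------------------------------------------------------------
# Nucleus


def make_nucleus(spec: PhantomSpec) -> tuple[np.ndarray, dict | None]:
    """Voxelize the superellipsoid nucleus.

    A voxel belongs to the nucleus iff its physical centre satisfies
    ``sum(|(r_i - c_i)/a_i|^p) <= 1``.  Returns the boolean mask and,
    for the exact-ellipsoid case (p = 2), the analytic volume (always
    exact) and surface area (exact for a sphere, Thomsen's approximation
    otherwise, flagged as such).
    """
    c = np.asarray(spec.nucleus_center, dtype=float)
    a = np.asarray(spec.nucleus_axes, dtype=float)
    extent = np.asarray(spec.grid_shape) * np.asarray(spec.spacing)
    margin = 2.0 * np.asarray(spec.spacing)
    if np.any(c - a < margin) or np.any(c + a > extent - margin - np.asarray(spec.spacing)):
        raise ValueError(
            f"nucleus (centre {tuple(c)}, semi-axes {tuple(a)} nm) does not fit inside the "
            f"{tuple(extent)} nm grid with a 2-voxel margin"
        )
    z, y, x = _coord_axes(spec)
    p = spec.nucleus_exponent
    lhs = (
        np.abs((z[:, None, None] - c[0]) / a[0]) ** p
        + np.abs((y[None, :, None] - c[1]) / a[1]) ** p
        + np.abs((x[None, None, :] - c[2]) / a[2]) ** p
    )
    mask = lhs <= 1.0
    analytic = None
    if p == 2.0:
        az, ay, ax = a
        volume = 4.0 / 3.0 * np.pi * az * ay * ax
        if az == ay == ax:
            area, exact = 4.0 * np.pi * az**2, True
        else:
            q = 1.6075  # Thomsen's approximation, |err| < 1.1%
            area = 4.0 * np.pi * (((az * ay) ** q + (az * ax) ** q + (ay * ax) ** q) / 3.0) ** (1.0 / q)
            exact = False
        analytic = {"volume_nm3": volume, "area_nm2": area, "area_exact": exact}
    return mask, analytic


# ---------------------------------------------------------------------------
# Invaginations


def _surface_radius_inplane(spec: PhantomSpec, z_nm: float, direction: np.ndarray) -> float:
    """Distance from the nucleus axis to the superellipsoid surface at height z,
    along an in-plane unit direction (dy, dx)."""
    c = np.asarray(spec.nucleus_center)
    a = np.asarray(spec.nucleus_axes)
    p = spec.nucleus_exponent
    zterm = np.abs((z_nm - c[0]) / a[0]) ** p
    if zterm >= 1.0:
        return 0.0
    denom = np.abs(direction[0] / a[1]) ** p + np.abs(direction[1] / a[2]) ** p
    return float(((1.0 - zterm) / denom) ** (1.0 / p))


def _segment_points(p0: np.ndarray, p1: np.ndarray, n: int = 50) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return p0[None, :] * (1 - t) + p1[None, :] * t


def carve_invaginations(
    mask: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Carve tubular envelope invaginations into the nucleus mask.

    Each invagination is a capsule of ``invagination_radius`` entering
    the surface horizontally (within a section plane) and pointing at
    the nucleus axis, reaching ``invagination_depth`` inward.  Tubes are
    resampled until pairwise axis separation is at least three radii;
    tubes that cannot be placed without merging raise.  Returns the
    carved mask, an int-labelled invagination volume and a table with
    one row per invagination (entry point, axis, depth, radius).
    """
    cols = ["label", "entry_z_nm", "entry_y_nm", "entry_x_nm", "axis_dy", "axis_dx",
            "depth_nm", "radius_nm"]
    if spec.n_invaginations == 0:
        return mask.copy(), np.zeros(mask.shape, dtype=np.int32), pd.DataFrame(columns=cols)
    if spec.invagination_depth >= min(spec.nucleus_axes):
        raise ValueError(
            f"invagination depth {spec.invagination_depth} nm would bisect a nucleus with "
            f"smallest semi-axis {min(spec.nucleus_axes)} nm"
        )
    c = np.asarray(spec.nucleus_center)
    R = spec.invagination_radius
    depth = spec.invagination_depth
    dz = spec.spacing[0]
    # candidate sections: central half of the nucleus z-extent, where the
    # cross-section is wide enough for the full tube depth
    zlo, zhi = c[0] - 0.5 * spec.nucleus_axes[0], c[0] + 0.5 * spec.nucleus_axes[0]
    segments: list[np.ndarray] = []
    rows = []
    for label in range(1, spec.n_invaginations + 1):
        for _ in range(200):
            z_nm = float(rng.uniform(zlo, zhi) // dz * dz)  # snap to a section plane
            phi = rng.uniform(0, 2 * np.pi)
            u = np.array([np.cos(phi), np.sin(phi)])  # (dy, dx) outward
            r_surf = _surface_radius_inplane(spec, z_nm, u)
            if r_surf < depth + 2 * R:
                continue
            entry = np.array([z_nm, c[1] + r_surf * u[0], c[2] + r_surf * u[1]])
            tip = np.array([z_nm, c[1] + (r_surf - depth) * u[0], c[2] + (r_surf - depth) * u[1]])
            seg = _segment_points(entry, tip)
            ok = all(
                np.min(np.linalg.norm(seg[:, None, :] - other[None, :, :], axis=2)) >= 3 * R
                for other in segments
            )
            if ok:
                break
        else:
            raise ValueError(
                f"could not place invagination {label} without merging "
                f"(separation < 2 radii is rejected by policy)"
            )
        segments.append(seg)
        rows.append(dict(zip(cols, [label, *entry, *u, depth, R])))

    carved = mask.copy()
    labels = np.zeros(mask.shape, dtype=np.int32)
    zax, yax, xax = _coord_axes(spec)
    for row, seg in zip(rows, segments):
        entry = np.array([row["entry_z_nm"], row["entry_y_nm"], row["entry_x_nm"]])
        tip = seg[-1]
        lo = np.minimum(entry, tip) - R - np.asarray(spec.spacing)
        hi = np.maximum(entry, tip) + R + np.asarray(spec.spacing)
        i0 = np.maximum(0, np.searchsorted(zax, lo[0]) - 1), np.searchsorted(zax, hi[0]) + 1
        j0 = np.maximum(0, np.searchsorted(yax, lo[1]) - 1), np.searchsorted(yax, hi[1]) + 1
        k0 = np.maximum(0, np.searchsorted(xax, lo[2]) - 1), np.searchsorted(xax, hi[2]) + 1
        zz = zax[i0[0]:i0[1]][:, None, None]
        yy = yax[j0[0]:j0[1]][None, :, None]
        xx = xax[k0[0]:k0[1]][None, None, :]
        # distance from voxel centres to the axis segment
        d_ax = tip - entry
        L2 = float(d_ax @ d_ax)
        pz, py, px = zz - entry[0], yy - entry[1], xx - entry[2]
        t = np.clip((pz * d_ax[0] + py * d_ax[1] + px * d_ax[2]) / L2, 0.0, 1.0)
        dist2 = (pz - t * d_ax[0]) ** 2 + (py - t * d_ax[1]) ** 2 + (px - t * d_ax[2]) ** 2
        box = (slice(*i0), slice(*j0), slice(*k0))
        inside_tube = dist2 <= R**2
        newly = inside_tube & carved[box]
        carved[box] &= ~inside_tube
        labels[box][newly] = row["label"]

    n_comp = ndimage.label(carved)[1]
    if n_comp != 1:
        raise RuntimeError(f"carving split the nucleus into {n_comp} components")
    return carved, labels, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Particles

_PARTICLE_COLS = [
    "id", "z_nm", "y_nm", "x_nm", "diameter_nm", "compartment", "region", "invagination_id",
]

# planting guard bands around the association criterion (see docs/methods.md):
# associated labels go within ASSOC_PLANT_MAX of the invagination surface,
# non-associated labels stay beyond NONASSOC_PLANT_MIN, so the planted
# percentage is unambiguous under detector z-quantization (≤ dz/2 = 45 nm).
ASSOC_PLANT_MAX = 50.0
NONASSOC_PLANT_MIN = 180.0
_INTERIOR_GUARD = 30.0   # nuclear labels at least this far inside the envelope
_CYTO_GUARD = 60.0       # cytosolic labels at least this far outside it


def _feasible(count: int, region_mask: np.ndarray, spec: PhantomSpec, name: str) -> None:
    if count == 0:
        return
    if not region_mask.any():
        raise PackingError(f"region '{name}' is empty; cannot place {count} particles")
    if spec.hardcore_radius > 0:
        vox_vol = float(np.prod(spec.spacing))
        region_vol = region_mask.sum() * vox_vol
        sphere_vol = 4.0 / 3.0 * np.pi * (spec.hardcore_radius / 2.0) ** 3
        if count * sphere_vol > 0.64 * region_vol:  # random close packing bound
            raise PackingError(
                f"{count} particles with a {spec.hardcore_radius} nm hard core cannot pack "
                f"into region '{name}' ({region_vol:.3g} nm³)"
            )


def place_particles(gt_masks: dict, spec: PhantomSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Plant gold-label centres by stratified hard-core sampling.

    Strata counts are exact (rounded once, never in expectation):
    cytosolic mislabels first, then invagination-associated nuclear
    labels, then the remaining nuclear labels split peripheral/central
    by ``peripheral_fraction``.  A candidate is rejected when closer
    than ``hardcore_radius`` to any accepted centre.

    ``gt_masks`` must provide ``nucleus``, ``peripheral``, ``central``
    and ``invagination`` (labelled) volumes.
    """
    nucleus = gt_masks["nucleus"].astype(bool)
    peripheral = gt_masks["peripheral"].astype(bool)
    central = gt_masks["central"].astype(bool)
    invag = gt_masks["invagination"]
    spacing = np.asarray(spec.spacing)

    n = spec.n_particles
    n_cyto = int(round(spec.cytosolic_fraction * n))
    n_nucl = n - n_cyto
    has_invag = bool((invag > 0).any())
    n_assoc = int(round(spec.invagination_fraction * n_nucl)) if has_invag else 0
    n_rest = n_nucl - n_assoc
    n_periph = int(round(spec.peripheral_fraction * n_rest))
    n_central = n_rest - n_periph

    d_in = ndimage.distance_transform_edt(nucleus, sampling=spec.spacing)
    d_out = ndimage.distance_transform_edt(~nucleus, sampling=spec.spacing)
    if has_invag:
        d_inv, inv_idx = ndimage.distance_transform_edt(
            invag == 0, sampling=spec.spacing, return_indices=True
        )
    else:
        d_inv = np.full(nucleus.shape, np.inf)
        inv_idx = None

    border = np.zeros(nucleus.shape, dtype=bool)
    m = 2
    border[:m], border[-m:] = True, True
    border[:, :m], border[:, -m:] = True, True
    border[:, :, :m], border[:, :, -m:] = True, True

    interior = nucleus & (d_in >= _INTERIOR_GUARD)
    strata = [
        ("cytosolic", n_cyto, ~nucleus & (d_out >= _CYTO_GUARD) & ~border & (invag == 0)),
        ("invagination-associated", n_assoc, interior & (d_inv <= ASSOC_PLANT_MAX)),
        ("peripheral", n_periph, interior & peripheral & (d_inv >= NONASSOC_PLANT_MIN)),
        ("central", n_central, interior & central & (d_inv >= NONASSOC_PLANT_MIN)),
    ]
    for name, count, region in strata:
        _feasible(count, region, spec, name)

    accepted: list[np.ndarray] = []
    rows = []
    pid = 0
    hc2 = spec.hardcore_radius**2
    for name, count, region in strata:
        if count == 0:
            continue
        flat = np.flatnonzero(region)
        placed = 0
        attempts = 0
        max_attempts = 400 * count
        while placed < count:
            attempts += 1
            if attempts > max_attempts:
                raise PackingError(
                    f"exceeded {max_attempts} attempts placing particles in region '{name}'"
                )
            vox = np.array(np.unravel_index(rng.choice(flat), region.shape))
            pos = vox * spacing + rng.uniform(-0.5, 0.5, 3) * spacing
            if accepted:
                arr = np.asarray(accepted)
                if np.min(np.sum((arr - pos) ** 2, axis=1)) < hc2:
                    continue
            accepted.append(pos)
            compartment = "nuclear" if nucleus[tuple(vox)] else "cytosolic"
            if compartment == "nuclear":
                region_label = "peripheral" if peripheral[tuple(vox)] else "central"
            else:
                region_label = "none"
            inv_id: float = np.nan
            if name == "invagination-associated" and inv_idx is not None:
                nearest = tuple(inv_idx[:, vox[0], vox[1], vox[2]])
                inv_id = float(invag[nearest])
            rows.append(
                {
                    "id": pid,
                    "z_nm": pos[0],
                    "y_nm": pos[1],
                    "x_nm": pos[2],
                    "diameter_nm": rng.uniform(*spec.particle_diameter_range),
                    "compartment": compartment,
                    "region": region_label,
                    "invagination_id": inv_id,
                }
            )
            pid += 1
            placed += 1
    return pd.DataFrame(rows, columns=_PARTICLE_COLS)


# ---------------------------------------------------------------------------
# Rendering


def _shift_slice(img: np.ndarray, dy: float, dx: float, cval: float) -> np.ndarray:
    """Translate one section, zero-order for integer shifts, linear otherwise."""
    if float(dy).is_integer() and float(dx).is_integer():
        out = np.full_like(img, cval)
        iy, ix = int(dy), int(dx)
        src_y = slice(max(0, -iy), img.shape[0] - max(0, iy))
        src_x = slice(max(0, -ix), img.shape[1] - max(0, ix))
        dst_y = slice(max(0, iy), img.shape[0] - max(0, -iy))
        dst_x = slice(max(0, ix), img.shape[1] - max(0, -ix))
        out[dst_y, dst_x] = img[src_y, src_x]
        return out
    return ndimage.shift(img, (dy, dx), order=1, mode="constant", cval=cval)


def render_stack(
    gt_masks: dict,
    particles: pd.DataFrame,
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> tuple[VoxelGrid, np.ndarray]:
    """Render the phantom to an intensity stack.

    Compositing order: cytosol background, nuclear interior with
    low-frequency chromatin texture, a bright membrane band traced along
    the (possibly invaginated) envelope, one 2D Gaussian spot per
    particle whose FWHM equals its diameter, then per-slice drift and
    finally Poisson–Gaussian noise.  Returns the stack and the applied
    per-slice shifts ``(dy, dx)`` in px relative to slice 0.
    """
    nucleus = gt_masks["nucleus"].astype(bool)
    nz, ny, nx = spec.grid_shape
    dz, dy_nm, dx_nm = spec.spacing
    vol = np.full(spec.grid_shape, spec.cytosol_intensity, dtype=np.float64)
    vol[nucleus] = spec.nucleus_intensity

    # cytosolic organelles: thresholded smooth random field, giving
    # sharp-membraned bodies a few hundred nm across that span 2-3
    # sections — the registerable content real sections always carry
    field = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), sigma=(3.0, 5, 5))
    sd = field.std()
    if sd > 0:
        field /= sd
        outside = ~nucleus
        vol[outside & (field > 0.9)] += 0.22
        vol[outside & (field < -0.9)] -= 0.14
    # chromatin granularity: ~100-300 nm domains persist across adjacent
    # 90 nm sections (z-coherent) and carry fine in-plane grain, as in
    # heavy-metal-stained heterochromatin
    texture = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), sigma=(2.5, 2, 2))
    sd = texture.std()
    if sd > 0:
        vol[nucleus] += 0.15 * (texture[nucleus] / sd)
    # fine cytosolic/resin grain, also section-spanning
    grain = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), sigma=(2.5, 1.5, 1.5))
    sd = grain.std()
    if sd > 0:
        vol[~nucleus] += 0.08 * (grain[~nucleus] / sd)

    d_in = ndimage.distance_transform_edt(nucleus, sampling=spec.spacing)
    d_out = ndimage.distance_transform_edt(~nucleus, sampling=spec.spacing)
    band = (nucleus & (d_in <= spec.membrane_halfwidth_nm)) | (
        ~nucleus & (d_out <= spec.membrane_halfwidth_nm)
    )
    vol[band] = spec.membrane_intensity

    fwhm_to_sigma = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    for row in particles.itertuples(index=False):
        zi = int(round(row.z_nm / dz))
        if not 0 <= zi < nz:
            continue
        sig_y = row.diameter_nm * fwhm_to_sigma / dy_nm
        sig_x = row.diameter_nm * fwhm_to_sigma / dx_nm
        cy, cx = row.y_nm / dy_nm, row.x_nm / dx_nm
        half = int(np.ceil(4 * max(sig_y, sig_x)))
        j0, j1 = max(0, int(cy) - half), min(ny, int(cy) + half + 2)
        k0, k1 = max(0, int(cx) - half), min(nx, int(cx) + half + 2)
        jj = np.arange(j0, j1)[:, None]
        kk = np.arange(k0, k1)[None, :]
        spot = spec.particle_intensity * np.exp(
            -0.5 * (((jj - cy) / sig_y) ** 2 + ((kk - cx) / sig_x) ** 2)
        )
        vol[zi, j0:j1, k0:k1] += spot

    shifts = np.zeros((nz, 2))
    if spec.drift_sigma > 0:
        steps = rng.normal(0.0, spec.drift_sigma, size=(nz - 1, 2))
        walk = np.cumsum(steps, axis=0)
        # field-of-view tracking: operators re-centre the ROI, so the
        # net excursion stays bounded; reflect the walk at +/- 15 px
        m = 15.0
        walk = np.abs((walk + m) % (4 * m) - 2 * m) - m
        shifts[1:] = walk
        if spec.integer_drift:
            shifts = np.round(shifts)
        for z in range(1, nz):
            vol[z] = _shift_slice(vol[z], shifts[z, 0], shifts[z, 1], spec.cytosol_intensity)

    gauss_sigma, poisson_scale = spec.noise
    if poisson_scale > 0:
        vol = rng.poisson(np.clip(vol, 0, None) * poisson_scale) / poisson_scale
    if gauss_sigma > 0:
        vol = vol + rng.normal(0.0, gauss_sigma, size=vol.shape)

    return VoxelGrid(vol.astype(np.float32), spec.spacing), shifts


# ---------------------------------------------------------------------------
# Orchestration


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, GroundTruth]:
    """Build the full phantom: geometry, truth masks, particles, rendering."""
    from .morphometry import shell_decompose

    ss = np.random.SeedSequence(spec.seed)
    rng_inv, rng_part, rng_render = (np.random.default_rng(s) for s in ss.spawn(3))

    mask, analytic = make_nucleus(spec)
    mask, invag_labels, invag_table = carve_invaginations(mask, spec, rng_inv)
    shell = shell_decompose(mask, spec.spacing, thickness_nm=spec.shell_thickness)
    masks = {
        "nucleus": mask,
        "peripheral": shell.peripheral_mask,
        "central": shell.central_mask,
        "invagination": invag_labels,
    }
    particles = place_particles(masks, spec, rng_part)
    grid, shifts = render_stack(masks, particles, spec, rng_render)
    gt = GroundTruth(
        spec=spec,
        nucleus_mask=mask,
        peripheral_mask=shell.peripheral_mask,
        central_mask=shell.central_mask,
        invagination_mask=invag_labels,
        invagination_table=invag_table,
        particles=particles,
        slice_shifts=shifts,
        analytic_volume_nm3=None if analytic is None else analytic["volume_nm3"],
        analytic_area_nm2=None if analytic is None else analytic["area_nm2"],
        analytic_area_exact=bool(analytic and analytic["area_exact"]),
    )
    return grid, gt


def write_ground_truth(grid: VoxelGrid, gt: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    """Persist the phantom bundle: stack + masks as TIFF, tables as CSV, spec as YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spacing = gt.spec.spacing
    paths = {
        "stack": write_stack(grid, outdir / "stack.tif"),
        "nucleus_mask": write_stack(
            VoxelGrid(gt.nucleus_mask.astype(np.uint8), spacing), outdir / "nucleus_mask.tif"
        ),
        "peripheral_mask": write_stack(
            VoxelGrid(gt.peripheral_mask.astype(np.uint8), spacing), outdir / "peripheral_mask.tif"
        ),
        "central_mask": write_stack(
            VoxelGrid(gt.central_mask.astype(np.uint8), spacing), outdir / "central_mask.tif"
        ),
        "invagination_mask": write_stack(
            VoxelGrid(gt.invagination_mask.astype(np.uint8), spacing),
            outdir / "invagination_mask.tif",
        ),
    }
    gt.particles.to_csv(outdir / "particles.csv", index=False)
    paths["particles"] = outdir / "particles.csv"
    pd.DataFrame(gt.slice_shifts, columns=["dy_px", "dx_px"]).to_csv(
        outdir / "shifts.csv", index_label="slice"
    )
    paths["shifts"] = outdir / "shifts.csv"
    spec_dict = asdict(gt.spec)
    for key, val in spec_dict.items():
        if isinstance(val, tuple):
            spec_dict[key] = list(val)
    (outdir / "phantom.yaml").write_text(yaml.safe_dump(spec_dict, sort_keys=False))
    paths["spec"] = outdir / "phantom.yaml"
    return paths
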