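"""Desk-scale synthetic cardiac geometries on regular voxel grids.

The reference geometries — MRI-derived bi-ventricular rabbit meshes, one with
fine-scale endocardial structure (vessels, papillary muscles, trabeculae) and
one smoothed — are cluster-scale FEM meshes. This module generates voxelised
stand-ins with the same salient contrasts at desk scale:

* :func:`make_sheet` — 2-D isotropic sheets for spiral-wave runs;
* :func:`make_slab` — 3-D slabs with linear transmural fiber rotation;
* :func:`make_biventricular_shell` — two intersecting ellipsoidal shells
  (thick "LV", thin "RV"), optionally perturbed with seeded vessel-like
  tunnels and endocardial ridges (:class:`StructureConfig`).

Conventions: 0-based voxel indices; world coordinates are ``index * spacing``
at voxel centres; all masks are single face-connected components; fiber
vectors are unit norm inside the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "Domain",
    "StructureConfig",
    "Conductivity",
    "make_sheet",
    "make_slab",
    "make_biventricular_shell",
    "conductivity_field",
    "CHI",
    "CM",
]

#: Surface-to-volume ratio (1/cm) and membrane capacitance (uF/cm^2).
CHI = 1400.0
CM = 1.0

SURFACE_NONE, SURFACE_EPI, SURFACE_ENDO = 0, 1, 2


@dataclass
class Domain:
    """Voxelised simulation geometry.

    ``mask`` is boolean occupancy on a regular grid (2-D arrays are treated
    as single-layer 3-D by the solver); ``fibers`` is an optional per-voxel
    unit vector field of shape ``mask.shape + (3,)``; ``surfaces`` labels
    boundary voxels epicardial (1) / endocardial (2).
    """

    spacing: float
    mask: np.ndarray
    dimensionality: int
    descriptor: str
    fibers: Optional[np.ndarray] = None
    surfaces: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != self.dimensionality:
            raise ValueError("mask dimensionality mismatch")
        if not self.mask.any():
            raise ValueError("empty domain mask")
        if self.fibers is not None:
            norms = np.linalg.norm(self.fibers[self.mask], axis=-1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("fiber vectors must be unit norm inside the mask")

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    @property
    def n_inside(self) -> int:
        return int(self.mask.sum())

    @property
    def volume(self) -> float:
        """Myocardial volume in cm^dim."""
        return self.n_inside * self.spacing ** self.dimensionality

    def world(self, idx) -> np.ndarray:
        """World coordinates (cm) of voxel indices (voxel centres)."""
        return np.asarray(idx, dtype=float) * self.spacing

    def is_connected(self) -> bool:
        structure = ndimage.generate_binary_structure(self.mask.ndim, 1)
        _, n = ndimage.label(self.mask, structure=structure)
        return n == 1


@dataclass
class StructureConfig:
    """Procedural fine-structure parameters for the shell generator.

    Real fine-structure statistics are not prescribed anywhere; these are free parameters
    swept at desk scale. Defaults perturb, and must not dominate: the
    structured shell volume stays within 15% of the smooth shell.
    """

    cavity_count: int = 6
    protrusion_density: float = 0.15
    feature_scale: float = 0.08  # cm
    seed: int = 0


def _label_surfaces(mask: np.ndarray, cavity: np.ndarray) -> np.ndarray:
    """Label mask voxels adjacent to cavity as endo, to outside as epi."""
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    outside = ~mask & ~cavity
    near_out = ndimage.binary_dilation(outside, structure) & mask
    near_cav = ndimage.binary_dilation(cavity, structure) & mask
    surf = np.zeros(mask.shape, dtype=np.uint8)
    surf[near_out] = SURFACE_EPI
    surf[near_cav] = SURFACE_ENDO  # endo wins on thin walls
    return surf


def make_sheet(side: float = 2.5, spacing: float = 0.0125,
               fiber_angle: Optional[float] = None) -> Domain:
    """Full rectangular 2-D sheet; isotropic (no fibers) by default, the
    standard setting for 2-D spiral-wave experiments. ``fiber_angle`` (degrees from +x) attaches a
    uniform in-plane fiber field for anisotropic conduction checks.

    Default spacing 0.0125 cm matches the ~125 um average edge length of
    MRI-derived rabbit ventricular meshes. Requires at least 50 voxels per side.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    n = int(round(side / spacing))
    if n < 50:
        raise ValueError(f"sheet of {n} voxels per side is degenerate (need >= 50)")
    mask = np.ones((n, n), dtype=bool)
    fibers = None
    if fiber_angle is not None:
        a = np.deg2rad(fiber_angle)
        fibers = np.zeros((n, n, 3))
        fibers[..., 0] = np.cos(a)
        fibers[..., 1] = np.sin(a)
    surf = np.zeros_like(mask, dtype=np.uint8)
    surf[0, :] = surf[-1, :] = surf[:, 0] = surf[:, -1] = SURFACE_EPI
    return Domain(spacing=spacing, mask=mask, dimensionality=2,
                  descriptor="sheet", fibers=fibers, surfaces=surf)


def make_slab(dims: tuple[float, float, float] = (2.0, 2.0, 0.4),
              spacing: float = 0.025, fiber_rotation: float = 0.0) -> Domain:
    """3-D slab with in-plane fibers rotating linearly across thickness (z).

    ``fiber_rotation`` is the total endo-to-epi rotation in degrees; the
    angle steps by ``rotation/(nz-1)`` between adjacent layers. The two large
    faces are labelled endo (z=0) and epi (z=top).
    """
    nx, ny, nz = (max(1, int(round(d / spacing))) for d in dims)
    if min(nx, ny) < 8 or nz < 2:
        raise ValueError("slab dimensions degenerate at this spacing")
    mask = np.ones((nx, ny, nz), dtype=bool)
    fibers = np.zeros((nx, ny, nz, 3))
    angles = (np.deg2rad(fiber_rotation) * np.arange(nz) / max(nz - 1, 1))
    fibers[..., 0] = np.cos(angles)[None, None, :]
    fibers[..., 1] = np.sin(angles)[None, None, :]
    surf = np.zeros(mask.shape, dtype=np.uint8)
    surf[:, :, 0] = SURFACE_ENDO
    surf[:, :, -1] = SURFACE_EPI
    return Domain(spacing=spacing, mask=mask, dimensionality=3,
                  descriptor="slab", fibers=fibers, surfaces=surf)


def _ellipsoid(shape, center, semi, spacing):
    idx = np.indices(shape, dtype=float)
    r2 = np.zeros(shape)
    for a in range(3):
        r2 += ((idx[a] * spacing - center[a]) / semi[a]) ** 2
    return r2 <= 1.0


def make_biventricular_shell(config: Optional[StructureConfig] = None,
                             spacing: float = 0.05,
                             outer_size: tuple[float, float, float] = (2.5, 2.5, 3.0),
                             lv_wall: float = 0.35, rv_wall: float = 0.15,
                             with_fibers: bool = False) -> Domain:
    """Idealised bi-ventricular shell: thick-walled "LV" ellipsoid with a
    thinner "RV" crescent wrapped around one side, apex closed, base open.

    With ``config`` given, fine structure is carved/added deterministically
    from ``config.seed``: vessel-like tunnels through the wall and
    trabecula-like endocardial ridges. Raises if the result is disconnected.
    With ``with_fibers``, a circumferential fiber field with +/-60 degree
    transmural rotation about the local z axis is attached.
    """
    sx, sy, sz = outer_size
    shape = (int(round(sx / spacing)) + 1, int(round(sy / spacing)) + 1,
             int(round(sz / spacing)) + 1)
    # LV: centred ellipsoid; long axis z, apex at low z, base cut at high z.
    lv_c = (0.5 * sx, 0.5 * sy, 0.56 * sz)
    lv_semi = (0.36 * sx, 0.36 * sy, 0.52 * sz)
    lv_out = _ellipsoid(shape, lv_c, lv_semi, spacing)
    lv_cav = _ellipsoid(shape, lv_c, tuple(s - lv_wall for s in lv_semi), spacing)
    # RV: larger, offset ellipsoid shell intersected with a half-space.
    rv_c = (0.5 * sx + 0.18 * sx, 0.5 * sy, 0.60 * sz)
    rv_semi = (0.42 * sx, 0.30 * sy, 0.44 * sz)
    rv_out = _ellipsoid(shape, rv_c, rv_semi, spacing)
    rv_cav = _ellipsoid(shape, rv_c, tuple(s - rv_wall for s in rv_semi), spacing)
    x_world = np.arange(shape[0])[:, None, None] * spacing
    rv_side = x_world > lv_c[0] + 0.1 * sx
    mask = (lv_out & ~lv_cav) | (rv_out & ~rv_cav & rv_side & ~lv_cav)
    cavity = (lv_cav | (rv_cav & rv_side))
    # open base: cut everything above the basal plane
    z_world = np.arange(shape[2])[None, None, :] * spacing
    base = z_world > 0.92 * sz
    mask &= ~base
    cavity &= ~base
    seed_used = None
    if config is not None:
        seed_used = config.seed
        rng = np.random.default_rng(config.seed)
        mask, cavity = _add_fine_structure(mask, cavity, spacing, config, rng)
    # keep the largest connected component, then verify it is the only one
    structure = ndimage.generate_binary_structure(3, 1)
    lab, n = ndimage.label(mask, structure=structure)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        if sizes.max() < 0.95 * mask.sum():
            raise ValueError("fine-structure parameters disconnected the shell")
        mask = lab == (1 + int(np.argmax(sizes)))
    surf = _label_surfaces(mask, cavity)
    fibers = _shell_fibers(mask, surf, spacing, lv_c) if with_fibers else None
    return Domain(spacing=spacing, mask=mask, dimensionality=3,
                  descriptor="shell_structured" if config else "shell_smooth",
                  fibers=fibers, surfaces=surf, seed=seed_used)


def _add_fine_structure(mask, cavity, spacing, config: StructureConfig, rng):
    """Carve vessel-like tunnels and add endocardial ridge protrusions."""
    shape = mask.shape
    r_vox = max(1, int(round(config.feature_scale / spacing)))
    structure = ndimage.generate_binary_structure(3, 1)
    wall = mask.copy()
    # tunnels: spheres marched along straight chords through the wall
    wall_idx = np.argwhere(wall)
    for _ in range(config.cavity_count):
        p = wall_idx[rng.integers(len(wall_idx))].astype(float)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        length = rng.uniform(3, 10) * r_vox
        for s in np.arange(0.0, length, 1.0):
            c = np.round(p + s * d).astype(int)
            if np.any(c < 0) or np.any(c >= np.array(shape)):
                break
            sl = tuple(slice(max(0, c[a] - r_vox), c[a] + r_vox + 1) for a in range(3))
            sub = np.indices(mask[sl].shape).transpose(1, 2, 3, 0)
            off = c - np.array([s0.start for s0 in sl])
            ball = ((sub - off) ** 2).sum(-1) <= r_vox ** 2
            carved = mask[sl] & ball
            mask[sl] &= ~ball
            cavity[sl] |= carved
    # protrusions: dilate the wall into the cavity at seeded endo patches
    endo = ndimage.binary_dilation(cavity, structure) & mask
    endo_idx = np.argwhere(endo)
    n_patches = int(config.protrusion_density * len(endo_idx) / max(r_vox ** 2, 1))
    for _ in range(n_patches):
        c = endo_idx[rng.integers(len(endo_idx))]
        sl = tuple(slice(max(0, c[a] - r_vox), c[a] + r_vox + 1) for a in range(3))
        sub = np.indices(mask[sl].shape).transpose(1, 2, 3, 0)
        off = c - np.array([s0.start for s0 in sl])
        ball = ((sub - off) ** 2).sum(-1) <= r_vox ** 2
        grown = cavity[sl] & ball
        mask[sl] |= grown
        cavity[sl] &= ~ball
    return mask, cavity


def _shell_fibers(mask, surfaces, spacing, axis_center):
    """Circumferential fibers with transmural rotation about local z.

    The helix angle varies linearly from -60 deg (endo) to +60 deg (epi)
    with normalised transmural depth d_endo/(d_endo + d_epi) from the
    labelled surfaces. The apex carries an unavoidable orientation vortex
    (a continuous non-vanishing tangent field cannot exist on a cap).
    """
    from scipy.ndimage import distance_transform_edt

    from scipy.ndimage import gaussian_filter

    d_endo = distance_transform_edt(surfaces != SURFACE_ENDO)
    d_epi = distance_transform_edt(surfaces != SURFACE_EPI)
    with np.errstate(invalid="ignore"):
        depth = np.where(d_endo + d_epi > 0, d_endo / (d_endo + d_epi), 0.5)
    # masked smoothing keeps the helix-angle step below ~25 deg/voxel even
    # across the thin (3-voxel) right-ventricular wall
    w = gaussian_filter(mask.astype(float), 1.5)
    depth = np.where(w > 1e-6, gaussian_filter(depth * mask, 1.5) / np.maximum(w, 1e-6), depth)
    idx = np.indices(mask.shape, dtype=float)
    x = idx[0] * spacing - axis_center[0]
    y = idx[1] * spacing - axis_center[1]
    r = np.hypot(x, y)
    on_axis = r == 0
    r[on_axis] = 1.0
    circ = np.stack([-y / r, x / r, np.zeros_like(r)], axis=-1)
    circ[on_axis] = (1.0, 0.0, 0.0)  # deterministic direction at the vortex core
    zhat = np.zeros_like(circ)
    zhat[..., 2] = 1.0
    alpha = np.deg2rad(-60.0 + 120.0 * depth)
    f = np.cos(alpha)[..., None] * circ + np.sin(alpha)[..., None] * zhat
    f /= np.linalg.norm(f, axis=-1, keepdims=True)
    f[~mask] = 0.0
    return f


@dataclass
class Conductivity:
    """Per-voxel diffusivity description consumed by the solver.

    Stored as diffusivities D = sigma/(chi*C_m) in cm^2/ms: either a scalar
    ``d_iso`` or a symmetric tensor field ``D_T I + (D_L - D_T) f f^T``
    given by its six unique components.
    """

    mode: str  # "isotropic" | "anisotropic"
    d_iso: float = 0.0
    tensor: Optional[np.ndarray] = None  # shape + (6,): xx, yy, zz, xy, xz, yz
    chi: float = CHI
    cm: float = CM

    @property
    def sigma_iso(self) -> float:
        """Scalar conductivity in mS/cm (chi * C_m * d_iso; with chi in
        1/cm, C_m in uF/cm^2 and D in cm^2/ms the product is mS/cm since
        mS/uF = 1/ms)."""
        return self.chi * self.cm * self.d_iso

    def max_diffusivity(self) -> float:
        if self.mode == "isotropic":
            return self.d_iso
        return float(self.tensor[..., :3].max())


def conductivity_field(domain: Domain, mode: str = "isotropic",
                       D_L: float = 0.001, D_T: Optional[float] = None,
                       sigma_iso: float = 0.466, chi: float = CHI,
                       cm: float = CM) -> Conductivity:
    """Build the conductivity description for a domain.

    Anisotropic: ``sigma = chi C_m (D_T I + (D_L - D_T) f f^T)`` with
    defaults D_L = 0.001 cm^2/ms and D_T = D_L/9 (fiber:cross-fiber velocity
    ratio 3:1). Isotropic: scalar ``sigma_iso`` in mS/cm, default 0.466,
    i.e. the geometric mean chi C_m sqrt(D_L D_T) that preserves wave area
    in planes containing the fiber direction.
    """
    if mode == "isotropic":
        d_iso = sigma_iso / (chi * cm)  # mS/cm -> cm^2/ms (mS/uF = 1/ms)
        return Conductivity(mode="isotropic", d_iso=d_iso, chi=chi, cm=cm)
    if mode != "anisotropic":
        raise ValueError(f"unknown conductivity mode {mode!r}")
    if domain.fibers is None:
        raise ValueError("anisotropic conductivity requires a fiber field")
    if D_T is None:
        D_T = D_L / 9.0
    f = domain.fibers
    t = np.zeros(domain.shape + (6,))
    t[..., 0] = D_T + (D_L - D_T) * f[..., 0] ** 2
    t[..., 1] = D_T + (D_L - D_T) * f[..., 1] ** 2
    t[..., 2] = D_T + (D_L - D_T) * f[..., 2] ** 2
    t[..., 3] = (D_L - D_T) * f[..., 0] * f[..., 1]
    t[..., 4] = (D_L - D_T) * f[..., 0] * f[..., 2]
    t[..., 5] = (D_L - D_T) * f[..., 1] * f[..., 2]
    t[~domain.mask] = 0.0
    return Conductivity(mode="anisotropic", tensor=t, chi=chi, cm=cm)
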