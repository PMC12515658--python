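"""Synthetic brain phantoms and paired tumor studies.

The phantom emulates the geometry and statistics of clinical surveillance
data at desk scale: a concentric-ellipsoid brain (gray-matter cortex over a
white-matter interior with two CSF ventricles) on an anisotropic grid
(~0.9 mm in-plane, ~7 mm slices), plus a spherical tumor with a necrotic
core, an enhancing rim, and an edema halo.  Intensity volumes are built to
be exactly consistent with the linear intensity-to-density mapping used to
initialize the model: with zero noise, imputing an initial state from a
generated baseline recovers the target density field identically, and a
follow-up can be manufactured by actually running the growth model — the
ground-truth pair for parameter-recovery experiments.

What the phantom does *not* emulate: MRI physics (bias fields, motion,
multi-scanner variation), irregular tumor shapes, mass effect, and
co-registration error between time points.  Tests passing on phantoms
validate the computational pipeline, not clinical accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .grids import TissueLabel, VoxelGrid
from .io import ImagingStudy
from .params import ModelParameters
from .pde import SolverOptions, build_coefficients, impute_initial_state, simulate
from .metrics import classify_state

__all__ = [
    "PhantomSpec",
    "make_brain_grid",
    "make_baseline_study",
    "make_followup_by_simulation",
]

# background intensity levels (arbitrary units on a 0-250 scale)
_T1C_TISSUE, _T1C_CSF, _T1C_NECROTIC = 30.0, 20.0, 10.0
_T2_TISSUE, _T2_CSF = 50.0, 180.0
# affine intensity<->density maps inside the tumor masks
_T1C_OFFSET, _T1C_SLOPE = 40.0, 200.0  # t1c = 40 + 200*density (increasing)
_T2_OFFSET, _T2_SLOPE = 250.0, 2500.0  # t2 = 250 - 2500*density (decreasing)


@dataclass
class PhantomSpec:
    """Geometry and noise settings for one synthetic tumor study.

    Radii are physical (mm) and must be strictly nested:
    necrotic < rim < edema.  ``tumor_center`` is a voxel index triple; when
    omitted it is placed off-center in the white matter, clear of the
    ventricles.  ``noise_sd`` is the standard deviation of additive
    Gaussian intensity noise (masks stay noise-free: manual segmentations
    are treated as ground truth).
    """

    dims: tuple[int, int, int] = (32, 32, 8)
    spacing: tuple[float, float, float] = (0.9, 0.9, 7.0)
    tumor_center: Optional[tuple[int, int, int]] = None
    rim_radius_mm: float = 3.5
    edema_radius_mm: float = 6.5
    necrotic_radius_mm: float = 1.2
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.necrotic_radius_mm < self.rim_radius_mm < self.edema_radius_mm):
            raise ValueError(
                "tumor shells must be strictly nested: "
                f"necrotic ({self.necrotic_radius_mm}) < rim ({self.rim_radius_mm}) "
                f"< edema ({self.edema_radius_mm}) mm"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _ellipsoid_radius2(grid_coords, center_mm, semi_axes_mm) -> np.ndarray:
    X, Y, Z = grid_coords
    return (
        ((X - center_mm[0]) / semi_axes_mm[0]) ** 2
        + ((Y - center_mm[1]) / semi_axes_mm[1]) ** 2
        + ((Z - center_mm[2]) / semi_axes_mm[2]) ** 2
    )


def make_brain_grid(
    dims: tuple[int, int, int] = (32, 32, 8),
    spacing: tuple[float, float, float] = (0.9, 0.9, 7.0),
) -> VoxelGrid:
    """Concentric-ellipsoid brain phantom.

    BACKGROUND outside the outer shell, a GRAY cortical shell, a WHITE
    interior, and two CSF ellipsoids (lateral ventricles) inside the white
    matter.  Requires at least 8 voxels per axis so all layers fit.
    """
    dims = tuple(int(n) for n in dims)
    spacing = tuple(float(s) for s in spacing)
    if any(n < 8 for n in dims):
        raise ValueError(f"dims must be >= 8 per axis to host all layers, got {dims}")

    labels = np.zeros(dims, dtype=np.uint8)
    axes = [
        (np.arange(n, dtype=float) - (n - 1) / 2.0) * h for n, h in zip(dims, spacing)
    ]
    coords = np.meshgrid(*axes, indexing="ij")

    # brain envelope: semi-axes at 42% of each physical extent keeps a
    # background margin even at the minimum 8-voxel dimension
    semi = tuple(0.42 * n * h for n, h in zip(dims, spacing))
    rho2 = _ellipsoid_radius2(coords, (0.0, 0.0, 0.0), semi)
    labels[rho2 <= 1.0] = TissueLabel.GRAY
    labels[rho2 <= 0.80**2] = TissueLabel.WHITE

    # two lateral ventricles, fully inside the white matter
    vent_semi = (0.12 * semi[0], 0.20 * semi[1], 0.16 * semi[2])
    for sx in (-1.0, 1.0):
        center = (sx * 0.30 * semi[0], -0.25 * semi[1], 0.0)
        v2 = _ellipsoid_radius2(coords, center, vent_semi)
        labels[(v2 <= 1.0) & (labels == TissueLabel.WHITE)] = TissueLabel.CSF

    return VoxelGrid(labels=labels, spacing=spacing)


def _default_center(grid: VoxelGrid) -> tuple[int, int, int]:
    nx, ny, nz = grid.dims
    hx, hy, hz = grid.spacing
    # offset toward +y, clear of the ventricles; central slice
    y_mm = 0.40 * 0.42 * ny * hy
    cy = int(round((ny - 1) / 2.0 + y_mm / hy))
    return (nx // 2, min(cy, ny - 1), nz // 2)


def _tumor_shells(grid: VoxelGrid, spec: PhantomSpec):
    center = spec.tumor_center or _default_center(grid)
    X, Y, Z = grid.coordinates_mm()
    c_mm = tuple(
        (center[a] - (grid.dims[a] - 1) / 2.0) * grid.spacing[a] for a in range(3)
    )
    r = np.sqrt((X - c_mm[0]) ** 2 + (Y - c_mm[1]) ** 2 + (Z - c_mm[2]) ** 2)
    necrotic = r <= spec.necrotic_radius_mm if spec.necrotic_radius_mm > 0 else np.zeros_like(r, bool)
    enhancing = (r <= spec.rim_radius_mm) & ~necrotic
    edema = (r <= spec.edema_radius_mm) & ~(enhancing | necrotic)
    whole = necrotic | enhancing | edema
    outside = whole & ~grid.tissue_mask
    if outside.any():
        raise ValueError(
            f"tumor shells extend outside gray/white tissue "
            f"({int(np.count_nonzero(outside))} voxel(s) in BACKGROUND/CSF); "
            "move the tumor center or shrink the radii"
        )
    if not enhancing.any():
        raise ValueError("enhancing rim contains no voxels; enlarge rim_radius_mm")
    return center, r, necrotic, enhancing, edema


def _span_window(raw: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Min-max rescale raw values onto [lo, hi]; constant input -> midpoint."""
    rmin, rmax = raw.min(), raw.max()
    if rmax > rmin:
        return lo + (raw - rmin) / (rmax - rmin) * (hi - lo)
    return np.full_like(raw, (lo + hi) / 2.0)


def make_baseline_study(
    grid: VoxelGrid, spec: PhantomSpec, params: ModelParameters
) -> ImagingStudy:
    """Generate a baseline study with intensities encoding a target density.

    The target density decreases radially from the core: across the
    enhancing rim it spans the window I_c (upper bound at the inner edge),
    across the edema halo it spans I_e.  T1C intensity increases linearly
    with target density inside the enhancing mask; T2 intensity decreases
    linearly with it inside the edema mask — so with ``noise_sd = 0``,
    :func:`~gliosim.pde.impute_initial_state` inverts the construction
    exactly.  Gaussian noise (clipped at 0) is added to intensities only.
    """
    center, r, necrotic, enhancing, edema = _tumor_shells(grid, spec)
    rng = np.random.default_rng(spec.seed)

    density = np.zeros(grid.dims, dtype=float)
    # radially decreasing raw profiles, rescaled to span each window exactly
    density[enhancing] = _span_window(
        (spec.rim_radius_mm - r[enhancing]), *params.I_c
    )
    if edema.any():
        density[edema] = _span_window(
            (spec.edema_radius_mm - r[edema]), *params.I_e
        )

    labels = grid.labels
    t1c = np.zeros(grid.dims, dtype=float)
    t1c[grid.tissue_mask] = _T1C_TISSUE
    t1c[labels == TissueLabel.CSF] = _T1C_CSF
    t1c[enhancing] = _T1C_OFFSET + _T1C_SLOPE * density[enhancing]
    t1c[necrotic] = _T1C_NECROTIC

    t2 = np.zeros(grid.dims, dtype=float)
    t2[grid.tissue_mask] = _T2_TISSUE
    t2[labels == TissueLabel.CSF] = _T2_CSF
    t2[edema] = _T2_OFFSET - _T2_SLOPE * density[edema]

    if spec.noise_sd > 0:
        t1c = t1c + rng.normal(0.0, spec.noise_sd, size=grid.dims)
        t2 = t2 + rng.normal(0.0, spec.noise_sd, size=grid.dims)
        np.clip(t1c, 0.0, None, out=t1c)
        np.clip(t2, 0.0, None, out=t2)

    return ImagingStudy(
        grid=grid,
        t1c=t1c,
        t2=t2,
        enhancing_mask=enhancing,
        edema_mask=edema,
        necrotic_mask=necrotic if necrotic.any() else None,
        day=0,
    )


def make_followup_by_simulation(
    baseline: ImagingStudy,
    params: ModelParameters,
    days: int,
    opts: Optional[SolverOptions] = None,
) -> ImagingStudy:
    """Manufacture a ground-truth follow-up by running the growth model.

    The baseline is imputed and simulated for ``days`` days with
    ``params``; the final state is re-segmented with the same windows, and
    intensities re-encode the simulated density through the inverse linear
    maps.  With ``days = 0`` the follow-up is the virtual segmentation of
    the imputed baseline state itself.  The construction is deterministic:
    the model has no stochastic components.
    """
    grid = baseline.grid
    state = impute_initial_state(baseline, params)
    if days > 0:
        coeffs = build_coefficients(grid, baseline, params)
        state = simulate(state, coeffs, grid, days, opts)
    enhancing, edema = classify_state(state, params)
    # simulated density can stray outside tissue labels only via masks; the
    # windows exclude zero-density voxels, so masks stay within tissue
    u = state.total

    labels = grid.labels
    t1c = np.zeros(grid.dims, dtype=float)
    t1c[grid.tissue_mask] = _T1C_TISSUE
    t1c[labels == TissueLabel.CSF] = _T1C_CSF
    t1c[enhancing] = _T1C_OFFSET + _T1C_SLOPE * u[enhancing]

    t2 = np.zeros(grid.dims, dtype=float)
    t2[grid.tissue_mask] = _T2_TISSUE
    t2[labels == TissueLabel.CSF] = _T2_CSF
    t2[edema] = _T2_OFFSET - _T2_SLOPE * u[edema]

    return ImagingStudy(
        grid=VoxelGrid(labels=grid.labels.copy(), spacing=grid.spacing),
        t1c=t1c,
        t2=t2,
        enhancing_mask=enhancing,
        edema_mask=edema,
        day=baseline.day + int(days),
    )
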