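"""Parametric R2*/T1 brain phantom with focal iron lesions.

The phantom is a uniform tissue background holding two disjoint spherical
regions of interest (ipsilateral, i.e. tumour-bearing, and contralateral
striatum) plus two families of focal R2* elevations:

* macrophage foci — endogenous iron-laden perivascular macrophages; present
  in both the pre- and post-contrast states, so they produce *pre-existing*
  hypointensities that cancel in the post-minus-pre difference;
* MPIO foci — endothelium-bound microparticles of iron oxide; present only
  in the post-contrast state, so they drive the contrast-induced difference.

Iron susceptibility "blooming" is modelled as a local ΔR2* sphere around
each focus centre; no dipole-field or phase simulation is attempted because
the downstream analysis consumes magnitude hypointensity only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FocusSpec", "PhantomSpec", "Phantom", "generate_phantom", "default_phantom_spec"]


@dataclass(frozen=True)
class FocusSpec:
    """A spherical focal R2* elevation.

    ``centre`` is in voxel coordinates (0-based, may be fractional),
    ``radius`` in mm (the effective blooming radius) and ``delta_r2star``
    in 1/s, added to every voxel whose centre lies within ``radius``.
    """

    centre: tuple[float, float, float]
    radius: float = 0.4
    delta_r2star: float = 500.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("focus radius must be positive")
        if self.delta_r2star < 0:
            raise ValueError("delta_r2star must be >= 0")


@dataclass
class PhantomSpec:
    """Specification of a two-state (pre/post contrast) phantom."""

    grid: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (0.3516, 0.3516, 0.3516)  # mm; 22.5 mm / 64
    tissue_r2star: float = 40.0  # 1/s, grey matter at 9.4 T
    tissue_t1: float = 1.9  # s
    proton_density: float = 1.0
    striatum_ipsi_mask: np.ndarray | None = None
    striatum_contra_mask: np.ndarray | None = None
    macrophage_foci: list[FocusSpec] = field(default_factory=list)
    mpio_foci: list[FocusSpec] = field(default_factory=list)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.striatum_ipsi_mask is None or self.striatum_contra_mask is None:
            raise ValueError("both striatum masks are required")
        ipsi = np.asarray(self.striatum_ipsi_mask, dtype=bool)
        contra = np.asarray(self.striatum_contra_mask, dtype=bool)
        if ipsi.shape != tuple(self.grid) or contra.shape != tuple(self.grid):
            raise ValueError("mask shapes must match the phantom grid")
        if np.any(ipsi & contra):
            raise ValueError("ipsilateral and contralateral masks overlap")
        if self.tissue_t1 <= 0:
            raise ValueError("tissue_t1 must be positive")
        for focus in list(self.macrophage_foci) + list(self.mpio_foci):
            if any(c < 0 or c > g - 1 for c, g in zip(focus.centre, self.grid)):
                raise ValueError(f"focus centre {focus.centre} outside grid {self.grid}")


@dataclass
class Phantom:
    """Realised pre/post-contrast R2* maps plus masks and tissue properties."""

    pre_r2star: np.ndarray
    post_r2star: np.ndarray
    t1: float
    proton_density: float
    ipsi: np.ndarray
    contra: np.ndarray
    voxel_size: tuple[float, float, float]
    spec: PhantomSpec


def _add_focus(r2star: np.ndarray, focus: FocusSpec, voxel_size: tuple[float, float, float]) -> None:
    """Add a spherical ΔR2* contribution in place, over a local bounding box."""
    vs = np.asarray(voxel_size, dtype=float)
    centre = np.asarray(focus.centre, dtype=float)
    half = np.ceil(focus.radius / vs).astype(int) + 1
    lo = np.maximum(np.floor(centre).astype(int) - half, 0)
    hi = np.minimum(np.ceil(centre).astype(int) + half + 1, r2star.shape)
    idx = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    d2 = sum(((ax - c) * v) ** 2 for ax, c, v in zip(idx, centre, vs))
    inside = d2 <= focus.radius**2
    sub = tuple(slice(a, b) for a, b in zip(lo, hi))
    r2star[sub][inside] += focus.delta_r2star


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Realise the pre- and post-contrast R2* maps of a phantom spec.

    The post-contrast map equals the pre-contrast map plus the summed
    contributions of all MPIO foci; macrophage foci contribute to both
    states. Deterministic: the same spec always yields the same phantom.
    """
    spec.validate()
    pre = np.full(tuple(spec.grid), float(spec.tissue_r2star))
    for focus in spec.macrophage_foci:
        _add_focus(pre, focus, spec.voxel_size)
    post = pre.copy()
    for focus in spec.mpio_foci:
        _add_focus(post, focus, spec.voxel_size)
    return Phantom(
        pre_r2star=pre,
        post_r2star=post,
        t1=float(spec.tissue_t1),
        proton_density=float(spec.proton_density),
        ipsi=np.asarray(spec.striatum_ipsi_mask, dtype=bool),
        contra=np.asarray(spec.striatum_contra_mask, dtype=bool),
        voxel_size=tuple(spec.voxel_size),
        spec=spec,
    )


def spherical_mask(
    grid: tuple[int, int, int], centre: tuple[float, float, float], radius_voxels: float
) -> np.ndarray:
    """Boolean mask of voxels within ``radius_voxels`` of ``centre`` (voxel units)."""
    idx = np.meshgrid(*[np.arange(g) for g in grid], indexing="ij")
    d2 = sum((ax - c) ** 2 for ax, c in zip(idx, centre))
    return d2 <= radius_voxels**2


def default_phantom_spec(grid: int = 64, **kwargs) -> PhantomSpec:
    """Desk-scale phantom: 64^3 grid, FOV-preserving voxels, mirrored 8-voxel
    striatal spheres in the two hemispheres. Foci are left empty; scenario
    presets populate them."""
    g = (grid, grid, grid)
    voxel = 22.5 / grid
    ipsi = spherical_mask(g, (grid / 2, grid * 0.33, grid * 0.47), grid / 8)
    contra = spherical_mask(g, (grid / 2, grid * 0.67, grid * 0.47), grid / 8)
    return PhantomSpec(
        grid=g,
        voxel_size=(voxel, voxel, voxel),
        striatum_ipsi_mask=ipsi,
        striatum_contra_mask=contra,
        **kwargs,
    )
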