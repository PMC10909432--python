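"""Scenario presets for the contrast-agent arms of the simulated study.

Each preset fixes the expected number of MPIO foci (endothelium-bound
contrast particles, post-contrast only) and macrophage foci (endogenous
iron-laden perivascular macrophages, present pre and post) in the
ipsilateral striatum. Targeting specificity orders the presets:
VCAM > RGD >> scrambled-peptide (RDG) ≈ IgG ≈ vehicle (PBS). Per-animal
focus counts are Poisson around the preset mean, reflecting biological
variability between tumours. The vehicle control carries no tumour and
therefore no endogenous macrophage iron either.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import FocusSpec, PhantomSpec, default_phantom_spec

__all__ = ["ScenarioPreset", "SCENARIOS", "build_phantom_spec"]


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    mpio_focus_mean: float  #: expected MPIO foci per animal (targeting specificity)
    macrophage_focus_mean: float  #: expected endogenous iron foci per animal
    gadolinium_enhancing: bool  #: BBB-breakdown flag; not used in the T2* simulation
    mpio_delta_r2star: float = 500.0  # 1/s
    mpio_radius_mm: float = 0.4
    macrophage_delta_r2star: float = 300.0  # 1/s
    macrophage_radius_mm: float = 0.4


SCENARIOS: dict[str, ScenarioPreset] = {
    "VCAM": ScenarioPreset("VCAM", 90.0, 12.0, True),
    "RGD": ScenarioPreset("RGD", 30.0, 12.0, True),
    "RDG": ScenarioPreset("RDG", 0.0, 12.0, True),
    "IgG": ScenarioPreset("IgG", 0.0, 12.0, True),
    "PBS": ScenarioPreset("PBS", 0.0, 0.0, False),
}


def build_phantom_spec(
    scenario: str, seed: int | None = None, grid: int = 64, **phantom_kwargs
) -> PhantomSpec:
    """Build a phantom spec for a named scenario with seed-controlled foci.

    Foci are dropped uniformly over the ipsilateral striatum mask; counts
    are Poisson with the preset means.
    """
    try:
        preset = SCENARIOS[scenario]
    except KeyError:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}") from None
    rng = np.random.default_rng(seed)
    spec = default_phantom_spec(grid=grid, **phantom_kwargs)
    spec.rng_seed = -1 if seed is None else int(seed)
    ipsi_voxels = np.argwhere(spec.striatum_ipsi_mask)

    def drop(mean: float, delta: float, radius: float) -> list[FocusSpec]:
        n = int(rng.poisson(mean)) if mean > 0 else 0
        picks = rng.integers(len(ipsi_voxels), size=n)
        return [
            FocusSpec(centre=tuple(float(v) for v in ipsi_voxels[p]), radius=radius, delta_r2star=delta)
            for p in picks
        ]

    spec.macrophage_foci = drop(
        preset.macrophage_focus_mean, preset.macrophage_delta_r2star, preset.macrophage_radius_mm
    )
    spec.mpio_foci = drop(preset.mpio_focus_mean, preset.mpio_delta_r2star, preset.mpio_radius_mm)
    return spec
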