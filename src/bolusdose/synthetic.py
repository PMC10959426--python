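"""Analytic electron depth-dose curves with controllable material scaling.

The generator produces central-axis percentage-depth-dose curves with the
qualitative anatomy of a clinical electron beam — surface dose, build-up to a
maximum, a steep Gaussian-CDF falloff through R50 toward the practical
range,
and a slowly decaying bremsstrahlung pedestal — plus two knobs that emulate
how bolus material changes the curve:

* depth remapping to water-equivalent depth through the slab stack
  (electron-density scaling: denser-electron boluses pull the falloff
  shallower), and
* an optional phenomenological tail multiplier linear in the bolus effective
  atomic number excess over water (high-Z boluses raise the deep pedestal).

Noise follows a depth-dependent relative-sigma envelope shaped like the
Monte Carlo uncertainty of the full transport runs (0.5 % in the falloff,
1 % in the deep tail), and the recorded ``rel_err`` always equals the
generating sigma, so analysis code is never tested against noise it is not
told about.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import erfc

from .curves import DepthDoseCurve
from .materials import (
    Material,
    default_materials,
    effective_atomic_number,
    electron_density,
)
from .phantoms import (
    ScenarioSpec,
    SlabPhantom,
    build_scenario_phantom,
    voxel_geometry,
)

__all__ = [
    "AnalyticPDDParams",
    "NoiseModel",
    "StudySet",
    "params_from_energy",
    "analytic_pdd",
    "water_equivalent_depth",
    "material_scaled_curve",
    "add_noise",
    "generate_study_set",
]


@dataclass(frozen=True)
class AnalyticPDDParams:
    """Shape parameters of the analytic electron PDD (depths in cm)."""

    d_max: float
    R50: float
    Rp: float
    surface_fraction: float = 80.0   # % of max at depth 0
    tail_fraction: float = 0.6       # % of max, bremsstrahlung pedestal
    tail_mu: float = 0.05            # 1/cm pedestal attenuation
    # falloff width scale: sigma_f = g*(Rp-R50); the default reproduces
    # clinical falloff gradients (~60 %/cm at 6 MeV, ~45 %/cm at 9 MeV)
    falloff_gradient: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.d_max < self.R50 < self.Rp:
            raise ValueError("need 0 < d_max < R50 < Rp")
        if not 0.0 <= self.tail_fraction < self.surface_fraction < 100.0:
            raise ValueError("need 0 <= tail_fraction < surface_fraction < 100")


@dataclass(frozen=True)
class NoiseModel:
    """Piecewise-linear relative sigma vs depth (cm), flat beyond the anchors."""

    anchor_depths: tuple[float, ...] = (3.1, 4.6, 9.5, 16.0)
    anchor_sigma: tuple[float, ...] = (0.005, 0.005, 0.01, 0.01)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.anchor_depths) != len(self.anchor_sigma):
            raise ValueError("anchor arrays must have equal length")
        if any(s < 0 for s in self.anchor_sigma):
            raise ValueError("relative sigma must be non-negative")
        if any(b <= a for a, b in zip(self.anchor_depths, self.anchor_depths[1:])):
            raise ValueError("anchor depths must be strictly increasing")

    def rel_sigma(self, depths: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(depths, dtype=float),
                         self.anchor_depths, self.anchor_sigma)


def params_from_energy(energy_mev: float) -> AnalyticPDDParams:
    """Empirical water-beam parameters from nominal energy.

    Standard broad-beam rules of thumb: Rp = 0.521 E - 0.376, R50 = E/2.33,
    d_max = 0.46 E^0.67 (all cm, E in MeV); valid for 4-20 MeV.
    """
    if not 4.0 <= energy_mev <= 20.0:
        raise ValueError("supported nominal energies are 4-20 MeV")
    return AnalyticPDDParams(
        d_max=0.46 * energy_mev ** 0.67,
        R50=energy_mev / 2.33,
        Rp=0.521 * energy_mev - 0.376,
    )


def _shape(params: AnalyticPDDParams, depths: np.ndarray) -> np.ndarray:
    """Unnormalized build-up x falloff component (no tail)."""
    d = np.asarray(depths, dtype=float)
    s = params.surface_fraction / 100.0
    frac = np.clip(d / params.d_max, 0.0, 1.0)
    # quintic smoothstep: C2-continuous at the peak, so sub-voxel peak
    # refinement is not biased by a curvature kink
    buildup = s + (1.0 - s) * (frac**3 * (10.0 - 15.0 * frac + 6.0 * frac**2))
    # Gaussian-CDF falloff: range straggling makes the log-slope of a real
    # electron falloff steepen with depth, which an exponential-tailed
    # sigmoid would not capture
    sigma_f = params.falloff_gradient * (params.Rp - params.R50)
    falloff = 0.5 * erfc((d - params.R50) / (np.sqrt(2.0) * sigma_f))
    return buildup * falloff


def _shape_norm(params: AnalyticPDDParams) -> float:
    fine = np.linspace(0.0, params.Rp, 4001)
    return float(_shape(params, fine).max())


def _tail(params: AnalyticPDDParams, depths: np.ndarray) -> np.ndarray:
    return params.tail_fraction * np.exp(-params.tail_mu * np.asarray(depths, float))


def analytic_pdd(params: AnalyticPDDParams, depths,
                 tail_multiplier: float = 1.0) -> np.ndarray:
    """Evaluate the analytic PDD (percent of maximum) at ``depths`` (cm)."""
    d = np.asarray(depths, dtype=float)
    if d.ndim != 1 or len(d) < 1 or np.any(d < 0) or np.any(np.diff(d) <= 0):
        raise ValueError("depths must be strictly increasing and non-negative")
    return (100.0 * _shape(params, d) / _shape_norm(params)
            + tail_multiplier * _tail(params, d))


def water_equivalent_depth(phantom: SlabPhantom, depths,
                           water: Material | None = None) -> np.ndarray:
    """Map physical depth to water-equivalent depth via electron densities."""
    water = water or default_materials()["water"]
    rho_e_w = electron_density(water)
    bounds = phantom.boundaries
    weq_bounds = np.concatenate([[0.0], np.cumsum([
        layer.thickness * electron_density(layer.material) / rho_e_w
        for layer in phantom.layers
    ])])
    d = np.asarray(depths, dtype=float)
    # beyond the back face, extrapolate with the last layer's scaling
    last_ratio = electron_density(phantom.layers[-1].material) / rho_e_w
    out = np.interp(d, bounds, weq_bounds)
    beyond = d > bounds[-1]
    out[beyond] = weq_bounds[-1] + (d[beyond] - bounds[-1]) * last_ratio
    return out


def material_scaled_curve(params: AnalyticPDDParams, phantom: SlabPhantom,
                          depths, tail_z_coeff: float = 0.0,
                          db: dict[str, Material] | None = None) -> np.ndarray:
    """Analytic PDD through a layered phantom.

    Depth is remapped to water-equivalent depth before evaluating the water
    shape, so raising the bolus electron density pulls every feature of the
    curve shallower in physical depth.  ``tail_z_coeff`` (per Z unit) scales
    the bremsstrahlung pedestal linearly in the bolus Z_eff excess over
    water — a labelled phenomenological knob, off by default.
    """
    db = db or default_materials()
    d_w = water_equivalent_depth(phantom, depths, db["water"])
    mult = 1.0
    if tail_z_coeff != 0.0:
        z_excess = (effective_atomic_number(phantom.layers[0].material)
                    - effective_atomic_number(db["water"]))
        mult = max(1.0 + tail_z_coeff * z_excess, 0.0)
    return (100.0 * _shape(params, d_w) / _shape_norm(params)
            + mult * _tail(params, d_w))


def add_noise(values: np.ndarray, depths: np.ndarray,
              noise: NoiseModel) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative Gaussian noise with the model's depth-dependent sigma.

    Returns ``(noisy_values, rel_err)`` where rel_err is exactly the
    generating sigma.  Reproducible under the model seed.
    """
    sigma = noise.rel_sigma(depths)
    rng = np.random.default_rng(noise.seed)
    noisy = np.asarray(values, float) * (1.0 + sigma * rng.normal(size=len(sigma)))
    return np.maximum(noisy, 0.0), sigma


@dataclass
class StudySet:
    """Labelled synthetic curves plus the ground truth that generated them."""

    curves: list[DepthDoseCurve]
    truth: dict[tuple[str, str], dict]  # (scenario label, material) -> record

    def curve(self, scenario_label: str, material: str) -> DepthDoseCurve:
        for c in self.curves:
            if (c.metadata.get("scenario") == scenario_label
                    and c.metadata.get("material") == material):
                return c
        raise KeyError((scenario_label, material))


def generate_study_set(scenarios: list[ScenarioSpec], seed: int = 0,
                       noise: bool = True, tail_z_coeff: float = 0.1,
                       db: dict[str, Material] | None = None) -> StudySet:
    """Synthetic curves for every (scenario, bolus material) with ground truth.

    Each scenario in ``scenarios`` names a bolus material; a full material
    sweep is built by passing one spec per material.  The truth record per
    curve holds the noiseless values, the true physical depth of maximum
    (fine-grid argmax of the noiseless curve) and the true d_max shift
    relative to the water-bolus curve of the same scenario geometry.
    """
    db = db or default_materials()
    curves: list[DepthDoseCurve] = []
    truth: dict[tuple[str, str], dict] = {}
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(scenarios)))

    # true physical d_max per (geometry, material): invert the weq map
    def true_dmax(spec: ScenarioSpec) -> float:
        params = params_from_energy(spec.beam_energy)
        phantom = build_scenario_phantom(spec, db)
        fine = np.linspace(1e-4, min(phantom.total_thickness, 3 * params.Rp), 20001)
        vals = material_scaled_curve(params, phantom, fine, tail_z_coeff, db)
        return float(fine[np.argmax(vals)])

    water_dmax_cache: dict[str, float] = {}
    for spec in scenarios:
        child = next(children)
        params = params_from_energy(spec.beam_energy)
        phantom = build_scenario_phantom(spec, db)
        grid = voxel_geometry(phantom)
        depths = grid.centers
        clean = material_scaled_curve(params, phantom, depths, tail_z_coeff, db)
        geo_key = spec.label
        if geo_key not in water_dmax_cache:
            water_spec = replace(spec, bolus_material="water")
            water_dmax_cache[geo_key] = true_dmax(water_spec)
        curve_seed = int(child.generate_state(1)[0] % (2**31))
        if noise:
            nm = NoiseModel(seed=curve_seed)
            vals, rel = add_noise(clean, depths, nm)
        else:
            vals, rel = clean.copy(), np.zeros_like(clean)
        meta = {
            "scenario": spec.label,
            "family": spec.family,
            "material": spec.bolus_material,
            "energy_mev": f"{spec.beam_energy:g}",
            "bolus_thickness_cm": f"{spec.bolus_thickness:g}",
            "layer3_thickness_cm": f"{spec.layer3_thickness:g}",
            "seed": str(curve_seed),
            "engine": "synthetic",
        }
        curves.append(DepthDoseCurve(depths, vals, rel, meta))
        dmax_m = true_dmax(spec)
        truth[(spec.label, spec.bolus_material)] = {
            "noiseless": clean,
            "depths": depths,
            "true_dmax_cm": dmax_m,
            "true_shift_vs_water_cm": water_dmax_cache[geo_key] - dmax_m,
            "params": params,
            "tail_z_coeff": tail_z_coeff,
        }
    return StudySet(curves=curves, truth=truth)
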