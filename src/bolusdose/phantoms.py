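"""Layered slab treatment models and the central-axis scoring geometry.

Two model families are bundled:

* S-T (superficial tumor): bolus / skin 0.3 cm / soft tissue / soft tissue 30 cm
* P-B (postoperative breast): bolus / skin 0.3 cm / muscle / lung 30 cm

The beam enters layer 1 (the bolus); depth 0 is the bolus top surface.  The
bundled scenario table pairs each layer-3 thickness with a beam energy and
bolus thickness chosen so the target sits inside the therapeutic range:

    layer 3 (cm)   energy (MeV)   bolus (cm)
    0.5            6              1.0
    1.0            6              0.5
    1.5            9              1.0

Dose is scored in 1.0 x 1.0 x 0.1 cm voxels along the field central axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .materials import Material, default_materials

__all__ = [
    "Layer",
    "SlabPhantom",
    "VoxelGrid",
    "ScenarioSpec",
    "GeometryError",
    "SKIN_THICKNESS_CM",
    "SCENARIO_TABLE",
    "DEFAULT_BOLUS_MATERIALS",
    "scenario_parameters",
    "build_st_model",
    "build_pb_model",
    "build_scenario_phantom",
    "voxel_geometry",
    "interface_depths",
]

VOXEL_DEPTH_CM = 0.1
VOXEL_AREA_CM2 = 1.0  # 1.0 x 1.0 cm lateral cross-section
SKIN_THICKNESS_CM = 0.3
DEEP_LAYER_THICKNESS_CM = 30.0

#: layer-3 thickness (cm) -> (beam energy MeV, bolus thickness cm)
SCENARIO_TABLE: dict[float, tuple[float, float]] = {
    0.5: (6.0, 1.0),
    1.0: (6.0, 0.5),
    1.5: (9.0, 1.0),
}

DEFAULT_BOLUS_MATERIALS = ["water", "PLA", "polystyrene", "silica-gel", "glycerol"]


class GeometryError(ValueError):
    """Phantom geometry incompatible with the 0.1 cm scoring grid."""


@dataclass(frozen=True)
class Layer:
    material: Material
    thickness: float  # cm

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("layer thickness must be positive")


@dataclass(frozen=True)
class SlabPhantom:
    """Ordered slab stack; the beam enters layer 1 at depth 0."""

    layers: tuple[Layer, ...]
    lateral_size: float = 30.0       # cm, square cross-section
    source_to_surface: float = 100.0  # cm (SAD, virtual source to bolus top)

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise ValueError("a slab phantom needs at least two layers")
        if self.lateral_size <= 0 or self.source_to_surface <= 0:
            raise ValueError("lateral size and source distance must be positive")

    @property
    def total_thickness(self) -> float:
        return float(sum(l.thickness for l in self.layers))

    @property
    def boundaries(self) -> np.ndarray:
        """Depths of layer interfaces including 0 and the back face."""
        return np.concatenate(
            [[0.0], np.cumsum([l.thickness for l in self.layers])]
        )

    def material_at(self, depth: float) -> Material:
        """Material of the layer containing ``depth`` (front-inclusive bins)."""
        if not 0.0 <= depth <= self.total_thickness:
            raise ValueError(f"depth {depth} outside phantom")
        idx = int(np.searchsorted(self.boundaries, depth, side="right")) - 1
        idx = min(idx, len(self.layers) - 1)
        return self.layers[idx].material


@dataclass(frozen=True)
class VoxelGrid:
    """Central-axis scoring column: 1 x 1 cm laterally, 0.1 cm depth bins."""

    edges: np.ndarray     # (n+1,) depth bin edges, cm
    materials: tuple[Material, ...]  # per voxel
    masses: np.ndarray    # (n,) grams

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def n_voxels(self) -> int:
        return len(self.masses)


@dataclass(frozen=True)
class ScenarioSpec:
    """One treatment scenario: family, geometry row and bolus choice."""

    family: Literal["ST", "PB"]
    layer3_thickness: float
    beam_energy: float
    bolus_thickness: float
    bolus_material: str

    @classmethod
    def from_table(cls, family: str, layer3_thickness: float,
                   bolus_material: str) -> "ScenarioSpec":
        energy, bolus = scenario_parameters(layer3_thickness)
        return cls(family, layer3_thickness, energy, bolus, bolus_material)  # type: ignore[arg-type]

    @property
    def label(self) -> str:
        return (f"{self.family}_L3-{self.layer3_thickness:g}cm"
                f"_E{self.beam_energy:g}MeV_bolus{self.bolus_thickness:g}cm")

    @property
    def reference_depth(self) -> float:
        """Center of the deepest layer-3 voxel (the P-B normalization point)."""
        return (self.bolus_thickness + SKIN_THICKNESS_CM
                + self.layer3_thickness - VOXEL_DEPTH_CM / 2)


def scenario_parameters(layer3_thickness: float) -> tuple[float, float]:
    """Beam energy (MeV) and bolus thickness (cm) paired with a layer-3 depth."""
    for key, val in SCENARIO_TABLE.items():
        if abs(layer3_thickness - key) < 1e-9:
            return val
    raise KeyError(
        f"no bundled scenario with layer-3 thickness {layer3_thickness} cm; "
        f"choose one of {sorted(SCENARIO_TABLE)}"
    )


def _resolve(material: Material | str, db: dict[str, Material] | None) -> Material:
    if isinstance(material, Material):
        return material
    db = db or default_materials()
    try:
        return db[material]
    except KeyError:
        raise KeyError(f"unknown material {material!r}") from None


def build_st_model(bolus: Material | str, bolus_thickness: float,
                   layer3_thickness: float,
                   db: dict[str, Material] | None = None) -> SlabPhantom:
    """Superficial-tumor model: bolus / skin / soft tissue / 30 cm soft tissue."""
    db = db or default_materials()
    return SlabPhantom(layers=(
        Layer(_resolve(bolus, db), bolus_thickness),
        Layer(db["skin"], SKIN_THICKNESS_CM),
        Layer(db["soft-tissue"], layer3_thickness),
        Layer(db["soft-tissue"], DEEP_LAYER_THICKNESS_CM),
    ))


def build_pb_model(bolus: Material | str, bolus_thickness: float,
                   muscle_thickness: float,
                   db: dict[str, Material] | None = None) -> SlabPhantom:
    """Postoperative-breast model: bolus / skin / muscle / 30 cm lung."""
    db = db or default_materials()
    return SlabPhantom(layers=(
        Layer(_resolve(bolus, db), bolus_thickness),
        Layer(db["skin"], SKIN_THICKNESS_CM),
        Layer(db["muscle"], muscle_thickness),
        Layer(db["lung"], DEEP_LAYER_THICKNESS_CM),
    ))


def build_scenario_phantom(spec: ScenarioSpec,
                           db: dict[str, Material] | None = None) -> SlabPhantom:
    builder = build_st_model if spec.family == "ST" else build_pb_model
    return builder(spec.bolus_material, spec.bolus_thickness,
                   spec.layer3_thickness, db)


def voxel_geometry(phantom: SlabPhantom) -> VoxelGrid:
    """Tile the phantom depth with 0.1 cm scoring voxels on the central axis.

    Every layer thickness must be a multiple of 0.1 cm so bins never straddle
    a material interface.  Voxel k spans [k*0.1, (k+1)*0.1); its material is
    the layer containing the bin center and its mass is rho * 0.1 g.
    """
    for layer in phantom.layers:
        n = layer.thickness / VOXEL_DEPTH_CM
        if abs(n - round(n)) > 1e-9:
            raise GeometryError(
                f"layer thickness {layer.thickness} cm is not a multiple of "
                f"{VOXEL_DEPTH_CM} cm; nearest commensurate value is "
                f"{round(n) * VOXEL_DEPTH_CM:.1f} cm"
            )
    n_voxels = int(round(phantom.total_thickness / VOXEL_DEPTH_CM))
    edges = np.arange(n_voxels + 1) * VOXEL_DEPTH_CM
    centers = 0.5 * (edges[:-1] + edges[1:])
    mats = tuple(phantom.material_at(c) for c in centers)
    masses = np.array([m.density * VOXEL_AREA_CM2 * VOXEL_DEPTH_CM for m in mats])
    return VoxelGrid(edges=edges, materials=mats, masses=masses)


def interface_depths(phantom: SlabPhantom) -> dict[str, float | int]:
    """Named boundary depths (cm from bolus top) plus the reference voxel.

    ``reference_voxel_index`` is the deepest layer-3 voxel — the voxel
    closest to layer 4 (the muscle/lung interface voxel in the P-B family).
    """
    b = phantom.boundaries
    out: dict[str, float | int] = {
        "bolus_top": 0.0,
        "skin_surface": float(b[1]),
        "layer3_top": float(b[2]),
        "layer4_top": float(b[3]),
    }
    out["lung_top"] = out["layer4_top"]  # alias for the P-B family
    out["reference_voxel_index"] = int(round(b[3] / VOXEL_DEPTH_CM)) - 1
    return out
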