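"""Depth-dose normalization, curve alignment, relative dose and extrema.

The comparison statistic is the relative dose

    RD(d) = PDD_M(d) / PDD_water(d) x 100%

evaluated beyond a reference depth, where M is a non-water bolus material and
the water-bolus curve of the same scenario is the standard.  Two
normalization conventions are supported, matching how the two treatment-model
families are analysed:

* ``max`` (S-T family): PDD = 100 at the depth of maximum dose; curves of
  different boluses are first shifted so their d_max coincide with water's.
* ``reference`` (P-B family): PDD = 100 at a chosen voxel — the deepest
  muscle voxel, i.e. the voxel closest to the lung — with no d_max
  alignment.

Extrema of |RD - 100| are searched inside the falloff region (water PDD
between 1% and 90% by default) and reported together with the co-located
water PDD; the deep stabilization region (water PDD < 1%) is summarized by
its mean RD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .curves import DepthDoseCurve
from .phantoms import ScenarioSpec

__all__ = [
    "PDDCurve",
    "RDProfile",
    "ExtremumResult",
    "TailSummary",
    "NormalizationError",
    "GridError",
    "RegionError",
    "WaterReferenceError",
    "FALLOFF_BAND_PCT",
    "TAIL_THRESHOLD_PCT",
    "WATER_PDD_FLOOR_PCT",
    "to_pdd",
    "find_dmax",
    "align_to_water",
    "relative_dose",
    "detect_extremum",
    "tail_summary",
    "rank_tail_means",
    "practical_range",
    "study_report",
]

#: falloff search window: water PDD within [low, high] percent
FALLOFF_BAND_PCT = (1.0, 90.0)
#: water PDD below this is the stabilization ("tail") region
TAIL_THRESHOLD_PCT = 1.0
#: water PDD below this is masked out of ratios entirely
WATER_PDD_FLOOR_PCT = 0.01


class NormalizationError(ValueError):
    """Reference dose is zero or the reference depth is off-grid."""


class GridError(ValueError):
    """Curves are not on a common depth grid."""


class RegionError(ValueError):
    """The requested analysis region is empty."""


class WaterReferenceError(ValueError):
    """A scenario is missing its water-bolus reference curve."""


@dataclass
class PDDCurve:
    """Percentage depth dose with the normalization convention recorded."""

    depths: np.ndarray
    pdd: np.ndarray          # percent
    convention: Literal["max", "reference"]
    reference_depth: float
    rel_err: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.pdd = np.asarray(self.pdd, dtype=float)
        if self.depths.shape != self.pdd.shape:
            raise ValueError("depths and pdd must have equal length")


@dataclass
class RDProfile:
    """Relative dose vs depth beyond the reference depth (masked = NaN)."""

    depths: np.ndarray
    rd: np.ndarray           # percent; NaN where water PDD < floor
    material: str
    water_pdd: np.ndarray    # co-located water PDD, percent
    from_depth: float
    metadata: dict = field(default_factory=dict)


class ExtremumResult(NamedTuple):
    rd_pct: float
    depth_cm: float
    water_pdd_pct: float


class TailSummary(NamedTuple):
    mean_rd_pct: float
    depth_lo_cm: float
    depth_hi_cm: float


def to_pdd(curve: DepthDoseCurve, convention: Literal["max", "reference"] = "max",
           reference_depth: float | None = None) -> PDDCurve:
    """Normalize a raw depth-dose curve to percent.

    ``max``: 100 at the (grid) maximum.  ``reference``: 100 at the voxel
    whose center matches ``reference_depth`` (must lie within half a bin).
    Idempotent: normalizing an already-normalized curve changes nothing.
    """
    dose = curve.dose
    if convention == "max":
        idx = int(np.argmax(dose))
        ref_depth = float(curve.depths[idx])
    elif convention == "reference":
        if reference_depth is None:
            raise ValueError("reference convention needs reference_depth")
        idx = int(np.argmin(np.abs(curve.depths - reference_depth)))
        if abs(curve.depths[idx] - reference_depth) > 1e-6:
            raise NormalizationError(
                f"reference depth {reference_depth} cm does not map to a "
                f"voxel center (nearest: {curve.depths[idx]} cm)")
        ref_depth = float(curve.depths[idx])
    else:
        raise ValueError(f"unknown convention {convention!r}")
    ref = dose[idx]
    if ref <= 0:
        raise NormalizationError("zero dose at the normalization reference")
    return PDDCurve(
        depths=curve.depths.copy(),
        pdd=100.0 * dose / ref,
        convention=convention,
        reference_depth=ref_depth,
        rel_err=None if curve.rel_err is None else curve.rel_err.copy(),
        metadata=dict(curve.metadata),
    )


def find_dmax(curve: DepthDoseCurve | PDDCurve) -> float:
    """Depth of maximum dose with sub-voxel refinement; ties go surface-side.

    The discrete argmax (first occurrence, i.e. the shallowest of equal
    maxima) is refined by maximizing a local cubic-spline interpolant over
    the surrounding window; a plateau or a boundary maximum is returned at
    the grid point itself.  On an exactly quadratic peak the refinement
    recovers the vertex to machine precision, like the classic three-point
    parabola it generalizes.
    """
    depths = curve.depths
    values = curve.dose if isinstance(curve, DepthDoseCurve) else curve.pdd
    i = int(np.argmax(values))          # first occurrence = shallowest
    if i == 0 or i == len(values) - 1:
        warnings.warn("maximum at a curve boundary; no sub-voxel refinement",
                      stacklevel=2)
        return float(depths[i])
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    if y0 == y1 or y1 == y2 or y0 - 2.0 * y1 + y2 >= 0:
        return float(depths[i])        # plateau/tie or degenerate: grid point
    lo, hi = max(i - 3, 0), min(i + 4, len(values))
    from scipy.interpolate import CubicSpline
    spline = CubicSpline(depths[lo:hi], values[lo:hi])
    a, b = depths[max(i - 1, lo)], depths[min(i + 1, hi - 1)]
    crit = spline.derivative().roots(extrapolate=False)
    crit = crit[(crit >= a) & (crit <= b)]
    candidates = np.concatenate([np.real(crit), [a, depths[i], b]])
    return float(candidates[np.argmax(spline(candidates))])


def align_to_water(curves: Sequence[PDDCurve], water: PDDCurve) -> list[PDDCurve]:
    """Shift max-normalized curves so every d_max coincides with water's.

    Each curve M is shifted by delta = d_max(water) - d_max(M) and linearly
    interpolated onto the water depth grid.
    """
    if water.convention != "max":
        raise ValueError("alignment applies to max-normalized curves")
    d_w = find_dmax(water)
    out = []
    for c in curves:
        if c.convention != "max":
            raise ValueError("alignment applies to max-normalized curves")
        delta = d_w - find_dmax(c)
        support = c.depths[-1] - c.depths[0]
        if abs(delta) > support:
            raise ValueError(
                f"alignment shift {delta:.3f} cm exceeds curve support")
        shifted = np.interp(water.depths - delta, c.depths, c.pdd)
        shifted_err = (None if c.rel_err is None else
                       np.interp(water.depths - delta, c.depths, c.rel_err))
        out.append(PDDCurve(
            depths=water.depths.copy(), pdd=shifted, convention="max",
            reference_depth=d_w, rel_err=shifted_err,
            metadata={**c.metadata, "alignment_shift_cm": f"{delta:.6g}"},
        ))
    return out


def relative_dose(pdd_m: PDDCurve, pdd_water: PDDCurve, from_depth: float,
                  floor_pct: float = WATER_PDD_FLOOR_PCT) -> RDProfile:
    """Pointwise RD = PDD_M / PDD_water x 100 for depths >= ``from_depth``.

    Depths where the water PDD is below ``floor_pct`` are masked (NaN), not
    divided.
    """
    if (pdd_m.depths.shape != pdd_water.depths.shape
            or np.any(np.abs(pdd_m.depths - pdd_water.depths) > 1e-9)):
        raise GridError("curves must share a common depth grid")
    sel = pdd_m.depths >= from_depth - 1e-9
    depths = pdd_m.depths[sel]
    wm = pdd_water.pdd[sel]
    mm = pdd_m.pdd[sel]
    with np.errstate(divide="ignore", invalid="ignore"):
        rd = np.where(wm >= floor_pct, 100.0 * mm / wm, np.nan)
    return RDProfile(
        depths=depths, rd=rd,
        material=str(pdd_m.metadata.get("material", "")),
        water_pdd=wm, from_depth=float(from_depth),
        metadata=dict(pdd_m.metadata),
    )


def detect_extremum(rd: RDProfile,
                    falloff_band: tuple[float, float] = FALLOFF_BAND_PCT
                    ) -> ExtremumResult:
    """Largest |RD - 100| inside the falloff region (ties: shallower depth).

    The falloff region is where the water PDD lies inside ``falloff_band``
    percent.  Returns the RD extremum, its depth, and the water PDD there.
    """
    lo, hi = falloff_band
    sel = ((rd.water_pdd >= lo) & (rd.water_pdd <= hi) & np.isfinite(rd.rd))
    if not sel.any():
        raise RegionError("falloff region is empty")
    dev = np.abs(rd.rd - 100.0)
    dev = np.where(sel, dev, -np.inf)
    i = int(np.argmax(dev))             # first occurrence -> shallowest tie
    return ExtremumResult(float(rd.rd[i]), float(rd.depths[i]),
                          float(rd.water_pdd[i]))


def tail_summary(rd: RDProfile, threshold_pct: float = TAIL_THRESHOLD_PCT,
                 floor_pct: float = WATER_PDD_FLOOR_PCT) -> TailSummary:
    """Mean RD over the stabilization region (water PDD < threshold).

    Masked points (water PDD below the division floor) are excluded.
    """
    sel = ((rd.water_pdd < threshold_pct) & (rd.water_pdd >= floor_pct)
           & np.isfinite(rd.rd))
    if not sel.any():
        raise RegionError("stabilization region is empty")
    return TailSummary(float(rd.rd[sel].mean()),
                       float(rd.depths[sel].min()),
                       float(rd.depths[sel].max()))


def rank_tail_means(profiles: Iterable[RDProfile],
                    threshold_pct: float = TAIL_THRESHOLD_PCT) -> list[tuple[str, float]]:
    """Materials ordered by descending stabilization-region mean RD."""
    pairs = [(p.material, tail_summary(p, threshold_pct).mean_rd_pct)
             for p in profiles]
    return sorted(pairs, key=lambda t: -t[1])


def practical_range(curve: DepthDoseCurve | PDDCurve) -> float:
    """Practical range: steepest-falloff tangent extrapolated to the tail level.

    The tail level is the mean of the last tenth of the curve (the
    bremsstrahlung pedestal; ~0 for the bundled engine, which ledgers rather
    than transports radiative losses).
    """
    depths = curve.depths
    values = curve.dose if isinstance(curve, DepthDoseCurve) else curve.pdd
    if len(values) < 8:
        raise ValueError("curve too short for range extrapolation")
    # light smoothing so MC noise does not pick a spurious gradient
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(values, kernel, mode="same")
    i_max = int(np.argmax(smooth))
    grad = np.gradient(smooth, depths)
    grad[: i_max + 1] = 0.0
    i_steep = int(np.argmin(grad))
    if grad[i_steep] >= 0:
        raise ValueError("no falloff found beyond the maximum")
    tail_level = float(np.mean(values[-max(len(values) // 10, 3):]))
    return float(depths[i_steep]
                 + (smooth[i_steep] - tail_level) / -grad[i_steep])


# ---------------------------------------------------------------------------
# study-level report


def _st_profiles(curves: dict[str, DepthDoseCurve]) -> dict[str, RDProfile]:
    water_pdd = to_pdd(curves["water"], "max")
    d_w = find_dmax(water_pdd)
    others = {m: to_pdd(c, "max") for m, c in curves.items() if m != "water"}
    aligned = align_to_water(list(others.values()), water_pdd)
    return {p.metadata.get("material", m): relative_dose(p, water_pdd, d_w)
            for (m, _), p in zip(others.items(), aligned)}


def _pb_profiles(curves: dict[str, DepthDoseCurve],
                 reference_depth: float) -> dict[str, RDProfile]:
    water_pdd = to_pdd(curves["water"], "reference", reference_depth)
    out = {}
    for m, c in curves.items():
        if m == "water":
            continue
        pdd = to_pdd(c, "reference", reference_depth)
        out[m] = relative_dose(pdd, water_pdd, reference_depth)
    return out


def scenario_rd_profiles(spec: ScenarioSpec,
                         curves: dict[str, DepthDoseCurve]) -> dict[str, RDProfile]:
    """Family-appropriate RD profiles for one scenario's material sweep."""
    if "water" not in curves:
        raise WaterReferenceError(
            f"scenario {spec.label}: water reference curve missing")
    if spec.family == "ST":
        return _st_profiles(curves)
    return _pb_profiles(curves, spec.reference_depth)


def study_report(results: dict[str, tuple[ScenarioSpec, dict[str, DepthDoseCurve]]]
                 ) -> pd.DataFrame:
    """Extremum/tail table over scenarios x non-water materials.

    ``results`` maps a scenario label to ``(spec, {material: curve})``.  One
    row per (scenario, material != water): the RD extremum, its depth from
    the bolus top and from the skin surface, the water PDD at the extremum,
    and the stabilization-region mean RD.  Deterministic given the curves.
    """
    rows = []
    for label, (spec, curves) in results.items():
        profiles = scenario_rd_profiles(spec, curves)
        for material, prof in profiles.items():
            ext = detect_extremum(prof)
            tail = tail_summary(prof)
            rows.append({
                "scenario": label,
                "family": spec.family,
                "energy_mev": spec.beam_energy,
                "bolus_thickness_cm": spec.bolus_thickness,
                "layer3_thickness_cm": spec.layer3_thickness,
                "material": material,
                "extremum_rd_pct": ext.rd_pct,
                "extremum_depth_cm_from_bolus_top": ext.depth_cm,
                "extremum_depth_cm_from_skin": ext.depth_cm - spec.bolus_thickness,
                "water_pdd_at_extremum_pct": ext.water_pdd_pct,
                "tail_mean_rd_pct": tail.mean_rd_pct,
                "tail_depth_lo_cm": tail.depth_lo_cm,
                "tail_depth_hi_cm": tail.depth_hi_cm,
            })
    return pd.DataFrame(rows)
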