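"""Central-axis depth-dose curve container shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DepthDoseCurve"]


@dataclass
class DepthDoseCurve:
    """Raw central-axis dose vs depth.

    ``depths`` are voxel centers in cm (strictly increasing; the bundled
    pipelines use a uniform 0.1 cm grid), ``dose`` is per-history dose in
    whatever unit the producer used (MeV/g per history for the transport
    engine, percent-like for the analytic generator — normalization removes
    the unit), ``rel_err`` is the per-point relative standard error (may be
    None when unknown).  ``metadata`` carries provenance strings such as
    scenario label, material and seed.
    """

    depths: np.ndarray
    dose: np.ndarray
    rel_err: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.rel_err is not None:
            self.rel_err = np.asarray(self.rel_err, dtype=float)
            if self.rel_err.shape != self.depths.shape:
                raise ValueError("rel_err length mismatch")
        if self.depths.shape != self.dose.shape or self.depths.ndim != 1:
            raise ValueError("depths and dose must be equal-length 1-D arrays")
        if len(self.depths) < 2:
            raise ValueError("a curve needs at least two points")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")

    def __len__(self) -> int:
        return len(self.depths)
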