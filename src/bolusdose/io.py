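"""Curve CSV dialect and small JSON helpers.

Curve files are human-diffable and bit-stable:

    #scenario: PB_L3-0.5cm_E6MeV_bolus1cm
    #material: glycerol
    #seed: 7
    depth_cm,dose_per_history_MeV_per_g,rel_err
    0.05,0.0123456,0.004

Comment lines hold ``key: value`` metadata; numbers are written with %.6g.
A missing ``rel_err`` column is accepted (rel_err becomes None) with a
logged warning.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .curves import DepthDoseCurve

__all__ = ["CurveFormatError", "read_curve_csv", "write_curve_csv",
           "write_json", "read_json"]

logger = logging.getLogger(__name__)

_HEADER = "depth_cm,dose_per_history_MeV_per_g,rel_err"
_FMT = "%.6g"


class CurveFormatError(ValueError):
    """Malformed curve CSV; the message carries the offending line number."""


def write_curve_csv(path: str | Path, curve: DepthDoseCurve) -> Path:
    path = Path(path)
    lines = [f"#{k}: {v}" for k, v in curve.metadata.items()]
    lines.append(_HEADER)
    has_err = curve.rel_err is not None
    for i in range(len(curve)):
        fields = [_FMT % curve.depths[i], _FMT % curve.dose[i]]
        fields.append(_FMT % curve.rel_err[i] if has_err else "")
        lines.append(",".join(fields).rstrip(","))
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_curve_csv(path: str | Path) -> DepthDoseCurve:
    path = Path(path)
    metadata: dict[str, str] = {}
    depths, dose, rel = [], [], []
    saw_header = False
    has_err_col: bool | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if saw_header:
                raise CurveFormatError(
                    f"{path}:{lineno}: comment after the data header")
            key, _, val = line[1:].partition(":")
            metadata[key.strip()] = val.strip()
            continue
        if not saw_header:
            cols = [c.strip() for c in line.split(",")]
            if cols[:2] != ["depth_cm", "dose_per_history_MeV_per_g"]:
                raise CurveFormatError(
                    f"{path}:{lineno}: unexpected header {line!r}")
            has_err_col = len(cols) >= 3 and cols[2] == "rel_err"
            if not has_err_col:
                logger.warning("%s: no rel_err column; uncertainties absent", path)
            saw_header = True
            continue
        parts = line.split(",")
        try:
            depths.append(float(parts[0]))
            dose.append(float(parts[1]))
            if has_err_col and len(parts) >= 3 and parts[2] != "":
                rel.append(float(parts[2]))
        except (ValueError, IndexError) as exc:
            raise CurveFormatError(f"{path}:{lineno}: bad row {line!r}") from exc
    if not saw_header:
        raise CurveFormatError(f"{path}: missing data header")
    rel_err = np.array(rel) if (rel and len(rel) == len(depths)) else None
    try:
        return DepthDoseCurve(np.array(depths), np.array(dose), rel_err, metadata)
    except ValueError as exc:
        raise CurveFormatError(f"{path}: {exc}") from exc


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
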