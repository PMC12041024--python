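"""Plain-text serialization of the analysis objects.

Curves travel as CSV (columns ``stretch, stress_kPa`` and, when available,
``lambda2, lambda3``), tensile records as CSV (``length_mm, force_N``) with
a YAML sidecar for the specimen geometry, GHO parameters and ring geometry
as flat YAML mappings.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gho_constitutive import Direction, GHOParams, StressStretchCurve
from .ring_residual_stress import RingGeometry
from .tensile_features import TensileRecord

__all__ = [
    "read_curve_csv",
    "write_curve_csv",
    "read_params_yaml",
    "write_params_yaml",
    "read_ring_yaml",
    "read_tensile_record",
    "write_tensile_record",
]


def write_curve_csv(curve: StressStretchCurve, path: str | Path) -> None:
    data = {"stretch": curve.stretch, "stress_kPa": curve.stress}
    if curve.lambda2 is not None:
        data["lambda2"] = curve.lambda2
    if curve.lambda3 is not None:
        data["lambda3"] = curve.lambda3
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def read_curve_csv(path: str | Path, direction: str | None = None) -> StressStretchCurve:
    df = pd.read_csv(path)
    return StressStretchCurve(
        stretch=df["stretch"].to_numpy(),
        stress=df["stress_kPa"].to_numpy(),
        direction=Direction(direction) if direction else None,
        lambda2=df["lambda2"].to_numpy() if "lambda2" in df else None,
        lambda3=df["lambda3"].to_numpy() if "lambda3" in df else None,
    )


def write_params_yaml(params: GHOParams, path: str | Path, extra: dict | None = None) -> None:
    d = params.to_dict()
    if extra:
        d.update(extra)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_params_yaml(path: str | Path) -> GHOParams:
    return GHOParams.from_dict(yaml.safe_load(Path(path).read_text()))


def read_ring_yaml(path: str | Path) -> RingGeometry:
    d = yaml.safe_load(Path(path).read_text())
    return RingGeometry(
        Ro=float(d["Ro_mm"]),
        to=float(d["to_mm"]),
        alpha=float(d["alpha_deg"]),
        Ro_is_external=bool(d.get("Ro_is_external", False)),
    )


def write_tensile_record(record: TensileRecord, csv_path: str | Path) -> None:
    """Record CSV plus a ``<stem>.yaml`` geometry sidecar."""
    csv_path = Path(csv_path)
    pd.DataFrame({"length_mm": record.length_mm, "force_N": record.force_N}).to_csv(
        csv_path, index=False, float_format="%.12g"
    )
    sidecar = {
        "direction": record.direction.value,
        "l0_mm": record.l0,
        "w0_mm": record.w0,
        "t0_mm": record.t0,
    }
    csv_path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_tensile_record(csv_path: str | Path) -> TensileRecord:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    side = yaml.safe_load(csv_path.with_suffix(".yaml").read_text())
    return TensileRecord(
        direction=Direction(side["direction"]),
        l0=float(side["l0_mm"]),
        w0=float(side["w0_mm"]),
        t0=float(side["t0_mm"]),
        length_mm=df["length_mm"].to_numpy(),
        force_N=df["force_N"].to_numpy(),
    )
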