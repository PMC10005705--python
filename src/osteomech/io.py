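"""Plain-text readers and writers for the pipeline's artifacts.

Curves and traces are CSV with a header row; DMA traces carry their drive
frequency in a ``# frequency_hz=...`` comment line.  Cohorts are tidy CSV.
Geometry and calibration blocks are JSON.  Voxel volumes go through NRRD
(via SimpleITK when available).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bending import LoadDisplacementCurve, TubeGeometry
from .dma import DMATrace
from .microct import VoxelVolume

__all__ = [
    "write_curve_csv", "read_curve_csv",
    "write_trace_csv", "read_trace_csv",
    "write_cohort_csv", "read_cohort_csv",
    "write_geometry_json", "read_geometry_json",
    "write_nrrd", "read_nrrd",
]


def write_curve_csv(curve: LoadDisplacementCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"displacement_mm": curve.displacement, "load_N": curve.load}
    ).to_csv(path, index=False)


def read_curve_csv(path: str | Path) -> LoadDisplacementCurve:
    df = pd.read_csv(path)
    return LoadDisplacementCurve(
        displacement=df["displacement_mm"].to_numpy(),
        load=df["load_N"].to_numpy(),
    )


def write_trace_csv(trace: DMATrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# frequency_hz={trace.frequency!r}\n")
        pd.DataFrame(
            {"time_s": trace.time, "stress_MPa": trace.stress, "strain": trace.strain}
        ).to_csv(fh, index=False)


def read_trace_csv(path: str | Path) -> DMATrace:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# frequency_hz="):
            raise ValueError(f"{path}: missing '# frequency_hz=' header line")
        frequency = float(first.split("=", 1)[1])
        df = pd.read_csv(fh)
    return DMATrace(
        time=df["time_s"].to_numpy(),
        stress=df["stress_MPa"].to_numpy(),
        strain=df["strain"].to_numpy(),
        frequency=frequency,
    )


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"animal_id", "group", "week", "body_weight_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing cohort columns {sorted(missing)}")
    return df


def write_geometry_json(geometry: TubeGeometry, path: str | Path) -> None:
    payload = {
        "outer_radius_mm": geometry.outer_radius,
        "inner_radius_mm": geometry.inner_radius,
        "span_mm": geometry.span,
        "tibial_length_mm": geometry.tibial_length,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_geometry_json(path: str | Path) -> TubeGeometry:
    payload = json.loads(Path(path).read_text())
    return TubeGeometry(
        outer_radius=payload["outer_radius_mm"],
        inner_radius=payload.get("inner_radius_mm", 0.0),
        span=payload.get("span_mm", 6.0),
        tibial_length=payload.get("tibial_length_mm"),
    )


def write_nrrd(volume: VoxelVolume, path: str | Path) -> None:
    """Write a volume as NRRD (spacing in mm) via SimpleITK."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(volume.values)
    img.SetSpacing(tuple(reversed(volume.spacing)))
    sitk.WriteImage(img, str(path))


def read_nrrd(path: str | Path, calibrated: bool = False) -> VoxelVolume:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    return VoxelVolume(
        values=sitk.GetArrayFromImage(img).astype(float),
        spacing=tuple(reversed(img.GetSpacing())),
        calibrated=calibrated,
    )
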