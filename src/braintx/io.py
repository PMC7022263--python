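"""Result serialization: CSV timelines/reports, VTK and NIfTI volumes.

Everything written is plain text except NIfTI (the standard binary label
format of neuroimaging tools). The legacy VTK "structured points" writer
emits ASCII so field snapshots can be inspected and diffed; grids are
voxel-centred with the phantom's isotropic spacing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import ModelConfig, non_default_keys
from .phantom import VoxelPhantom
from .scenarios import ExposureReport

try:
    from importlib.metadata import version as _pkg_version
    _VERSION = _pkg_version("braintx")
except Exception:                                    # pragma: no cover
    _VERSION = "unknown"


def write_vtk_structured_points(path: str | Path, phantom: VoxelPhantom,
                                fields: dict[str, np.ndarray]) -> Path:
    """Write scalar voxel fields as an ASCII legacy-VTK structured-points file.

    Vector fields (shape grid+(3,)) are written as VECTORS; everything else
    as one SCALARS array per entry. Data are emitted in x-fastest order as
    the format requires.
    """
    path = Path(path)
    nx, ny, nz = phantom.grid_shape
    h = phantom.spacing
    lines = ["# vtk DataFile Version 3.0", "braintx field snapshot", "ASCII",
             "DATASET STRUCTURED_POINTS",
             f"DIMENSIONS {nx} {ny} {nz}",
             f"ORIGIN {-nx * h / 2 + h / 2:g} {-ny * h / 2 + h / 2:g} "
             f"{-nz * h / 2 + h / 2:g}",
             f"SPACING {h:g} {h:g} {h:g}",
             f"POINT_DATA {nx * ny * nz}"]
    for name, arr in fields.items():
        arr = np.asarray(arr)
        if arr.shape == (nx, ny, nz):
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            flat = np.nan_to_num(arr).transpose(2, 1, 0).ravel()
            lines.extend(" ".join(f"{v:.9g}" for v in chunk)
                         for chunk in np.array_split(flat, max(1, len(flat) // 9)))
        elif arr.shape == (nx, ny, nz, 3):
            lines.append(f"VECTORS {name} double")
            flat = np.nan_to_num(arr).transpose(2, 1, 0, 3).reshape(-1, 3)
            lines.extend(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}" for v in flat)
        else:
            raise ValueError(f"field {name!r} has shape {arr.shape}, "
                             f"expected {(nx, ny, nz)} or {(nx, ny, nz, 3)}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_nifti_labels(path: str | Path, phantom: VoxelPhantom) -> Path:
    """Export the phantom label volume as NIfTI with isotropic spacing (mm)."""
    import nibabel as nib

    h_mm = phantom.spacing * 1e3
    affine = np.diag([h_mm, h_mm, h_mm, 1.0])
    img = nib.Nifti1Image(phantom.labels.astype(np.int16), affine)
    img.header.set_zooms((h_mm, h_mm, h_mm))
    path = Path(path)
    nib.save(img, str(path))
    return path


def write_timeline_csv(path: str | Path, report: ExposureReport) -> Path:
    """Compartment timelines as CSV (full float precision round-trip)."""
    path = Path(path)
    df = report.result.to_dataframe()
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def export_results(report: ExposureReport, out_dir: str | Path,
                   config: ModelConfig | None = None,
                   phantom: VoxelPhantom | None = None,
                   write_fields: bool = False) -> dict[str, Path]:
    """Write a scenario report: summary CSV, timelines and a run manifest.

    The manifest echoes every non-default configuration key plus the code
    version, so a run can be reconstructed exactly from its output
    directory. Optional VTK snapshots of the final concentration fields are
    written when ``write_fields`` is set and the simulation kept them.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    import pandas as pd

    written["report"] = out / "report.csv"
    pd.DataFrame([report.row()]).to_csv(written["report"], index=False,
                                        float_format="%.17g")
    written["timeline"] = write_timeline_csv(out / "timeline.csv", report)

    manifest = {
        "code_version": _VERSION,
        "scenario": report.row(),
        "config_overrides": non_default_keys(config) if config else {},
    }
    written["manifest"] = out / "manifest.json"
    written["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))

    if write_fields and phantom is not None and report.result.final_state:
        st = report.result.final_state
        written["fields"] = write_vtk_structured_points(
            out / "final_fields.vtk", phantom,
            {"C_L_ECS_mg_ml": st.c_l_ecs, "C_F_ECS_mg_ml": st.c_f_ecs})
    return written
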