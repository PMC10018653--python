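"""Reading and writing volumes, 4D phase sets, projections and DVFs.

Scalar and vector images go through SimpleITK (MHA by default, NIfTI by
extension); acquisition and phase metadata live in JSON sidecars next to the
image files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .phantom import RoiSet
from .projector import Protocol, ProjectionSet, ScanGeometry
from .volume import DVF, Volume, Volume4D

__all__ = [
    "write_volume", "read_volume",
    "write_volume4d", "read_volume4d",
    "write_projections", "read_projections",
    "write_dvf", "read_dvf",
]


def _to_image(values: np.ndarray, spacing, origin, vector: bool = False):
    # package arrays are (x, y, z[, c]); SimpleITK arrays are (z, y, x[, c])
    if vector:
        arr = np.ascontiguousarray(np.transpose(values, (2, 1, 0, 3)))
        img = sitk.GetImageFromArray(arr.astype(np.float64), isVector=True)
    else:
        arr = np.ascontiguousarray(np.transpose(values, (2, 1, 0)))
        img = sitk.GetImageFromArray(arr.astype(np.float32))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def write_volume(vol: Volume, path) -> None:
    sitk.WriteImage(_to_image(vol.values, vol.spacing, vol.origin), str(path))


def read_volume(path) -> Volume:
    img = sitk.ReadImage(str(path))
    values = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return Volume(values, img.GetSpacing(), img.GetOrigin())


def write_volume4d(v4d: Volume4D, out_dir, prefix: str = "phase",
                   rois: RoiSet | None = None, extra: dict | None = None,
                   ext: str = "mha") -> None:
    """One image per phase plus a JSON sidecar (phase fractions, peak-inhale
    index, optional ROI boxes and extra metadata)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, vol in enumerate(v4d.phases):
        write_volume(vol, out / f"{prefix}_{k:02d}.{ext}")
    meta = {
        "n_phases": v4d.n_phases,
        "phase_fractions": list(v4d.phase_fractions),
        "peak_inhale": v4d.peak_inhale,
        "prefix": prefix,
        "ext": ext,
    }
    if rois is not None:
        meta["rois"] = rois.to_dict()
    if extra:
        meta.update(extra)
    (out / f"{prefix}.json").write_text(json.dumps(meta, indent=2))


def read_volume4d(out_dir, prefix: str = "phase") -> Volume4D:
    out = Path(out_dir)
    meta = json.loads((out / f"{prefix}.json").read_text())
    ext = meta.get("ext", "mha")
    phases = [
        read_volume(out / f"{prefix}_{k:02d}.{ext}")
        for k in range(meta["n_phases"])
    ]
    return Volume4D(phases, meta["phase_fractions"], meta["peak_inhale"])


def write_projections(pset: ProjectionSet, out_dir, name: str = "proj") -> None:
    """Projection stack as one MHA plus JSON geometry/timing sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img = sitk.GetImageFromArray(pset.images.astype(np.float32))
    sitk.WriteImage(img, str(out / f"{name}.mha"))
    geo = pset.geometry
    meta = {
        "geometry": {
            "sid": geo.sid, "sdd": geo.sdd,
            "detector_cols": geo.detector_cols,
            "detector_rows": geo.detector_rows,
            "pixel_pitch": geo.pixel_pitch, "arc_deg": geo.arc_deg,
            "start_angle_deg": geo.start_angle_deg, "full_fan": geo.full_fan,
        },
        "protocol": None if pset.protocol is None else {
            "name": pset.protocol.name,
            "n_projections": pset.protocol.n_projections,
            "duration_s": pset.protocol.duration_s,
            "breathing_rate_bpm": pset.protocol.breathing_rate_bpm,
        },
        "n_phases": pset.n_phases,
        "angles_deg": pset.angles_deg.tolist(),
        "timestamps_s": pset.timestamps_s.tolist(),
        "phase_fractions": pset.phase_fractions.tolist(),
        "phase_bins": pset.phase_bins.tolist(),
    }
    (out / f"{name}.json").write_text(json.dumps(meta, indent=2))


def read_projections(out_dir, name: str = "proj") -> ProjectionSet:
    out = Path(out_dir)
    meta = json.loads((out / f"{name}.json").read_text())
    images = sitk.GetArrayFromImage(sitk.ReadImage(str(out / f"{name}.mha")))
    geometry = ScanGeometry(**meta["geometry"])
    protocol = Protocol(**meta["protocol"]) if meta["protocol"] else None
    return ProjectionSet(
        images,
        np.asarray(meta["angles_deg"]),
        np.asarray(meta["timestamps_s"]),
        np.asarray(meta["phase_fractions"]),
        np.asarray(meta["phase_bins"], dtype=int),
        geometry, protocol, meta["n_phases"],
    )


def write_dvf(dvf: DVF, path, sidecar: bool = True) -> None:
    sitk.WriteImage(
        _to_image(dvf.vectors, dvf.spacing, dvf.origin, vector=True), str(path)
    )
    if sidecar:
        meta = {"from_phase": dvf.from_phase, "to_phase": dvf.to_phase}
        Path(str(path) + ".json").write_text(json.dumps(meta))


def read_dvf(path) -> DVF:
    img = sitk.ReadImage(str(path))
    vec = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0, 3))
    from_phase, to_phase = 0, 0
    side = Path(str(path) + ".json")
    if side.exists():
        meta = json.loads(side.read_text())
        from_phase = meta.get("from_phase", 0)
        to_phase = meta.get("to_phase", 0)
    return DVF(vec, img.GetSpacing(), img.GetOrigin(), from_phase, to_phase)
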