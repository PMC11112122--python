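"""File formats: track CSVs, ROI JSON, calibrated TIFFs, profile CSVs.

Conventions:

* Tracks: CSV with columns ``track_id,frame,x_px`` (0-based contiguous
  frames, pixel coordinates), one file per axon; an optional JSON sidecar
  per axon carries ``kymo_length_um``, ``anterograde_sign`` and the
  calibration.
* Images (kymographs, AIS stacks): TIFF, with calibration
  (``pixel_size_um``, ``frame_interval_s`` or ``px_nm``) in a ``.json``
  sidecar next to the TIFF.
* Intensity profiles: CSV with columns ``position_nm,intensity``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

from .ais import IntensityProfile
from .errors import CalibrationError, InputError
from .kymograph import Kymograph, PolylineROI
from .track_motion import AxonRecord, Track

__all__ = [
    "write_tracks_csv",
    "read_tracks_csv",
    "write_axon_metadata",
    "read_axon_metadata",
    "load_axon_dir",
    "write_kymograph_tiff",
    "read_kymograph_tiff",
    "write_roi_json",
    "read_roi_json",
    "write_profile_csv",
    "read_profile_csv",
]


def write_tracks_csv(tracks: Iterable[Track], path: str | Path) -> None:
    frames = []
    for t in tracks:
        frames.append(
            pd.DataFrame(
                {"track_id": t.track_id, "frame": t.frames, "x_px": t.x_px}
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["track_id", "frame", "x_px"])
    )
    df.to_csv(path, index=False)


def read_tracks_csv(path: str | Path, axon_id: str = "") -> list[Track]:
    df = pd.read_csv(path)
    required = {"track_id", "frame", "x_px"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: track CSV needs columns {sorted(required)}")
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        tracks.append(
            Track(
                track_id=str(tid),
                frames=sub["frame"].to_numpy(),
                x_px=sub["x_px"].to_numpy(),
                axon_id=axon_id,
            )
        )
    return tracks


def write_axon_metadata(path: str | Path, kymo_length_um: float,
                        anterograde_sign: int = 1,
                        pixel_size_um: float = 0.175,
                        frame_interval_s: float = 1.0) -> None:
    Path(path).write_text(json.dumps({
        "kymo_length_um": kymo_length_um,
        "anterograde_sign": anterograde_sign,
        "pixel_size_um": pixel_size_um,
        "frame_interval_s": frame_interval_s,
    }, indent=2))


def read_axon_metadata(path: str | Path) -> dict:
    meta = json.loads(Path(path).read_text())
    if "kymo_length_um" not in meta:
        raise CalibrationError(f"{path}: missing kymo_length_um")
    return meta


def load_axon_dir(directory: str | Path) -> tuple[list[AxonRecord], dict]:
    """Load every ``<axon>.csv`` + ``<axon>.json`` pair in a directory.

    Returns the axon records (sorted by id) and the shared calibration;
    inconsistent calibration across axons raises.
    """
    directory = Path(directory)
    records = []
    calibration: dict | None = None
    for csv_path in sorted(directory.glob("*.csv")):
        axon_id = csv_path.stem
        meta_path = csv_path.with_suffix(".json")
        if not meta_path.exists():
            raise CalibrationError(f"{csv_path}: missing metadata sidecar {meta_path.name}")
        meta = read_axon_metadata(meta_path)
        cal = {k: meta.get(k) for k in ("pixel_size_um", "frame_interval_s")}
        if calibration is None:
            calibration = cal
        elif cal != calibration:
            raise CalibrationError(f"{csv_path}: calibration differs from other axons")
        tracks = read_tracks_csv(csv_path, axon_id=axon_id)
        records.append(
            AxonRecord(axon_id=axon_id, tracks=tuple(tracks),
                       kymo_length_um=float(meta["kymo_length_um"]))
        )
    return records, (calibration or {})


def write_kymograph_tiff(kymo: Kymograph, path: str | Path) -> None:
    path = Path(path)
    mat = np.clip(kymo.matrix, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, mat)
    path.with_suffix(".json").write_text(json.dumps({
        "pixel_size_um": kymo.pixel_size_um,
        "frame_interval_s": kymo.frame_interval_s,
        "source_id": kymo.source_id,
    }, indent=2))


def read_kymograph_tiff(path: str | Path) -> Kymograph:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise CalibrationError(f"{path}: missing calibration sidecar")
    meta = json.loads(sidecar.read_text())
    return Kymograph(
        matrix=tifffile.imread(path).astype(np.float64),
        pixel_size_um=float(meta["pixel_size_um"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        source_id=meta.get("source_id", ""),
    )


def write_roi_json(roi: PolylineROI, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "vertices": np.asarray(roi.vertices).tolist(),
        "width_px": roi.width_px,
        "soma_at_start": roi.soma_at_start,
    }, indent=2))


def read_roi_json(path: str | Path) -> PolylineROI:
    d = json.loads(Path(path).read_text())
    return PolylineROI(
        vertices=np.asarray(d["vertices"], dtype=np.float64),
        width_px=int(d.get("width_px", 10)),
        soma_at_start=bool(d.get("soma_at_start", True)),
    )


def write_profile_csv(profile: IntensityProfile, path: str | Path) -> None:
    pd.DataFrame({
        "position_nm": np.arange(len(profile.values)) * profile.px_nm,
        "intensity": profile.values,
    }).to_csv(path, index=False)


def read_profile_csv(path: str | Path, origin: str = "") -> IntensityProfile:
    df = pd.read_csv(path)
    if not {"position_nm", "intensity"}.issubset(df.columns):
        raise InputError(f"{path}: profile CSV needs position_nm,intensity")
    pos = df["position_nm"].to_numpy(dtype=np.float64)
    steps = np.diff(pos)
    if len(steps) == 0 or not np.allclose(steps, steps[0]):
        raise InputError(f"{path}: positions must be evenly spaced")
    return IntensityProfile(values=df["intensity"].to_numpy(dtype=np.float64),
                            px_nm=float(steps[0]), origin=origin or str(path))
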