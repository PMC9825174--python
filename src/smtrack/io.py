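"""File formats: track/dwell CSV dialects, kymograph TIFF+JSON and HDF5.

All tables are UTF-8 comma-separated with a mandatory header row and '.'
decimals; positions are stored in micrometers. Kymographs are written either
as a 2D grayscale TIFF with a JSON sidecar carrying the pixel and frame
calibration, or as a single HDF5 container holding image and metadata.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .kinetics import DwellRecord
from .tracking import Kymograph, Trajectory

__all__ = [
    "tracks_to_frame",
    "frame_to_tracks",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_dwells_csv",
    "read_dwells_csv",
    "write_kymograph_tiff",
    "read_kymograph_tiff",
    "write_kymograph_hdf5",
    "read_kymograph_hdf5",
]

TRACK_COLUMNS = [
    "particle_id",
    "channel",
    "frame",
    "time_s",
    "position_um",
    "amplitude",
    "sigma_px",
    "censored_end",
    "merged_gaps",
]
DWELL_COLUMNS = [
    "particle_id",
    "channel",
    "start_s",
    "end_s",
    "duration_s",
    "censored",
    "on_target",
]


def tracks_to_frame(tracks: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        amps = t.amplitudes if t.amplitudes is not None else np.full(len(t), np.nan)
        sigs = t.sigmas_px if t.sigmas_px is not None else np.full(len(t), np.nan)
        for k in range(len(t)):
            rows.append(
                {
                    "particle_id": t.particle_id,
                    "channel": t.channel,
                    "frame": int(t.frames[k]),
                    "time_s": float(t.frames[k] * t.frame_interval),
                    "position_um": float(t.positions_um[k]),
                    "amplitude": float(amps[k]),
                    "sigma_px": float(sigs[k]),
                    "censored_end": bool(t.censored_end),
                    "merged_gaps": int(t.merged_gaps),
                }
            )
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def frame_to_tracks(df: pd.DataFrame, frame_interval: float) -> list[Trajectory]:
    _validate_columns(df, ["particle_id", "channel", "frame", "position_um"], TRACK_COLUMNS)
    tracks = []
    for (pid, channel), grp in df.groupby(["particle_id", "channel"], sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Trajectory(
                particle_id=int(pid),
                channel=str(channel),
                frames=grp["frame"].to_numpy(),
                positions_um=grp["position_um"].to_numpy(),
                frame_interval=frame_interval,
                amplitudes=grp["amplitude"].to_numpy() if "amplitude" in grp else None,
                sigmas_px=grp["sigma_px"].to_numpy() if "sigma_px" in grp else None,
                censored_end=bool(grp["censored_end"].iloc[0])
                if "censored_end" in grp
                else False,
                merged_gaps=int(grp["merged_gaps"].iloc[0])
                if "merged_gaps" in grp
                else 0,
            )
        )
    return tracks


def _validate_columns(df: pd.DataFrame, mandatory: list[str], known: list[str]) -> None:
    for col in mandatory:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col!r}")
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"unknown columns ignored: {unknown}")


def write_tracks_csv(tracks: list[Trajectory], path) -> None:
    # %.17g guarantees bit-exact float64 round trips
    tracks_to_frame(tracks).to_csv(path, index=False, float_format="%.17g")


def read_tracks_csv(path, frame_interval: float) -> list[Trajectory]:
    return frame_to_tracks(pd.read_csv(path, float_precision="round_trip"), frame_interval)


def write_dwells_csv(dwells: list[DwellRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "particle_id": d.particle_id,
                "channel": d.channel,
                "start_s": d.start_s,
                "end_s": d.end_s,
                "duration_s": d.duration_s,
                "censored": d.censored,
                "on_target": d.on_target,
            }
            for d in dwells
        ],
        columns=DWELL_COLUMNS,
    ).to_csv(path, index=False, float_format="%.17g")


def read_dwells_csv(path) -> list[DwellRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _validate_columns(df, ["particle_id", "start_s", "end_s"], DWELL_COLUMNS)
    out = []
    for _, row in df.iterrows():
        on_target = row.get("on_target")
        out.append(
            DwellRecord(
                particle_id=int(row["particle_id"]),
                channel=str(row.get("channel", "default")),
                start_s=float(row["start_s"]),
                end_s=float(row["end_s"]),
                censored=bool(row.get("censored", False)),
                on_target=None if pd.isna(on_target) else bool(on_target),
            )
        )
    return out


def write_kymograph_tiff(kymo: Kymograph, path) -> None:
    """2D grayscale TIFF plus a `<stem>.json` calibration sidecar."""
    path = Path(path)
    tifffile.imwrite(path, kymo.data.astype(np.float32))
    sidecar = {
        "pixel_size_um": kymo.pixel_size,
        "frame_interval_s": kymo.frame_interval,
        "channel": kymo.channel,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_kymograph_tiff(path) -> Kymograph:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ValueError(f"missing calibration sidecar: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("pixel_size_um", "frame_interval_s"):
        if key not in meta:
            raise ValueError(f"sidecar missing mandatory key: {key!r}")
    return Kymograph(
        data=tifffile.imread(path).astype(float),
        pixel_size=meta["pixel_size_um"],
        frame_interval=meta["frame_interval_s"],
        channel=meta.get("channel", "default"),
    )


def write_kymograph_hdf5(kymo: Kymograph, path, config: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("kymograph/image", data=kymo.data)
        ds.attrs["pixel_size_um"] = kymo.pixel_size
        ds.attrs["frame_interval_s"] = kymo.frame_interval
        ds.attrs["channel"] = kymo.channel
        if config is not None:
            f.create_dataset("config_json", data=json.dumps(config))


def read_kymograph_hdf5(path) -> tuple[Kymograph, dict | None]:
    with h5py.File(path, "r") as f:
        if "kymograph/image" not in f:
            raise ValueError("missing dataset: kymograph/image")
        ds = f["kymograph/image"]
        kymo = Kymograph(
            data=ds[...],
            pixel_size=float(ds.attrs["pixel_size_um"]),
            frame_interval=float(ds.attrs["frame_interval_s"]),
            channel=str(ds.attrs.get("channel", "default")),
        )
        config = (
            json.loads(f["config_json"][()]) if "config_json" in f else None
        )
    return kymo, config
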