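"""File I/O: CSV/TSV trace tables, YAML session configs, JSON sidecars.

Trace tables are plain CSV with one row per frame; session metadata
(frame interval, application layout, bands, thresholds) lives in YAML so
files stay self-describing without binary containers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .photometry import BurstLayout, RawPmtStream
from .ratio_imaging import Application, RatiometricRecording
from .sleep_staging import Hypnogram
from .tst_behavior import AreaSeries, ImmobilityTrack


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


# -- ratiometric recordings -------------------------------------------------

def write_yc_recording(rec: RatiometricRecording, traces_csv, session_yaml) -> None:
    """Trace CSV (frame + per-ROI YFP/CFP columns) and session YAML."""
    cols = {"frame": np.arange(rec.n_frames)}
    for j in range(rec.n_rois):
        cols[f"yfp_{j}"] = rec.yfp[:, j]
    for j in range(rec.n_rois):
        cols[f"cfp_{j}"] = rec.cfp[:, j]
    pd.DataFrame(cols).to_csv(traces_csv, index=False)
    meta = {
        "frame_interval": rec.frame_interval,
        "animal_id": rec.animal_id,
        "slice_id": rec.slice_id,
        "sex": rec.sex,
        "applications": [
            {"substance": a.substance, "onset": a.onset, "duration": a.duration}
            for a in rec.applications
        ],
    }
    Path(session_yaml).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_yc_recording(traces_csv, session_yaml) -> RatiometricRecording:
    df = pd.read_csv(traces_csv)
    meta = yaml.safe_load(Path(session_yaml).read_text())
    ycols = sorted(
        (c for c in df.columns if c.startswith("yfp_")),
        key=lambda c: int(c.split("_")[1]),
    )
    ccols = sorted(
        (c for c in df.columns if c.startswith("cfp_")),
        key=lambda c: int(c.split("_")[1]),
    )
    return RatiometricRecording(
        yfp=df[ycols].to_numpy(),
        cfp=df[ccols].to_numpy(),
        frame_interval=float(meta["frame_interval"]),
        applications=[
            Application(a["substance"], float(a["onset"]), float(a.get("duration", 120.0)))
            for a in meta.get("applications", [])
        ],
        animal_id=str(meta.get("animal_id", "")),
        slice_id=str(meta.get("slice_id", "")),
        sex=str(meta.get("sex", "")),
    )


# -- tail suspension --------------------------------------------------------

def write_area_series(a: AreaSeries, csv_path) -> None:
    pd.DataFrame({"frame": np.arange(a.n_frames), "area": a.area}).to_csv(
        csv_path, index=False
    )


def read_area_series(csv_path, frame_rate: float, **kwargs) -> AreaSeries:
    df = pd.read_csv(csv_path)
    return AreaSeries(area=df["area"].to_numpy(), frame_rate=frame_rate, **kwargs)


def write_immobility(track: ImmobilityTrack, csv_path) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(track.immobile.shape[0]),
            "ts_wlt": track.ts_wlt,
            "immobile": track.immobile.astype(int),
        }
    ).to_csv(csv_path, index=False)


def read_immobile_mask(csv_path) -> np.ndarray:
    return pd.read_csv(csv_path)["immobile"].to_numpy().astype(bool)


# -- sleep staging ----------------------------------------------------------

def write_signals(eeg, emg, ir, csv_path) -> None:
    pd.DataFrame({"eeg": eeg, "emg": emg, "ir": ir}).to_csv(csv_path, index=False)


def read_signals(csv_path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(csv_path)
    return df["eeg"].to_numpy(), df["emg"].to_numpy(), df["ir"].to_numpy()


def write_hypnogram(h: Hypnogram, csv_path) -> None:
    pd.DataFrame(
        {
            "epoch": np.arange(h.n_epochs),
            "label": h.labels,
            "provenance": h.provenance,
        }
    ).to_csv(csv_path, index=False)


def read_hypnogram(csv_path, epoch_length: float = 4.0) -> Hypnogram:
    df = pd.read_csv(csv_path)
    return Hypnogram(
        labels=df["label"].to_numpy(dtype=object),
        epoch_length=epoch_length,
        provenance=df["provenance"].to_numpy(dtype=object)
        if "provenance" in df
        else None,
    )


# -- photometry -------------------------------------------------------------

def write_raw_stream(raw: RawPmtStream, path) -> None:
    """Flat binary (float64 little-endian) for .bin paths, else CSV."""
    path = Path(path)
    if path.suffix == ".bin":
        raw.voltage.astype("<f8").tofile(path)
    else:
        pd.DataFrame({"voltage": raw.voltage}).to_csv(path, index=False)


def read_raw_stream(path, layout: BurstLayout | None = None) -> RawPmtStream:
    path = Path(path)
    if path.suffix == ".bin":
        voltage = np.fromfile(path, dtype="<f8")
    else:
        voltage = pd.read_csv(path)["voltage"].to_numpy()
    return RawPmtStream(voltage=voltage, layout=layout or BurstLayout())


def read_layout_yaml(path) -> BurstLayout:
    meta = yaml.safe_load(Path(path).read_text()) or {}
    return BurstLayout(
        points_per_burst=int(meta.get("points_per_burst", 25)),
        cycle_points=int(meta.get("cycle_points", 50)),
        first_channel=int(meta.get("first_channel", 470)),
    )
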