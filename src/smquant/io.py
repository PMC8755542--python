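"""Readers and writers for the pipeline's on-disk formats.

Kymographs travel as uncompressed TIFF (one page per channel) with a JSON
sidecar carrying the scan calibration; traces and tables as headed CSV
(comma-separated, '.' decimal, UTF-8); reads as FASTA; fit summaries and
ground truth as JSON.  Every writer's output round-trips through its paired
reader within CSV precision (6 significant digits).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .kinetics import DecayTrace, DwellSet
from .motion import DistanceTrace
from .tracking import Kymograph, Localization, Trajectory

__all__ = [
    "write_kymograph",
    "read_kymograph",
    "write_trace_csv",
    "read_distance_trace",
    "read_decay_trace",
    "write_localizations",
    "write_trajectories",
    "read_trajectories",
    "write_dwells",
    "read_dwells",
    "write_fasta",
    "read_fasta",
    "write_json",
    "read_json",
]

CSV_FLOAT_FMT = "%.6g"


def write_kymograph(path: str | Path, kymo: Kymograph) -> None:
    """Write a kymograph as uncompressed TIFF plus a .json calibration sidecar."""
    path = Path(path)
    tifffile.imwrite(path, kymo.intensity.astype(np.float32), compression=None)
    sidecar = {
        "pixel_size_nm": kymo.pixel_size,
        "line_time_s": kymo.line_time,
        "channel": kymo.channel,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_kymograph(path: str | Path) -> Kymograph:
    path = Path(path)
    img = tifffile.imread(path).astype(float)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return Kymograph(
        intensity=img,
        pixel_size=meta.get("pixel_size_nm", 100.0),
        line_time=meta.get("line_time_s", 0.997),
        channel=meta.get("channel", ""),
    )


def write_trace_csv(
    path: str | Path, time: np.ndarray, value: np.ndarray,
    time_col: str, value_col: str,
) -> None:
    pd.DataFrame({time_col: time, value_col: value}).to_csv(
        path, index=False, float_format=CSV_FLOAT_FMT
    )


def read_distance_trace(path: str | Path) -> DistanceTrace:
    df = pd.read_csv(path)
    return DistanceTrace(
        time=df["time_s"].to_numpy(), distance=df["distance_nm"].to_numpy()
    )


def read_decay_trace(path: str | Path) -> DecayTrace:
    df = pd.read_csv(path)
    return DecayTrace(
        time=df["time_min"].to_numpy(), intensity=df["intensity"].to_numpy()
    )


def write_localizations(path: str | Path, locs: list[Localization]) -> None:
    pd.DataFrame([dataclasses.asdict(l) for l in locs]).to_csv(
        path, index=False, float_format=CSV_FLOAT_FMT
    )


def write_trajectories(
    path: str | Path, tracks: list[Trajectory]
) -> None:
    if tracks:
        df = pd.concat([t.to_frame() for t in tracks], ignore_index=True)
    else:
        df = pd.DataFrame(columns=["track_id", "time_s", "position_nm"])
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FMT)


def read_trajectories(path: str | Path) -> list[Trajectory]:
    df = pd.read_csv(path)
    out = []
    for tid, grp in df.groupby("track_id", sort=True):
        out.append(
            Trajectory(
                time=grp["time_s"].to_numpy(),
                position=grp["position_nm"].to_numpy(),
                particle_id=int(tid),
            )
        )
    return out


def write_dwells(path: str | Path, dwells: DwellSet) -> None:
    pd.DataFrame(
        {"duration_s": dwells.durations, "censored": dwells.censored.astype(int)}
    ).to_csv(path, index=False, float_format=CSV_FLOAT_FMT)


def read_dwells(path: str | Path, condition: str = "") -> DwellSet:
    df = pd.read_csv(path)
    return DwellSet(
        durations=df["duration_s"].to_numpy(),
        censored=df["censored"].to_numpy().astype(bool),
        condition=condition,
    )


def write_fasta(path: str | Path, reads: list[tuple[str, str]]) -> None:
    records = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in reads]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
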