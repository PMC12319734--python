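"""BIDS-like on-disk layout for synthetic sessions and result tables.

A session directory holds an HDF5 array container with the channel x time
data, a ``*_events.tsv`` table, a ``*_channels.tsv`` geometry table and a
JSON sidecar with sampling rate and platform metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import SensorArray
from .paradigm import write_events_tsv, read_events_tsv
from .simulate import Recording

__all__ = ["write_recording", "read_recording", "write_image_tsv"]


def _stem(rec: Recording) -> str:
    return f"{rec.subject}_ses-{rec.platform}{rec.run}_task-braille"


def write_recording(rec: Recording, session_dir: str | Path) -> Path:
    session_dir = Path(session_dir)
    session_dir.mkdir(parents=True, exist_ok=True)
    stem = _stem(rec)
    with h5py.File(session_dir / f"{stem}_meg.h5", "w") as f:
        f.create_dataset("data_fT", data=rec.data, compression="gzip", compression_opts=1)
        f.attrs["sampling_rate_hz"] = rec.sampling_rate_hz
        f.attrs["lead_in_s"] = rec.lead_in_s
    write_events_tsv(rec.events, session_dir / f"{stem}_events.tsv")
    rec.array.to_tsv(session_dir / f"{stem}_channels.tsv")
    sidecar = {
        "subject": rec.subject,
        "platform": rec.platform,
        "run": rec.run,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "units": "fT",
        "lead_in_s": rec.lead_in_s,
    }
    (session_dir / f"{stem}_meg.json").write_text(json.dumps(sidecar, indent=1))
    return session_dir


def read_recording(session_dir: str | Path) -> Recording:
    session_dir = Path(session_dir)
    meta_path = next(session_dir.glob("*_meg.json"))
    meta = json.loads(meta_path.read_text())
    stem = meta_path.name[: -len("_meg.json")]
    with h5py.File(session_dir / f"{stem}_meg.h5", "r") as f:
        data = f["data_fT"][()]
    events = read_events_tsv(session_dir / f"{stem}_events.tsv")
    ch = pd.read_csv(session_dir / f"{stem}_channels.tsv", sep="\t")
    side = json.loads((session_dir / f"{stem}_channels.json").read_text())
    array = SensorArray(
        platform=side["platform"],
        positions=ch[["x", "y", "z"]].to_numpy(),
        orientations=ch[["ox", "oy", "oz"]].to_numpy(),
        kinds=ch["kind"].tolist(),
        sampling_rate_hz=side["sampling_rate_hz"],
        noise_floor=ch["noise_floor_fT_sqrtHz"].to_numpy(),
        sphere_centre=np.asarray(side["sphere_centre_m"]),
        grad_baseline_m=side["grad_baseline_m"],
        names=ch["name"].tolist(),
    )
    return Recording(
        platform=meta["platform"],
        subject=meta["subject"],
        run=meta["run"],
        data=data,
        sampling_rate_hz=meta["sampling_rate_hz"],
        events=events,
        array=array,
        lead_in_s=meta["lead_in_s"],
    )


def write_image_tsv(positions: np.ndarray, values: np.ndarray, path: str | Path) -> None:
    """Voxel-table image: x, y, z (m) and the per-voxel value."""
    pd.DataFrame(
        {"x": positions[:, 0], "y": positions[:, 1], "z": positions[:, 2], "value": values}
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")
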