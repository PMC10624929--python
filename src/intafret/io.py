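"""Tabular trace and sidecar-JSON input/output.

Traces travel as plain tab-separated text with columns
``frame_index, time_s, donor, acceptor`` plus a ``# key: value`` header
carrying the frame interval and injection frame; ground truth and
provenance are JSON sidecars.  Rendered movies are multi-page TIFFs with
the channel split recorded in metadata.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .simulate import GroundTruth, SimConfig
from .traces import IntensityTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_ground_truth",
    "read_ground_truth",
    "write_movie_tiff",
    "read_movie_tiff",
    "write_provenance",
]


def write_trace(path: str | Path, trace: IntensityTrace) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# frame_interval_s: {trace.frame_interval}\n")
        if trace.injection_frame is not None:
            fh.write(f"# injection_frame: {trace.injection_frame}\n")
        fh.write("frame_index\ttime_s\tdonor\tacceptor\n")
        for i, (d, a) in enumerate(zip(trace.donor, trace.acceptor)):
            fh.write(f"{i}\t{i * trace.frame_interval:.6g}\t{d:.6f}\t{a:.6f}\n")


def read_trace(path: str | Path) -> IntensityTrace:
    path = Path(path)
    frame_interval = None
    injection_frame = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            key = key.strip()
            if key == "frame_interval_s":
                frame_interval = float(value)
            elif key == "injection_frame":
                injection_frame = int(value)
    if frame_interval is None:
        raise ValueError(f"{path}: missing '# frame_interval_s' header")
    df = pd.read_csv(path, sep="\t", comment="#")
    return IntensityTrace(
        frame_interval,
        df["donor"].to_numpy(),
        df["acceptor"].to_numpy(),
        injection_frame=injection_frame,
    )


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    payload = {
        "intervals": [[lbl, s, e] for lbl, s, e in truth.intervals],
        "stc": truth.stc,
        "bleach_donor": truth.bleach_donor if np.isfinite(truth.bleach_donor) else None,
        "bleach_acceptor": truth.bleach_acceptor if np.isfinite(truth.bleach_acceptor) else None,
        "pseudo_excursions": [list(x) for x in truth.pseudo_excursions],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        intervals=[tuple(iv) for iv in payload["intervals"]],
        stc=payload["stc"],
        bleach_donor=payload["bleach_donor"] if payload["bleach_donor"] is not None else np.inf,
        bleach_acceptor=payload["bleach_acceptor"] if payload["bleach_acceptor"] is not None else np.inf,
        pseudo_excursions=[tuple(x) for x in payload.get("pseudo_excursions", [])],
    )


def write_movie_tiff(path: str | Path, donor: np.ndarray, acceptor: np.ndarray) -> None:
    """Two-channel stack as a multi-page TIFF, channels interleaved as
    (frame, channel, row, col) with the split recorded in metadata."""
    stack = np.stack([donor, acceptor], axis=1).astype(np.float32)
    tifffile.imwrite(str(path), stack, metadata={"axes": "TCYX", "channels": "donor,acceptor"})


def read_movie_tiff(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    stack = tifffile.imread(str(path))
    if stack.ndim != 4 or stack.shape[1] != 2:
        raise ValueError("expected a (frames, 2, H, W) two-channel stack")
    return stack[:, 0].astype(float), stack[:, 1].astype(float)


def write_provenance(path: str | Path, config: SimConfig | dict, seed: Optional[int] = None, **extra) -> None:
    payload = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
    payload = {"parameters": payload, "seed": seed, **extra}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
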