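"""Plain-text readers/writers for the pipeline's interchange formats.

* traces: CSV with columns ``t_ms, pupil_l_mm, pupil_r_mm, gaze_x_deg,
  gaze_y_deg, valid`` (UTF-8, dot decimal), one file per session
* schedules: JSON with the participant id, state and per-stimulus blocks
* eye images: ASCII portable greymap (PGM, P2) plus a sidecar JSON carrying
  the ground-truth circle geometry
* feature tables and baseline profiles: CSV / JSON
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .irisid import EyeImage
from .oculometrics import BaselineProfile
from .simgen import Block, BlockSchedule

TRACE_COLUMNS = ["t_ms", "pupil_l_mm", "pupil_r_mm", "gaze_x_deg",
                 "gaze_y_deg", "valid"]


def write_trace(df: pd.DataFrame, path) -> None:
    df.loc[:, TRACE_COLUMNS].to_csv(path, index=False)


def read_trace(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace file {path} lacks columns {sorted(missing)}")
    return df


def write_schedule(schedule: BlockSchedule, path) -> None:
    rec = {
        "participant_id": schedule.participant_id,
        "state": schedule.state,
        "blocks": [
            {"onset_ms": b.onset_ms, "baseline_ms": b.baseline_ms,
             "stimulus_ms": b.stimulus_ms, "rest_ms": b.rest_ms,
             "valence": b.valence}
            for b in schedule.blocks
        ],
    }
    Path(path).write_text(json.dumps(rec, indent=1), encoding="utf-8")


def read_schedule(path) -> BlockSchedule:
    rec = json.loads(Path(path).read_text(encoding="utf-8"))
    blocks = [Block(**b) for b in rec["blocks"]]
    return BlockSchedule(participant_id=rec["participant_id"],
                         state=rec["state"], blocks=blocks)


def write_pgm(image: EyeImage, path, maxval: int = 255) -> None:
    """ASCII (P2) portable greymap; the ground-truth circles, when present,
    go to a ``.json`` sidecar next to the image."""
    data = np.clip(np.rint(image.data * maxval), 0, maxval).astype(int)
    h, w = data.shape
    lines = [f"P2", f"{w} {h}", f"{maxval}"]
    lines += [" ".join(map(str, row)) for row in data]
    Path(path).write_text("\n".join(lines) + "\n", encoding="ascii")
    if image.ground_truth is not None:
        Path(path).with_suffix(".json").write_text(
            json.dumps(image.ground_truth), encoding="utf-8")


def read_pgm(path) -> EyeImage:
    tokens = []
    for line in Path(path).read_text(encoding="ascii").splitlines():
        line = line.split("#")[0]
        tokens.extend(line.split())
    if tokens[0] != "P2":
        raise ValueError("only ASCII (P2) PGM files are supported")
    w, h, maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
    data = np.array(tokens[4:4 + w * h], dtype=float).reshape(h, w) / maxval
    sidecar = Path(path).with_suffix(".json")
    gt = json.loads(sidecar.read_text(encoding="utf-8")) if sidecar.exists() else None
    return EyeImage(data=data, ground_truth=gt)


FEATURE_CSV_COLUMNS = ["participant_id", "session_id", "state", "stimulus_idx",
                       "valence", "PDA", "CL", "CL_censored", "PDV", "FD",
                       "SV", "SA", "GDE", "EMA"]


def write_features(df: pd.DataFrame, path) -> None:
    df.loc[:, FEATURE_CSV_COLUMNS].to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_profiles(profiles: dict[str, BaselineProfile], path) -> None:
    rec = {
        pid: {"stats": {k: list(v) for k, v in prof.stats.items()},
              "n_sessions": prof.n_sessions, "states": list(prof.states)}
        for pid, prof in profiles.items()
    }
    Path(path).write_text(json.dumps(rec, indent=1), encoding="utf-8")


def read_profiles(path) -> dict[str, BaselineProfile]:
    rec = json.loads(Path(path).read_text(encoding="utf-8"))
    return {
        pid: BaselineProfile(stats={k: tuple(v) for k, v in d["stats"].items()},
                             n_sessions=d["n_sessions"],
                             states=tuple(d["states"]))
        for pid, d in rec.items()
    }
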