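"""CSV/JSON interchange for recordings, resultants, markers, scores and weights.

The simulator's CSV dialect is one file per (subject, session, sensor,
modality) with columns ``t_s, x, y, z`` plus a manifest CSV naming the files
and their labels.  Indices written to CSV are the package's native 0-based,
half-open convention.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .cycles import CycleIndex
from .fusion import FusionWeights, ScoreTensor
from .preprocess import ImuRecording, ResultantSignal

MANIFEST_NAME = "manifest.csv"


def write_session(recordings: Dict[Tuple[int, str], ImuRecording],
                  out_dir, session_id: int = 0) -> Path:
    """Write one session's ten streams plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (sensor_id, modality), rec in sorted(recordings.items()):
        name = (f"subject{rec.subject_id:02d}_session{session_id:02d}"
                f"_sensor{sensor_id}_{modality}.csv")
        t = np.arange(len(rec)) / rec.fs
        pd.DataFrame({"t_s": t, "x": rec.rx, "y": rec.ry, "z": rec.rz}).to_csv(
            out_dir / name, index=False, float_format="%.6f")
        rows.append({"path": name, "subject_id": rec.subject_id,
                     "session_id": session_id, "sensor_id": sensor_id,
                     "modality": modality, "fs": rec.fs,
                     "rest_start": rec.rest_span[0], "rest_end": rec.rest_span[1]})
    manifest = out_dir / MANIFEST_NAME
    header = not manifest.exists()
    pd.DataFrame(rows).to_csv(manifest, mode="a", header=header, index=False)
    return manifest


def read_session(manifest_path) -> List[ImuRecording]:
    """Read every recording listed in a manifest CSV."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path)
    out = []
    for _, row in table.iterrows():
        data = pd.read_csv(base / row["path"])
        out.append(ImuRecording(
            subject_id=int(row["subject_id"]), sensor_id=int(row["sensor_id"]),
            modality=str(row["modality"]), fs=float(row["fs"]),
            rx=data["x"].to_numpy(), ry=data["y"].to_numpy(),
            rz=data["z"].to_numpy(),
            rest_span=(int(row["rest_start"]), int(row["rest_end"])),
            session_id=int(row["session_id"])))
    return out


def write_resultant(sig: ResultantSignal, path) -> None:
    t = np.arange(len(sig)) / sig.fs
    pd.DataFrame({"t_s": t, "mag": sig.mag}).to_csv(path, index=False,
                                                    float_format="%.6f")


def write_cycle_markers(cycles: List[CycleIndex], subject_id: int, path) -> None:
    pd.DataFrame([{"cycle_id": k, "subject": subject_id, "start": c.start,
                   "end": c.end, "offset": c.offset,
                   "zero_cross_adjust": c.zero_cross_adjust}
                  for k, c in enumerate(cycles)]).to_csv(path, index=False)


def write_scores(scores: ScoreTensor, path) -> None:
    """Score table: one row per (segment, model) with S_1..S_M and the label."""
    T, N, M = scores.scores.shape
    rows = []
    for t in range(T):
        for i in range(N):
            row = {"segment_id": t, "model_id": i + 1,
                   "true_subject": int(scores.labels[t])}
            row.update({f"S_{j + 1}": scores.scores[t, i, j] for j in range(M)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def read_scores(path) -> ScoreTensor:
    table = pd.read_csv(path)
    score_cols = sorted([c for c in table.columns if c.startswith("S_")],
                        key=lambda c: int(c.split("_")[1]))
    seg_ids = np.sort(table["segment_id"].unique())
    model_ids = np.sort(table["model_id"].unique())
    T, N, M = len(seg_ids), len(model_ids), len(score_cols)
    S = np.zeros((T, N, M))
    labels = np.zeros(T, dtype=int)
    table = table.set_index(["segment_id", "model_id"]).sort_index()
    for ti, t in enumerate(seg_ids):
        for ni, n in enumerate(model_ids):
            row = table.loc[(t, n)]
            S[ti, ni] = row[score_cols].to_numpy(dtype=float)
        labels[ti] = int(table.loc[(t, model_ids[0])]["true_subject"])
    return ScoreTensor(scores=S, labels=labels)


def write_weights(weights: FusionWeights, path) -> None:
    with open(path, "w") as fh:
        json.dump({"w": weights.w.tolist(), "theta": weights.theta.tolist(),
                   "error_trace": list(map(int, weights.error_trace))}, fh, indent=1)


def read_weights(path) -> FusionWeights:
    with open(path) as fh:
        d = json.load(fh)
    return FusionWeights(w=np.asarray(d["w"]), theta=np.asarray(d["theta"]),
                         error_trace=list(d["error_trace"]))
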