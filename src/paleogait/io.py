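"""File formats: meshes, landmarks, trials, warps, models, tidy tables.

Canonical interchange is diffable columnar text plus JSON sidecars; meshes
travel as ASCII OBJ/PLY via trimesh.  Numeric text is written with 9
significant digits, so write-then-read round-trips are exact to that
precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd
import trimesh
import yaml

from .core import GaitTrial, HipShapeParams, PlateRecord, SubjectAnthropometry
from .model import MuscleElement, SkeletonModel, build_subject_model
from .morphology import LandmarkedMesh, TPSWarp

__all__ = [
    "write_mesh", "read_mesh", "write_landmarks", "read_landmarks",
    "write_trial", "read_trial", "write_warp", "read_warp",
    "write_model_config", "read_model_config", "write_table", "read_table",
]

_FMT = "%.9g"


def write_mesh(mesh: LandmarkedMesh, path: str | Path, landmarks_path: str | Path | None = None) -> None:
    """Write a mesh as ASCII OBJ/PLY plus a landmark JSON sidecar."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    data = tm.export(file_type=path.suffix.lstrip(".") or "obj")
    if isinstance(data, bytes):
        data = data.decode()
    path.write_text(data)
    if landmarks_path is None:
        landmarks_path = path.with_suffix(".landmarks.json")
    write_landmarks(mesh.landmarks, landmarks_path)


def read_mesh(path: str | Path, landmarks_path: str | Path | None = None) -> LandmarkedMesh:
    path = Path(path)
    tm = trimesh.load(path, process=False, force="mesh")
    if landmarks_path is None:
        landmarks_path = path.with_suffix(".landmarks.json")
    lms = read_landmarks(landmarks_path) if Path(landmarks_path).exists() else {}
    return LandmarkedMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=int),
        landmarks=lms,
    )


def _no_duplicate_pairs(pairs):
    d = {}
    for k, v in pairs:
        if k in d:
            raise ValueError(f"duplicate landmark name {k!r}")
        d[k] = v
    return d


def write_landmarks(landmarks: Dict[str, np.ndarray], path: str | Path) -> None:
    out = {k: [float(f"{x:.9g}") for x in v] for k, v in landmarks.items()}
    Path(path).write_text(json.dumps(out, indent=1))


def read_landmarks(path: str | Path) -> Dict[str, np.ndarray]:
    raw = json.loads(Path(path).read_text(), object_pairs_hook=_no_duplicate_pairs)
    return {k: np.asarray(v, dtype=float) for k, v in raw.items()}


# ---------------------------------------------------------------------------
# Gait trials: two columnar text files + a JSON sidecar


def write_trial(trial: GaitTrial, directory: str | Path, stem: str = "trial") -> Dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, arr in trial.marker_trajectories.items():
        for f, (x, y, z) in enumerate(arr):
            rows.append((f, name, x, y, z))
    markers = pd.DataFrame(rows, columns=["frame", "marker", "x", "y", "z"])
    mpath = directory / f"{stem}_markers.txt"
    markers.to_csv(mpath, sep="\t", index=False, float_format=_FMT)

    rows = []
    for plate, rec in enumerate(trial.grf_records):
        for f in range(rec.n_frames()):
            rows.append((f, plate, *rec.force[f], *rec.cop[f], rec.free_moment[f]))
    grf = pd.DataFrame(rows, columns=["frame", "plate", "Fx", "Fy", "Fz",
                                      "COPx", "COPy", "COPz", "Tz"])
    gpath = directory / f"{stem}_grf.txt"
    grf.to_csv(gpath, sep="\t", index=False, float_format=_FMT)

    s = trial.subject
    sidecar = {
        "side": trial.side,
        "sample_rate": trial.sample_rate,
        "events": trial.events,
        "subject": {
            "subject_id": s.subject_id, "sex": s.sex, "body_mass": s.body_mass,
            "stature": s.stature, "hip_breadth": s.hip_breadth,
            "femur_length": s.femur_length,
        },
        "meta": {k: (list(v) if isinstance(v, tuple) else v) for k, v in trial.meta.items()},
    }
    jpath = directory / f"{stem}.json"
    jpath.write_text(json.dumps(sidecar, indent=1))
    return {"markers": mpath, "grf": gpath, "sidecar": jpath}


def read_trial(directory: str | Path, stem: str = "trial") -> GaitTrial:
    directory = Path(directory)
    try:
        markers = pd.read_csv(directory / f"{stem}_markers.txt", sep="\t")
        grf = pd.read_csv(directory / f"{stem}_grf.txt", sep="\t")
        sidecar = json.loads((directory / f"{stem}.json").read_text())
    except (pd.errors.ParserError, json.JSONDecodeError) as err:
        raise ValueError(f"malformed trial files in {directory}: {err}") from err
    traj = {}
    for name, g in markers.groupby("marker", sort=False):
        g = g.sort_values("frame")
        traj[str(name)] = g[["x", "y", "z"]].to_numpy()
    plates = []
    for plate, g in grf.groupby("plate", sort=True):
        g = g.sort_values("frame")
        plates.append(PlateRecord(
            force=g[["Fx", "Fy", "Fz"]].to_numpy(),
            cop=g[["COPx", "COPy", "COPz"]].to_numpy(),
            free_moment=g["Tz"].to_numpy(),
        ))
    subj = SubjectAnthropometry(**sidecar["subject"])
    meta = sidecar.get("meta", {})
    if "plate_feet" in meta:
        meta["plate_feet"] = tuple(meta["plate_feet"])
    return GaitTrial(
        subject=subj, side=sidecar["side"], marker_trajectories=traj,
        grf_records=tuple(plates), events={k: int(v) for k, v in sidecar["events"].items()},
        sample_rate=float(sidecar["sample_rate"]), meta=meta,
    )


# ---------------------------------------------------------------------------
# Warps, model configs, tidy tables


def write_warp(warp: TPSWarp, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "source_landmarks": warp.source_landmarks.tolist(),
        "target_landmarks": warp.target_landmarks.tolist(),
        "affine_part": warp.affine_part.tolist(),
        "kernel_weights": warp.kernel_weights.tolist(),
        "regularization": warp.regularization,
    }))


def read_warp(path: str | Path) -> TPSWarp:
    d = json.loads(Path(path).read_text())
    return TPSWarp(
        source_landmarks=np.array(d["source_landmarks"]),
        target_landmarks=np.array(d["target_landmarks"]),
        affine_part=np.array(d["affine_part"]),
        kernel_weights=np.array(d["kernel_weights"]),
        regularization=float(d["regularization"]),
    )


def write_model_config(model: SkeletonModel, path: str | Path) -> None:
    """Serialize a model to YAML (subject, variant, muscles; schema v1)."""
    p = model.shape_params
    doc = {
        "schema": "paleogait-model/1",
        "subject": {
            "subject_id": model.subject.subject_id, "sex": model.subject.sex,
            "body_mass": model.subject.body_mass, "stature": model.subject.stature,
            "hip_breadth": model.subject.hip_breadth,
            "femur_length": model.subject.femur_length,
        },
        "shape_params": {
            "variant": p.variant,
            "biacetabular_breadth_ratio": p.biacetabular_breadth_ratio,
            "neck_length_ratio": p.neck_length_ratio,
            "iliac_flare_angle": p.iliac_flare_angle,
            "ap_depth_ratio": p.ap_depth_ratio,
        },
        "muscles": [
            {
                "name": m.name, "group": m.anatomical_group, "side": m.side,
                "origin": [m.origin[0], [float(x) for x in m.origin[1]]],
                "insertion": [m.insertion[0], [float(x) for x in m.insertion[1]]],
                "via_points": [[s, [float(x) for x in v]] for s, v in m.via_points],
                "max_strength": float(m.max_strength),
            }
            for m in model.muscles
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_model_config(path: str | Path) -> SkeletonModel:
    doc = yaml.safe_load(Path(path).read_text())
    if doc.get("schema") != "paleogait-model/1":
        raise ValueError(f"unsupported model schema {doc.get('schema')!r}")
    subject = SubjectAnthropometry(**doc["subject"])
    params = HipShapeParams(**doc["shape_params"])
    model = build_subject_model(params, subject)
    model.muscles = [
        MuscleElement(
            name=m["name"], anatomical_group=m["group"], side=m["side"],
            origin=(m["origin"][0], np.array(m["origin"][1])),
            insertion=(m["insertion"][0], np.array(m["insertion"][1])),
            via_points=[(s, np.array(v)) for s, v in m["via_points"]],
            max_strength=m["max_strength"],
        )
        for m in doc["muscles"]
    ]
    return model


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
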