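"""End-to-end pipeline driver: generate → model → dynamics → recruit → compare.

One :func:`run_pipeline` call executes the whole comparative experiment on a
synthetic cohort: build a cohort, generate walking trials, fit kinematics
and run inverse dynamics ONCE per trial, then resolve muscle recruitment
separately for the modern-human-like and australopithecine-like hip models
— both consuming the identical kinematics and external joint loads, which
is the design's central control — and finally stride-normalize, aggregate,
mirror and compare the curves with permutation SPM.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .core import SubjectAnthropometry, hip_shape_preset
from .dynamics import extract_stride, fit_kinematics, net_joint_loads, residual_loads
from .io import write_table, write_trial
from .model import build_subject_model
from .redundancy import RedundancyConfig, joint_reaction_with_muscles, solve_stride
from .stats import (
    N_NODES, SPMResult, StrideCurves, aggregate_elements, mirror_left_to_right,
    normalize_loads, spm_rm_anova, time_normalize,
)
from .synthetic import generate_cohort, generate_gait_trial

__all__ = ["PipelineConfig", "run_pipeline", "trial_curves", "CONDITIONS"]

log = logging.getLogger("paleogait")

CONDITIONS = ("human_like", "australopith_like")

#: Gluteal groups reported by default, plus hip loads.
REPORTED_GROUPS = ("gluteus_medius", "gluteus_minimus", "gluteus_maximus")


@dataclass(frozen=True)
class PipelineConfig:
    """Desk-scale defaults: 10 subjects x 3 trials x 2 hip variants."""

    n_subjects: int = 10
    trials_per_subject: int = 3
    seed: int = 1
    speed_range: Tuple[float, float] = (1.15, 1.45)  # self-selected speeds, m/s
    noise_std: float = 0.0  # marker noise (m)
    sample_rate: float = 100.0
    filter_cutoff: float = 6.0
    alpha: float = 0.05
    n_permutations: int = 1000
    redundancy: RedundancyConfig = field(default_factory=RedundancyConfig)
    out_dir: Optional[str] = None
    version: str = "1"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "redundancy" in doc:
            doc["redundancy"] = RedundancyConfig(**doc["redundancy"])
        if "speed_range" in doc:
            doc["speed_range"] = tuple(doc["speed_range"])
        return cls(**doc)


def trial_curves(
    models: Dict[str, object],
    trial,
    config: PipelineConfig,
    subject_label: str,
    trial_label: str,
) -> pd.DataFrame:
    """Run one trial through dynamics and both variants' recruitment.

    Returns tidy rows (subject, trial, condition, side, quantity, node,
    value).  Kinematics and external loads are computed once and shared by
    both variant models.
    """
    human = models["human_like"]
    kin = fit_kinematics(trial, human, config.filter_cutoff)
    loads = net_joint_loads(human, kin, trial)
    window, side = extract_stride(trial)
    bw = trial.subject.body_weight
    hip = f"hip_{side}"

    rows = []
    # external (muscle-independent) hip loads, identical for both conditions
    ext_moment = time_normalize(normalize_loads(loads.moment[hip], bw), window)
    for condition in CONDITIONS:
        model = models[condition]
        sol = solve_stride(model, kin, loads, config.redundancy, frames=window)
        grouping = {m.name: m.anatomical_group for m in model.muscles}
        side_cols = [j for j, m in enumerate(model.muscles) if m.side == side]
        act, _force = aggregate_elements(
            sol.activations[:, side_cols], sol.forces[:, side_cols],
            [model.muscles[j].name for j in side_cols], grouping,
            strengths=np.array([model.muscles[j].max_strength for j in side_cols]),
        )
        jrf = joint_reaction_with_muscles(model, kin, sol, loads, hip)
        jrf_n = time_normalize(normalize_loads(jrf, bw))
        for g in REPORTED_GROUPS:
            nodes = time_normalize(act[g])
            for node, v in enumerate(nodes):
                rows.append((subject_label, trial_label, condition, side,
                             f"{g}_activation", node, v))
        for ax_i, ax in enumerate("xyz"):
            for node in range(N_NODES):
                rows.append((subject_label, trial_label, condition, side,
                             f"hip_jrf_force_{ax}", node, jrf_n[node, ax_i]))
                rows.append((subject_label, trial_label, condition, side,
                             f"hip_external_moment_{ax}", node, ext_moment[node, ax_i]))
        if any(st == "infeasible" for st in sol.status):
            log.warning("%s/%s/%s: infeasible frames present",
                        subject_label, trial_label, condition)
    return pd.DataFrame(rows, columns=[
        "subject", "trial", "condition", "side", "quantity", "node", "value"])


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute the full comparative pipeline; returns a run manifest.

    The manifest records the config, seeds, per-stage timing, SPM summaries
    and SHA-256 hashes of all written outputs, so every output is traceable
    to (config, seed).
    """
    t_start = time.time()
    rng = np.random.default_rng(config.seed)
    cohort = generate_cohort(config.n_subjects, config.seed)
    speeds = {s.subject_id: float(rng.uniform(*config.speed_range)) for s in cohort}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    frames: List[pd.DataFrame] = []
    timing: Dict[str, float] = {}
    t0 = time.time()
    written: Dict[str, str] = {}
    for si, subject in enumerate(cohort):
        models = {
            c: build_subject_model(hip_shape_preset(c), subject) for c in CONDITIONS
        }
        for ti in range(config.trials_per_subject):
            trial_seed = int(rng.integers(0, 2**31 - 1))
            side = "right" if ti % 2 == 0 else "left"
            trial = generate_gait_trial(
                subject, speeds[subject.subject_id], trial_seed,
                noise_std=config.noise_std, sample_rate=config.sample_rate,
                side=side, model=models["human_like"],
            )
            if out_dir:
                paths = write_trial(trial, out_dir / "trials", f"{subject.subject_id}_t{ti}")
                written.update({str(p): _sha256(p) for p in paths.values()})
            frames.append(trial_curves(
                models, trial, config, subject.subject_id, f"t{ti}"))
            log.info("subject %s trial %d done", subject.subject_id, ti)
    timing["simulation_s"] = time.time() - t0

    data = pd.concat(frames, ignore_index=True)
    curves = mirror_left_to_right(StrideCurves(data=data, units={
        **{f"{g}_activation": "dimensionless" for g in REPORTED_GROUPS},
        **{f"hip_jrf_force_{ax}": "N/N" for ax in "xyz"},
        **{f"hip_external_moment_{ax}": "N.m/N" for ax in "xyz"},
    }))

    t0 = time.time()
    spm: Dict[str, SPMResult] = {}
    stats_seed = int(rng.integers(0, 2**31 - 1))
    for q in sorted(curves.data["quantity"].unique()):
        spm[q] = spm_rm_anova(curves, q, config.alpha, config.n_permutations,
                              seed=stats_seed)
    timing["spm_s"] = time.time() - t0

    if out_dir:
        write_table(curves.data, out_dir / "curves.csv")
        written[str(out_dir / "curves.csv")] = _sha256(out_dir / "curves.csv")
        spm_doc = {
            q: {
                "critical_threshold": r.critical_threshold,
                "clusters": r.clusters,
                "significant": r.significant,
            } for q, r in spm.items()
        }
        (out_dir / "spm.json").write_text(json.dumps(spm_doc, indent=1))
        written[str(out_dir / "spm.json")] = _sha256(out_dir / "spm.json")

    manifest = {
        "config": _config_dict(config),
        "version": config.version,
        "n_conditions": len(CONDITIONS),
        "n_subjects": config.n_subjects,
        "n_trials": config.n_subjects * config.trials_per_subject,
        "speeds": speeds,
        "timing": timing,
        "total_s": time.time() - t_start,
        "outputs": written,
        "spm": {q: {"significant": r.significant,
                    "critical_threshold": r.critical_threshold,
                    "clusters": r.clusters} for q, r in spm.items()},
    }
    if out_dir:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"manifest": manifest, "curves": curves, "spm": spm, "cohort": cohort}


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["redundancy"] = dataclasses.asdict(config.redundancy)
    return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
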