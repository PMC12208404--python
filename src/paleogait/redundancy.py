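"""Muscle redundancy resolution by a polynomial recruitment criterion.

At every frame the net joint torques from inverse dynamics are apportioned
among the muscle elements by solving

    min  sum_i a_i^p      subject to  B a = tau,  a >= 0,

with activation a_i = F_i / Fmax_i, B the (DOFs x elements) matrix of
tendon-excursion moment arms scaled by element strengths, and exponent p = 3
by default.  For p >= 2 the problem is convex with a unique minimizer on the
feasible set; it is solved here via the dual KKT system (a damped Newton
root-find on the constraint multipliers, with a scipy SLSQP fallback), which
is deterministic and accurate to tight tolerances.

Activations may exceed 1 — an overloaded frame is flagged, not hidden — and
infeasible frames fall back to the best least-squares feasible point with a
warning, so a run never silently aborts mid-stride.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize, nnls

from .core import GaitTrial
from .dynamics import JointLoads, KinematicsTrajectory, generalized_net_torques
from .model import RECRUITED_DOFS, Posture, SkeletonModel, forward_kinematics, moment_arm_matrix

__all__ = [
    "RedundancyConfig",
    "RedundancySolution",
    "solve_frame",
    "solve_stride",
    "joint_reaction_with_muscles",
]


@dataclass(frozen=True)
class RedundancyConfig:
    """Settings for the recruitment solver."""

    exponent: float = 3.0
    bound_policy: str = "allow_overload_with_flag"  # or "cap_at_1"
    tolerance: float = 1e-9
    dofs: Tuple[str, ...] = RECRUITED_DOFS

    def __post_init__(self) -> None:
        if self.exponent < 2:
            raise ValueError("exponent must be >= 2")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.bound_policy not in ("allow_overload_with_flag", "cap_at_1"):
            raise ValueError(f"unknown bound policy {self.bound_policy!r}")


@dataclass
class RedundancySolution:
    """Frame-wise activations, forces and constraint residuals for a stride."""

    activations: np.ndarray  # (n_frames, n_elements)
    forces: np.ndarray  # (n_frames, n_elements), a_i * Fmax_i
    residuals: np.ndarray  # (n_frames,), ||B a - tau|| per frame
    status: List[str]  # per frame: "ok", "overloaded", "infeasible"
    element_names: List[str]
    dofs: Tuple[str, ...]
    frames: slice

    def max_residual(self) -> float:
        return float(self.residuals.max()) if len(self.residuals) else 0.0


def _dual_solve(
    B: np.ndarray, tau: np.ndarray, p: float, tol: float,
    lam0: Optional[np.ndarray] = None,
) -> Tuple[Optional[np.ndarray], Optional[np.ndarray]]:
    """Damped-Newton solve of the dual KKT system.

    Stationarity gives a_i = (max(0, (B^T lam)_i) / p)^(1/(p-1)); we root-find
    g(lam) = B a(lam) - tau = 0.  The Jacobian B diag(a') B^T is PSD; a small
    ridge plus backtracking keeps steps well-defined at the a_i = 0 kinks.
    Rows are equilibrated so strong and weak DOFs converge together.
    ``lam0`` warm-starts from a neighbouring frame.  Returns (a, lam) or
    (None, None) on failure.
    """
    D, n = B.shape
    row = np.linalg.norm(B, axis=1)
    row = np.where(row > 0, row, 1.0)
    Bs = B / row[:, None]
    ts = tau / row
    scale = max(np.abs(ts).max(), 1.0)

    def activations(l: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        s = Bs.T @ l
        pos = s > 0
        a = np.zeros(n)
        a[pos] = (s[pos] / p) ** (1.0 / (p - 1.0))
        da = np.zeros(n)
        da[pos] = a[pos] / ((p - 1.0) * s[pos])
        return a, da

    lam = (lam0 * row if lam0 is not None
           else np.linalg.lstsq(Bs @ Bs.T + 1e-9 * np.eye(D), ts, rcond=None)[0])
    a, da = activations(lam)
    g = Bs @ a - ts
    for _ in range(300):
        nrm = np.linalg.norm(g)
        if nrm < tol * scale:
            return a, lam / row
        J = (Bs * da) @ Bs.T
        ridge = 1e-12 * max(np.trace(J) / D, 1.0)
        try:
            step = np.linalg.solve(J + ridge * np.eye(D), -g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -g, rcond=None)[0]
        # backtracking line search on ||g||
        alpha = 1.0
        for _ls in range(30):
            a_new, da_new = activations(lam + alpha * step)
            g_new = Bs @ a_new - ts
            if np.linalg.norm(g_new) < nrm * (1.0 - 1e-4 * alpha):
                break
            alpha *= 0.5
        else:
            return None, None
        lam = lam + alpha * step
        a, da, g = a_new, da_new, g_new
    if np.linalg.norm(g) < tol * scale * 10:
        return a, lam / row
    return None, None


def solve_frame(
    moment_arms: np.ndarray,
    strengths: np.ndarray,
    net_moments: np.ndarray,
    config: Optional[RedundancyConfig] = None,
    warm_start: Optional[np.ndarray] = None,
    return_multipliers: bool = False,
):
    """Resolve one frame's net moments into non-negative activations.

    ``moment_arms`` is (DOFs, elements) in metres, ``strengths`` the element
    max forces (N), ``net_moments`` the generalized torques (N·m).  Returns
    ``(activations, status)`` with status "ok", "overloaded" (some a_i > 1
    under the allow-overload policy) or "infeasible" (least-squares fallback).
    """
    config = config or RedundancyConfig()
    R = np.asarray(moment_arms, dtype=float)
    s = np.asarray(strengths, dtype=float)
    tau = np.asarray(net_moments, dtype=float)
    if not np.all(np.isfinite(R)):
        raise ValueError("moment arms must be finite")
    B = R * s[None, :]

    def ret(a, status, lam=None):
        return (a, status, lam) if return_multipliers else (a, status)

    if np.allclose(tau, 0.0):
        return ret(np.zeros(B.shape[1]), "ok")

    p = config.exponent
    a = lam = None
    if config.bound_policy == "allow_overload_with_flag":
        a, lam = _dual_solve(B, tau, p, config.tolerance, warm_start)
        if a is None and warm_start is not None:
            a, lam = _dual_solve(B, tau, p, config.tolerance)  # cold restart
    if a is None:
        bounds = [(0.0, 1.0 if config.bound_policy == "cap_at_1" else None)] * B.shape[1]
        a0 = np.maximum(nnls(B, tau)[0], 0.0)
        res = minimize(
            lambda x: np.sum(x**p), a0, jac=lambda x: p * x ** (p - 1),
            constraints=[{"type": "eq", "fun": lambda x: B @ x - tau, "jac": lambda x: B}],
            bounds=bounds, method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        a = np.maximum(res.x, 0.0)

    resid = np.linalg.norm(B @ a - tau)
    scale = max(np.abs(tau).max(), 1.0)
    if resid > 1e-6 * scale:
        a_ls, _ = nnls(B, tau)
        warnings.warn(
            f"infeasible recruitment frame (residual {resid:.3g}); "
            "using least-squares feasible point", stacklevel=2,
        )
        return ret(a_ls, "infeasible")
    if config.bound_policy == "allow_overload_with_flag" and np.any(a > 1.0):
        return ret(a, "overloaded", lam)
    return ret(a, "ok", lam)


def solve_stride(
    model: SkeletonModel,
    kin: KinematicsTrajectory,
    loads: JointLoads,
    config: Optional[RedundancyConfig] = None,
    frames: Optional[slice] = None,
) -> RedundancySolution:
    """Frame-wise recruitment over a stride window.

    All included DOFs (bilateral hip ball, knee and ankle flexion by default)
    are solved simultaneously, so biarticular elements couple the joints the
    way the mechanics dictate.
    """
    config = config or RedundancyConfig()
    frames = frames or slice(0, kin.n_frames)
    idx = range(*frames.indices(kin.n_frames))
    tau_all = generalized_net_torques(model, kin, loads, config.dofs)
    strengths = np.array([m.max_strength for m in model.muscles])
    n_frames = len(idx)
    acts = np.zeros((n_frames, len(model.muscles)))
    residuals = np.zeros(n_frames)
    status: List[str] = []
    lam = None
    for row, f in enumerate(idx):
        R = moment_arm_matrix(model, kin.posture(f), config.dofs)
        a, st, lam = solve_frame(R, strengths, tau_all[f], config,
                                 warm_start=lam, return_multipliers=True)
        acts[row] = a
        residuals[row] = np.linalg.norm((R * strengths[None, :]) @ a - tau_all[f])
        status.append(st)
    return RedundancySolution(
        activations=acts, forces=acts * strengths[None, :],
        residuals=residuals, status=status,
        element_names=[m.name for m in model.muscles],
        dofs=tuple(config.dofs), frames=frames,
    )


# ---------------------------------------------------------------------------
# Muscle-inclusive joint reaction forces


_SUBTREE = {
    "hip_left": ("thigh_left", "shank_left", "talus_left", "foot_left"),
    "hip_right": ("thigh_right", "shank_right", "talus_right", "foot_right"),
    "knee_left": ("shank_left", "talus_left", "foot_left"),
    "knee_right": ("shank_right", "talus_right", "foot_right"),
}


def joint_reaction_with_muscles(
    model: SkeletonModel,
    kin: KinematicsTrajectory,
    solution: RedundancySolution,
    loads: JointLoads,
    joint: str = "hip_left",
) -> np.ndarray:
    """Bone-on-bone joint force including muscle pulls, in lab axes.

    Reported as the force the distal bone exerts on the proximal one (the
    femoral head on the acetabulum for a hip), the same convention as the
    intersegmental force in :class:`~paleogait.dynamics.JointLoads` — with no
    active muscle the two are identical.  Each muscle crossing the joint adds
    the pull it exerts across it: the force acts on the distal subtree at its
    first attachment inside the subtree, directed toward the neighbouring
    path point outside it.
    """
    if joint not in _SUBTREE:
        raise ValueError(f"unsupported joint {joint!r}")
    subtree = set(_SUBTREE[joint])
    idx = range(*solution.frames.indices(kin.n_frames))
    out = np.zeros((len(idx), 3))

    # precompute, per crossing muscle, the path-point pair straddling the joint
    crossing: List[Tuple[int, Tuple[str, np.ndarray], Tuple[str, np.ndarray]]] = []
    for j, m in enumerate(model.muscles):
        path = m.path()
        inside = [pt[0] in subtree for pt in path]
        if all(inside) or not any(inside):
            continue
        k = inside.index(True)
        outside_pt = path[k - 1] if k > 0 else path[inside.index(False)]
        crossing.append((j, path[k], outside_pt))

    for row, f in enumerate(idx):
        poses = forward_kinematics(model, kin.posture(f))
        pull = np.zeros(3)
        for j, (seg_a, loc_a), (seg_b, loc_b) in crossing:
            Ra, pa = poses[seg_a]
            Rb, pb = poses[seg_b]
            u = (pb + Rb @ loc_b) - (pa + Ra @ loc_a)
            nrm = np.linalg.norm(u)
            if nrm > 1e-12:
                pull += (solution.forces[row, j] / nrm) * u
        # bone-on-bone force on the proximal segment: the intersegmental
        # force plus the reaction to the muscle pull on the subtree
        out[row] = loads.force[joint][f] + pull
    return out
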