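"""Stride-normalized curve handling and 1D permutation SPM statistics.

Curves (activations, joint loads, moments) are resampled onto 101 stride
nodes (0-100%), aggregated from muscle elements to anatomical muscles,
normalized by body weight, and mirrored so left-foot trials can be compared
with right-foot ones.  Condition effects along the stride are tested with a
repeated-measures ANOVA at every node and family-wise error across the curve
is controlled non-parametrically: the critical threshold is the (1 - alpha)
quantile of the permutation distribution of the field maximum, permuting
condition labels of whole trial blocks within subject.  For the two-level
condition factor this RM-ANOVA F-field is exactly the squared paired t-field
on per-subject condition means, and within-subject label flips are sign
flips of the paired differences — which is how the permutations are done.

Suprathreshold clusters get p-values from the permutation distribution of
the maximal suprathreshold cluster extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "StrideCurves",
    "SPMResult",
    "N_NODES",
    "time_normalize",
    "aggregate_elements",
    "normalize_loads",
    "mirror_left_to_right",
    "spm_rm_anova",
]

N_NODES = 101

#: Sign flips that map a left-side gait record onto a pseudo-right one:
#: reflection through the sagittal plane flips mediolateral (Y) forces and,
#: for axial (pseudo-)vectors, the moments about the X and Z axes.
MIRROR_SIGN = {"force": {"x": 1.0, "y": -1.0, "z": 1.0},
               "moment": {"x": -1.0, "y": 1.0, "z": -1.0}}


@dataclass
class StrideCurves:
    """Tidy container of stride-normalized curves.

    ``data`` columns: subject, trial, condition, side, quantity, node, value.
    ``units`` maps each quantity name to its unit string.
    """

    data: pd.DataFrame
    units: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"subject", "trial", "condition", "side", "quantity", "node", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"StrideCurves missing columns {sorted(missing)}")
        nodes = self.data["node"].unique()
        if len(nodes) and (nodes.min() < 0 or nodes.max() >= N_NODES):
            raise ValueError("nodes must lie in [0, 101)")
        bad = set(self.data["condition"].unique()) - {"human_like", "australopith_like"}
        if bad:
            raise ValueError(f"unknown condition labels {sorted(bad)}")

    def quantity(self, name: str) -> pd.DataFrame:
        return self.data[self.data["quantity"] == name]

    def curve_matrix(self, quantity: str, condition: str) -> pd.DataFrame:
        """(subject, trial) x node wide matrix for one quantity/condition."""
        sub = self.data[
            (self.data["quantity"] == quantity) & (self.data["condition"] == condition)
        ]
        return sub.pivot_table(index=["subject", "trial"], columns="node", values="value")


@dataclass
class SPMResult:
    """Pointwise F-field with its permutation threshold and clusters."""

    f_field: np.ndarray  # (N_NODES,)
    critical_threshold: float
    clusters: List[Dict[str, float]]  # {"start", "end", "extent", "p"}
    alpha: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        for c in self.clusters:
            if not 0.0 < c["p"] <= 1.0:
                raise ValueError("cluster p-values must lie in (0, 1]")
            if np.any(self.f_field[int(c["start"]):int(c["end"]) + 1] < self.critical_threshold):
                raise ValueError("clusters must be suprathreshold")

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0


def time_normalize(
    series: np.ndarray, stride_window: Optional[slice] = None, n_nodes: int = N_NODES
) -> np.ndarray:
    """Linearly resample a frame series onto equally spaced stride nodes.

    ``series`` may be (n_frames,) or (n_frames, k); the window endpoints map
    to 0% and 100% exactly.  Resampling an already length-``n_nodes`` series
    with a full window is the identity.
    """
    x = np.asarray(series, dtype=float)
    if stride_window is not None:
        x = x[stride_window]
    if x.shape[0] < 2:
        raise ValueError("stride window must span at least 2 frames")
    src = np.linspace(0.0, 1.0, x.shape[0])
    dst = np.linspace(0.0, 1.0, n_nodes)
    if x.ndim == 1:
        return np.interp(dst, src, x)
    return np.column_stack([np.interp(dst, src, x[:, j]) for j in range(x.shape[1])])


def aggregate_elements(
    activations: np.ndarray,
    forces: np.ndarray,
    element_names: Sequence[str],
    grouping: Mapping[str, str],
    strengths: Optional[np.ndarray] = None,
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Combine muscle elements into anatomical muscles.

    Group force is the plain sum of element forces; group activation is the
    strength-weighted mean of element activations (so it lies between 0 and
    the largest element activation in the group, and a group of equal
    activations aggregates to that value).  ``grouping`` must cover every
    element name.
    """
    unmapped = [n for n in element_names if n not in grouping]
    if unmapped:
        raise KeyError(f"elements not covered by the grouping: {unmapped[:5]}")
    activations = np.atleast_2d(np.asarray(activations, dtype=float))
    forces = np.atleast_2d(np.asarray(forces, dtype=float))
    if strengths is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            strengths = np.where(
                activations.max(axis=0) > 0,
                forces.max(axis=0) / np.maximum(activations.max(axis=0), 1e-30),
                1.0,
            )
    groups: Dict[str, List[int]] = {}
    for j, n in enumerate(element_names):
        groups.setdefault(grouping[n], []).append(j)
    act_out, force_out = {}, {}
    for g, cols in groups.items():
        w = np.asarray(strengths)[cols]
        act_out[g] = activations[:, cols] @ w / w.sum()
        force_out[g] = forces[:, cols].sum(axis=1)
    return act_out, force_out


def normalize_loads(curves: np.ndarray, body_weight: float) -> np.ndarray:
    """Divide load curves by body weight: forces to N/N, moments to N·m/N."""
    if body_weight <= 0:
        raise ValueError("body weight must be positive")
    return np.asarray(curves, dtype=float) / body_weight


def mirror_left_to_right(curves: StrideCurves) -> StrideCurves:
    """Convert left-side trials to pseudo-right ones by sign flips.

    Mediolateral (Y) forces change sign; for moments the X and Z components
    flip instead (reflection rules for axial vectors).  Quantities whose
    names end in ``_force_y``, ``_moment_x`` or ``_moment_z`` are flipped on
    left-side rows only; everything else is untouched.  Applied twice, the
    operation is the identity.
    """
    df = curves.data.copy()
    if df["side"].isna().any():
        raise ValueError("every row needs a side label for mirroring")
    left = df["side"] == "left"

    def flip_factor(q: str) -> float:
        for kind, signs in MIRROR_SIGN.items():
            for axis, s in signs.items():
                if q.endswith(f"{kind}_{axis}"):
                    return s
        return 1.0

    factors = df["quantity"].map(flip_factor)
    df.loc[left, "value"] = df.loc[left, "value"] * factors[left]
    df.loc[left, "side"] = "pseudo_right"
    return StrideCurves(data=df, units=dict(curves.units))


def _rm_anova_f(d: np.ndarray) -> np.ndarray:
    """Node-wise RM-ANOVA F for a two-level factor from paired differences.

    ``d`` is (subjects, nodes) of per-subject condition-mean differences;
    F(1, n-1) = t^2 of the paired t-statistic.
    """
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    sd = np.maximum(sd, 1e-300)
    t = mean / (sd / np.sqrt(n))
    return t**2


def spm_rm_anova(
    curves: StrideCurves,
    quantity: str,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> SPMResult:
    """Permutation RM-ANOVA over the stride for the hip-variant factor.

    Requires a balanced design (equal trial counts per subject and
    condition); unbalanced input raises with instructions to subset.  The
    F-field tests the condition effect with subjects as the blocking factor;
    the critical threshold controls family-wise error across the 101 nodes
    via the permutation distribution of the field maximum.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    a = curves.curve_matrix(quantity, "human_like")
    b = curves.curve_matrix(quantity, "australopith_like")
    counts_a = a.groupby("subject").size()
    counts_b = b.groupby("subject").size()
    if (
        set(counts_a.index) != set(counts_b.index)
        or counts_a.nunique() != 1
        or counts_b.nunique() != 1
        or counts_a.iloc[0] != counts_b.iloc[0]
    ):
        raise ValueError(
            "SPM RM-ANOVA requires a balanced design (equal trials per "
            "subject per condition); subset the trials to equal counts first"
        )
    subjects = sorted(counts_a.index)
    mean_a = a.groupby("subject").mean().loc[subjects].to_numpy()
    mean_b = b.groupby("subject").mean().loc[subjects].to_numpy()
    d = mean_b - mean_a  # (subjects, nodes)
    n_sub = len(subjects)
    f_obs = _rm_anova_f(d)

    rng = np.random.default_rng(seed)
    if 2**n_sub <= 2 * n_permutations:
        # the within-subject flip group is small enough to enumerate: the
        # permutation test becomes exact (and conservative) at level alpha
        codes = np.arange(2**n_sub)
        signs = 1.0 - 2.0 * ((codes[:, None] >> np.arange(n_sub)[None, :]) & 1)
        exact = True
    else:
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_sub))
        exact = False
    n_perm_used = signs.shape[0]
    # vectorized sign-flip permutation t^2 fields
    dm = signs @ d / n_sub  # (perms, nodes) permuted means
    d2 = d**2
    ssq = d2.sum(axis=0)[None, :]
    var = (ssq - n_sub * dm**2) / (n_sub - 1)
    var = np.maximum(var, 1e-300)
    f_perm = n_sub * dm**2 / var  # (perms, nodes)
    max_f = f_perm.max(axis=1)
    threshold = float(np.quantile(max_f, 1.0 - alpha, method="higher"))

    def clusters_of(f: np.ndarray) -> List[Tuple[int, int]]:
        # a strictly positive F guards the degenerate identical-condition
        # case, where the permutation threshold collapses to zero
        above = (f >= threshold) & (f > 1e-12)
        out = []
        start = None
        for i, flag in enumerate(above):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                out.append((start, i - 1))
                start = None
        if start is not None:
            out.append((start, len(f) - 1))
        return out

    obs_clusters = clusters_of(f_obs)
    max_extent = np.array([
        max((e - s + 1 for s, e in clusters_of(f)), default=0) for f in f_perm
    ])
    clusters = []
    for s, e in obs_clusters:
        extent = e - s + 1
        if exact:
            p = float(np.mean(max_extent >= extent))
        else:
            p = float((1 + np.sum(max_extent >= extent)) / (n_perm_used + 1))
        clusters.append({"start": float(s), "end": float(e), "extent": float(extent), "p": p})
    return SPMResult(
        f_field=f_obs, critical_threshold=threshold, clusters=clusters,
        alpha=alpha, n_permutations=n_perm_used, seed=seed,
    )
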