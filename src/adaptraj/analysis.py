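"""Post-processing of trajectories: fluxes, fold changes, dispersion, PCA ellipses.

These routines turn ensembles of parameter trajectories into the quantities
one actually interprets: how reaction fluxes redistribute along the
transition, how consistently each parameter adapts across repetitions and
ensemble members, and which qualitative scenarios (clusters of endpoint fold
changes) the data still admits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .model import ModelDefinition, compute_fluxes
from .trajectory import ParameterTrajectory, TrajectoryBundle

__all__ = [
    "FluxTrajectory",
    "Ellipse",
    "ScenarioCluster",
    "flux_trajectories",
    "fold_change",
    "pca_ellipse",
    "classify_scenarios",
    "dispersion_summary",
    "consistency_scores",
]


@dataclass
class FluxTrajectory:
    """One reaction's (or flux observable's) values along a trajectory."""

    id: str
    q: np.ndarray
    values: np.ndarray
    units: str = "mM/h"
    member_index: int = -1
    repetition: int = 0
    direction: str = "forward"
    undefined: bool = False  # set when fold normalization hits a zero baseline


def flux_trajectories(
    model: ModelDefinition, trajectory: ParameterTrajectory
) -> list[FluxTrajectory]:
    """Evaluate every reaction flux at each stored trajectory point."""
    q = trajectory.q_grid
    n_r = len(model.reactions)
    vals = np.empty((len(trajectory.points), n_r))
    for i, p in enumerate(trajectory.points):
        vals[i] = compute_fluxes(model, p.state, p.theta, p.inputs)
    out = []
    for j, rid in enumerate(model.reaction_ids):
        out.append(
            FluxTrajectory(
                id=rid,
                q=q.copy(),
                values=vals[:, j].copy(),
                member_index=trajectory.member_index,
                repetition=trajectory.repetition,
                direction=trajectory.direction,
            )
        )
    return out


def fold_change(traj: FluxTrajectory) -> FluxTrajectory:
    """Normalize a trajectory by its own q = 0 (wild-type) value."""
    order = np.argsort(traj.q)
    baseline_idx = order[0] if traj.q[order[0]] == 0.0 else int(np.argmin(traj.q))
    baseline = traj.values[baseline_idx]
    if baseline == 0.0 or not np.isfinite(baseline):
        return FluxTrajectory(
            id=traj.id, q=traj.q.copy(), values=np.full_like(traj.values, np.nan),
            units="fold", member_index=traj.member_index,
            repetition=traj.repetition, direction=traj.direction, undefined=True,
        )
    return FluxTrajectory(
        id=traj.id, q=traj.q.copy(), values=traj.values / baseline, units="fold",
        member_index=traj.member_index, repetition=traj.repetition,
        direction=traj.direction,
    )


@dataclass
class Ellipse:
    """A chi-square coverage ellipse from PCA of a 2-D point cloud."""

    center: np.ndarray
    semi_axes: np.ndarray  # lengths along the principal directions
    rotation: float  # radians, angle of the major axis
    axes_directions: np.ndarray  # 2x2, columns = principal directions
    coverage_nominal: float
    coverage_empirical: float
    degenerate: bool = False

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points) - self.center
        proj = pts @ self.axes_directions
        with np.errstate(divide="ignore", invalid="ignore"):
            d2 = np.sum((proj / self.semi_axes) ** 2, axis=1)
        return d2 <= 1.0 + 1e-12


def pca_ellipse(points, coverage: float = 0.95) -> Ellipse:
    """PCA coverage ellipse: center at the mean, axes along the principal
    directions, semi-axis lengths sqrt(eigenvalue * chi2.ppf(coverage, 2)).

    Collinear clouds yield a degenerate (zero-minor-axis) ellipse with a
    flag rather than an error.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 two-dimensional points")
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must lie in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    quant = chi2.ppf(coverage, df=2)
    semi = np.sqrt(evals * quant)
    degenerate = bool(semi[1] <= 1e-12 * max(semi[0], 1.0))
    rotation = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    ell = Ellipse(
        center=center,
        semi_axes=semi,
        rotation=rotation,
        axes_directions=evecs,
        coverage_nominal=coverage,
        coverage_empirical=np.nan,
        degenerate=degenerate,
    )
    if not degenerate:
        ell.coverage_empirical = float(np.mean(ell.contains(pts)))
    else:
        ell.coverage_empirical = 0.0
    return ell


@dataclass
class ScenarioCluster:
    """Members grouped by the direction of a pivot observable's fold change."""

    label: str
    member_ids: list[int]
    ellipses: dict[tuple[str, str], Ellipse] = field(default_factory=dict)


def classify_scenarios(
    endpoint_folds: pd.DataFrame,
    pivot: str,
    threshold: float = 1.0,
    pairs: Sequence[tuple[str, str]] = (),
    coverage: float = 0.95,
) -> list[ScenarioCluster]:
    """Split endpoint fold changes into increased/decreased scenarios.

    ``endpoint_folds`` is indexed by member id with one column per observable
    (values are endpoint/wild-type folds).  A pivot exactly at the threshold
    is assigned to the "decreased" cluster.  For each requested observable
    pair a PCA coverage ellipse is attached per cluster with >= 3 points.
    """
    if pivot not in endpoint_folds.columns:
        raise ValueError(f"pivot observable {pivot!r} not in fold table")
    increased = endpoint_folds[endpoint_folds[pivot] > threshold]
    decreased = endpoint_folds[endpoint_folds[pivot] <= threshold]
    clusters = []
    for label, sub in (("increased", increased), ("decreased", decreased)):
        cluster = ScenarioCluster(label=label, member_ids=list(sub.index))
        for a, b in pairs:
            pts = sub[[a, b]].to_numpy(float)
            pts = pts[np.all(np.isfinite(pts), axis=1)]
            if len(pts) >= 3:
                cluster.ellipses[(a, b)] = pca_ellipse(pts, coverage)
        clusters.append(cluster)
    return clusters


def dispersion_summary(
    bundle: TrajectoryBundle | Iterable[ParameterTrajectory],
    parameter_ids: Sequence[str] | None = None,
    quantiles: tuple[float, float] = (0.05, 0.95),
) -> pd.DataFrame:
    """Per-parameter, per-q quantiles of log10 parameter values.

    Distributions over ensemble members are heavy-tailed in linear space, so
    spread is summarized by quantiles of log10 values across all passes in
    the bundle (forward and backward alike, aligned on q).
    """
    trajectories = list(bundle)
    if not trajectories:
        raise ValueError("empty bundle")
    n_par = trajectories[0].theta_matrix.shape[1]
    if parameter_ids is None:
        parameter_ids = [f"p{j}" for j in range(n_par)]
    records: dict[tuple[float, int], list[np.ndarray]] = {}
    for traj in trajectories:
        for p in traj.points:
            key = round(float(p.q), 12)
            records.setdefault(key, []).append(np.log10(p.theta))
    rows = []
    lo_q, hi_q = quantiles
    for q_val in sorted(records):
        arr = np.array(records[q_val])
        med = np.median(arr, axis=0)
        lo = np.quantile(arr, lo_q, axis=0)
        hi = np.quantile(arr, hi_q, axis=0)
        for j, pid in enumerate(parameter_ids):
            rows.append(
                {
                    "parameter": pid,
                    "q": q_val,
                    "median_log10": med[j],
                    "q_lo_log10": lo[j],
                    "q_hi_log10": hi[j],
                    "width_log10": hi[j] - lo[j],
                }
            )
    return pd.DataFrame(rows)


def consistency_scores(summary: pd.DataFrame) -> pd.Series:
    """Per-parameter consistency score: max inter-quantile width over q.

    Small scores mean the parameter's path is reproduced consistently;
    large scores flag poorly constrained (or structurally non-identifiable)
    parameters.
    """
    return summary.groupby("parameter")["width_log10"].max()
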