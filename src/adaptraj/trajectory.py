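"""Parameter-adaptation trajectories between two phenotypes.

The data of phenotype A is interpolated toward phenotype B over a coordinate
q in [0, 1] (artificial intermediate phenotypes), and at each step the
parameters are re-optimized against the interpolated data under a penalty on
relative parameter change from the pass's starting set:

    X(theta_q) = X_d(theta_q) + lambda * X_r(theta_q)
    X_r = sum_j ((theta_j - theta_ref_j) / theta_ref_j)^2

The final state and parameters of each step warm-start the next.  Backward
passes (B -> A) reuse the machinery with the reference set swapped to the
pass's own starting set; they probe the consistency of a trajectory, not a
physiological reversal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .estimation import (
    DataRealization,
    Dataset,
    EnsembleMember,
    EstimationConfig,
    acceptance_test,
    derive_seed,
    realize_dataset,
    weighted_sse,
)
from .model import (
    ConfigurationError,
    ModelDefinition,
    compute_outputs,
    parameter_values,
    steady_state,
)

__all__ = [
    "InterpolationScheme",
    "get_scheme",
    "interpolate_data",
    "regularized_cost",
    "TrajectoryPoint",
    "ParameterTrajectory",
    "TrajectoryBundle",
    "TrajectoryConfig",
    "forward_trajectory",
    "backward_trajectory",
    "consistency_cycles",
    "lambda_sweep",
    "DEFAULT_LAMBDA",
    "DEFAULT_STEPS",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA = 0.1
DEFAULT_STEPS = 100
DEFAULT_REPETITIONS = 100
#: log-spaced sweep grid spanning 1e-4 ... 1e3
DEFAULT_LAMBDA_GRID = tuple(float(x) for x in np.logspace(-4, 3, 8))


@dataclass(frozen=True)
class InterpolationScheme:
    """Monotone weight w(q): [0,1] -> [0,1] with exact endpoints."""

    name: str
    w: Callable[[float], float]

    def __call__(self, q: float) -> float:
        return self.w(q)


_SCHEMES = {
    "linear": InterpolationScheme("linear", lambda q: q),
    "quadratic_like": InterpolationScheme("quadratic_like", lambda q: q * q),
    "inverse_quadratic_like": InterpolationScheme(
        "inverse_quadratic_like", lambda q: 1.0 - (1.0 - q) ** 2
    ),
}


def get_scheme(scheme) -> InterpolationScheme:
    if isinstance(scheme, InterpolationScheme):
        return scheme
    try:
        return _SCHEMES[scheme]
    except KeyError:
        raise ConfigurationError(
            f"unknown interpolation scheme {scheme!r}; choose from {sorted(_SCHEMES)}"
        )


def interpolate_data(
    realA: DataRealization,
    realB: DataRealization,
    q: float,
    scheme="linear",
) -> DataRealization:
    """Interpolated target d^q, sigma^q (and inputs) at coordinate q.

    d^q = (1 - w(q)) d^A + w(q) d^B, and the standard deviations and model
    inputs are interpolated with the same weight.
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must lie in [0, 1]")
    if realA.observable_ids != realB.observable_ids:
        raise ConfigurationError("realizations have mismatched observables")
    w = float(get_scheme(scheme)(q))
    values = (1.0 - w) * realA.values + w * realB.values
    sigmas = (1.0 - w) * realA.sigmas + w * realB.sigmas
    keys = set(realA.inputs) | set(realB.inputs)
    inputs = {
        k: (1.0 - w) * realA.inputs.get(k, 0.0) + w * realB.inputs.get(k, 0.0)
        for k in keys
    }
    return DataRealization(
        phenotype=f"q={q:.6g}",
        observable_ids=realA.observable_ids,
        values=values,
        sigmas=sigmas,
        inputs=inputs,
        seed=realA.seed,
    )


def regularized_cost(outputs, data_q: DataRealization, theta, theta_ref, lam: float):
    """(X, X_d, X_r) of the regularized objective."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    t = parameter_values(theta)
    t_ref = parameter_values(theta_ref)
    x_d = weighted_sse(outputs, data_q)
    rel = (t - t_ref) / t_ref
    x_r = float(np.dot(rel, rel))
    return x_d + lam * x_r, x_d, x_r


@dataclass
class TrajectoryPoint:
    q: float
    theta: np.ndarray
    state: np.ndarray
    outputs: np.ndarray
    X_d: float
    X_r: float
    inputs: dict = field(default_factory=dict)


@dataclass
class TrajectoryConfig:
    """Per-step optimizer settings for trajectory passes."""

    lo: float = 1e-6
    hi: float = 1e6
    max_nfev: int = 200  # per-step budget; warm starts keep steps cheap
    ss_atol: float = 1e-9
    ss_method: str = "linear"


@dataclass
class ParameterTrajectory:
    """An ordered pass over the q-grid with per-point diagnostics."""

    direction: str  # "forward" or "backward"
    points: list[TrajectoryPoint]
    lam: float
    scheme_name: str
    seeds: dict[str, int]
    theta_ref: np.ndarray
    observable_ids: tuple[str, ...]
    completed: bool = True
    member_index: int = -1
    repetition: int = 0

    @property
    def q_grid(self) -> np.ndarray:
        return np.array([p.q for p in self.points])

    @property
    def theta_matrix(self) -> np.ndarray:
        return np.array([p.theta for p in self.points])

    @property
    def start(self) -> TrajectoryPoint:
        return self.points[0]

    @property
    def end(self) -> TrajectoryPoint:
        return self.points[-1]

    def output_at(self, q: float, observable_id: str) -> float:
        i = int(np.argmin(np.abs(self.q_grid - q)))
        return float(self.points[i].outputs[self.observable_ids.index(observable_id)])

    def path_length(self) -> float:
        """Total squared relative parameter movement along the pass."""
        th = self.theta_matrix
        steps = (th[1:] - th[:-1]) / th[:-1]
        return float(np.sum(steps * steps))

    def to_dataframe(self, parameter_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Long format (q, parameter, value, direction, repetition)."""
        rows = []
        for p in self.points:
            for j, val in enumerate(p.theta):
                pid = parameter_ids[j] if parameter_ids else f"p{j}"
                rows.append(
                    {
                        "q": p.q,
                        "parameter": pid,
                        "value": val,
                        "direction": self.direction,
                        "repetition": self.repetition,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class TrajectoryBundle:
    """A collection of forward/backward passes sharing one q-grid."""

    trajectories: list[ParameterTrajectory]
    steps: int
    member_index: int = -1

    def __iter__(self):
        return iter(self.trajectories)

    def __len__(self):
        return len(self.trajectories)


def _step_optimize(model, theta_start, data_q, theta_ref, lam, config):
    """One regularized re-optimization; returns (theta, X_d, X_r, ok)."""
    idx = [model._obs_index[o] for o in data_q.observable_ids]
    n_obs = len(idx)
    lo_log, hi_log = math.log10(config.lo), math.log10(config.hi)
    sqrt_lam = math.sqrt(lam)

    def residuals(log_theta):
        theta = 10.0 ** log_theta
        ss = steady_state(model, theta, data_q.inputs, atol=config.ss_atol, method=config.ss_method)
        if not ss.converged:
            r_data = np.full(n_obs, 1e6)
        else:
            try:
                y = compute_outputs(model, ss.state, theta, data_q.inputs)[idx]
                r_data = (y - data_q.values) / data_q.sigmas
                r_data = np.where(np.isfinite(r_data), r_data, 1e6)
            except Exception:
                r_data = np.full(n_obs, 1e6)
        if lam == 0.0:
            return r_data
        r_reg = sqrt_lam * (theta / theta_ref - 1.0)
        return np.concatenate([r_data, r_reg])

    x0 = np.clip(np.log10(theta_start), lo_log, hi_log)
    try:
        sol = least_squares(
            residuals,
            x0,
            bounds=(lo_log, hi_log),
            method="trf",
            max_nfev=config.max_nfev,
            x_scale="jac",
        )
        x_hat, ok = sol.x, bool(sol.status > 0)
    except Exception:
        x_hat, ok = x0, False
    theta = 10.0 ** x_hat
    ss = steady_state(model, theta, data_q.inputs, atol=config.ss_atol, method=config.ss_method)
    if not ss.converged:
        return theta, None, None, None, False
    y = compute_outputs(model, ss.state, theta, data_q.inputs)[idx]
    _, x_d, x_r = regularized_cost(y, data_q, theta, theta_ref, lam)
    return theta, ss.state, (x_d, x_r, y), idx, ok


def _evaluate_point(model, theta, data_q, theta_ref, lam, config):
    idx = [model._obs_index[o] for o in data_q.observable_ids]
    ss = steady_state(model, theta, data_q.inputs, atol=config.ss_atol, method=config.ss_method)
    y = compute_outputs(model, ss.state, theta, data_q.inputs)[idx]
    _, x_d, x_r = regularized_cost(y, data_q, theta, theta_ref, lam)
    return ss.state, y, x_d, x_r


def _run_pass(
    model,
    theta_start,
    realA,
    realB,
    q_values,
    lam,
    scheme,
    config,
    direction,
    seeds,
    member_index=-1,
    repetition=0,
) -> ParameterTrajectory:
    """Shared engine for forward and backward passes.

    q_values is the full ordered grid including the recorded (not
    re-optimized) starting coordinate; theta_ref is theta_start throughout.
    """
    theta_ref = np.array(theta_start, float)
    scheme = get_scheme(scheme)
    points: list[TrajectoryPoint] = []
    completed = True

    data0 = interpolate_data(realA, realB, q_values[0], scheme)
    state0, y0, xd0, xr0 = _evaluate_point(model, theta_ref, data0, theta_ref, lam, config)
    points.append(
        TrajectoryPoint(
            q_values[0], theta_ref.copy(), state0, y0, xd0, xr0, dict(data0.inputs)
        )
    )

    theta = theta_ref.copy()
    for q in q_values[1:]:
        data_q = interpolate_data(realA, realB, q, scheme)
        theta_new, state, payload, idx, ok = _step_optimize(
            model, theta, data_q, theta_ref, lam, config
        )
        if payload is None:
            completed = False
            break
        x_d, x_r, y = payload
        theta = theta_new
        points.append(
            TrajectoryPoint(float(q), theta.copy(), state, y, x_d, x_r, dict(data_q.inputs))
        )
    return ParameterTrajectory(
        direction=direction,
        points=points,
        lam=lam,
        scheme_name=scheme.name,
        seeds=dict(seeds),
        theta_ref=theta_ref,
        observable_ids=realA.observable_ids,
        completed=completed,
        member_index=member_index,
        repetition=repetition,
    )


def _member_theta(member) -> np.ndarray:
    if isinstance(member, EnsembleMember):
        return np.array(member.theta, float)
    return parameter_values(member)


def forward_trajectory(
    model: ModelDefinition,
    member,
    dataset: Dataset,
    steps: int = DEFAULT_STEPS,
    lam: float = DEFAULT_LAMBDA,
    scheme="linear",
    seed: int = 0,
    config: TrajectoryConfig | None = None,
    phenotypes: tuple[str, str] = ("A", "B"),
) -> ParameterTrajectory:
    """A -> B pass: q = 0, 1/steps, ..., 1 with theta_ref fixed at the start set.

    One realization each of the phenotype-A and phenotype-B data is drawn for
    the whole trajectory and interpolated deterministically between steps.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    config = config or TrajectoryConfig()
    theta0 = _member_theta(member)
    seed_a, seed_b = derive_seed(seed, 0), derive_seed(seed, 1)
    realA = realize_dataset(dataset, phenotypes[0], seed_a)
    realB = realize_dataset(dataset, phenotypes[1], seed_b)
    q_values = [i / steps for i in range(steps + 1)]
    mi = member.index if isinstance(member, EnsembleMember) else -1
    return _run_pass(
        model, theta0, realA, realB, q_values, lam, scheme, config,
        direction="forward",
        seeds={"trajectory": int(seed), "realization_A": seed_a, "realization_B": seed_b},
        member_index=mi,
    )


def backward_trajectory(
    model: ModelDefinition,
    forward: ParameterTrajectory,
    dataset: Dataset,
    lam: float | None = None,
    seed: int = 0,
    config: TrajectoryConfig | None = None,
    phenotypes: tuple[str, str] = ("A", "B"),
) -> ParameterTrajectory:
    """B -> A pass starting from the forward pass's endpoint.

    The reference set for the regularization penalty is swapped to the
    backward pass's own starting parameters (the set representing
    phenotype B); fresh data realizations are drawn for the pass.
    """
    if not forward.completed or forward.end.q != 1.0:
        raise ConfigurationError("forward trajectory did not reach q = 1")
    config = config or TrajectoryConfig()
    lam = forward.lam if lam is None else lam
    steps = len(forward.points) - 1
    seed_a, seed_b = derive_seed(seed, 2), derive_seed(seed, 3)
    realA = realize_dataset(dataset, phenotypes[0], seed_a)
    realB = realize_dataset(dataset, phenotypes[1], seed_b)
    q_values = [(steps - i) / steps for i in range(steps + 1)]  # exact grid match
    return _run_pass(
        model, forward.end.theta, realA, realB, q_values, lam,
        forward.scheme_name, config,
        direction="backward",
        seeds={"trajectory": int(seed), "realization_A": seed_a, "realization_B": seed_b},
        member_index=forward.member_index,
        repetition=forward.repetition,
    )


def consistency_cycles(
    model: ModelDefinition,
    member,
    dataset: Dataset,
    repetitions: int = 10,
    steps: int = DEFAULT_STEPS,
    lam: float = DEFAULT_LAMBDA,
    scheme="linear",
    seed: int = 0,
    config: TrajectoryConfig | None = None,
    chain: bool = False,
) -> TrajectoryBundle:
    """Repeated forward+backward cycles with fresh realizations per repetition.

    With ``chain=True`` each cycle starts from the previous cycle's final
    parameters and state instead of restarting from the member.
    """
    trajectories: list[ParameterTrajectory] = []
    theta_start = _member_theta(member)
    for rep in range(repetitions):
        fwd = forward_trajectory(
            model,
            theta_start if chain else _member_theta(member),
            dataset,
            steps=steps,
            lam=lam,
            scheme=scheme,
            seed=derive_seed(seed, 10, rep),
            config=config,
        )
        fwd.repetition = rep
        bwd = backward_trajectory(
            model, fwd, dataset, lam=lam, seed=derive_seed(seed, 11, rep), config=config
        )
        bwd.repetition = rep
        trajectories.extend([fwd, bwd])
        if chain:
            theta_start = bwd.end.theta
    mi = member.index if isinstance(member, EnsembleMember) else -1
    return TrajectoryBundle(trajectories=trajectories, steps=steps, member_index=mi)


def lambda_sweep(
    model: ModelDefinition,
    members: Iterable,
    dataset: Dataset,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    steps: int = DEFAULT_STEPS,
    seed: int = 0,
    scheme="linear",
    config: TrajectoryConfig | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Endpoint X_d / X_r and acceptance for a grid of regularization strengths.

    For comparability, the same trajectory seed (hence the same data
    realizations) is reused across the lambda grid for a given member.
    """
    grid = list(lambda_grid)
    if not grid or any(l < 0 for l in grid):
        raise ValueError("lambda grid must be nonempty and nonnegative")
    members = list(members)
    rows = []
    for mi, member in enumerate(members):
        traj_seed = derive_seed(seed, 20, mi)
        for lam in grid:
            traj = forward_trajectory(
                model, member, dataset, steps=steps, lam=lam, scheme=scheme,
                seed=traj_seed, config=config,
            )
            end = traj.end
            if traj.completed:
                rep = acceptance_test(
                    end.outputs, dataset, "B", alpha,
                    observable_ids=list(traj.observable_ids),
                )
                accepted = rep.accepted
            else:
                accepted = False
            rows.append(
                {
                    "lambda": lam,
                    "member": mi,
                    "X_d_end": end.X_d,
                    "X_r_end": end.X_r,
                    "path_length": traj.path_length(),
                    "accepted": accepted,
                    "completed": traj.completed,
                }
            )
    return pd.DataFrame(rows)
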