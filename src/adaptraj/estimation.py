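"""Ensemble parameter estimation for one phenotype.

The protocol: sample parameter sets log-uniformly over twelve orders of
magnitude, score each by the weighted sum of squared errors of its
steady-state outputs against a Monte-Carlo realization of the data, optimize
the best-scoring sets with weighted nonlinear least squares in log-parameter
space, and keep those whose outputs fall inside Bonferroni-adjusted
confidence intervals of the data means and whose fluxes stay physiological.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import norm

from .model import (
    ConfigurationError,
    ModelDefinition,
    compute_fluxes,
    compute_outputs,
    parameter_values,
    steady_state,
)

__all__ = [
    "Dataset",
    "DataRealization",
    "EnsembleMember",
    "EstimationConfig",
    "AcceptanceReport",
    "sample_parameters",
    "realize_dataset",
    "weighted_sse",
    "fit_parameters",
    "acceptance_test",
    "flux_feasibility",
    "run_multistart",
    "PAPER_SCALE",
    "TEST_SCALE",
]

#: (n_samples, n_top) at full protocol scale and at desk/test scale.
PAPER_SCALE = (100_000_000, 10_000)
TEST_SCALE = (2_000, 20)

_REQUIRED_COLUMNS = ("observable", "phenotype", "mean", "sd", "units")


@dataclass
class Dataset:
    """Two-phenotype observable measurements plus model input values.

    ``table`` has columns observable, phenotype, mean, sd, units; each
    (observable, phenotype) pair appears at most once and every sd is
    strictly positive.  ``inputs`` maps phenotype label to a mapping of model
    input values (e.g. plasma FFA).
    """

    table: pd.DataFrame
    inputs: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ConfigurationError(f"dataset missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        dup = self.table.duplicated(subset=["observable", "phenotype"])
        if dup.any():
            rows = self.table.loc[dup, ["observable", "phenotype"]]
            raise ConfigurationError(
                f"duplicated (observable, phenotype) rows: {rows.values.tolist()}"
            )
        bad = self.table["sd"] <= 0
        if bad.any():
            raise ConfigurationError(
                f"non-positive sd at rows {list(self.table.index[bad])}"
            )

    def phenotypes(self) -> list[str]:
        return sorted(self.table["phenotype"].unique())

    def observables(self, phenotype: str) -> list[str]:
        sub = self.table[self.table["phenotype"] == phenotype]
        return list(sub["observable"])

    def arrays(self, phenotype: str, observable_ids: Sequence[str] | None = None):
        """(ids, means, sds) for one phenotype, in stable table order."""
        sub = self.table[self.table["phenotype"] == phenotype]
        if sub.empty:
            raise ConfigurationError(f"phenotype {phenotype!r} not in dataset")
        if observable_ids is None:
            observable_ids = list(sub["observable"])
        sub = sub.set_index("observable")
        missing = [o for o in observable_ids if o not in sub.index]
        if missing:
            raise ConfigurationError(f"observables missing for {phenotype}: {missing}")
        mu = sub.loc[list(observable_ids), "mean"].to_numpy(float)
        sd = sub.loc[list(observable_ids), "sd"].to_numpy(float)
        return list(observable_ids), mu, sd

    def inputs_for(self, phenotype: str) -> dict[str, float]:
        return dict(self.inputs.get(phenotype, {}))

    def mask(self, observable_ids: Iterable[str]) -> "Dataset":
        """Return a copy without the listed observables (all phenotypes)."""
        drop = set(observable_ids)
        tab = self.table[~self.table["observable"].isin(drop)].reset_index(drop=True)
        return Dataset(tab, {k: dict(v) for k, v in self.inputs.items()})

    def validate_against(self, model: ModelDefinition) -> list[str]:
        """Names of dataset observables unknown to the model."""
        known = set(model.observable_ids)
        return sorted(set(self.table["observable"]) - known)


@dataclass
class DataRealization:
    """One Gaussian draw of a phenotype's data; self-contained fit target.

    Carries the drawn values together with the dataset standard deviations
    (weights always come from the dataset, never from the draw) and the
    phenotype's model inputs.
    """

    phenotype: str
    observable_ids: tuple[str, ...]
    values: np.ndarray
    sigmas: np.ndarray
    inputs: dict[str, float]
    seed: int


def sample_parameters(
    n: int,
    n_params: int,
    lo: float = 1e-6,
    hi: float = 1e6,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Draw ``n`` parameter sets, each coordinate log10-uniform on [lo, hi]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    rng = np.random.default_rng(seed)
    logs = rng.uniform(math.log10(lo), math.log10(hi), size=(n, n_params))
    return 10.0 ** logs


def realize_dataset(
    dataset: Dataset, phenotype: str, seed: int, exact: bool = False
) -> DataRealization:
    """Independent Gaussian draw per observable; raw draws kept untruncated.

    ``exact=True`` gives the sigma -> 0 limit (the draws are the means),
    useful for noiseless fixtures and debugging.
    """
    ids, mu, sd = dataset.arrays(phenotype)
    rng = np.random.default_rng(seed)
    draws = mu.copy() if exact else rng.normal(mu, sd)
    return DataRealization(
        phenotype=phenotype,
        observable_ids=tuple(ids),
        values=draws,
        sigmas=sd,
        inputs=dataset.inputs_for(phenotype),
        seed=int(seed),
    )


def weighted_sse(outputs: np.ndarray, realization: DataRealization) -> float:
    """X_d = sum(((y - d) / sigma)^2); NaN outputs give +inf."""
    y = np.asarray(outputs, float)
    if y.shape != realization.values.shape:
        raise ConfigurationError("outputs misaligned with realization")
    if np.any(~np.isfinite(y)):
        return float("inf")
    r = (y - realization.values) / realization.sigmas
    return float(np.dot(r, r))


@dataclass
class AcceptanceReport:
    accepted: bool
    z_crit: float
    table: pd.DataFrame  # observable, y, mu, sd, z, within


def acceptance_test(
    outputs: np.ndarray,
    dataset: Dataset,
    phenotype: str,
    alpha: float = 0.05,
    observable_ids: Sequence[str] | None = None,
) -> AcceptanceReport:
    """Bonferroni-adjusted interval check of outputs against data means.

    Accept iff |y_i - mu_i| <= z_{1 - alpha'/2} * sigma_i for all i with
    alpha' = alpha / N, N the number of compared outputs.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    ids, mu, sd = dataset.arrays(phenotype, observable_ids)
    y = np.asarray(outputs, float)
    if y.shape != mu.shape:
        raise ConfigurationError("outputs misaligned with dataset observables")
    n = len(ids)
    z_crit = float(norm.ppf(1.0 - (alpha / n) / 2.0))
    with np.errstate(invalid="ignore"):
        z = np.abs(y - mu) / sd
    within = np.isfinite(y) & (z <= z_crit)
    table = pd.DataFrame(
        {"observable": ids, "y": y, "mean": mu, "sd": sd, "z": z, "within": within}
    )
    return AcceptanceReport(bool(within.all()), z_crit, table)


def flux_feasibility(fluxes: np.ndarray, bound: float = 100.0) -> bool:
    """True iff every flux <= bound (mM/h); equality passes."""
    if bound <= 0:
        raise ValueError("bound must be positive")
    f = np.asarray(fluxes, float)
    return bool(np.all(np.isfinite(f)) and np.all(f <= bound))


@dataclass
class EstimationConfig:
    """Protocol constants for ensemble estimation."""

    lo: float = 1e-6
    hi: float = 1e6
    alpha: float = 0.05
    flux_bound: float = 100.0
    max_nfev: int = 500
    ss_atol: float = 1e-9
    ss_method: str = "linear"  # exact for this model class; "auto" adds integration fallback

    @property
    def log_bounds(self):
        return math.log10(self.lo), math.log10(self.hi)


@dataclass
class EnsembleMember:
    """An optimized parameter set with diagnostics and screening flags."""

    theta: np.ndarray
    cost: float
    accepted: bool
    flux_feasible: bool
    converged: bool
    state: np.ndarray
    outputs: np.ndarray
    observable_ids: tuple[str, ...]
    realization_seed: int
    index: int = -1

    def output(self, observable_id: str) -> float:
        return float(self.outputs[self.observable_ids.index(observable_id)])


def _screen_cost(model, theta, realization, config) -> float:
    ss = steady_state(model, theta, realization.inputs, atol=config.ss_atol, method=config.ss_method)
    if not ss.converged:
        return float("inf")
    try:
        y_full = compute_outputs(model, ss.state, theta, realization.inputs)
    except Exception:
        return float("inf")
    idx = [model._obs_index[o] for o in realization.observable_ids]
    return weighted_sse(y_full[idx], realization)


def _residual_builder(model, realization, config):
    idx = [model._obs_index[o] for o in realization.observable_ids]
    n_obs = len(idx)

    def residuals(log_theta):
        theta = 10.0 ** log_theta
        ss = steady_state(model, theta, realization.inputs, atol=config.ss_atol, method=config.ss_method)
        if not ss.converged:
            return np.full(n_obs, 1e6)
        try:
            y = compute_outputs(model, ss.state, theta, realization.inputs)[idx]
        except Exception:
            return np.full(n_obs, 1e6)
        r = (y - realization.values) / realization.sigmas
        return np.where(np.isfinite(r), r, 1e6)

    return residuals


def fit_parameters(
    model: ModelDefinition,
    realization: DataRealization,
    theta_init,
    dataset: Dataset | None = None,
    config: EstimationConfig | None = None,
    index: int = -1,
) -> EnsembleMember:
    """Weighted nonlinear least squares in log10-parameter space.

    Positivity is enforced by optimizing log10(theta) inside the sampling box.
    A steady-state failure during the search penalizes the candidate instead
    of aborting.  The returned cost never exceeds the starting cost.
    """
    config = config or EstimationConfig()
    theta0 = parameter_values(theta_init)
    lo_log, hi_log = config.log_bounds
    x0 = np.clip(np.log10(theta0), lo_log, hi_log)
    residuals = _residual_builder(model, realization, config)

    r0 = residuals(x0)
    cost0 = float(np.dot(r0, r0))
    try:
        sol = least_squares(
            residuals,
            x0,
            bounds=(lo_log, hi_log),
            method="trf",
            max_nfev=config.max_nfev,
            x_scale="jac",
        )
        x_hat, cost_hat = sol.x, 2.0 * sol.cost
        opt_converged = bool(sol.status > 0)
    except Exception:
        x_hat, cost_hat, opt_converged = x0, cost0, False
    if cost_hat > cost0:  # keep the no-worse point
        x_hat, cost_hat = x0, cost0
    theta_hat = 10.0 ** x_hat

    ss = steady_state(model, theta_hat, realization.inputs, atol=config.ss_atol, method=config.ss_method)
    if ss.converged:
        fluxes = compute_fluxes(model, ss.state, theta_hat, realization.inputs)
        y_full = compute_outputs(model, ss.state, theta_hat, realization.inputs)
        idx = [model._obs_index[o] for o in realization.observable_ids]
        y = y_full[idx]
        feasible = flux_feasibility(fluxes, config.flux_bound)
        if dataset is not None:
            rep = acceptance_test(
                y, dataset, realization.phenotype, config.alpha,
                observable_ids=list(realization.observable_ids),
            )
            accepted = rep.accepted and feasible
        else:
            accepted = False
    else:
        y = np.full(len(realization.observable_ids), np.nan)
        feasible = False
        accepted = False
    return EnsembleMember(
        theta=theta_hat,
        cost=float(cost_hat),
        accepted=accepted,
        flux_feasible=feasible,
        converged=bool(ss.converged and opt_converged),
        state=ss.state,
        outputs=y,
        observable_ids=tuple(realization.observable_ids),
        realization_seed=realization.seed,
        index=index,
    )


@dataclass
class Ensemble:
    """Multistart result: members sorted by final cost ascending."""

    members: list[EnsembleMember]
    seed: int
    n_samples: int
    n_top: int

    def __iter__(self):
        return iter(self.members)

    def __len__(self):
        return len(self.members)

    @property
    def accepted(self) -> list[EnsembleMember]:
        return [m for m in self.members if m.accepted]

    def best(self, accepted_only: bool = True) -> EnsembleMember:
        pool = self.accepted if accepted_only and self.accepted else self.members
        return pool[0]

    def theta_matrix(self, accepted_only: bool = True) -> np.ndarray:
        pool = self.accepted if accepted_only else self.members
        return np.array([m.theta for m in pool])


def derive_seed(global_seed: int, *indices: int) -> int:
    """Deterministic per-task seed below 2**31 from a global seed."""
    ss = np.random.SeedSequence(entropy=int(global_seed), spawn_key=tuple(int(i) for i in indices))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_multistart(
    model: ModelDefinition,
    dataset: Dataset,
    phenotype: str = "A",
    n_samples: int = TEST_SCALE[0],
    n_top: int = TEST_SCALE[1],
    seed: int = 0,
    config: EstimationConfig | None = None,
) -> Ensemble:
    """Sample, screen, optimize, and flag an ensemble for one phenotype.

    Each candidate is scored (and later optimized) against its own
    Monte-Carlo realization of the data; the realization seed is derived from
    (global seed, candidate index) so runs are reproducible.  Screening ties
    in the top-``n_top`` selection are broken by candidate index.
    """
    if n_top > n_samples:
        raise ValueError("n_top must not exceed n_samples")
    config = config or EstimationConfig()
    thetas = sample_parameters(
        n_samples, model.n_parameters, config.lo, config.hi,
        seed=np.random.SeedSequence(entropy=int(seed), spawn_key=(0,)),
    )
    realizations = [
        realize_dataset(dataset, phenotype, derive_seed(seed, 1, i))
        for i in range(n_samples)
    ]
    scores = np.array(
        [_screen_cost(model, thetas[i], realizations[i], config) for i in range(n_samples)]
    )
    order = np.argsort(scores, kind="stable")  # stable sort = index tie-break
    top = order[:n_top]
    members = []
    for i in top:
        m = fit_parameters(
            model, realizations[i], thetas[i], dataset=dataset, config=config, index=int(i)
        )
        members.append(m)
    members.sort(key=lambda m: (m.cost, m.index))
    if not any(m.accepted for m in members):
        import warnings

        warnings.warn("multistart produced no accepted members", stacklevel=2)
    return Ensemble(members=members, seed=int(seed), n_samples=n_samples, n_top=n_top)
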