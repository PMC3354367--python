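"""Mass-action ODE models: definition, simulation, fluxes, outputs, steady states.

A model is a network of molecular species connected by mass-action reactions.
Each reaction carries at most one *modifier* (a state or a constant input);
its flux is ``rate_constant * modifier`` (or just ``rate_constant`` for a
zeroth-order source).  The state dynamics are ``dx/dt = S v(x, theta, u)``
where ``S`` is the stoichiometric matrix assembled from the reaction list.

Because every flux is linear in at most one state, the resulting ODE system
is linear time-invariant for constant inputs, which the steady-state solver
exploits as a fast path; a generic long-integration + root-refinement path is
kept as the reference method.

Units: concentrations in mM, fluxes in mM/h, first-order rate constants in
1/h, zeroth-order constants in mM/h.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "ModelError",
    "ConfigurationError",
    "DomainError",
    "SimulationError",
    "Reaction",
    "ObservableSpec",
    "ParameterSet",
    "ModelDefinition",
    "SteadyStateResult",
    "compute_fluxes",
    "time_course",
    "steady_state",
    "compute_outputs",
    "register_derived_formula",
    "DERIVED_FORMULAS",
]


class ModelError(Exception):
    """Base class for model-layer errors."""


class ConfigurationError(ModelError):
    """A model, parameter, or input specification is inconsistent."""


class DomainError(ModelError):
    """A numerical argument is outside its physical domain."""


class SimulationError(ModelError):
    """Integration failed; carries the last time reached in ``t_last``."""

    def __init__(self, message: str, t_last: float | None = None):
        super().__init__(message)
        self.t_last = t_last


@dataclass(frozen=True)
class Reaction:
    """A single mass-action reaction.

    flux = theta[rate_constant] * value(modifier), with value 1 when the
    reaction is a zeroth-order source (``modifier is None``).  The
    stoichiometry maps state ids to signed integer coefficients; it may be
    empty for reactions that carry no mass (bookkeeping rates used only in
    derived observables).
    """

    id: str
    rate_constant: str
    modifier: str | None = None
    stoichiometry: Mapping[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class ObservableSpec:
    """A model output.

    kind:
        ``state_sum``   weighted sum of state concentrations
        ``flux``        weighted sum of reaction fluxes
        ``flux_ratio``  ratio of two reaction fluxes (exactly two terms)
        ``derived``     dispatched to a registered formula by
                        ``derived_formula_id``; terms list the referenced
                        reactions in the order the formula expects
    terms: sequence of (coefficient, referenced identifier).
    """

    id: str
    kind: str
    terms: tuple[tuple[float, str], ...] = ()
    derived_formula_id: str | None = None


@dataclass
class ParameterSet:
    """Strictly positive, finite parameter values aligned to parameter_ids."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ConfigurationError("parameter values must be a 1-D vector")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ConfigurationError("parameters must be finite and strictly positive")

    def __len__(self):  # pragma: no cover - trivial
        return len(self.values)


def parameter_values(params) -> np.ndarray:
    """Coerce a ParameterSet / mapping-free array-like to a float vector."""
    if isinstance(params, ParameterSet):
        return params.values
    return np.asarray(params, dtype=float)


_OBSERVABLE_KINDS = ("state_sum", "flux", "flux_ratio", "derived")

#: registry of derived-observable formulas.  Signature:
#: fn(model, fluxes, params, inputs, terms) -> float
DERIVED_FORMULAS: dict[str, Callable] = {}


def register_derived_formula(name: str, fn: Callable) -> None:
    DERIVED_FORMULAS[name] = fn


@dataclass
class ModelDefinition:
    """A mass-action reaction network with observables.

    All identifier lists are ordered and define the alignment of state,
    parameter, flux, and output vectors throughout the package.
    """

    state_ids: list[str]
    parameter_ids: list[str]
    input_ids: list[str]
    reactions: list[Reaction]
    observables: list[ObservableSpec]
    default_initial_state: np.ndarray | None = None
    constants: dict[str, float] = field(default_factory=dict)
    name: str = "model"

    def __post_init__(self):
        self.state_ids = list(self.state_ids)
        self.parameter_ids = list(self.parameter_ids)
        self.input_ids = list(self.input_ids)
        if self.default_initial_state is None:
            self.default_initial_state = np.ones(len(self.state_ids))
        self.default_initial_state = np.asarray(self.default_initial_state, float)
        self._validate()
        self._compile()

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        for label, ids in (
            ("state", self.state_ids),
            ("parameter", self.parameter_ids),
            ("input", self.input_ids),
            ("reaction", [r.id for r in self.reactions]),
            ("observable", [o.id for o in self.observables]),
        ):
            if len(set(ids)) != len(ids):
                raise ConfigurationError(f"duplicate {label} identifiers")
        states = set(self.state_ids)
        inputs = set(self.input_ids)
        params = set(self.parameter_ids)
        rxn_ids = {r.id for r in self.reactions}
        for r in self.reactions:
            if r.rate_constant not in params:
                raise ConfigurationError(
                    f"reaction {r.id}: unknown rate constant {r.rate_constant}"
                )
            if r.modifier is not None and r.modifier not in states | inputs:
                raise ConfigurationError(
                    f"reaction {r.id}: modifier {r.modifier} is not a state or input"
                )
            for sid in r.stoichiometry:
                if sid not in states:
                    raise ConfigurationError(
                        f"reaction {r.id}: stoichiometry references unknown state {sid}"
                    )
        for obs in self.observables:
            if obs.kind not in _OBSERVABLE_KINDS:
                raise ConfigurationError(f"observable {obs.id}: unknown kind {obs.kind}")
            refs = states | rxn_ids | inputs
            for _, ref in obs.terms:
                if ref not in refs:
                    raise ConfigurationError(
                        f"observable {obs.id}: unknown reference {ref}"
                    )
            if obs.kind == "flux_ratio" and len(obs.terms) != 2:
                raise ConfigurationError(
                    f"observable {obs.id}: flux_ratio needs exactly two reaction terms"
                )
            if obs.kind == "derived" and obs.derived_formula_id is None:
                raise ConfigurationError(
                    f"observable {obs.id}: derived observable without formula id"
                )
        if len(self.default_initial_state) != len(self.state_ids):
            raise ConfigurationError("default_initial_state misaligned with states")
        if np.any(self.default_initial_state < 0):
            raise ConfigurationError("default_initial_state must be nonnegative")

    # -- compiled arrays -------------------------------------------------
    def _compile(self) -> None:
        ns, nr = len(self.state_ids), len(self.reactions)
        sidx = {s: i for i, s in enumerate(self.state_ids)}
        pidx = {p: i for i, p in enumerate(self.parameter_ids)}
        uidx = {u: i for i, u in enumerate(self.input_ids)}
        S = np.zeros((ns, nr))
        rate_idx = np.zeros(nr, dtype=np.intp)
        mod_kind = np.zeros(nr, dtype=np.intp)  # 0 none, 1 state, 2 input
        mod_idx = np.zeros(nr, dtype=np.intp)
        for j, r in enumerate(self.reactions):
            rate_idx[j] = pidx[r.rate_constant]
            if r.modifier is None:
                mod_kind[j] = 0
            elif r.modifier in sidx:
                mod_kind[j], mod_idx[j] = 1, sidx[r.modifier]
            else:
                mod_kind[j], mod_idx[j] = 2, uidx[r.modifier]
            for sid, coeff in r.stoichiometry.items():
                S[sidx[sid], j] += coeff
        self._S = S
        self._rate_idx = rate_idx
        self._mod_kind = mod_kind
        self._mod_idx = mod_idx
        self._state_index = sidx
        self._param_index = pidx
        self._input_index = uidx
        self._reaction_index = {r.id: j for j, r in enumerate(self.reactions)}
        self._obs_index = {o.id: j for j, o in enumerate(self.observables)}

    # -- convenience -----------------------------------------------------
    @property
    def stoichiometric_matrix(self) -> np.ndarray:
        return self._S

    @property
    def n_states(self) -> int:
        return len(self.state_ids)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_ids)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def observable_ids(self) -> list[str]:
        return [o.id for o in self.observables]

    def parameter_index(self, pid: str) -> int:
        return self._param_index[pid]

    def reaction_index(self, rid: str) -> int:
        return self._reaction_index[rid]

    def parameter_dict(self, params) -> dict[str, float]:
        vals = parameter_values(params)
        return dict(zip(self.parameter_ids, vals.tolist()))

    def parameters_from_dict(self, mapping: Mapping[str, float]) -> np.ndarray:
        try:
            return np.array([float(mapping[p]) for p in self.parameter_ids])
        except KeyError as exc:  # pragma: no cover - defensive
            raise ConfigurationError(f"missing parameter value for {exc.args[0]}")

    def input_vector(self, inputs: Mapping[str, float]) -> np.ndarray:
        missing = [u for u in self.input_ids if u not in inputs]
        if missing:
            raise ConfigurationError(f"missing input values: {missing}")
        return np.array([float(inputs[u]) for u in self.input_ids])

    # -- linear form -----------------------------------------------------
    def linear_system(self, params, inputs: Mapping[str, float]):
        """Return (A, b) with dx/dt = A x + b for constant inputs.

        Valid for every model expressible in this class (each flux is linear
        in at most one state).
        """
        theta = parameter_values(params)
        u = self.input_vector(inputs)
        ns = self.n_states
        A = np.zeros((ns, ns))
        b = np.zeros(ns)
        k = theta[self._rate_idx]
        for j in range(len(self.reactions)):
            col = self._S[:, j]
            if self._mod_kind[j] == 1:
                A[:, self._mod_idx[j]] += col * k[j]
            elif self._mod_kind[j] == 2:
                b += col * k[j] * u[self._mod_idx[j]]
            else:
                b += col * k[j]
        return A, b

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "name": self.name,
            "states": self.state_ids,
            "parameters": self.parameter_ids,
            "inputs": self.input_ids,
            "reactions": [
                {
                    "id": r.id,
                    "rate_constant": r.rate_constant,
                    "modifier": r.modifier,
                    "stoichiometry": dict(r.stoichiometry),
                }
                for r in self.reactions
            ],
            "observables": [
                {
                    "id": o.id,
                    "kind": o.kind,
                    "terms": [[c, ref] for c, ref in o.terms],
                    "derived_formula_id": o.derived_formula_id,
                }
                for o in self.observables
            ],
            "default_initial_state": self.default_initial_state.tolist(),
            "constants": self.constants,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelDefinition":
        doc = json.loads(text)
        return cls(
            state_ids=doc["states"],
            parameter_ids=doc["parameters"],
            input_ids=doc["inputs"],
            reactions=[
                Reaction(
                    id=r["id"],
                    rate_constant=r["rate_constant"],
                    modifier=r.get("modifier"),
                    stoichiometry={k: int(v) for k, v in r["stoichiometry"].items()},
                )
                for r in doc["reactions"]
            ],
            observables=[
                ObservableSpec(
                    id=o["id"],
                    kind=o["kind"],
                    terms=tuple((float(c), ref) for c, ref in o["terms"]),
                    derived_formula_id=o.get("derived_formula_id"),
                )
                for o in doc["observables"]
            ],
            default_initial_state=np.asarray(doc["default_initial_state"], float),
            constants=dict(doc.get("constants", {})),
            name=doc.get("name", "model"),
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_fluxes(model: ModelDefinition, state, params, inputs) -> np.ndarray:
    """Per-reaction mass-action fluxes (mM/h), aligned to model.reactions."""
    x = np.asarray(state, float)
    if x.shape != (model.n_states,):
        raise ConfigurationError("state vector misaligned with model states")
    if np.any(x < -1e-12):
        raise DomainError("negative state concentration")
    theta = parameter_values(params)
    u = model.input_vector(inputs)
    mod = np.ones(len(model.reactions))
    is_state = model._mod_kind == 1
    is_input = model._mod_kind == 2
    mod[is_state] = x[model._mod_idx[is_state]]
    mod[is_input] = u[model._mod_idx[is_input]]
    return theta[model._rate_idx] * mod


def time_course(
    model: ModelDefinition,
    params,
    inputs,
    x0,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> np.ndarray:
    """Integrate dx/dt = S v(x) over t_grid; rows are states at each time."""
    t = np.asarray(t_grid, float)
    if t.ndim != 1 or len(t) < 1 or np.any(np.diff(t) <= 0):
        raise ConfigurationError("t_grid must be strictly increasing")
    x0 = np.asarray(x0, float)
    if np.any(x0 < 0):
        raise DomainError("initial state must be nonnegative")
    theta = parameter_values(params)
    u = model.input_vector(inputs)
    uid_map = dict(zip(model.input_ids, u))
    S = model.stoichiometric_matrix

    def rhs(_t, x):
        v = _fluxes_unchecked(model, x, theta, u)
        return S @ v

    sol = solve_ivp(
        rhs, (t[0], t[-1]), x0, t_eval=t, method=method, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise SimulationError(
            f"integration failed: {sol.message}",
            t_last=float(sol.t[-1]) if len(sol.t) else float(t[0]),
        )
    return sol.y.T


def _fluxes_unchecked(model, x, theta, u):
    mod = np.ones(len(model.reactions))
    is_state = model._mod_kind == 1
    is_input = model._mod_kind == 2
    mod[is_state] = x[model._mod_idx[is_state]]
    mod[is_input] = u[model._mod_idx[is_input]]
    return theta[model._rate_idx] * mod


@dataclass
class SteadyStateResult:
    """Steady state with diagnostics; ``converged`` is a flag, not a throw."""

    state: np.ndarray
    residual: float
    converged: bool
    method: str

    def __iter__(self):  # allow tuple-ish unpacking in quick scripts
        return iter((self.state, self.residual, self.converged))


def steady_state(
    model: ModelDefinition,
    params,
    inputs,
    x0=None,
    atol: float = 1e-9,
    method: str = "auto",
    horizon: float = 1e6,
) -> SteadyStateResult:
    """Solve S v(x*) = 0.

    method "auto" first tries the direct linear solve (exact for this model
    class); if that yields a non-finite or negative state it falls back to
    long integration with horizon doubling followed by root refinement
    ("integrate").  Non-convergence is reported through the ``converged``
    flag so ensemble screening can discard the parameter set.
    """
    theta = parameter_values(params)
    u_map = {k: float(v) for k, v in dict(inputs).items()}
    if x0 is None:
        x0 = model.default_initial_state
    x0 = np.asarray(x0, float)

    if method in ("auto", "linear"):
        res = _steady_state_linear(model, theta, u_map, atol)
        if res.converged or method == "linear":
            return res
    return _steady_state_integrate(model, theta, u_map, x0, atol, horizon)


def _residual_norm(model, x, theta, u_map) -> float:
    u = model.input_vector(u_map)
    v = _fluxes_unchecked(model, x, theta, u)
    return float(np.max(np.abs(model.stoichiometric_matrix @ v)))


def _steady_state_linear(model, theta, u_map, atol) -> SteadyStateResult:
    A, b = model.linear_system(theta, u_map)
    try:
        x = np.linalg.solve(A, -b)
    except np.linalg.LinAlgError:
        return SteadyStateResult(np.full(model.n_states, np.nan), np.inf, False, "linear")
    # negative entries beyond the solve's backward-error scale mean no
    # physical steady state; tiny negatives are round-off and are clipped
    scale_x = float(np.max(np.abs(x))) if x.size else 1.0
    if not np.all(np.isfinite(x)) or np.any(x < -1e-9 * max(scale_x, 1.0)):
        return SteadyStateResult(x, np.inf, False, "linear")
    x = np.clip(x, 0.0, None)
    r = _residual_norm(model, x, theta, u_map)
    # absolute tolerance, relaxed by the attainable float64 backward error
    flux_scale = float(np.max(np.abs(A) @ np.abs(x) + np.abs(b))) if x.size else 1.0
    tol = max(atol, 1e-10 * flux_scale)
    return SteadyStateResult(x, r, r <= tol, "linear")


def _steady_state_integrate(model, theta, u_map, x0, atol, horizon) -> SteadyStateResult:
    u = model.input_vector(u_map)
    S = model.stoichiometric_matrix

    def rhs(_t, x):
        return S @ _fluxes_unchecked(model, x, theta, u)

    x = np.asarray(x0, float)
    t_end = 100.0
    while True:
        sol = solve_ivp(rhs, (0.0, t_end), x, method="LSODA", rtol=1e-8, atol=1e-10)
        if not sol.success:
            return SteadyStateResult(x, np.inf, False, "integrate")
        x = sol.y[:, -1]
        r = _residual_norm(model, np.clip(x, 0, None), theta, u_map)
        if r <= atol or t_end >= horizon:
            break
        t_end *= 2.0

    # root refinement
    def fun(z):
        return rhs(0.0, z)

    try:
        refined = root(fun, x, method="hybr", tol=1e-12)
        xr = refined.x
        if np.all(np.isfinite(xr)) and np.all(xr >= -1e-9):
            rr = _residual_norm(model, np.clip(xr, 0, None), theta, u_map)
            if rr < r:
                x, r = xr, rr
    except Exception:  # refinement is best-effort
        pass
    x = np.clip(x, 0.0, None)
    return SteadyStateResult(x, r, r <= atol, "integrate")


def compute_outputs(model: ModelDefinition, state, params, inputs) -> np.ndarray:
    """Observable vector aligned to model.observables.

    An undefined output (flux ratio with a zero denominator) is reported as
    NaN, which downstream cost functions treat as an unacceptable fit.
    """
    x = np.asarray(state, float)
    fluxes = compute_fluxes(model, x, params, inputs)
    out = np.empty(len(model.observables))
    for i, obs in enumerate(model.observables):
        if obs.kind == "state_sum":
            out[i] = sum(c * x[model._state_index[ref]] for c, ref in obs.terms)
        elif obs.kind == "flux":
            out[i] = sum(c * fluxes[model._reaction_index[ref]] for c, ref in obs.terms)
        elif obs.kind == "flux_ratio":
            (ca, ra), (cb, rb) = obs.terms
            num = ca * fluxes[model._reaction_index[ra]]
            den = cb * fluxes[model._reaction_index[rb]]
            out[i] = num / den if den != 0 else np.nan
        else:  # derived
            fn = DERIVED_FORMULAS.get(obs.derived_formula_id)
            if fn is None:
                raise ConfigurationError(
                    f"no formula registered for {obs.derived_formula_id}"
                )
            out[i] = fn(model, fluxes, parameter_values(params), dict(inputs), obs.terms)
    return out
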