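"""Synthetic two-phenotype datasets with a known ground truth.

The generator emulates the structure of the study data: steady-state pools,
fluxes, and derived quantities of the bundled hepatic model for a wild-type
phenotype (A) and a treated phenotype (B), with independent Gaussian
measurement noise whose standard deviations scale with the means.  Phenotype
B is obtained from the shipped wild-type parameter fixture by applying fold
factors to a declared parameter subset; the default perturbation follows the
directions expected under pharmacological LXR activation and is sized so the
VLDL-TG secretion flux roughly two-and-a-half-folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .estimation import Dataset
from .hepatic import build_hepatic_model, load_ground_truth_parameters
from .model import ModelDefinition, compute_fluxes, compute_outputs, steady_state

__all__ = [
    "GroundTruth",
    "GenerationError",
    "make_ground_truth",
    "generate_dataset",
    "lxr_demo_dataset",
    "LITERATURE_ANCHORS",
    "DEFAULT_CV",
    "DEFAULT_MASK",
    "SD_FLOOR",
]

#: default relative measurement noise, similar to the study's lipid data
#: (roughly 20-40 % relative SDs on hepatic triglyceride levels).
DEFAULT_CV = 0.2
SD_FLOOR = 1e-6

#: only the total pools of triglyceride are "measured" by default;
#: the cytosol/ER split is left to the fraction production-rate observables.
DEFAULT_MASK = ("hepatic_TG_cyt", "hepatic_TG_er")


class GenerationError(Exception):
    """Raised when a requested ground truth violates physiological bounds."""


@dataclass
class GroundTruth:
    """A pair of feasible parameter sets defining the two phenotypes."""

    theta_A: np.ndarray
    theta_B: np.ndarray
    inputs: dict[str, dict[str, float]]
    perturbation: dict[str, float]
    seed: int
    parameter_ids: list[str] = field(default_factory=list)


def _check_feasible(model, theta, inputs, flux_bound, label):
    ss = steady_state(model, theta, inputs)
    if not ss.converged:
        raise GenerationError(f"{label}: no steady state found")
    if np.any(ss.state < 0):
        raise GenerationError(f"{label}: negative steady-state concentration")
    fluxes = compute_fluxes(model, ss.state, theta, inputs)
    over = np.flatnonzero(fluxes > flux_bound)
    if over.size:
        rid = model.reaction_ids[over[0]]
        raise GenerationError(
            f"{label}: flux {rid} = {fluxes[over[0]]:.3g} mM/h exceeds "
            f"the {flux_bound:g} mM/h bound"
        )
    return ss.state


def make_ground_truth(
    seed: int = 0,
    perturbation: Mapping[str, float] | None = None,
    model: ModelDefinition | None = None,
    flux_bound: float = 100.0,
) -> GroundTruth:
    """Fixture-backed wild-type parameters plus a fold-perturbed phenotype B.

    ``perturbation`` maps parameter ids to fold factors applied to the
    wild-type values; when omitted the shipped default perturbation is used.
    An empty mapping gives theta_B = theta_A.  Both phenotypes are validated
    for steady-state feasibility and the flux bound; violations raise a
    :class:`GenerationError` naming the offending flux.
    """
    model = model or build_hepatic_model()
    doc = load_ground_truth_parameters()
    theta_A = model.parameters_from_dict(doc["phenotype_A"]["parameters"])
    inputs_A = {k: float(v) for k, v in doc["phenotype_A"]["inputs"].items()}
    if perturbation is None:
        perturbation = doc["phenotype_B"]["fold_perturbation"]
    perturbation = {str(k): float(v) for k, v in perturbation.items()}
    unknown = sorted(set(perturbation) - set(model.parameter_ids))
    if unknown:
        raise GenerationError(f"perturbation references unknown parameters: {unknown}")
    theta_B = theta_A.copy()
    for pid, fold in perturbation.items():
        theta_B[model.parameter_index(pid)] *= fold
    inputs_B = {k: float(v) for k, v in doc["phenotype_B"]["inputs"].items()}
    _check_feasible(model, theta_A, inputs_A, flux_bound, "phenotype A")
    _check_feasible(model, theta_B, inputs_B, flux_bound, "phenotype B")
    return GroundTruth(
        theta_A=theta_A,
        theta_B=theta_B,
        inputs={"A": inputs_A, "B": inputs_B},
        perturbation=perturbation,
        seed=int(seed),
        parameter_ids=list(model.parameter_ids),
    )


def generate_dataset(
    model: ModelDefinition,
    truth: GroundTruth,
    cv: float = DEFAULT_CV,
    seed: int = 0,
    mask: Iterable[str] = (),
    noisy_means: bool = False,
    phenotypes: Sequence[str] = ("A", "B"),
) -> Dataset:
    """Steady-state observables of both phenotypes as a measurement table.

    Means are the exact model outputs at the ground-truth steady states
    (optionally perturbed by a single Gaussian draw when ``noisy_means`` is
    set, emulating noisy reported means); sd = cv * |mean| with a small
    floor.  ``mask`` drops observables to emulate partial measurement.
    """
    if cv < 0:
        raise ValueError("cv must be nonnegative")
    mask = set(mask)
    rng = np.random.default_rng(seed)
    rows = []
    for ph in phenotypes:
        theta = truth.theta_A if ph == "A" else truth.theta_B
        inputs = truth.inputs[ph]
        ss = steady_state(model, theta, inputs)
        if not ss.converged:
            raise GenerationError(f"phenotype {ph}: steady state failed")
        y = compute_outputs(model, ss.state, theta, inputs)
        for obs, val in zip(model.observables, y):
            if obs.id in mask:
                continue
            sd = max(cv * abs(val), SD_FLOOR)
            mean = float(rng.normal(val, sd)) if noisy_means else float(val)
            units = "nm" if obs.id == "VLDL_diameter" else (
                "" if obs.kind == "flux_ratio" else (
                    "mM/h" if obs.kind in ("flux", "derived") else "mM"
                )
            )
            rows.append(
                {
                    "observable": obs.id,
                    "phenotype": ph,
                    "mean": mean,
                    "sd": float(sd),
                    "units": units,
                }
            )
    table = pd.DataFrame(rows)
    return Dataset(table, {ph: dict(truth.inputs[ph]) for ph in phenotypes})


#: literature-reported measurements for wild-type vs T0901317-treated
#: (LXR-agonist) mice: total hepatic triglyceride (nmol/mg liver) and nascent
#: VLDL particle diameter (nm), as (mean, sd) per phenotype.
LITERATURE_ANCHORS = {
    "hepatic_TG": {"A": (6.92, 2.65), "B": (57.74, 16.61), "units": "nmol/mg liver"},
    "VLDL_diameter": {"A": (94.0, 12.0), "B": (129.0, 9.0), "units": "nm"},
}


def lxr_demo_dataset(
    model: ModelDefinition | None = None,
    cv: float = DEFAULT_CV,
    seed: int = 0,
    truth: GroundTruth | None = None,
) -> Dataset:
    """Demonstration dataset for the LXR-activation transition.

    Combines the literature-reported hepatic triglyceride and VLDL diameter
    measurements (see :data:`LITERATURE_ANCHORS`) with ground-truth-derived
    synthetic values for the remaining observables.  Each observable carries
    its own units, so mixing nmol/mg-liver pools with mM/h fluxes is fine:
    the weighted objective is scale-free per observable.
    """
    model = model or build_hepatic_model()
    truth = truth or make_ground_truth()
    ds = generate_dataset(model, truth, cv=cv, seed=seed, mask=DEFAULT_MASK)
    table = ds.table.copy()
    for obs, anchors in LITERATURE_ANCHORS.items():
        for ph in ("A", "B"):
            mean, sd = anchors[ph]
            sel = (table["observable"] == obs) & (table["phenotype"] == ph)
            table.loc[sel, ["mean", "sd", "units"]] = [mean, sd, anchors["units"]]
    return Dataset(table, ds.inputs)
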