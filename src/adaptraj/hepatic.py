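"""Bundled hepatic lipid / plasma lipoprotein model.

Three conceptual compartments (liver, plasma, periphery), eight mass-carrying
molecular species, twenty-two mass-action rate constants, and one constant
input (plasma free fatty acids).  Triglyceride (TG) handling: uptake and de
novo lipogenesis feed a cytosolic pool which exchanges with an endoplasmic-
reticulum (ER) pool from which VLDL-TG is secreted; plasma VLDL-TG is cleared
by peripheral lipolysis and hepatic remnant uptake.  Cholesterol handling:
hepatic free cholesterol (FC) is synthesized, excreted into bile, and
esterified into cytosolic and ER cholesterylester (CE) pools; ER CE is
secreted as VLDL-CE; HDL-CE formed in the periphery returns to the liver
(SR-B1) or is taken up peripherally.

The apoB particle-production rate (v15, rate constant k15) carries no mass:
it only sets the number of nascent VLDL particles over which the secreted
lipid flux is spread, and thereby the particle diameter (see
:func:`vldl_diameter`).
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .model import (
    DomainError,
    ModelDefinition,
    ObservableSpec,
    Reaction,
    register_derived_formula,
)

__all__ = [
    "build_hepatic_model",
    "vldl_diameter",
    "load_ground_truth_parameters",
    "VLDL_DIAMETER_REFERENCE",
    "C_GEOM_DEFAULT",
]

#: reference wild-type secretion fluxes (TG mM/h, CE mM/h, particle rate 1/h)
#: anchoring the geometric prefactor so the wild-type particle measures 94 nm.
VLDL_DIAMETER_REFERENCE = (1.0, 0.3, 0.05, 94.0)

_ref_volume = (VLDL_DIAMETER_REFERENCE[0] + VLDL_DIAMETER_REFERENCE[1]) / VLDL_DIAMETER_REFERENCE[2]
C_GEOM_DEFAULT = VLDL_DIAMETER_REFERENCE[3] / _ref_volume ** (1.0 / 3.0)


def vldl_diameter(
    tg_secretion_flux: float,
    ce_secretion_flux: float,
    particle_rate: float,
    nu_tg: float = 1.0,
    nu_ce: float = 1.0,
    c_geom: float = C_GEOM_DEFAULT,
) -> float:
    """Nascent VLDL particle diameter (nm).

    The lipid volume secreted per particle is
    ``V = (nu_tg * tg_flux + nu_ce * ce_flux) / particle_rate``; the diameter
    scales as the cube root of that volume.  ``c_geom`` is calibrated once so
    the wild-type reference flux triple maps to 94 nm.
    """
    if particle_rate <= 0:
        raise DomainError("particle production rate must be strictly positive")
    if tg_secretion_flux <= 0 or ce_secretion_flux <= 0:
        raise DomainError("lipid secretion fluxes must be strictly positive")
    volume = (nu_tg * tg_secretion_flux + nu_ce * ce_secretion_flux) / particle_rate
    return c_geom * volume ** (1.0 / 3.0)


def _vldl_diameter_formula(model, fluxes, params, inputs, terms):
    # terms reference the TG-secretion, CE-secretion, and particle reactions
    (c_tg, r_tg), (c_ce, r_ce), (c_p, r_p) = terms
    return vldl_diameter(
        c_tg * fluxes[model.reaction_index(r_tg)],
        c_ce * fluxes[model.reaction_index(r_ce)],
        c_p * fluxes[model.reaction_index(r_p)],
        nu_tg=model.constants.get("nu_tg", 1.0),
        nu_ce=model.constants.get("nu_ce", 1.0),
        c_geom=model.constants.get("c_geom", C_GEOM_DEFAULT),
    )


register_derived_formula("vldl_diameter", _vldl_diameter_formula)


_STATES = [
    "TG_cyt", "TG_er", "FC_liv", "CE_cyt", "CE_er", "VLDL_TG", "VLDL_CE", "HDL_CE",
]

_REACTIONS = [
    # (id, rate constant, modifier, stoichiometry, role)
    ("v1", "k1", "FFA_plasma", {"TG_cyt": 1}),        # FFA uptake / esterification
    ("v2", "k2", None, {"TG_cyt": 1}),                # de novo lipogenesis
    ("v3", "k3", "TG_cyt", {"TG_cyt": -1}),           # TG utilization / oxidation
    ("v4", "k4", "TG_cyt", {"TG_cyt": -1, "TG_er": 1}),   # cytosol -> ER mobilization
    ("v5", "k5", "TG_er", {"TG_er": -1, "TG_cyt": 1}),    # ER -> cytosol back-transfer
    ("v6", "k6", "TG_er", {"TG_er": -1, "VLDL_TG": 1}),   # VLDL-TG secretion
    ("v7", "k7", None, {"FC_liv": 1}),                # cholesterol synthesis
    ("v8", "k8", "FC_liv", {"FC_liv": -1}),           # biliary excretion (ABCG5)
    ("v9", "k9", "FC_liv", {"FC_liv": -1, "CE_cyt": 1}),  # ACAT, cytosol
    ("v10", "k10", "CE_cyt", {"CE_cyt": -1, "FC_liv": 1}),  # CE hydrolysis, cytosol
    ("v11", "k11", "FC_liv", {"FC_liv": -1, "CE_er": 1}),   # esterification, ER
    ("v12", "k12", "CE_er", {"CE_er": -1, "FC_liv": 1}),    # CE hydrolysis, ER
    ("v13", "k13", "CE_cyt", {"CE_cyt": -1, "CE_er": 1}),   # CE mobilization to ER
    ("v14", "k14", "CE_er", {"CE_er": -1, "VLDL_CE": 1}),   # VLDL-CE secretion
    ("v15", "k15", None, {}),                          # apoB particle production
    ("v16", "k16", "VLDL_TG", {"VLDL_TG": -1}),        # peripheral lipolysis (LPL)
    ("v17", "k17", "VLDL_TG", {"VLDL_TG": -1, "TG_cyt": 1}),  # hepatic remnant TG uptake
    ("v18", "k18", "VLDL_CE", {"VLDL_CE": -1, "FC_liv": 1}),  # hepatic remnant CE uptake
    ("v19", "k19", "VLDL_CE", {"VLDL_CE": -1}),        # peripheral lipoprotein chol uptake
    ("v20", "k20", None, {"HDL_CE": 1}),               # peripheral efflux (ABCA1) + LCAT
    ("v21", "k21", "HDL_CE", {"HDL_CE": -1, "FC_liv": 1}),  # hepatic HDL-CE uptake (SR-B1)
    ("v22", "k22", "HDL_CE", {"HDL_CE": -1}),          # peripheral HDL-CE uptake
]

_OBSERVABLES = [
    ObservableSpec("hepatic_TG", "state_sum", ((1.0, "TG_cyt"), (1.0, "TG_er"))),
    ObservableSpec("hepatic_TG_cyt", "state_sum", ((1.0, "TG_cyt"),)),
    ObservableSpec("hepatic_TG_er", "state_sum", ((1.0, "TG_er"),)),
    ObservableSpec("hepatic_FC", "state_sum", ((1.0, "FC_liv"),)),
    ObservableSpec("hepatic_CE", "state_sum", ((1.0, "CE_cyt"), (1.0, "CE_er"))),
    ObservableSpec("plasma_TG", "state_sum", ((1.0, "VLDL_TG"),)),
    ObservableSpec("plasma_total_chol", "state_sum", ((1.0, "VLDL_CE"), (1.0, "HDL_CE"))),
    ObservableSpec("HDL_chol", "state_sum", ((1.0, "HDL_CE"),)),
    ObservableSpec("VLDL_TG_prod", "flux", ((1.0, "v6"),)),
    ObservableSpec("VLDL_TGC_ratio", "flux_ratio", ((1.0, "v6"), (1.0, "v14"))),
    ObservableSpec("chol_synthesis", "flux", ((1.0, "v7"),)),
    ObservableSpec("HDL_CE_uptake_liver", "flux", ((1.0, "v21"),)),
    ObservableSpec("periph_chol_uptake", "flux", ((1.0, "v19"), (1.0, "v22"))),
    ObservableSpec("TG_prod_cyt", "flux", ((1.0, "v1"), (1.0, "v2"))),
    ObservableSpec("TG_prod_er", "flux", ((1.0, "v4"),)),
    ObservableSpec(
        "VLDL_diameter",
        "derived",
        ((1.0, "v6"), (1.0, "v14"), (1.0, "v15")),
        derived_formula_id="vldl_diameter",
    ),
]


def build_hepatic_model() -> ModelDefinition:
    """Construct the bundled 8-state, 22-parameter hepatic model."""
    return ModelDefinition(
        state_ids=list(_STATES),
        parameter_ids=[f"k{i}" for i in range(1, 23)],
        input_ids=["FFA_plasma"],
        reactions=[
            Reaction(rid, k, mod, stoich) for rid, k, mod, stoich in _REACTIONS
        ],
        observables=list(_OBSERVABLES),
        default_initial_state=np.ones(len(_STATES)),
        constants={"nu_tg": 1.0, "nu_ce": 1.0, "c_geom": C_GEOM_DEFAULT},
        name="hepatic_lipoprotein",
    )


def load_ground_truth_parameters() -> dict:
    """Shipped ground-truth fixture: wild-type parameters, inputs, and the
    default phenotype-B fold perturbation.  Returns the parsed JSON document.
    """
    text = resources.files("adaptraj.data").joinpath("hepatic_ground_truth.json").read_text()
    return json.loads(text)
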