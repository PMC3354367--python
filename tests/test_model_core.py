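"""Core model layer: fluxes, time courses, steady states, outputs."""

import numpy as np
import pytest

from adaptraj.model import (
    ConfigurationError,
    DomainError,
    ModelDefinition,
    ObservableSpec,
    ParameterSet,
    Reaction,
    compute_fluxes,
    compute_outputs,
    steady_state,
    time_course,
)


def linear_chain_model():
    """Single pool with a zeroth-order source and first-order loss."""
    return ModelDefinition(
        state_ids=["X"],
        parameter_ids=["p", "d"],
        input_ids=[],
        reactions=[
            Reaction("prod", "p", None, {"X": 1}),
            Reaction("loss", "d", "X", {"X": -1}),
        ],
        observables=[ObservableSpec("X_total", "state_sum", ((1.0, "X"),))],
        default_initial_state=[0.0],
        name="source_loss",
    )


class TestComputeFluxes:
    def test_first_order_flux(self):
        m = linear_chain_model()
        f = compute_fluxes(m, [2.0], [0.7, 0.5], {})
        assert f[1] == pytest.approx(0.5 * 2.0)

    def test_zero_rate_constant_gives_zero_flux(self):
        m = linear_chain_model()
        f = compute_fluxes(m, [2.0], [0.0, 0.0], {})
        assert np.all(f == 0.0)

    def test_bundled_model_matches_per_reaction_oracle(self, model, rng):
        # independent element-by-element evaluation of every reaction
        x = rng.uniform(0.1, 5.0, model.n_states)
        theta = rng.uniform(0.01, 10.0, model.n_parameters)
        inputs = {"FFA_plasma": 0.8}
        f = compute_fluxes(model, x, theta, inputs)
        sidx = {s: i for i, s in enumerate(model.state_ids)}
        pidx = {p: i for i, p in enumerate(model.parameter_ids)}
        for j, r in enumerate(model.reactions):
            if r.modifier is None:
                expected = theta[pidx[r.rate_constant]]
            elif r.modifier in sidx:
                expected = theta[pidx[r.rate_constant]] * x[sidx[r.modifier]]
            else:
                expected = theta[pidx[r.rate_constant]] * inputs[r.modifier]
            assert f[j] == pytest.approx(expected, rel=1e-12)

    def test_missing_input_is_configuration_error(self, model):
        with pytest.raises(ConfigurationError):
            compute_fluxes(model, np.ones(8), np.ones(22), {})

    def test_negative_state_is_domain_error(self, model):
        x = np.ones(8)
        x[0] = -0.5
        with pytest.raises(DomainError):
            compute_fluxes(model, x, np.ones(22), {"FFA_plasma": 0.8})


class TestTimeCourse:
    def test_matches_closed_form_source_loss(self):
        m = linear_chain_model()
        p, d, x0 = 2.0, 0.5, 1.0
        t = np.linspace(0.0, 10.0, 25)
        sol = time_course(m, [p, d], {}, [x0], t)
        expected = p / d + (x0 - p / d) * np.exp(-d * t)
        np.testing.assert_allclose(sol[:, 0], expected, rtol=1e-6)

    def test_all_rates_zero_keeps_state_constant(self):
        m = linear_chain_model()
        sol = time_course(m, [1e-300, 1e-300], {}, [3.0], [0.0, 1.0, 5.0])
        np.testing.assert_allclose(sol[:, 0], 3.0, rtol=1e-9)

    def test_initial_derivative_equals_stoichiometry_times_fluxes(self, model, rng):
        # finite-difference check of dx/dt = S v at t = 0
        x0 = rng.uniform(0.5, 3.0, model.n_states)
        theta = rng.uniform(0.05, 2.0, model.n_parameters)
        inputs = {"FFA_plasma": 0.8}
        dt = 1e-6
        sol = time_course(model, theta, inputs, x0, [0.0, dt], rtol=1e-10, atol=1e-12)
        fd = (sol[1] - sol[0]) / dt
        expected = model.stoichiometric_matrix @ compute_fluxes(model, x0, theta, inputs)
        # forward difference carries an O(dt) curvature term; 1e-3 relative
        # still catches any stoichiometry wiring error
        np.testing.assert_allclose(fd, expected, rtol=1e-3, atol=1e-6)

    def test_non_increasing_grid_rejected(self, model):
        with pytest.raises(ConfigurationError):
            time_course(model, np.ones(22), {"FFA_plasma": 0.8}, np.ones(8), [0.0, 0.0])


class TestSteadyState:
    def test_source_loss_closed_form(self):
        m = linear_chain_model()
        res = steady_state(m, [2.0, 0.5], {})
        assert res.converged
        assert res.state[0] == pytest.approx(4.0, rel=1e-9)

    def test_zero_sources_give_zero_steady_state(self, model):
        theta = np.ones(22)
        for pid in ("k2", "k7", "k20"):  # mass-carrying sources
            theta[model.parameter_index(pid)] = 1e-300
        res = steady_state(model, theta, {"FFA_plasma": 0.0})
        assert res.converged
        np.testing.assert_allclose(res.state, 0.0, atol=1e-12)

    def test_two_method_agreement_on_bundled_model(self, model, truth):
        lin = steady_state(model, truth.theta_A, truth.inputs["A"], method="linear")
        integ = steady_state(model, truth.theta_A, truth.inputs["A"], method="integrate")
        assert lin.converged and integ.converged
        np.testing.assert_allclose(integ.state, lin.state, rtol=1e-6)

    def test_idempotence(self, model, truth):
        res = steady_state(model, truth.theta_A, truth.inputs["A"])
        res2 = steady_state(model, truth.theta_A, truth.inputs["A"], x0=res.state)
        np.testing.assert_allclose(res2.state, res.state, rtol=1e-12)
        assert res2.residual <= 1e-9

    def test_nonconvergence_is_flagged_not_raised(self):
        # a pool with no loss grows without bound: no steady state exists
        m = ModelDefinition(
            state_ids=["X"],
            parameter_ids=["p"],
            input_ids=[],
            reactions=[Reaction("prod", "p", None, {"X": 1})],
            observables=[],
            name="unbounded",
        )
        res = steady_state(m, [1.0], {}, horizon=200.0)
        assert not res.converged


class TestComputeOutputs:
    def test_state_sum(self, model, truth):
        res = steady_state(model, truth.theta_A, truth.inputs["A"])
        y = compute_outputs(model, res.state, truth.theta_A, truth.inputs["A"])
        i = model.observable_ids.index("hepatic_TG")
        j0 = model.state_ids.index("TG_cyt")
        j1 = model.state_ids.index("TG_er")
        assert y[i] == pytest.approx(res.state[j0] + res.state[j1], rel=1e-12)

    def test_flux_ratio_of_identical_reactions_is_one(self):
        m = ModelDefinition(
            state_ids=["X"],
            parameter_ids=["k"],
            input_ids=[],
            reactions=[
                Reaction("a", "k", "X", {"X": -1}),
                Reaction("b", "k", "X", {}),
            ],
            observables=[
                ObservableSpec("r", "flux_ratio", ((1.0, "a"), (1.0, "b")))
            ],
        )
        y = compute_outputs(m, [2.0], [0.3], {})
        assert y[0] == pytest.approx(1.0)

    def test_zero_denominator_gives_nan_marker(self):
        m = ModelDefinition(
            state_ids=["X"],
            parameter_ids=["k", "z"],
            input_ids=[],
            reactions=[
                Reaction("a", "k", "X", {}),
                Reaction("b", "z", "X", {}),
            ],
            observables=[
                ObservableSpec("r", "flux_ratio", ((1.0, "a"), (1.0, "b")))
            ],
        )
        y = compute_outputs(m, [0.0], [0.3, 0.4], {})
        assert np.isnan(y[0])

    def test_full_observable_vector_against_spreadsheet_oracle(self, model, truth, rng):
        # independent recomputation of each observable from fluxes/states
        x = rng.uniform(0.2, 4.0, model.n_states)
        theta = truth.theta_A
        inputs = truth.inputs["A"]
        f = dict(zip(model.reaction_ids, compute_fluxes(model, x, theta, inputs)))
        s = dict(zip(model.state_ids, x))
        y = dict(zip(model.observable_ids, compute_outputs(model, x, theta, inputs)))
        assert y["hepatic_CE"] == pytest.approx(s["CE_cyt"] + s["CE_er"])
        assert y["plasma_total_chol"] == pytest.approx(s["VLDL_CE"] + s["HDL_CE"])
        assert y["VLDL_TG_prod"] == pytest.approx(f["v6"])
        assert y["VLDL_TGC_ratio"] == pytest.approx(f["v6"] / f["v14"])
        assert y["periph_chol_uptake"] == pytest.approx(f["v19"] + f["v22"])
        assert y["TG_prod_cyt"] == pytest.approx(f["v1"] + f["v2"])


class TestInvariantsAndSerialization:
    def test_nonnegativity_from_nonnegative_start(self, model, truth, rng):
        x0 = rng.uniform(0.0, 5.0, model.n_states)
        sol = time_course(
            model, truth.theta_A, truth.inputs["A"], x0, np.linspace(0, 50, 40)
        )
        assert np.all(sol >= -1e-9)

    def test_json_round_trip(self, model):
        clone = ModelDefinition.from_json(model.to_json())
        assert clone.state_ids == model.state_ids
        assert clone.parameter_ids == model.parameter_ids
        np.testing.assert_array_equal(
            clone.stoichiometric_matrix, model.stoichiometric_matrix
        )
        assert [o.id for o in clone.observables] == model.observable_ids

    def test_parameter_set_rejects_nonpositive(self):
        with pytest.raises(ConfigurationError):
            ParameterSet(np.array([1.0, 0.0]))

    def test_duplicate_state_ids_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelDefinition(
                state_ids=["X", "X"],
                parameter_ids=["k"],
                input_ids=[],
                reactions=[],
                observables=[],
            )
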