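"""Trajectory identification: interpolation, regularization, passes, sweeps."""

import numpy as np
import pytest

from adaptraj.estimation import acceptance_test, realize_dataset
from adaptraj.synthetic import generate_dataset
from adaptraj.trajectory import (
    TrajectoryConfig,
    backward_trajectory,
    consistency_cycles,
    forward_trajectory,
    get_scheme,
    interpolate_data,
    lambda_sweep,
    regularized_cost,
)


@pytest.fixture(scope="module")
def stationary_dataset(model, truth):
    """Phenotype B identical to A (empty perturbation), near-zero noise."""
    from adaptraj.synthetic import DEFAULT_MASK, make_ground_truth

    same = make_ground_truth(perturbation={})
    return generate_dataset(model, same, cv=0.0, seed=0, mask=DEFAULT_MASK)


class TestInterpolation:
    def test_endpoints_exact(self, dataset):
        ra = realize_dataset(dataset, "A", 1)
        rb = realize_dataset(dataset, "B", 2)
        d0 = interpolate_data(ra, rb, 0.0)
        d1 = interpolate_data(ra, rb, 1.0)
        np.testing.assert_array_equal(d0.values, ra.values)
        np.testing.assert_array_equal(d0.sigmas, ra.sigmas)
        np.testing.assert_array_equal(d1.values, rb.values)
        np.testing.assert_array_equal(d1.sigmas, rb.sigmas)

    def test_linear_midpoint(self, dataset):
        ra = realize_dataset(dataset, "A", 1)
        rb = realize_dataset(dataset, "B", 2)
        ra.values = np.full_like(ra.values, 2.0)
        rb.values = np.full_like(rb.values, 4.0)
        dq = interpolate_data(ra, rb, 0.25, "linear")
        np.testing.assert_allclose(dq.values, 2.5)

    @pytest.mark.parametrize(
        "scheme,q,expected_w",
        [("linear", 0.5, 0.5), ("quadratic_like", 0.5, 0.25),
         ("inverse_quadratic_like", 0.5, 0.75)],
    )
    def test_scheme_weights(self, scheme, q, expected_w):
        assert get_scheme(scheme)(q) == pytest.approx(expected_w)

    def test_schemes_monotone_with_exact_endpoints(self):
        qs = np.linspace(0, 1, 101)
        for name in ("linear", "quadratic_like", "inverse_quadratic_like"):
            w = np.array([get_scheme(name)(q) for q in qs])
            assert w[0] == 0.0 and w[-1] == 1.0
            assert np.all(np.diff(w) >= 0)


class TestRegularizedCost:
    def test_reference_point_has_zero_penalty(self, dataset):
        real = realize_dataset(dataset, "A", 1)
        theta = np.ones(5)
        x, x_d, x_r = regularized_cost(real.values, real, theta, theta, 0.7)
        assert x_r == 0.0
        assert x == x_d

    def test_lambda_zero_ignores_parameters(self, dataset):
        real = realize_dataset(dataset, "A", 1)
        x, x_d, x_r = regularized_cost(real.values, real, np.full(5, 9.0), np.ones(5), 0.0)
        assert x == x_d == 0.0
        assert x_r > 0.0

    def test_single_doubled_parameter_at_lambda_point_one(self, dataset):
        real = realize_dataset(dataset, "A", 1)
        x, x_d, x_r = regularized_cost(
            real.values, real, np.array([2.0]), np.array([1.0]), 0.1
        )
        assert x_r == pytest.approx(1.0)
        assert x == pytest.approx(x_d + 0.1)


class TestForwardTrajectory:
    def test_grid_covers_unit_interval(self, model, truth, dataset):
        traj = forward_trajectory(model, truth.theta_A, dataset, steps=10, seed=1)
        np.testing.assert_allclose(traj.q_grid, np.arange(11) / 10)
        assert len(traj.points) == 11

    def test_first_point_is_supplied_parameter_set(self, model, truth, dataset):
        traj = forward_trajectory(model, truth.theta_A, dataset, steps=5, seed=1)
        np.testing.assert_array_equal(traj.start.theta, truth.theta_A)

    def test_stationary_data_leaves_parameters_unchanged(
        self, model, truth, stationary_dataset
    ):
        traj = forward_trajectory(
            model, truth.theta_A, stationary_dataset, steps=20, lam=0.1, seed=3
        )
        rel = np.abs(traj.end.theta - truth.theta_A) / truth.theta_A
        assert rel.max() <= 1e-4

    def test_endpoint_passes_acceptance_on_fixture(self, model, demo_dataset, demo_ensemble):
        traj = forward_trajectory(
            model, demo_ensemble.best(), demo_dataset, steps=100, lam=0.1, seed=2
        )
        rep = acceptance_test(
            traj.end.outputs, demo_dataset, "B", observable_ids=list(traj.observable_ids)
        )
        assert traj.completed and rep.accepted


class TestBackwardTrajectory:
    def test_q_sequence_strictly_decreasing(self, model, truth, dataset):
        fwd = forward_trajectory(model, truth.theta_A, dataset, steps=8, seed=1)
        bwd = backward_trajectory(model, fwd, dataset, seed=2)
        assert np.all(np.diff(bwd.q_grid) < 0)
        assert bwd.q_grid[0] == 1.0 and bwd.q_grid[-1] == 0.0

    def test_identical_phenotypes_return_to_start(self, model, truth, stationary_dataset):
        fwd = forward_trajectory(
            model, truth.theta_A, stationary_dataset, steps=10, lam=0.1, seed=4
        )
        bwd = backward_trajectory(model, fwd, stationary_dataset, seed=5)
        rel = np.abs(bwd.end.theta - fwd.end.theta) / fwd.end.theta
        assert rel.max() <= 1e-4

    def test_backward_endpoint_accepted_against_phenotype_A(
        self, model, demo_dataset, demo_ensemble
    ):
        fwd = forward_trajectory(
            model, demo_ensemble.best(), demo_dataset, steps=50, lam=0.1, seed=6
        )
        bwd = backward_trajectory(model, fwd, demo_dataset, seed=7)
        rep = acceptance_test(
            bwd.end.outputs, demo_dataset, "A", observable_ids=list(bwd.observable_ids)
        )
        assert bwd.completed and rep.accepted

    def test_reference_set_swapped_to_backward_start(self, model, truth, dataset):
        fwd = forward_trajectory(model, truth.theta_A, dataset, steps=5, seed=1)
        bwd = backward_trajectory(model, fwd, dataset, seed=2)
        np.testing.assert_array_equal(bwd.theta_ref, fwd.end.theta)


class TestConsistencyCycles:
    def test_repetitions_share_grid_and_record_seeds(self, model, truth, dataset):
        bundle = consistency_cycles(
            model, truth.theta_A, dataset, repetitions=3, steps=5, seed=9
        )
        assert len(bundle) == 6  # forward + backward per repetition
        grids = {tuple(np.sort(t.q_grid)) for t in bundle}
        assert len(grids) == 1
        seeds = [t.seeds["trajectory"] for t in bundle]
        assert len(set(seeds)) == len(seeds)

    def test_cycle_stability_for_pinned_parameters(self, model, truth, tight_dataset):
        """One forward+backward cycle on near-noiseless data returns the
        structurally pinned parameters (k7, k15, k21) within 0.01 log10."""
        fwd = forward_trajectory(
            model, truth.theta_A, tight_dataset, steps=100, lam=0.1, seed=5
        )
        bwd = backward_trajectory(model, fwd, tight_dataset, seed=6)
        shift = np.abs(np.log10(bwd.end.theta / truth.theta_A))
        for pid in ("k7", "k15", "k21"):
            assert shift[model.parameter_index(pid)] <= 0.01


class TestLambdaSweep:
    def test_lambda_zero_reproduces_unregularized(self, model, truth, dataset):
        traj0 = forward_trajectory(model, truth.theta_A, dataset, steps=5, lam=0.0, seed=8)
        assert all(p.X_d >= 0 for p in traj0.points)
        # with lam = 0 the recorded X contribution is X_d alone
        x, x_d, _ = regularized_cost(
            traj0.end.outputs,
            realize_dataset(dataset, "B", 1),
            traj0.end.theta,
            traj0.theta_ref,
            0.0,
        )
        assert x == x_d

    def test_default_selected_lambda(self):
        from adaptraj.trajectory import DEFAULT_LAMBDA

        assert DEFAULT_LAMBDA == 0.1

    def test_regularization_shrinks_path_length(self, model, demo_dataset, demo_ensemble):
        member = demo_ensemble.best()
        reg = forward_trajectory(model, member, demo_dataset, steps=25, lam=0.1, seed=10)
        unreg = forward_trajectory(model, member, demo_dataset, steps=25, lam=0.0, seed=10)
        assert reg.path_length() <= unreg.path_length() + 1e-9

    def test_sweep_table_shape_and_flags(self, model, demo_dataset, demo_ensemble):
        table = lambda_sweep(
            model, demo_ensemble.accepted[:2], demo_dataset,
            lambda_grid=[0.0, 0.1, 10.0], steps=10, seed=3,
        )
        assert set(table["lambda"]) == {0.0, 0.1, 10.0}
        assert len(table) == 6
        assert table["X_r_end"].ge(0).all()


class TestSingleVsMultiStep:
    def test_single_step_fails_where_multi_step_succeeds(
        self, model, demo_dataset, demo_ensemble
    ):
        """At a per-step budget of 2 trust-region iterations, a single jump
        to the treated phenotype misses endpoint acceptance while 100
        warm-started interpolation steps succeed (pinned fixture)."""
        member = demo_ensemble.accepted[0]
        cfg = TrajectoryConfig(max_nfev=2)
        single = forward_trajectory(
            model, member, demo_dataset, steps=1, lam=0.1, seed=0, config=cfg
        )
        multi = forward_trajectory(
            model, member, demo_dataset, steps=100, lam=0.1, seed=0, config=cfg
        )
        ok_single = single.completed and acceptance_test(
            single.end.outputs, demo_dataset, "B",
            observable_ids=list(single.observable_ids),
        ).accepted
        ok_multi = multi.completed and acceptance_test(
            multi.end.outputs, demo_dataset, "B",
            observable_ids=list(multi.observable_ids),
        ).accepted
        assert not ok_single
        assert ok_multi
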