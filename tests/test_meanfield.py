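"""Mean-field dynamics: fitness, drift, stability and thresholds."""

import numpy as np
import pytest
from scipy.optimize import brentq

from intercoop import (
    BreakingSchedule,
    ModelParams,
    PayoffScheme,
    PopulationConfig,
    average_fitness,
    classify_equilibria,
    critical_benefit_cost,
    critical_intra_group_bias,
    integrate_trajectory,
    interior_fixed_point,
    jacobian,
    replicator_field,
    transition_probabilities,
)
from intercoop.meanfield import basin_threshold_diagonal, equilibrium_eigenvalues


def _params(b=1.0, c=0.3, kcc=0.3, kcd=0.6, kdd=0.9, p=0.6, w=0.1):
    return ModelParams(
        payoff=PayoffScheme(b=b, c=c),
        schedule=BreakingSchedule(kcc, kcd, kdd),
        config=PopulationConfig(100, 100, 300, 300, 200, p=p, W=1e-3, w=w),
    )


class TestFitness:
    def test_all_defector_boundary(self, bistable_params):
        fit = average_fitness((0.0, 0.0), bistable_params)
        Mp = bistable_params.rescaled_matrix
        assert fit.fC1 == pytest.approx(Mp[0, 1])  # C against all-D neighbors
        assert fit.fD1 == pytest.approx(Mp[1, 1]) == 0.0
        assert fit.fC2 == fit.fC1 and fit.fD2 == fit.fD1

    def test_group_symmetry_on_diagonal(self, bistable_params):
        fit = average_fitness((0.37, 0.37), bistable_params)
        assert fit.fC1 == pytest.approx(fit.fC2)
        assert fit.fD1 == pytest.approx(fit.fD2)

    def test_unit_k_reduces_to_well_mixed_expectation(self, rng):
        """With k = 1 and equal frequencies the fitness is the plain average
        payoff of the original matrix against a Bernoulli(x) opponent."""
        params = _params(kcc=1.0, kcd=1.0, kdd=1.0, p=0.35)
        M = params.payoff.matrix
        for _ in range(5):
            x = float(rng.uniform(0, 1))
            fit = average_fitness((x, x), params)
            assert fit.fC1 == pytest.approx(x * M[0, 0] + (1 - x) * M[0, 1])
            assert fit.fD1 == pytest.approx(x * M[1, 0] + (1 - x) * M[1, 1])

    def test_group_dependent_schedule_rejected(self, bistable_params):
        from intercoop import LinkType

        override = {LinkType.of(("C", 1), ("C", 2)): 0.9}
        params = bistable_params.with_(overrides=override)
        with pytest.raises(ValueError, match="pair-keyed"):
            average_fitness((0.5, 0.5), params)


class TestTransitionProbabilities:
    def test_neutral_selection_balances_on_diagonal(self, bistable_params):
        for x in (0.2, 0.5, 0.8):
            for cross in (True, False):
                (t1p, t1m), (t2p, t2m) = transition_probabilities(
                    (x, x), bistable_params, w=0.0, cross_imitation=cross
                )
                assert t1p == pytest.approx(t1m)
                assert t2p == pytest.approx(t2m)

    def test_neutral_selection_balances_everywhere_within_group(self, bistable_params):
        (t1p, t1m), (t2p, t2m) = transition_probabilities(
            (0.2, 0.9), bistable_params, w=0.0, cross_imitation=False
        )
        assert t1p == pytest.approx(t1m) and t2p == pytest.approx(t2m)

    def test_cross_channel_supplies_cooperators_at_x1_zero(self, bistable_params):
        (t1p, _), _ = transition_probabilities(
            (0.0, 0.6), bistable_params, cross_imitation=True
        )
        assert t1p > 0.0  # group-2 cooperators can invade group 1
        (t1p_within, _), _ = transition_probabilities(
            (0.0, 0.6), bistable_params, cross_imitation=False
        )
        assert t1p_within == 0.0

    def test_drift_matches_one_step_multinomial_simulation(self, bistable_params):
        """T+ - T- equals the mean frequency change of the direct pairwise
        process simulated for one step at large N (within MC error)."""
        rng = np.random.default_rng(7)
        n = 10_000
        state = (0.3, 0.7)
        w = 2.0  # strong selection so the drift dominates MC noise
        (t1p, t1m), _ = transition_probabilities(state, bistable_params, w=w)
        fit = average_fitness(state, bistable_params)
        p = bistable_params.p
        trials = 200_000
        # simulate the group-1 update channel: target D/C, model from own
        # group w.p. p, else other group, Fermi acceptance at intensity w
        x1, x2 = state
        ups = downs = 0
        for _ in range(trials):
            target_is_c = rng.random() < x1
            same = rng.random() < p
            model_is_c = rng.random() < (x1 if same else x2)
            if target_is_c == model_is_c:
                continue
            f_target = (fit.fC1 if target_is_c else fit.fD1)
            f_model = (fit.fC1 if model_is_c else fit.fD1) if same else (
                fit.fC2 if model_is_c else fit.fD2
            )
            if rng.random() < 1.0 / (1.0 + np.exp(-w * (f_model - f_target))):
                if model_is_c:
                    ups += 1
                else:
                    downs += 1
        drift_mc = (ups - downs) / trials
        assert drift_mc == pytest.approx(t1p - t1m, abs=4.0 / np.sqrt(trials))


class TestReplicatorField:
    def test_corners_are_fixed_points(self, rng):
        for _ in range(10):
            params = _params(
                c=float(rng.uniform(0.05, 0.9)),
                kcc=float(rng.uniform(0.05, 1)),
                kcd=float(rng.uniform(0.05, 1)),
                kdd=float(rng.uniform(0.05, 1)),
                p=float(rng.uniform(0, 1)),
            )
            assert np.allclose(replicator_field((0, 0), params), 0.0)
            assert np.allclose(replicator_field((1, 1), params), 0.0)

    def test_diagonal_is_invariant_under_symmetric_parameters(self, bistable_params):
        for x in (0.1, 0.4, 0.9):
            v = replicator_field((x, x), bistable_params)
            assert v[0] == pytest.approx(v[1])

    def test_finite_intensity_drift_converges_to_weak_selection_field(
        self, bistable_params
    ):
        state = (0.3, 0.7)
        f8 = replicator_field(state, bistable_params)
        ratios = []
        for w in (1e-2, 1e-3, 1e-4):
            f7 = replicator_field(state, bistable_params, w=w, cross_imitation=False)
            ratios.append(f7 / (w / 2.0) / f8)
        assert np.allclose(ratios[-1], 1.0, atol=1e-6)
        # errors shrink with w
        errs = [np.max(np.abs(r - 1.0)) for r in ratios]
        assert errs[2] < errs[1] < errs[0]

    def test_unit_square_forward_invariant(self, bistable_params):
        """Boundary normal component of the field is never outward."""
        grid = np.linspace(0.0, 1.0, 100)
        for x in grid:
            assert replicator_field((x, 0.0), bistable_params)[1] >= -1e-14
            assert replicator_field((x, 1.0), bistable_params)[1] <= 1e-14
            assert replicator_field((0.0, x), bistable_params)[0] >= -1e-14
            assert replicator_field((1.0, x), bistable_params)[0] <= 1e-14


class TestJacobian:
    def test_matches_finite_differences(self, bistable_params, rng):
        eps = 1e-6
        for _ in range(20):
            x = rng.uniform(0.02, 0.98, size=2)
            J = jacobian(x, bistable_params)
            J_fd = np.empty((2, 2))
            for j in range(2):
                e = np.zeros(2)
                e[j] = eps
                J_fd[:, j] = (
                    replicator_field(x + e, bistable_params)
                    - replicator_field(x - e, bistable_params)
                ) / (2 * eps)
            assert np.max(np.abs(J - J_fd)) < 1e-6

    def test_corner_jacobians_are_diagonal(self, bistable_params):
        for pt in ((0.0, 0.0), (1.0, 1.0)):
            J = jacobian(pt, bistable_params)
            assert J[0, 1] == 0.0 and J[1, 0] == 0.0

    def test_commutes_with_swap_on_diagonal(self, bistable_params):
        S = np.array([[0.0, 1.0], [1.0, 0.0]])
        J = jacobian((0.3, 0.3), bistable_params)
        assert np.allclose(J @ S, S @ J)

    def test_closed_form_eigenvalues_match_numeric(self, bistable_params):
        eigs = equilibrium_eigenvalues(bistable_params)
        xs = interior_fixed_point(bistable_params)
        for pt, key in (((0, 0), "(0,0)"), ((1, 1), "(1,1)"), ((xs, xs), "(x*,x*)")):
            numeric = np.sort(np.linalg.eigvals(jacobian(pt, bistable_params)).real)
            assert np.allclose(numeric, np.sort(eigs[key]), atol=1e-8)


class TestEquilibriaAndThresholds:
    def test_bistable_classification(self, bistable_params):
        report = classify_equilibria(bistable_params)
        assert report.labels["(0,0)"] == "stable"
        assert report.labels["(1,1)"] == "stable"
        assert report.labels["(x*,x*)"] == "unstable"
        assert report.bistable
        assert report.x_star == pytest.approx(3.0 / 7.0)
        assert report.bc_critical == pytest.approx(2.0)
        assert report.p_critical == pytest.approx(0.5, abs=1e-6)

    def test_defection_dominant_classification(self, defection_params):
        report = classify_equilibria(defection_params)
        assert report.x_star is None
        assert report.labels["(1,1)"] != "stable"
        assert not report.bistable
        assert np.isinf(report.bc_critical)

    def test_labels_agree_with_long_run_integration(self, bistable_params, rng):
        xs = interior_fixed_point(bistable_params)
        for _ in range(20):
            x0 = float(rng.uniform(0.02, 0.98))
            traj = integrate_trajectory((x0, x0), bistable_params, horizon=4000.0)
            target = 2.0 if x0 > xs else 0.0
            assert traj.terminal.sum() == pytest.approx(target, abs=1e-3)

    def test_threshold_monotone_in_breaking_probabilities(self):
        base = critical_benefit_cost(_params(kcd=0.6))
        assert critical_benefit_cost(_params(kcd=0.8)) < base  # fragile CD helps
        assert critical_benefit_cost(_params(kcc=0.4)) > base  # fragile CC hurts
        assert np.isinf(critical_benefit_cost(_params(kcc=0.6, kcd=0.6)))

    def test_threshold_is_eigenvalue_sign_change(self, bistable_params):
        """Bisection of the (1,1) eigenvalue sign in b/c recovers Eq. 9."""
        c = bistable_params.payoff.c

        def top_eig(b):
            return equilibrium_eigenvalues(
                bistable_params.with_(b=b)
            )["(1,1)"][0]

        b_crit = brentq(top_eig, c + 1e-9, 10.0, xtol=1e-10)
        assert b_crit / c == pytest.approx(
            critical_benefit_cost(bistable_params), abs=1e-6
        )

    def test_stability_flips_across_threshold(self, bistable_params):
        bc = critical_benefit_cost(bistable_params)
        c = bistable_params.payoff.c
        above = classify_equilibria(bistable_params.with_(b=(bc + 1e-3) * c))
        below = classify_equilibria(bistable_params.with_(b=(bc - 1e-3) * c))
        assert above.labels["(1,1)"] == "stable"
        assert below.labels["(1,1)"] != "stable"
        assert below.x_star is None

    def test_interior_point_agrees_with_diagonal_root(self, bistable_params):
        xs = interior_fixed_point(bistable_params)
        root = brentq(
            lambda x: replicator_field((x, x), bistable_params)[0], 1e-9, 1 - 1e-9,
            xtol=1e-12,
        )
        assert xs == pytest.approx(root, abs=1e-8)

    def test_interior_point_monotone_in_k(self):
        """Sturdier C-C links widen the basin; sturdier C-D links shrink it."""
        xs = [interior_fixed_point(_params(kcc=k)) for k in (0.2, 0.3, 0.4)]
        assert xs[0] < xs[1] < xs[2]
        xs = [interior_fixed_point(_params(kcd=k)) for k in (0.5, 0.6, 0.8)]
        assert xs[0] > xs[1] > xs[2]

    def test_critical_bias_bisection(self, bistable_params):
        pc = critical_intra_group_bias(bistable_params)
        assert pc == pytest.approx(0.5, abs=1e-6)
        pc_fine = critical_intra_group_bias(bistable_params, tol=1e-12)
        assert abs(pc - pc_fine) < 1e-5
        saddle = classify_equilibria(bistable_params.with_(p=pc - 0.05))
        node = classify_equilibria(bistable_params.with_(p=pc + 0.05))
        assert saddle.labels["(x*,x*)"] == "saddle"
        assert node.labels["(x*,x*)"] == "unstable"

    def test_no_interior_no_critical_bias(self, defection_params):
        assert critical_intra_group_bias(defection_params) is None


class TestIntegration:
    def test_constant_trajectory_from_corner(self, bistable_params):
        traj = integrate_trajectory((0.0, 0.0), bistable_params, horizon=50.0)
        assert np.allclose(traj.states, 0.0)
        assert traj.converged

    def test_basin_bisection_matches_interior_point(self, bistable_params):
        bt = basin_threshold_diagonal(bistable_params, tol=1e-6)
        assert bt == pytest.approx(interior_fixed_point(bistable_params), abs=1e-5)

    def test_terminal_state_robust_to_tolerance(self, bistable_params):
        a = integrate_trajectory((0.7, 0.6), bistable_params, rtol=1e-8).terminal
        b = integrate_trajectory((0.7, 0.6), bistable_params, rtol=5e-9).terminal
        assert np.allclose(a, b, atol=1e-6)

    def test_not_bistable_returns_none(self, defection_params):
        assert basin_threshold_diagonal(defection_params) is None
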