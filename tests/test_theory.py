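import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contiguity import (
    DepressionMode,
    PlasticityRule,
    TransitionMatrix,
    averaged_trajectory,
    event_statistics,
    sample_sequence,
    simulate,
    steady_state,
    transfer_bistable,
    transfer_multistate,
    transient_timescale,
)
from contiguity.theory import fit_exponential_transient, transfer_bistable_deriv


def birth_death_stationary_mean(up: float, down: float, m: int) -> float:
    """Independent oracle: numerically solved stationary mean of the m-state
    chain with uniform up/down step probabilities, normalized to [0, 1].

    Solves (P - I) rho = 0 with the last equation replaced by the
    normalization sum(rho) = 1 (robust even when the stationary vector is
    concentrated on one boundary state).
    """
    P = np.zeros((m, m))
    for k in range(m):
        if k < m - 1:
            P[k + 1, k] += up
        if k > 0:
            P[k - 1, k] += down
        P[k, k] += 1 - P[:, k].sum()
    A = P - np.eye(m)
    A[-1, :] = 1.0
    b = np.zeros(m)
    b[-1] = 1.0
    rho = np.linalg.solve(A, b)
    return float(np.arange(m) @ rho / (m - 1))


class TestTransferBistable:
    def test_basic_values(self):
        assert transfer_bistable(0.0, 0.06, 0.03) == 0.0
        assert transfer_bistable(0.5, 0.06, 0.03) == pytest.approx(0.5)  # ratio 2
        assert transfer_bistable(1.0, 0.05, 0.05) == pytest.approx(0.5)  # ratio 1

    def test_rejects_negative_ratio(self):
        with pytest.raises(ValueError):
            transfer_bistable(-0.1, 0.1, 0.1)

    def test_strictly_increasing_and_saturating(self):
        x = np.linspace(0, 50, 500)
        for r in (0.1, 1.0, 10.0):
            F = transfer_bistable(x, r * 0.01, 0.01)
            assert np.all(np.diff(F) > 0)
            assert F[0] == 0 and F[-1] < 1
        assert transfer_bistable(1e9, 0.1, 0.1) > 0.999999

    def test_derivative_matches_finite_difference(self):
        x = np.linspace(0.01, 3, 20)
        h = 1e-7
        fd = (transfer_bistable(x + h, 0.06, 0.03) - transfer_bistable(x - h, 0.06, 0.03)) / (2 * h)
        np.testing.assert_allclose(transfer_bistable_deriv(x, 0.06, 0.03), fd, rtol=1e-6)


class TestTransferMultistate:
    def test_reduces_to_bistable_at_m2(self):
        x = np.concatenate([np.linspace(0, 5, 200), [10.0, 100.0]])
        a = transfer_multistate(x, 0.06, 0.03, 2)
        b = transfer_bistable(x, 0.06, 0.03)
        assert np.abs(a - b).max() < 1e-12

    @pytest.mark.parametrize("m", [2, 3, 5, 10, 50, 100])
    def test_value_half_at_singularity(self, m):
        """F(q_minus/q_plus) = 1/2 for every m (removable singularity)."""
        assert transfer_multistate(0.5, 0.06, 0.03, m) == pytest.approx(0.5, abs=1e-12)

    def test_matches_printed_closed_form(self):
        """Cross-check against the closed-form expression away from y = 1."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = int(rng.integers(2, 40))
            qp, qm = rng.uniform(0.01, 0.5, 2)
            x = rng.uniform(0, 3)
            y = qp / qm * x
            if abs(y - 1) < 1e-3:
                continue
            if y == 0:
                expected = 0.0
            else:
                expected = (y / (1 - y) + m * y**m / (y**m - 1)) / (m - 1)
            got = transfer_multistate(x, qp, qm, m)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_matches_birth_death_oracle(self):
        """Equals the numerically solved stationary mean of the m-state chain."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            m = int(rng.integers(2, 30))
            qp, qm = rng.uniform(0.01, 0.4, 2)
            x = rng.uniform(0.0, 2.0)
            f_minus = 0.2  # sets the chain's timescale, cancels in the mean
            oracle = birth_death_stationary_mean(qp * x * f_minus, qm * f_minus, m)
            assert transfer_multistate(x, qp, qm, m) == pytest.approx(oracle, abs=1e-8)

    def test_steep_sigmoid_at_many_states(self):
        # ratio 2: center at x = 0.5.  At m = 50 the transfer is nearly a
        # step; its tails close on {0, 1} like E/(m-1) with E the mean of
        # the untruncated geometric (exact values 1/49 and 47/49 here).
        assert transfer_multistate(0.25, 0.06, 0.03, 50) == pytest.approx(1 / 49, abs=1e-10)
        assert transfer_multistate(0.75, 0.06, 0.03, 50) == pytest.approx(0.9592, abs=1e-3)
        # contrast across the center is nearly total
        lo = transfer_multistate(0.25, 0.06, 0.03, 50)
        hi = transfer_multistate(0.75, 0.06, 0.03, 50)
        assert hi - lo > 0.9

    def test_converges_to_step_function_in_m(self):
        """F(x) approaches 1[x > q_minus/q_plus] monotonically as m grows."""
        ms = [2, 4, 8, 16, 32, 64]
        below = np.array([transfer_multistate(0.3, 0.06, 0.03, m) for m in ms])
        above = np.array([transfer_multistate(0.8, 0.06, 0.03, m) for m in ms])
        assert np.all(np.diff(below) < 0) and below[-1] < 0.03
        assert np.all(np.diff(above) > 0) and above[-1] > 0.97

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        m=st.integers(2, 60),
        r=st.floats(0.1, 10.0),
    )
    def test_monotone_in_x(self, m, r):
        x = np.linspace(0, 3, 100)
        F = transfer_multistate(x, r * 0.01, 0.01, m)
        assert np.all(np.diff(F) > -1e-15)
        assert np.all((F >= 0) & (F <= 1))

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            transfer_multistate(0.5, 0.1, 0.1, 1)


class TestSteadyState:
    def test_pre_rule_is_transfer_of_transition_probability(self, two_state_chain):
        rule = PlasticityRule(0.06, 0.03, depression="pre")
        pred = steady_state(event_statistics(two_state_chain), rule)
        # P(0->1) = 0.8, ratio 2 -> F = 1.6/2.6
        assert pred.x[1, 0] == pytest.approx(0.8)
        assert pred.J_bar[1, 0] == pytest.approx(1.6 / 2.6)

    def test_ratio_two_at_half_gives_half(self):
        T = TransitionMatrix(np.array([[0.5, 0.5], [0.5, 0.5]]))
        pred = steady_state(event_statistics(T), PlasticityRule(0.06, 0.03, depression="pre"))
        assert pred.J_bar[1, 0] == pytest.approx(0.5)

    def test_unspecific_zero_pair_frequency_gives_zero(self):
        T = TransitionMatrix(np.array([[0.0, 0.5, 0.5], [0.0, 0.0, 0.5], [1.0, 0.5, 0.0]]))
        pred = steady_state(event_statistics(T), PlasticityRule(0.06, 0.03, depression="unspecific"))
        assert pred.J_bar[1, 0] == 0.0
        assert not pred.defined[1, 0]

    def test_rule_arguments_differ(self, chain12):
        """POST encodes f_AB/f_B, which differs from P(A->B) in general."""
        stats = event_statistics(chain12)
        pre = steady_state(stats, PlasticityRule(0.06, 0.03, depression="pre"))
        post = steady_state(stats, PlasticityRule(0.06, 0.03, depression="post"))
        uns = steady_state(stats, PlasticityRule(0.06, 0.03, depression="unspecific"))
        d = pre.defined
        assert np.nanmax(np.abs(pre.x[d] - post.x[d])) > 0.05
        np.testing.assert_allclose(uns.x[d], stats.f_pair[d], atol=1e-14)
        # POST argument is the conditional probability f_AB / f_B
        np.testing.assert_allclose(post.x[d], stats.f_cond[d], atol=1e-12)

    def test_diagonal_is_flagged(self, chain12):
        pred = steady_state(event_statistics(chain12), PlasticityRule(0.06, 0.03))
        assert np.all(np.isnan(np.diag(pred.J_bar)))
        assert not pred.defined.diagonal().any()


class TestAveragedTrajectory:
    def test_fixed_point_is_constant(self):
        J_bar = 0.5  # q_plus f_plus = q_minus f_minus
        traj = averaged_trajectory(J_bar, 0.2, 0.2, 0.05, 0.05, 100)
        np.testing.assert_allclose(traj, J_bar, atol=1e-14)

    def test_closed_form_half_life(self):
        traj = averaged_trajectory(0.0, 0.5, 0.5, 0.02, 0.02, 500)
        t = np.arange(501)
        np.testing.assert_allclose(traj, 0.5 * (1 - 0.98**t), atol=1e-12)

    def test_matches_monte_carlo_ensemble(self, two_state_chain):
        """Ensemble mean of stochastic runs follows the averaged recursion."""
        rule = PlasticityRule(0.05, 0.05, depression="pre")
        stats = event_statistics(two_state_chain)
        f_plus = stats.f_pair[1, 0]
        f_minus = stats.f[0]
        steps, n_runs = 400, 300
        acc = np.zeros(steps)
        for s in range(n_runs):
            tr = simulate(two_state_chain, rule, steps=steps, seed=1000 + s, record=[(0, 1)])
            acc += tr.J[:, 0]
        mc = acc / n_runs
        theory = averaged_trajectory(0.0, f_plus, f_minus, 0.05, 0.05, steps - 1)
        # 3 SEM with the trajectory spread estimated from the tail
        sem = 3 * mc[200:].std() / np.sqrt(n_runs) + 3e-3
        assert np.abs(mc - theory).max() < 5 * sem


class TestTransientTimescale:
    def test_direct_substitution(self):
        """tau = J_bar / (q_plus f_AB) on a hand-built chain."""
        # two-state symmetric chain: f = (0.5, 0.5), P(0->1) = 0.5
        T = TransitionMatrix(np.array([[0.5, 0.5], [0.5, 0.5]]))
        stats = event_statistics(T)
        rule = PlasticityRule(0.02, 0.02, depression="pre")
        tau = transient_timescale(stats, rule, pre=0, post=1)
        # J_bar = F(0.5) = 1/3, f_AB = 0.25 -> tau = (1/3)/(0.02*0.25)
        assert tau == pytest.approx((1 / 3) / (0.02 * 0.25))

    def test_identity_with_rate_sum(self, chain12):
        """J_bar/(q+ f_AB) == 1/(q+ f+ + q- f-) for every defined pair."""
        stats = event_statistics(chain12)
        for mode in DepressionMode:
            rule = PlasticityRule(0.06, 0.03, depression=mode)
            pred = steady_state(stats, rule)
            f_plus = stats.f_pair
            if mode is DepressionMode.PRE:
                f_minus = np.tile(stats.f, (12, 1))
            elif mode is DepressionMode.POST:
                f_minus = np.tile(stats.f[:, None], (1, 12))
            else:
                f_minus = np.ones((12, 12))
            alt = 1.0 / (0.06 * f_plus + 0.03 * f_minus)
            d = pred.defined
            np.testing.assert_allclose(pred.tau_steps[d], alt[d], rtol=1e-12)

    def test_inverse_in_q_plus_at_fixed_ratio(self, chain12):
        stats = event_statistics(chain12)
        p1 = steady_state(stats, PlasticityRule(0.01, 0.005, depression="pre"))
        p2 = steady_state(stats, PlasticityRule(0.02, 0.010, depression="pre"))
        d = p1.defined
        np.testing.assert_allclose(p1.tau_steps[d], 2 * p2.tau_steps[d], rtol=1e-12)

    def test_undefined_for_absent_pair(self):
        T = TransitionMatrix(np.array([[0.0, 0.5, 0.5], [0.0, 0.0, 0.5], [1.0, 0.5, 0.0]]))
        with pytest.raises(ValueError, match="undefined"):
            transient_timescale(event_statistics(T), PlasticityRule(0.06, 0.03), 0, 1)

    def test_exponential_fit_recovers_noiseless_tau(self):
        t = np.arange(4000)
        true_tau, true_J = 700.0, 0.4
        y = true_J * (1 - np.exp(-t / true_tau))
        J_fit, tau_fit = fit_exponential_transient(t, y, 0.3, 500.0)
        assert tau_fit == pytest.approx(true_tau, rel=1e-4)
        assert J_fit == pytest.approx(true_J, rel=1e-4)
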