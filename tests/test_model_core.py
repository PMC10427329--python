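"""Single-agent primitives: marginal payoff, theta, utility, best response,
belief updates and normalised weights."""

import numpy as np
import pytest

from normdyn.model_core import (
    AgentState,
    Authority,
    BeliefWeights,
    NonConcavePayoffError,
    NormWeights,
    PayoffCoeffs,
    best_response,
    best_response_coeffs,
    marginal_payoff,
    normalized_weights,
    theta,
    update_beliefs,
    utility,
)

NO_AUTH = Authority()


@pytest.mark.parametrize(
    "pc, x, x_exp, expected",
    [
        # coordination coefficients (c=d=1, preferred action 1): zero marginal
        # at the preferred consensus
        (PayoffCoeffs(2, 2, 4), 1.0, 1.0, 0.0),
        # x_exp has no effect when D1 = 0
        (PayoffCoeffs(1, 0, 1), 0.0, 7.0, 1.0),
        # CPR coefficients for b=10, c=1, d=1, n=20
        (PayoffCoeffs(9, -9.5, 1), 0.0, 0.0, 9.0),
    ],
)
def test_marginal_payoff_examples(pc, x, x_exp, expected):
    assert marginal_payoff(pc, x, x_exp) == pytest.approx(expected)


@pytest.mark.parametrize(
    "pc, expected",
    [
        (PayoffCoeffs(1, 0, 1), 1.0),           # PGG: benefit-to-cost ratio
        (PayoffCoeffs(2, 2, 4), 1.0),           # coordination: preferred action
        (PayoffCoeffs(9, -9.5, 1), 18.0 / 21.0),  # CPR: 2(b-c)/(d(n+1))
    ],
)
def test_theta_examples(pc, expected):
    assert theta(pc) == pytest.approx(expected, abs=1e-12)


def test_theta_solves_self_consistent_first_order_condition():
    rng = np.random.default_rng(0)
    for _ in range(50):
        pc = PayoffCoeffs(rng.uniform(0.1, 5), rng.uniform(-3, 1), rng.uniform(1.5, 5))
        t = theta(pc)
        assert marginal_payoff(pc, t, t) == pytest.approx(0.0, abs=1e-12)


def test_theta_rejects_degenerate_payoff():
    with pytest.raises(NonConcavePayoffError):
        theta(PayoffCoeffs(1, 2, 2))  # D2 - D1 = 0


def test_utility_reduces_to_material_payoff_without_norms():
    pc = PayoffCoeffs(2, 1, 3)
    st = AgentState(x=0.0, y=0.7, x_exp=0.4, y_exp=0.9)
    x = np.linspace(0, 2, 9)
    u = utility(pc, NormWeights(), NO_AUTH, st, x)
    pi = pc.D0 * x + pc.D1 * st.x_exp * x - pc.D2 * x ** 2 / 2
    np.testing.assert_allclose(u, pi)


def test_best_response_examples():
    # pure material optimum: coordination with c=1, d=0, preferred action 1
    pc = PayoffCoeffs(D0=2 * 1 * 1, D1=0.0, D2=2 * 1)
    st = AgentState(x=0.0, y=5.0, x_exp=3.0, y_exp=2.0)
    assert best_response(pc, NormWeights(), NO_AUTH, st) == pytest.approx(1.0)

    # authority-only regime: no material payoff, A4 alone pulls to G
    pc0 = PayoffCoeffs(0, 0, 0)
    st0 = AgentState(x=0.0, y=0.0, x_exp=0.0, y_exp=0.0)
    assert best_response(pc0, NormWeights(A4=1.0), Authority(True, 2.0),
                         st0) == pytest.approx(2.0)

    # all forces mixed: numerator 12 over denominator 12
    pc1 = PayoffCoeffs(2, 2, 4)
    st1 = AgentState(x=0.0, y=0.5, x_exp=1.0, y_exp=0.5)
    assert best_response(pc1, NormWeights(1, 1, 1, 1), Authority(True, 2.0),
                         st1) == pytest.approx(1.0)


def test_best_response_signals_nonconcavity():
    st = AgentState(x=0.0, y=0.0, x_exp=0.0, y_exp=0.0)
    with pytest.raises(NonConcavePayoffError):
        best_response(PayoffCoeffs(1, 0, 0), NormWeights(), NO_AUTH, st)


def _grid_argmax(pc, nw, auth, st, hi=15.0, step=1e-4):
    x = np.arange(0.0, hi, step)
    return x[np.argmax(utility(pc, nw, auth, st, x))]


def test_best_response_matches_grid_search_maximiser():
    """Closed form agrees with a dense grid search over the utility."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        pc = PayoffCoeffs(rng.uniform(0, 3), rng.uniform(-1, 1), rng.uniform(0.5, 3))
        nw = NormWeights(*rng.uniform(0, 2, 4))
        auth = Authority(True, rng.uniform(0, 2))
        st = AgentState(*rng.uniform(0, 2, 4))
        assert best_response(pc, nw, auth, st) == pytest.approx(
            _grid_argmax(pc, nw, auth, st), abs=1e-3)


def test_best_response_monotone_in_attitude_and_standard():
    """Raising G (with A4 > 0) or y (with A1 > 0) never lowers the response."""
    pc = PayoffCoeffs(1, 0.5, 2)
    nw = NormWeights(0.5, 0.3, 0.2, 0.8)
    st = AgentState(x=0.0, y=0.5, x_exp=0.7, y_exp=0.6)
    br_g = [best_response(pc, nw, Authority(True, g), st) for g in (0.0, 0.5, 1.5, 3.0)]
    assert np.all(np.diff(br_g) >= 0)
    auth = Authority(True, 1.0)
    br_y = [best_response(pc, nw, auth, AgentState(0.0, y, 0.7, 0.6)) for y in
            (0.0, 0.4, 1.0, 2.5)]
    assert np.all(np.diff(br_y) >= 0)


def test_best_response_coeffs_match_closed_form():
    pc = PayoffCoeffs(2, 2, 4)
    nw = NormWeights(1, 1, 1, 1)
    auth = Authority(True, 2.0)
    B = best_response_coeffs(pc, nw, auth)
    st = AgentState(x=0.0, y=0.5, x_exp=1.0, y_exp=0.5)
    linear = B.B0 + B.B1 * st.x_exp + B.B2 * st.y + B.B3 * st.y_exp + B.B4 * auth.G
    assert linear == pytest.approx(best_response(pc, nw, auth, st))


def test_update_beliefs_identity_cases():
    st = AgentState(x=0.3, y=0.8, x_exp=0.1, y_exp=0.5)
    zero = BeliefWeights(np.zeros((3, 3)))
    out = update_beliefs(zero, st, X_obs=2.0, auth=NO_AUTH)
    assert (out.y, out.y_exp, out.x_exp) == (st.y, st.y_exp, st.x_exp)

    # consensus fixed point: everything equal (including G) is stationary
    th = 0.8571
    cons = AgentState(x=th, y=th, x_exp=th, y_exp=th)
    bw = BeliefWeights(np.full((3, 3), 0.1))
    out = update_beliefs(bw, cons, X_obs=th, auth=Authority(True, th))
    for v in ("y", "y_exp", "x_exp"):
        assert getattr(out, v) == pytest.approx(th)


def test_update_beliefs_linear_form():
    # y' = 1 + 0.2*(2-1) + 0.1*(0-1) = 1.1
    C = np.zeros((3, 3))
    C[0, 0], C[0, 1] = 0.2, 0.1
    st = AgentState(x=2.0, y=1.0, x_exp=0.0, y_exp=0.0)
    out = update_beliefs(BeliefWeights(C), st, X_obs=0.0, auth=NO_AUTH)
    assert out.y == pytest.approx(1.1)
    assert out.x == st.x


def test_update_beliefs_clips_at_zero():
    C = np.zeros((3, 3))
    C[1, 1] = 1.0  # y_exp moves all the way to X
    st = AgentState(x=0.0, y=0.0, x_exp=0.0, y_exp=0.5)
    out = update_beliefs(BeliefWeights(C), st, X_obs=0.0, auth=NO_AUTH)
    assert out.y_exp == 0.0
    for v in ("y", "y_exp", "x_exp"):
        assert np.all(np.asarray(getattr(out, v)) >= 0)


def test_belief_rows_bounded_by_one():
    with pytest.raises(ValueError):
        BeliefWeights(np.full((3, 3), 0.4))  # row sums 1.2


@pytest.mark.parametrize(
    "row, expected",
    [((0.2, 0.1, 0.1), (0.5, 0.25, 0.25)),
     ((0.25, 0.25, 0.0), (0.5, 0.5, 0.0)),
     ((1 / 3, 1 / 3, 1 / 3), (1 / 3, 1 / 3, 1 / 3))],
)
def test_normalized_weights_rows(row, expected):
    C = np.tile(np.asarray(row), (3, 1))
    nwts = normalized_weights(BeliefWeights(C))
    np.testing.assert_allclose(nwts.alpha + nwts.beta + nwts.gamma, 1.0)
    np.testing.assert_allclose(
        np.stack([nwts.alpha[0], nwts.beta[0], nwts.gamma[0]]), expected)


def test_normalized_weights_flags_zero_rows():
    C = np.zeros((3, 3))
    C[0, 0] = 0.5
    with pytest.warns(UserWarning, match="zero-sum"):
        nwts = normalized_weights(BeliefWeights(C))
    assert nwts.alpha[0] == 1.0
    assert np.isnan(nwts.alpha[1]) and np.isnan(nwts.alpha[2])


def test_consensus_is_exact_fixed_point_of_both_operations():
    """Shared theta, no authority, state at theta: best response returns theta
    and the belief update is the identity."""
    pc = PayoffCoeffs(2, 2, 4)
    th = theta(pc)
    nw = NormWeights(0.7, 0.2, 0.9, 0.0)
    st = AgentState(x=th, y=th, x_exp=th, y_exp=th)
    assert best_response(pc, nw, NO_AUTH, st) == pytest.approx(th, abs=1e-14)
    bw = BeliefWeights(np.array([[0.1, 0.2, 0.0], [0.3, 0.1, 0.0], [0.2, 0.2, 0.0]]))
    out = update_beliefs(bw, st, X_obs=th, auth=NO_AUTH)
    for v in ("y", "y_exp", "x_exp"):
        assert getattr(out, v) == pytest.approx(th, abs=1e-14)


def test_pure_authority_standard_is_exact_fixed_point():
    """All D = 0, authority on, state at G: best response returns G and the
    belief update is the identity."""
    G = 2.0
    auth = Authority(True, G)
    st = AgentState(x=G, y=G, x_exp=G, y_exp=G)
    pc0 = PayoffCoeffs(0, 0, 0)
    assert best_response(pc0, NormWeights(0.5, 0.5, 0.5, 0.5), auth,
                         st) == pytest.approx(G, abs=1e-14)
    bw = BeliefWeights(np.full((3, 3), 0.15))
    out = update_beliefs(bw, st, X_obs=G, auth=auth)
    for v in ("y", "y_exp", "x_exp"):
        assert getattr(out, v) == pytest.approx(G, abs=1e-14)
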