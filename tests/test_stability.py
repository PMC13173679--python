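import numpy as np
import pytest

from beebloom import dynamics
from beebloom.equilibria import boundary_equilibria, find_coexistence
from beebloom.model import attracting_box, jacobian, rhs
from beebloom.stability import (
    check_global_conditions,
    classify_local,
    compute_bounds,
    lyapunov_descent,
    lyapunov_gradient,
    lyapunov_value,
    persistence_check,
    _s5_block,
)
from tests.conftest import random_params

# a parameter set satisfying the extinction-point global conditions:
# heavy depletion, weak growth, weak coupling
GAS_KW = dict(r1=0.01, gamma1=0.5, r2=0.01, gamma2=0.5,
              alpha1=0.001, alpha2=0.001, alpha3=0.001)


def _by_label(theta, seed=0):
    return {eq.label: eq for eq in boundary_equilibria(theta) + find_coexistence(theta, seed=seed)}


def test_bounds_closed_forms_at_baseline(baseline):
    B = compute_bounds(baseline)
    # pm = sqrt((r1 + alpha1*k2 - gamma1)*k1/r1), hand-evaluated
    assert B.pm == pytest.approx(np.sqrt((0.56 + 0.04 * 6 - 0.04) * 10 / 0.56), abs=1e-12)
    assert B.pm == pytest.approx(3.683941988065036, abs=1e-12)
    assert B.hm == pytest.approx(np.sqrt(6 * (0.18 + 0.08 * B.pm - 0.03) / 0.18), abs=1e-12)
    assert B.nm == pytest.approx(0.01 * B.hm / 0.0018, abs=1e-9)
    assert B.L1 == pytest.approx(9.285714285714286)
    assert B.L2 == pytest.approx(5.0)
    assert B.L3 is not None and B.L3 > 0


def test_bounds_undefined_below_thresholds(baseline):
    B = compute_bounds(baseline.replace(r1=0.01, gamma1=0.9, alpha1=0.01))
    assert B.pm is None and B.hm is None and B.nm is None and B.L1 is None
    B2 = compute_bounds(baseline.replace(r2=0.02))
    assert B2.L2 is None and B2.L3 is None


def test_persistence_check(baseline):
    assert persistence_check(baseline) == (True, True)
    assert persistence_check(baseline.replace(gamma1=0.6)) == (False, True)
    assert persistence_check(baseline.replace(gamma2=0.2)) == (True, False)


def test_classification_at_baseline(baseline):
    eqs = _by_label(baseline)
    assert classify_local(eqs["S1"], baseline).classification == "saddle"
    assert classify_local(eqs["S2"], baseline).classification == "saddle"
    assert classify_local(eqs["S4"], baseline).classification == "saddle"
    rep = classify_local(eqs["S5"], baseline)
    assert rep.classification == "stable node"
    assert rep.a11 < 0 and rep.a22 < 0
    assert rep.trace2 == pytest.approx(rep.a11 + rep.a22)
    assert rep.det2 > 0
    assert rep.conditions == {"(16)": True, "(17)": True}


def test_nonexistent_equilibrium_raises(baseline):
    eqs = _by_label(baseline)
    with pytest.raises(ValueError, match="S3"):
        classify_local(eqs["S3"], baseline)


def test_named_conditions_track_eigenvalues(baseline, rng):
    # wherever the printed sufficient conditions hold, the eigenvalues agree
    for _ in range(20):
        theta = random_params(rng, baseline)
        eqs = _by_label(theta, seed=3)
        rep = classify_local(eqs["S1"], theta)
        if all(rep.conditions.values()):
            assert rep.classification in ("stable node", "stable focus")


def test_s5_third_eigenvalue_factorizes(baseline):
    # the honey equation decouples: one eigenvalue is exactly -beta*h4-gamma3
    eq = _by_label(baseline)["S5"]
    eigs = np.linalg.eigvals(jacobian(eq.state, baseline))
    lam3 = -baseline.beta * eq.state[1] - baseline.gamma3
    assert np.min(np.abs(eigs - lam3)) < 1e-12
    # and the other two are the roots of the (p, h) block
    a11, a22, tr2, det2 = _s5_block(eq.state, baseline)
    rest = sorted(x for x in eigs.real if abs(x - lam3) > 1e-12)
    assert rest[0] + rest[1] == pytest.approx(tr2, rel=1e-9)
    assert rest[0] * rest[1] == pytest.approx(det2, rel=1e-9)


def test_interior_block_diagonal_is_always_negative(baseline, rng):
    # at any interior equilibrium a11 < 0 and a22 < 0 (so no Hopf is possible)
    found = 0
    for _ in range(40):
        theta = random_params(rng, baseline)
        for eq in find_coexistence(theta, seed=11):
            a11, a22, tr2, _ = _s5_block(eq.state, theta)
            assert a11 < 0 and a22 < 0 and tr2 < 0
            found += 1
    assert found >= 10  # the property was actually exercised


def test_stability_nonhyperbolic_at_threshold(baseline):
    theta = baseline.replace(r2=baseline.gamma2)
    eqs = _by_label(theta)
    assert classify_local(eqs["S1"], theta).classification == "nonhyperbolic"


def test_global_conditions_hold_for_heavy_depletion(baseline):
    theta = baseline.replace(**GAS_KW)
    out = check_global_conditions("S1", theta)
    assert out["(20)"] and out["(21)"] and out["conjunction"]


def test_global_conditions_fail_at_baseline(baseline):
    out = check_global_conditions("S1", baseline)
    assert not out["conjunction"]


def test_global_implies_local(baseline):
    # when the global conjunction holds, the local classification is stable
    theta = baseline.replace(**GAS_KW)
    assert check_global_conditions("S1", theta)["conjunction"]
    eqs = _by_label(theta)
    assert classify_local(eqs["S1"], theta).classification.startswith("stable")


def test_global_conditions_missing_point(baseline):
    out = check_global_conditions("S4", baseline.replace(r2=0.02))
    assert out == {"exists": False, "conjunction": False}
    with pytest.raises(ValueError):
        check_global_conditions("S9", baseline)


def test_lyapunov_values_and_gradients(baseline):
    ref = np.array([2.0, 3.0, 4.0])
    # at the reference point each shifted term vanishes; the linear terms
    # (plain population totals) remain
    expected_at_ref = {"S1": 9.0, "S2": 7.0, "S3": 6.0, "S4": 2.0, "S5": 0.0}
    for label, value in expected_at_ref.items():
        assert lyapunov_value(label, ref, ref) == pytest.approx(value, abs=1e-14)
    for label in ("S1", "S2", "S3", "S4", "S5"):
        x = np.array([1.5, 2.5, 3.5])
        g = lyapunov_gradient(label, x, ref)
        eps = 1e-6
        for i in range(3):
            hi = x.copy(); hi[i] += eps
            lo = x.copy(); lo[i] -= eps
            fd = (lyapunov_value(label, hi, ref) - lyapunov_value(label, lo, ref)) / (2 * eps)
            assert g[i] == pytest.approx(fd, abs=1e-7)


def test_lyapunov_descent_full_under_global_conditions(baseline):
    theta = baseline.replace(**GAS_KW)
    check = lyapunov_descent("S1", theta, n_samples=500, seed=3)
    assert check.function_id == "E1"
    assert check.descent_fraction == 1.0


def test_lyapunov_descent_partial_at_baseline(baseline):
    # S1 is a saddle at baseline, so the candidate function must fail somewhere
    check = lyapunov_descent("S1", baseline, n_samples=300, seed=5)
    assert check.descent_fraction < 1.0


def test_trajectories_stay_in_attracting_box(baseline, rng):
    # the rigorous box really traps the flow (unlike the closed-form report)
    caps = np.array(attracting_box(baseline))
    for _ in range(5):
        start = rng.uniform(0.0, 1.0, 3) * caps
        traj = dynamics.simulate(baseline, start, t_end=500.0, dt_out=0.5)
        assert np.all(traj.states <= caps * (1.0 + 1e-9) + 1e-9)
        assert np.all(traj.states >= 0.0)


def test_inward_flow_on_box_faces_random_draws(baseline, rng):
    for _ in range(10):
        theta = random_params(rng, baseline, spread=0.3)
        p_cap, h_cap, n_cap = attracting_box(theta)
        h = rng.uniform(0, h_cap)
        assert rhs((p_cap, h, 0.0), theta)[0] <= 1e-12
        p = rng.uniform(0, p_cap)
        assert rhs((p, h_cap, 0.0), theta)[1] <= 1e-12
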