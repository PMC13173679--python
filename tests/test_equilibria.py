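import numpy as np
import pytest

from beebloom.equilibria import (
    RESIDUAL_TOL,
    boundary_equilibria,
    coexistence_cubic,
    cross_validate_cubic,
    cubic_coefficients,
    find_coexistence,
    h_from_p,
    honey_closed_form,
    nullcline_residuals,
)
from beebloom.model import attracting_box, rhs
from tests.conftest import random_params

# frozen from an independent run of the multi-start nullcline solver
S5_BASELINE = (11.08288514985797, 11.478303268771986, 1.407364501980279)


def _by_label(points):
    return {eq.label: eq for eq in points}


def test_boundary_closed_forms_at_baseline(baseline):
    eqs = _by_label(boundary_equilibria(baseline))
    assert np.allclose(eqs["S1"].state, 0.0) and eqs["S1"].exists
    # p1 = k1(r1-gamma1)/r1 = 10*0.52/0.56
    assert eqs["S2"].state[0] == pytest.approx(9.285714285714286, abs=1e-12)
    assert eqs["S2"].exists
    # h2 = k2(r2-gamma2)/r2 = 6*0.15/0.18 = 5
    assert eqs["S3"].state[1] == pytest.approx(5.0, abs=1e-12)
    assert eqs["S4"].state[1] == pytest.approx(5.0, abs=1e-12)
    # n3 = alpha3*h2 / ((1+w+c*h2)(beta*h2+gamma3)), hand-evaluated
    n3_hand = 0.01 * 5 / ((1 + 3 + 0.01 * 5) * (0.00157 * 5 + 0.0018))
    assert eqs["S4"].state[2] == pytest.approx(n3_hand, abs=1e-12)
    assert eqs["S4"].exists


def test_bees_only_point_without_honey_is_not_a_fixed_point(baseline):
    # at n = 0 with h2 > 0 honey still accumulates, so (0, h2, 0) has a
    # nonzero residual and must not be flagged as existing
    eqs = _by_label(boundary_equilibria(baseline))
    s3 = eqs["S3"]
    assert not s3.exists
    assert s3.residual == pytest.approx(
        baseline.alpha3 * 5.0 / (1 + baseline.w + baseline.c * 5.0)
    )
    assert "S4" in s3.note


def test_bees_only_point_exists_when_production_vanishes(baseline):
    eqs = _by_label(boundary_equilibria(baseline.replace(alpha3=0.0)))
    assert eqs["S3"].exists and eqs["S3"].residual < RESIDUAL_TOL


def test_existence_flips_at_persistence_thresholds(baseline):
    below = _by_label(boundary_equilibria(baseline.replace(r1=0.03)))  # r1 < gamma1
    assert not below["S2"].exists and below["S2"].state[0] == 0.0
    below_b = _by_label(boundary_equilibria(baseline.replace(r2=0.02)))  # r2 < gamma2
    assert not below_b["S4"].exists
    raw = _by_label(boundary_equilibria(baseline.replace(r1=0.03), allow_negative=True))
    assert raw["S2"].state[0] < 0.0  # mathematical branch crosses the origin


def test_existing_equilibria_have_tiny_residuals(baseline, rng):
    for _ in range(20):
        theta = random_params(rng, baseline)
        for eq in boundary_equilibria(theta) + find_coexistence(theta, seed=7):
            if eq.exists:
                assert eq.residual < RESIDUAL_TOL


def test_coexistence_baseline_frozen_oracle(baseline):
    points = find_coexistence(baseline, seed=0)
    assert len(points) == 1
    assert np.allclose(points[0].state, S5_BASELINE, rtol=1e-9)
    assert points[0].residual < RESIDUAL_TOL
    # honey coordinate agrees with its closed form
    assert points[0].state[2] == pytest.approx(
        honey_closed_form(points[0].state[1], baseline), abs=1e-12
    )


def test_coexistence_seed_invariance(baseline):
    a = find_coexistence(baseline, seed=0)
    b = find_coexistence(baseline, seed=99)
    assert len(a) == len(b) == 1
    assert np.allclose(a[0].state, b[0].state, rtol=1e-8)


def test_coexistence_grid_scan_oracle(baseline):
    # brute-force: the nullcline residual norm over the attracting box is
    # minimized in the grid cell containing the solver's root
    p_cap, h_cap, _ = attracting_box(baseline)
    p = np.linspace(0.2, p_cap, 300)
    h = np.linspace(0.2, h_cap, 300)
    P, H = np.meshgrid(p, h, indexing="ij")
    D = 1 + baseline.w + baseline.a * H + baseline.b * P
    f = baseline.r1 * (1 - P / baseline.k1) + baseline.alpha1 * H / D - baseline.gamma1
    g = baseline.r2 * (1 - H / baseline.k2) + baseline.alpha2 * P / D - baseline.gamma2
    i, j = np.unravel_index(np.argmin(np.abs(f) + np.abs(g)), P.shape)
    assert abs(p[i] - S5_BASELINE[0]) < (p[1] - p[0])
    assert abs(h[j] - S5_BASELINE[1]) < (h[1] - h[0])


def test_coexistence_absent_when_decoupled_and_nonpersistent(baseline):
    theta = baseline.replace(alpha1=0.0, alpha2=0.0, r2=0.02)  # bees die alone
    assert find_coexistence(theta, seed=0) == []


def test_coexistence_decoupled_limit_is_the_logistic_pair(baseline):
    # with no mutualism the interior point is just (p1, h2)
    theta = baseline.replace(alpha1=0.0, alpha2=0.0)
    points = find_coexistence(theta, seed=0)
    assert len(points) == 1
    assert points[0].state[0] == pytest.approx(9.285714285714286, rel=1e-9)
    assert points[0].state[1] == pytest.approx(5.0, rel=1e-9)


def test_coexistence_full_output_diagnostics(baseline):
    points, diag = find_coexistence(baseline, seed=0, full_output=True)
    assert diag["n_roots"] == len(points) == 1
    assert diag["n_converged"] >= 1
    assert diag["search_box"][0] > S5_BASELINE[0]


def test_nullcline_residuals_vanish_at_s5(baseline):
    assert np.max(np.abs(nullcline_residuals(S5_BASELINE[:2], baseline))) < 1e-12


def test_cubic_transcription_reports_but_is_not_asserted(baseline):
    coeffs = cubic_coefficients(baseline)
    assert len(coeffs.sign_pattern) == 4
    assert coeffs.sign_changes >= 0
    _, roots = coexistence_cubic(baseline)
    for r in roots:
        assert r["p4"] > 0
    report = cross_validate_cubic(baseline, seed=0)
    # the consistency verdict is reported either way; the solver roots are
    # authoritative and must contain the frozen baseline point
    assert report["solver_roots"][0] == pytest.approx(S5_BASELINE[0], rel=1e-9)
    assert isinstance(report["consistent"], bool)


def test_h_from_p_recovers_known_pairs(baseline):
    # the re-derived p-nullcline recovery must invert the nullcline itself:
    # for (p4, h4) on the p-nullcline, h_from_p(p4) == h4
    h4 = h_from_p(S5_BASELINE[0], baseline)
    assert h4 == pytest.approx(S5_BASELINE[1], rel=1e-9)
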