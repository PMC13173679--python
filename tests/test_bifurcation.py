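import numpy as np
import pytest

from beebloom.bifurcation import (
    hopf_closed_form,
    refine_hopf,
    sotomayor_scalars,
    sweep_hopf,
    sweep_zero_eigenvalue,
    transcritical_thresholds,
)
from beebloom.equilibria import find_coexistence
from beebloom.model import jacobian
from tests.conftest import random_params


def test_closed_form_thresholds_at_baseline(baseline):
    points = {(pt.equilibrium_label, pt.parameter): pt for pt in transcritical_thresholds(baseline)}
    s1_pt = points[("S1", "r2")]
    assert s1_pt.critical_value == pytest.approx(baseline.gamma2, abs=1e-15)
    assert s1_pt.diagnostics["verified"]
    s2_pt = points[("S2", "r1")]
    assert s2_pt.critical_value == pytest.approx(baseline.gamma1, abs=1e-15)
    assert s2_pt.diagnostics["verified"]
    # the printed bee-point candidates move h2 with r2 and are not genuine
    # zero-eigenvalue points at baseline; they must come back flagged
    for label in ("S3", "S4"):
        assert not points[(label, "r2")].diagnostics["verified"]


def test_sotomayor_anchors_at_s1(baseline):
    theta_c = baseline.replace(r2=baseline.gamma2)
    s = sotomayor_scalars(theta_c, np.zeros(3), "r2")
    assert s.s1 == pytest.approx(0.0, abs=1e-6)
    assert s.s2 == pytest.approx(1.0, abs=1e-6)
    assert s.s3 == pytest.approx(-2.0 * baseline.gamma2 / baseline.k2, abs=1e-6)


def test_sotomayor_anchors_at_s2(baseline):
    theta_c = baseline.replace(r1=baseline.gamma1)
    s = sotomayor_scalars(theta_c, np.zeros(3), "r1")
    assert s.s1 == pytest.approx(0.0, abs=1e-6)
    assert s.s2 == pytest.approx(1.0, abs=1e-6)
    assert s.s3 == pytest.approx(-2.0 * baseline.gamma1 / baseline.k1, abs=1e-6)


def test_sweep_finds_r2_threshold(baseline):
    points = sweep_zero_eigenvalue(baseline, "r2", 0.001, 0.2, equilibrium="S1")
    assert len(points) == 1
    assert points[0].critical_value == pytest.approx(0.03, abs=1e-6)
    assert points[0].diagnostics["zero_eigenvalue_magnitude"] < 1e-8


def test_sweep_finds_r1_threshold(baseline):
    points = sweep_zero_eigenvalue(baseline, "r1", 0.005, 0.2, equilibrium="S2")
    assert len(points) == 1
    assert points[0].critical_value == pytest.approx(0.04, abs=1e-6)


def test_sweep_agrees_with_closed_form(baseline):
    sweep = sweep_zero_eigenvalue(baseline, "r2", 0.001, 0.2, equilibrium="S1")[0]
    closed = next(
        pt for pt in transcritical_thresholds(baseline)
        if pt.equilibrium_label == "S1" and pt.parameter == "r2"
    )
    assert sweep.critical_value == pytest.approx(closed.critical_value, abs=1e-6)


def test_sweep_nonphysical_branch_is_filtered(baseline):
    # tracking S2 over small r1 the extended algebraic branch (p1 < 0) has
    # its own det(J) zero; only the physical collision at r1 = gamma1 counts
    raw = sweep_zero_eigenvalue(baseline, "r1", 0.005, 0.2, equilibrium="S2",
                                physical_only=False)
    filtered = sweep_zero_eigenvalue(baseline, "r1", 0.005, 0.2, equilibrium="S2")
    assert len(raw) == 2 and len(filtered) == 1
    assert filtered[0].critical_value == pytest.approx(0.04, abs=1e-6)


def test_sweep_empty_range(baseline):
    assert sweep_zero_eigenvalue(baseline, "r2", 0.05, 0.2, equilibrium="S1") == []
    with pytest.raises(ValueError):
        sweep_zero_eigenvalue(baseline, "r2", 0.2, 0.05)


def test_sweep_threshold_matches_existence_flip(baseline):
    # the detected transcritical value is exactly where S2's state collides
    # with the origin
    mu = sweep_zero_eigenvalue(baseline, "r1", 0.005, 0.2, equilibrium="S2")[0].critical_value
    p1 = baseline.k1 * (mu - baseline.gamma1) / mu
    assert abs(p1) < 1e-8


def test_hopf_closed_form_baseline_has_no_admissible_candidate(baseline):
    eq = find_coexistence(baseline, seed=0)[0]
    hq = hopf_closed_form(baseline, eq)
    assert all(not c["admissible"] or c["Tr"] < 0 for c in hq.candidates)
    # no candidate wind level revives the pair: refinement reports failure
    out = refine_hopf(baseline, seed=0)
    assert not out["success"]


def test_hopf_sweep_empty_everywhere_sampled(baseline):
    # the interior trace is strictly negative, so no sweep can find a Hopf
    assert sweep_hopf(baseline, "w", 0.0, 10.0, n_grid=21, seed=0) == []
    assert sweep_hopf(baseline, "alpha1", 0.005, 0.5, n_grid=21, seed=0) == []


def test_no_complex_pair_crosses_axis_random_draws(baseline, rng):
    # spot-check the analytic no-Hopf argument on random parameter draws:
    # every interior equilibrium has all eigenvalue real parts negative or
    # at least a strictly negative pair real part
    for _ in range(25):
        theta = random_params(rng, baseline)
        for eq in find_coexistence(theta, seed=17):
            eigs = np.linalg.eigvals(jacobian(eq.state, theta))
            pair = eigs[np.abs(eigs.imag) > 1e-9]
            if len(pair) == 2:
                assert np.all(pair.real < 0)


def test_unknown_parameter_rejected(baseline):
    with pytest.raises(ValueError, match="zeta"):
        sweep_zero_eigenvalue(baseline, "zeta", 0.0, 1.0)
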