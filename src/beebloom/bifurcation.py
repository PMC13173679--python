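"""Transcritical and Hopf bifurcation detection.

Closed-form transcritical candidates (growth rate = depletion rate, and
the two printed bee-point expressions) are always cross-verified by
recomputing the Jacobian at the candidate; a generic eigenvalue-sweep
detector brackets zero crossings of det(J) along any parameter and
refines them by Brent's method, attaching Sotomayor nondegeneracy
scalars computed by numeric directional differentiation of the vector
field.

For the Hopf side, the closed-form quadratic in v = 1+w (with the
coexistence coordinates frozen, as in the quoted derivation) and a
robust complex-pair sweep are both provided.  Substituting the
equilibrium conditions into the (p, h) Jacobian block shows that
a11 = -r1*p4/k1 - alpha1*b*p4*h4/D**2 < 0 and likewise a22 < 0 at every
interior equilibrium, so the block trace is strictly negative and no
Hopf bifurcation of the coexistence point can occur anywhere in
parameter space; the sweep correctly comes back empty, and the frozen
closed form either yields no admissible root or fails the fixed-point
refinement that re-solves the equilibrium at each candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import dynamics
from .equilibria import Equilibrium, find_coexistence, honey_closed_form
from .model import jacobian, rhs
from .params import PARAM_NAMES, ModelParams
from .stability import _s5_block

logger = logging.getLogger(__name__)

EIGENVALUE_TOL = 1e-8

#: Which model equation a parameter enters (used to normalize the right
#: null eigenvector the way the standard eigenvector choices are scaled).
_PARAM_EQUATION = {
    "r1": 0, "k1": 0, "alpha1": 0, "gamma1": 0,
    "r2": 1, "k2": 1, "alpha2": 1, "gamma2": 1,
    "alpha3": 2, "beta": 2, "gamma3": 2, "c": 2,
}


@dataclass(frozen=True)
class TranscriticalDiagnostics:
    """Sotomayor scalars at a simple zero eigenvalue.

    ``s1`` must vanish, ``s2`` and ``s3`` must not, for a genuine
    transcritical point.
    """

    v: np.ndarray
    t: np.ndarray
    s1: float
    s2: float
    s3: float


@dataclass(frozen=True)
class BifurcationPoint:
    btype: str  # "transcritical" | "hopf"
    parameter: str
    critical_value: float
    equilibrium_label: str
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class HopfQuantities:
    b1: float
    b2: float
    b3: float
    b4: float
    Delta: float
    roots_v: tuple
    candidates: tuple  # dicts: w_star, Tr, Det, transversality, admissible
    note: str = ""


# ---------------------------------------------------------------------------
# helpers


def _tracked_state(label: str, theta: ModelParams) -> np.ndarray:
    """Closed-form boundary equilibrium, mathematical branch included."""
    if label == "S1":
        return np.zeros(3)
    if label == "S2":
        return np.array([theta.k1 * (theta.r1 - theta.gamma1) / theta.r1, 0.0, 0.0])
    h2 = theta.k2 * (theta.r2 - theta.gamma2) / theta.r2
    if label == "S3":
        return np.array([0.0, h2, 0.0])
    if label == "S4":
        return np.array([0.0, h2, honey_closed_form(h2, theta)])
    raise ValueError(f"sweep tracks closed-form boundary equilibria, not {label!r}")


def _set_param(theta: ModelParams, parameter: str, value: float) -> ModelParams:
    if parameter not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {parameter!r}")
    return theta.replace(**{parameter: value})


def sotomayor_scalars(
    theta: ModelParams, state: np.ndarray, parameter: str
) -> TranscriticalDiagnostics:
    """Numeric Sotomayor quantities at a (near-)singular Jacobian.

    The right/left null eigenvectors come from the Jacobian; the
    parameter derivative of the field and of the Jacobian, and the
    second directional derivative D2F(v, v), are central differences.
    The right vector is scaled so its component in the equation the
    parameter enters equals one (matching the standard eigenvector
    choices); the left vector is scaled so <t, v> = 1.
    """
    J = jacobian(state, theta)
    eigval, eigvec = np.linalg.eig(J)
    idx = int(np.argmin(np.abs(eigval)))
    v = np.real(eigvec[:, idx])
    norm_idx = _PARAM_EQUATION.get(parameter)
    if norm_idx is None or abs(v[norm_idx]) < 1e-8 * np.max(np.abs(v)):
        norm_idx = int(np.argmax(np.abs(v)))
    v = v / v[norm_idx]

    eigval_t, eigvec_t = np.linalg.eig(J.T)
    idx_t = int(np.argmin(np.abs(eigval_t)))
    t = np.real(eigvec_t[:, idx_t])
    tv = float(t @ v)
    if abs(tv) < 1e-12:
        raise ValueError("left/right null vectors are orthogonal; not a simple zero")
    t = t / tv

    mu = getattr(theta, parameter)
    d_mu = 1e-6 * (1.0 + abs(mu))
    lo_ok = mu - d_mu
    theta_hi = _set_param(theta, parameter, mu + d_mu)
    # stay inside the valid parameter domain for the backward step
    theta_lo = _set_param(theta, parameter, lo_ok) if lo_ok > 0 else theta
    span = (mu + d_mu) - getattr(theta_lo, parameter)
    F_mu = (rhs(state, theta_hi) - rhs(state, theta_lo)) / span
    dJ_mu = (jacobian(state, theta_hi) - jacobian(state, theta_lo)) / span

    eps = 1e-4 * (1.0 + float(np.linalg.norm(state)))
    d2 = (rhs(state + eps * v, theta) - 2.0 * rhs(state, theta) + rhs(state - eps * v, theta)) / eps**2

    return TranscriticalDiagnostics(
        v=v,
        t=t,
        s1=float(t @ F_mu),
        s2=float(t @ (dJ_mu @ v)),
        s3=float(t @ d2),
    )


# ---------------------------------------------------------------------------
# Transcritical


def transcritical_thresholds(theta: ModelParams) -> list[BifurcationPoint]:
    """Closed-form transcritical candidates, each eigenvalue-verified.

    Candidates: r2* = gamma2 (extinction point), r1* = gamma1 (plant
    point), and the printed bee-point expressions
    r2** = gamma2*k2/(k2-2*h2) at S3 and the analogous one at S4
    (evaluated with h2, h3 at the *current* parameters, as printed; note
    h2 itself moves with r2, so these generally fail verification and
    are returned flagged rather than reconciled).
    """
    h2 = theta.k2 * (theta.r2 - theta.gamma2) / theta.r2
    candidates = [
        ("r2", theta.gamma2, "S1"),
        ("r1", theta.gamma1, "S2"),
    ]
    for label in ("S3", "S4"):
        denom = theta.k2 - 2.0 * h2
        if abs(denom) < 1e-12 * theta.k2:
            logger.info("printed %s candidate undefined: k2 - 2*h2 = 0", label)
            candidates.append((None, float("nan"), label))
        else:
            candidates.append(("r2", theta.gamma2 * theta.k2 / denom, label))

    points = []
    for parameter, value, label in candidates:
        diag: dict = {}
        if parameter is None or not np.isfinite(value):
            diag["verified"] = False
            diag["note"] = "candidate undefined (k2 - 2*h2 = 0)"
            points.append(BifurcationPoint("transcritical", "r2", float("nan"), label, diag))
            continue
        if value <= 0:
            diag["verified"] = False
            diag["note"] = "candidate outside the parameter domain"
            points.append(BifurcationPoint("transcritical", parameter, float(value), label, diag))
            continue
        theta_c = _set_param(theta, parameter, value)
        state_c = _tracked_state(label, theta_c)
        eigs = np.linalg.eigvals(jacobian(state_c, theta_c))
        zero_mag = float(np.min(np.abs(eigs)))
        diag["zero_eigenvalue_magnitude"] = zero_mag
        diag["verified"] = zero_mag < EIGENVALUE_TOL
        if not diag["verified"]:
            diag["note"] = "no zero eigenvalue at the printed candidate"
        else:
            s = sotomayor_scalars(theta_c, state_c, parameter)
            diag["sotomayor"] = s
        points.append(BifurcationPoint("transcritical", parameter, float(value), label, diag))
    return points


def sweep_zero_eigenvalue(
    theta: ModelParams,
    parameter: str,
    lo: float,
    hi: float,
    n_grid: int = 201,
    equilibrium: str = "S1",
    physical_only: bool = True,
) -> list[BifurcationPoint]:
    """Bracket and refine zero-eigenvalue crossings of a tracked point.

    The boundary equilibrium named by ``equilibrium`` is recomputed from
    its closed form at each grid value (following the mathematical
    branch through existence boundaries, which is where the colliding
    equilibria exchange); sign changes of det(J) are bisected by
    Brent's method and Sotomayor diagnostics attached at each root.
    With ``physical_only`` (default) crossings whose tracked state lies
    outside the nonnegative octant are dropped: they are zero
    eigenvalues of the extended algebraic branch, not of a model
    equilibrium.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    if parameter not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {parameter!r}")

    def detJ(mu: float) -> float:
        theta_mu = _set_param(theta, parameter, mu)
        return float(np.linalg.det(jacobian(_tracked_state(equilibrium, theta_mu), theta_mu)))

    grid = np.linspace(lo, hi, n_grid)
    values = []
    for mu in grid:
        try:
            values.append(detJ(mu))
        except ValueError:
            logger.info("equilibrium undefined at %s=%s; segment skipped", parameter, mu)
            values.append(np.nan)

    points = []
    for i in range(n_grid - 1):
        f0, f1 = values[i], values[i + 1]
        if not (np.isfinite(f0) and np.isfinite(f1)):
            continue
        if f0 == 0.0:
            mu_c = float(grid[i])
        elif f0 * f1 < 0:
            mu_c = float(brentq(detJ, grid[i], grid[i + 1], xtol=1e-12, rtol=8.9e-16))
        else:
            continue
        theta_c = _set_param(theta, parameter, mu_c)
        state_c = _tracked_state(equilibrium, theta_c)
        if physical_only and np.min(state_c) < -1e-8:
            logger.info(
                "zero eigenvalue at %s=%s lies on a nonphysical branch (state %s); dropped",
                parameter, mu_c, state_c,
            )
            continue
        eigs = np.linalg.eigvals(jacobian(state_c, theta_c))
        diag = {
            "zero_eigenvalue_magnitude": float(np.min(np.abs(eigs))),
            "sotomayor": sotomayor_scalars(theta_c, state_c, parameter),
        }
        points.append(BifurcationPoint("transcritical", parameter, mu_c, equilibrium, diag))
    return points


# ---------------------------------------------------------------------------
# Hopf


def hopf_closed_form(theta: ModelParams, eq: Equilibrium) -> HopfQuantities:
    """The commonly quoted critical-wind quadratic with (p4, h4) frozen.

    Solves b1*v**2 + (2*b1*b2+b4)*v + (b1*b2**2+b3) = 0 for v = 1+w and
    reports each admissible root (v >= 1, i.e. w* >= 0) together with
    the frozen-block trace/determinant and the printed transversality
    expression at w*.
    """
    p4, h4 = float(eq.state[0]), float(eq.state[1])
    b1 = (
        (theta.r1 - theta.gamma1)
        + (theta.r2 - theta.gamma2)
        - 2.0 * theta.r1 * p4 / theta.k1
        - 2.0 * theta.r2 * h4 / theta.k2
    )
    b2 = theta.a * h4 + theta.b * p4
    b3 = theta.alpha1 * theta.a * h4**2 + theta.alpha2 * theta.b * p4**2
    b4 = theta.alpha1 * h4 + theta.alpha2 * p4
    if abs(b1) < 1e-12:
        return HopfQuantities(b1, b2, b3, b4, float("nan"), (), (), note="b1 = 0: closed form inapplicable")
    Delta = (2.0 * b1 * b2 + b4) ** 2 - 4.0 * b1 * (b1 * b2**2 + b3)
    if Delta < 0:
        return HopfQuantities(b1, b2, b3, b4, Delta, (), (), note="negative discriminant: no real candidate")
    sq = np.sqrt(Delta)
    roots_v = tuple(sorted(((-(2.0 * b1 * b2 + b4) + s * sq) / (2.0 * b1)) for s in (+1.0, -1.0)))
    candidates = []
    for v in roots_v:
        if v < 1.0:  # w = v - 1 must be a physical wind level
            continue
        w_star = v - 1.0
        theta_w = theta.replace(w=w_star)
        _, _, tr2, det2 = _s5_block((p4, h4), theta_w)
        transversality = (
            (theta.b * theta.alpha1 + theta.a * theta.alpha2) * p4 * h4
            - theta.alpha1 * h4 * (v + theta.a * h4)
            - theta.alpha2 * p4 * (v + theta.b * p4)
        ) / (v + b2) ** 3
        candidates.append(
            {
                "w_star": w_star,
                "Tr": tr2,
                "Det": det2,
                "transversality": transversality,
                "admissible": det2 > 0,
            }
        )
    return HopfQuantities(b1, b2, b3, b4, Delta, roots_v, tuple(candidates))


def refine_hopf(theta: ModelParams, seed: int = 0, max_iter: int = 50, tol: float = 1e-8) -> dict:
    """Fixed-point refinement: alternate equilibrium solve and closed form.

    The frozen closed form ignores that (p4, h4) depend on w; this
    iteration re-solves the coexistence point at each candidate w* and
    recomputes the quadratic until |dw*| < tol.  Returns a dict with
    ``success``, the final ``w_star`` (if any), the residual frozen-block
    trace, and the iteration history.
    """
    w = theta.w
    history = [w]
    guess = None
    for _ in range(max_iter):
        theta_w = theta.replace(w=w)
        points = find_coexistence(theta_w, guess=guess, seed=seed)
        if not points:
            return {"success": False, "note": f"no coexistence point at w={w}", "history": history}
        eq = points[0]
        guess = eq.state
        hq = hopf_closed_form(theta_w, eq)
        admissible = [c for c in hq.candidates if c["admissible"]]
        if not admissible:
            return {
                "success": False,
                "note": hq.note or "no admissible closed-form candidate",
                "history": history,
                "quantities": hq,
            }
        w_new = min(admissible, key=lambda c: abs(c["w_star"] - w))["w_star"]
        history.append(w_new)
        if abs(w_new - w) < tol:
            theta_w = theta.replace(w=w_new)
            points = find_coexistence(theta_w, guess=guess, seed=seed)
            _, _, tr2, det2 = _s5_block(points[0].state, theta_w)
            return {
                "success": True,
                "w_star": w_new,
                "Tr": tr2,
                "Det": det2,
                "history": history,
            }
        w = w_new
    return {"success": False, "note": "fixed-point iteration did not converge", "history": history}


def _complex_pair_re(theta: ModelParams, guess, seed: int):
    """(Re of the conjugate pair, equilibrium) or (None, None)."""
    points = find_coexistence(theta, guess=guess, seed=seed)
    if not points:
        return None, None
    eq = points[0]
    eigs = np.linalg.eigvals(jacobian(eq.state, theta))
    pair = eigs[np.abs(eigs.imag) > 1e-6]
    if len(pair) != 2:
        return None, eq
    return float(pair.real.mean()), eq


def sweep_hopf(
    theta: ModelParams,
    parameter: str,
    lo: float,
    hi: float,
    n_grid: int = 101,
    seed: int = 0,
    t_end_confirm: float = 3000.0,
) -> list[BifurcationPoint]:
    """Track the coexistence pair's real part and bracket sign changes.

    Continuation over the grid (each equilibrium solve is seeded by its
    neighbour); brackets where the pair collides with the real axis are
    discarded with a log record.  Refined points must pass a numeric
    transversality check, and a limit cycle is confirmed by simulating
    on the unstable side.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    grid = np.linspace(lo, hi, n_grid)
    re_vals: list[float | None] = []
    guess = None
    for mu in grid:
        re, eq = _complex_pair_re(_set_param(theta, parameter, mu), guess, seed)
        if eq is not None:
            guess = eq.state
        re_vals.append(re)

    points = []
    for i in range(n_grid - 1):
        f0, f1 = re_vals[i], re_vals[i + 1]
        if f0 is None or f1 is None or f0 * f1 >= 0:
            continue
        a_mu, b_mu, fa = float(grid[i]), float(grid[i + 1]), f0
        discarded = False
        for _ in range(80):  # bisection robust to pair collapse
            mid = 0.5 * (a_mu + b_mu)
            fm, _ = _complex_pair_re(_set_param(theta, parameter, mid), guess, seed)
            if fm is None:
                logger.info("complex pair collided with the real axis near %s=%s; bracket discarded", parameter, mid)
                discarded = True
                break
            if fa * fm <= 0:
                b_mu = mid
            else:
                a_mu, fa = mid, fm
            if b_mu - a_mu < 1e-10:
                break
        if discarded:
            continue
        mu_c = 0.5 * (a_mu + b_mu)
        theta_c = _set_param(theta, parameter, mu_c)
        re_c, eq_c = _complex_pair_re(theta_c, guess, seed)
        if re_c is None or abs(re_c) > EIGENVALUE_TOL:
            continue
        d_mu = 1e-5 * (1.0 + abs(mu_c))
        re_hi, _ = _complex_pair_re(_set_param(theta, parameter, mu_c + d_mu), eq_c.state, seed)
        re_lo, _ = _complex_pair_re(_set_param(theta, parameter, mu_c - d_mu), eq_c.state, seed)
        if re_hi is None or re_lo is None:
            continue
        slope = (re_hi - re_lo) / (2.0 * d_mu)
        if abs(slope) <= 1e-8:
            continue
        unstable_mu = mu_c + (d_mu if re_hi > 0 else -d_mu) * 0.05 * abs(mu_c) / d_mu if mu_c else mu_c + d_mu
        cycle_confirmed = False
        try:
            theta_u = _set_param(theta, parameter, unstable_mu)
            traj = dynamics.simulate(theta_u, eq_c.state * (1.0 + 1e-3), t_end=t_end_confirm)
            summary = dynamics.classify_attractor(traj)
            cycle_confirmed = summary.kind == "cycle"
        except Exception as exc:  # pragma: no cover - diagnostic path
            logger.info("cycle confirmation failed at %s=%s: %s", parameter, unstable_mu, exc)
        eigs = np.linalg.eigvals(jacobian(eq_c.state, theta_c))
        pair = eigs[np.abs(eigs.imag) > 1e-6]
        points.append(
            BifurcationPoint(
                "hopf",
                parameter,
                mu_c,
                "S5",
                {
                    "re_pair": re_c,
                    "im_pair": float(np.abs(pair.imag).mean()) if len(pair) else float("nan"),
                    "transversality_slope": slope,
                    "cycle_confirmed": cycle_confirmed,
                },
            )
        )
    return points
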