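"""Local/global stability machinery and boundedness/persistence bounds.

Three layers:

* :func:`classify_local` — eigenvalue classification of any equilibrium
  plus the named sufficient local-stability inequalities, evaluated literally;
* :func:`check_global_conditions` / :func:`lyapunov_descent` — the
  printed Lyapunov sufficient conditions per equilibrium, with
  state-dependent expressions checked at their worst case over a dense
  grid of the bounding box, and an empirical descent check of the
  corresponding Lyapunov functions;
* :func:`compute_bounds` — the printed closed-form bounds pm, hm, nm
  and persistence floors L1-L3.

A caution on the printed bounds: the closed forms for pm and hm are
transcribed exactly as commonly quoted, but they are *not* honoured by the
flow (the derivation both misapplies the comparison lemma, introducing
a spurious square root, and caps the bee density at its bare carrying
capacity although mutualism pushes it higher).  At the baseline
parameter set the coexistence attractor sits far outside the
[0,pm]x[0,hm] box.  Wherever a region that genuinely traps the
dynamics is required, use :func:`beebloom.model.attracting_box`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .equilibria import Equilibrium, boundary_equilibria, find_coexistence
from .model import attracting_box, jacobian, rhs
from .params import ModelParams

NONHYPERBOLIC_TOL = 1e-10


@dataclass(frozen=True)
class Bounds:
    """Printed upper bounds and persistence floors; ``None`` = undefined."""

    pm: float | None
    hm: float | None
    nm: float | None
    L1: float | None
    L2: float | None
    L3: float | None


@dataclass(frozen=True)
class StabilityReport:
    equilibrium_label: str
    eigenvalues: np.ndarray
    classification: str
    conditions: dict[str, bool] = field(default_factory=dict)
    a11: float | None = None
    a22: float | None = None
    trace2: float | None = None
    det2: float | None = None


@dataclass(frozen=True)
class LyapunovCheck:
    function_id: str
    n_samples: int
    descent_fraction: float
    n_rejected: int


def compute_bounds(theta: ModelParams) -> Bounds:
    """Evaluate the printed bounds pm, hm, nm and floors L1, L2, L3.

    ``pm = sqrt((r1+alpha1*k2-gamma1)*k1/r1)`` (undefined when the
    radicand is nonpositive), ``hm = sqrt(k2*(r2+alpha2*pm-gamma2)/r2)``
    (with the bee carrying capacity k2, as the derivation requires),
    ``nm = alpha3*hm/gamma3``.  ``L1``/``L2`` exist above the
    persistence thresholds; ``L3`` only when ``beta*hm > gamma3``.
    """
    pm = hm = nm = L1 = L2 = L3 = None
    rad_p = (theta.r1 + theta.alpha1 * theta.k2 - theta.gamma1) * theta.k1 / theta.r1
    if rad_p > 0:
        pm = math.sqrt(rad_p)
        rad_h = theta.k2 * (theta.r2 + theta.alpha2 * pm - theta.gamma2) / theta.r2
        if rad_h > 0:
            hm = math.sqrt(rad_h)
            nm = theta.alpha3 * hm / theta.gamma3
    if theta.r1 > theta.gamma1:
        L1 = theta.k1 * (theta.r1 - theta.gamma1) / theta.r1
    if theta.r2 > theta.gamma2:
        L2 = theta.k2 * (theta.r2 - theta.gamma2) / theta.r2
        if hm is not None and theta.beta * hm > theta.gamma3:
            L3 = (
                theta.alpha3
                * L2
                / ((1.0 + theta.w + theta.c * L2) * (theta.beta * hm - theta.gamma3))
            )
    return Bounds(pm, hm, nm, L1, L2, L3)


def persistence_check(theta: ModelParams) -> tuple[bool, bool]:
    """(r1 > gamma1, r2 > gamma2): both species self-persistent."""
    return (theta.r1 > theta.gamma1, theta.r2 > theta.gamma2)


# ---------------------------------------------------------------------------
# Local stability


def _s5_block(state, theta: ModelParams):
    """a11, a22, trace and determinant of the (p, h) block at an interior point."""
    p4, h4 = float(state[0]), float(state[1])
    v = 1.0 + theta.w
    D = v + theta.a * h4 + theta.b * p4
    a11 = (
        theta.r1
        - theta.gamma1
        - 2.0 * theta.r1 * p4 / theta.k1
        + theta.alpha1 * h4 * (v + theta.a * h4) / D**2
    )
    a22 = (
        theta.r2
        - theta.gamma2
        - 2.0 * theta.r2 * h4 / theta.k2
        + theta.alpha2 * p4 * (v + theta.b * p4) / D**2
    )
    cross = (
        theta.alpha1
        * theta.alpha2
        * p4
        * h4
        * (v + theta.b * p4)
        * (v + theta.a * h4)
        / D**4
    )
    return a11, a22, a11 + a22, a11 * a22 - cross


def _named_conditions(label: str, state, theta: ModelParams) -> dict[str, bool]:
    v = 1.0 + theta.w
    cond: dict[str, bool] = {}
    if label == "S1":
        cond["(5)"] = theta.gamma1 > theta.r1
        cond["(6)"] = theta.gamma2 > theta.r2
    elif label == "S2":
        p1 = float(state[0])
        cond["(8)"] = theta.r2 + theta.alpha2 * p1 / (v + theta.b * p1) < theta.gamma2
    elif label == "S3":
        h2 = float(state[1])
        cond["(10)"] = theta.r1 + theta.alpha1 * h2 / (v + theta.a * h2) < theta.gamma1
        cond["(11)"] = (theta.r2 - theta.gamma2) < 2.0 * theta.r2 * h2 / theta.k2
    elif label == "S4":
        h3 = float(state[1])
        cond["(13)"] = theta.r1 + theta.alpha1 * h3 / (v + theta.a * h3) < theta.gamma1
        # transcribed as printed (the eigenvalue itself carries a factor 2)
        cond["(14)"] = (theta.r2 - theta.gamma2) < theta.r2 * h3 / theta.k2
    elif label == "S5":
        a11, a22, _, det2 = _s5_block(state, theta)
        cond["(16)"] = a11 < 0 and a22 < 0
        cond["(17)"] = det2 > 0  # a11*a22 exceeds the cross term
    return cond


def classify_local(eq: Equilibrium, theta: ModelParams) -> StabilityReport:
    """Eigenvalue classification plus the printed named conditions.

    Raises ``ValueError`` for a non-existing equilibrium.  The
    classification is ``nonhyperbolic`` as soon as any eigenvalue's real
    part is within 1e-10 of zero, stable/unstable node or focus
    otherwise, and ``saddle`` for mixed signs.
    """
    if not eq.exists:
        raise ValueError(f"equilibrium {eq.label} does not exist for these parameters")
    J = jacobian(eq.state, theta)
    eigs = np.linalg.eigvals(J)
    re = eigs.real
    scale = max(1.0, float(np.max(np.abs(eigs))))
    has_complex = bool(np.any(np.abs(eigs.imag) > 1e-9 * scale))
    if np.any(np.abs(re) < NONHYPERBOLIC_TOL):
        classification = "nonhyperbolic"
    elif np.all(re < 0):
        classification = "stable focus" if has_complex else "stable node"
    elif np.all(re > 0):
        classification = "unstable focus" if has_complex else "unstable node"
    else:
        classification = "saddle"
    report = dict(
        equilibrium_label=eq.label,
        eigenvalues=eigs,
        classification=classification,
        conditions=_named_conditions(eq.label, eq.state, theta),
    )
    if eq.label == "S5":
        a11, a22, tr2, det2 = _s5_block(eq.state, theta)
        report.update(a11=a11, a22=a22, trace2=tr2, det2=det2)
    return StabilityReport(**report)


# ---------------------------------------------------------------------------
# Global (Lyapunov) sufficient conditions


def _grid_box(theta: ModelParams, bounds: Bounds | None, resolution: int):
    """Axis grids over [0,pm]x[0,hm]x[0,nm], falling back to the rigorous box."""
    if bounds is None:
        bounds = compute_bounds(theta)
    caps = attracting_box(theta)
    pm = bounds.pm if bounds.pm is not None else caps[0]
    hm = bounds.hm if bounds.hm is not None else caps[1]
    nm = bounds.nm if bounds.nm is not None else caps[2]
    p = np.linspace(0.0, pm, resolution)
    h = np.linspace(0.0, hm, resolution)
    n = np.linspace(0.0, nm, resolution)
    return p, h, n, Bounds(pm, hm, nm, bounds.L1, bounds.L2, bounds.L3)


def check_global_conditions(
    label: str,
    theta: ModelParams,
    bounds: Bounds | None = None,
    resolution: int = 50,
    seed: int = 0,
) -> dict:
    """Evaluate the printed global-stability conditions for one point.

    Each sufficient inequality is evaluated literally; expressions that
    depend on the state are required to hold at every node of a dense
    grid over the bounding box (the quoted statements leave the
    quantifier implicit).  Returns per-condition booleans plus the
    ``"conjunction"`` for the full criterion.
    """
    v = 1.0 + theta.w
    p_ax, h_ax, n_ax, B = _grid_box(theta, bounds, resolution)
    P, H = np.meshgrid(p_ax, h_ax, indexing="ij")
    D = v + theta.a * H + theta.b * P  # interaction denominator over (p, h)
    rr = theta.r1 * theta.r2
    kk = theta.k1 * theta.k2
    cond: dict[str, bool] = {}

    if label == "S1":
        cond["(20)"] = theta.r1 + B.hm * (theta.alpha1 + theta.alpha2) / v < theta.gamma1
        cond["(21)"] = theta.r2 + theta.alpha3 / v < theta.gamma2
    elif label == "S2":
        cond["(22)"] = theta.r2 + theta.alpha2 * B.pm + theta.alpha3 / v < theta.gamma2
        cond["(23)"] = bool(np.max((theta.alpha1 / D) ** 2) <= rr / kk)
    elif label == "S3":
        cond["(24)"] = theta.r1 + theta.alpha1 * B.hm / v < theta.gamma1
        cond["(25)"] = bool(np.max((theta.alpha2 / D) ** 2) <= rr / kk)
        # literal worst case over the box: must hold down to n = 0
        cond["(26)"] = (
            theta.beta > 0 and theta.alpha3 / (theta.beta * v) < float(np.min(n_ax))
        )
    elif label == "S4":
        h3 = theta.k2 * (theta.r2 - theta.gamma2) / theta.r2
        if h3 <= 0:
            return {"exists": False, "conjunction": False}
        cond["(27)"] = bool(np.max((theta.alpha2 / D) ** 2) <= rr / (2.0 * kk))
        D1 = v + theta.c * h_ax  # state-dependent honey denominator
        D2 = v + theta.c * h3
        lhs = (theta.alpha3 * v / (D1[:, None] * D2) - theta.beta * n_ax[None, :]) ** 2
        cond["(28)"] = bool(
            np.max(lhs) <= theta.r2 * (theta.beta * h3 + theta.gamma3) / (2.0 * theta.k2)
        )
    elif label == "S5":
        points = find_coexistence(theta, seed=seed)
        if not points:
            return {"exists": False, "conjunction": False}
        p4, h4, _ = points[0].state
        N2 = v + theta.a * h4 + theta.b * p4
        num = (theta.alpha1 + theta.alpha2) * v + theta.alpha1 * theta.b * p4 + theta.alpha2 * theta.a * h4
        lhs29 = (num / (D * N2)) ** 2
        rhs29 = 0.5 * (
            theta.r1 / theta.k1 + theta.alpha1 * theta.b * h4 / (D * N2)
        ) * (theta.r2 / theta.k2 + theta.alpha2 * theta.a * p4 / (D * N2))
        cond["(29)"] = bool(np.min(rhs29 - lhs29) >= 0.0)
        D1 = v + theta.c * H  # honey denominator over the (p, h) grid
        D2h = v + theta.c * h4
        rhs30 = 0.5 * (
            theta.r2 / theta.k2 + theta.alpha2 * theta.a * p4 / (D * N2)
        ) * (theta.beta * h4 + theta.gamma3)
        # joint worst case over (p, h, n)
        worst = -np.inf
        for n_val in n_ax:
            lhs30 = (theta.alpha3 * v / (D1 * D2h) - theta.beta * n_val) ** 2
            worst = max(worst, float(np.max(lhs30 - rhs30)))
        cond["(30)"] = worst <= 0.0
    else:
        raise ValueError(f"unknown equilibrium label {label!r}")

    out: dict = dict(cond)
    out["conjunction"] = all(cond.values())
    return out


# ---------------------------------------------------------------------------
# Lyapunov descent sampling

_LYAPUNOV_IDS = {"S1": "E1", "S2": "E2", "S3": "E3", "S4": "E4", "S5": "E5"}


def _reference_point(label: str, theta: ModelParams, seed: int = 0) -> np.ndarray:
    if label == "S5":
        points = find_coexistence(theta, seed=seed)
        if not points:
            raise ValueError("no coexistence point exists for these parameters")
        return points[0].state
    for eq in boundary_equilibria(theta):
        if eq.label == label:
            if not eq.exists:
                raise ValueError(f"equilibrium {label} does not exist for these parameters")
            return eq.state
    raise ValueError(f"unknown equilibrium label {label!r}")


def lyapunov_value(label: str, state, ref: np.ndarray) -> float:
    """Value of the candidate Lyapunov function E1..E5 for ``label``."""
    p, h, n = np.asarray(state, dtype=float)
    p_s, h_s, n_s = ref

    def vlog(x, x_s):
        return x - x_s - x_s * math.log(x / x_s)

    if label == "S1":
        return p + h + n
    if label == "S2":
        return vlog(p, p_s) + h + n
    if label == "S3":
        return p + vlog(h, h_s) + n
    if label == "S4":
        return p + vlog(h, h_s) + 0.5 * (n - n_s) ** 2
    if label == "S5":
        return vlog(p, p_s) + vlog(h, h_s) + 0.5 * (n - n_s) ** 2
    raise ValueError(f"unknown equilibrium label {label!r}")


def lyapunov_gradient(label: str, state, ref: np.ndarray) -> np.ndarray:
    """Analytic gradient of :func:`lyapunov_value` (log terms need x > 0)."""
    p, h, n = np.asarray(state, dtype=float)
    p_s, h_s, n_s = ref
    if label == "S1":
        return np.array([1.0, 1.0, 1.0])
    if label == "S2":
        return np.array([(p - p_s) / p, 1.0, 1.0])
    if label == "S3":
        return np.array([1.0, (h - h_s) / h, 1.0])
    if label == "S4":
        return np.array([1.0, (h - h_s) / h, n - n_s])
    if label == "S5":
        return np.array([(p - p_s) / p, (h - h_s) / h, n - n_s])
    raise ValueError(f"unknown equilibrium label {label!r}")


def lyapunov_descent(
    label: str,
    theta: ModelParams,
    n_samples: int = 500,
    seed: int = 0,
    bounds: Bounds | None = None,
) -> LyapunovCheck:
    """Fraction of sampled states where dE/dt = grad(E) . rhs < 0.

    States are drawn uniformly from the bounding box (printed box when
    defined, rigorous attracting box otherwise); coordinates entering a
    logarithm must be strictly positive, so samples touching zero there
    are rejected and redrawn.  Under parameters satisfying the
    corresponding global criterion the fraction is 1.0.
    """
    ref = _reference_point(label, theta, seed=seed)
    _, _, _, B = _grid_box(theta, bounds, resolution=2)
    caps = np.array([B.pm, B.hm, B.nm])
    needs_positive = {
        "S1": (), "S2": (0,), "S3": (1,), "S4": (1,), "S5": (0, 1),
    }[label]
    rng = np.random.default_rng(seed)
    kept = 0
    rejected = 0
    descending = 0
    while kept < n_samples:
        s = rng.uniform(0.0, 1.0, 3) * caps
        if any(s[i] <= 1e-8 * caps[i] for i in needs_positive) or np.all(s == 0):
            rejected += 1
            continue
        kept += 1
        dE = float(lyapunov_gradient(label, s, ref) @ rhs(s, theta))
        if dE < 0:
            descending += 1
    return LyapunovCheck(
        function_id=_LYAPUNOV_IDS[label],
        n_samples=n_samples,
        descent_fraction=descending / n_samples,
        n_rejected=rejected,
    )
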