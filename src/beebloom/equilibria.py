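"""Equilibrium points of the model.

Five families of fixed points exist:

* ``S1`` — total extinction (0, 0, 0), always present;
* ``S2`` — plants only, ``p1 = k1(r1-gamma1)/r1``, present when r1 > gamma1;
* ``S3`` — bees only (honey ignored), ``h2 = k2(r2-gamma2)/r2``;
* ``S4`` — plant-free with honey, ``(0, h3, n3)`` with ``h3 = h2``;
* ``S5`` — coexistence, found numerically at the intersection of the two
  reduced nullclines (the per-capita growth rates of p and h).

The authoritative coexistence solver is direct 2-D multi-start root
finding; the cubic resultant in :func:`coexistence_cubic` is a
transcription of a printed closed form that is kept only as a
cross-check and is not asserted to be correct (its intermediate
constants carry evident typos; see the consistency helpers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root
from scipy.stats import qmc

from .model import attracting_box, rhs
from .params import ModelParams

#: Residual below which a candidate is accepted as a genuine fixed point.
RESIDUAL_TOL = 1e-9

#: Coordinates below this are not counted as strictly positive.
POSITIVITY_TOL = 1e-9


@dataclass(frozen=True)
class Equilibrium:
    """A labelled fixed point with its existence flag and residual."""

    label: str
    state: np.ndarray
    exists: bool
    residual: float
    note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "state", np.asarray(self.state, dtype=float))


def _make_equilibrium(label: str, state, exists: bool, theta: ModelParams, note: str = "") -> Equilibrium:
    state = np.asarray(state, dtype=float)
    if np.all(state >= 0):
        residual = float(np.max(np.abs(rhs(state, theta))))
    else:  # mathematical branch outside the model domain
        residual = float("nan")
    return Equilibrium(label, state, exists, residual, note)


def honey_closed_form(h: float, theta: ModelParams) -> float:
    """Honey level n = alpha3*h / ((1+w+c*h)(beta*h+gamma3)) sustained by ``h`` bees."""
    return theta.alpha3 * h / (
        (1.0 + theta.w + theta.c * h) * (theta.beta * h + theta.gamma3)
    )


def boundary_equilibria(theta: ModelParams, allow_negative: bool = False) -> list[Equilibrium]:
    """Closed-form boundary equilibria S1-S4.

    Non-existing points (growth rate below depletion rate) are returned
    with ``exists=False``; their coordinates are clamped into the model
    domain unless ``allow_negative`` is set, in which case the raw
    mathematical branch (possibly negative) is reported, which is what
    bifurcation sweeps track through an existence boundary.
    """
    p1 = theta.k1 * (theta.r1 - theta.gamma1) / theta.r1
    h2 = theta.k2 * (theta.r2 - theta.gamma2) / theta.r2
    plants_exist = theta.r1 > theta.gamma1
    bees_exist = theta.r2 > theta.gamma2
    if not allow_negative:
        p1 = max(p1, 0.0)
        h2 = max(h2, 0.0)
    n3 = honey_closed_form(h2, theta) if (bees_exist or allow_negative) else 0.0
    s3 = _make_equilibrium("S3", (0.0, h2, 0.0), bees_exist, theta)
    if s3.exists and not s3.residual < RESIDUAL_TOL:
        # The bees-only point with zero honey is a fixed point only when
        # honey production vanishes (alpha3*h2 = 0); otherwise honey
        # accumulates and the genuine bees-only equilibrium is S4.
        s3 = Equilibrium(
            "S3", s3.state, False, s3.residual,
            note="not a fixed point: honey production is nonzero at n=0 (see S4)",
        )
    return [
        _make_equilibrium("S1", (0.0, 0.0, 0.0), True, theta),
        _make_equilibrium("S2", (p1, 0.0, 0.0), plants_exist, theta),
        s3,
        _make_equilibrium("S4", (0.0, h2, n3), bees_exist, theta),
    ]


def nullcline_residuals(x, theta: ModelParams) -> np.ndarray:
    """Per-capita growth rates of p and h (the reduced nullcline system)."""
    p, h = x
    D = 1.0 + theta.w + theta.a * h + theta.b * p
    f = theta.r1 * (1.0 - p / theta.k1) + theta.alpha1 * h / D - theta.gamma1
    g = theta.r2 * (1.0 - h / theta.k2) + theta.alpha2 * p / D - theta.gamma2
    return np.array([f, g])


def find_coexistence(
    theta: ModelParams,
    guess=None,
    n_starts: int = 16,
    seed: int = 0,
    full_output: bool = False,
):
    """Locate interior equilibria S5 = (p4, h4, n4) with p4, h4 > 0.

    Multi-start 2-D root finding of the reduced nullcline system over
    the rigorous attracting box; starts come from a seeded
    low-discrepancy (Halton) design plus the decoupled closed forms and
    the optional ``guess``.  Distinct positive roots are merged at
    tolerance 1e-6 and returned ordered by p4.  The honey coordinate
    follows from its closed form.  Returns a (possibly empty) list; with
    ``full_output`` also a diagnostics dict.
    """
    p_cap, h_cap, _ = attracting_box(theta)
    starts: list[np.ndarray] = []
    if guess is not None:
        g = np.asarray(guess, dtype=float)
        starts.append(g[:2])
    # decoupled closed-form corner: where each species would settle alone
    starts.append(
        np.array(
            [
                max(theta.k1 * (theta.r1 - theta.gamma1) / theta.r1, 0.1 * theta.k1),
                max(theta.k2 * (theta.r2 - theta.gamma2) / theta.r2, 0.1 * theta.k2),
            ]
        )
    )
    sampler = qmc.Halton(d=2, scramble=True, seed=seed)
    unit = sampler.random(n_starts)
    starts.extend(np.column_stack([unit[:, 0] * p_cap, unit[:, 1] * h_cap]))

    roots: list[np.ndarray] = []
    n_converged = 0
    for x0 in starts:
        sol = root(nullcline_residuals, x0, args=(theta,), method="hybr", tol=1e-13)
        if not sol.success:
            continue
        n_converged += 1
        p4, h4 = sol.x
        if p4 <= POSITIVITY_TOL or h4 <= POSITIVITY_TOL:
            continue
        if p4 > 2.0 * p_cap or h4 > 2.0 * h_cap:
            continue
        if np.max(np.abs(nullcline_residuals(sol.x, theta))) > 1e-10:
            continue
        if not any(
            abs(p4 - r[0]) < 1e-6 * (1 + abs(p4)) and abs(h4 - r[1]) < 1e-6 * (1 + abs(h4))
            for r in roots
        ):
            roots.append(np.array([p4, h4]))

    points = []
    for p4, h4 in sorted(roots, key=lambda r: r[0]):
        n4 = honey_closed_form(h4, theta)
        eq = _make_equilibrium("S5", (p4, h4, n4), True, theta)
        if eq.residual < RESIDUAL_TOL:
            points.append(eq)
    diagnostics = {
        "n_starts": len(starts),
        "n_converged": n_converged,
        "n_roots": len(points),
        "search_box": (p_cap, h_cap),
    }
    if full_output:
        return points, diagnostics
    return points


# ---------------------------------------------------------------------------
# Printed cubic cross-check


@dataclass(frozen=True)
class CubicCoeffs:
    """Coefficients of the printed coexistence resultant A0 p^3 + ... + A3."""

    z1: float
    z2: float
    z3: float
    A0: float
    A1: float
    A2: float
    A3: float
    sign_pattern: tuple[int, ...] = field(default=())

    @property
    def sign_changes(self) -> int:
        signs = [s for s in self.sign_pattern if s != 0]
        return sum(1 for u, v in zip(signs, signs[1:]) if u * v < 0)

    @property
    def unique_positive_root_guaranteed(self) -> bool:
        """Any of the printed Descartes condition sets holds."""
        A0, A1, A2, A3 = self.A0, self.A1, self.A2, self.A3
        return (
            (A0 > 0 and A2 < 0 and A3 < 0)
            or (A0 > 0 and A1 > 0 and A3 < 0)
            or (A0 < 0 and A2 > 0 and A3 > 0)
            or (A0 < 0 and A1 < 0 and A2 > 0 and A3 > 0)
        )


def cubic_coefficients(theta: ModelParams) -> CubicCoeffs:
    """Evaluate the printed intermediate constants and cubic coefficients.

    ``z1`` and ``z2`` are transcribed exactly as printed; ``z3`` is
    evaluated as ``k1*(alpha1 + a*(r1-gamma1))`` because the printed
    expression carries a stray state variable.  These coefficients are a
    cross-check only and are not asserted against the nullcline solver.
    """
    r1, r2 = theta.r1, theta.r2
    k1, k2 = theta.k1, theta.k2
    w, a, b = theta.w, theta.a, theta.b
    g1, g2 = theta.gamma1, theta.gamma2
    al2 = theta.alpha2

    z1 = r1 * (1.0 + w - k1 * b) + g1 * k1 * b
    z2 = k1 * (g1 * (1.0 + w) - (r1 + w))
    z3 = k1 * (theta.alpha1 + a * (r1 - g1))

    A0 = r1 * (r1 * a * (r2 * b + r2 * b * w + al2 * a * k2) - r2 * b * (b * z3 + a * z1))
    A1 = (
        (r2 - g2) * (r1 * (a * k2 * (r1 + w * a * r1 - b * z3 - a * z1)))
        + r2 * (a * z1 + a * w * z1 - b * w - b * w * z3 - a * b * z2)
        - r2 * b * z1 * z3
        - r2 * a * z1**2
        - a * r1 * al2 * z3 * k2
        - a * al2 * r1 * z3 * k2
    )
    A2 = (
        (r2 - g2)
        * (z3 * k2 * (z3 * b - r1 - 2.0 * r1 * a * w + a * z1 - r1 * a) - k2 * r1 * a**2 * z2)
        + r2
        * (
            z2 * (a * (r1 - 2.0 * z1 + w * r1) - b * z3)
            + z3 * (k2 * al2 - r1 - z1 * w)
        )
    )
    A3 = (r2 - g2) * (z3 * (z3 - k2 * (w * z3 - a * z2))) - r2 * z2 * (z3 + w * z3 + a * z2)

    sign_pattern = tuple(int(np.sign(A)) for A in (A0, A1, A2, A3))
    return CubicCoeffs(z1, z2, z3, A0, A1, A2, A3, sign_pattern)


def h_from_p(p4: float, theta: ModelParams):
    """Recover h4 from a plant coordinate via the p-nullcline closed form.

    Uses the re-derived constant ``z2 = k1*(gamma1-r1)*(1+w)`` (the
    printed one is dimensionally inconsistent).  Returns ``None`` when
    the denominator ``z3 - a*r1*p4`` is degenerate.
    """
    z1 = theta.r1 * (1.0 + theta.w - theta.k1 * theta.b) + theta.gamma1 * theta.k1 * theta.b
    z2 = theta.k1 * (theta.gamma1 - theta.r1) * (1.0 + theta.w)
    z3 = theta.k1 * (theta.alpha1 + theta.a * (theta.r1 - theta.gamma1))
    denom = z3 - theta.a * theta.r1 * p4
    scale = abs(z3) + abs(theta.a * theta.r1 * p4) + 1.0
    if abs(denom) < 1e-12 * scale:
        return None
    return (theta.r1 * theta.b * p4**2 + z1 * p4 + z2) / denom


def coexistence_cubic(theta: ModelParams):
    """Printed cubic plus its real positive roots.

    Returns ``(coeffs, roots)`` where ``roots`` is a list of dicts with
    the plant coordinate, the recovered ``h4`` (or ``None`` when the
    recovery denominator degenerates), and a ``degenerate`` flag.
    """
    coeffs = cubic_coefficients(theta)
    poly = np.array([coeffs.A0, coeffs.A1, coeffs.A2, coeffs.A3])
    if np.allclose(poly, 0.0):
        return coeffs, []
    raw = np.roots(poly)
    scale = np.max(np.abs(raw)) if len(raw) else 1.0
    roots = []
    for z in raw:
        if abs(z.imag) > 1e-9 * max(scale, 1.0) or z.real <= POSITIVITY_TOL:
            continue
        p4 = float(z.real)
        h4 = h_from_p(p4, theta)
        roots.append({"p4": p4, "h4": h4, "degenerate": h4 is None})
    roots.sort(key=lambda r: r["p4"])
    return coeffs, roots


def cross_validate_cubic(theta: ModelParams, seed: int = 0) -> dict:
    """Compare cubic roots with the nullcline solver; report, never hide.

    Returns a dict with both root lists and the matched/unmatched
    pairing at absolute tolerance 1e-6 on p4.
    """
    points = find_coexistence(theta, seed=seed)
    _, cubic_roots = coexistence_cubic(theta)
    solver_p = [float(pt.state[0]) for pt in points]
    cubic_p = [r["p4"] for r in cubic_roots]
    matched = [
        (ps, pc)
        for ps in solver_p
        for pc in cubic_p
        if abs(ps - pc) < 1e-6 * (1.0 + abs(ps))
    ]
    return {
        "solver_roots": solver_p,
        "cubic_roots": cubic_p,
        "matched": matched,
        "consistent": len(matched) == len(solver_p) == len(cubic_p),
    }
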