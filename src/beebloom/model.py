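"""The plant-honeybee-honey vector field and its analytic Jacobian.

The model reads

.. math::

    \\dot p &= r_1 p (1 - p/k_1)
              + \\frac{\\alpha_1 h p}{1 + w + a h + b p} - \\gamma_1 p \\\\
    \\dot h &= r_2 h (1 - h/k_2)
              + \\frac{\\alpha_2 h p}{1 + w + a h + b p} - \\gamma_2 h \\\\
    \\dot n &= \\frac{\\alpha_3 h}{1 + w + c h} - \\beta n h - \\gamma_3 n

The mutualistic interaction is a Beddington-DeAngelis response whose
common denominator :math:`1 + w + a h + b p` is inflated by the wind
level ``w``: wind attenuates both the pollination benefit to plants and
the nutrient gain of bees, and likewise the honey-production term.
Honey ``n`` is slaved to the populations: it does not feed back into
either of the first two equations.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams, as_state_array


def wind_efficiency(w: float) -> float:
    """Efficiency factor 1/(1+w) of the mutualistic interaction.

    Strictly decreasing in the wind level ``w``; equals 1 in still air
    and tends to 0 in the high-wind limit.
    """
    w = float(w)
    if w < 0:
        raise ValueError(f"wind level must be nonnegative, got {w}")
    return 1.0 / (1.0 + w)


def rhs(state, theta: ModelParams) -> np.ndarray:
    """Time derivatives (dp/dt, dh/dt, dn/dt) at ``state``.

    ``state`` may be a :class:`~beebloom.params.State` or any length-3
    sequence.  With nonnegative inputs both denominators are >= 1, so no
    regularization is needed.
    """
    p, h, n = as_state_array(state)
    D = 1.0 + theta.w + theta.a * h + theta.b * p
    dp = theta.r1 * p * (1.0 - p / theta.k1) + theta.alpha1 * h * p / D - theta.gamma1 * p
    dh = theta.r2 * h * (1.0 - h / theta.k2) + theta.alpha2 * h * p / D - theta.gamma2 * h
    dn = theta.alpha3 * h / (1.0 + theta.w + theta.c * h) - theta.beta * n * h - theta.gamma3 * n
    return np.array([dp, dh, dn])


def jacobian(state, theta: ModelParams) -> np.ndarray:
    """Analytic 3x3 Jacobian of :func:`rhs` at ``state``.

    Entries (1,3) and (2,3) are identically zero (honey does not enter
    the population equations); entry (3,3) is ``-beta*h - gamma3``.
    """
    p, h, n = as_state_array(state)
    v = 1.0 + theta.w
    D = v + theta.a * h + theta.b * p
    D2 = D * D
    Dc = v + theta.c * h

    a11 = (
        theta.r1
        - theta.gamma1
        - 2.0 * theta.r1 * p / theta.k1
        + theta.alpha1 * h * (v + theta.a * h) / D2
    )
    a12 = theta.alpha1 * p * (v + theta.b * p) / D2
    a21 = theta.alpha2 * h * (v + theta.a * h) / D2
    a22 = (
        theta.r2
        - theta.gamma2
        - 2.0 * theta.r2 * h / theta.k2
        + theta.alpha2 * p * (v + theta.b * p) / D2
    )
    a32 = theta.alpha3 * v / (Dc * Dc) - theta.beta * n
    a33 = -theta.beta * h - theta.gamma3
    return np.array(
        [
            [a11, a12, 0.0],
            [a21, a22, 0.0],
            [0.0, a32, a33],
        ]
    )


def attracting_box(theta: ModelParams) -> tuple[float, float, float]:
    """A rigorous attracting box (p_cap, h_cap, n_cap) for the dynamics.

    Uses the interference saturation of the Beddington-DeAngelis term:
    ``alpha1*h/D <= alpha1/a`` (for ``a > 0``) and ``alpha2*p/D <=
    alpha2/b`` (for ``b > 0``), which turns each population equation
    into a logistic comparison ODE with an explicit limsup.  When an
    interference coefficient vanishes the partner's cap is substituted
    through the ``1+w`` floor of the denominator; if both vanish the
    mutualism is unsaturated and a documented heuristic multiple of the
    carrying capacity is returned.

    These caps, unlike the closed-form report of
    :func:`beebloom.stability.compute_bounds`, are honoured by the flow
    and are used as root-search domains and sampling boxes.
    """
    v = 1.0 + theta.w
    if theta.b > 0:
        h_boost = theta.alpha2 / theta.b
        h_cap = theta.k2 * max(theta.r2 - theta.gamma2 + h_boost, 0.0) / theta.r2
        h_cap = max(h_cap, theta.k2)
    else:
        h_cap = None

    if theta.a > 0:
        p_boost = theta.alpha1 / theta.a
    elif h_cap is not None:
        p_boost = theta.alpha1 * h_cap / v
    else:
        p_boost = None
    if p_boost is not None:
        p_cap = theta.k1 * max(theta.r1 - theta.gamma1 + p_boost, 0.0) / theta.r1
        p_cap = max(p_cap, theta.k1)
    else:
        p_cap = 10.0 * theta.k1

    if h_cap is None:
        if theta.a > 0:
            h_cap = theta.k2 * max(
                theta.r2 - theta.gamma2 + theta.alpha2 * p_cap / v, 0.0
            ) / theta.r2
            h_cap = max(h_cap, theta.k2)
        else:
            h_cap = 10.0 * theta.k2

    n_cap = theta.alpha3 * h_cap / ((v + theta.c * h_cap) * theta.gamma3)
    return (p_cap, h_cap, n_cap)
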