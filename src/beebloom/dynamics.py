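"""Trajectory integration, attractor classification, parameter sweeps.

Defaults are tuned to the slowest baseline rate (the honey-loss rate
gamma3 = 0.0018 relaxes on a ~500-time-unit scale): adaptive stiff-
capable integration at rtol=1e-8/atol=1e-10 to t_end=5000, discarding
the first half of the record as transient before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .model import rhs
from .params import ModelParams, Trajectory, as_state_array

EXTINCTION_TOL = 1e-5


class SimulationError(RuntimeError):
    """Integration failed; carries the last valid time reached."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time {last_time})")
        self.last_time = last_time


@dataclass(frozen=True)
class AttractorSummary:
    kind: str  # point | cycle | aperiodic | boundary-collapse
    final_state: np.ndarray
    extrema: dict[str, tuple[float, float]]  # per-variable (min, max) post-transient
    period: float | None = None
    collapsed_components: tuple[str, ...] = ()
    note: str = ""


@dataclass(frozen=True)
class SweepResult:
    parameter: str
    grid: np.ndarray
    summaries: list  # AttractorSummary | None per grid value
    extrema: list  # per grid value: {var: (min, max, mean)}
    errors: dict[int, str] = field(default_factory=dict)


def simulate(
    theta: ModelParams,
    init,
    t_end: float = 5000.0,
    dt_out: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate from ``init`` and sample the solution every ``dt_out``.

    Components that dip below zero by floating-point error are clamped
    to zero in the reported trajectory only; an excursion below
    ``-10*atol`` inside the solver is treated as a failure.
    """
    init = as_state_array(init)
    if np.any(init < 0):
        raise ValueError("initial state must be nonnegative")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if dt_out is None:
        dt_out = t_end / 5000.0
    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_eval[-1] = min(t_eval[-1], t_end)
    sol = solve_ivp(
        lambda t, s: rhs(s, theta),
        (0.0, t_end),
        init,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(sol.message, float(sol.t[-1]) if len(sol.t) else 0.0)
    states = sol.y.T
    worst = float(states.min(initial=0.0))
    if worst < -10.0 * atol:
        raise SimulationError(f"state left the nonnegative octant ({worst})", float(sol.t[-1]))
    return Trajectory(times=sol.t, states=np.clip(states, 0.0, None))


def _refined_peaks(t: np.ndarray, y: np.ndarray):
    """Peak times/heights with quadratic interpolation through the 3 samples."""
    idx, _ = find_peaks(y)
    times, heights = [], []
    for i in idx:
        if i == 0 or i == len(y) - 1:
            continue
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = y0 - 2.0 * y1 + y2
        delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        dt = t[i + 1] - t[i]
        times.append(t[i] + delta * dt)
        heights.append(y1 - 0.25 * (y0 - y2) * delta)
    return np.array(times), np.array(heights)


def classify_attractor(
    traj: Trajectory,
    transient_fraction: float = 0.5,
    point_tol: float = 1e-6,
    cycle_tol: float = 1e-3,
    extinction_tol: float = EXTINCTION_TOL,
) -> AttractorSummary:
    """Classify the post-transient behaviour of a trajectory.

    A flat tail (per-variable standard deviation below
    ``point_tol*(1+|mean|)``) is a point attractor, or a boundary
    collapse when components sit below the extinction tolerance.
    Otherwise peaks of the most strongly oscillating variable are
    analysed: near-equal successive peak heights (relative spread below
    ``cycle_tol``) make a cycle with the mean peak spacing as period
    estimate; anything else is reported aperiodic.
    """
    start = int(len(traj.times) * transient_fraction)
    t = traj.times[start:]
    X = traj.states[start:]
    means = X.mean(axis=0)
    stds = X.std(axis=0)
    if len(t) < 1000:
        var0 = int(np.argmax(stds / (1.0 + np.abs(means)))) if len(t) else 0
        n_peaks = len(_refined_peaks(t, X[:, var0])[0]) if len(t) > 2 else 0
        if n_peaks < 20:
            raise ValueError(
                "post-transient window too short to classify; integrate longer"
            )
    names = ("p", "h", "n")
    extrema = {v: (float(X[:, i].min()), float(X[:, i].max())) for i, v in enumerate(names)}
    collapsed = tuple(v for i, v in enumerate(names) if X[:, i].max() < extinction_tol)

    if np.all(stds < point_tol * (1.0 + np.abs(means))):
        kind = "boundary-collapse" if collapsed else "point"
        return AttractorSummary(kind, traj.final_state(), extrema, None, collapsed)

    # the most strongly oscillating variable carries the peak analysis
    rel = stds / (1.0 + np.abs(means))
    var = int(np.argmax(rel))
    times, heights = _refined_peaks(t, X[:, var])
    if len(heights) < 3:
        return AttractorSummary(
            "aperiodic", traj.final_state(), extrema, None, collapsed,
            note="fewer than 3 peaks post-transient; possibly a slow transient",
        )
    spread = (heights.max() - heights.min()) / (1.0 + abs(float(np.mean(heights))))
    if spread < cycle_tol:
        period = float(np.mean(np.diff(times)))
        return AttractorSummary("cycle", traj.final_state(), extrema, period, collapsed)
    return AttractorSummary("aperiodic", traj.final_state(), extrema, None, collapsed)


def parameter_sweep(
    theta: ModelParams,
    parameter: str,
    lo: float,
    hi: float,
    n_grid: int,
    init=(1.0, 1.0, 1.0),
    t_end: float = 5000.0,
    continuation: bool = False,
    **simulate_kwargs,
) -> SweepResult:
    """Simulate-and-classify over a parameter grid (bifurcation diagram data).

    With ``continuation`` the final state at one grid value seeds the
    next (hysteresis-friendly); otherwise every run starts from
    ``init``.  Per-grid-point failures are recorded, not raised.
    """
    if n_grid < 1:
        raise ValueError("n_grid must be >= 1")
    grid = np.linspace(lo, hi, n_grid)
    summaries: list = []
    extrema: list = []
    errors: dict[int, str] = {}
    current = as_state_array(init)
    for i, mu in enumerate(grid):
        try:
            theta_mu = theta.replace(**{parameter: float(mu)})
            traj = simulate(theta_mu, current, t_end=t_end, **simulate_kwargs)
            summary = classify_attractor(traj)
            start = int(len(traj.times) * 0.5)
            X = traj.states[start:]
            stats = {
                v: (float(X[:, j].min()), float(X[:, j].max()), float(X[:, j].mean()))
                for j, v in enumerate(("p", "h", "n"))
            }
            summaries.append(summary)
            extrema.append(stats)
            if continuation:
                current = traj.final_state()
        except Exception as exc:
            errors[i] = str(exc)
            summaries.append(None)
            extrema.append(None)
            if continuation:
                current = as_state_array(init)
    return SweepResult(parameter, grid, summaries, extrema, errors)
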