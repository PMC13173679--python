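"""PRCC sensitivity of the coexistence point to all fifteen parameters.

Latin-hypercube samples around a baseline (default +-25%; the original
analysis states no ranges) are pushed through the coexistence solver;
partial rank correlation coefficients between each parameter and each
of (p4, h4, n4) are computed by rank-transforming every column and
correlating the residuals of the two rank regressions against all
other parameters.  Draws for which no coexistence point exists are
dropped and counted: silent dropping would bias the coefficients, so
the count is part of the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc, rankdata

from .equilibria import find_coexistence
from .params import PARAM_NAMES, ModelParams

OUTPUT_NAMES = ("p4", "h4", "n4")


@dataclass(frozen=True)
class PRCCResult:
    parameters: tuple[str, ...]
    outputs: tuple[str, ...]
    coefficients: pd.DataFrame  # rows = parameters, columns = outputs
    n_samples: int
    n_used: int
    n_discarded: int
    seed: int
    ranges: dict[str, tuple[float, float]]

    def sign_summary(self) -> pd.DataFrame:
        """+1 / -1 / 0 per (parameter, output): monotone direction."""
        return self.coefficients.apply(np.sign).astype(int)


def latin_hypercube(ranges: dict[str, tuple[float, float]], n: int, seed: int) -> pd.DataFrame:
    """Stratified LHS design: one sample per equal-probability stratum.

    Each parameter's n values occupy distinct strata of its [lo, hi]
    range, permuted independently; fully determined by ``seed``.
    """
    if n < 10:
        raise ValueError("need at least 10 samples")
    names = list(ranges)
    bounds = np.array([ranges[name] for name in names], dtype=float)
    if np.any(bounds[:, 0] >= bounds[:, 1]):
        bad = [names[i] for i in np.where(bounds[:, 0] >= bounds[:, 1])[0]]
        raise ValueError(f"need lo < hi for parameters: {bad}")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    scaled = qmc.scale(unit, bounds[:, 0], bounds[:, 1])
    return pd.DataFrame(scaled, columns=names)


def _rank_residuals(R: np.ndarray, j: int) -> tuple[np.ndarray, np.ndarray]:
    """Residuals of rank-column j and of the last column (the output)
    after regressing each on all other rank-columns plus an intercept."""
    d = R.shape[1] - 1
    others = [k for k in range(d) if k != j]
    Z = np.column_stack([np.ones(len(R)), R[:, others]])
    coef_x, *_ = np.linalg.lstsq(Z, R[:, j], rcond=None)
    coef_y, *_ = np.linalg.lstsq(Z, R[:, -1], rcond=None)
    return R[:, j] - Z @ coef_x, R[:, -1] - Z @ coef_y


def prcc(samples: pd.DataFrame, outputs: pd.DataFrame, seed: int = 0,
         ranges: dict | None = None) -> PRCCResult:
    """Partial rank correlation of every input column with every output.

    Output rows containing NaN (no coexistence point for that draw) are
    discarded and counted.  Raises when fewer than (n_parameters + 2)
    rows survive.
    """
    names = tuple(samples.columns)
    out_names = tuple(outputs.columns)
    keep = ~outputs.isna().any(axis=1).to_numpy()
    n_total = len(samples)
    X = samples.to_numpy()[keep]
    Y = outputs.to_numpy()[keep]
    n_used = len(X)
    if n_used < len(names) + 2:
        raise ValueError(
            f"only {n_used} usable samples for {len(names)} parameters; need at least {len(names) + 2}"
        )
    Rx = np.column_stack([rankdata(X[:, j]) for j in range(X.shape[1])])
    coeffs = np.empty((len(names), len(out_names)))
    for m in range(len(out_names)):
        R = np.column_stack([Rx, rankdata(Y[:, m])])
        for j in range(len(names)):
            res_x, res_y = _rank_residuals(R, j)
            denom = np.linalg.norm(res_x) * np.linalg.norm(res_y)
            coeffs[j, m] = 0.0 if denom == 0 else float(res_x @ res_y / denom)
    frame = pd.DataFrame(coeffs, index=list(names), columns=list(out_names))
    return PRCCResult(
        parameters=names,
        outputs=out_names,
        coefficients=frame,
        n_samples=n_total,
        n_used=n_used,
        n_discarded=n_total - n_used,
        seed=seed,
        ranges=ranges or {},
    )


def coexistence_outputs(samples: pd.DataFrame, guess=None, seed: int = 0) -> pd.DataFrame:
    """Solve the coexistence point per sample row; NaN rows where none."""
    rows = []
    current_guess = guess
    for _, row in samples.iterrows():
        theta = ModelParams(**{k: float(row[k]) for k in PARAM_NAMES})
        points = find_coexistence(theta, guess=current_guess, n_starts=8, seed=seed)
        if points:
            state = points[0].state
            rows.append(state)
        else:
            rows.append(np.full(3, np.nan))
    return pd.DataFrame(rows, columns=list(OUTPUT_NAMES))


def sensitivity_report(
    theta_baseline: ModelParams,
    spread_fraction: float = 0.25,
    n: int = 1000,
    seed: int = 0,
) -> PRCCResult:
    """Full pipeline: LHS around the baseline -> coexistence -> PRCC.

    Ranges are baseline*(1 -+ spread_fraction) per parameter.
    """
    if not 0.0 < spread_fraction < 1.0:
        raise ValueError("spread_fraction must be in (0, 1)")
    ranges = {
        name: (
            getattr(theta_baseline, name) * (1.0 - spread_fraction),
            getattr(theta_baseline, name) * (1.0 + spread_fraction),
        )
        for name in PARAM_NAMES
    }
    samples = latin_hypercube(ranges, n, seed)
    baseline_points = find_coexistence(theta_baseline, seed=seed)
    guess = baseline_points[0].state if baseline_points else None
    outputs = coexistence_outputs(samples, guess=guess, seed=seed)
    return prcc(samples, outputs, seed=seed, ranges=ranges)
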