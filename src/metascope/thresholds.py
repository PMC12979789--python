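"""Ecological thresholds by two-breakpoint segmented regression.

The fitness-vs-phi prediction curve (log-odds scale) is approximated by a
continuous piecewise-linear model with two estimated breakpoints: the lower
one (phi_crit) marks where further declines in phi stop costing fitness, the
upper one (phi_stable) where further gains stop helping.  Estimation is the
classic iterative-linearization scheme (gap-variable update) started from a
coarse grid search; an exhaustive grid oracle is provided for verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .fitmodels import FittedSmoothModel, predict_curve


@dataclass
class SegmentedFit:
    breakpoints: tuple
    ci_bp1: tuple
    ci_bp2: tuple
    slopes: tuple           # slopes of the three segments
    intercept: float
    r_squared: float
    relative_se: float
    converged: bool
    sse: float = np.nan


class DegenerateBreakpointsError(ValueError):
    """No identifiable breakpoints (e.g., the input is a straight line)."""


def _piecewise_design(x: np.ndarray, bps) -> np.ndarray:
    cols = [np.ones_like(x), x] + [np.clip(x - b, 0.0, None) for b in bps]
    return np.column_stack(cols)


def _exact_ls(x, y, bps):
    X = _piecewise_design(x, bps)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def brute_force_breakpoints(x, y, grid: np.ndarray | None = None, n_grid: int = 50):
    """Exhaustive search over candidate breakpoint pairs.

    For every ordered pair on the candidate grid the continuous
    piecewise-linear model is solved exactly; returns (bp1, bp2, sse) at the
    global minimum.  Intended as a verification oracle for small grids.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if grid is None:
        interior = np.linspace(0.02, 0.98, n_grid)
        grid = np.quantile(x, interior)
    grid = np.unique(grid)
    best = (np.nan, np.nan, np.inf)
    for i in range(len(grid) - 1):
        for j in range(i + 1, len(grid)):
            _, sse = _exact_ls(x, y, (grid[i], grid[j]))
            if sse < best[2]:
                best = (float(grid[i]), float(grid[j]), sse)
    return best


def fit_segmented(
    x,
    y,
    n_breakpoints: int = 2,
    tol: float = 1e-8,
    max_iter: int = 50,
    init: tuple | None = None,
    n_init_grid: int = 20,
) -> SegmentedFit:
    """Continuous piecewise-linear least squares with estimated breakpoints.

    Iterative linearization: at the current breakpoints the model gains
    per-breakpoint gap covariates whose coefficients drive the breakpoint
    update; convergence is declared when the breakpoints stop moving.
    Confidence intervals use the delta method (SE of the gap coefficient
    over the slope change).  ``relative_se`` is the residual standard error
    divided by the mean absolute fitted value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 20:
        raise ValueError("need at least 20 points for a two-breakpoint fit")
    if n_breakpoints != 2:
        raise ValueError("only two breakpoints are supported")
    order = np.argsort(x)
    x, y = x[order], y[order]

    # degenerate input: a straight line has no identifiable breakpoints
    lin_beta, lin_sse = np.polynomial.polynomial.polyfit(x, y, 1, full=True)[0], None
    lin_resid = y - (lin_beta[0] + lin_beta[1] * x)
    lin_sse = float(lin_resid @ lin_resid)
    yscale = max(float(np.var(y)) * len(y), 1e-12)

    if init is None:
        qs = np.quantile(x, np.linspace(0.05, 0.95, n_init_grid))
        bp1, bp2, _ = brute_force_breakpoints(x, y, grid=qs)
    else:
        bp1, bp2 = init
    if lin_sse <= 1e-10 * yscale:
        raise DegenerateBreakpointsError("input is a straight line: no breakpoints")

    grid_step = np.median(np.diff(np.unique(x)))
    lo, hi = x.min(), x.max()
    converged = False
    beta = se_gamma = None
    for _ in range(max_iter):
        U1 = np.clip(x - bp1, 0.0, None)
        U2 = np.clip(x - bp2, 0.0, None)
        V1 = -(x > bp1).astype(float)
        V2 = -(x > bp2).astype(float)
        X = np.column_stack([np.ones_like(x), x, U1, U2, V1, V2])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        d1, d2, g1, g2 = beta[2], beta[3], beta[4], beta[5]
        if abs(d1) < 1e-12 or abs(d2) < 1e-12:
            break
        step1, step2 = g1 / d1, g2 / d2
        new1 = float(np.clip(bp1 + step1, lo + 1e-9, hi - 1e-9))
        new2 = float(np.clip(bp2 + step2, lo + 1e-9, hi - 1e-9))
        if new2 < new1:
            new1, new2 = new2, new1
        moved = max(abs(new1 - bp1), abs(new2 - bp2))
        bp1, bp2 = new1, new2
        if moved < tol:
            converged = True
            break

    if abs(bp2 - bp1) < grid_step:
        raise ValueError("breakpoints collapsed onto each other")

    # final exact fit at the estimated breakpoints
    final_beta, sse = _exact_ls(x, y, (bp1, bp2))
    n, p = len(x), 4
    sigma2 = sse / max(n - p - 2, 1)  # 2 extra dof for the breakpoints
    # delta-method SEs from the linearized (gap-variable) model
    U1 = np.clip(x - bp1, 0.0, None)
    U2 = np.clip(x - bp2, 0.0, None)
    V1 = -(x > bp1).astype(float)
    V2 = -(x > bp2).astype(float)
    Xg = np.column_stack([np.ones_like(x), x, U1, U2, V1, V2])
    XtX_inv = np.linalg.pinv(Xg.T @ Xg)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0.0, None))
    d1, d2 = final_beta[2], final_beta[3]
    se_bp1 = se[4] / max(abs(d1), 1e-12)
    se_bp2 = se[5] / max(abs(d2), 1e-12)
    tcrit = scipy.stats.t.ppf(0.975, df=max(n - 6, 1))

    fitted = _piecewise_design(x, (bp1, bp2)) @ final_beta
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else np.nan
    resid_se = np.sqrt(sigma2)
    rel_se = resid_se / max(float(np.mean(np.abs(fitted))), 1e-12)
    slopes = (
        float(final_beta[1]),
        float(final_beta[1] + final_beta[2]),
        float(final_beta[1] + final_beta[2] + final_beta[3]),
    )
    return SegmentedFit(
        breakpoints=(float(bp1), float(bp2)),
        ci_bp1=(float(bp1 - tcrit * se_bp1), float(bp1 + tcrit * se_bp1)),
        ci_bp2=(float(bp2 - tcrit * se_bp2), float(bp2 + tcrit * se_bp2)),
        slopes=slopes,
        intercept=float(final_beta[0]),
        r_squared=float(r2),
        relative_se=float(rel_se),
        converged=converged,
        sse=float(sse),
    )


def percent_between(crit: float, stable: float) -> float:
    """Percent by which the stable threshold exceeds the critical one."""
    if crit <= 0:
        raise ValueError("crit must be positive")
    return 100.0 * (stable - crit) / crit


@dataclass
class ThresholdPair:
    crit: float
    stable: float
    ci_crit: tuple
    ci_stable: tuple
    r_squared: float
    relative_se: float
    converged: bool

    def to_dict(self) -> dict:
        return {
            "crit": self.crit,
            "stable": self.stable,
            "ci_crit": list(self.ci_crit),
            "ci_stable": list(self.ci_stable),
            "r_squared": self.r_squared,
            "relative_se": self.relative_se,
            "converged": self.converged,
        }


def estimate_thresholds(
    model: FittedSmoothModel,
    variable: str = "phi",
    averaging: str = "mean",
    grid_size: int = 200,
) -> ThresholdPair:
    """phi_crit / phi_stable from a fitted fitness model.

    Chains the model's log-odds prediction curve (other covariates averaged)
    into the two-breakpoint segmented fit; log-odds are used to avoid the
    spurious inflections the probability transform introduces.
    """
    curve = predict_curve(model, variable, grid_size=grid_size, averaging=averaging)
    seg = fit_segmented(curve.grid, curve.log_odds, n_breakpoints=2)
    return ThresholdPair(
        crit=seg.breakpoints[0],
        stable=seg.breakpoints[1],
        ci_crit=seg.ci_bp1,
        ci_stable=seg.ci_bp2,
        r_squared=seg.r_squared,
        relative_se=seg.relative_se,
        converged=seg.converged,
    )
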