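"""The metabolic-index engine.

phi = pO2 / O2crit(T) compares environmental O2 supply against the
temperature-dependent O2 demand of standard metabolism; at the reference
pressure (21 kPa) it equals factorial aerobic scope.  Besides the pointwise
arithmetic this module provides daily phi series, a robust seasonal smooth
(cyclic spline on day-of-water-year with site intercepts and Student-t
errors), threshold classification, presence-weighted exposure fractions and
the predator-vs-prey phi surplus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .envio import inverse_temperature, po2_from_do, water_year_day
from .traits import P_REF_KPA, TraitSet

# ---------------------------------------------------------------------------
# Pointwise arithmetic
# ---------------------------------------------------------------------------

def o2crit_at_temperature(traits: TraitSet, temp_C):
    """O2crit(T) = exp(A - E / (k_B T)), kPa."""
    return np.exp(traits.A - traits.E * inverse_temperature(temp_C))


def phi(po2_kPa, temp_C, traits: TraitSet):
    """Metabolic index: O2 supply over O2 demand."""
    po2 = np.asarray(po2_kPa, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("po2_kPa must be >= 0")
    return po2 / o2crit_at_temperature(traits, temp_C)


def fas_at_saturation(traits: TraitSet, temp_C, p_ref_kPa: float = P_REF_KPA):
    """Factorial aerobic scope under non-limiting O2: phi at the reference
    pressure (air saturation at sea level)."""
    return phi(p_ref_kPa, temp_C, traits)


# ---------------------------------------------------------------------------
# Series
# ---------------------------------------------------------------------------

def phi_series(env: pd.DataFrame, traits: TraitSet) -> pd.DataFrame:
    """Daily phi over an environmental table.

    ``env`` needs ``date``, ``temp_C`` and either ``po2_kPa`` or
    (``do_mgL`` + ``salinity``), plus optionally ``site_id``.  Rows with
    missing temperature or O2 are dropped with a warning.
    """
    out = env.copy()
    if len(out) == 0:
        warnings.warn("empty environmental input: returning empty phi series")
        out["phi"] = pd.Series(dtype=float)
        return out
    if "po2_kPa" not in out.columns or out["po2_kPa"].isna().all():
        sal = out["salinity"] if "salinity" in out.columns else 0.0
        ok = out["do_mgL"].notna() & out["temp_C"].notna()
        out.loc[ok, "po2_kPa"] = po2_from_do(
            out.loc[ok, "do_mgL"], out.loc[ok, "temp_C"],
            sal[ok] if np.ndim(sal) else sal,
        )
    usable = out["temp_C"].notna() & out["po2_kPa"].notna()
    n_drop = int((~usable).sum())
    if n_drop:
        warnings.warn(f"dropping {n_drop} records with missing temperature or pO2")
    out = out.loc[usable].copy()
    out["phi"] = phi(out["po2_kPa"].to_numpy(), out["temp_C"].to_numpy(), traits)
    out.attrs["label"] = traits.label
    out.attrs["n_dropped_missing"] = n_drop
    return out


# ---------------------------------------------------------------------------
# Seasonal robust smooth
# ---------------------------------------------------------------------------

@dataclass
class SeasonalPhiFit:
    label: str
    day_grid: np.ndarray
    predicted: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    site_intercepts: dict
    t_dof: float
    lam: float
    edf: float


def seasonal_phi_smooth(
    series: pd.DataFrame,
    basis_dim: int = 9,
    t_dof: float = 5.0,
    lam: float | None = None,
    period: float = 366.0,
    max_iter: int = 200,
) -> SeasonalPhiFit:
    """Penalized cyclic-spline smooth of phi against day of water year.

    Sites enter as fixed intercepts; observation error is Student-t with
    ``t_dof`` degrees of freedom, fit by iteratively reweighted penalized
    least squares (the EM weights of the t likelihood).  ``lam=None``
    selects the smoothing parameter by GCV on the final weighted problem.
    Returns predictions with a 95% band on a daily grid, centred on the
    average site.
    """
    from .fitmodels import _constraint_nullspace, build_spline_basis  # avoids a cycle

    if "phi" not in series.columns:
        raise ValueError("series must carry a 'phi' column (see phi_series)")
    df = series.dropna(subset=["phi"]).copy()
    day = np.asarray(water_year_day(df["date"]), dtype=float)
    if np.ptp(day) < period / 2:
        raise ValueError("need at least one seasonal cycle of data")
    y = df["phi"].to_numpy(dtype=float)

    basis = build_spline_basis(day, k=basis_dim, kind="cyclic", period=period)
    B = basis.transform(day)
    # sum-to-zero constraint so the intercept is identifiable
    Z = _constraint_nullspace(B)
    Bc = B @ Z
    S_seasonal = Z.T @ basis.penalty @ Z
    sites = sorted(df["site_id"].unique()) if "site_id" in df.columns else ["all"]
    site_codes = (
        pd.Categorical(df["site_id"], categories=sites).codes
        if "site_id" in df.columns
        else np.zeros(len(df), dtype=int)
    )
    # intercept + centred site dummies (first site as baseline)
    D = np.zeros((len(df), len(sites) - 1))
    for j in range(1, len(sites)):
        D[site_codes == j, j - 1] = 1.0
    X = np.column_stack([np.ones(len(df)), D, Bc])
    p_fixed = 1 + D.shape[1]
    S = np.zeros((X.shape[1], X.shape[1]))
    S[p_fixed:, p_fixed:] = S_seasonal

    def _pirls(lam_val, weights):
        A = X.T @ (X * weights[:, None]) + lam_val * S
        beta = np.linalg.solve(A, X.T @ (weights * y))
        return beta, A

    def _fit_at(lam_val):
        weights = np.ones(len(y))
        beta, A = _pirls(lam_val, weights)
        sigma2 = max(np.mean((y - X @ beta) ** 2), 1e-12)
        for _ in range(max_iter):
            resid = y - X @ beta
            if np.isfinite(t_dof):
                weights = (t_dof + 1.0) / (t_dof + resid**2 / sigma2)
            else:
                weights = np.ones(len(y))
            beta_new, A = _pirls(lam_val, weights)
            sigma2_new = max(np.sum(weights * (y - X @ beta_new) ** 2) / len(y), 1e-12)
            if np.max(np.abs(beta_new - beta)) < 1e-10 and abs(sigma2_new - sigma2) < 1e-12:
                beta, sigma2 = beta_new, sigma2_new
                break
            beta, sigma2 = beta_new, sigma2_new
        return beta, A, weights, sigma2

    if lam is None:
        grid = 10.0 ** np.linspace(-4, 6, 21)
        best = (np.inf, grid[0])
        for g in grid:
            beta, A, weights, sigma2 = _fit_at(g)
            H_inv = np.linalg.inv(A)
            edf = float(np.trace(H_inv @ (X.T @ (X * weights[:, None]))))
            rss = float(np.sum(weights * (y - X @ beta) ** 2))
            gcv = len(y) * rss / max(len(y) - edf, 1.0) ** 2
            if gcv < best[0]:
                best = (gcv, g)
        lam = best[1]

    beta, A, weights, sigma2 = _fit_at(lam)
    H_inv = np.linalg.inv(A)
    edf = float(np.trace(H_inv @ (X.T @ (X * weights[:, None]))))
    # asymptotic variance factor of the t maximum-likelihood location fit
    t_factor = (t_dof + 3.0) / (t_dof + 1.0) if np.isfinite(t_dof) else 1.0
    cov = H_inv * sigma2 * t_factor

    day_grid = np.arange(1.0, period + 1.0)
    Bg = basis.transform(day_grid) @ Z
    mean_site = np.concatenate([[1.0], np.full(D.shape[1], 1.0 / len(sites))])
    Xg = np.column_stack([np.tile(mean_site, (len(day_grid), 1)), Bg])
    pred = Xg @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, cov, Xg))
    z = scipy.stats.norm.ppf(0.975)
    site_effects = {sites[0]: 0.0}
    for j in range(1, len(sites)):
        site_effects[sites[j]] = float(beta[j])
    return SeasonalPhiFit(
        label=series.attrs.get("label", ""),
        day_grid=day_grid,
        predicted=pred,
        lower=pred - z * se,
        upper=pred + z * se,
        site_intercepts=site_effects,
        t_dof=t_dof,
        lam=float(lam),
        edf=edf,
    )


# ---------------------------------------------------------------------------
# Threshold classification and summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Thresholds:
    crit: float
    stable: float

    def __post_init__(self):
        if not self.crit < self.stable:
            raise ValueError("require crit < stable")


BELOW_CRIT = "below_crit"
BETWEEN = "between"
ABOVE_STABLE = "above_stable"


def classify_phi(phi_value, thresholds: Thresholds):
    """Partition phi into below_crit / between / above_stable.

    The interval [crit, stable] is closed: values at either threshold count
    as "between".
    """
    v = np.asarray(phi_value, dtype=float)
    out = np.where(v < thresholds.crit, BELOW_CRIT,
                   np.where(v > thresholds.stable, ABOVE_STABLE, BETWEEN))
    return str(out[()]) if out.ndim == 0 else out


@dataclass
class ExposureFractions:
    label: str
    frac_below_crit: float
    frac_between: float
    frac_above_stable: float
    n_days: int

    def __post_init__(self):
        total = self.frac_below_crit + self.frac_between + self.frac_above_stable
        if abs(total - 1.0) > 1e-9:
            raise ValueError("exposure fractions must sum to 1")


def presence_weighted_fractions(
    series: pd.DataFrame, presence_dates, thresholds: Thresholds
) -> ExposureFractions:
    """Fractions of presence days in each phi category."""
    presence = pd.DatetimeIndex(pd.to_datetime(presence_dates)).normalize()
    if len(presence) == 0:
        raise ValueError("empty presence set")
    dates = pd.to_datetime(series["date"]).dt.normalize()
    if not set(presence).issubset(set(dates)):
        raise ValueError("presence dates must be a subset of the series dates")
    daily = series.assign(_d=dates).groupby("_d")["phi"].mean()
    vals = daily.loc[daily.index.isin(presence)].to_numpy()
    cats = classify_phi(vals, thresholds)
    n = len(vals)
    return ExposureFractions(
        label=series.attrs.get("label", ""),
        frac_below_crit=float(np.mean(cats == BELOW_CRIT)),
        frac_between=float(np.mean(cats == BETWEEN)),
        frac_above_stable=float(np.mean(cats == ABOVE_STABLE)),
        n_days=n,
    )


def predator_surplus(
    predator: pd.DataFrame, prey: pd.DataFrame, presence_dates=None
) -> tuple[pd.DataFrame, float]:
    """Per-day percent phi surplus of the predator over the prey.

    Series must share their dates exactly.  ``presence_dates`` optionally
    restricts the mean to days the prey was present.
    """
    pred_daily = predator.groupby(pd.to_datetime(predator["date"]).dt.normalize())["phi"].mean()
    prey_daily = prey.groupby(pd.to_datetime(prey["date"]).dt.normalize())["phi"].mean()
    if not pred_daily.index.equals(prey_daily.index):
        raise ValueError("predator and prey series dates are misaligned")
    pct = 100.0 * (pred_daily - prey_daily) / prey_daily
    out = pd.DataFrame({"date": pct.index, "surplus_pct": pct.to_numpy()})
    if presence_dates is not None:
        keep = pct.index.isin(pd.DatetimeIndex(pd.to_datetime(presence_dates)).normalize())
        mean = float(pct[keep].mean())
    else:
        mean = float(pct.mean())
    return out, mean
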