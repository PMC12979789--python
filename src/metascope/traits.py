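"""Arrhenius metabolic-trait estimation from respirometry summaries.

A respirometry record carries paired SMR/MMR rates; the critical O2 tension
of SMR follows from the factorial-scope identity

    MMR / SMR = O2crit(MMR) / O2crit(SMR),   with O2crit(MMR) = 21 kPa.

O2crit is temperature-standardized (pooled ln-O2crit vs inverse-temperature
regression) only to estimate the mass-scaling exponent alpha; the original
O2crit values are then mass-standardized with alpha, and the final
Arrhenius models

    ln O2crit = A - E / (k_B T)

are fit with lifestage/population fixed effects (OLS) or a by-population
random intercept (REML mixed model with parametric-bootstrap CIs).  The
reported temperature sensitivity E is the magnitude of the negative
Arrhenius slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from .envio import inverse_temperature

REF_TEMP_C = 16.6
REF_MASS_KG = 0.02
P_REF_KPA = 21.0

REQUIRED_COLUMNS = ("fish_id", "lifestage", "population", "mass_kg", "test_temp_C", "smr", "mmr")


def validate_respirometry(records: pd.DataFrame) -> pd.DataFrame:
    """Check the respirometry schema invariants; returns the frame unchanged."""
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"missing respirometry columns: {missing}")
    if (records["smr"] <= 0).any() or (records["mmr"] <= 0).any():
        raise ValueError("SMR and MMR must be positive")
    if (records["mmr"] < records["smr"]).any():
        raise ValueError("MMR must be >= SMR (factorial scope >= 1)")
    if (records["mass_kg"] <= 0).any():
        raise ValueError("mass_kg must be positive")
    return records


# ---------------------------------------------------------------------------
# O2crit and standardization
# ---------------------------------------------------------------------------

def o2crit_from_fas(smr, mmr, p_ref_kPa: float = P_REF_KPA):
    """O2crit of SMR (kPa) from paired metabolic rates: p_ref * SMR / MMR."""
    smr = np.asarray(smr, dtype=float)
    mmr = np.asarray(mmr, dtype=float)
    if np.any(smr <= 0) or np.any(mmr <= 0):
        raise ValueError("metabolic rates must be positive")
    if np.any(mmr < smr):
        raise ValueError("MMR < SMR implies factorial scope < 1, which is unphysical")
    return p_ref_kPa * smr / mmr


def add_o2crit(records: pd.DataFrame, p_ref_kPa: float = P_REF_KPA) -> pd.DataFrame:
    """Append ``o2crit_kPa`` and ``invT`` columns."""
    out = records.copy()
    out["o2crit_kPa"] = o2crit_from_fas(out["smr"], out["mmr"], p_ref_kPa)
    out["invT"] = inverse_temperature(out["test_temp_C"])
    return out


@dataclass
class TempStandardization:
    slope: float        # d ln(O2crit) / d invT, pooled
    intercept: float
    ref_temp_C: float
    r_squared: float


def standardize_temperature(
    records: pd.DataFrame, ref_temp_C: float = REF_TEMP_C
) -> tuple[pd.DataFrame, TempStandardization]:
    """Shift each O2crit to the reference temperature along the pooled
    ln(O2crit) ~ invT regression; adds ``o2crit_Tstd``.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records to standardize temperature")
    out = records.copy()
    if "o2crit_kPa" not in out.columns:
        out = add_o2crit(out)
    inv_t = out["invT"].to_numpy()
    if np.ptp(inv_t) == 0:
        raise ValueError("all records at a single temperature: slope not identifiable")
    y = np.log(out["o2crit_kPa"].to_numpy())
    X = sm.add_constant(inv_t)
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[1])
    inv_ref = float(inverse_temperature(ref_temp_C))
    out["o2crit_Tstd"] = np.exp(y - slope * (inv_t - inv_ref))
    return out, TempStandardization(
        slope=slope,
        intercept=float(fit.params[0]),
        ref_temp_C=ref_temp_C,
        r_squared=float(fit.rsquared),
    )


@dataclass
class MassScalingFit:
    alpha: float        # ln-ln slope of O2crit vs mass
    beta: float         # intercept (ln O2crit at ref mass... see note)
    se_alpha: float
    se_beta: float
    ref_mass_kg: float
    ref_temp_C: float
    r_squared: float = np.nan


def fit_mass_scaling(
    records: pd.DataFrame,
    ref_temp_C: float = REF_TEMP_C,
    ref_mass_kg: float = REF_MASS_KG,
) -> MassScalingFit:
    """OLS of ln(temperature-standardized O2crit) on ln(mass)."""
    if "o2crit_Tstd" not in records.columns:
        raise ValueError("run standardize_temperature first (o2crit_Tstd missing)")
    if len(records) < 3:
        raise ValueError("need at least 3 records to fit mass scaling")
    ln_mass = np.log(records["mass_kg"].to_numpy(dtype=float))
    if np.ptp(ln_mass) == 0:
        raise ValueError("all records at a single mass: alpha not identifiable")
    y = np.log(records["o2crit_Tstd"].to_numpy(dtype=float))
    X = sm.add_constant(ln_mass)
    fit = sm.OLS(y, X).fit()
    return MassScalingFit(
        alpha=float(fit.params[1]),
        beta=float(fit.params[0]),
        se_alpha=float(fit.bse[1]),
        se_beta=float(fit.bse[0]),
        ref_mass_kg=ref_mass_kg,
        ref_temp_C=ref_temp_C,
        r_squared=float(fit.rsquared),
    )


def standardize_mass(records: pd.DataFrame, scaling: MassScalingFit) -> pd.DataFrame:
    """Mass-standardize the original (not temperature-shifted) O2crit:

    o2crit_std = o2crit * (ref_mass / mass) ** alpha.
    """
    out = records.copy()
    if "o2crit_kPa" not in out.columns:
        out = add_o2crit(out)
    ratio = scaling.ref_mass_kg / out["mass_kg"].to_numpy(dtype=float)
    out["o2crit_std"] = out["o2crit_kPa"].to_numpy() * ratio**scaling.alpha
    return out


# ---------------------------------------------------------------------------
# Arrhenius fits
# ---------------------------------------------------------------------------

@dataclass
class TraitSet:
    """Arrhenius traits for one organism group.

    ``A`` is the ln-O2crit intercept at infinite temperature; ``E`` (eV) is
    the magnitude of the Arrhenius slope, so O2crit = exp(A - E/(k_B T)).
    """

    label: str
    A: float
    E: float
    ci_A: tuple = (np.nan, np.nan)
    ci_E: tuple = (np.nan, np.nan)
    source: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.E < 0:
            raise ValueError("E is a magnitude and must be >= 0")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "A": self.A,
            "E": self.E,
            "ci_A": list(self.ci_A),
            "ci_E": list(self.ci_E),
            "source": self.source,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TraitSet":
        return cls(
            label=d["label"],
            A=d["A"],
            E=d["E"],
            ci_A=tuple(d.get("ci_A", (np.nan, np.nan))),
            ci_E=tuple(d.get("ci_E", (np.nan, np.nan))),
            source=d.get("source", ""),
            meta=d.get("meta", {}),
        )


def _design_fixed(records: pd.DataFrame):
    """Design for ln(o2crit_std) ~ invT * lifestage + population.

    Treatment coding against the first (sorted) lifestage and population.
    """
    lifestages = sorted(records["lifestage"].unique())
    pops = sorted(records["population"].astype(str).unique())
    inv_t = records["invT"].to_numpy(dtype=float)
    n = len(records)
    cols, names = [np.ones(n)], ["intercept"]
    for ls in lifestages[1:]:
        cols.append((records["lifestage"] == ls).to_numpy(dtype=float))
        names.append(f"lifestage[{ls}]")
    for p in pops[1:]:
        cols.append((records["population"].astype(str) == p).to_numpy(dtype=float))
        names.append(f"population[{p}]")
    cols.append(inv_t)
    names.append("invT")
    for ls in lifestages[1:]:
        cols.append(inv_t * (records["lifestage"] == ls).to_numpy(dtype=float))
        names.append(f"invT:lifestage[{ls}]")
    X = np.column_stack(cols)
    return X, names, lifestages, pops


def fit_arrhenius_fixed(records: pd.DataFrame) -> list[TraitSet]:
    """Multiple regression: per lifestage x population A, per-lifestage E.

    Model: ln(o2crit_std) ~ invT + lifestage + population + invT:lifestage.
    Group A values are intercepts at invT = 0; E is minus the lifestage
    slope.  95% CIs by linear contrasts on the OLS covariance.
    """
    if "o2crit_std" not in records.columns:
        raise ValueError("run standardize_mass first (o2crit_std missing)")
    y = np.log(records["o2crit_std"].to_numpy(dtype=float))
    X, names, lifestages, pops = _design_fixed(records)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the first aliased column for the error message
        _, r = np.linalg.qr(X)
        aliased = names[int(np.argmin(np.abs(np.diag(r))))]
        raise ValueError(f"rank-deficient design: term {aliased!r} is aliased")
    fit = sm.OLS(y, X).fit()
    cov = fit.cov_params()
    tcrit = scipy.stats.t.ppf(0.975, df=fit.df_resid)
    name_idx = {nm: i for i, nm in enumerate(names)}

    def _contrast(weights: dict):
        c = np.zeros(X.shape[1])
        for nm, w in weights.items():
            c[name_idx[nm]] = w
        est = float(c @ fit.params)
        se = float(np.sqrt(c @ cov @ c))
        return est, se

    out = []
    # which populations occur within each lifestage
    seen = records.groupby("lifestage")["population"].unique().to_dict()
    for ls in lifestages:
        w_e = {"invT": -1.0}
        if ls != lifestages[0]:
            w_e[f"invT:lifestage[{ls}]"] = -1.0
        e_est, e_se = _contrast(w_e)
        for p in sorted(np.asarray(seen[ls]).astype(str)):
            w_a = {"intercept": 1.0}
            if ls != lifestages[0]:
                w_a[f"lifestage[{ls}]"] = 1.0
            if p != pops[0]:
                w_a[f"population[{p}]"] = 1.0
            a_est, a_se = _contrast(w_a)
            out.append(
                TraitSet(
                    label=f"{ls}/{p}",
                    A=a_est,
                    E=e_est,
                    ci_A=(a_est - tcrit * a_se, a_est + tcrit * a_se),
                    ci_E=(e_est - tcrit * e_se, e_est + tcrit * e_se),
                    source="MR",
                    meta={
                        "r_squared": float(fit.rsquared),
                        "f_stat": float(fit.fvalue),
                        "df_model": int(fit.df_model),
                        "df_resid": int(fit.df_resid),
                    },
                )
            )
    return out


def fit_arrhenius_mixed(
    records: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[TraitSet]:
    """Lifestage-level traits averaged across populations.

    REML mixed model ln(o2crit_std) ~ invT * lifestage with a by-population
    random intercept; CIs by parametric bootstrap (random-intercept and
    residual draws) with ``n_boot`` refits.
    """
    if "o2crit_std" not in records.columns:
        raise ValueError("run standardize_mass first (o2crit_std missing)")
    n_pop = records["population"].nunique()
    if n_pop < 2:
        warnings.warn("single population: falling back to fixed-effects fit")
        fixed = fit_arrhenius_fixed(records) if records["lifestage"].nunique() > 1 else None
        if fixed is not None:
            return fixed
        # degenerate: single lifestage, single population -> simple line
        y = np.log(records["o2crit_std"].to_numpy(dtype=float))
        X = sm.add_constant(records["invT"].to_numpy(dtype=float))
        f = sm.OLS(y, X).fit()
        ci = f.conf_int()
        ls = records["lifestage"].iloc[0]
        return [
            TraitSet(
                label=str(ls), A=float(f.params[0]), E=float(-f.params[1]),
                ci_A=(float(ci[0, 0]), float(ci[0, 1])),
                ci_E=(float(-ci[1, 1]), float(-ci[1, 0])), source="LR",
            )
        ]

    y = np.log(records["o2crit_std"].to_numpy(dtype=float))
    X, names, lifestages, _ = _design_mixed(records)
    groups = records["population"].astype(str).to_numpy()

    def _fit(yvec):
        last_err = None
        for method in ("bfgs", "powell", "cg"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = MixedLM(yvec, X, groups=groups).fit(reml=True, method=method)
            if res.converged and np.all(np.isfinite(res.params)):
                return res
            last_err = f"optimizer {method}: converged={res.converged}, params={res.params}"
        raise RuntimeError(f"mixed-model fit failed to converge ({last_err})")

    res = _fit(y)
    point = _traits_from_params(res.fe_params, names, lifestages)

    rng = np.random.default_rng(seed)
    sigma_g = float(np.sqrt(np.asarray(res.cov_re)[0, 0]))
    sigma_e = float(np.sqrt(res.scale))
    fitted_fixed = X @ res.fe_params
    pop_codes, pop_index = pd.factorize(groups)
    draws = {ls: {"A": [], "E": []} for ls in lifestages}
    for _ in range(n_boot):
        re_draw = rng.normal(0.0, sigma_g, size=len(pop_index))
        y_b = fitted_fixed + re_draw[pop_codes] + rng.normal(0.0, sigma_e, size=len(y))
        try:
            res_b = _fit(y_b)
        except RuntimeError:
            continue
        for t in _traits_from_params(res_b.fe_params, names, lifestages):
            draws[t.label]["A"].append(t.A)
            draws[t.label]["E"].append(t.E)

    var_fixed = float(np.var(fitted_fixed))
    var_re = sigma_g**2
    var_resid = sigma_e**2
    r2_marginal = var_fixed / (var_fixed + var_re + var_resid)
    r2_conditional = (var_fixed + var_re) / (var_fixed + var_re + var_resid)

    out = []
    for t in point:
        a_draws = np.asarray(draws[t.label]["A"])
        e_draws = np.asarray(draws[t.label]["E"])
        ci_a = (np.nan, np.nan) if a_draws.size < 10 else tuple(np.quantile(a_draws, [0.025, 0.975]))
        ci_e = (np.nan, np.nan) if e_draws.size < 10 else tuple(np.quantile(e_draws, [0.025, 0.975]))
        out.append(
            TraitSet(
                label=t.label, A=t.A, E=t.E, ci_A=ci_a, ci_E=ci_e, source="LMER",
                meta={
                    "r2_marginal": r2_marginal,
                    "r2_conditional": r2_conditional,
                    "sigma_population": sigma_g,
                    "sigma_resid": sigma_e,
                    "n_boot_used": int(min(len(draws[ls]["A"]) for ls in draws) if n_boot else 0),
                },
            )
        )
    return out


def _design_mixed(records: pd.DataFrame):
    """Fixed-effect design for the mixed model: invT * lifestage."""
    lifestages = sorted(records["lifestage"].unique())
    inv_t = records["invT"].to_numpy(dtype=float)
    n = len(records)
    cols, names = [np.ones(n)], ["intercept"]
    for ls in lifestages[1:]:
        cols.append((records["lifestage"] == ls).to_numpy(dtype=float))
        names.append(f"lifestage[{ls}]")
    cols.append(inv_t)
    names.append("invT")
    for ls in lifestages[1:]:
        cols.append(inv_t * (records["lifestage"] == ls).to_numpy(dtype=float))
        names.append(f"invT:lifestage[{ls}]")
    return np.column_stack(cols), names, lifestages, None


def _traits_from_params(params, names, lifestages) -> list[TraitSet]:
    idx = {nm: i for i, nm in enumerate(names)}
    p = np.asarray(params, dtype=float)
    out = []
    for ls in lifestages:
        a = p[idx["intercept"]]
        e = -p[idx["invT"]]
        if ls != lifestages[0]:
            a += p[idx[f"lifestage[{ls}]"]]
            e -= p[idx[f"invT:lifestage[{ls}]"]]
        out.append(TraitSet(label=str(ls), A=float(a), E=float(e), source="LMER"))
    return out


def run_trait_pipeline(
    records: pd.DataFrame,
    model: str = "lmer",
    ref_temp_C: float = REF_TEMP_C,
    ref_mass_kg: float = REF_MASS_KG,
    n_boot: int = 1000,
    seed: int | None = None,
):
    """Full chain: O2crit -> temperature-standardize -> mass scaling ->
    mass-standardize -> Arrhenius fit.

    Returns (traits, mass_scaling_fit, standardized records).
    """
    validate_respirometry(records)
    recs = add_o2crit(records)
    recs, _ = standardize_temperature(recs, ref_temp_C)
    scaling = fit_mass_scaling(recs, ref_temp_C, ref_mass_kg)
    recs = standardize_mass(recs, scaling)
    if model.lower() in ("lmer", "mixed"):
        traits = fit_arrhenius_mixed(recs, n_boot=n_boot, seed=seed)
    elif model.lower() in ("mr", "fixed"):
        traits = fit_arrhenius_fixed(recs)
    else:
        raise ValueError(f"unknown trait model {model!r}")
    return traits, scaling, recs
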