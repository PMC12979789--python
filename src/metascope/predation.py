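"""Predator-side analysis: predation-probability models and seasonal
predator/prey alignment.

Largemouth-bass traits are estimated with the same machinery as the prey
(see :mod:`metascope.traits`); deployment-level predation outcomes are then
modelled as a binomial smooth of predator phi (or temperature) with
by-method and by-site random intercepts and a z-scored duration term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .envio import po2_from_do
from .fitmodels import (
    FittedSmoothModel,
    SmoothModelSpec,
    SmoothTerm,
    compare_bic,
    fit_binomial_smooth,
)
from .phi import o2crit_at_temperature
from .traits import TraitSet


def zscore_within(
    records: pd.DataFrame, value: str, by: Sequence[str]
) -> pd.DataFrame:
    """Replace ``value`` by its z-score within groups defined by ``by``.

    Zero-variance groups get 0 with a warning.
    """
    out = records.copy()
    grouped = out.groupby(list(by))[value]
    mean = grouped.transform("mean")
    sd = grouped.transform("std")
    if (sd.fillna(0.0) == 0.0).any():
        warnings.warn(f"zero-variance group(s) while z-scoring {value!r}; setting 0")
    z = (out[value] - mean) / sd
    out[value] = z.where(sd > 0, 0.0).fillna(0.0)
    return out


def fit_predation_model(
    deployments: pd.DataFrame,
    bass_traits: TraitSet,
    driver: str = "phi",
    optional_terms: Sequence[str] = (),
    k: int = 7,
    lam=None,
) -> dict:
    """Binomial smooth model of bass predation on deployment conditions.

    Computes bass phi per deployment (from temperature/DO/salinity means),
    z-scores duration within method and site, and fits the k-knot smooth of
    the chosen driver with by-method and by-site random intercepts.
    Returns the fitted model plus a BIC table over {phi, temp} drivers.
    """
    df = deployments.copy()
    if "po2_kPa" not in df.columns:
        df["po2_kPa"] = po2_from_do(df["do_mgL"], df["temp_C"], df.get("salinity", 0.0))
    df["phi"] = df["po2_kPa"] / o2crit_at_temperature(bass_traits, df["temp_C"])
    df = zscore_within(df, "duration_min", ["method", "site_id"])

    def _spec(var):
        smooths = [SmoothTerm(var, k=k)] + [SmoothTerm(v, k=k) for v in optional_terms]
        return SmoothModelSpec(
            outcome="predated_by_bass",
            smooth_terms=smooths,
            parametric_terms=["duration_min"],
            random_intercepts=["method", "site_id"],
        )

    models = {}
    for var in ("phi", "temp_C"):
        models[var] = fit_binomial_smooth(df, _spec(var), lam=lam)
    comparison = compare_bic(models["phi"], models["temp_C"])
    chosen = models["phi" if driver == "phi" else "temp_C"]
    return {
        "model": chosen,
        "model_phi": models["phi"],
        "model_temp": models["temp_C"],
        "bic_comparison": comparison,
        "data": df,
        "mean_predicted": float(np.mean(_fitted_probability(chosen))),
        "observed_rate": float(df["predated_by_bass"].mean()),
    }


def _fitted_probability(model: FittedSmoothModel) -> np.ndarray:
    from scipy.special import expit

    return expit(model._X @ model.coef)


@dataclass
class AlignmentRecord:
    days: np.ndarray
    prey_fitness: np.ndarray
    predation: np.ndarray
    rank_correlation: float
    inverse_windows: list   # (start_day, end_day) where predation high & prey low


def predation_alignment(
    prey_curve: pd.DataFrame, predation_curve: pd.DataFrame
) -> AlignmentRecord:
    """Day-wise pairing of prey fitness and predation probability curves.

    Both frames need ``day`` and ``value`` columns on an identical grid.
    Reports the Spearman rank correlation and the contiguous day windows
    where predation exceeds its mean while prey fitness sits below its own.
    """
    d1 = np.asarray(prey_curve["day"], dtype=float)
    d2 = np.asarray(predation_curve["day"], dtype=float)
    if len(d1) != len(d2) or not np.allclose(d1, d2):
        raise ValueError("curves are not on a common day grid")
    prey = np.asarray(prey_curve["value"], dtype=float)
    pred = np.asarray(predation_curve["value"], dtype=float)
    rho = scipy.stats.spearmanr(prey, pred).statistic
    mask = (pred > pred.mean()) & (prey < prey.mean())
    windows = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = d1[i]
        elif not m and start is not None:
            windows.append((float(start), float(d1[i - 1])))
            start = None
    if start is not None:
        windows.append((float(start), float(d1[-1])))
    return AlignmentRecord(
        days=d1,
        prey_fitness=prey,
        predation=pred,
        rank_correlation=float(rho),
        inverse_windows=windows,
    )
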