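"""Environmental physics and field-data preparation.

Converts dissolved-oxygen concentration to partial pressure, expresses
temperature on the inverse (Boltzmann) scale used by Arrhenius trait models,
handles the water-year calendar, applies quantile quality-control trimming,
classifies wild fry in seine catches, and builds per-fish exposure windows
from acoustic-telemetry detection series.

Tabular inputs are plain pandas DataFrames whose columns follow the field
names documented on each function; dates are ISO-8601 / ``datetime64``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Boltzmann constant in eV / K.
KB_EV = 8.617333e-5

#: Mole fraction of O2 in dry air.
O2_MOLE_FRACTION = 0.2095

#: Standard sea-level atmospheric pressure, kPa.
PATM_STANDARD_KPA = 101.325


# ---------------------------------------------------------------------------
# Physics: DO -> pO2, inverse temperature
# ---------------------------------------------------------------------------

def vapor_pressure_kPa(temp_C):
    """Saturation water-vapor pressure (kPa) by the Buck (1981) approximation.

    Valid for liquid water over roughly -20..50 degC.
    """
    t = np.asarray(temp_C, dtype=float)
    return 0.61121 * np.exp((18.678 - t / 234.5) * (t / (257.14 + t)))


def _pressure_factor(temp_C, patm_kPa):
    """Benson & Krause pressure correction for non-standard barometric pressure."""
    t = np.asarray(temp_C, dtype=float)
    p_atm = np.asarray(patm_kPa, dtype=float) / PATM_STANDARD_KPA  # atm
    pwv_atm = vapor_pressure_kPa(t) / PATM_STANDARD_KPA
    theta = 0.000975 - 1.426e-5 * t + 6.436e-8 * t**2
    return p_atm * ((1.0 - pwv_atm / p_atm) * (1.0 - theta * p_atm)) / (
        (1.0 - pwv_atm) * (1.0 - theta)
    )


def o2_saturation_mgL(temp_C, salinity=0.0, patm_kPa=PATM_STANDARD_KPA):
    """Air-saturated dissolved-O2 concentration (mg/L).

    Benson & Krause (1984) freshwater formulation with the standard salinity
    correction (as tabulated by USGS), plus the barometric-pressure factor.

    Parameters
    ----------
    temp_C : array_like
        Water temperature, degC; valid 0-40.
    salinity : array_like
        Practical salinity (unitless, >= 0).
    patm_kPa : float
        Barometric pressure, kPa.
    """
    t = np.asarray(temp_C, dtype=float)
    s = np.asarray(salinity, dtype=float)
    if np.any(t < 0.0) or np.any(t > 40.0):
        raise ValueError("temp_C outside the 0-40 degC solubility-formula validity range")
    if np.any(s < 0.0):
        raise ValueError("salinity must be >= 0")
    tk = t + 273.15
    ln_c = (
        -139.34411
        + 1.575701e5 / tk
        - 6.642308e7 / tk**2
        + 1.243800e10 / tk**3
        - 8.621949e11 / tk**4
    )
    ln_c = ln_c - s * (0.017674 - 10.754 / tk + 2140.7 / tk**2)
    return np.exp(ln_c) * _pressure_factor(t, patm_kPa)


def po2_from_do(do_mgL, temp_C, salinity=0.0, patm_kPa=PATM_STANDARD_KPA):
    """Convert dissolved O2 (mg/L) to O2 partial pressure (kPa).

    pO2 = (DO / DO_sat) * chi_O2 * (P_atm - P_vapor): the fractional air
    saturation times the partial pressure O2 would have at full saturation.
    Linear in ``do_mgL`` by construction.
    """
    do = np.asarray(do_mgL, dtype=float)
    if np.any(do < 0.0):
        raise ValueError("do_mgL must be >= 0")
    sat = o2_saturation_mgL(temp_C, salinity, patm_kPa)
    return (do / sat) * O2_MOLE_FRACTION * (patm_kPa - vapor_pressure_kPa(temp_C))


def inverse_temperature(temp_C):
    """Inverse temperature 1 / (k_B * T) in eV^-1, with T in kelvin."""
    t = np.asarray(temp_C, dtype=float)
    if np.any(t <= -273.15):
        raise ValueError("temp_C must exceed absolute zero")
    return 1.0 / (KB_EV * (t + 273.15))


# ---------------------------------------------------------------------------
# Calendar
# ---------------------------------------------------------------------------

def water_year_day(date):
    """1-based day index within the water year (1 October start).

    Accepts a scalar date-like or an array/Series; returns int or int array.
    """
    d = pd.to_datetime(date)
    scalar = not isinstance(d, (pd.Series, pd.DatetimeIndex))
    idx = pd.DatetimeIndex([d]) if scalar else pd.DatetimeIndex(d)
    start_year = np.where(idx.month >= 10, idx.year, idx.year - 1)
    starts = pd.to_datetime({"year": start_year, "month": 10, "day": 1})
    days = (idx.normalize() - pd.DatetimeIndex(starts)).days + 1
    out = np.asarray(days, dtype=int)
    return int(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Quality control and survey classification
# ---------------------------------------------------------------------------

def qc_bounds(records: pd.DataFrame, variables: Sequence[str], q: float = 0.005):
    """Empirical [q, 1-q] quantile bounds per variable, computed once."""
    if not 0.0 < q < 0.5:
        raise ValueError("q must lie in (0, 0.5)")
    return {
        v: (records[v].quantile(q), records[v].quantile(1.0 - q)) for v in variables
    }


def qc_trim(
    records: pd.DataFrame,
    variables: Sequence[str],
    q: float = 0.005,
    bounds: Mapping[str, tuple] | None = None,
) -> pd.DataFrame:
    """Drop records where any named variable falls strictly outside its
    [q, 1-q] empirical quantiles.

    Quantile bounds are computed once on the input set (or supplied via
    ``bounds`` for reproducible re-application).
    """
    if len(records) == 0:
        raise ValueError("qc_trim requires a non-empty input")
    if bounds is None:
        bounds = qc_bounds(records, variables, q)
    keep = pd.Series(True, index=records.index)
    for v, (lo, hi) in bounds.items():
        keep &= records[v].between(lo, hi)
    return records.loc[keep].copy()


def filter_sites_by_occupancy(
    events: pd.DataFrame, min_frequency: float = 0.05
) -> list:
    """Sites whose fraction of fry-positive sampling events is >= threshold.

    ``events`` needs ``site_id`` and binary ``fry_present`` columns. The
    boundary is inclusive: a site at exactly the threshold is retained.
    """
    if not 0.0 <= min_frequency <= 1.0:
        raise ValueError("min_frequency must lie in [0, 1]")
    freq = events.groupby("site_id")["fry_present"].mean()
    return sorted(freq.index[freq >= min_frequency].tolist())


def wild_fry_cutoff(marked_lengths_cm, q: float = 0.05) -> float:
    """Length cutoff: the ``q`` quantile of marked hatchery-fish lengths."""
    lengths = np.asarray(marked_lengths_cm, dtype=float)
    if lengths.size == 0:
        raise ValueError("no marked lengths supplied")
    return float(np.quantile(lengths, q))


def classify_wild_fry(length_cm, marked, length_cutoff_cm: float = 6.7):
    """True iff the fish is unmarked and shorter than the hatchery cutoff."""
    length = np.asarray(length_cm, dtype=float)
    if np.any(length <= 0):
        raise ValueError("length_cm must be positive")
    is_marked = np.asarray(marked, dtype=bool)
    out = (~is_marked) & (length < length_cutoff_cm)
    return bool(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Telemetry exposure windows
# ---------------------------------------------------------------------------

@dataclass
class DetectionSeries:
    """One tagged fish's ordered acoustic detections.

    ``detections`` is a DataFrame with columns ``receiver_id``, ``timestamp``
    (datetime64) and ``river_position_km`` (increasing downstream).
    """

    tag_id: str
    release_group: str
    route: str
    detections: pd.DataFrame
    success: int
    fish_length_cm: float = np.nan
    release_distance_km: float = np.nan

    def __post_init__(self):
        ts = pd.to_datetime(self.detections["timestamp"])
        if len(ts) and not ts.is_monotonic_increasing:
            raise ValueError(f"{self.tag_id}: detection timestamps must be increasing")
        if self.success not in (0, 1):
            raise ValueError("success must be 0 or 1")


@dataclass
class TravelRates:
    """Average travel rates (km/day) with a precedence hierarchy.

    Lookup order: (release_group, route) -> route -> overall.
    """

    by_group_route: Mapping[tuple, float] = field(default_factory=dict)
    by_route: Mapping[str, float] = field(default_factory=dict)
    overall: float | None = None

    def rate_for(self, release_group: str, route: str) -> float:
        if (release_group, route) in self.by_group_route:
            return self.by_group_route[(release_group, route)]
        if route in self.by_route:
            return self.by_route[route]
        if self.overall is not None:
            return self.overall
        raise ValueError(
            f"no travel rate available for group={release_group!r}, route={route!r}"
        )


@dataclass
class ExposureWindow:
    tag_id: str
    entry_time: pd.Timestamp
    exit_time: pd.Timestamp
    interpolated_entry: bool = False
    interpolated_exit: bool = False
    mean_temp_C: float = np.nan
    mean_po2_kPa: float = np.nan
    mean_flow: float = np.nan

    def __post_init__(self):
        if self.exit_time < self.entry_time:
            raise ValueError("exit_time must be >= entry_time")


def transit_window(
    series: DetectionSeries,
    entry_km: float,
    exit_km: float,
    rates: TravelRates,
    position_tol_km: float = 0.5,
) -> ExposureWindow:
    """Entry/exit times for the reach [entry_km, exit_km].

    Observed detections at the reach boundaries are used directly; a missing
    boundary is imputed from the temporally closest detection using the
    shortest river distance and the most precise travel rate available
    (release-group-by-route, then route, then overall).
    """
    det = series.detections
    if len(det) == 0:
        raise ValueError("transit_window requires at least one detection")
    pos = det["river_position_km"].to_numpy(dtype=float)
    ts = pd.to_datetime(det["timestamp"])

    def _boundary(target_km: float, is_entry: bool):
        at = np.abs(pos - target_km) <= position_tol_km
        if at.any():
            # entry = first detection at the boundary, exit = last
            t = ts[at].iloc[0] if is_entry else ts[at].iloc[-1]
            return pd.Timestamp(t), False
        rate = rates.rate_for(series.release_group, series.route)
        i = int(np.argmin(np.abs(pos - target_km)))
        # downstream travel at `rate`: time at target = time at detection
        # + signed river distance / rate
        lag_days = (target_km - pos[i]) / rate
        return pd.Timestamp(ts.iloc[i] + pd.Timedelta(days=lag_days)), True

    entry_time, entry_flag = _boundary(entry_km, is_entry=True)
    exit_time, exit_flag = _boundary(exit_km, is_entry=False)
    return ExposureWindow(
        tag_id=series.tag_id,
        entry_time=entry_time,
        exit_time=exit_time,
        interpolated_entry=entry_flag,
        interpolated_exit=exit_flag,
    )


def exposure_summary(window: ExposureWindow, env: pd.DataFrame) -> ExposureWindow:
    """Fill the window's mean temperature, pO2 and flow from a daily series.

    ``env`` carries ``date`` plus any of ``temp_C``, ``po2_kPa``, ``flow``.
    Days with missing values are excluded from the corresponding mean; a
    window with no overlapping days is an error.
    """
    dates = pd.to_datetime(env["date"]).dt.normalize()
    lo = window.entry_time.normalize()
    hi = window.exit_time.normalize()
    sel = env.loc[(dates >= lo) & (dates <= hi)]
    if len(sel) == 0:
        raise ValueError("exposure window does not overlap the environmental series")
    for col, attr in (("temp_C", "mean_temp_C"), ("po2_kPa", "mean_po2_kPa"), ("flow", "mean_flow")):
        if col in sel.columns:
            vals = sel[col].dropna()
            if len(vals) == 0:
                warnings.warn(f"no non-missing {col} in window for {window.tag_id}")
            else:
                setattr(window, attr, float(vals.mean()))
    return window


def fill_missing_salinity(env: pd.DataFrame, station_col: str = "site_id") -> pd.DataFrame:
    """Impute missing salinity: station mean first, then cross-station mean."""
    out = env.copy()
    station_mean = out.groupby(station_col)["salinity"].transform("mean")
    out["salinity"] = out["salinity"].fillna(station_mean)
    out["salinity"] = out["salinity"].fillna(out["salinity"].mean())
    return out
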