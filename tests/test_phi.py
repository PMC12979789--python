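import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metascope import phi as pm
from metascope.phi import (
    ExposureFractions,
    Thresholds,
    classify_phi,
    fas_at_saturation,
    o2crit_at_temperature,
    phi,
    phi_series,
    predator_surplus,
    presence_weighted_fractions,
    seasonal_phi_smooth,
)
from metascope.envio import water_year_day
from metascope.synthetic_data import BASS_TRAITS, FRY_TRAITS, SMOLT_TRAITS
from metascope.traits import TraitSet

traits_st = st.builds(
    TraitSet,
    label=st.just("x"),
    A=st.floats(5.0, 20.0),
    E=st.floats(0.0, 0.5),
)


class TestPointwise:
    def test_o2crit_reference_values(self):
        assert o2crit_at_temperature(SMOLT_TRAITS, 16.6) == pytest.approx(4.92, abs=0.01)
        assert o2crit_at_temperature(FRY_TRAITS, 16.6) == pytest.approx(4.82, abs=0.01)

    def test_e_zero_constant(self, flat_traits):
        temps = np.linspace(0, 30, 7)
        assert np.allclose(o2crit_at_temperature(flat_traits, temps), 5.0)

    def test_phi_definition(self, smolt_traits):
        oc = o2crit_at_temperature(smolt_traits, 12.0)
        assert phi(oc, 12.0, smolt_traits) == pytest.approx(1.0)
        assert phi(21.0, 16.6, smolt_traits) == pytest.approx(4.27, abs=0.01)

    def test_phi_monotonicity(self, smolt_traits):
        assert phi(10.0, 15.0, smolt_traits) < phi(12.0, 15.0, smolt_traits)
        assert phi(10.0, 18.0, smolt_traits) < phi(10.0, 15.0, smolt_traits)

    def test_fas_reference(self):
        assert fas_at_saturation(BASS_TRAITS, 16.6) == pytest.approx(5.87, abs=0.01)

    @given(tr=traits_st, temp=st.floats(2.0, 28.0))
    @settings(max_examples=60, deadline=None)
    def test_eq2_identity(self, tr, temp):
        # FAS at saturation times O2crit is exactly the reference pressure
        assert fas_at_saturation(tr, temp) * o2crit_at_temperature(tr, temp) == pytest.approx(
            21.0, rel=1e-12
        )

    @given(tr=traits_st, temp=st.floats(2.0, 28.0), po2=st.floats(0.1, 25.0), c=st.floats(0.1, 10.0))
    @settings(max_examples=60, deadline=None)
    def test_scale_equivariance(self, tr, temp, po2, c):
        assert phi(c * po2, temp, tr) == pytest.approx(c * phi(po2, temp, tr), rel=1e-12)


class TestPhiSeries:
    def test_constant_env(self, flat_traits):
        env = pd.DataFrame(
            {"date": pd.date_range("2020-01-01", periods=5), "temp_C": 15.0, "po2_kPa": 20.0}
        )
        out = phi_series(env, flat_traits)
        assert np.allclose(out["phi"], 4.0)

    def test_monotone_pair(self, smolt_traits):
        env = pd.DataFrame(
            {
                "date": pd.date_range("2020-01-01", periods=2),
                "temp_C": [12.0, 20.0],
                "po2_kPa": [21.0, 15.0],
            }
        )
        out = phi_series(env, smolt_traits)
        assert len(out) == 2
        assert out["phi"].iloc[0] > out["phi"].iloc[1]

    def test_missing_dates_dropped_with_warning(self, smolt_traits):
        env = pd.DataFrame(
            {
                "date": pd.date_range("2020-01-01", periods=3),
                "temp_C": [12.0, np.nan, 14.0],
                "po2_kPa": [20.0, 20.0, 20.0],
            }
        )
        with pytest.warns(UserWarning, match="dropping 1"):
            out = phi_series(env, smolt_traits)
        assert len(out) == 2

    def test_empty_input(self, smolt_traits):
        env = pd.DataFrame({"date": [], "temp_C": [], "po2_kPa": []})
        with pytest.warns(UserWarning, match="empty"):
            out = phi_series(env, smolt_traits)
        assert len(out) == 0


class TestClassifyPhi:
    th_rearing = Thresholds(2.82, 3.81)
    th_migration = Thresholds(3.72, 4.33)

    def test_examples(self):
        assert classify_phi(2.5, self.th_rearing) == "below_crit"
        assert classify_phi(2.82, self.th_rearing) == "between"  # boundary closed
        assert classify_phi(5.0, self.th_migration) == "above_stable"

    @given(v=st.floats(0.01, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_partition(self, v):
        cats = [classify_phi(v, self.th_rearing)]
        assert cats[0] in ("below_crit", "between", "above_stable")
        # exactly one category: re-evaluate boundaries explicitly
        n = sum(
            [
                v < self.th_rearing.crit,
                self.th_rearing.crit <= v <= self.th_rearing.stable,
                v > self.th_rearing.stable,
            ]
        )
        assert n == 1

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            Thresholds(4.0, 3.0)


class TestFractions:
    @staticmethod
    def _series(values):
        return pd.DataFrame(
            {"date": pd.date_range("2020-01-01", periods=len(values)), "phi": values}
        )

    def test_all_above(self):
        s = self._series([5.0] * 4)
        f = presence_weighted_fractions(s, s["date"], Thresholds(2.82, 3.81))
        assert (f.frac_below_crit, f.frac_between, f.frac_above_stable) == (0.0, 0.0, 1.0)

    def test_counting(self):
        vals = [2.0, 2.5] + [3.0, 3.2, 3.5] + [4.0] * 5
        s = self._series(vals)
        f = presence_weighted_fractions(s, s["date"], Thresholds(2.82, 3.81))
        assert f.frac_below_crit == pytest.approx(0.2)
        assert f.frac_between == pytest.approx(0.3)
        assert f.frac_above_stable == pytest.approx(0.5)

    def test_sum_to_one_enforced(self):
        with pytest.raises(ValueError):
            ExposureFractions("x", 0.5, 0.2, 0.2, 10)

    def test_empty_presence_error(self):
        s = self._series([3.0, 4.0])
        with pytest.raises(ValueError, match="empty"):
            presence_weighted_fractions(s, [], Thresholds(2.82, 3.81))


class TestPredatorSurplus:
    @staticmethod
    def _series(values):
        return pd.DataFrame(
            {"date": pd.date_range("2020-01-01", periods=len(values)), "phi": values}
        )

    def test_identical_zero(self):
        s = self._series([4.0, 5.0])
        _, mean = predator_surplus(s, s.copy())
        assert mean == pytest.approx(0.0)

    def test_constant_ratio(self):
        _, mean = predator_surplus(self._series([6.0] * 3), self._series([4.0] * 3))
        assert mean == pytest.approx(50.0)

    def test_bass_vs_fry_single_condition(self):
        v_bass = phi(21.0, 16.6, BASS_TRAITS)
        v_fry = phi(21.0, 16.6, FRY_TRAITS)
        pred = self._series([v_bass])
        prey = self._series([v_fry])
        _, mean = predator_surplus(pred, prey)
        assert mean == pytest.approx(35.0, abs=1.0)

    def test_misaligned_error(self):
        a = self._series([4.0, 5.0])
        b = a.copy()
        b["date"] = b["date"] + pd.Timedelta(days=30)
        with pytest.raises(ValueError, match="misaligned"):
            predator_surplus(a, b)


def _seasonal_frame(n_years=2, sites=("a", "b"), noise=None, seed=0, const=None):
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2019-10-01", periods=int(365 * n_years), freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    frames = []
    for s in sites:
        truth = 4.0 + 1.2 * np.sin(2 * np.pi * doy / 365.25) if const is None else np.full(len(doy), const)
        y = truth.copy()
        if noise is not None:
            y = y + noise(rng, len(doy))
        frames.append(pd.DataFrame({"site_id": s, "date": dates, "phi": y, "_truth": truth}))
    return pd.concat(frames, ignore_index=True)


class TestSeasonalSmooth:
    def test_constant_input_flat(self):
        df = _seasonal_frame(const=3.5)
        fit = seasonal_phi_smooth(df, basis_dim=9, t_dof=5.0)
        assert np.allclose(fit.predicted, 3.5, atol=1e-6)

    def test_sinusoid_recovery_within_band(self):
        hits = []
        for seed in range(5):
            df = _seasonal_frame(noise=lambda r, n: 0.3 * r.standard_t(5, n), seed=seed)
            fit = seasonal_phi_smooth(df, basis_dim=9, t_dof=5.0)
            daily_truth = (
                df.assign(wyd=water_year_day(df["date"])).groupby("wyd")["_truth"].mean()
            )
            idx = daily_truth.index.to_numpy() - 1
            inside = (daily_truth.to_numpy() >= fit.lower[idx]) & (
                daily_truth.to_numpy() <= fit.upper[idx]
            )
            hits.append(inside.mean())
        assert np.mean(hits) >= 0.9

    def test_robust_beats_gaussian_on_outliers(self):
        def noise(rng, n):
            e = 0.15 * rng.normal(size=n)
            k = max(1, n // 100)
            idx = rng.choice(n, k, replace=False)
            e[idx] += 12.0  # 10x the seasonal amplitude
            return e

        df = _seasonal_frame(noise=noise, seed=4)
        robust = seasonal_phi_smooth(df, basis_dim=9, t_dof=5.0)
        gaussian = seasonal_phi_smooth(df, basis_dim=9, t_dof=np.inf)
        daily_truth = (
            df.assign(wyd=water_year_day(df["date"])).groupby("wyd")["_truth"].mean()
        )
        idx = daily_truth.index.to_numpy() - 1
        dev_r = np.max(np.abs(robust.predicted[idx] - daily_truth.to_numpy()))
        dev_g = np.max(np.abs(gaussian.predicted[idx] - daily_truth.to_numpy()))
        assert dev_r < dev_g

    def test_large_dof_matches_penalized_ls(self):
        df = _seasonal_frame(noise=lambda r, n: 0.2 * r.normal(size=n), seed=7)
        a = seasonal_phi_smooth(df, basis_dim=9, t_dof=1e9, lam=10.0)
        b = seasonal_phi_smooth(df, basis_dim=9, t_dof=np.inf, lam=10.0)
        assert np.allclose(a.predicted, b.predicted, atol=1e-6)

    def test_band_brackets_prediction(self):
        df = _seasonal_frame(noise=lambda r, n: 0.2 * r.normal(size=n), seed=2)
        fit = seasonal_phi_smooth(df)
        assert np.all(fit.lower <= fit.predicted)
        assert np.all(fit.predicted <= fit.upper)

    def test_insufficient_span_error(self):
        df = _seasonal_frame().iloc[:100]
        with pytest.raises(ValueError, match="seasonal cycle"):
            seasonal_phi_smooth(df)
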