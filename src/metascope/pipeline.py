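"""End-to-end orchestration: traits -> phi -> fitness models -> thresholds
-> predation -> exposure fractions, with JSON artifacts and a run log."""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, envio, phi as phimod, predation as predmod, synthetic_data, thresholds as thmod, traits as traitsmod
from .fitmodels import SmoothModelSpec, SmoothTerm, compare_bic, fit_binomial_smooth
from .synthetic_data import BASS_TRAITS, SynthConfig


@dataclass
class PipelineConfig:
    """Paths (optional: synthesize when absent) and analysis choices."""

    respirometry_csv: str | None = None
    environment_csv: str | None = None
    rearing_csv: str | None = None
    migration_csv: str | None = None
    predation_csv: str | None = None
    trait_model: str = "lmer"           # or "mr"
    driver: str = "phi"                 # or "temperature"
    k_fitness: int = 7
    k_seasonal: int = 9
    qc_quantile: float = 0.005
    n_boot: int = 200
    seed: int = 0
    outdir: str = "metascope_out"
    synth: SynthConfig = field(default_factory=SynthConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**raw.pop("synth", {}))
        cfg = cls(**raw, synth=synth)
        for key in ("respirometry_csv", "environment_csv", "rearing_csv", "migration_csv", "predation_csv"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p} does not exist")
        return cfg

    def config_hash(self) -> str:
        d = asdict(self)
        d["synth"] = {k: v for k, v in asdict(self.synth).items() if not isinstance(v, dict)}
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def spec_for_kind(kind: str, driver: str = "phi", k: int = 7) -> SmoothModelSpec:
    """Model specification per behavior: rearing (site intercepts, flow),
    migration (flow, release distance, length), predation (duration,
    method/site intercepts)."""
    var = "phi" if driver == "phi" else "temp_C"
    if kind == "rearing":
        return SmoothModelSpec(
            outcome="fry_present",
            smooth_terms=[SmoothTerm(var, k=k), SmoothTerm("flow", k=k)],
            parametric_terms=[f"flow:{var}"],
            random_intercepts=["site_id"],
        )
    if kind == "migration":
        parametric = [f"flow:{var}"] if driver == "phi" else []
        return SmoothModelSpec(
            outcome="success",
            smooth_terms=[
                SmoothTerm(var, k=k),
                SmoothTerm("flow", k=k),
                SmoothTerm("release_distance_km", k=k),
                SmoothTerm("fish_length_cm", k=k),
            ],
            parametric_terms=parametric,
        )
    if kind == "predation":
        return SmoothModelSpec(
            outcome="predated_by_bass",
            smooth_terms=[SmoothTerm(var, k=k)],
            parametric_terms=["duration_min"],
            random_intercepts=["method", "site_id"],
        )
    raise ValueError(f"unknown model kind {kind!r}")


def _write_json(path: Path, obj: dict, cfg_hash: str):
    obj = dict(obj)
    obj["config_hash"] = cfg_hash
    path.write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns {artifact name: path or object}."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.synth.seed = config.seed
    cfg_hash = config.config_hash()
    log = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": cfg_hash,
        "dropped": {},
        "timings_s": {},
    }
    synth = config.synth
    synth.seed = config.seed
    artifacts = {}

    # --- stage 1: metabolic traits -------------------------------------
    t = time.time()
    try:
        if config.respirometry_csv:
            resp = pd.read_csv(config.respirometry_csv)
        else:
            resp = synthetic_data.gen_respirometry(synth)
        trait_sets, scaling, _ = traitsmod.run_trait_pipeline(
            resp, model=config.trait_model, n_boot=config.n_boot, seed=config.seed
        )
    except Exception as e:
        raise RuntimeError(f"stage 'traits' failed (n={len(resp) if 'resp' in dir() else '?'}): {e}") from e
    traits_by_label = {t_.label: t_ for t_ in trait_sets}
    _write_json(
        outdir / "traits.json",
        {
            "traits": [t_.to_dict() for t_ in trait_sets],
            "mass_scaling": {
                "alpha": scaling.alpha,
                "beta": scaling.beta,
                "se_alpha": scaling.se_alpha,
                "se_beta": scaling.se_beta,
            },
        },
        cfg_hash,
    )
    artifacts["traits"] = outdir / "traits.json"
    log["timings_s"]["traits"] = round(time.time() - t, 2)

    fry_tr = traits_by_label.get("fry", synthetic_data.FRY_TRAITS)
    smolt_tr = traits_by_label.get("smolt", synthetic_data.SMOLT_TRAITS)

    # --- stage 2: environment ------------------------------------------
    t = time.time()
    env = pd.read_csv(config.environment_csv, parse_dates=["date"]) if config.environment_csv else synthetic_data.gen_environment(synth)
    n0 = len(env)
    env = envio.qc_trim(env, ["temp_C", "do_mgL", "salinity"], q=config.qc_quantile)
    log["dropped"]["env_qc"] = n0 - len(env)
    if "po2_kPa" not in env.columns or env["po2_kPa"].isna().any():
        env["po2_kPa"] = envio.po2_from_do(env["do_mgL"], env["temp_C"], env["salinity"])
    log["timings_s"]["environment"] = round(time.time() - t, 2)

    # --- stage 3: fitness models, BIC comparison, thresholds -----------
    threshold_pairs = {}
    for kind, tr in (("rearing", fry_tr), ("migration", smolt_tr)):
        t = time.time()
        csv = config.rearing_csv if kind == "rearing" else config.migration_csv
        if csv:
            data = pd.read_csv(csv, parse_dates=["date"])
        else:
            data = synthetic_data.gen_fitness_outcomes(env, tr, synth, kind)
        try:
            m_phi = fit_binomial_smooth(data, spec_for_kind(kind, "phi", config.k_fitness))
            m_temp = fit_binomial_smooth(data, spec_for_kind(kind, "temperature", config.k_fitness))
        except Exception as e:
            raise RuntimeError(f"stage '{kind} models' failed (n={len(data)}): {e}") from e
        comparison = compare_bic(m_phi, m_temp)
        if config.driver == "phi":
            pair = thmod.estimate_thresholds(m_phi)
            threshold_pairs[kind] = pair
            _write_json(
                outdir / f"thresholds_{kind}.json",
                {**pair.to_dict(), "bic_comparison": comparison,
                 "model_r_squared": m_phi.r_squared, "model_edf": m_phi.edf_total, "n": m_phi.n},
                cfg_hash,
            )
            artifacts[f"thresholds_{kind}"] = outdir / f"thresholds_{kind}.json"
        else:
            _write_json(
                outdir / f"model_{kind}_temperature.json",
                {"bic_comparison": comparison, "model_r_squared": m_temp.r_squared, "n": m_temp.n},
                cfg_hash,
            )
            artifacts[f"model_{kind}_temperature"] = outdir / f"model_{kind}_temperature.json"
        log["timings_s"][kind] = round(time.time() - t, 2)

    # --- stage 4: predation --------------------------------------------
    t = time.time()
    per = pd.read_csv(config.predation_csv, parse_dates=["date"]) if config.predation_csv else synthetic_data.gen_predation(env, BASS_TRAITS, synth)
    try:
        pred_fit = predmod.fit_predation_model(per, BASS_TRAITS, driver="phi" if config.driver == "phi" else "temp")
    except Exception as e:
        raise RuntimeError(f"stage 'predation' failed (n={len(per)}): {e}") from e
    _write_json(
        outdir / "predation.json",
        {
            "bic_comparison": pred_fit["bic_comparison"],
            "mean_predicted": pred_fit["mean_predicted"],
            "observed_rate": pred_fit["observed_rate"],
            "r_squared": pred_fit["model"].r_squared,
            "n": pred_fit["model"].n,
        },
        cfg_hash,
    )
    artifacts["predation"] = outdir / "predation.json"
    log["timings_s"]["predation"] = round(time.time() - t, 2)

    # --- stage 5: exposure fractions -----------------------------------
    if config.driver == "phi":
        t = time.time()
        fracs = {}
        for kind, tr in (("rearing", fry_tr), ("migration", smolt_tr)):
            series = phimod.phi_series(env, tr)
            pair = threshold_pairs[kind]
            th = phimod.Thresholds(pair.crit, pair.stable)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f = phimod.presence_weighted_fractions(series, series["date"].unique(), th)
            fracs[kind] = {
                "below_crit": f.frac_below_crit,
                "between": f.frac_between,
                "above_stable": f.frac_above_stable,
                "n_days": f.n_days,
            }
        _write_json(outdir / "fractions.json", fracs, cfg_hash)
        artifacts["fractions"] = outdir / "fractions.json"
        log["timings_s"]["fractions"] = round(time.time() - t, 2)

    log["timings_s"]["total"] = round(time.time() - t0, 2)
    _write_json(outdir / "run_log.json", log, cfg_hash)
    artifacts["run_log"] = outdir / "run_log.json"
    return artifacts
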