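"""End-to-end orchestration: config-driven tasks and the synthetic report.

The ``report`` task regenerates the package's full synthetic study: the four
membrane systems (pure DMPC and DMPC with cyclosporin, the cyclodextrin
copolymer, or their amorphous solid dispersion) at 298 K and 308 K, analysed
through de-Pake-ing to fluidity profiles and relative-fluidity histograms,
plus the ³¹P CSA measurements, CSA- and ESR-order transition fits, and the
Job/binding analysis.  All randomness flows from one global seed, fanned out
deterministically per stage, so a report is bit-reproducible.

Per-system synthetic parameters other than the ²H endpoint splittings (which
have published values) are package choices consistent with the qualitative
record: CSA near 58 ppm in the fluid phase with an ~18 ppm rise below the
transition, a ~297 K midpoint (~1 K lower with cyclosporin), and 5-doxyl
hyperfine extrema relaxing across the transition.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import binding as bd
from . import deuterium as deu
from . import esr as esr_mod
from . import phosphorus as ph
from . import spectra as sio
from . import synthetic as syn
from .errors import ConfigError

logger = logging.getLogger("memspec")

TASKS = ("simulate", "depake", "csa", "esr", "binding", "transition", "report")

SYSTEMS = ("DMPC", "DMPC+CYSP", "DMPC+POLYA", "DMPC+ASD")

# per-system synthetic study conditions (see module docstring)
CSA_DEFAULTS = {  # fluid-phase CSA ppm, low-T CSA ppm, midpoint K
    "DMPC": (58.0, 76.0, 297.0),
    "DMPC+CYSP": (58.0, 66.0, 296.0),
    "DMPC+POLYA": (57.0, 73.0, 297.0),
    "DMPC+ASD": (57.0, 73.0, 297.0),
}
ESR_DEFAULTS = {  # (2T_par gel, 2T_par fluid) Gauss; 2T_perp fixed at 20 G
    "DMPC": (62.0, 52.0),
    "DMPC+CYSP": (60.0, 54.0),
    "DMPC+POLYA": (58.0, 50.0),
    "DMPC+ASD": (60.0, 51.0),
}

# deterministic per-stage seed fan-out offsets
_STAGE_OFFSET = {"pake": 11, "csa": 23, "esr": 37, "binding": 53, "transition": 71}


def _stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    return (int(global_seed) * 1009 + _STAGE_OFFSET[stage] * 97 + index) % (2**31)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def validate_config(config: dict) -> None:
    problems = []
    task = config.get("task")
    if task not in TASKS:
        problems.append(f"task: got {task!r}, expected one of {TASKS}")
    if task in ("depake", "csa", "esr", "binding", "transition") and not config.get("input"):
        problems.append("input: required for this task")
    if task == "simulate" and config.get("generator") not in (
        "pake", "csa", "esr", "transition", "job", None,
    ):
        problems.append(f"generator: unknown {config.get('generator')!r}")
    seed = config.get("seed", 0)
    if not isinstance(seed, (int, np.integer)):
        problems.append("seed: must be an integer")
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))


def _snr_noise(intensity: np.ndarray, snr: float) -> float:
    return float(np.max(np.abs(intensity)) / snr)


def fixture_spectrum(
    system: str,
    temperature: float = 298.0,
    snr: float = 100.0,
    seed: int | None = None,
    n_points: int = 2048,
    broadening_khz: float = 0.5,
    axis_range_khz: float = 45.0,
) -> sio.Spectrum1D:
    """Noisy DMPC-d54 fixture powder spectrum for one system/temperature."""
    comps = syn.dmpc_d54_fixture(system, temperature)
    clean = syn.simulate_pake_spectrum(
        comps, broadening_khz=broadening_khz, axis_range_khz=axis_range_khz,
        n_points=n_points, noise_sd=0.0,
    )
    noise_sd = _snr_noise(clean.intensity, snr) if snr else 0.0
    s = syn.simulate_pake_spectrum(
        comps, broadening_khz=broadening_khz, axis_range_khz=axis_range_khz,
        n_points=n_points, noise_sd=noise_sd, seed=seed,
    )
    s.temperature = float(temperature)
    s.metadata["system"] = system
    return s


def analyze_fixture(
    system: str,
    temperature: float = 298.0,
    seed: int | None = None,
    snr: float = 100.0,
    lam="lcurve",
    n_points: int = 2048,
) -> deu.FluidityProfile:
    """Generate, de-Pake and assign one fixture system."""
    s = fixture_spectrum(system, temperature, snr=snr, seed=seed, n_points=n_points)
    dist = deu.depake(s, lam=lam)
    comps = deu.extract_splittings(dist, max_components=8)
    return deu.assign_profile(comps, system=system, temperature=temperature)


def _write_json(obj, path: Path, seed, cfg_hash) -> None:
    payload = {"seed": seed, "config_hash": cfg_hash, "result": obj}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")


def run_report(outdir: Path, seed: int = 0, config: dict | None = None) -> dict:
    """Full synthetic reproduction; returns the in-memory report dict."""
    config = dict(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash({"task": "report", "seed": seed, **config})
    systems = config.get("systems", list(SYSTEMS))
    temperatures = config.get("temperatures", [298.0, 308.0])
    n_points = int(config.get("n_points", 2048))
    snr = float(config.get("snr", 100.0))
    report: dict = {"seed": seed, "config_hash": cfg_hash}

    # --- 2H fluidity profiles and relative-fluidity histograms ----------
    profiles: dict = {}
    t0 = time.time()
    for ti, temp in enumerate(temperatures):
        for si, system in enumerate(systems):
            stage_seed = _stage_seed(seed, "pake", 10 * ti + si)
            prof = analyze_fixture(system, temp, seed=stage_seed, snr=snr, n_points=n_points)
            profiles[(system, temp)] = prof
            rows = [
                {"label": lab, "delta_nu_q_kHz": dnq, "S_CD": scd, "weight": wt}
                for lab, dnq, scd, wt in prof.records
            ]
            name = f"profile_{system.replace('+', '_')}_{int(temp)}K"
            _write_json(rows, outdir / f"{name}.json", seed, cfg_hash)
    logger.info("2H profiles done in %.1f s", time.time() - t0)
    histograms: dict = {}
    for temp in temperatures:
        ref = profiles.get(("DMPC", temp))
        if ref is None:
            continue
        for system in systems:
            if system == "DMPC":
                continue
            prof = profiles[(system, temp)]
            common = [lab for lab in ref.labels if lab in prof.labels]
            sub_x = deu.FluidityProfile(
                [r for r in prof.records if r[0] in common], prof.system, prof.temperature
            )
            sub_r = deu.FluidityProfile(
                [r for r in ref.records if r[0] in common], ref.system, ref.temperature
            )
            rel = deu.relative_fluidity(sub_x, sub_r)
            histograms[(system, temp)] = rel.values
    hist_rows = [
        {"system": system, "T_K": temp, **values}
        for (system, temp), values in sorted(histograms.items())
    ]
    _write_json(hist_rows, outdir / "relative_fluidity.json", seed, cfg_hash)
    report["profiles"] = {
        f"{sys_}@{temp:g}K": prof.records for (sys_, temp), prof in profiles.items()
    }
    report["relative_fluidity"] = {
        f"{sys_}@{temp:g}K": vals for (sys_, temp), vals in histograms.items()
    }

    # --- 31P CSA measurements and transition fits -----------------------
    csa_out = {}
    for si, system in enumerate(systems):
        fluid_csa, gel_csa, midpoint = CSA_DEFAULTS[system]
        model = syn.CsaModel(csa=fluid_csa, broadening=1.0)
        clean = syn.simulate_csa_powder(model, n_points=n_points)
        s = syn.simulate_csa_powder(
            model, n_points=n_points, noise_sd=_snr_noise(clean.intensity, snr),
            seed=_stage_seed(seed, "csa", si),
        )
        m = ph.measure_csa(s)
        temps = np.arange(290.0, 310.5, 1.0)
        series = syn.simulate_transition_series(
            syn.TransitionGroundTruth(gel_csa, fluid_csa, midpoint, 0.8),
            temps, noise_sd=0.02 * (gel_csa - fluid_csa),
            seed=_stage_seed(seed, "transition", si), observable_name="CSA_ppm",
        )
        fit = ph.fit_transition(series)
        csa_out[system] = {
            "csa_ppm": m.csa,
            "transition_midpoint_K": fit.midpoint,
            "transition_amplitude_ppm": fit.amplitude,
        }
    _write_json(csa_out, outdir / "csa.json", seed, cfg_hash)
    report["csa"] = csa_out

    # --- ESR order-parameter temperature profiles ------------------------
    esr_out = {}
    for si, system in enumerate(systems):
        par_gel, par_fluid = ESR_DEFAULTS[system]
        gt = syn.TransitionGroundTruth(par_gel, par_fluid, CSA_DEFAULTS[system][2], 0.8)
        temps = np.arange(290.0, 310.5, 2.0)
        pairs = []
        for ti, temp in enumerate(temps):
            two_t_par = float(syn.logistic_transition(temp, gt))
            model = syn.EsrModel(two_T_par=two_t_par, two_T_perp=20.0)
            clean = syn.simulate_esr_spectrum(model, n_points=1024)
            spec = syn.simulate_esr_spectrum(
                model, n_points=1024, noise_sd=_snr_noise(clean.intensity, snr),
                seed=_stage_seed(seed, "esr", 100 * si + ti),
            )
            pairs.append((temp, spec))
        table = esr_mod.order_temperature_profile(pairs)
        sio.write_series(
            table, outdir / f"esr_{SYSTEMS.index(system) if system in SYSTEMS else si}.csv",
            {"system": system, "seed": seed, "config_hash": cfg_hash},
        )
        fit = ph.fit_transition(table, column="S")
        esr_out[system] = {
            "transition_midpoint_K": fit.midpoint,
            "S_low_T": fit.low_value,
            "S_high_T": fit.high_value,
        }
    _write_json(esr_out, outdir / "esr.json", seed, cfg_hash)
    report["esr"] = esr_out

    # --- binding ----------------------------------------------------------
    gt = syn.polya_titration_ground_truth(log_ka=4.5)
    fractions = np.arange(0.10, 0.901, 0.05)
    series = syn.simulate_job_series(gt, fractions, noise_sd_ppm=0.002,
                                     seed=_stage_seed(seed, "binding"))
    job = bd.job_transform(series)
    fit = bd.fit_association_constant(series)
    binding_out = {
        "job_argmax": job.pooled_argmax,
        "log_ka": fit.log_ka,
        "rss": fit.rss,
        "converged": fit.converged,
    }
    _write_json(binding_out, outdir / "binding.json", seed, cfg_hash)
    report["binding"] = binding_out
    return report


def run(config: dict, outdir=None) -> dict:
    """Execute one configured task; returns a result dict."""
    validate_config(config)
    task = config["task"]
    seed = int(config.get("seed", 0))
    outdir = Path(outdir or config.get("out", "memspec_out"))
    if task == "report":
        return run_report(outdir, seed=seed, config=config.get("report", {}))
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(config)
    if task == "simulate":
        return _run_simulate(config, outdir, seed)
    if task == "depake":
        s = sio.read_spectrum(config["input"], unit="kHz", mode="2H")
        dist = deu.depake(s, lam=config.get("lam", "lcurve"))
        comps = deu.extract_splittings(
            dist,
            min_separation_khz=float(config.get("min_separation_khz", 1.0)),
            max_components=int(config.get("max_components", 10)),
        )
        prof = deu.assign_profile(comps, system=config.get("system", "unknown"),
                                  temperature=float(config.get("temperature", 298.0)))
        result = {
            "residual": dist.residual,
            "lambda": dist.lam,
            "profile": [
                {"label": lab, "delta_nu_q_kHz": d, "S_CD": sc, "weight": w}
                for lab, d, sc, w in prof.records
            ],
        }
        _write_json(result, outdir / "depake.json", seed, cfg_hash)
        return result
    if task == "csa":
        s = sio.read_spectrum(config["input"], unit="ppm", mode="31P")
        m = ph.measure_csa(s, edge_threshold=float(config.get("edge_threshold", 0.05)))
        result = vars(m)
        if config.get("reference_frequency"):
            iso = ph.detect_isotropic(s, float(config["reference_frequency"]))
            result["isotropic"] = vars(iso)
        _write_json(result, outdir / "csa.json", seed, cfg_hash)
        return result
    if task == "esr":
        s = sio.read_spectrum(config["input"], unit="Gauss", mode="ESR-derivative")
        m = esr_mod.measure_hyperfine(s)
        order = esr_mod.esr_order_parameter(m, form=config.get("form", "as-printed"))
        result = {
            "two_T_par_G": m.two_T_par,
            "two_T_perp_G": m.two_T_perp,
            "C_G": order.c_correction,
            "S": order.s,
            "unincorporated_probe": m.unincorporated_probe,
        }
        _write_json(result, outdir / "esr.json", seed, cfg_hash)
        return result
    if task == "binding":
        table = sio.read_series(config["input"], key="F")
        shift_cols = [c for c in table.df.columns if c != "F"]
        free = config.get("delta_free")
        series = bd.TitrationSeries(
            fractions=table.key_values,
            shifts={c: table.df[c].to_numpy(float) for c in shift_cols},
            total_conc=float(config.get("total_conc", 2e-3)),
            delta_free=free,
        )
        job = bd.job_transform(series)
        fit = bd.fit_association_constant(series)
        result = {
            "job_argmax": job.pooled_argmax,
            "log_ka": fit.log_ka,
            "delta_bound": fit.delta_bound,
            "rss": fit.rss,
            "converged": fit.converged,
        }
        _write_json(result, outdir / "binding.json", seed, cfg_hash)
        job_table = sio.SeriesTable.from_columns(
            "F", job.fractions, **{f"y_{lab}": y for lab, y in job.response.items()}
        )
        sio.write_series(job_table, outdir / "job_curve.csv",
                         {"seed": seed, "config_hash": cfg_hash})
        return result
    if task == "transition":
        table = sio.read_series(config["input"])
        fit = ph.fit_transition(table)
        result = vars(fit)
        _write_json(result, outdir / "transition.json", seed, cfg_hash)
        return result
    raise ConfigError(f"unhandled task {task!r}")  # pragma: no cover


def _run_simulate(config: dict, outdir: Path, seed: int) -> dict:
    gen = config.get("generator", "pake")
    params = dict(config.get("params", {}))
    out_path = outdir / config.get("output", f"{gen}.txt")
    if gen == "pake":
        comps = [syn.PakeComponent(**c) for c in params.pop("components", [])]
        if not comps and params.get("system"):
            comps = syn.dmpc_d54_fixture(params.pop("system"),
                                         params.pop("temperature", 298.0))
        s = syn.simulate_pake_spectrum(comps, seed=seed, **params)
    elif gen == "csa":
        model = syn.CsaModel(**params.pop("model", {"csa": 58.0}))
        s = syn.simulate_csa_powder(model, seed=seed, **params)
    elif gen == "esr":
        model = syn.EsrModel(**params.pop("model", {"two_T_par": 60.0, "two_T_perp": 20.0}))
        s = syn.simulate_esr_spectrum(model, seed=seed, **params)
    elif gen == "transition":
        gt = syn.TransitionGroundTruth(**params.pop("ground_truth"))
        table = syn.simulate_transition_series(gt, seed=seed, **params)
        sio.write_series(table, out_path, {"seed": seed})
        return {"output": str(out_path), "rows": len(table)}
    elif gen == "job":
        gt = syn.BindingGroundTruth(**params.pop("ground_truth", {"log_ka": 4.5}))
        fractions = params.pop("fractions", list(np.arange(0.1, 0.91, 0.1)))
        series = syn.simulate_job_series(gt, fractions, seed=seed, **params)
        table = sio.SeriesTable.from_columns(
            "F", series.fractions, **{lab: v for lab, v in series.shifts.items()}
        )
        sio.write_series(table, out_path, {"seed": seed})
        return {"output": str(out_path), "rows": len(table)}
    else:
        raise ConfigError(f"unknown generator {gen!r}")
    s.metadata["seed"] = seed
    sio.write_spectrum(s, out_path)
    return {"output": str(out_path), "points": s.n}
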