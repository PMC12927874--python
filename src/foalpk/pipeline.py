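"""Reproducible fit -> diagnostics -> PTA pipeline driven by a config mapping.

Every stage derives its random stream from named seeds in the config; the
run log records the dataset hash, config hash, per-stage wall times and
package versions so any artifact can be traced back to its inputs.  A
stored fit (``fit.json``) is reused when the config carries no ``fit``
block, so PTA-only reruns do not re-estimate.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compartmental import Regimen
from .cohort import CohortSpec, generate_dataset, mic_fixture
from .dataset import PKDataset, read_dataset, write_dataset
from .diagnostics import iwres, npde, parametric_bootstrap_sse, pc_vpc
from .estimation import ModelSpec, SaemSettings, saem_fit
from .popmodel import PopulationModel, reference_model, reference_rse
from .pta import (
    DEFAULT_MIC_GRID,
    DEFAULT_REGIMEN_GRID,
    DEFAULT_TARGETS,
    PKPDTarget,
    PopulationScenario,
    pta_report,
    simulate_pta,
)

__all__ = ["run_pipeline", "load_config"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _model_from_config(cfg: dict) -> PopulationModel:
    if cfg.get("model", "reference") == "reference":
        return reference_model()
    return PopulationModel(**cfg["model"])


def _scenario_from_config(block: dict) -> PopulationScenario:
    src = block.get("age_source", "cohort")
    if isinstance(src, str) and src.startswith("age:"):
        _, med, sd = src.split(":")
        age_source = ("lognormal", float(med), float(sd))
    elif src == "cohort":
        age_source = ("cohort", None)
    else:
        age_source = tuple(src)
    return PopulationScenario(
        n_subjects=block.get("n", 1000),
        age_source=age_source,
        parameter_uncertainty=block.get("parameter_uncertainty", True),
        fu=block.get("fu", 0.85),
        name=block.get("name", "study"),
    )


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> Path:
    """Run the configured stages; returns the artifact directory.

    Raises at the first failing stage, leaving the artifacts of completed
    stages in place, with the stage name in the exception message.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(output_dir or config.get("output_dir", "foalpk_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    log: dict = {
        "config_hash": _hash(config),
        "seed": seed,
        "version": __version__,
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                res = fn()
            except Exception as exc:  # halt with the stage name, keep artifacts
                log["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_log(out, log)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log["stages"][name] = {"status": "ok", "wall_s": round(time.time() - t0, 3)}
            return res

        return deco

    # --- data ---------------------------------------------------------
    @stage("data")
    def dataset() -> PKDataset:
        dcfg = config.get("data", {})
        if "path" in dcfg:
            ds = read_dataset(dcfg["path"])
        else:
            spec = CohortSpec(**dcfg.get("cohort", {}))
            reg = Regimen(**dcfg.get("regimen", {"dose_per_kg": 20.0, "interval": 6.0}))
            gen = _model_from_config(config)
            ds = generate_dataset(spec, gen, reg, np.random.default_rng(seed))
        write_dataset(ds, out / "dataset.csv")
        return ds

    log["dataset_hash"] = hashlib.sha256(
        pd.util.hash_pandas_object(dataset.frame).values.tobytes()
    ).hexdigest()[:16]

    # --- fit ----------------------------------------------------------
    fit = None
    model = _model_from_config(config)
    fit_json = out / "fit.json"
    if "fit" in config:

        @stage("fit")
        def fit():
            fcfg = config["fit"] or {}
            spec = ModelSpec.from_population_model(model)
            settings = SaemSettings(seed=seed, **fcfg.get("saem", {}))
            f = saem_fit(dataset, spec, settings)
            f.parameter_table().to_csv(out / "fit_parameters.csv", index=False)
            payload = {
                "estimates": f.estimates,
                "rse": f.rse,
                "loglik": f.loglik,
                "bicc": f.bicc,
                "converged": f.converged,
                "warnings": f.warnings,
                "shrinkage": f.shrinkage,
            }
            fit_json.write_text(json.dumps(payload, indent=2, default=float))
            log["fit_converged"] = f.converged
            return f

        sim_model = fit.to_population_model()
        sim_rse = fit.rse
    elif fit_json.exists():
        stored = json.loads(fit_json.read_text())
        est = stored["estimates"]
        sim_model = reference_model().with_updates(
            **{k: v for k, v in est.items() if hasattr(reference_model(), k)}
        )
        sim_rse = stored.get("rse", {})
        log["stages"]["fit"] = {"status": "reused", "source": str(fit_json)}
    else:
        sim_model = model
        sim_rse = reference_rse()

    # --- diagnostics --------------------------------------------------
    if "diagnostics" in config:

        @stage("diagnostics")
        def _diag():
            dcfg = config["diagnostics"] or {}
            rng = np.random.default_rng(seed + 1)
            if dcfg.get("vpc", True):
                v = pc_vpc(dataset, sim_model, n_sim=dcfg.get("n_sim", 500),
                           binning=dcfg.get("binning", "time"), rng=rng)
                v.bands.to_csv(out / "vpc_bands.csv", index=False)
                log["stages"].setdefault("diagnostics", {})
                log["vpc_coverage"] = v.coverage
            if dcfg.get("npde", True):
                nd = npde(dataset, sim_model, n_sim=dcfg.get("n_sim", 500), rng=rng)
                nd["table"].to_csv(out / "npde.csv", index=False)
                log["npde_shapiro_p"] = nd["shapiro_p"]
            if dcfg.get("iwres", True) and fit is not None:
                iwres(fit).to_csv(out / "iwres.csv", index=False)

    # --- bootstrap ----------------------------------------------------
    if "bootstrap" in config:

        @stage("bootstrap")
        def _boot():
            bcfg = config["bootstrap"] or {}
            settings = SaemSettings(
                seed=seed + 2, compute_loglik=False, compute_fim=False,
                **bcfg.get("saem", {}),
            )
            sse = parametric_bootstrap_sse(
                sim_model, dataset, n_rep=bcfg.get("n_rep", 100),
                settings=settings, rng=np.random.default_rng(seed + 2),
            )
            sse.table.to_csv(out / "bootstrap.csv", index=False)
            log["bootstrap_convergence_rate"] = sse.convergence_rate

    # --- pta ----------------------------------------------------------
    if "pta" in config:

        @stage("pta")
        def _pta():
            pcfg = config["pta"] or {}
            regs = [
                Regimen(d, i)
                for d in pcfg.get("doses", (15.0, 20.0, 30.0, 40.0))
                for i in pcfg.get("intervals", (4.0, 6.0, 8.0))
            ] if "doses" in pcfg or "intervals" in pcfg else list(DEFAULT_REGIMEN_GRID)
            mics = tuple(pcfg.get("mic_grid", DEFAULT_MIC_GRID))
            targets = [
                PKPDTarget(t["fraction"], t.get("multiplier", 1.0))
                for t in pcfg.get("targets", [])
            ] or list(DEFAULT_TARGETS)
            frames = []
            for block in pcfg.get("scenarios", [{"name": "study"}]):
                scen = _scenario_from_config(block)
                res = simulate_pta(
                    sim_model, regs, mics, targets, scen,
                    rng=np.random.default_rng(seed + 3),
                    rse=sim_rse or None,
                )
                frames.append(res.table)
                rep = pta_report(res)
                rep.to_csv(out / f"pta_report_{scen.name}.csv", index=False)
            pd.concat(frames, ignore_index=True).to_csv(out / "pta.csv", index=False)
            mic_fixture().to_csv(out / "mic_isolates.csv", index=False)

    _write_log(out, log)
    return out


def _write_log(out: Path, log: dict) -> None:
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=float))
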