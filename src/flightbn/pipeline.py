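"""End-to-end orchestration: simulate -> filter -> discretize -> curves ->
learn -> evaluate -> crossval -> influence, with a reproducible run
directory and machine-readable manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .curvefit import cooks_outliers, fit_gaussian, interval_maxima
from .data_model import (
    SPECIES,
    AnomalyRules,
    CaseFile,
    casefile_hash,
    exclude_fault_days,
    flag_anomalies,
    read_casefile,
    summarize_positive_hours,
    write_casefile,
)
from .discretize import unsupervised_bins
from .evaluate import GRID, THRESHOLDS_REPORTED
from .model import FlightActivityModel
from .synthetic_data import GeneratorConfig, generate_casefile

log = logging.getLogger("flightbn")


@dataclass
class PipelineConfig:
    """Everything a run needs; all randomness flows from ``seed``."""

    out_dir: str = "runs/run"
    casefile: str | None = None  # path; None -> simulate
    species: tuple[str, ...] = SPECIES
    seed: int = 0
    structure: str = "tan"
    alpha: float = 1.0
    em_tol: float = 1e-6
    em_max_iter: int = 200
    thresholds: tuple[float, ...] = THRESHOLDS_REPORTED
    cv_k: int = 4
    cv_iterations: int = 100
    run_cv: bool = False
    n_curve_bins: int = 20
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        if self.cv_k < 2:
            raise ValueError("cv_k must be >= 2")
        if any(not 0 < t <= 1 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen:
            cfg.generator = GeneratorConfig(**gen)
        return cfg


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write all artifacts under the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    _stage("simulate/load")
    if config.casefile is None:
        cf = generate_casefile(config.generator, seed=int(rng.integers(2**31)))
        write_casefile(cf, out / "casefile.csv")
    else:
        cf = read_casefile(config.casefile)

    _stage("filter")
    cf = exclude_fault_days(cf)
    cf, flag_report = flag_anomalies(cf, AnomalyRules())
    (out / "anomaly_report.json").write_text(json.dumps(flag_report, indent=2))
    summaries = {sp: summarize_positive_hours(cf, sp) for sp in config.species}
    (out / "positive_hours.json").write_text(json.dumps(summaries, indent=2))

    _stage("curves")
    curve_out = {}
    for sp in config.species:
        try:
            scheme = unsupervised_bins(
                cf.data["max_temp_c"].to_numpy(), config.n_curve_bins, variable="max_temp_c"
            )
            bins = interval_maxima(
                cf.data["max_temp_c"].to_numpy(), cf.modelling_counts(sp).to_numpy(), scheme
            )
            fit = fit_gaussian(bins)
            screen = cooks_outliers(fit, bins, refit=fit_gaussian)
            if screen["refit"] is not None:
                fit = screen["refit"]
            curve_out[sp] = fit.to_dict()
        except (ValueError, RuntimeError) as err:
            curve_out[sp] = {"error": f"temperature curve fit failed: {err}"}
    (out / "curve_fits.json").write_text(json.dumps(curve_out, indent=2))

    _stage("learn/evaluate/influence")
    metrics_all = {}
    for sp in config.species:
        res = FlightActivityModel(
            cf, sp, structure=config.structure, alpha=config.alpha
        ).fit(em_tol=config.em_tol, em_max_iter=config.em_max_iter)
        (out / f"model_{sp}.json").write_text(res.bn.to_json())
        metrics_all[sp] = {
            "scores": res.metrics,
            "network": res.network_summary(),
            "threshold_errors": res.threshold_errors(config.thresholds).to_dict("records"),
        }
        res.sensitivity().to_csv(out / f"sensitivity_{sp}.tsv", sep="\t", index=False)
        res.tornado().to_csv(out / f"tornado_{sp}.tsv", sep="\t", index=False)
        res.type2_roc().to_csv(out / f"type2_roc_{sp}.tsv", sep="\t", index=False)
        if config.run_cv:
            _stage(f"crossval:{sp}")
            cv = res.crossval(
                k=config.cv_k,
                iterations=config.cv_iterations,
                seed=int(rng.integers(2**31)),
            )
            cv.to_frame().to_csv(out / f"cv_{sp}.tsv", sep="\t", index=False)
    (out / "metrics.json").write_text(json.dumps(metrics_all, indent=2, default=float))

    manifest = {
        "flightbn_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "casefile_hash": casefile_hash(cf),
        "config": _config_dict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
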