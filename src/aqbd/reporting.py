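"""Verification arithmetic and the end-to-end pipeline report bundle.

The pipeline ties the stages together: read a measured design table, fit
and prune one quadratic model per response, summarise fit quality, map the
sweet spot and the Monte Carlo design space, locate the optimal operating
point, and (when a verification table is supplied) check every robustness
run against the CMA criteria.  Everything is written as machine-readable
CSV/JSON; reruns with identical inputs and seeds produce byte-identical
numeric output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import StudyConfig
from .design import DesignTable, read_design_csv
from .model import (ResponseModel, backward_eliminate, coefficient_intervals,
                    fit_statistics, model_to_json)
from .space import (OptimizationResult, ProbabilityMap, VerificationReport,
                    modr_region, optimize_conditions, sweet_spot_map,
                    verify_runs)

__all__ = ["recovery_percent", "relative_difference_percent",
           "run_pipeline", "ReportBundle"]

log = logging.getLogger("aqbd")


def recovery_percent(added: float, found: float) -> float:
    """Spiked recovery, 100 x found/added, reported to 2 decimals.

    Recovery is the standard accuracy metric for an analytical method:
    how much of a known added amount the method finds.
    """
    if added <= 0:
        raise ValueError("added concentration must be > 0")
    return round(100.0 * found / added, 2)


def relative_difference_percent(predicted: float, observed: float) -> float:
    """Predicted-vs-observed agreement, 100 x |pred - obs| / |pred|."""
    if predicted == 0:
        raise ValueError("predicted value must be nonzero")
    return 100.0 * abs(predicted - observed) / abs(predicted)


@dataclass
class ReportBundle:
    """In-memory results of :func:`run_pipeline` plus written file paths."""

    models: dict[str, ResponseModel]
    statistics: pd.DataFrame
    coefficients: pd.DataFrame
    sweet_spot: pd.DataFrame
    modr: ProbabilityMap
    optimum: OptimizationResult
    verification: VerificationReport | None
    paths: dict[str, Path] = field(default_factory=dict)


def _stats_frame(models: dict[str, ResponseModel],
                 design: DesignTable) -> pd.DataFrame:
    rows = []
    for rname, model in models.items():
        st = fit_statistics(model, design)
        rows.append({"response": rname, **st.as_dict()})
    return pd.DataFrame(rows)


def run_pipeline(config: StudyConfig, design_csv, output_dir,
                 verification_csv=None) -> ReportBundle:
    """Run the full optimization workflow and write the report bundle.

    Outputs under *output_dir*: ``models.json``, ``statistics.csv``
    (per-response regression p-value, R^2, adjusted R^2, Q^2,
    reproducibility), ``coefficients.csv`` (estimates with confidence
    intervals), ``sweet_spot.csv``, ``modr.csv`` + ``modr_summary.json``,
    ``optimum.json``, and ``verification.csv`` when a verification table
    is supplied.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = read_design_csv(design_csv, config.factors, config.responses,
                             name=str(design_csv))
    log.info("pipeline: %d runs, %d responses, alpha=%g, seed=%d",
             design.n_runs, len(config.responses), config.alpha, config.seed)

    models: dict[str, ResponseModel] = {}
    coef_rows = []
    for rname in config.responses:
        model = backward_eliminate(design, rname, alpha=config.alpha)
        models[rname] = model
        ci = coefficient_intervals(model)
        ci.insert(0, "response", rname)
        coef_rows.append(ci)
        log.info("fit %s: %d terms retained", rname, len(model.terms))
    coefficients = pd.concat(coef_rows, ignore_index=True)
    statistics = _stats_frame(models, design)

    model_list = [models[c.response_name] for c in config.cmas]
    grid = config.default_grid()
    counts = sweet_spot_map(model_list, config.cmas, grid)
    pmap = modr_region(model_list, config.cmas, grid,
                       assurance_level=config.assurance_level,
                       n_simulations=config.n_simulations, seed=config.seed,
                       include_residual=config.include_residual)
    sweet_frame = pmap.to_frame()[[grid.axes[0].name, grid.axes[1].name]].copy()
    sweet_frame["criteria_met"] = counts.ravel()
    optimum = optimize_conditions(model_list, config.cmas,
                                  n_simulations=config.n_simulations,
                                  seed=config.seed,
                                  include_residual=config.include_residual)
    log.info("optimum: %s (probability %.4f)", optimum.point,
             optimum.pass_probability)

    verification = None
    if verification_csv is not None:
        vtable = read_design_csv(verification_csv, config.factors,
                                 config.responses,
                                 name=str(verification_csv))
        verification = verify_runs(vtable, config.cmas)
        log.info("verification: %d runs, overall %s", vtable.n_runs,
                 "PASS" if verification.overall_pass else "FAIL")

    paths: dict[str, Path] = {}

    def _write_csv(key: str, frame: pd.DataFrame) -> None:
        p = outdir / f"{key}.csv"
        frame.to_csv(p, index=False, float_format="%.17g")
        paths[key] = p

    meta = {"aqbd_version": __version__, "seed": config.seed,
            "n_simulations": config.n_simulations,
            "include_residual": config.include_residual}
    p = outdir / "models.json"
    p.write_text(json.dumps(
        {"meta": meta,
         "models": {r: json.loads(model_to_json(m))
                    for r, m in models.items()}}, indent=1))
    paths["models"] = p
    _write_csv("statistics", statistics)
    _write_csv("coefficients", coefficients)
    _write_csv("sweet_spot", sweet_frame)
    _write_csv("modr", pmap.to_frame())
    p = outdir / "modr_summary.json"
    p.write_text(json.dumps({"meta": meta, **pmap.summary()}, indent=1))
    paths["modr_summary"] = p
    p = outdir / "optimum.json"
    p.write_text(json.dumps({"meta": meta, **optimum.as_dict()}, indent=1))
    paths["optimum"] = p
    if verification is not None:
        _write_csv("verification", verification.table)

    return ReportBundle(models=models, statistics=statistics,
                        coefficients=coefficients, sweet_spot=sweet_frame,
                        modr=pmap, optimum=optimum,
                        verification=verification, paths=paths)
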