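"""Synthetic design-response data with the structure the analysis assumes.

The modelling stack assumes each response is a quadratic polynomial in the
coded factors plus independent homoscedastic Gaussian noise; the generator
here realizes exactly that, so every downstream stage (fitting, term
selection, design-space mapping) can be exercised with known ground truth.
It makes no attempt at mechanistic chromatography (plate theory, retention
models): only the statistical structure is emulated, so conclusions from
synthetic runs speak to the statistics, not to real selectivity behaviour.

:func:`celecoxib_truth` provides a realistic default scenario: truth
surfaces taken from the models fitted to the bundled 17-run study design,
with noise scales set to the centre-replicate spread of the measured data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignTable
from .model import TermSpec, backward_eliminate, coefficient_intervals, fit_ols

__all__ = [
    "TruthSurface",
    "simulate_design_responses",
    "celecoxib_truth",
    "parameter_recovery_report",
]


@dataclass(frozen=True)
class TruthSurface:
    """A known polynomial response surface with replicate noise scale.

    Coefficients are in coded units.  ``noise_sd`` is the standard
    deviation of independent Gaussian measurement noise added per run.
    """

    response_name: str
    terms: tuple[TermSpec, ...]
    true_coefficients: tuple[float, ...]
    noise_sd: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.terms) != len(self.true_coefficients):
            raise ValueError("one coefficient per term required")

    def evaluate(self, coded: dict[str, float]) -> float:
        return float(sum(b * t.evaluate(coded)
                         for t, b in zip(self.terms, self.true_coefficients)))


def simulate_design_responses(truths: list[TruthSurface], design: DesignTable,
                              seed: int) -> DesignTable:
    """Measure each truth surface at every design point, with noise.

    Response value = polynomial at the run's coded levels + N(0, noise_sd);
    noise is independent across runs and responses.  Reproducible given the
    seed.
    """
    rng = np.random.default_rng(seed)
    responses: dict[str, list[float]] = {}
    for truth in truths:
        for t in truth.terms:
            for f in t.factors:
                if f not in design.factor_names:
                    raise KeyError(
                        f"truth {truth.response_name!r} uses factor {f!r} "
                        "absent from the design")
        clean = np.array([truth.evaluate(p.coded) for p in design.points])
        noise = rng.normal(0.0, truth.noise_sd, size=len(clean)) \
            if truth.noise_sd > 0 else 0.0
        responses[truth.response_name] = list(clean + noise)
    return design.with_responses(responses)


def celecoxib_truth(alpha: float = 0.05) -> list[TruthSurface]:
    """Truth surfaces emulating the celecoxib impurity-method study.

    Coefficients come from hierarchy-preserving backward elimination fits
    to the bundled 17-run design; each ``noise_sd`` is the sample standard
    deviation of the design's three centre replicates (zero for R2, whose
    replicates are identical).
    """
    from .datasets import RESPONSE_NAMES, load_celecoxib_ccf

    design = load_celecoxib_ccf()
    cen = design.center_mask()
    out = []
    for rname in RESPONSE_NAMES:
        model = backward_eliminate(design, rname, alpha=alpha)
        sd = float(np.std(design.response(rname)[cen], ddof=1))
        out.append(TruthSurface(
            response_name=rname,
            terms=tuple(model.terms),
            true_coefficients=tuple(float(b) for b in model.coefficients),
            noise_sd=sd,
            provenance="fitted to bundled celecoxib_ccf.csv; noise from "
                       "centre-replicate spread",
        ))
    return out


def parameter_recovery_report(truths: list[TruthSurface], design: DesignTable,
                              n_replicates: int, seed: int,
                              level: float = 0.95) -> pd.DataFrame:
    """Simulate-and-refit calibration of the fitting stage.

    Repeats ``simulate -> fit_ols`` (with each truth's own term set)
    *n_replicates* times and reports, per truth coefficient: bias, RMSE,
    and the empirical coverage of the ``level`` confidence interval with
    its binomial standard error.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    est: dict[tuple[str, str], list[float]] = {}
    cover: dict[tuple[str, str], list[bool]] = {}
    for _ in range(n_replicates):
        sim = simulate_design_responses(truths, design,
                                        seed=int(rng.integers(2 ** 31)))
        for truth in truths:
            model = fit_ols(sim, truth.response_name, list(truth.terms))
            ci = coefficient_intervals(model, level=level)
            for t, b_true, lo, hi, b_hat in zip(
                    truth.terms, truth.true_coefficients,
                    ci["lower"], ci["upper"], model.coefficients):
                key = (truth.response_name, t.label)
                est.setdefault(key, []).append(float(b_hat))
                # tolerance keeps zero-width (noise-free) intervals from
                # missing the truth by floating-point rounding alone
                eps = 1e-12 * (1.0 + abs(b_true))
                cover.setdefault(key, []).append(
                    bool(lo - eps <= b_true <= hi + eps))
    rows = []
    for truth in truths:
        for t, b_true in zip(truth.terms, truth.true_coefficients):
            key = (truth.response_name, t.label)
            e = np.array(est[key])
            c = np.array(cover[key], dtype=float)
            cov_rate = float(c.mean())
            rows.append({
                "response": truth.response_name,
                "term": t.label,
                "true": b_true,
                "bias": float(e.mean() - b_true),
                "rmse": float(np.sqrt(((e - b_true) ** 2).mean())),
                "ci_coverage": cov_rate,
                "ci_coverage_se": float(np.sqrt(
                    cov_rate * (1 - cov_rate) / n_replicates)),
            })
    return pd.DataFrame(rows)
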