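"""Quadratic factor-response models: OLS fit, term selection, fit statistics.

Each measured response ``y`` is modelled as a quadratic polynomial in coded
factor levels ``x_i``::

    y = b0 + sum_i b_i x_i + sum_i b_ii x_i^2 + sum_{i<j} b_ij x_i x_j + e

with homoscedastic Gaussian residuals.  Coefficients are estimated by
ordinary least squares via QR decomposition (never the explicit normal
equations), reported in coded units so effect sizes are directly
comparable across factors.

Term selection follows hierarchy-preserving backward elimination: starting
from the full quadratic, the single worst non-significant term (two-sided
t-test, p > alpha) is dropped and the model refitted, with the intercept
never removed and a linear term protected while any retained square or
interaction involves its factor.

Fit quality is summarised MODDE-style: R^2, adjusted R^2, cross-validated
Q^2 = 1 - PRESS/SS_tot (PRESS from closed-form leave-one-out residuals
``e_i / (1 - h_ii)``), reproducibility ``1 - MS_pure_error/MS_total`` with
pure error taken from replicated centre points, and the regression ANOVA
F test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .design import DesignTable, Factor

__all__ = [
    "TermSpec",
    "ResponseModel",
    "FitStats",
    "full_quadratic",
    "build_model_matrix",
    "fit_ols",
    "backward_eliminate",
    "fit_statistics",
    "coefficient_intervals",
    "predict",
    "model_to_json",
    "model_from_json",
]

_KINDS = ("intercept", "linear", "square", "interaction")


@dataclass(frozen=True)
class TermSpec:
    """One polynomial term: intercept, linear, square, or interaction."""

    kind: str
    factors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}")
        need = {"intercept": 0, "linear": 1, "square": 1, "interaction": 2}[self.kind]
        if len(self.factors) != need:
            raise ValueError(f"{self.kind} term needs {need} factor name(s)")
        if self.kind == "interaction" and self.factors[0] == self.factors[1]:
            raise ValueError("interaction requires two distinct factors")

    @property
    def label(self) -> str:
        if self.kind == "intercept":
            return "const"
        if self.kind == "linear":
            return self.factors[0]
        if self.kind == "square":
            return f"{self.factors[0]}^2"
        return f"{self.factors[0]}*{self.factors[1]}"

    def evaluate(self, coded: dict[str, float]) -> float:
        if self.kind == "intercept":
            return 1.0
        if self.kind == "linear":
            return coded[self.factors[0]]
        if self.kind == "square":
            return coded[self.factors[0]] ** 2
        return coded[self.factors[0]] * coded[self.factors[1]]


def full_quadratic(factor_names: list[str]) -> list[TermSpec]:
    """Intercept + linear + square + all pairwise interaction terms."""
    terms = [TermSpec("intercept")]
    terms += [TermSpec("linear", (n,)) for n in factor_names]
    terms += [TermSpec("square", (n,)) for n in factor_names]
    terms += [TermSpec("interaction", (a, b))
              for i, a in enumerate(factor_names)
              for b in factor_names[i + 1:]]
    return terms


def build_model_matrix(design: DesignTable, terms: list[TermSpec]) -> np.ndarray:
    """Runs x terms matrix of term values at the design's coded levels."""
    known = set(design.factor_names)
    for t in terms:
        for f in t.factors:
            if f not in known:
                raise KeyError(f"term {t.label!r} references unknown factor {f!r}")
    return np.array([[t.evaluate(p.coded) for t in terms]
                     for p in design.points], dtype=float)


@dataclass
class ResponseModel:
    """A fitted polynomial model for one response, in coded units."""

    response_name: str
    factors: list[Factor]
    terms: list[TermSpec]
    coefficients: np.ndarray
    coefficient_covariance: np.ndarray
    residual_variance: float
    residual_dof: int
    fitted_values: np.ndarray
    residuals: np.ndarray
    design_ref: str = ""
    term_p_values: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def observed(self) -> np.ndarray:
        return self.fitted_values + self.residuals

    @property
    def n_runs(self) -> int:
        return len(self.fitted_values)

    def design_row(self, point: dict[str, float]) -> np.ndarray:
        """Model-matrix row for a *physical* point (coded internally)."""
        coded = {}
        for f in self.factors:
            if f.name not in point:
                raise KeyError(f"point is missing factor {f.name!r}")
            coded[f.name] = f.code(point[f.name])
        return np.array([t.evaluate(coded) for t in self.terms])

    def predict(self, point: dict[str, float]) -> float:
        return float(self.design_row(point) @ self.coefficients)


def _term_p_values(coefficients: np.ndarray, covariance: np.ndarray,
                   dof: int) -> np.ndarray:
    se = np.sqrt(np.clip(np.diag(covariance), 0.0, None))
    p = np.empty_like(coefficients)
    for i, (b, s) in enumerate(zip(coefficients, se)):
        if s == 0.0:
            # degenerate (zero residual variance): any nonzero effect is exact
            p[i] = 0.0 if b != 0.0 else 1.0
        else:
            p[i] = 2.0 * stats.t.sf(abs(b) / s, dof)
    return p


def fit_ols(design: DesignTable, response_name: str,
            terms: list[TermSpec]) -> ResponseModel:
    """Ordinary least squares fit of *terms* to one response.

    Uses a QR decomposition of the model matrix; raises on rank deficiency,
    naming the collinear terms.
    """
    y = design.response(response_name)
    M = build_model_matrix(design, terms)
    n, p = M.shape
    if n <= p:
        raise ValueError(
            f"{response_name}: {n} runs cannot identify {p} terms "
            "with residual degrees of freedom"
        )
    # rank check via pivoted QR: pivots beyond the numerical rank are the
    # columns that are linear combinations of earlier ones
    from scipy.linalg import qr as _qr
    _, Rp, piv = _qr(M, mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rp))
    tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < p:
        bad = [terms[j].label for j in piv[rank:]]
        raise ValueError(
            f"{response_name}: model matrix is rank deficient; "
            f"collinear terms: {bad}"
        )
    Q, R = np.linalg.qr(M)
    coef = solve_triangular(R, Q.T @ y)
    fitted = M @ coef
    resid = y - fitted
    dof = n - p
    rss = float(resid @ resid)
    s2 = rss / dof
    Rinv = solve_triangular(R, np.eye(p))
    xtx_inv = Rinv @ Rinv.T
    cov = s2 * xtx_inv
    cov = 0.5 * (cov + cov.T)  # exact symmetry
    return ResponseModel(
        response_name=response_name,
        factors=list(design.factors),
        terms=list(terms),
        coefficients=coef,
        coefficient_covariance=cov,
        residual_variance=s2,
        residual_dof=dof,
        fitted_values=fitted,
        residuals=resid,
        design_ref=design.name,
        term_p_values=_term_p_values(coef, cov, dof),
    )


def _removable(terms: list[TermSpec]) -> list[int]:
    """Indices of terms eligible for elimination under hierarchy."""
    out = []
    for i, t in enumerate(terms):
        if t.kind == "intercept":
            continue
        if t.kind == "linear":
            fac = t.factors[0]
            if any(u.kind in ("square", "interaction") and fac in u.factors
                   for u in terms):
                continue
        out.append(i)
    return out


def backward_eliminate(design: DesignTable, response_name: str,
                       alpha: float = 0.05,
                       start_terms: list[TermSpec] | None = None) -> ResponseModel:
    """Hierarchy-preserving one-at-a-time backward elimination at *alpha*.

    Starts from the full quadratic in all design factors (or *start_terms*),
    repeatedly refits and drops the removable term with the largest
    two-sided t-test p-value above *alpha*; stops when every removable term
    is significant.  Deterministic.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    terms = list(start_terms) if start_terms is not None \
        else full_quadratic(design.factor_names)
    while True:
        model = fit_ols(design, response_name, terms)
        p = model.term_p_values
        worst, worst_p = None, alpha
        for i in _removable(terms):
            if p[i] > worst_p:
                worst, worst_p = i, p[i]
        if worst is None:
            return model
        terms.pop(worst)


@dataclass(frozen=True)
class FitStats:
    """MODDE-style fit summary for one response model."""

    r2: float
    r2_adjusted: float
    q2: float
    press: float
    reproducibility: float | None
    ms_pure_error: float | None
    f_statistic: float
    p_regression: float
    lack_of_fit_f: float | None = None
    lack_of_fit_p: float | None = None

    def as_dict(self) -> dict:
        return {
            "p_value": self.p_regression,
            "r2": self.r2,
            "r2_adjusted": self.r2_adjusted,
            "q2": self.q2,
            "reproducibility": self.reproducibility,
        }


def fit_statistics(model: ResponseModel, design: DesignTable) -> FitStats:
    """Compute R^2, adjusted R^2, Q^2 (PRESS), reproducibility, and ANOVA.

    Reproducibility uses pure error from centre replicates only:
    ``1 - MS_pure_error / MS_total``; it is ``None`` when the design has
    fewer than two centre replicates.  A supplementary lack-of-fit F test
    is included when pure error is available and nonzero.
    """
    y = design.response(model.response_name)
    M = build_model_matrix(design, model.terms)
    n, p = M.shape
    resid = y - M @ model.coefficients
    rss = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst <= 0.0:
        raise ValueError("response is constant; fit statistics undefined")
    dof = n - p
    r2 = 1.0 - rss / sst
    r2_adj = 1.0 - (rss / dof) / (sst / (n - 1))

    # PRESS via closed-form leave-one-out residuals
    Q, _ = np.linalg.qr(M)
    h = (Q ** 2).sum(axis=1)
    if np.any(h >= 1.0 - 1e-12):
        raise ValueError("leverage 1 for some run: model is saturated, "
                         "PRESS undefined")
    press = float(((resid / (1.0 - h)) ** 2).sum())
    q2 = 1.0 - press / sst

    # regression ANOVA (model vs residual; intercept excluded from numerator)
    df_model = p - 1
    if df_model >= 1 and rss > 0.0:
        f_stat = ((sst - rss) / df_model) / (rss / dof)
        p_reg = float(stats.f.sf(f_stat, df_model, dof))
    elif df_model >= 1:
        f_stat, p_reg = np.inf, 0.0
    else:
        f_stat, p_reg = np.nan, np.nan

    repro = ms_pe = None
    lof_f = lof_p = None
    cen = design.center_mask()
    n_cen = int(cen.sum())
    if n_cen >= 2:
        yc = y[cen]
        ss_pe = float(((yc - yc.mean()) ** 2).sum())
        ms_pe = ss_pe / (n_cen - 1)
        ms_tot = sst / (n - 1)
        repro = 1.0 - ms_pe / ms_tot
        df_lof = dof - (n_cen - 1)
        if ms_pe > 0.0 and df_lof > 0:
            ss_lof = max(rss - ss_pe, 0.0)
            lof_f = (ss_lof / df_lof) / ms_pe
            lof_p = float(stats.f.sf(lof_f, df_lof, n_cen - 1))
    return FitStats(r2=r2, r2_adjusted=r2_adj, q2=q2, press=press,
                    reproducibility=repro, ms_pure_error=ms_pe,
                    f_statistic=float(f_stat), p_regression=p_reg,
                    lack_of_fit_f=lof_f, lack_of_fit_p=lof_p)


def coefficient_intervals(model: ResponseModel,
                          level: float = 0.95) -> pd.DataFrame:
    """Per-term estimates with symmetric t confidence intervals.

    Columns: term, estimate, se, lower, upper, p.
    """
    if model.residual_dof < 1:
        raise ValueError("need at least 1 residual degree of freedom")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    se = np.sqrt(np.clip(np.diag(model.coefficient_covariance), 0.0, None))
    tq = stats.t.ppf(0.5 + level / 2.0, model.residual_dof)
    est = model.coefficients
    return pd.DataFrame({
        "term": [t.label for t in model.terms],
        "estimate": est,
        "se": se,
        "lower": est - tq * se,
        "upper": est + tq * se,
        "p": model.term_p_values,
    })


def predict(model: ResponseModel, point: dict[str, float]) -> float:
    """Predict the response at a physical point (coded internally)."""
    return model.predict(point)


# ---------------------------------------------------------------------------
# JSON round-trip
# ---------------------------------------------------------------------------

def model_to_json(model: ResponseModel) -> str:
    """Serialize a fitted model; floats round-trip bit-exactly."""
    payload = {
        "response_name": model.response_name,
        "factors": [{"name": f.name, "low": f.low, "high": f.high,
                     "unit": f.unit} for f in model.factors],
        "terms": [{"kind": t.kind, "factors": list(t.factors)}
                  for t in model.terms],
        "coefficients": model.coefficients.tolist(),
        "coefficient_covariance": model.coefficient_covariance.tolist(),
        "residual_variance": model.residual_variance,
        "residual_dof": model.residual_dof,
        "fitted_values": model.fitted_values.tolist(),
        "residuals": model.residuals.tolist(),
        "design_ref": model.design_ref,
    }
    return json.dumps(payload, indent=1)


def model_from_json(text: str) -> ResponseModel:
    d = json.loads(text)
    coef = np.array(d["coefficients"])
    cov = np.array(d["coefficient_covariance"])
    return ResponseModel(
        response_name=d["response_name"],
        factors=[Factor(**f) for f in d["factors"]],
        terms=[TermSpec(t["kind"], tuple(t["factors"])) for t in d["terms"]],
        coefficients=coef,
        coefficient_covariance=cov,
        residual_variance=d["residual_variance"],
        residual_dof=d["residual_dof"],
        fitted_values=np.array(d["fitted_values"]),
        residuals=np.array(d["residuals"]),
        design_ref=d.get("design_ref", ""),
        term_p_values=_term_p_values(coef, cov, d["residual_dof"]),
    )
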