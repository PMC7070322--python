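"""Design-space analysis: criteria, sweet spots, Monte Carlo assurance maps.

A critical method attribute (CMA) criterion is a one-sided limit on a
response — "not less than" (NLT) for a chromatographic resolution,
"not more than" (NMT) for a run time.  The *sweet spot* is the factor
region where every criterion is met at the model-mean prediction.  The
*design space* (method operable design region, MODR) is stricter: it keeps
only points where the probability of jointly meeting all criteria — with
coefficient-estimate uncertainty and, by default, future single-measurement
noise propagated by Monte Carlo — reaches an assurance level (99% here).

Uncertainty propagation draws coefficient vectors from the multivariate
normal defined by each model's estimates and covariance; responses are
simulated independently (each CMA has its own model).  All stochastic
operations take an explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ResponseModel, TermSpec

__all__ = [
    "CMASpec",
    "GridAxis",
    "GridSpec",
    "ProbabilityMap",
    "OptimizationResult",
    "VerificationReport",
    "evaluate_criteria",
    "sweet_spot_map",
    "mc_pass_probability",
    "modr_region",
    "optimize_conditions",
    "verify_runs",
    "resolve_targets",
    "DEFAULT_SEED",
    "DEFAULT_N_SIMULATIONS",
    "DEFAULT_GRID_POINTS",
]

DEFAULT_SEED = 20200813
DEFAULT_N_SIMULATIONS = 10_000
DEFAULT_GRID_POINTS = 101

_DIRECTIONS = ("not_less_than", "not_more_than")


@dataclass(frozen=True)
class CMASpec:
    """One acceptance criterion on one response.

    ``not_less_than`` passes iff value >= limit; ``not_more_than`` passes
    iff value <= limit (both inclusive at the boundary).  ``target`` is an
    optional desired value beyond the limit, used to normalize margins
    during optimization.
    """

    response_name: str
    direction: str
    limit: float
    target: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")
        if self.target is not None:
            if self.direction == "not_less_than" and self.target < self.limit:
                raise ValueError("target must be >= limit for not_less_than")
            if self.direction == "not_more_than" and self.target > self.limit:
                raise ValueError("target must be <= limit for not_more_than")

    @property
    def sign(self) -> float:
        """+1 for NLT (bigger is better), -1 for NMT."""
        return 1.0 if self.direction == "not_less_than" else -1.0

    def passes(self, value: float) -> bool:
        return bool(self.sign * (value - self.limit) >= 0.0)

    def margin(self, value: float) -> float:
        """Signed distance from the limit; positive means passing."""
        return self.sign * (value - self.limit)


def evaluate_criteria(values: dict[str, float],
                      cmas: list[CMASpec]) -> tuple[dict[str, bool], int]:
    """Check each criterion against measured/predicted response values.

    Returns per-CMA pass flags (keyed by response name) and the count of
    criteria met.
    """
    flags: dict[str, bool] = {}
    for cma in cmas:
        if cma.response_name not in values:
            raise KeyError(f"no value supplied for response "
                           f"{cma.response_name!r}")
        flags[cma.response_name] = cma.passes(values[cma.response_name])
    return flags, sum(flags.values())


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridAxis:
    name: str
    low: float
    high: float
    n_points: int = DEFAULT_GRID_POINTS

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("each grid axis needs >=2 points")
        if not self.low < self.high:
            raise ValueError(f"grid axis {self.name!r}: low must be < high")

    def values(self) -> np.ndarray:
        return np.linspace(self.low, self.high, self.n_points)


@dataclass(frozen=True)
class GridSpec:
    """A 2-D evaluation grid over two factors, remaining factors fixed."""

    axes: tuple[GridAxis, GridAxis]
    fixed: dict[str, float] = field(default_factory=dict)

    def shape(self) -> tuple[int, int]:
        return (self.axes[0].n_points, self.axes[1].n_points)

    def points(self) -> dict[str, np.ndarray]:
        """Flattened physical coordinates for every grid point (row-major)."""
        a1, a2 = np.meshgrid(self.axes[0].values(), self.axes[1].values(),
                             indexing="ij")
        pts = {self.axes[0].name: a1.ravel(), self.axes[1].name: a2.ravel()}
        n = a1.size
        for name, value in self.fixed.items():
            pts[name] = np.full(n, float(value))
        return pts


def _check_grid(models: list[ResponseModel], grid: GridSpec) -> None:
    factors = {f.name: f for f in models[0].factors}
    for ax in grid.axes:
        f = factors.get(ax.name)
        if f is None:
            raise KeyError(f"grid axis {ax.name!r} is not a model factor")
        if ax.low < f.low or ax.high > f.high:
            raise ValueError(
                f"grid axis {ax.name!r} range [{ax.low}, {ax.high}] outside "
                f"factor range [{f.low}, {f.high}]"
            )
    missing = set(factors) - {a.name for a in grid.axes} - set(grid.fixed)
    if missing:
        raise KeyError(f"grid fixes no value for factors {sorted(missing)}")


def _rows_for_points(model: ResponseModel,
                     points: dict[str, np.ndarray]) -> np.ndarray:
    """Vectorized model-matrix rows for many physical points."""
    coded = {f.name: (np.asarray(points[f.name], dtype=float) - f.center)
             / f.half_range for f in model.factors}
    cols = []
    for t in model.terms:
        if t.kind == "intercept":
            cols.append(np.ones_like(next(iter(coded.values()))))
        elif t.kind == "linear":
            cols.append(coded[t.factors[0]])
        elif t.kind == "square":
            cols.append(coded[t.factors[0]] ** 2)
        else:
            cols.append(coded[t.factors[0]] * coded[t.factors[1]])
    return np.column_stack(cols)


def _model_for(models: list[ResponseModel], response_name: str) -> ResponseModel:
    for m in models:
        if m.response_name == response_name:
            return m
    raise KeyError(f"no model supplied for response {response_name!r}")


# ---------------------------------------------------------------------------
# sweet spot (mean-prediction criteria counts)
# ---------------------------------------------------------------------------

def sweet_spot_map(models: list[ResponseModel], cmas: list[CMASpec],
                   grid: GridSpec) -> np.ndarray:
    """Criteria-met count at the model-mean prediction, per grid point.

    Returns an integer array with the grid's shape; overlapping the
    per-criterion contours this way is the classical sweet-spot plot.
    """
    _check_grid(models, grid)
    pts = grid.points()
    counts = np.zeros(grid.shape()[0] * grid.shape()[1], dtype=int)
    for cma in cmas:
        m = _model_for(models, cma.response_name)
        pred = _rows_for_points(m, pts) @ m.coefficients
        counts += (cma.sign * (pred - cma.limit) >= 0.0).astype(int)
    return counts.reshape(grid.shape())


# ---------------------------------------------------------------------------
# Monte Carlo machinery
# ---------------------------------------------------------------------------

def _covariance_root(cov: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD covariance.

    Eigenvalues are clipped at zero; a materially negative eigenvalue
    (beyond numerical jitter) triggers a warning — the matrix is then
    regularized by the clip rather than failing silently.
    """
    sym = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(sym)
    floor = -1e-8 * max(abs(w).max(), 1.0)
    if w.min() < floor:
        warnings.warn(
            "coefficient covariance is not positive semi-definite "
            f"(min eigenvalue {w.min():.3g}); clipping negative eigenvalues",
            RuntimeWarning, stacklevel=3,
        )
    return v * np.sqrt(np.clip(w, 0.0, None))


def _simulate_pass(models: list[ResponseModel], cmas: list[CMASpec],
                   points: dict[str, np.ndarray], n_simulations: int,
                   rng: np.random.Generator, include_residual: bool,
                   chunk: int = 1024) -> np.ndarray:
    """Fraction of Monte Carlo draws meeting all criteria, per point.

    One set of coefficient draws is shared across grid points for each
    model (each point's marginal pass probability is unchanged; only the
    spatial correlation of the Monte Carlo noise differs from independent
    per-point sampling).
    """
    n_pts = len(next(iter(points.values())))
    draws = {}
    rows = {}
    for cma in cmas:
        m = _model_for(models, cma.response_name)
        if m.response_name not in draws:
            L = _covariance_root(m.coefficient_covariance)
            z = rng.standard_normal((n_simulations, len(m.coefficients)))
            draws[m.response_name] = m.coefficients + z @ L.T
            rows[m.response_name] = _rows_for_points(m, points)
    pass_count = np.zeros(n_pts, dtype=np.int64)
    for start in range(0, n_pts, chunk):
        sl = slice(start, min(start + chunk, n_pts))
        all_pass = None
        for cma in cmas:
            m = _model_for(models, cma.response_name)
            pred = draws[m.response_name] @ rows[m.response_name][sl].T
            if include_residual and m.residual_variance > 0.0:
                pred = pred + rng.standard_normal(pred.shape) * np.sqrt(
                    m.residual_variance)
            ok = cma.sign * (pred - cma.limit) >= 0.0
            all_pass = ok if all_pass is None else (all_pass & ok)
        pass_count[sl] = all_pass.sum(axis=0)
    return pass_count / float(n_simulations)


def mc_pass_probability(models: list[ResponseModel], cmas: list[CMASpec],
                        point: dict[str, float],
                        n_simulations: int = DEFAULT_N_SIMULATIONS,
                        seed: int = DEFAULT_SEED,
                        include_residual: bool = True) -> float:
    """Probability that all criteria hold at one operating point.

    Coefficient vectors are drawn from each model's estimated multivariate
    normal; with ``include_residual`` (default) an independent zero-mean
    disturbance with the model's residual variance is added to every draw,
    so the probability refers to a future single measurement rather than
    to the noiseless model mean.
    """
    if n_simulations < 1:
        raise ValueError("n_simulations must be >= 1")
    rng = np.random.default_rng(seed)
    pts = {k: np.array([float(v)]) for k, v in point.items()}
    prob = _simulate_pass(models, cmas, pts, n_simulations, rng,
                          include_residual)
    return float(prob[0])


@dataclass
class ProbabilityMap:
    """Monte Carlo assurance map over a 2-D factor grid."""

    grid: GridSpec
    pass_probability: np.ndarray
    criteria_met_count: np.ndarray
    region_mask: np.ndarray
    assurance_level: float
    n_simulations: int
    seed: int
    include_residual: bool

    def region_area_fraction(self) -> float:
        return float(self.region_mask.mean())

    def to_frame(self) -> pd.DataFrame:
        """Long format: axis coordinates, probability, count, in-region."""
        pts = self.grid.points()
        a1, a2 = self.grid.axes
        return pd.DataFrame({
            a1.name: pts[a1.name],
            a2.name: pts[a2.name],
            "probability": self.pass_probability.ravel(),
            "criteria_met": self.criteria_met_count.ravel(),
            "in_region": self.region_mask.ravel(),
        })

    def summary(self) -> dict:
        return {
            "axes": [{"name": a.name, "low": a.low, "high": a.high,
                      "n_points": a.n_points} for a in self.grid.axes],
            "fixed": dict(self.grid.fixed),
            "assurance_level": self.assurance_level,
            "n_simulations": self.n_simulations,
            "seed": self.seed,
            "include_residual": self.include_residual,
            "region_area_fraction": self.region_area_fraction(),
        }


def modr_region(models: list[ResponseModel], cmas: list[CMASpec],
                grid: GridSpec, assurance_level: float = 0.99,
                n_simulations: int = DEFAULT_N_SIMULATIONS,
                seed: int = DEFAULT_SEED,
                include_residual: bool = True) -> ProbabilityMap:
    """Method operable design region: where assurance meets the level.

    Computes the Monte Carlo pass probability at every grid point and masks
    the points at or above ``assurance_level``; the mean-prediction
    criteria count (sweet spot) is carried along for comparison.
    """
    if not 0.0 < assurance_level <= 1.0:
        raise ValueError("assurance_level must be in (0, 1]")
    _check_grid(models, grid)
    rng = np.random.default_rng(seed)
    pts = grid.points()
    prob = _simulate_pass(models, cmas, pts, n_simulations, rng,
                          include_residual).reshape(grid.shape())
    counts = sweet_spot_map(models, cmas, grid)
    return ProbabilityMap(
        grid=grid,
        pass_probability=prob,
        criteria_met_count=counts,
        region_mask=prob >= assurance_level,
        assurance_level=assurance_level,
        n_simulations=n_simulations,
        seed=seed,
        include_residual=include_residual,
    )


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

def resolve_targets(models: list[ResponseModel],
                    cmas: list[CMASpec]) -> dict[str, float]:
    """Target value per CMA, defaulting beyond the limit when unstated.

    A criterion without an explicit target gets limit ± 10% of the span of
    the observed response in the fitting data (toward the passing side);
    if the observed span is zero the limit magnitude is used instead.
    Targets normalize margins so criteria on different scales compete
    fairly during optimization.
    """
    out: dict[str, float] = {}
    for cma in cmas:
        if cma.target is not None:
            out[cma.response_name] = cma.target
            continue
        m = _model_for(models, cma.response_name)
        span = float(np.ptp(m.observed))
        step = 0.1 * span if span > 0.0 else abs(cma.limit)
        out[cma.response_name] = cma.limit + cma.sign * step
    return out


def _min_norm_margin(models, cmas, targets, point: dict[str, float]) -> float:
    worst = np.inf
    for cma in cmas:
        m = _model_for(models, cma.response_name)
        pred = m.predict(point)
        span = abs(targets[cma.response_name] - cma.limit)
        if span == 0.0:
            span = max(abs(cma.limit), 1.0)
        worst = min(worst, cma.margin(pred) / span)
    return worst


@dataclass
class OptimizationResult:
    """Optimal operating point with predictions and assurance."""

    point: dict[str, float]
    predictions: dict[str, float]
    pass_probability: float
    min_normalized_margin: float
    targets: dict[str, float]
    n_simulations: int
    seed: int
    include_residual: bool

    def as_dict(self) -> dict:
        return {
            "optimal_point": self.point,
            "predictions": self.predictions,
            "pass_probability": self.pass_probability,
            "min_normalized_margin": self.min_normalized_margin,
            "targets": self.targets,
            "n_simulations": self.n_simulations,
            "seed": self.seed,
            "include_residual": self.include_residual,
        }


def optimize_conditions(models: list[ResponseModel], cmas: list[CMASpec],
                        search_ranges: dict[str, tuple[float, float]] | None = None,
                        n_simulations: int = DEFAULT_N_SIMULATIONS,
                        seed: int = DEFAULT_SEED,
                        include_residual: bool = True,
                        n_coarse: int = 11) -> OptimizationResult:
    """Find operating conditions maximizing Monte Carlo pass probability.

    A coarse grid over all factors is scored by Monte Carlo probability;
    ties (the probability typically saturates at 1 over a plateau) are
    broken by the minimum normalized margin — distance of each mean
    prediction from its limit, scaled by the limit-to-target span (see
    :func:`resolve_targets`).  The best coarse point is refined by a
    Nelder–Mead polytope search on the margin with a penalty for dropping
    below the best observed probability.  Deterministic given the seed.
    """
    from scipy.optimize import minimize

    factors = models[0].factors
    names = [f.name for f in factors]
    ranges = {f.name: (f.low, f.high) for f in factors}
    if search_ranges:
        for k, (lo, hi) in search_ranges.items():
            if k not in ranges:
                raise KeyError(f"unknown factor {k!r} in search_ranges")
            ranges[k] = (float(lo), float(hi))
    targets = resolve_targets(models, cmas)

    axes = [np.linspace(*ranges[n], n_coarse) for n in names]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = {n: m.ravel() for n, m in zip(names, mesh)}
    rng = np.random.default_rng(seed)
    prob = _simulate_pass(models, cmas, pts, n_simulations, rng,
                          include_residual)
    best_prob = float(prob.max())
    if best_prob <= 0.0:
        raise ValueError("no conditions satisfy criteria: pass probability "
                         "is zero everywhere on the search grid")
    tie = np.flatnonzero(prob >= best_prob - 1e-12)
    margins = np.array([
        _min_norm_margin(models, cmas, targets,
                         {n: pts[n][i] for n in names})
        for i in tie
    ])
    start_idx = tie[int(np.argmax(margins))]
    x0 = np.array([pts[n][start_idx] for n in names])

    # deterministic refinement: reuse one set of coefficient draws so the
    # probability penalty is a fixed function of the point
    rng2 = np.random.default_rng(seed + 1)
    frozen_draws = []
    for m in models:
        L = _covariance_root(m.coefficient_covariance)
        z = rng2.standard_normal((n_simulations, len(m.coefficients)))
        noise = (rng2.standard_normal(n_simulations)
                 * np.sqrt(m.residual_variance) if include_residual else 0.0)
        frozen_draws.append((m, m.coefficients + z @ L.T, noise))

    def frozen_prob(point: dict[str, float]) -> float:
        all_ok = np.ones(n_simulations, dtype=bool)
        for cma in cmas:
            for m, coefs, noise in frozen_draws:
                if m.response_name == cma.response_name:
                    pred = coefs @ m.design_row(point) + noise
                    all_ok &= cma.sign * (pred - cma.limit) >= 0.0
        return float(all_ok.mean())

    def objective(x: np.ndarray) -> float:
        point = dict(zip(names, x))
        pen = max(0.0, best_prob - frozen_prob(point))
        return -(_min_norm_margin(models, cmas, targets, point) - 1e3 * pen)

    res = minimize(objective, x0, method="Nelder-Mead",
                   bounds=[ranges[n] for n in names],
                   options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000})
    x_best = res.x if -res.fun >= -objective(x0) else x0
    point = {n: float(v) for n, v in zip(names, x_best)}
    predictions = {m.response_name: m.predict(point) for m in models}
    final_prob = mc_pass_probability(models, cmas, point,
                                     n_simulations=n_simulations, seed=seed,
                                     include_residual=include_residual)
    return OptimizationResult(
        point=point,
        predictions=predictions,
        pass_probability=final_prob,
        min_normalized_margin=_min_norm_margin(models, cmas, targets, point),
        targets=targets,
        n_simulations=n_simulations,
        seed=seed,
        include_residual=include_residual,
    )


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------

@dataclass
class VerificationReport:
    """Per-run criteria evaluation for a verification design."""

    table: pd.DataFrame              # run_id, per-CMA flags/margins, count
    worst_run: dict[str, str]        # response -> run_id with smallest margin
    overall_pass: bool

    def failing_runs(self) -> list[str]:
        ok = self.table["all_pass"]
        return list(self.table.loc[~ok, "run_id"])


def verify_runs(table, cmas: list[CMASpec]) -> VerificationReport:
    """Evaluate every measured run of a verification design.

    Reports per-run pass flags and margins, the minimum-margin run for each
    criterion, and the overall verdict (every run meets every criterion).
    """
    if table.n_runs == 0:
        raise ValueError("verification table has no runs")
    rows = []
    for i, p in enumerate(table.points):
        row: dict = {"run_id": p.run_id}
        n_ok = 0
        for cma in cmas:
            value = table.response(cma.response_name)[i]
            row[f"{cma.response_name}_value"] = value
            row[f"{cma.response_name}_margin"] = cma.margin(value)
            ok = cma.passes(value)
            row[f"{cma.response_name}_pass"] = ok
            n_ok += ok
        row["criteria_met"] = n_ok
        row["all_pass"] = n_ok == len(cmas)
        rows.append(row)
    frame = pd.DataFrame(rows)
    worst = {
        cma.response_name: str(
            frame.loc[frame[f"{cma.response_name}_margin"].idxmin(), "run_id"])
        for cma in cmas
    }
    return VerificationReport(table=frame, worst_run=worst,
                              overall_pass=bool(frame["all_pass"].all()))
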