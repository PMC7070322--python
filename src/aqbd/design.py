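"""Factors, coded units, and response-surface / screening designs.

A :class:`Factor` is a controllable method parameter (e.g. % acetonitrile in
the mobile phase) with a physical operating range.  Designs and models work
in *coded units*: the affine rescaling of the physical range onto [-1, +1]
via the midrange and half-range.  Coded units make coefficient magnitudes
comparable across factors with wildly different physical scales.

Two design generators are provided:

* :func:`generate_ccf` — face-centred central composite design (CCF):
  ``2**k`` factorial corners at coded ±1, ``2k`` axial points on the face
  centres (one coordinate at ±1, the rest 0), plus centre replicates.
* :func:`generate_full_factorial_2level` — two-level full factorial with
  centre replicates, used for robustness verification around an operating
  point (optionally with a shifted centre).

Designs are held in a :class:`DesignTable`, which round-trips through plain
CSV (physical units only; coded values are always recomputed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "DesignPoint",
    "DesignTable",
    "DesignParseError",
    "code_value",
    "decode_value",
    "generate_ccf",
    "generate_full_factorial_2level",
    "read_design_csv",
    "write_design_csv",
]

#: coordinates closer than this to a coded grid value are snapped for role
#: classification only; stored coded values keep full precision
_ROLE_TOL = 1e-9


@dataclass(frozen=True)
class Factor:
    """A controllable method parameter with a physical range.

    Parameters
    ----------
    name : str
        Identifier used in design tables and model terms.
    low, high : float
        Physical range bounds; ``low < high`` is required.
    unit : str, optional
        Physical unit, for reporting only.
    """

    name: str
    low: float
    high: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.low) or not np.isfinite(self.high):
            raise ValueError(f"factor {self.name!r}: bounds must be finite")
        if not self.low < self.high:
            raise ValueError(
                f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def code(self, physical: float) -> float:
        """Physical value -> coded unit in [-1, +1] (outside range allowed)."""
        return (physical - self.center) / self.half_range

    def decode(self, coded: float) -> float:
        """Coded unit -> physical value; exact inverse of :meth:`code`."""
        return self.center + coded * self.half_range


def code_value(factor: Factor, physical: float) -> float:
    """Convert a physical value to coded units for *factor*."""
    return factor.code(physical)


def decode_value(factor: Factor, coded: float) -> float:
    """Convert a coded value back to physical units for *factor*."""
    return factor.decode(coded)


@dataclass(frozen=True)
class DesignPoint:
    """One experimental run: physical levels plus derived coded levels."""

    run_id: str
    levels: dict[str, float]
    coded: dict[str, float]
    role: str  # "factorial" | "axial" | "center"

    def coded_vector(self, factor_names: list[str]) -> np.ndarray:
        return np.array([self.coded[n] for n in factor_names], dtype=float)


def _classify_role(coded: dict[str, float]) -> str:
    vals = np.array(list(coded.values()), dtype=float)
    nonzero = np.abs(vals) > _ROLE_TOL
    if not nonzero.any():
        return "center"
    if nonzero.sum() == 1:
        return "axial"
    return "factorial"


def _make_point(run_id: str, factors: list[Factor], coded: list[float],
                center_phys: dict[str, float] | None = None) -> DesignPoint:
    levels: dict[str, float] = {}
    coded_map: dict[str, float] = {}
    for f, c in zip(factors, coded):
        center = f.center if center_phys is None else center_phys[f.name]
        # snap the designed levels exactly onto the declared bounds where
        # they coincide, so generated tables match hand-written ones bitwise
        if center == f.center and c == -1.0:
            phys = f.low
        elif center == f.center and c == 1.0:
            phys = f.high
        elif c == 0.0:
            phys = center
        else:
            phys = center + c * f.half_range
        levels[f.name] = phys
        coded_map[f.name] = float(c)
    return DesignPoint(run_id=run_id, levels=levels, coded=coded_map,
                       role=_classify_role(coded_map))


@dataclass
class DesignTable:
    """An ordered set of runs with optional measured responses.

    Responses are stored as name -> list of floats aligned with ``points``.
    At least two centre replicates are needed for pure-error statistics
    (checked by the model layer, not here).
    """

    factors: list[Factor]
    points: list[DesignPoint]
    responses: dict[str, list[float]] = field(default_factory=dict)
    name: str = "design"

    def __post_init__(self) -> None:
        for rname, vals in self.responses.items():
            if len(vals) != len(self.points):
                raise ValueError(
                    f"response {rname!r} has {len(vals)} values for "
                    f"{len(self.points)} runs"
                )

    # -- basic introspection -------------------------------------------------

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def n_runs(self) -> int:
        return len(self.points)

    @property
    def n_center(self) -> int:
        return sum(1 for p in self.points if p.role == "center")

    def factor(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(f"unknown factor {name!r}")

    def coded_matrix(self) -> np.ndarray:
        """Runs x factors matrix of coded levels."""
        return np.array([p.coded_vector(self.factor_names) for p in self.points])

    def physical_matrix(self) -> np.ndarray:
        return np.array(
            [[p.levels[n] for n in self.factor_names] for p in self.points]
        )

    def center_mask(self) -> np.ndarray:
        return np.array([p.role == "center" for p in self.points])

    def response(self, name: str) -> np.ndarray:
        if name not in self.responses:
            raise KeyError(f"response {name!r} not measured in this design")
        return np.asarray(self.responses[name], dtype=float)

    def with_responses(self, responses: dict[str, list[float]]) -> "DesignTable":
        return DesignTable(factors=self.factors, points=self.points,
                           responses=dict(responses), name=self.name)

    def to_frame(self) -> pd.DataFrame:
        """Long table: run_id, physical factor columns, response columns."""
        data: dict[str, list] = {"run_id": [p.run_id for p in self.points]}
        for n in self.factor_names:
            data[n] = [p.levels[n] for p in self.points]
        for rname, vals in self.responses.items():
            data[rname] = list(vals)
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# design generators
# ---------------------------------------------------------------------------

def _corner_block(k: int) -> list[tuple[int, ...]]:
    # binary counting order, first factor slowest, -1 before +1
    return [tuple(-1 if b == 0 else 1 for b in bits)
            for bits in itertools.product((0, 1), repeat=k)]


def generate_ccf(factors: list[Factor], n_center: int = 3,
                 name: str = "ccf") -> DesignTable:
    """Face-centred central composite design.

    Rows: ``2**k`` factorial corners (coded ±1 everywhere), then ``2k``
    axial face points (one coordinate ±1, rest 0; low face first), then
    ``n_center`` centre replicates.  Run ids are ``N1 ... Nn`` in this
    canonical order; randomized execution order is an experimental concern
    and does not affect the fitted models.
    """
    k = len(factors)
    if k < 2:
        raise ValueError("CCF requires >=2 factors")
    if n_center < 0:
        raise ValueError("n_center must be >= 0")
    coded_rows: list[tuple[float, ...]] = list(_corner_block(k))
    for i in range(k):
        for level in (-1.0, 1.0):
            row = [0.0] * k
            row[i] = level
            coded_rows.append(tuple(row))
    coded_rows.extend([(0.0,) * k] * n_center)
    points = [_make_point(f"N{i + 1}", factors, list(c))
              for i, c in enumerate(coded_rows)]
    return DesignTable(factors=factors, points=points, name=name)


def generate_full_factorial_2level(
    factors: list[Factor],
    n_center: int = 0,
    center_override: dict[str, float] | None = None,
    name: str = "full_factorial",
) -> DesignTable:
    """Two-level full factorial with centre replicates.

    ``center_override`` moves the coded-0 reference of a factor to a
    different physical value (e.g. a column temperature capped below the
    nominal optimum); its corners then sit at override ± half_range of the
    configured range.  Overrides must lie within [low, high].
    """
    k = len(factors)
    if k < 1:
        raise ValueError("full factorial requires >=1 factor")
    if n_center < 0:
        raise ValueError("n_center must be >= 0")
    center_override = dict(center_override or {})
    for fname, value in center_override.items():
        f = next((x for x in factors if x.name == fname), None)
        if f is None:
            raise KeyError(f"center_override names unknown factor {fname!r}")
        if not (f.low <= value <= f.high):
            raise ValueError(
                f"center override {value} for {fname!r} outside "
                f"[{f.low}, {f.high}]"
            )
    center_phys = {f.name: center_override.get(f.name, f.center)
                   for f in factors}
    coded_rows: list[tuple[float, ...]] = list(_corner_block(k))
    coded_rows.extend([(0.0,) * k] * n_center)
    points = [_make_point(f"N{i + 1}", factors, list(c), center_phys=center_phys)
              for i, c in enumerate(coded_rows)]
    return DesignTable(factors=factors, points=points, name=name)


# ---------------------------------------------------------------------------
# CSV I/O — physical units only; coded levels are recomputed on read
# ---------------------------------------------------------------------------

class DesignParseError(ValueError):
    """A design CSV does not match the declared factors/responses."""


def write_design_csv(table: DesignTable, path) -> None:
    """Write ``run_id, <factors...>, <responses...>`` with full precision."""
    table.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_design_csv(path, factors: list[Factor],
                    response_names: list[str] | None = None,
                    name: str | None = None) -> DesignTable:
    """Read a design CSV against declared factors.

    Columns: ``run_id``, one column per factor (physical units), remaining
    numeric columns are responses (restricted to *response_names* when
    given).  Raises :class:`DesignParseError` with the offending row number
    on missing columns, non-numeric cells, or missing values.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DesignParseError(f"cannot parse {path}: {exc}") from exc
    if "run_id" not in frame.columns:
        raise DesignParseError("missing required column 'run_id'")
    for f in factors:
        if f.name not in frame.columns:
            raise DesignParseError(f"missing factor column {f.name!r}")
    factor_cols = [f.name for f in factors]
    other = [c for c in frame.columns if c not in factor_cols + ["run_id"]]
    if response_names is None:
        response_names = other
    else:
        missing = [r for r in response_names if r not in frame.columns]
        if missing:
            raise DesignParseError(f"missing response columns {missing}")

    def cell(row_idx: int, col: str) -> float:
        raw = frame.iloc[row_idx][col].strip()
        if raw == "":
            raise DesignParseError(
                f"row {row_idx + 2}: empty value in column {col!r}"
            )
        try:
            return float(raw)
        except ValueError:
            raise DesignParseError(
                f"row {row_idx + 2}: non-numeric value {raw!r} in column {col!r}"
            ) from None

    points = []
    for i in range(len(frame)):
        levels = {c: cell(i, c) for c in factor_cols}
        coded = {f.name: f.code(levels[f.name]) for f in factors}
        points.append(DesignPoint(run_id=str(frame.iloc[i]["run_id"]),
                                  levels=levels, coded=coded,
                                  role=_classify_role(coded)))
    responses = {r: [cell(i, r) for i in range(len(frame))]
                 for r in response_names}
    return DesignTable(factors=factors, points=points, responses=responses,
                       name=name or str(path))
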