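"""Bundled celecoxib impurity-method study data and its declarations.

The study optimized a reversed-phase HPLC method for seven process-related
impurities of celecoxib on a Chiralpak IA-3 column.  Three critical method
parameters were varied — acetonitrile content in the mobile phase
(42–50 % v/v), flow rate (0.5–1.0 mL/min), and column temperature
(30–40 °C) — and four critical method attributes measured: the resolutions
around the main peak (R1: EP impurity A / celecoxib; R2: celecoxib / USP
related compound C; R3: USP related compound C / D) and the retention time
of the last-eluting impurity, EP impurity B (RT, minutes).

Shipped fixtures:

* ``celecoxib_ccf.csv`` — the 17-run face-centred central composite design
  with measured responses (14 distinct conditions + 3 centre replicates).
* ``celecoxib_verification.csv`` — the 11-run two-level full factorial
  robustness verification around the optimum (8 corners + 3 centres).
* ``celecoxib_optimum_observed.csv`` — model-predicted vs experimentally
  observed responses at the optimal conditions.
* ``celecoxib_recovery.csv`` — spiked recovery results (added vs found
  concentration, µg/mL) for the seven impurities at three levels.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .design import DesignTable, Factor, read_design_csv
from .space import CMASpec

__all__ = [
    "celecoxib_factors",
    "celecoxib_verification_factors",
    "celecoxib_cmas",
    "celecoxib_optimum",
    "load_celecoxib_ccf",
    "load_celecoxib_verification",
    "load_celecoxib_optimum_observed",
    "load_celecoxib_recovery",
    "RESPONSE_NAMES",
    "fixture_path",
]

RESPONSE_NAMES = ["R1", "R2", "R3", "RT"]


def fixture_path(name: str):
    """Filesystem path of a bundled fixture CSV."""
    return resources.files("aqbd.data").joinpath(name)


def celecoxib_factors() -> list[Factor]:
    """The three critical method parameters with their study ranges."""
    return [
        Factor("acetonitrile", 42.0, 50.0, unit="% (v/v)"),
        Factor("flow_rate", 0.5, 1.0, unit="mL/min"),
        Factor("temperature", 30.0, 40.0, unit="degC"),
    ]


def celecoxib_verification_factors() -> list[Factor]:
    """Narrow robustness ranges around the optimum (±1.5 %, ±0.05 mL/min,
    ±1.5 °C with the temperature centre capped at 38.5 °C)."""
    return [
        Factor("acetonitrile", 43.5, 46.5, unit="% (v/v)"),
        Factor("flow_rate", 0.75, 0.85, unit="mL/min"),
        Factor("temperature", 37.0, 40.0, unit="degC"),
    ]


def celecoxib_cmas() -> list[CMASpec]:
    """Acceptance criteria on the four critical method attributes."""
    return [
        CMASpec("R1", "not_less_than", 2.3),
        CMASpec("R2", "not_less_than", 3.2),
        CMASpec("R3", "not_less_than", 2.0),
        CMASpec("RT", "not_more_than", 45.0),
    ]


def celecoxib_optimum() -> dict[str, float]:
    """The study's reported optimal operating point."""
    return {"acetonitrile": 44.918, "flow_rate": 0.795, "temperature": 39.998}


def load_celecoxib_ccf() -> DesignTable:
    """The 17-run CCF optimization design with measured CMAs."""
    return read_design_csv(fixture_path("celecoxib_ccf.csv"),
                           celecoxib_factors(), RESPONSE_NAMES,
                           name="celecoxib_ccf")


def load_celecoxib_verification() -> DesignTable:
    """The 11-run full-factorial verification design with measured CMAs."""
    return read_design_csv(fixture_path("celecoxib_verification.csv"),
                           celecoxib_verification_factors(), RESPONSE_NAMES,
                           name="celecoxib_verification")


def load_celecoxib_optimum_observed() -> pd.DataFrame:
    """Predicted vs observed responses at the optimum (columns: response,
    predicted, observed)."""
    with resources.as_file(fixture_path("celecoxib_optimum_observed.csv")) as p:
        return pd.read_csv(p)


def load_celecoxib_recovery() -> pd.DataFrame:
    """Spiked-recovery table: impurity, level, added/found conc (µg/mL),
    printed recovery (%)."""
    with resources.as_file(fixture_path("celecoxib_recovery.csv")) as p:
        return pd.read_csv(p)
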