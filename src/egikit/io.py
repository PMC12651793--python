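"""Domain types and delimited-text I/O for composition tables and hydrolysis curves.

File dialect: comma-separated UTF-8 with a mandatory header row and dot
decimals.  ``foods.csv`` carries per-100 g composition plus the human GI;
``curves.csv`` is long-format starch-hydrolysis time courses keyed by
(food_id, digestion_model, replicate).  Loaders are order-preserving,
tolerate extra columns, and are stable under column reordering.

Hydrolysis percentages slightly outside [0, 100] (within +/-2, i.e. assay
noise from the reducing-sugar measurement) are clipped with a warning;
larger excursions indicate unit errors and are rejected.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParseError, SchemaError

__all__ = [
    "FoodRecord",
    "HydrolysisCurve",
    "EgiCoefficients",
    "GlucoseCalibration",
    "DIGESTION_MODELS",
    "INTESTINAL_GRID",
    "load_food_table",
    "load_curves",
    "write_food_table",
    "write_curves",
    "write_egi_report",
]

#: Recognized digestion protocols: a peristalsis-driven dynamic gastric rig
#: versus a conventional shaken-vessel static protocol.
DIGESTION_MODELS = ("dynamic", "static")

#: Default intestinal-phase sampling grid, minutes from SIF addition.
INTESTINAL_GRID = (0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0)

# Clip tolerance for assay noise on percentages, in percentage points.
_CLIP_TOL = 2.0


@dataclass(frozen=True)
class FoodRecord:
    """Composition (g per 100 g), human GI and identity of one food."""

    food_id: str
    name: str
    carbohydrate: float
    protein: float
    fat: float
    fiber: float
    human_gi: Optional[float] = None
    total_starch: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("FoodRecord.name must be non-empty")
        for attr in ("carbohydrate", "protein", "fat", "fiber"):
            if getattr(self, attr) < 0:
                raise ValueError(f"FoodRecord.{attr} must be >= 0")
        if self.human_gi is not None and not self.human_gi > 0:
            raise ValueError("FoodRecord.human_gi must be > 0 when present")


@dataclass(frozen=True)
class HydrolysisCurve:
    """One starch-hydrolysis time course (% hydrolyzed vs minutes).

    Times are minutes from the start of the intestinal phase (t = 0 at
    simulated-intestinal-fluid addition).  Values must already satisfy the
    [0, 100] policy; use :func:`clip_hydrolysis_values` on raw assay data.
    """

    food_id: str
    digestion_model: str
    times: tuple = ()
    values: tuple = ()
    replicate: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if self.digestion_model not in DIGESTION_MODELS:
            raise ValueError(
                f"digestion_model must be one of {DIGESTION_MODELS}, "
                f"got {self.digestion_model!r}"
            )
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have the same length")
        if len(self.times) < 2:
            raise ValueError("a curve needs at least 2 sampled points")
        t = np.asarray(self.times)
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and start at >= 0")
        v = np.asarray(self.values)
        if np.any(v < 0) or np.any(v > 100):
            raise ValueError(
                "hydrolysis values must lie in [0, 100]; clip raw assay "
                "values with clip_hydrolysis_values first"
            )

    @property
    def key(self) -> tuple:
        return (self.food_id, self.digestion_model, self.replicate)


@dataclass(frozen=True)
class EgiCoefficients:
    """Fixed empirical coefficients of the two eGI predictors.

    ``goni_intercept + goni_slope * H90`` is the classic single-point
    formula; the kinetics formula adds the A constant (30 above the
    carbohydrate threshold, 15 below), the S60/S120 x HI kinetic term and
    the macronutrient corrections.  ``starch_glucose_factor`` is the
    anhydroglucose mass ratio 162/180 converting free glucose back to
    starch equivalents.
    """

    goni_intercept: float = 39.21
    goni_slope: float = 0.803
    protein_coef: float = -0.26
    fat_coef: float = 0.54
    fiber_coef: float = -0.43
    a_high: float = 30.0
    a_low: float = 15.0
    carb_threshold: float = 55.0
    starch_glucose_factor: float = 0.9

    def replace(self, **overrides) -> "EgiCoefficients":
        """Return a copy with the given fields overridden."""
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ValueError(f"unknown coefficient overrides: {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)


@dataclass(frozen=True)
class GlucoseCalibration:
    """Glucose standard curve: absorbance = slope * (mg/mL) + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("calibration slope must be > 0")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


def clip_hydrolysis_values(values: Sequence[float], context: str = "") -> np.ndarray:
    """Apply the [0, 100] policy: clip within-tolerance noise, reject beyond.

    Values in (100, 102] or [-2, 0) are clipped with a warning; anything
    outside +/-2 of the bounds raises ``ValueError``.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < -_CLIP_TOL) or np.any(v > 100 + _CLIP_TOL):
        bad = v[(v < -_CLIP_TOL) | (v > 100 + _CLIP_TOL)]
        raise ValueError(
            f"hydrolysis values {bad.tolist()} outside [-2, 102]{context}; "
            "likely a unit error"
        )
    clipped = np.clip(v, 0.0, 100.0)
    if np.any(clipped != v):
        warnings.warn(
            f"clipped {int(np.sum(clipped != v))} hydrolysis value(s) "
            f"into [0, 100]{context}",
            stacklevel=2,
        )
    return clipped


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_FOOD_REQUIRED = ("food_id", "name", "carbohydrate", "protein", "fat", "fiber")
_CURVE_REQUIRED = ("food_id", "digestion_model", "replicate", "time_min", "hydrolysis_pct")


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _cell_float(df_value: str, row: int, column: str, path) -> float:
    try:
        return float(df_value)
    except (TypeError, ValueError):
        raise ParseError(
            f"{path}: non-numeric value {df_value!r} at row {row}, column {column!r}"
        ) from None


def load_food_table(path) -> list:
    """Read a composition table; one :class:`FoodRecord` per data row.

    Extra columns are ignored; ``human_gi`` and ``total_starch`` are
    optional and may be blank per-row.
    """
    df = _read_csv(path, _FOOD_REQUIRED)
    records = []
    for i, row in df.iterrows():
        kwargs = {}
        for col in ("carbohydrate", "protein", "fat", "fiber"):
            kwargs[col] = _cell_float(row[col], i, col, path)
        for col in ("human_gi", "total_starch"):
            if col in df.columns and pd.notna(row[col]) and str(row[col]).strip():
                kwargs[col] = _cell_float(row[col], i, col, path)
        records.append(FoodRecord(food_id=row["food_id"], name=row["name"], **kwargs))
    return records


def load_curves(path) -> list:
    """Read long-format hydrolysis time courses into curves.

    Rows are grouped by (food_id, digestion_model, replicate); times are
    sorted ascending within each curve.  Duplicate (key, time) rows and
    values beyond the +/-2 clip tolerance are rejected.
    """
    df = _read_csv(path, _CURVE_REQUIRED)
    if len(df) == 0:
        return []
    df = df.assign(
        time_min=[_cell_float(v, i, "time_min", path) for i, v in df["time_min"].items()],
        hydrolysis_pct=[
            _cell_float(v, i, "hydrolysis_pct", path)
            for i, v in df["hydrolysis_pct"].items()
        ],
        replicate=[
            int(_cell_float(v, i, "replicate", path)) for i, v in df["replicate"].items()
        ],
    )
    curves = []
    for key, grp in df.groupby(["food_id", "digestion_model", "replicate"], sort=False):
        grp = grp.sort_values("time_min")
        times = grp["time_min"].to_numpy()
        if len(np.unique(times)) != len(times):
            dup = times[np.flatnonzero(np.diff(times) == 0)]
            raise ValueError(f"{path}: duplicated time(s) {dup.tolist()} for curve {key}")
        values = clip_hydrolysis_values(
            grp["hydrolysis_pct"].to_numpy(), context=f" for curve {key}"
        )
        curves.append(
            HydrolysisCurve(
                food_id=key[0],
                digestion_model=key[1],
                replicate=int(key[2]),
                times=tuple(times),
                values=tuple(values),
            )
        )
    return curves


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_food_table(foods: Iterable[FoodRecord], path) -> None:
    """Write a composition table in the ``foods.csv`` dialect (round-trip safe)."""
    rows = []
    for f in foods:
        rows.append(
            {
                "food_id": f.food_id,
                "name": f.name,
                "carbohydrate": f.carbohydrate,
                "protein": f.protein,
                "fat": f.fat,
                "fiber": f.fiber,
                "human_gi": f.human_gi,
                "total_starch": f.total_starch,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_curves(curves: Iterable[HydrolysisCurve], path) -> None:
    """Write curves in the long-format ``curves.csv`` dialect."""
    rows = []
    for c in curves:
        for t, v in zip(c.times, c.values):
            rows.append(
                {
                    "food_id": c.food_id,
                    "digestion_model": c.digestion_model,
                    "replicate": c.replicate,
                    "time_min": t,
                    "hydrolysis_pct": repr(v),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_egi_report(
    foods: Sequence[FoodRecord],
    results: Sequence,
    reports: Mapping[str, object],
    path,
) -> None:
    """Write the per-food report: composition, human GI, both eGIs, deviations.

    ``results`` are :class:`~egikit.egi.EgiResult` rows (metrics may be
    None when eGI values were supplied externally); ``reports`` maps a
    formula label (e.g. ``"goni"``, ``"new"``) to its
    :class:`~egikit.validation.ValidationReport`.  Deviations and eGIs are
    rounded to 1 decimal; the regression line of each formula is appended
    as ``#`` footer lines.
    """
    results = list(results)
    if not results:
        raise ValueError("write_egi_report requires a non-empty results list")
    by_id = {f.food_id: f for f in foods}
    dev = {
        label: {fid: d for fid, _, _, d in rep.per_food}
        for label, rep in reports.items()
    }
    rows = []
    for r in results:
        f = by_id[r.food_id]
        row = {
            "food_id": f.food_id,
            "name": f.name,
            "carbohydrate": f.carbohydrate,
            "protein": f.protein,
            "fat": f.fat,
            "fiber": f.fiber,
            "human_gi": f.human_gi,
            "egi_goni": round(r.egi_goni, 1),
            "egi_new": round(r.egi_new, 1),
        }
        for label in reports:
            d = dev[label].get(r.food_id)
            row[f"deviation_{label}"] = None if d is None else round(d, 1)
        rows.append(row)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        pd.DataFrame(rows).to_csv(fh, index=False)
        for label, rep in reports.items():
            fh.write(
                f"# {label}: slope={rep.slope:.4f} intercept={rep.intercept:.2f} "
                f"r={rep.pearson_r:.2f} n={rep.n_foods}\n"
            )
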