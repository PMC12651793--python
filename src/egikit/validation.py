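"""Prediction-versus-human-GI validation.

Per-food agreement is summarized by the deviation statistic

    deviation % = (GI_human - eGI) / GI_human * 100

(positive = under-prediction), and panel-level agreement by the OLS line
of eGI on human GI plus the Pearson correlation.  The regression
orientation is fixed as x = human GI, y = eGI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.stats import linregress

from .exceptions import DegenerateDesignError, DomainError
from .io import FoodRecord

__all__ = ["ValidationReport", "deviation_pct", "ols_line", "validate_panel"]


@dataclass(frozen=True)
class ValidationReport:
    """Per-food deviations plus the eGI-on-human-GI regression summary.

    Regression fields (slope, intercept, pearson_r) are populated only
    when the panel has at least 3 paired foods; otherwise they are NaN.
    Raw full-precision values are stored; tabular output rounds slope to
    4, intercept and r to 2 decimals.
    """

    n_foods: int
    per_food: Tuple[Tuple[str, float, float, float], ...]  # (food_id, human_gi, egi, deviation %)
    slope: float
    intercept: float
    pearson_r: float

    def summary_dict(self) -> dict:
        return {
            "n": self.n_foods,
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.pearson_r,
        }


def deviation_pct(human_gi: float, egi: float) -> float:
    """Relative prediction error (GI_human - eGI)/GI_human * 100, in percent.

    Full precision is returned; report writers round to 1 decimal.
    """
    if human_gi <= 0:
        raise DomainError("human_gi must be > 0")
    return (human_gi - egi) / human_gi * 100.0


def ols_line(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, float]:
    """OLS of y on x: (slope, intercept, pearson_r).

    Convention: x = human GI, y = eGI.  Requires >= 3 points and
    non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("ols_line needs >= 3 paired observations")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("x is constant; regression is undefined")
    res = linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def validate_panel(
    foods: Sequence[FoodRecord],
    egi_column: Sequence[Tuple[str, float]],
) -> ValidationReport:
    """Assemble the validation report for one eGI column.

    Every entry in ``egi_column`` must match a food (by id) that carries a
    human GI; output preserves food-table order.
    """
    by_id = {f.food_id: f for f in foods}
    egi_by_id = {}
    for fid, egi in egi_column:
        if fid not in by_id:
            raise ValueError(f"eGI entry for unknown food_id {fid!r}")
        if by_id[fid].human_gi is None:
            raise ValueError(f"food {fid!r} has no human GI to validate against")
        egi_by_id[fid] = float(egi)

    per_food = []
    for f in foods:
        if f.food_id in egi_by_id:
            egi = egi_by_id[f.food_id]
            per_food.append((f.food_id, float(f.human_gi), egi, deviation_pct(f.human_gi, egi)))

    gi = [p[1] for p in per_food]
    eg = [p[2] for p in per_food]
    if len(per_food) >= 3 and np.ptp(gi) > 0:
        slope, intercept, r = ols_line(gi, eg)
    else:
        slope = intercept = r = float("nan")
    return ValidationReport(
        n_foods=len(per_food),
        per_food=tuple(per_food),
        slope=slope,
        intercept=intercept,
        pearson_r=r,
    )
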