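"""Estimated glycemic index (eGI) under two empirical predictors.

The classic single-point predictor uses only the 90-min hydrolysis
percentage:

    eGI = 39.21 + 0.803 * H90

The kinetics + macronutrient predictor combines the shape of the
hydrolysis curve with composition:

    eGI = A + (S60/S120) * HI - 0.26*Protein + 0.54*Fat - 0.43*Fiber

with A = 30 when carbohydrate exceeds 55 g/100 g and 15 otherwise.  The
kinetic term is read as (S60/S120) * HI — for a monotone non-decreasing
curve S60/S120 <= 1, so the term never exceeds HI.  Results are never
clamped; negative or out-of-range values are flagged instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import DomainError
from .hydrolysis import HydrolysisMetrics, compute_metrics
from .io import EgiCoefficients, FoodRecord, HydrolysisCurve

__all__ = ["EgiResult", "PanelResult", "choose_A", "egi_goni", "egi_new", "compute_panel"]


@dataclass(frozen=True)
class EgiResult:
    """All derived quantities for one food.

    ``metrics`` is None when eGI values were supplied externally (e.g. a
    transcribed published table) rather than derived from curves.
    """

    food_id: str
    digestion_model: Optional[str]
    metrics: Optional[HydrolysisMetrics]
    a_constant: Optional[float]
    egi_goni: float
    egi_new: float
    flags: Tuple[str, ...] = ()


@dataclass(frozen=True)
class PanelResult:
    """Outcome of a panel computation: per-food results plus skipped foods."""

    results: Tuple[EgiResult, ...]
    skipped: Tuple[Tuple[str, str], ...]  # (food_id, reason)


def choose_A(carbohydrate: float, coefs: EgiCoefficients = EgiCoefficients()) -> float:
    """Intercept A of the kinetics formula: a_high iff carbohydrate strictly
    exceeds the threshold (55 g/100 g by default), else a_low."""
    if carbohydrate < 0:
        raise DomainError("carbohydrate must be >= 0")
    return coefs.a_high if carbohydrate > coefs.carb_threshold else coefs.a_low


def egi_goni(s90: float, coefs: EgiCoefficients = EgiCoefficients()) -> float:
    """Single-point eGI from the 90-min hydrolysis percentage."""
    if not 0 <= s90 <= 100:
        raise DomainError("s90 must lie in [0, 100]")
    return coefs.goni_intercept + coefs.goni_slope * s90


def egi_new(
    metrics: HydrolysisMetrics,
    food: FoodRecord,
    coefs: EgiCoefficients = EgiCoefficients(),
) -> float:
    """Kinetics + macronutrient eGI.

    Requires S120 > 0 (an all-zero curve has no defined kinetic ratio).
    The value is returned unclamped; callers flag negatives.
    """
    if metrics.s120 <= 0:
        raise DomainError(
            f"S120 = {metrics.s120} for {food.food_id}: kinetic ratio undefined"
        )
    a = choose_A(food.carbohydrate, coefs)
    return (
        a
        + metrics.s60 / metrics.s120 * metrics.hi
        + coefs.protein_coef * food.protein
        + coefs.fat_coef * food.fat
        + coefs.fiber_coef * food.fiber
    )


def _mean_curve(curves: Sequence[HydrolysisCurve]) -> HydrolysisCurve:
    """Pointwise mean of replicate curves on their common grid.

    Replicates sampled on identical grids are averaged directly; replicates
    on differing grids are linearly interpolated onto the union of times
    restricted to the overlapping range.
    """
    if len(curves) == 1:
        return curves[0]
    grids = {c.times for c in curves}
    if len(grids) == 1:
        times = np.asarray(curves[0].times)
        vals = np.mean([c.values for c in curves], axis=0)
    else:
        lo = max(c.times[0] for c in curves)
        hi = min(c.times[-1] for c in curves)
        if hi <= lo:
            raise ValueError("replicate curves have no overlapping time range")
        union = np.unique(np.concatenate([c.times for c in curves]))
        times = union[(union >= lo) & (union <= hi)]
        vals = np.mean(
            [np.interp(times, c.times, c.values) for c in curves], axis=0
        )
    return HydrolysisCurve(
        food_id=curves[0].food_id,
        digestion_model=curves[0].digestion_model,
        replicate=0,
        times=tuple(times),
        values=tuple(vals),
    )


def compute_panel(
    foods: Sequence[FoodRecord],
    curves: Iterable[HydrolysisCurve],
    digestion_model: str = "dynamic",
    coefs: EgiCoefficients = EgiCoefficients(),
    reference: Optional[HydrolysisCurve] = None,
    t_start: float = 0.0,
    t_end: float = 120.0,
) -> PanelResult:
    """Both eGI values for every food with curves under the chosen protocol.

    Replicate curves are averaged pointwise before metric extraction.
    Foods without a usable curve are reported in ``skipped`` rather than
    raising; the computation is deterministic given its inputs.
    """
    by_food: dict = {}
    for c in curves:
        if c.digestion_model == digestion_model:
            by_food.setdefault(c.food_id, []).append(c)

    results: List[EgiResult] = []
    skipped: List[Tuple[str, str]] = []
    for food in foods:
        reps = by_food.get(food.food_id)
        if not reps:
            skipped.append((food.food_id, f"no {digestion_model}-model curve"))
            continue
        try:
            mean = _mean_curve(reps)
            metrics = compute_metrics(mean, reference, t_start, t_end)
            a = choose_A(food.carbohydrate, coefs)
            goni = egi_goni(metrics.s90, coefs)
            new = egi_new(metrics, food, coefs)
        except (ValueError, DomainError) as exc:
            skipped.append((food.food_id, str(exc)))
            continue
        flags = []
        if new < 0:
            flags.append("negative_egi_new")
        if goni < 0:
            flags.append("negative_egi_goni")
        results.append(
            EgiResult(
                food_id=food.food_id,
                digestion_model=digestion_model,
                metrics=metrics,
                a_constant=a,
                egi_goni=goni,
                egi_new=new,
                flags=tuple(flags),
            )
        )
    return PanelResult(results=tuple(results), skipped=tuple(skipped))
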