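"""Starch-hydrolysis quantification and kinetic summaries.

Raw reducing-sugar measurements (DNS assay, absorbance at 520 nm against a
0-1 mg/mL glucose standard curve) are converted to percent starch
hydrolyzed via the anhydroglucose factor:

    hydrolysis % = (Gt * 0.9) / TS * 100

where Gt is glucose released at time t and TS the total starch, both in
the same mass units.  Sampled curves are then summarized by

* S60, H90 (= S90), S120 — cumulative percent hydrolyzed at 60/90/120 min,
  linearly interpolated when a time falls between samples;
* AUC — composite trapezoid over the sampled grid;
* HI — the hydrolysis index, 100 x AUC(curve)/AUC(reference).  The default
  reference is the ideal instantaneous-digestion curve (constant 100 %),
  which puts HI on a 0-100 scale; pass an explicit reference curve (e.g.
  white bread) for a Goni-style index.

A bounded first-order kinetic model C(t) = c0 + (c_inf - c0)(1 - e^{-kt})
is available as a smooth summary and as the simulator's ground truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .exceptions import DegenerateDesignError, DomainError, ExtrapolationError, FitError
from .io import EgiCoefficients, GlucoseCalibration, HydrolysisCurve

__all__ = [
    "KineticFit",
    "HydrolysisMetrics",
    "fit_glucose_calibration",
    "glucose_from_absorbance",
    "starch_hydrolysis_pct",
    "value_at",
    "auc_trapezoid",
    "hydrolysis_index",
    "fit_first_order",
    "first_order_curve",
    "compute_metrics",
]

# threshold below which a curve's spread is treated as flat (k indeterminate)
_FLAT_PTP = 1e-9


@dataclass(frozen=True)
class KineticFit:
    """First-order fit C(t) = c0 + (c_inf - c0)(1 - e^{-k t}).

    ``rss`` is the residual sum of squares in %^2.  ``flags`` records
    degenerate conditions, e.g. ``k_indeterminate`` for a flat curve where
    the rate constant is unidentifiable and reported as 0.
    """

    c0: float
    c_inf: float
    k: float
    rss: float
    flags: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.c0 <= self.c_inf <= 100.0 + 1e-9):
            raise ValueError("fit must satisfy 0 <= c0 <= c_inf <= 100")
        if self.k < 0 or self.rss < 0:
            raise ValueError("k and rss must be >= 0")

    def predict(self, t) -> np.ndarray:
        return first_order_curve(np.asarray(t, dtype=float), self.c0, self.c_inf, self.k)


@dataclass(frozen=True)
class HydrolysisMetrics:
    """Scalar summaries of one hydrolysis curve.

    ``s90`` is the 90-min hydrolysis percentage (H90 of the single-point
    eGI formula); ``auc`` is in %*min over the metric window; ``hi`` is the
    dimensionless hydrolysis index.
    """

    s60: float
    s90: float
    s120: float
    auc: float
    hi: float

    def __post_init__(self) -> None:
        for attr in ("s60", "s90", "s120"):
            if not -1e-9 <= getattr(self, attr) <= 100 + 1e-9:
                raise ValueError(f"{attr} must lie in [0, 100]")
        if self.auc < 0 or self.hi < 0:
            raise ValueError("auc and hi must be >= 0")


def first_order_curve(t, c0: float, c_inf: float, k: float) -> np.ndarray:
    """Closed-form first-order hydrolysis curve, vectorized over t."""
    t = np.asarray(t, dtype=float)
    return c0 + (c_inf - c0) * (1.0 - np.exp(-k * t))


def fit_glucose_calibration(standards: Sequence[Tuple[float, float]]) -> GlucoseCalibration:
    """OLS line absorbance = slope * concentration + intercept.

    ``standards`` are (concentration mg/mL, absorbance) pairs with at least
    two distinct concentrations in [0, 1] mg/mL.
    """
    conc = np.asarray([s[0] for s in standards], dtype=float)
    absb = np.asarray([s[1] for s in standards], dtype=float)
    if len(conc) < 2:
        raise DegenerateDesignError("need at least 2 standards")
    if np.any(conc < 0) or np.any(conc > 1):
        raise DomainError("standard concentrations must lie in [0, 1] mg/mL")
    if np.ptp(conc) == 0:
        raise DegenerateDesignError("all standard concentrations identical")
    res = linregress(conc, absb)
    r2 = 1.0 if len(conc) == 2 else float(res.rvalue) ** 2
    return GlucoseCalibration(slope=float(res.slope), intercept=float(res.intercept), r_squared=r2)


def glucose_from_absorbance(a520: float, cal: GlucoseCalibration, dilution: float = 1.0) -> float:
    """Invert the standard curve: ((a520 - intercept)/slope) * dilution, in mg/mL."""
    if dilution < 1:
        raise DomainError("dilution factor must be >= 1")
    conc = (a520 - cal.intercept) / cal.slope * dilution
    if conc < 0:
        warnings.warn(f"negative glucose concentration {conc:.4g} clipped to 0", stacklevel=2)
        conc = 0.0
    return conc


def starch_hydrolysis_pct(
    g_t: float, ts: float, coefs: EgiCoefficients = EgiCoefficients()
) -> float:
    """Percent of starch hydrolyzed from released glucose mass.

    ``g_t`` (glucose released) and ``ts`` (total starch) must share units;
    the 0.9 anhydroglucose factor converts glucose back to starch
    equivalents.  The result is not clipped here — the caller applies the
    [0, 100] policy.
    """
    if ts <= 0:
        raise DomainError("total starch must be > 0")
    if g_t < 0:
        raise DomainError("released glucose must be >= 0")
    return g_t * coefs.starch_glucose_factor / ts * 100.0


def value_at(curve: HydrolysisCurve, t: float) -> float:
    """Linearly interpolated hydrolysis % at time t; exact on grid points.

    Raises :class:`ExtrapolationError` outside the sampled range — with 7
    samples per curve, extrapolation is never safe.
    """
    times = np.asarray(curve.times)
    if t < times[0] or t > times[-1]:
        raise ExtrapolationError(
            f"t={t} outside sampled range [{times[0]}, {times[-1]}] "
            f"for curve {curve.key}"
        )
    return float(np.interp(t, times, np.asarray(curve.values)))


def auc_trapezoid(curve: HydrolysisCurve, t_start: float, t_end: float) -> float:
    """Composite-trapezoid area (%*min) over [t_start, t_end].

    The grid is restricted to the window with linearly interpolated
    endpoints when the window edges fall between samples.
    """
    if not t_start < t_end:
        raise ValueError(f"need t_start < t_end, got [{t_start}, {t_end}]")
    times = np.asarray(curve.times)
    values = np.asarray(curve.values)
    if t_start < times[0] or t_end > times[-1]:
        raise ExtrapolationError(
            f"window [{t_start}, {t_end}] outside sampled range "
            f"[{times[0]}, {times[-1]}]"
        )
    inside = (times > t_start) & (times < t_end)
    grid = np.concatenate(([t_start], times[inside], [t_end]))
    vals = np.interp(grid, times, values)
    return float(np.trapezoid(vals, grid))


def hydrolysis_index(
    curve: HydrolysisCurve,
    reference: Optional[HydrolysisCurve] = None,
    t_start: float = 0.0,
    t_end: float = 120.0,
) -> float:
    """Hydrolysis index HI = 100 x AUC(curve)/AUC(reference).

    With no reference the ideal instantaneous-digestion curve (constant
    100 %) is used, i.e. HI = AUC / (span x 100) x 100, bounded to
    [0, 100].  An explicit reference (e.g. white bread digested under the
    same protocol) gives the conventional Goni-style index.
    """
    auc = auc_trapezoid(curve, t_start, t_end)
    if reference is None:
        ref_auc = (t_end - t_start) * 100.0
    else:
        ref_auc = auc_trapezoid(reference, t_start, t_end)
        if ref_auc <= 0:
            raise DomainError("reference curve has non-positive AUC")
    return 100.0 * auc / ref_auc


def fit_first_order(curve: HydrolysisCurve) -> KineticFit:
    """Bounded nonlinear least squares of the first-order model.

    Multi-start and deterministic: c0 starts at the first sampled value,
    c_inf at the last, k on the grid {0.005, 0.02, 0.05} min^-1; bounds
    0 <= c0, c_inf <= 100 and k in [0, 1]; the best-RSS converged fit is
    returned.  A flat curve gets c0 = c_inf = mean with k = 0 and the
    ``k_indeterminate`` flag.
    """
    times = np.asarray(curve.times)
    values = np.asarray(curve.values)
    if len(times) < 4:
        raise ValueError("fit_first_order needs at least 4 points")
    if times[-1] - times[0] < 60:
        raise ValueError("fit_first_order needs samples spanning >= 60 min")

    if np.ptp(values) < _FLAT_PTP:
        level = float(values.mean())
        rss = float(np.sum((values - level) ** 2))
        return KineticFit(c0=level, c_inf=level, k=0.0, rss=rss, flags=("k_indeterminate",))

    def resid(p):
        return first_order_curve(times, *p) - values

    lo, hi = [0.0, 0.0, 0.0], [100.0, 100.0, 1.0]
    c0_start = float(np.clip(values[0], 0, 100))
    cinf_start = float(np.clip(values[-1], 0, 100))
    best = None
    diagnostics = []
    for k0 in (0.005, 0.02, 0.05):
        try:
            sol = least_squares(
                resid,
                x0=[c0_start, max(cinf_start, c0_start), k0],
                bounds=(lo, hi),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
        except Exception as exc:  # pragma: no cover - scipy rarely raises here
            diagnostics.append(f"k0={k0}: {exc}")
            continue
        if not sol.success:
            diagnostics.append(f"k0={k0}: {sol.message}")
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise FitError("first-order fit failed from all starts: " + "; ".join(diagnostics))
    rss, (c0, c_inf, k) = best
    flags = ()
    if c0 > c_inf:  # numerically flat fit collapsed the plateau below c0
        c0 = c_inf = float(values.mean())
        k, flags = 0.0, ("k_indeterminate",)
        rss = float(np.sum((values - c0) ** 2))
    return KineticFit(c0=float(c0), c_inf=float(c_inf), k=float(k), rss=rss, flags=flags)


def compute_metrics(
    curve: HydrolysisCurve,
    reference: Optional[HydrolysisCurve] = None,
    t_start: float = 0.0,
    t_end: float = 120.0,
) -> HydrolysisMetrics:
    """S60/S90/S120, AUC and HI for one curve over the metric window."""
    return HydrolysisMetrics(
        s60=value_at(curve, 60.0),
        s90=value_at(curve, 90.0),
        s120=value_at(curve, 120.0),
        auc=auc_trapezoid(curve, t_start, t_end),
        hi=hydrolysis_index(curve, reference, t_start, t_end),
    )
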