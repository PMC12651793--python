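"""Statsmodels-style front end: a model built from panel data whose fit()
returns a results object with estimates, validation and a summary table.

    >>> model = GlycemicIndexModel(foods, curves, digestion_model="dynamic")
    >>> res = model.fit()
    >>> print(res.summary())

The model holds the inputs (composition records, hydrolysis curves, the
eGI coefficients and metric window); fitting extracts kinetic metrics per
food, scores both eGI predictors, and — for foods carrying a human GI —
assembles the prediction-versus-human-GI validation reports.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .egi import EgiResult, PanelResult, compute_panel
from .io import (
    EgiCoefficients,
    FoodRecord,
    HydrolysisCurve,
    load_curves,
    load_food_table,
    write_egi_report,
)
from .validation import ValidationReport, validate_panel

__all__ = ["GlycemicIndexModel", "GlycemicIndexResults"]


class GlycemicIndexModel:
    """Estimated-glycemic-index model over a food panel.

    Parameters
    ----------
    foods : sequence of FoodRecord
        Composition table; human GI is optional per food but required for
        validation.
    curves : sequence of HydrolysisCurve
        Starch-hydrolysis time courses; replicates are averaged at fit time.
    digestion_model : {"dynamic", "static"}
        Which protocol's curves enter the fit.
    coefficients : EgiCoefficients, optional
        Empirical coefficient overrides.
    reference : HydrolysisCurve, optional
        Reference curve for a Goni-style hydrolysis index; the default is
        the ideal instantaneous-digestion (constant 100 %) reference.
    """

    def __init__(
        self,
        foods: Sequence[FoodRecord],
        curves: Iterable[HydrolysisCurve],
        digestion_model: str = "dynamic",
        coefficients: Optional[EgiCoefficients] = None,
        reference: Optional[HydrolysisCurve] = None,
        t_start: float = 0.0,
        t_end: float = 120.0,
    ) -> None:
        self.foods = list(foods)
        self.curves = list(curves)
        self.digestion_model = digestion_model
        self.coefficients = coefficients or EgiCoefficients()
        self.reference = reference
        self.t_start = t_start
        self.t_end = t_end

    @classmethod
    def from_csv(cls, foods_path, curves_path, **kwargs) -> "GlycemicIndexModel":
        """Build the model from ``foods.csv`` / ``curves.csv`` files."""
        return cls(load_food_table(foods_path), load_curves(curves_path), **kwargs)

    def fit(self) -> "GlycemicIndexResults":
        panel = compute_panel(
            self.foods,
            self.curves,
            digestion_model=self.digestion_model,
            coefs=self.coefficients,
            reference=self.reference,
            t_start=self.t_start,
            t_end=self.t_end,
        )
        validation: Dict[str, ValidationReport] = {}
        with_gi = [f for f in self.foods if f.human_gi is not None]
        scored = {r.food_id for r in panel.results}
        usable = [f for f in with_gi if f.food_id in scored]
        if len(usable) >= 3:
            for label, attr in (("goni", "egi_goni"), ("new", "egi_new")):
                column = [
                    (r.food_id, getattr(r, attr))
                    for r in panel.results
                    if r.food_id in {f.food_id for f in usable}
                ]
                validation[label] = validate_panel(usable, column)
        return GlycemicIndexResults(self, panel, validation)


class GlycemicIndexResults:
    """Estimates and diagnostics from a fitted :class:`GlycemicIndexModel`."""

    def __init__(
        self,
        model: GlycemicIndexModel,
        panel: PanelResult,
        validation: Dict[str, ValidationReport],
    ) -> None:
        self.model = model
        self.panel = panel
        self.validation = validation

    @property
    def results(self) -> Sequence[EgiResult]:
        return self.panel.results

    @property
    def skipped(self):
        return self.panel.skipped

    @property
    def frame(self) -> pd.DataFrame:
        """Per-food estimates as a DataFrame (one row per scored food)."""
        by_id = {f.food_id: f for f in self.model.foods}
        rows = []
        for r in self.results:
            f = by_id[r.food_id]
            rows.append(
                {
                    "food_id": r.food_id,
                    "name": f.name,
                    "human_gi": f.human_gi,
                    "s60": r.metrics.s60,
                    "s90": r.metrics.s90,
                    "s120": r.metrics.s120,
                    "hi": r.metrics.hi,
                    "a_constant": r.a_constant,
                    "egi_goni": r.egi_goni,
                    "egi_new": r.egi_new,
                    "flags": ";".join(r.flags),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable panel summary with per-food eGIs and the
        validation regressions."""
        lines = [
            "Estimated Glycemic Index panel",
            f"  digestion model: {self.model.digestion_model}",
            f"  foods scored: {len(self.results)}"
            + (f" (skipped: {len(self.skipped)})" if self.skipped else ""),
            "",
            f"{'food':<28}{'human GI':>9}{'eGI(H90)':>10}{'eGI(kinetic)':>13}",
        ]
        by_id = {f.food_id: f for f in self.model.foods}
        for r in self.results:
            f = by_id[r.food_id]
            gi = f"{f.human_gi:.0f}" if f.human_gi is not None else "-"
            lines.append(
                f"{f.name[:27]:<28}{gi:>9}{r.egi_goni:>10.1f}{r.egi_new:>13.1f}"
            )
        for label, rep in self.validation.items():
            lines.append("")
            lines.append(
                f"validation [{label}]: eGI = {rep.slope:.4f} x humanGI "
                f"{rep.intercept:+.2f}   (r = {rep.pearson_r:.2f}, n = {rep.n_foods})"
            )
        for fid, reason in self.skipped:
            lines.append(f"skipped {fid}: {reason}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        """Write the per-food report (composition, eGIs, deviations, footer
        regression lines) in the ``report.csv`` dialect."""
        write_egi_report(self.model.foods, self.results, self.validation, path)

    def plot_curves(self, ax=None):
        """Plot the hydrolysis curves entering the fit (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for c in self.model.curves:
            if c.digestion_model == self.model.digestion_model:
                ax.plot(c.times, c.values, marker="o", alpha=0.7, label=c.food_id)
        ax.set_xlabel("intestinal-phase time (min)")
        ax.set_ylabel("starch hydrolysis (%)")
        ax.set_ylim(0, 100)
        return ax

    def plot_validation(self, formula: str = "new", ax=None):
        """Scatter of eGI vs human GI with the fitted line and identity."""
        import matplotlib.pyplot as plt

        rep = self.validation[formula]
        if ax is None:
            _, ax = plt.subplots()
        gi = np.array([p[1] for p in rep.per_food])
        eg = np.array([p[2] for p in rep.per_food])
        ax.scatter(gi, eg)
        xs = np.linspace(gi.min(), gi.max(), 2)
        ax.plot(xs, rep.slope * xs + rep.intercept, label=(
            f"y = {rep.slope:.4f}x {rep.intercept:+.2f} (r = {rep.pearson_r:.2f})"))
        ax.plot(xs, xs, linestyle=":", color="grey", label="identity")
        ax.set_xlabel("human GI")
        ax.set_ylabel(f"eGI ({formula})")
        ax.legend()
        return ax
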