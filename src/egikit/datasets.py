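"""Packaged reference data.

``table2.csv`` transcribes a published 14-food panel: per-100 g
composition, human GI (China Food Composition Table, 6th edition), and
the two published eGI columns (single-point H90 formula and the
kinetics + macronutrient formula).  The per-food hydrolysis metrics
behind the published eGI columns were not published, so the eGI values
here are transcribed inputs, not recomputable quantities.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import FoodRecord, load_food_table

__all__ = ["reference_table_path", "load_reference_foods", "load_reference_egi"]


def reference_table_path():
    """Path to the packaged 14-food reference table."""
    return resources.files("egikit").joinpath("data/table2.csv")


def load_reference_foods() -> list:
    """The 14 reference foods as :class:`FoodRecord` rows (table order)."""
    with resources.as_file(reference_table_path()) as p:
        return load_food_table(p)


def load_reference_egi() -> pd.DataFrame:
    """The published eGI columns: food_id, human_gi, egi_goni, egi_new."""
    with resources.as_file(reference_table_path()) as p:
        df = pd.read_csv(p)
    return df[["food_id", "human_gi", "egi_goni", "egi_new"]]
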