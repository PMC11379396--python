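"""Packaged reference loading matrices and cross-group set mappings.

The package ships the final rotated pattern matrices reported for three
macaque species in two rating situations (values at two decimals, as
printed), the per-species item-exclusion annotations, and the factor-to-set
mappings used for the cross-species fuzzy intersections. These fixtures let
the comparison stages run and be validated without the raw ratings, which
were never deposited.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .fuzzy_sets import FactorMapping

SPECIES = ("rhesus", "longtailed", "bonnet")
FAMILIES = ("general", "human")


def _res(name: str):
    return resources.files("crossfa.data.published").joinpath(name)


def load_published_loadings(family: str) -> dict[str, pd.DataFrame]:
    """Per-species final pattern matrices (items x named factors)."""
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    out = {}
    for sp in SPECIES:
        with _res(f"{family}_{sp}.csv").open("r", encoding="utf-8") as fh:
            out[sp] = pd.read_csv(fh, index_col="item")
    return out


def load_published_exclusions(family: str) -> pd.DataFrame:
    with _res(f"{family}_exclusions.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_set_mappings(family: str) -> list[FactorMapping]:
    """The cross-species fuzzy-set assignments, reversals included."""
    raw = json.loads(_res("fuzzy_sets.json").read_text("utf-8"))[family]
    order = raw["species_order"]
    mappings = []
    for set_name, spec in raw["sets"].items():
        assignment = {
            sp: (spec[sp]["factor"], bool(spec[sp]["reversed"]))
            for sp in order
            if sp in spec
        }
        mappings.append(FactorMapping(set_name=set_name, assignment=assignment))
    return mappings
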