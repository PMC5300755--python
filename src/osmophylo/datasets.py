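"""Packaged reference data.

The packaged table of published osmoregulatory traits for 25 fiddler-crab
species (habitat and hemolymph osmolality, lethal limits, hemolymph
osmolality at the limits, isosmotic point and the two regulation indices,
with standard errors where reported) is the standard species-level input
for the comparative stages.  A "-" (unobserved) lower lethal limit is
encoded as a missing value.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .osmo_traits import TRAIT_COLUMNS

_COLUMN_MAP = {
    "habitat_mosm": "habitat_osmolality",
    "hemolymph_mosm": "hemolymph_osmolality",
    "ll50": "ll50",
    "ul50": "ul50",
    "osm_ll50": "osm_ll50",
    "osm_ul50": "osm_ul50",
    "isosmotic_point": "isosmotic_point",
    "rc_hyper": "rc_hyper",
    "rc_hypo": "rc_hypo",
}


def load_reference_table() -> pd.DataFrame:
    """Full published trait table, one row per species, SEs included."""
    with resources.files("osmophylo.data").joinpath("uca_table1.csv").open() as fh:
        return pd.read_csv(fh, index_col="species")


def load_reference_traits() -> pd.DataFrame:
    """The nine traits in canonical column order (species x trait)."""
    tab = load_reference_table()
    out = tab[list(_COLUMN_MAP)].rename(columns=_COLUMN_MAP)
    return out[TRAIT_COLUMNS]
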