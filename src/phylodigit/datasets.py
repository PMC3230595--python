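"""Loaders for the packaged species-level fixtures.

The fixtures carry the species-level study data:
per-species, per-sex morphometrics (sample size, snout-vent length and
digit II/IV lengths for front and hind limbs, means and standard errors in
mm), per-species substrate-use proportions over five substrate classes,
and the composite rooted topology of the 25 species.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .tree import PhyloTree, parse_newick

SUBSTRATES = ("sand", "rocks", "trunks", "ground", "perches")


def _fixture_text(name: str) -> str:
    return (resources.files("phylodigit") / "fixtures" / name).read_text()


def load_morphometrics() -> pd.DataFrame:
    """Species x sex morphometric table (lengths in mm)."""
    with resources.as_file(
        resources.files("phylodigit") / "fixtures" / "table1.csv"
    ) as path:
        return pd.read_csv(path, comment="#")


def load_substrate_indices() -> pd.DataFrame:
    """Per-species substrate-use proportions, indexed by species."""
    with resources.as_file(
        resources.files("phylodigit") / "fixtures" / "table2.csv"
    ) as path:
        df = pd.read_csv(path, comment="#")
    return df.set_index("species")


def load_tree() -> PhyloTree:
    """Composite rooted topology of the 25 species (no branch lengths)."""
    return parse_newick(_fixture_text("iguania.nwk"))
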