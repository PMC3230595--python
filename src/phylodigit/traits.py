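"""Species-level trait construction: digit ratios, size correction, SDI.

The analysis trait is the digit ratio 2D:4D, computed on log10-transformed
lengths as log10(digit II) / log10(digit IV); with digit II shorter than
digit IV the ratio lies in (0, 1), approaching 1 when the two digits are
nearly equal.  Because digit ratio covaries with body size, ratios are
size-corrected as the residuals of a phylogenetic GLS regression on
log10 SVL; the regression slope accounts for shared ancestry via the tree
covariance but residuals are returned on the original trait scale.

Sexual dimorphism is summarized per limb by an index (SDI) built from the
(+1-shifted) size-corrected male and female residuals: male/female when
male-biased and 2 - female/male when female-biased, so the index is
continuous at equality (value 1) and values above 1 indicate male bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, KeyingError
from .regression import HIERARCHICAL, gls_fit
from .tree import PhyloTree, assign_branch_lengths, phylo_covariance

LIMBS = ("fl", "hl")
SEXES = ("male", "female")

#: canonical-name synonyms seen across printed tables
_SYNONYMS = {
    "enyalius_iheringi": "Enyalius_iheringii",
}


def canonical_species(name: str) -> str:
    """Normalize a species name to the fixture convention (Genus_species)."""
    key = name.strip().replace(" ", "_")
    return _SYNONYMS.get(key.lower(), key)


def compute_digit_ratio(len2d: float, len4d: float) -> float:
    """Digit ratio 2D:4D on log10-transformed lengths (lengths in mm).

    Both lengths must exceed 1 mm so both logs are positive.
    """
    len2d = np.asarray(len2d, dtype=float)
    len4d = np.asarray(len4d, dtype=float)
    if np.any(len2d <= 1.0) or np.any(len4d <= 1.0):
        raise DataError(
            "digit lengths must exceed 1 mm for a log-scale ratio"
        )
    out = np.log10(len2d) / np.log10(len4d)
    return float(out) if out.ndim == 0 else out


def size_correct(
    tree: PhyloTree,
    trait: dict[str, float],
    log_svl: dict[str, float],
    branch_lengths: str = "nee",
) -> dict[str, float]:
    """Residuals of a phylogenetic regression of a trait on log10 SVL.

    Fits trait ~ intercept + log10(SVL) by GLS with the Brownian covariance
    of ``tree`` (branch lengths assigned with ``branch_lengths`` if unset)
    and returns the raw residuals e = y - X beta per species.  The slope is
    estimated phylogenetically; the residuals stay on the trait scale.
    """
    if not tree.has_branch_lengths():
        tree = assign_branch_lengths(tree, branch_lengths)
    species = tree.tip_labels
    missing = [s for s in species if s not in trait or s not in log_svl]
    if missing:
        raise DataError(f"trait or SVL values missing for: {missing}")
    C = phylo_covariance(tree)
    y = np.array([trait[s] for s in species])
    x = np.array([log_svl[s] for s in species])
    X = np.column_stack([np.ones_like(x), x])
    fit = gls_fit(y, X, C, model=HIERARCHICAL)
    return dict(zip(species, fit.residuals))


def sdi(male_resid: float, female_resid: float) -> float:
    """Sexual dimorphism index from size-corrected residuals.

    Residuals are shifted by +1 to make both values positive; with
    m = male + 1 and f = female + 1 the index is m/f when m >= f and
    2 - f/m otherwise, so values > 1 mean male bias and the index is
    continuous (= 1) at m = f.
    """
    m = male_resid + 1.0
    f = female_resid + 1.0
    if m <= 0.0 or f <= 0.0:
        raise DataError(
            f"+1 shift insufficient: shifted values m={m:.4f}, f={f:.4f}"
        )
    return m / f if m >= f else 2.0 - f / m


@dataclass
class SpeciesDataset:
    """Joined species-level morphometrics, derived traits and ecology.

    ``table`` is indexed by species and carries, per sex x limb, the digit
    ratio, its size-corrected residual and log10 SVL, the per-limb SDI,
    and the five substrate-use proportions.  ``validation`` lists the
    invariant checks performed at build time.
    """

    table: pd.DataFrame
    tree: PhyloTree
    branch_lengths: str
    validation: list[str] = field(default_factory=list)

    @property
    def species(self) -> list[str]:
        return list(self.table.index)

    def trait_frame(self, traits: list[str]) -> pd.DataFrame:
        return self.table[traits]

    def substrate_frame(self) -> pd.DataFrame:
        from .datasets import SUBSTRATES

        return self.table[list(SUBSTRATES)]


def build_species_table(
    morph: pd.DataFrame,
    eco: pd.DataFrame,
    tree: PhyloTree,
    branch_lengths: str = "nee",
    substrate_sum_tol: float = 0.02,
) -> SpeciesDataset:
    """Join morphometrics, ecology and tree into the analysis dataset.

    Applies canonical species-name normalization, computes per sex x limb
    digit ratios and log10 SVL from species means, size-corrects each
    ratio phylogenetically (four separate regressions), derives per-limb
    SDI, and validates the dataset invariants.  Raises
    :class:`KeyingError` when the three sources do not cover the same
    species set.
    """
    morph = morph.copy()
    morph["species"] = morph["species"].map(canonical_species)
    eco = eco.copy()
    eco.index = [canonical_species(s) for s in eco.index]

    tips = set(tree.tip_labels)
    morph_sp = set(morph["species"])
    eco_sp = set(eco.index)
    problems = []
    for name, got in (("morphometrics", morph_sp), ("ecology", eco_sp)):
        if got != tips:
            problems.append(
                f"{name} vs tree: only-in-{name}={sorted(got - tips)}, "
                f"only-in-tree={sorted(tips - got)}"
            )
    if problems:
        raise KeyingError("; ".join(problems))

    validation: list[str] = []
    from .datasets import SUBSTRATES

    sums = eco[list(SUBSTRATES)].sum(axis=1)
    bad = sums[(sums - 1.0).abs() > substrate_sum_tol]
    if len(bad):
        raise DataError(
            f"substrate proportions do not sum to 1: {bad.to_dict()}"
        )
    validation.append(
        f"substrate rows sum to 1 within {substrate_sum_tol} (max dev "
        f"{float((sums - 1).abs().max()):.3f})"
    )

    if (morph["n"] < 1).any():
        raise DataError("sample sizes must be >= 1")
    length_cols = [c for c in morph.columns if c.endswith("_mean")]
    if (morph[length_cols] <= 1.0).any().any():
        raise DataError("all length means must exceed 1 mm")
    validation.append("all sample sizes >= 1 and length means > 1 mm")

    species = tree.tip_labels  # canonical analysis order
    rows = {}
    for sex in SEXES:
        sub = morph[morph.sex == sex].set_index("species").loc[species]
        rows[sex] = sub
        tag = sex[0]
        col = {}
        col[f"log_svl_{tag}"] = np.log10(sub["svl_mean"])
        for limb in LIMBS:
            col[f"ratio_{limb}_{tag}"] = compute_digit_ratio(
                sub[f"{limb}_d2_mean"].to_numpy(),
                sub[f"{limb}_d4_mean"].to_numpy(),
            )
        rows[f"cols_{sex}"] = col

    table = pd.DataFrame(index=pd.Index(species, name="species"))
    for sex in SEXES:
        for name, values in rows[f"cols_{sex}"].items():
            table[name] = np.asarray(values)
        table[f"n_{sex[0]}"] = rows[sex]["n"].to_numpy()

    work_tree = (
        tree if tree.has_branch_lengths()
        else assign_branch_lengths(tree, branch_lengths)
    )
    for sex in SEXES:
        tag = sex[0]
        logsvl = table[f"log_svl_{tag}"].to_dict()
        for limb in LIMBS:
            resid = size_correct(
                work_tree, table[f"ratio_{limb}_{tag}"].to_dict(), logsvl
            )
            table[f"resid_{limb}_{tag}"] = [resid[s] for s in species]
    for limb in LIMBS:
        table[f"sdi_{limb}"] = [
            sdi(table.loc[s, f"resid_{limb}_m"], table.loc[s, f"resid_{limb}_f"])
            for s in species
        ]
    validation.append(
        "size-corrected residuals and SDI computed with "
        f"{work_tree.method or branch_lengths} branch lengths"
    )

    table = table.join(eco[list(SUBSTRATES)])
    return SpeciesDataset(
        table=table,
        tree=work_tree,
        branch_lengths=work_tree.method or branch_lengths,
        validation=validation,
    )
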