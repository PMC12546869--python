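"""PRM inclusion-list generation for differentially methylated histone peptides.

Enumerates the chemical forms a propionyl-derivatized histone peptide takes
across lysine methylation states (me0..me3; me1 has two forms, free and
propionylated mono-methyl) and emits a vendor-neutral precursor target list
for parallel reaction monitoring.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .chem import (
    DEFAULT_CONSTANTS,
    ChemicalConstants,
    ModifiedPeptide,
    precursor_mz,
    propionylate,
    render_modified_peptide,
)

__all__ = [
    "PrecursorTarget",
    "enumerate_methyl_forms",
    "build_inclusion_list",
    "h3k36_inclusion_list",
    "H3K36_PEPTIDE",
    "H3K36_SITE",
    "write_inclusion_list",
]

#: Histone H3 residues 27-40; K36 is position 10 in peptide coordinates.
H3K36_PEPTIDE = "KSAPSTGGVKKPHR"
H3K36_SITE = 10


@dataclass(frozen=True)
class PrecursorTarget:
    """One row of a PRM inclusion list: a peptidoform at one charge state."""

    label: str
    peptidoform: ModifiedPeptide
    charge: int
    mz: float

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.mz <= 0:
            raise ValueError("mz must be positive")


def enumerate_methyl_forms(
    base: ModifiedPeptide, site: int
) -> list[tuple[str, ModifiedPeptide]]:
    """Enumerate the five chemical forms of a methylatable lysine site.

    The site lysine is rendered as: propionylated (me0), free mono-methyl
    (me1-free), propionylated mono-methyl (me1-prop), dimethyl (me2) and
    trimethyl (me3).  All other lysines are propionylated.  Order follows
    the conventional me0, me1 (both forms), me2, me3 listing.
    """
    if not 1 <= site <= len(base.sequence):
        raise ValueError(f"site {site} outside peptide")
    if base.sequence[site - 1] != "K":
        raise ValueError(
            f"site {site} is {base.sequence[site - 1]!r}, not a lysine"
        )
    if base.modification_at(site) is not None:
        raise ValueError(f"site {site} already carries a modification")

    def with_site_mod(name: str | None) -> ModifiedPeptide:
        mods = list(base.modifications)
        if name is not None:
            mods.append((site, name))
        return propionylate(base.with_modifications(mods), derivatize_nterm=False)

    forms = [
        ("me0", with_site_mod(None)),  # propionylate() adds propionyl at site
        ("me1-free", _without_site_propionyl(with_site_mod("methyl"), site)),
        ("me1-prop", with_site_mod("methyl")),  # methyl -> propionyl-methyl
        ("me2", with_site_mod("dimethyl")),
        ("me3", with_site_mod("trimethyl")),
    ]
    return forms


def _without_site_propionyl(p: ModifiedPeptide, site: int) -> ModifiedPeptide:
    """Revert the derivatization at one site to a bare mono-methyl lysine."""
    mods = [
        (pos, "methyl" if pos == site and name == "propionyl-methyl" else name)
        for pos, name in p.modifications
    ]
    return p.with_modifications(mods)


def build_inclusion_list(
    forms: Sequence[tuple[str, ModifiedPeptide]],
    charges: Sequence[int] = (2, 3),
    constants: ChemicalConstants = DEFAULT_CONSTANTS,
) -> list[PrecursorTarget]:
    """Build PRM targets: one row per (form, charge), in form order then
    ascending charge."""
    if not charges:
        raise ValueError("charge list must not be empty")
    targets = []
    for label, peptidoform in forms:
        for charge in sorted(charges):
            targets.append(
                PrecursorTarget(
                    label=label,
                    peptidoform=peptidoform,
                    charge=charge,
                    mz=precursor_mz(peptidoform, charge, constants),
                )
            )
    return targets


def h3k36_inclusion_list(
    charges: Sequence[int] = (2, 3),
    constants: ChemicalConstants = DEFAULT_CONSTANTS,
) -> list[PrecursorTarget]:
    """The default H3K36 PRM list: 5 forms of KSAPSTGGVKKPHR x the charges
    (10 rows at the default 2+/3+)."""
    base = ModifiedPeptide(H3K36_PEPTIDE)
    return build_inclusion_list(
        enumerate_methyl_forms(base, H3K36_SITE), charges, constants
    )


def write_inclusion_list(
    targets: Iterable[PrecursorTarget],
    path: str | Path,
    constants: ChemicalConstants = DEFAULT_CONSTANTS,
) -> None:
    """Write targets to CSV: label, sequence, modifications, charge, mz
    (m/z printed to 5 decimals)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "sequence", "modifications", "charge", "mz"])
        for t in targets:
            writer.writerow(
                [
                    t.label,
                    t.peptidoform.sequence,
                    render_modified_peptide(t.peptidoform, constants),
                    t.charge,
                    f"{t.mz:.5f}",
                ]
            )
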