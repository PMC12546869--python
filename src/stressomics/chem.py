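"""Monoisotopic mass arithmetic for modified peptides.

This module is the chemical foundation of the package: peptide neutral-mass
and precursor m/z calculation, a parser/renderer for the peptidoform string
dialect used in targeted histone-PTM work (``K(Pr/56.03)SAPSTGGVK...``),
in-silico tryptic digestion with cleavage-blocking rules, and the
propionylation derivatization model used to equalize peptide chemistry
across lysine methylation states.

All masses are monoisotopic and in daltons.  Residue coordinates are
1-based; the sentinels ``"N-term"`` and ``"C-term"`` address the peptide
termini.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, Union

from pyteomics import mass as _pyteomics_mass

__all__ = [
    "ChemicalConstants",
    "ModifiedPeptide",
    "DigestSpec",
    "PeptideParseError",
    "DEFAULT_CONSTANTS",
    "parse_modified_peptide",
    "render_modified_peptide",
    "neutral_mass",
    "precursor_mz",
    "digest",
    "propionylate",
    "load_constants_config",
]

Position = Union[int, str]  # 1-based residue index, or "N-term"/"C-term"

_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Full-precision monoisotopic mass shifts (Da).  The two-decimal labels
#: printed in inclusion lists ("Pr/56.03") are display names only; all
#: arithmetic uses these values.
_DEFAULT_MOD_MASSES: dict[str, float] = {
    "propionyl": 56.026215,
    "methyl": 14.015650,
    "dimethyl": 28.031300,
    "trimethyl": 42.046950,
    # propionyl + methyl on one lysine epsilon-amine (mono-methylated
    # lysine still carries a derivatizable proton)
    "propionyl-methyl": 70.041865,
    "phospho": 79.966331,
    "carbamidomethyl": 57.021464,
    "oxidation": 15.994915,
    "acetyl-Nterm": 42.010565,
    # SILAC labels: 13C6 15N4 arginine, 13C6 15N2 lysine, 13C5 15N1 proline
    "Arg10": 10.008269,
    "Lys8": 8.014199,
    "Pro6": 6.013809,
}

#: Short tag names of the peptidoform dialect mapped to canonical keys.
_TAG_ALIASES: dict[str, str] = {
    "pr": "propionyl",
    "me": "methyl",
    "di": "dimethyl",
    "tri": "trimethyl",
    "ph": "phospho",
    "ox": "oxidation",
    "cam": "carbamidomethyl",
    "ac": "acetyl-Nterm",
}

#: Preferred short display tags, used by the renderer.
_DISPLAY_TAGS: dict[str, str] = {
    "propionyl": "Pr",
    "methyl": "Me",
    "dimethyl": "Di",
    "trimethyl": "Tri",
    "phospho": "Ph",
    "oxidation": "Ox",
    "carbamidomethyl": "Cam",
    "acetyl-Nterm": "Ac",
}

#: Composite keys rendered/parsed as "A + B" pairs.
_COMPOSITES: dict[frozenset[str], str] = {
    frozenset({"propionyl", "methyl"}): "propionyl-methyl",
}
_COMPOSITE_PARTS: dict[str, tuple[str, str]] = {
    "propionyl-methyl": ("propionyl", "methyl"),
}


class PeptideParseError(ValueError):
    """Raised when a peptidoform string cannot be parsed."""


@dataclass(frozen=True)
class ChemicalConstants:
    """Monoisotopic mass tables used throughout the package.

    Parameters
    ----------
    residue_masses
        One-letter amino-acid code -> monoisotopic residue mass (Da).
    water_mass
        Mass of H2O added once per peptide (Da).
    proton_mass
        Mass of a proton, used for m/z conversion (Da).
    modification_masses
        Modification key -> monoisotopic mass shift (Da).
    """

    residue_masses: Mapping[str, float]
    modification_masses: Mapping[str, float]
    water_mass: float = 18.010565
    proton_mass: float = 1.007276

    def __post_init__(self) -> None:
        missing = [aa for aa in _STANDARD_AA if aa not in self.residue_masses]
        if missing:
            raise ValueError(f"residue_masses missing standard residues: {missing}")
        bad = [aa for aa, m in self.residue_masses.items() if m <= 0]
        if bad:
            raise ValueError(f"non-positive residue masses for: {bad}")

    def residue_mass(self, aa: str) -> float:
        try:
            return self.residue_masses[aa]
        except KeyError:
            raise KeyError(f"unknown residue {aa!r}") from None

    def modification_mass(self, name: str) -> float:
        try:
            return self.modification_masses[name]
        except KeyError:
            raise KeyError(f"unknown modification {name!r}") from None


def _default_residue_masses() -> dict[str, float]:
    return {aa: _pyteomics_mass.std_aa_mass[aa] for aa in _STANDARD_AA}


DEFAULT_CONSTANTS = ChemicalConstants(
    residue_masses=_default_residue_masses(),
    modification_masses=dict(_DEFAULT_MOD_MASSES),
)


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with positioned modifications.

    ``modifications`` is a tuple of ``(position, name)`` pairs where
    position is a 1-based residue index or ``"N-term"``/``"C-term"``.
    At most one side-chain modification may sit on a residue; a
    propionylated mono-methyl lysine is the single composite key
    ``"propionyl-methyl"``.
    """

    sequence: str
    modifications: tuple[tuple[Position, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        bad = [c for c in self.sequence if c not in _STANDARD_AA]
        if bad:
            raise ValueError(f"invalid residue letters: {bad}")
        seen: set[Position] = set()
        for pos, _name in self.modifications:
            if isinstance(pos, int):
                if not 1 <= pos <= len(self.sequence):
                    raise ValueError(
                        f"modification position {pos} outside 1..{len(self.sequence)}"
                    )
            elif pos not in ("N-term", "C-term"):
                raise ValueError(f"invalid modification position {pos!r}")
            if pos in seen:
                raise ValueError(f"multiple modifications at position {pos!r}")
            seen.add(pos)
        # normalize ordering: terminal mods first, then by residue index
        object.__setattr__(
            self, "modifications", tuple(sorted(self.modifications, key=_mod_sort_key))
        )

    def modification_at(self, pos: Position) -> str | None:
        for p, name in self.modifications:
            if p == pos:
                return name
        return None

    def with_modifications(
        self, modifications: Iterable[tuple[Position, str]]
    ) -> "ModifiedPeptide":
        return replace(self, modifications=tuple(modifications))


def _mod_sort_key(mod: tuple[Position, str]):
    pos = mod[0]
    if pos == "N-term":
        return (0, 0)
    if pos == "C-term":
        return (2, 0)
    return (1, pos)


@dataclass(frozen=True)
class DigestSpec:
    """Proteolytic digestion rules.

    Only trypsin is supported: cleavage C-terminal to K/R, blocked when
    the following residue is proline or when the lysine at the cleavage
    site carries a side-chain modification listed in
    ``blocked_lysine_mods`` (derivatized or methylated lysines are not
    cleaved).
    """

    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    blocked_lysine_mods: frozenset[str] = frozenset(
        {"propionyl", "propionyl-methyl", "methyl", "dimethyl", "trimethyl"}
    )

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise ValueError(f"unsupported enzyme {self.enzyme!r}")
        if not 0 <= self.max_missed_cleavages <= 5:
            raise ValueError("max_missed_cleavages must be in 0..5")


# ---------------------------------------------------------------------------
# peptidoform string dialect
#
# EBNF:
#   peptidoform = [ "[" tag "]" "-" ] , { residue , [ "(" tag ")" ] } ,
#                 [ "-" "[" tag "]" ] ;
#   tag         = modterm , { " + " modterm } ;
#   modterm     = name , [ "/" number ] ;
#   residue     = "A" | "C" | ... | "Y" ;
#
# The numeric shift after "/" is informational; masses always come from
# ChemicalConstants by name.  "Pr + Me" on one residue parses to the
# composite key "propionyl-methyl".
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"([A-Za-z])(\(([^()]*)\))?")


def _resolve_tag_name(token: str, constants: ChemicalConstants) -> str:
    name = token.strip()
    if not name:
        raise PeptideParseError("empty modification name")
    lowered = name.lower()
    if lowered in _TAG_ALIASES:
        return _TAG_ALIASES[lowered]
    for key in constants.modification_masses:
        if key.lower() == lowered:
            return key
    raise PeptideParseError(f"unknown modification name {name!r}")


def _parse_tag(tag: str, constants: ChemicalConstants) -> str:
    """Parse one parenthesized tag into a canonical modification key."""
    parts = [p for p in tag.split("+")]
    names = []
    for part in parts:
        term = part.strip()
        name = term.split("/", 1)[0]
        names.append(_resolve_tag_name(name, constants))
    if len(names) == 1:
        return names[0]
    key = frozenset(names)
    if key in _COMPOSITES:
        return _COMPOSITES[key]
    raise PeptideParseError(f"unsupported composite modification {tag!r}")


def parse_modified_peptide(
    notation: str, constants: ChemicalConstants = DEFAULT_CONSTANTS
) -> ModifiedPeptide:
    """Parse a peptidoform string like ``"K(Pr/56.03)SAPSTGGVK(Di/28.03)K(Pr/56.03)PHR"``.

    Raises :class:`PeptideParseError` on unknown residues, unknown
    modification names, or unbalanced parentheses.
    """
    if notation.count("(") != notation.count(")"):
        raise PeptideParseError(f"unbalanced parentheses in {notation!r}")
    mods: list[tuple[Position, str]] = []
    rest = notation
    # optional N-terminal "[tag]-" prefix
    m = re.match(r"^\[([^\[\]]*)\]-", rest)
    if m:
        mods.append(("N-term", _parse_tag(m.group(1), constants)))
        rest = rest[m.end():]
    # optional C-terminal "-[tag]" suffix
    m = re.search(r"-\[([^\[\]]*)\]$", rest)
    if m:
        mods.append(("C-term", _parse_tag(m.group(1), constants)))
        rest = rest[: m.start()]

    sequence_chars: list[str] = []
    cursor = 0
    while cursor < len(rest):
        m = _TOKEN_RE.match(rest, cursor)
        if not m:
            raise PeptideParseError(
                f"unparseable token at {rest[cursor:cursor + 12]!r} in {notation!r}"
            )
        residue = m.group(1).upper()
        if residue not in _STANDARD_AA:
            raise PeptideParseError(f"unknown residue letter {m.group(1)!r}")
        sequence_chars.append(residue)
        if m.group(2) is not None:
            mods.append((len(sequence_chars), _parse_tag(m.group(3), constants)))
        cursor = m.end()
    if not sequence_chars:
        raise PeptideParseError(f"no residues found in {notation!r}")
    try:
        return ModifiedPeptide("".join(sequence_chars), tuple(mods))
    except ValueError as exc:
        raise PeptideParseError(str(exc)) from exc


def _render_tag(name: str, constants: ChemicalConstants) -> str:
    if name in _COMPOSITE_PARTS:
        a, b = _COMPOSITE_PARTS[name]
        return f"{_render_tag(a, constants)} + {_render_tag(b, constants)}"
    display = _DISPLAY_TAGS.get(name, name)
    shift = constants.modification_mass(name)
    return f"{display}/{shift:.5f}"


def render_modified_peptide(
    p: ModifiedPeptide, constants: ChemicalConstants = DEFAULT_CONSTANTS
) -> str:
    """Render a peptidoform back to the string dialect (inverse of parsing)."""
    by_pos = dict(p.modifications)
    out = []
    nterm = by_pos.pop("N-term", None)
    cterm = by_pos.pop("C-term", None)
    if nterm:
        out.append(f"[{_render_tag(nterm, constants)}]-")
    for i, aa in enumerate(p.sequence, start=1):
        out.append(aa)
        if i in by_pos:
            out.append(f"({_render_tag(by_pos[i], constants)})")
    if cterm:
        out.append(f"-[{_render_tag(cterm, constants)}]")
    return "".join(out)


# ---------------------------------------------------------------------------
# mass arithmetic
# ---------------------------------------------------------------------------

def neutral_mass(
    p: ModifiedPeptide, constants: ChemicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Monoisotopic neutral mass: residue masses + water + modification shifts."""
    total = constants.water_mass
    for aa in p.sequence:
        total += constants.residue_mass(aa)
    for _pos, name in p.modifications:
        total += constants.modification_mass(name)
    return total


def precursor_mz(
    p: ModifiedPeptide, charge: int, constants: ChemicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Precursor m/z of the protonated peptide at the given charge state."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass(p, constants) + charge * constants.proton_mass) / charge


# ---------------------------------------------------------------------------
# in-silico digestion
# ---------------------------------------------------------------------------

def digest(
    protein_sequence: str,
    spec: DigestSpec = DigestSpec(),
    fixed_mods: Sequence[tuple[int, str]] = (),
) -> list[ModifiedPeptide]:
    """In-silico tryptic digestion with cleavage-blocking modifications.

    Cleaves C-terminal to K/R except before proline or when the K at the
    cleavage site carries a modification in ``spec.blocked_lysine_mods``.
    ``fixed_mods`` are (1-based protein position, modification name) pairs
    remapped onto peptide coordinates in the output.  Peptides with
    0..max_missed_cleavages retained internal sites are emitted, ordered by
    start position then length.
    """
    seq = protein_sequence.upper()
    if not seq:
        raise ValueError("empty protein sequence")
    bad = [c for c in seq if c not in _STANDARD_AA]
    if bad:
        raise ValueError(f"invalid residue letters: {sorted(set(bad))}")
    mods_by_pos = {}
    for pos, name in fixed_mods:
        if not 1 <= pos <= len(seq):
            raise ValueError(f"fixed modification position {pos} outside protein")
        if pos in mods_by_pos:
            raise ValueError(f"multiple fixed modifications at position {pos}")
        mods_by_pos[pos] = name

    # cleavage sites: cut after residue i (1-based) when allowed
    cut_after: list[int] = []
    for i in range(1, len(seq)):  # no cut after the final residue
        aa = seq[i - 1]
        if aa not in "KR":
            continue
        if seq[i] == "P":
            continue
        if aa == "K" and mods_by_pos.get(i) in spec.blocked_lysine_mods:
            continue
        cut_after.append(i)

    boundaries = [0, *cut_after, len(seq)]
    keyed: list[tuple[int, int, ModifiedPeptide]] = []
    for bi in range(len(boundaries) - 1):
        for bj in range(
            bi + 1, min(bi + 2 + spec.max_missed_cleavages, len(boundaries))
        ):
            start, end = boundaries[bi], boundaries[bj]  # 0-based half-open
            pep_mods = [
                (pos - start, name)
                for pos, name in sorted(mods_by_pos.items())
                if start < pos <= end
            ]
            keyed.append((start, end, ModifiedPeptide(seq[start:end], tuple(pep_mods))))
    keyed.sort(key=lambda item: (item[0], item[1]))
    return [pep for _start, _end, pep in keyed]


# ---------------------------------------------------------------------------
# propionylation derivatization
# ---------------------------------------------------------------------------

def propionylate(
    p: ModifiedPeptide, derivatize_nterm: bool = False
) -> ModifiedPeptide:
    """Apply the propionic-anhydride derivatization model.

    Unmodified lysines gain ``propionyl``; mono-methyl lysines become the
    composite ``propionyl-methyl`` (the mono-methyl epsilon-amine retains a
    derivatizable proton); di-/tri-methylated lysines and all other
    residues are untouched.  The alpha-amine is derivatized only when
    ``derivatize_nterm`` is true and the N-terminus is not yet modified.
    """
    mods = dict(p.modifications)
    for i, aa in enumerate(p.sequence, start=1):
        if aa != "K":
            continue
        current = mods.get(i)
        if current is None:
            mods[i] = "propionyl"
        elif current == "methyl":
            mods[i] = "propionyl-methyl"
    if derivatize_nterm and "N-term" not in mods:
        mods["N-term"] = "propionyl"
    return p.with_modifications(tuple(mods.items()))


# ---------------------------------------------------------------------------
# constants override config
# ---------------------------------------------------------------------------

def load_constants_config(
    path, base: ChemicalConstants = DEFAULT_CONSTANTS
) -> ChemicalConstants:
    """Load mass overrides from a plain-text ``key = value`` file.

    Keys are residue letters, modification names, or ``water``/``proton``.
    Lines starting with ``#`` and blank lines are ignored.
    """
    residues = dict(base.residue_masses)
    mods = dict(base.modification_masses)
    water, proton = base.water_mass, base.proton_mass
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            mass_value = float(value)
            if key == "water":
                water = mass_value
            elif key == "proton":
                proton = mass_value
            elif len(key) == 1 and key.upper() in _STANDARD_AA:
                residues[key.upper()] = mass_value
            else:
                mods[key] = mass_value
    return ChemicalConstants(
        residue_masses=residues,
        modification_masses=mods,
        water_mass=water,
        proton_mass=proton,
    )
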