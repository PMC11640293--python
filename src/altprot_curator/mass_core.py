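"""Monoisotopic mass arithmetic for peptides and backbone fragment ions.

Everything downstream — PSM annotation, spectral-library m/z values,
precursor windows — rests on the residue-mass table and the b/y fragment
formulas in this module. Masses are monoisotopic throughout (Orbitrap-type
high-resolution data); average masses are deliberately not supported.

Conventions
-----------
* b ion of index i = the N-terminal fragment retaining i residues:
  ``mz = (sum(residues[:i]) + n_term_mods + z * PROTON) / z``
* y ion of index j = the C-terminal fragment retaining j residues:
  ``mz = (sum(residues[-j:]) + mods + WATER + z * PROTON) / z``
* N-terminal modifications (e.g. protein N-terminal acetylation) shift all
  b ions and the precursor, never y ions.

Modified peptides are written with inline bracket tags carrying the signed
monoisotopic delta, e.g. ``"AC[+57.02146]K"``; an N-terminal modification
is a leading tag joined with a dash: ``"[+42.01057]-MKR"``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "PROTON",
    "WATER",
    "RESIDUE_MASSES",
    "Modification",
    "CARBAMIDOMETHYL",
    "OXIDATION",
    "ACETYL_PROTEIN_NTERM",
    "Peptide",
    "FragmentIon",
    "digest",
    "peptide_neutral_mass",
    "fragment_mz",
    "precursor_mz",
    "enumerate_fragments",
    "parse_modified_sequence",
    "format_modified_sequence",
    "apply_fixed_modifications",
]

PROTON = 1.007276
WATER = 18.010565

# Standard monoisotopic residue (amino-acid minus water) masses, Da.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}


@dataclass(frozen=True)
class Modification:
    """A residue- or terminus-level mass modification.

    ``site`` is either ``"residue:<letter>"`` (e.g. ``"residue:C"``),
    ``"peptide_n_term"`` or ``"protein_n_term"``.
    """

    name: str
    delta_mass: float
    site: str
    fixed: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_mass):
            raise ValueError(f"modification {self.name!r}: non-finite delta mass")
        if self.site not in ("peptide_n_term", "protein_n_term") and not re.fullmatch(
            r"residue:[A-Z]", self.site
        ):
            raise ValueError(f"modification {self.name!r}: malformed site {self.site!r}")


# The search configuration used throughout: carbamidomethyl-C fixed,
# Met oxidation and protein N-terminal acetylation variable.
CARBAMIDOMETHYL = Modification("Carbamidomethyl", 57.02146, "residue:C", fixed=True)
OXIDATION = Modification("Oxidation", 15.99491, "residue:M", fixed=False)
ACETYL_PROTEIN_NTERM = Modification("Acetyl", 42.01057, "protein_n_term", fixed=False)

DEFAULT_FIXED_MODIFICATIONS = (CARBAMIDOMETHYL,)


@dataclass
class Peptide:
    """A (possibly modified) enzymatic peptide.

    Modification positions are 1-based residue indices; position 0 denotes
    the peptide/protein N-terminus. At most one modification per position.
    """

    sequence: str
    modifications: list[tuple[int, Modification]] = field(default_factory=list)
    missed_cleavages: int = 0
    parent_accessions: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        bad = [c for c in self.sequence if c not in RESIDUE_MASSES]
        if bad:
            raise ValueError(f"unknown residue {bad[0]!r} in peptide {self.sequence!r}")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        seen: set[int] = set()
        for pos, mod in self.modifications:
            if not 0 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside [0, {len(self.sequence)}]"
                )
            if pos in seen:
                raise ValueError(f"more than one modification at position {pos}")
            seen.add(pos)
            if pos >= 1 and mod.site.startswith("residue:"):
                want = mod.site.split(":", 1)[1]
                have = self.sequence[pos - 1]
                if have != want:
                    raise ValueError(
                        f"{mod.name} targets {want} but position {pos} is {have}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def mod_delta_at(self, pos: int) -> float:
        for p, mod in self.modifications:
            if p == pos:
                return mod.delta_mass
        return 0.0


@dataclass(frozen=True)
class FragmentIon:
    series: str  # "b" or "y"
    index: int
    charge: int
    mz: float

    def __post_init__(self) -> None:
        if self.series not in ("b", "y"):
            raise ValueError(f"unknown ion series {self.series!r}")
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")

    @property
    def annotation(self) -> str:
        return f"{self.series}{self.index}^{self.charge}"


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def _cleavage_sites(sequence: str, proline_rule: bool) -> list[int]:
    """Positions after which trypsin cleaves (index of the residue N-terminal
    to the scissile bond, 0-based)."""
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR":
            if proline_rule and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def digest(
    sequence: str,
    missed_cleavages_max: int = 0,
    length_range: tuple[int, int] | None = None,
    proline_rule: bool = True,
) -> list[Peptide]:
    """In-silico tryptic digestion: cleave after K/R (by default not before P).

    Returns every product carrying 0..``missed_cleavages_max`` internal
    cleavage sites, optionally filtered to ``length_range`` (inclusive).
    With no missed cleavages and no length filter, the products concatenate
    back to the input sequence.
    """
    if "X" in sequence:
        raise ValueError("undigestible residue X in sequence")
    bad = [c for c in sequence if c not in RESIDUE_MASSES]
    if bad:
        raise ValueError(f"unknown residue {bad[0]!r} in sequence")
    if missed_cleavages_max < 0:
        raise ValueError("missed_cleavages_max must be >= 0")

    sites = _cleavage_sites(sequence, proline_rule)
    # fragment boundaries: start indices of fully-cleaved products
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    peptides: list[Peptide] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for mc in range(missed_cleavages_max + 1):
            j = i + mc + 1
            if j > n_frag:
                break
            sub = sequence[bounds[i] : bounds[j]]
            if length_range is not None and not (
                length_range[0] <= len(sub) <= length_range[1]
            ):
                continue
            peptides.append(Peptide(sub, missed_cleavages=mc))
    return peptides


# ---------------------------------------------------------------------------
# mass computation
# ---------------------------------------------------------------------------

def peptide_neutral_mass(peptide: Peptide) -> float:
    """Monoisotopic neutral mass: residues + water + modification deltas."""
    mass = WATER
    for aa in peptide.sequence:
        mass += RESIDUE_MASSES[aa]
    for _, mod in peptide.modifications:
        mass += mod.delta_mass
    return mass


def precursor_mz(peptide: Peptide, charge: int) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (peptide_neutral_mass(peptide) + charge * PROTON) / charge


def fragment_mz(peptide: Peptide, series: str, index: int, charge: int) -> float:
    """m/z of the b- or y-ion of the given index and charge.

    N-terminal modifications (position 0) contribute to b ions only.
    """
    n = len(peptide)
    if not 1 <= index <= n - 1:
        raise ValueError(f"fragment index {index} out of range [1, {n - 1}]")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if series == "b":
        mass = peptide.mod_delta_at(0)
        for pos in range(1, index + 1):
            mass += RESIDUE_MASSES[peptide.sequence[pos - 1]]
            mass += peptide.mod_delta_at(pos)
    elif series == "y":
        mass = WATER
        for pos in range(n - index + 1, n + 1):
            mass += RESIDUE_MASSES[peptide.sequence[pos - 1]]
            mass += peptide.mod_delta_at(pos)
    else:
        raise ValueError(f"unknown ion series {series!r}")
    return (mass + charge * PROTON) / charge


def enumerate_fragments(
    peptide: Peptide, charges: Iterable[int] = (1, 2)
) -> list[FragmentIon]:
    """All b and y ions for indices 1..n-1 at each requested charge."""
    charges = sorted(set(charges))
    if any(z < 1 for z in charges):
        raise ValueError("fragment charges must be >= 1")
    ions = []
    for series in ("b", "y"):
        for index in range(1, len(peptide)):
            for z in charges:
                ions.append(
                    FragmentIon(series, index, z, fragment_mz(peptide, series, index, z))
                )
    return ions


# ---------------------------------------------------------------------------
# inline modification notation
# ---------------------------------------------------------------------------

_TAG = re.compile(r"\[([+-]\d+(?:\.\d+)?)\]")

_KNOWN_MODS = {
    round(CARBAMIDOMETHYL.delta_mass, 5): CARBAMIDOMETHYL,
    round(OXIDATION.delta_mass, 5): OXIDATION,
    round(ACETYL_PROTEIN_NTERM.delta_mass, 5): ACETYL_PROTEIN_NTERM,
}


def _mod_for_delta(delta: float, site: str) -> Modification:
    known = _KNOWN_MODS.get(round(delta, 5))
    if known is not None and (
        known.site == site or (site.startswith("residue:") and known.site == site)
    ):
        return known
    if known is not None:
        # same delta on a different site (e.g. acetyl written mid-peptide)
        return Modification(known.name, known.delta_mass, site, known.fixed)
    return Modification(f"delta{delta:+.5f}", delta, site)


def parse_modified_sequence(text: str) -> Peptide:
    """Parse inline-tag notation (``"AC[+57.02146]K"``, ``"[+42.01057]-MK"``)."""
    mods: list[tuple[int, Modification]] = []
    if text.startswith("["):
        m = _TAG.match(text)
        if m is None or not text[m.end() :].startswith("-"):
            raise ValueError(f"malformed N-terminal tag in {text!r}")
        mods.append((0, _mod_for_delta(float(m.group(1)), "protein_n_term")))
        text = text[m.end() + 1 :]
    sequence = []
    pos = 0
    i = 0
    while i < len(text):
        c = text[i]
        if c == "[":
            m = _TAG.match(text, i)
            if m is None:
                raise ValueError(f"malformed modification tag at offset {i} in {text!r}")
            if pos == 0:
                raise ValueError(f"modification tag before any residue in {text!r}")
            mods.append((pos, _mod_for_delta(float(m.group(1)), f"residue:{sequence[-1]}")))
            i = m.end()
        else:
            if c not in RESIDUE_MASSES:
                raise ValueError(f"unknown residue {c!r} in {text!r}")
            sequence.append(c)
            pos += 1
            i += 1
    return Peptide("".join(sequence), modifications=mods)


def format_modified_sequence(peptide: Peptide) -> str:
    """Inverse of :func:`parse_modified_sequence` (deltas printed to 5 dp)."""
    by_pos = {pos: mod for pos, mod in peptide.modifications}
    out = []
    if 0 in by_pos:
        out.append(f"[{by_pos[0].delta_mass:+.5f}]-")
    for i, aa in enumerate(peptide.sequence, start=1):
        out.append(aa)
        if i in by_pos:
            out.append(f"[{by_pos[i].delta_mass:+.5f}]")
    return "".join(out)


def apply_fixed_modifications(
    peptide: Peptide, fixed: Sequence[Modification] = DEFAULT_FIXED_MODIFICATIONS
) -> Peptide:
    """Return a copy with every fixed residue modification applied
    (default: carbamidomethylation of all cysteines)."""
    occupied = {pos for pos, _ in peptide.modifications}
    mods = list(peptide.modifications)
    for mod in fixed:
        if not mod.site.startswith("residue:"):
            continue
        target = mod.site.split(":", 1)[1]
        for i, aa in enumerate(peptide.sequence, start=1):
            if aa == target and i not in occupied:
                mods.append((i, mod))
                occupied.add(i)
    return Peptide(
        peptide.sequence,
        modifications=sorted(mods, key=lambda pm: pm[0]),
        missed_cleavages=peptide.missed_cleavages,
        parent_accessions=set(peptide.parent_accessions),
    )
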