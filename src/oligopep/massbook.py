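"""Neutral-mass and m/z bookkeeping for modified oligonucleotides, peptides
and oligonucleotide-peptide click conjugates.

All masses are derived from a single atomic-mass table (IUPAC 2021 standard
atomic weights for the average scale; CODATA/AME monoisotopic masses for the
monoisotopic scale), so every reported number is traceable to an elemental
formula.  Nothing in this module is an opaque constant: in-chain residues are
nucleoside-5'-monophosphates or amino acids minus water, terminal groups and
modification deltas are explicit compositions.

Conventions
-----------
* Oligo sequences are written 5'->3'; positions are 1-based inclusive.
* Synthetic (vendor) oligos default to 5'-OH / 3'-OH termini.
* The default mass scale is ``average``; monoisotopic is always available
  and the scale is explicit in every API.
* Negative-mode electrospray m/z is computed as deprotonation only:
  ``m/z = (M - z * m_H+) / z``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .errors import (
    ChargeError,
    EmptySequenceError,
    IncompatibleModificationError,
    MissingComponentError,
    UnknownModificationError,
    UnknownResidueError,
)

Scale = Literal["average", "monoisotopic"]

ELEMENTS = ("C", "H", "N", "O", "P", "S", "Br")

#: IUPAC 2021 standard atomic weights (Da).
ATOMIC_MASS_AVERAGE: Mapping[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973761998,
    "S": 32.06,
    "Br": 79.904,
}

#: Monoisotopic masses of the principal isotopes (Da).
ATOMIC_MASS_MONO: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Br": 78.9183371,
}

#: Proton mass used for deprotonation arithmetic, per scale. The average-scale
#: value follows the convention of using the standard atomic weight of H minus
#: the electron mass.
PROTON_MASS: Mapping[str, float] = {"monoisotopic": 1.007276, "average": 1.00739}


@dataclass(frozen=True)
class ElementalComposition:
    """An element -> count map supporting addition, subtraction and mass.

    Counts may be negative in intermediate *deltas* (e.g. a C-terminal amide
    is -O +N +H); assembled molecules are expected to be non-negative and can
    be checked with :meth:`assert_molecular`.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        clean = {e: int(c) for e, c in self.counts.items() if c != 0}
        for e in clean:
            if e not in ELEMENTS:
                raise UnknownResidueError(f"unknown element {e!r}")
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for e, c in other.counts.items():
            merged[e] = merged.get(e, 0) + c
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for e, c in other.counts.items():
            merged[e] = merged.get(e, 0) - c
        return ElementalComposition(merged)

    def __mul__(self, n: int) -> "ElementalComposition":
        return ElementalComposition({e: c * n for e, c in self.counts.items()})

    __rmul__ = __mul__

    def mass(self, scale: Scale = "average") -> float:
        table = _mass_table(scale)
        return sum(table[e] * c for e, c in self.counts.items())

    def assert_molecular(self, context: str = "") -> "ElementalComposition":
        neg = {e: c for e, c in self.counts.items() if c < 0}
        if neg:
            raise ValueError(f"negative element counts {neg} {context}".strip())
        return self

    def formula(self) -> str:
        return "".join(
            f"{e}{self.counts[e]}" for e in ELEMENTS if self.counts.get(e)
        )

    @classmethod
    def parse(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-style formula like ``C10H14N2O5`` or ``Br1H-1``."""
        counts: dict[str, int] = {}
        for m in re.finditer(r"([A-Z][a-z]?)(-?\d*)", formula):
            if not m.group(1):
                continue
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        return cls(counts)


def _mass_table(scale: Scale) -> Mapping[str, float]:
    if scale == "average":
        return ATOMIC_MASS_AVERAGE
    if scale == "monoisotopic":
        return ATOMIC_MASS_MONO
    raise ValueError(f"unknown mass scale {scale!r}")


EC = ElementalComposition.parse

WATER = EC("H2O")
#: HPO3: the phosphate group removed when a chain terminus is a hydroxyl.
PHOSPHO = EC("HPO3")

#: In-chain deoxynucleotide residues: nucleoside-5'-monophosphate minus water.
DNA_RESIDUES: Mapping[str, ElementalComposition] = {
    "A": EC("C10H12N5O5P"),
    "C": EC("C9H12N3O6P"),
    "G": EC("C10H12N5O6P"),
    "T": EC("C10H13N2O7P"),
}

#: In-chain amino-acid residues (free amino acid minus water), 3-letter codes.
AA_RESIDUES: Mapping[str, ElementalComposition] = {
    "GLY": EC("C2H3NO"),
    "ALA": EC("C3H5NO"),
    "SER": EC("C3H5NO2"),
    "PRO": EC("C5H7NO"),
    "VAL": EC("C5H9NO"),
    "THR": EC("C4H7NO2"),
    "CYS": EC("C3H5NOS"),
    "LEU": EC("C6H11NO"),
    "ILE": EC("C6H11NO"),
    "ASN": EC("C4H6N2O2"),
    "ASP": EC("C4H5NO3"),
    "GLN": EC("C5H8N2O2"),
    "LYS": EC("C6H12N2O"),
    "GLU": EC("C5H7NO3"),
    "MET": EC("C5H9NOS"),
    "HIS": EC("C6H7N3O"),
    "PHE": EC("C9H9NO"),
    "ARG": EC("C6H12N4O"),
    "TYR": EC("C9H9NO2"),
    "TRP": EC("C11H10N2O"),
}

#: Oligo terminal chemistries as deltas relative to the bare residue chain.
#: A chain of n in-chain residues carries n phosphates; an OH terminus at the
#: 5' end removes one HPO3, a phosphate terminus keeps it. Water closes the
#: chain (one H at the 5' oxygen, one OH at the 3' end).
OLIGO_TERMINI = {"OH": -1 * PHOSPHO, "phosphate": ElementalComposition()}

PEPTIDE_N_TERMINI = {"H": ElementalComposition()}
PEPTIDE_C_TERMINI = {"OH": ElementalComposition(), "NH2": EC("N1H1O-1")}


@dataclass(frozen=True)
class ModificationDelta:
    """A named compositional change applied at one residue position."""

    id: str
    description: str
    delta: ElementalComposition
    applies_to: frozenset[str]

    def check_applies(self, residue_code: str) -> None:
        if residue_code not in self.applies_to:
            raise IncompatibleModificationError(
                f"modification {self.id!r} applies to {sorted(self.applies_to)}, "
                f"not {residue_code!r}"
            )


def _builtin_modifications() -> dict[str, ModificationDelta]:
    mods = [
        ModificationDelta(
            "8-bromo-dG",
            "8-bromo-2'-deoxyguanosine: bromine replaces H8 of guanine",
            EC("Br1H-1"),
            frozenset({"G"}),
        ),
        ModificationDelta(
            "C8-alkyne-dC",
            "octa-1,7-diynyl arm on C5 of deoxycytidine (click alkyne handle)",
            EC("C8H8"),
            frozenset({"C"}),
        ),
        ModificationDelta(
            "Lys-azide",
            "epsilon-amine of lysine replaced by an azide (-NH2 +N3)",
            EC("N2H-2"),
            frozenset({"LYS"}),
        ),
    ]
    return {m.id: m for m in mods}


#: Shipped modification registry; user-extensible via :func:`register_modification`.
MODIFICATIONS: dict[str, ModificationDelta] = _builtin_modifications()


def register_modification(mod: ModificationDelta) -> None:
    MODIFICATIONS[mod.id] = mod


def _resolve_mod(mod_id: str) -> ModificationDelta:
    try:
        return MODIFICATIONS[mod_id]
    except KeyError:
        raise UnknownModificationError(
            f"modification {mod_id!r} not in registry "
            f"(known: {sorted(MODIFICATIONS)})"
        ) from None


@dataclass(frozen=True)
class ModifiedOligo:
    """A single DNA strand with terminal chemistry and site modifications.

    ``sequence`` is 5'->3' over {A,C,G,T}; ``modifications`` is a tuple of
    ``(position, modification_id)`` with 1-based positions.
    """

    id: str
    sequence: str
    five_prime: str = "OH"
    three_prime: str = "OH"
    modifications: tuple[tuple[int, str], ...] = ()

    def __post_init__(self):
        if not self.sequence:
            raise EmptySequenceError(f"oligo {self.id!r} has an empty sequence")
        for base in self.sequence:
            if base not in DNA_RESIDUES:
                raise UnknownResidueError(
                    f"oligo {self.id!r}: unknown residue {base!r}"
                )
        if self.five_prime not in OLIGO_TERMINI:
            raise UnknownResidueError(f"unknown 5' chemistry {self.five_prime!r}")
        if self.three_prime not in OLIGO_TERMINI:
            raise UnknownResidueError(f"unknown 3' chemistry {self.three_prime!r}")
        seen: set[int] = set()
        for pos, mod_id in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise IncompatibleModificationError(
                    f"oligo {self.id!r}: position {pos} outside 1..{len(self.sequence)}"
                )
            if pos in seen:
                raise IncompatibleModificationError(
                    f"oligo {self.id!r}: more than one modification at {pos}"
                )
            seen.add(pos)
            _resolve_mod(mod_id).check_applies(self.sequence[pos - 1])

    def __len__(self) -> int:
        return len(self.sequence)

    def composition(self) -> ElementalComposition:
        comp = WATER
        for base in self.sequence:
            comp = comp + DNA_RESIDUES[base]
        # 3'-phosphate adds a group the bare chain does not carry; the chain
        # already holds one phosphate per residue, so a 5'-OH removes one.
        comp = comp + OLIGO_TERMINI[self.five_prime]
        if self.three_prime == "phosphate":
            comp = comp + PHOSPHO
        for _, mod_id in self.modifications:
            comp = comp + _resolve_mod(mod_id).delta
        return comp.assert_molecular(f"in oligo {self.id!r}")


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide as 3-letter residue codes with terminal chemistry and mods."""

    id: str
    residues: tuple[str, ...]
    n_term: str = "H"
    c_term: str = "OH"
    modifications: tuple[tuple[int, str], ...] = ()

    def __post_init__(self):
        if not self.residues:
            raise EmptySequenceError(f"peptide {self.id!r} has no residues")
        for code in self.residues:
            if code not in AA_RESIDUES:
                raise UnknownResidueError(
                    f"peptide {self.id!r}: unknown residue {code!r}"
                )
        if self.n_term not in PEPTIDE_N_TERMINI:
            raise UnknownResidueError(f"unknown N-terminus {self.n_term!r}")
        if self.c_term not in PEPTIDE_C_TERMINI:
            raise UnknownResidueError(f"unknown C-terminus {self.c_term!r}")
        seen: set[int] = set()
        for pos, mod_id in self.modifications:
            if not 1 <= pos <= len(self.residues):
                raise IncompatibleModificationError(
                    f"peptide {self.id!r}: position {pos} outside 1..{len(self.residues)}"
                )
            if pos in seen:
                raise IncompatibleModificationError(
                    f"peptide {self.id!r}: more than one modification at {pos}"
                )
            seen.add(pos)
            _resolve_mod(mod_id).check_applies(self.residues[pos - 1])

    def __len__(self) -> int:
        return len(self.residues)

    def composition(self) -> ElementalComposition:
        comp = WATER
        for code in self.residues:
            comp = comp + AA_RESIDUES[code]
        comp = comp + PEPTIDE_N_TERMINI[self.n_term]
        comp = comp + PEPTIDE_C_TERMINI[self.c_term]
        for _, mod_id in self.modifications:
            comp = comp + _resolve_mod(mod_id).delta
        return comp.assert_molecular(f"in peptide {self.id!r}")


@dataclass(frozen=True)
class ConjugateSpec:
    """A triazole-linked oligo-peptide conjugate.

    Copper-catalysed azide-alkyne cycloaddition is atom-conserving, so the
    conjugate composition is the exact sum of its components; the attachment
    position must carry the alkyne handle on the oligo.
    """

    oligo: ModifiedOligo | None
    peptide: ModifiedPeptide | None
    attachment_position: int | None = None

    def __post_init__(self):
        if self.oligo is None or self.peptide is None:
            raise MissingComponentError(
                "conjugate requires both an oligo and a peptide"
            )
        if self.attachment_position is not None:
            mods = {pos: mid for pos, mid in self.oligo.modifications}
            if mods.get(self.attachment_position) != "C8-alkyne-dC":
                raise IncompatibleModificationError(
                    f"attachment position {self.attachment_position} of oligo "
                    f"{self.oligo.id!r} does not carry the alkyne handle"
                )

    def composition(self) -> ElementalComposition:
        return self.oligo.composition() + self.peptide.composition()


def oligo_neutral_mass(oligo: ModifiedOligo, scale: Scale = "average") -> float:
    """Neutral mass (Da) of a modified oligonucleotide on the given scale."""
    return oligo.composition().mass(scale)


def peptide_neutral_mass(peptide: ModifiedPeptide, scale: Scale = "average") -> float:
    """Neutral mass (Da) of a modified peptide on the given scale."""
    return peptide.composition().mass(scale)


def conjugate_mass(spec: ConjugateSpec, scale: Scale = "average") -> float:
    """Neutral mass of the click conjugate: oligo + peptide, no loss term."""
    return spec.composition().mass(scale)


def duplex_mass(
    strand_a: ModifiedOligo, strand_b: ModifiedOligo, scale: Scale = "average"
) -> float:
    """Mass of a duplex: the plain sum of the strand masses (no correction)."""
    return oligo_neutral_mass(strand_a, scale) + oligo_neutral_mass(strand_b, scale)


def mz_for_charges(
    neutral_mass: float,
    charges: Iterable[int],
    mode: str = "negative",
    scale: Scale = "monoisotopic",
) -> list[tuple[int, float]]:
    """Deprotonated m/z values for a set of negative charge states.

    Returns ``(z, m/z)`` pairs sorted by descending m/z.  Only negative-mode
    deprotonation is supported; adducts are out of scope.
    """
    if mode != "negative":
        raise ChargeError(f"only negative ionization mode is supported, got {mode!r}")
    proton = PROTON_MASS[scale]
    out = []
    for z in charges:
        z = int(z)
        if z < 1:
            raise ChargeError(f"charge state must be >= 1, got {z}")
        if neutral_mass <= z * proton:
            raise ChargeError(
                f"neutral mass {neutral_mass} too small for charge {z}"
            )
        out.append((z, (neutral_mass - z * proton) / z))
    return sorted(out, key=lambda t: -t[1])


# ---------------------------------------------------------------------------
# Study constructs: the GCN4 basic-region peptide and its GCRE target strands.
# ---------------------------------------------------------------------------

GCRE_HALF_SITE = "GTCATC"  # positions 5-10 of ssDNA A (complement of TGACTC)

_PEP_RESIDUES = (
    "ASP PRO ALA ALA LEU LYS ARG ALA ARG ASN THR GLU "
    "ALA ALA ARG ARG SER ARG ALA ARG LYS GLY GLY LYS"
).split()


def ssdna_a() -> ModifiedOligo:
    """Unmodified target strand carrying the GCRE half-site at 5-10."""
    return ModifiedOligo("ssDNA A", "GCACGTCATCCGTATAG")


def ssdna_a_star() -> ModifiedOligo:
    """Target strand with the click alkyne handle on dC4."""
    return ModifiedOligo(
        "ssDNA A*", "GCACGTCATCCGTATAG", modifications=((4, "C8-alkyne-dC"),)
    )


def ssdna_a_double_star() -> ModifiedOligo:
    """Alkyne handle on dC4 plus the 8-bromo-dG photosensitizer label on G5."""
    return ModifiedOligo(
        "ssDNA A**",
        "GCACGTCATCCGTATAG",
        modifications=((4, "C8-alkyne-dC"), (5, "8-bromo-dG")),
    )


def ssdna_b() -> ModifiedOligo:
    """Complementary strand of the duplex."""
    return ModifiedOligo("ssDNA B", "CTATACGGATGACGTGC")


def gcn4_peptide() -> ModifiedPeptide:
    """GCN4 basic-region peptide, C-terminal amide, azide on the last Lys."""
    n = len(_PEP_RESIDUES)
    return ModifiedPeptide(
        "PEP",
        tuple(_PEP_RESIDUES),
        n_term="H",
        c_term="NH2",
        modifications=((n, "Lys-azide"),),
    )


def study_conjugate(labeled: bool = False) -> ConjugateSpec:
    """The ssDNA A*-PEP (or A**-PEP) triazole conjugate."""
    oligo = ssdna_a_double_star() if labeled else ssdna_a_star()
    return ConjugateSpec(oligo, gcn4_peptide(), attachment_position=4)
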