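"""Monoisotopic mass engine.

All m/z arithmetic in the package goes through this module: elemental
compositions with integer atom counts, residue masses for the monosaccharides
and amino acids that occur on N-glycopeptides, and charged-species m/z using
the proton-mass convention (1.007276 Da, H minus electron). Average masses and
isotope envelopes are deliberately out of scope — identification and EIC
quantification operate on monoisotopic species only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

__all__ = [
    "ElementalComposition",
    "IonSpec",
    "monoisotopic_mass",
    "ion_mz",
    "oxonium_mz",
    "peptide_mass",
    "RESIDUES",
    "AA_RESIDUES",
    "WATER",
    "PROTON_MASS",
    "WATER_MASS",
    "CARBAMIDOMETHYL",
    "CMP",
    "CMP_NEU5AC",
]

# IUPAC monoisotopic atomic masses (Da), most abundant isotope.
ATOMIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

#: Mass of a proton (H minus one electron), used for all charge arithmetic.
PROTON_MASS = 1.007276


@dataclass(frozen=True)
class ElementalComposition:
    """Integer atom counts over C, H, N, O, P, S.

    Compositions form a commutative monoid under ``+``; ``-`` is partial and
    raises if any count would go negative.
    """

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    P: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for el in ATOMIC_MASS:
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count in composition: {self}")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            **{el: getattr(self, el) + getattr(other, el) for el in ATOMIC_MASS}
        )

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = {el: getattr(self, el) - getattr(other, el) for el in ATOMIC_MASS}
        if any(v < 0 for v in counts.values()):
            raise ValueError(f"composition subtraction would be negative: {self} - {other}")
        return ElementalComposition(**counts)

    def __mul__(self, n: int) -> "ElementalComposition":
        if n < 0:
            raise ValueError("multiplier must be >= 0")
        return ElementalComposition(
            **{el: getattr(self, el) * n for el in ATOMIC_MASS}
        )

    __rmul__ = __mul__

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def monoisotopic_mass(composition: ElementalComposition) -> float:
    """Monoisotopic mass in Da (sum of atom count x atomic mass)."""
    return sum(getattr(composition, el) * m for el, m in ATOMIC_MASS.items())


WATER = ElementalComposition(H=2, O=1)
WATER_MASS = monoisotopic_mass(WATER)

# Glycosidically bound monosaccharide residues (free sugar minus water).
RESIDUES: dict[str, ElementalComposition] = {
    "Hex": ElementalComposition(C=6, H=10, O=5),
    "HexNAc": ElementalComposition(C=8, H=13, N=1, O=5),
    "Neu5Ac": ElementalComposition(C=11, H=17, N=1, O=8),
    "Pent": ElementalComposition(C=5, H=8, O=4),
    "Xyl": ElementalComposition(C=5, H=8, O=4),
    "dHex": ElementalComposition(C=6, H=10, O=4),
}

# Amino-acid residue compositions (peptide-bonded, i.e. minus water).
AA_RESIDUES: dict[str, ElementalComposition] = {
    "G": ElementalComposition(C=2, H=3, N=1, O=1),
    "A": ElementalComposition(C=3, H=5, N=1, O=1),
    "S": ElementalComposition(C=3, H=5, N=1, O=2),
    "P": ElementalComposition(C=5, H=7, N=1, O=1),
    "V": ElementalComposition(C=5, H=9, N=1, O=1),
    "T": ElementalComposition(C=4, H=7, N=1, O=2),
    "C": ElementalComposition(C=3, H=5, N=1, O=1, S=1),
    "L": ElementalComposition(C=6, H=11, N=1, O=1),
    "I": ElementalComposition(C=6, H=11, N=1, O=1),
    "N": ElementalComposition(C=4, H=6, N=2, O=2),
    "D": ElementalComposition(C=4, H=5, N=1, O=3),
    "Q": ElementalComposition(C=5, H=8, N=2, O=2),
    "K": ElementalComposition(C=6, H=12, N=2, O=1),
    "E": ElementalComposition(C=5, H=7, N=1, O=3),
    "M": ElementalComposition(C=5, H=9, N=1, O=1, S=1),
    "H": ElementalComposition(C=6, H=7, N=3, O=1),
    "F": ElementalComposition(C=9, H=9, N=1, O=1),
    "R": ElementalComposition(C=6, H=12, N=4, O=1),
    "Y": ElementalComposition(C=9, H=9, N=1, O=2),
    "W": ElementalComposition(C=11, H=10, N=2, O=1),
}

#: Fixed S-carbamidomethylation of cysteine (iodoacetamide alkylation), +57.02146 Da.
CARBAMIDOMETHYL = ElementalComposition(C=2, H=3, N=1, O=1)

#: Cytidine 5'-monophosphate, free acid.
CMP = ElementalComposition(C=9, H=14, N=3, O=8, P=1)

#: CMP-activated sialic acid: CMP + free Neu5Ac condensed with loss of water.
CMP_NEU5AC = CMP + (RESIDUES["Neu5Ac"] + WATER) - WATER


@dataclass(frozen=True)
class IonSpec:
    """A charged species: neutral mass (Da), charge >= 1, and polarity."""

    neutral_mass: float
    charge: int = 1
    polarity: Literal["positive", "negative"] = "positive"
    composition: ElementalComposition | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity: {self.polarity!r}")

    @classmethod
    def from_composition(
        cls,
        composition: ElementalComposition,
        charge: int = 1,
        polarity: Literal["positive", "negative"] = "positive",
    ) -> "IonSpec":
        return cls(monoisotopic_mass(composition), charge, polarity, composition)


def ion_mz(ion: IonSpec) -> float:
    """m/z of a protonated/deprotonated species.

    Positive mode: (M + z*m_p)/z; negative mode: (M - z*m_p)/z with
    m_p = 1.007276 Da.
    """
    if ion.neutral_mass <= 0:
        raise ValueError("neutral mass must be > 0")
    sign = 1.0 if ion.polarity == "positive" else -1.0
    return (ion.neutral_mass + sign * ion.charge * PROTON_MASS) / ion.charge


def oxonium_mz(
    fragment: Iterable[str],
    water_losses: int = 0,
    neutral_loss: ElementalComposition | None = None,
) -> float:
    """m/z of a singly protonated glycan oxonium fragment.

    ``fragment`` is a sequence of monosaccharide residue names; the ion mass is
    the sum of residue masses plus one proton, optionally minus ``water_losses``
    waters and/or an arbitrary ``neutral_loss`` composition (the cross-ring
    GlcNAc fragments are conventionally written as such losses).
    """
    names = list(fragment)
    if not names:
        raise ValueError("fragment must contain at least one residue")
    if water_losses < 0:
        raise ValueError("water_losses must be >= 0")
    total = ElementalComposition()
    for name in names:
        try:
            total = total + RESIDUES[name]
        except KeyError:
            raise ValueError(f"unknown monosaccharide residue: {name!r}") from None
    mass = monoisotopic_mass(total) - water_losses * WATER_MASS
    if neutral_loss is not None:
        mass -= monoisotopic_mass(neutral_loss)
    if mass <= 0:
        raise ValueError("neutral losses exceed fragment mass")
    return mass + PROTON_MASS


def peptide_mass(sequence: str, carbamidomethyl_cys: bool = True) -> float:
    """Neutral monoisotopic mass of a peptide (plus water, plus fixed Cys mods)."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    total = WATER
    for aa in sequence:
        try:
            total = total + AA_RESIDUES[aa]
        except KeyError:
            raise ValueError(f"unknown amino acid: {aa!r}") from None
        if aa == "C" and carbamidomethyl_cys:
            total = total + CARBAMIDOMETHYL
    return monoisotopic_mass(total)


def round_half_away(value: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (display convention)."""
    import math

    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)
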