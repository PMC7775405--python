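"""Glycoform catalog, tryptic digestion and glycopeptide candidate tables.

Glycoforms are identified at composition level, not linkage level: AM, MA or a
mixture of both are a single entry "AM". A short code names the two antennae on
the invariant HexNAc2Hex3 core (M mannose-terminated, Gn terminal GlcNAc,
A galactosylated, Na sialylated), optionally suffixed "+P"/"+2P" for one or two
pentoses on galactosylated, non-sialylated structures. Codes are canonicalized
with the heavier antenna first (Na > A > Gn > M).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .chem import (
    ElementalComposition,
    RESIDUES,
    PROTON_MASS,
    monoisotopic_mass,
    peptide_mass,
)

__all__ = [
    "Glycoform",
    "Peptide",
    "GlycopeptideCandidate",
    "glycoform_catalog",
    "parse_code",
    "tryptic_digest",
    "find_sequons",
    "build_candidate_table",
    "candidate_frame",
    "read_reporter_fasta",
    "reporter_protein",
    "write_candidate_table",
    "REPORTER_SEQUENCE",
    "REPORTER_NAME",
]

#: Invariant N-glycan core shared by every catalog entry.
CORE = {"HexNAc": 2, "Hex": 3}

#: Composition increments per antenna letter, on top of the core.
ANTENNA_INCREMENTS = {
    "M": (0, 0, 0),  # mannose-terminated (core mannose, nothing added)
    "Gn": (1, 0, 0),  # terminal GlcNAc
    "A": (1, 1, 0),  # GlcNAc + beta1,4-galactose
    "Na": (1, 1, 1),  # GlcNAc + galactose + Neu5Ac
}

# Heavier antenna first in canonical codes.
_ANTENNA_ORDER = {"Na": 0, "A": 1, "Gn": 2, "M": 3}


@dataclass(frozen=True)
class Glycoform:
    """A composition-level N-glycan: short code plus monosaccharide counts."""

    code: str
    hexnac: int
    hex: int
    neu5ac: int = 0
    pent: int = 0
    xyl: int = 0
    dhex: int = 0

    def __post_init__(self) -> None:
        if self.hexnac < CORE["HexNAc"] or self.hex < CORE["Hex"]:
            raise ValueError(f"{self.code}: composition lacks the HexNAc2Hex3 core")
        if self.pent not in (0, 1, 2):
            raise ValueError(f"{self.code}: Pent count must be 0, 1 or 2")
        if self.pent > 0 and self.galactoses == 0:
            raise ValueError(f"{self.code}: pentoses require at least one galactose")
        if self.neu5ac > self.galactoses:
            raise ValueError(f"{self.code}: Neu5Ac count exceeds galactose count")

    @property
    def galactoses(self) -> int:
        """Hexoses beyond the trimannosyl core (the beta1,4-galactoses)."""
        return self.hex - CORE["Hex"]

    @property
    def is_sialylated(self) -> bool:
        return self.neu5ac > 0

    @property
    def composition(self) -> ElementalComposition:
        total = (
            self.hexnac * RESIDUES["HexNAc"]
            + self.hex * RESIDUES["Hex"]
            + self.neu5ac * RESIDUES["Neu5Ac"]
            + self.pent * RESIDUES["Pent"]
            + self.xyl * RESIDUES["Xyl"]
            + self.dhex * RESIDUES["dHex"]
        )
        return total

    @property
    def mass(self) -> float:
        """Summed residue mass added to a peptide upon glycosylation (Da)."""
        return monoisotopic_mass(self.composition)


def _make_glycoform(antennae: tuple[str, str], pent: int = 0,
                    xyl: int = 0, dhex: int = 0) -> Glycoform:
    a, b = sorted(antennae, key=_ANTENNA_ORDER.__getitem__)
    hexnac, hexose, neu = CORE["HexNAc"], CORE["Hex"], 0
    for ant in (a, b):
        dn, dh, ds = ANTENNA_INCREMENTS[ant]
        hexnac += dn
        hexose += dh
        neu += ds
    code = a + b
    if pent:
        code += "+P" if pent == 1 else f"+{pent}P"
    if xyl:
        code += "+X"
    if dhex:
        code += "+F"
    return Glycoform(code, hexnac, hexose, neu, pent, xyl, dhex)


def glycoform_catalog(
    include_sialylated: bool = True,
    include_pentose_variants: bool = True,
    include_plant_controls: bool = False,
) -> list[Glycoform]:
    """Composition-level glycoform catalog for complex-type N-glycans.

    Antenna pairs over {M, Gn, A, Na}; pentose-decorated variants ("+P"/"+2P")
    only for galactosylated, non-sialylated forms (pentoses were never
    observed together with sialylation). Plant-specific controls (+X xylose,
    +F core fucose) are optional negative controls, expected absent in
    glyco-engineered Deltaxt/ft lines.
    """
    letters = ["M", "Gn", "A"] + (["Na"] if include_sialylated else [])
    pairs = []
    for i, a in enumerate(letters):
        for b in letters[i:]:
            pairs.append((a, b))
    catalog: list[Glycoform] = []
    for pair in pairs:
        base = _make_glycoform(pair)
        catalog.append(base)
        if include_pentose_variants and base.galactoses > 0 and not base.is_sialylated:
            catalog.append(_make_glycoform(pair, pent=1))
            catalog.append(_make_glycoform(pair, pent=2))
    if include_plant_controls:
        for pair in [("M", "M"), ("Gn", "M"), ("Gn", "Gn")]:
            catalog.append(_make_glycoform(pair, xyl=1))
            catalog.append(_make_glycoform(pair, xyl=1, dhex=1))
            catalog.append(_make_glycoform(pair, dhex=1))
    return catalog


def parse_code(code: str) -> Glycoform:
    """Decode a catalog short code (e.g. "AM+P") into its Glycoform.

    Inverse of ``Glycoform.code`` for every catalog entry (bijective within
    the catalog).
    """
    for gf in glycoform_catalog(include_plant_controls=True):
        if gf.code == code:
            return gf
    # also accept non-canonical antenna order, e.g. "MA"
    base, _, suffix = code.partition("+")
    for gf in glycoform_catalog(include_plant_controls=True):
        gbase, _, gsuffix = gf.code.partition("+")
        if gsuffix == suffix and sorted(_split_antennae(base)) == sorted(
            _split_antennae(gbase)
        ):
            return gf
    raise ValueError(f"unknown glycoform code: {code!r}")


def _split_antennae(base: str) -> list[str]:
    out, i = [], 0
    while i < len(base):
        if base[i : i + 2] in ("Gn", "Na"):
            out.append(base[i : i + 2])
            i += 2
        elif base[i] in ("M", "A"):
            out.append(base[i])
            i += 1
        else:
            raise ValueError(f"cannot parse antenna code: {base!r}")
    if len(out) != 2:
        raise ValueError(f"expected two antennae in code: {base!r}")
    return out


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with fixed carbamidomethyl-Cys.

    ``start``/``end`` are 0-based half-open positions in the parent protein.
    """

    sequence: str
    start: int = 0
    end: int = 0
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        bad = set(self.sequence) - set("ACDEFGHIKLMNPQRSTVWY")
        if bad:
            raise ValueError(f"non-standard residues in peptide: {sorted(bad)}")
        if self.missed_cleavages < 0:
            raise ValueError("missed cleavages must be >= 0")

    @property
    def mass(self) -> float:
        return peptide_mass(self.sequence)

    @property
    def sequons(self) -> list[int]:
        return find_sequons(self.sequence)


def tryptic_digest(protein_sequence: str, max_missed_cleavages: int = 0) -> list[Peptide]:
    """Tryptic peptides: cleave C-terminal to K/R except before P.

    Returns peptides with 0..max missed cleavages, ordered by start position
    then length; positions are 0-based half-open in the input sequence.
    """
    seq = protein_sequence.strip().upper()
    if not seq:
        raise ValueError("empty protein sequence")
    # cut points after K/R not followed by P
    cuts = [0]
    for i, aa in enumerate(seq[:-1]):
        if aa in "KR" and seq[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(seq))
    peptides = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + max_missed_cleavages, len(cuts))):
            peptides.append(
                Peptide(seq[cuts[i] : cuts[j]], cuts[i], cuts[j], missed_cleavages=j - i - 1)
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def find_sequons(sequence: str) -> list[int]:
    """Positions i of N-glycosylation sequons N-X-S/T with X != P."""
    seq = sequence.upper()
    return [
        i
        for i in range(len(seq) - 2)
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST"
    ]


@dataclass(frozen=True)
class GlycopeptideCandidate:
    """A (peptide, glycosite, glycoform) with neutral mass and per-charge m/z."""

    peptide: Peptide
    glycosite: int
    glycoform: Glycoform
    neutral_mass: float = field(init=False)

    def __post_init__(self) -> None:
        if self.glycosite not in self.peptide.sequons:
            raise ValueError(
                f"position {self.glycosite} is not a sequon of {self.peptide.sequence}"
            )
        object.__setattr__(
            self, "neutral_mass", self.peptide.mass + self.glycoform.mass
        )

    def mz(self, charge: int) -> float:
        if charge < 1:
            raise ValueError("charge must be >= 1")
        return (self.neutral_mass + charge * PROTON_MASS) / charge


def build_candidate_table(
    peptides: list[Peptide],
    catalog: list[Glycoform],
    charges: tuple[int, ...] = (2, 3, 4),
) -> list[GlycopeptideCandidate]:
    """Cartesian product of sequon-bearing peptides x glycoforms.

    Peptides without sequons are excluded; peptides with several sequons yield
    one candidate per sequon (composition-level identity cannot distinguish
    them by precursor mass, but the site is carried for bookkeeping).
    """
    if not catalog:
        raise ValueError("empty glycoform catalog")
    if not charges or any(z < 1 for z in charges):
        raise ValueError("charges must be positive integers")
    candidates = [
        GlycopeptideCandidate(pep, site, gf)
        for pep in peptides
        for site in pep.sequons
        for gf in catalog
    ]
    candidates.sort(key=lambda c: c.neutral_mass)
    return candidates


def candidate_frame(
    candidates: list[GlycopeptideCandidate], charges: tuple[int, ...] = (2, 3, 4)
) -> pd.DataFrame:
    """Flat (candidate, charge) table sorted by theoretical m/z."""
    rows = [
        {
            "peptide": c.peptide.sequence,
            "glycosite": c.glycosite,
            "glycoform": c.glycoform.code,
            "neutral_mass": c.neutral_mass,
            "charge": z,
            "mz": c.mz(z),
            "candidate_index": i,
        }
        for i, c in enumerate(candidates)
        for z in charges
    ]
    return pd.DataFrame(rows).sort_values("mz", ignore_index=True)


def write_candidate_table(
    candidates: list[GlycopeptideCandidate],
    path: str | Path,
    charges: tuple[int, ...] = (2, 3, 4),
) -> None:
    """TSV export: peptide, glycosite, code, composition, neutral mass, m/z per charge."""
    frame = candidate_frame(candidates, charges)
    comp = {
        c.glycoform.code: f"HexNAc{c.glycoform.hexnac}Hex{c.glycoform.hex}"
        + (f"Neu5Ac{c.glycoform.neu5ac}" if c.glycoform.neu5ac else "")
        + (f"Pent{c.glycoform.pent}" if c.glycoform.pent else "")
        for c in candidates
    }
    frame.insert(3, "composition", frame["glycoform"].map(comp))
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


# --- packaged synthetic reporter -------------------------------------------

#: Synthetic reporter glycoprotein (not a natural sequence): its tryptic digest
#: yields exactly three sequon-bearing peptides, matching the three analyzed
#: glycopeptides of the study design this package emulates.
REPORTER_SEQUENCE = "MAKLNDTFSAKVVNHTEFLKGYNCSSLVRAGLEQK"
REPORTER_NAME = "synthetic_reporter"


def reporter_protein() -> str:
    """Sequence of the packaged synthetic reporter glycoprotein."""
    return REPORTER_SEQUENCE


def read_reporter_fasta(path: str | Path) -> str:
    """First record of a FASTA file, as the reporter protein sequence."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return str(records[0].seq).upper()
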