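"""Domain types shared by every stage of the pipeline.

The pipeline works on intronless coding sequences of a four-member
desaturase gene family cloned from allotetraploid rapeseed, so the
fundamental objects are small: named nucleotide sequences, restriction
enzymes with IUPAC-degenerate recognition sites, per-line fatty-acid
profiles, and population lines carrying a two-locus genotype.

Coordinates: every externally visible CDS position is 1-based counting
from the A of the ATG start codon; residue numbers are 1-based from the
initiator Met.  Internally, 0-based half-open indexing is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

__all__ = [
    "IUPAC_CODES",
    "SequenceRecord",
    "RestrictionEnzyme",
    "FattyAcidProfile",
    "PopulationLine",
    "GENOTYPES_LOCUS1",
    "GENOTYPES_LOCUS2",
    "POPULATIONS",
    "translate_cds",
    "reverse_complement",
]

#: IUPAC degenerate nucleotide codes -> set of concrete bases matched.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SEQ_ALPHABET = frozenset("ACGTN")

GENOTYPES_LOCUS1 = ("AA", "Aa", "aa", "unknown")
GENOTYPES_LOCUS2 = ("BB", "Bb", "bb", "unknown")
POPULATIONS = ("P1", "P2", "F1", "F2", "BC1")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (clone, reference or amplicon).

    ``seq`` is restricted to the alphabet {A, C, G, T, N}; readers
    upper-case input and map U to T before construction.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record needs a non-empty id")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - _SEQ_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r} "
                "(expected A/C/G/T/N)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type-II restriction enzyme.

    ``recognition`` may contain IUPAC degeneracy codes (e.g. GANTC).
    ``cut_offset`` is the 0-based offset of the top-strand cut relative
    to the first base of the recognition site: an enzyme cutting G^ANTC
    has ``cut_offset=1``.  Offsets beyond the site length describe
    outside cutters and are permitted.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValueError(
                f"enzyme {self.name}: recognition site shorter than 4 bp"
            )
        bad = set(self.recognition) - set(IUPAC_CODES)
        if bad:
            raise ValueError(
                f"enzyme {self.name}: invalid IUPAC code(s) {sorted(bad)!r}"
            )
        if self.cut_offset < 0:
            raise ValueError(f"enzyme {self.name}: negative cut offset")


@dataclass(frozen=True)
class FattyAcidProfile:
    """Major seed fatty acids as percent of total fatty acids, plus oil
    content as percent of seed mass (``None`` when not measured).

    The five listed species need not sum to 100 because minor acids are
    unlisted, but the sum may not exceed 100.
    """

    c16_0: float
    c18_0: float
    c18_1: float
    c18_2: float
    c18_3: float
    oil: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("c16_0", "c18_0", "c18_1", "c18_2", "c18_3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        total = self.c16_0 + self.c18_0 + self.c18_1 + self.c18_2 + self.c18_3
        if total > 100.0 + 1e-9:
            raise ValueError(f"fatty-acid components sum to {total:.2f} > 100")
        if self.oil is not None and not 0.0 <= self.oil <= 100.0:
            raise ValueError(f"oil={self.oil} outside [0, 100]")


@dataclass(frozen=True)
class PopulationLine:
    """One plant: two-locus genotype plus its seed fatty-acid profile.

    Locus 1 is the constitutively expressed desaturase on chromosome A5
    (genotypes AA/Aa/aa, lowercase = mutant allele); locus 2 the copy on
    C5 (BB/Bb/bb).  Parental lines are fixed: P1 (the high-oleic mutant)
    is aabb, P2 (normal oleic) is AABB.
    """

    line_id: str
    population: str
    location: str
    genotype_locus1: str
    genotype_locus2: str
    profile: FattyAcidProfile

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(
                f"line {self.line_id}: population {self.population!r} not in "
                f"{POPULATIONS}"
            )
        if self.genotype_locus1 not in GENOTYPES_LOCUS1:
            raise ValueError(
                f"line {self.line_id}: locus-1 genotype "
                f"{self.genotype_locus1!r} not in {GENOTYPES_LOCUS1}"
            )
        if self.genotype_locus2 not in GENOTYPES_LOCUS2:
            raise ValueError(
                f"line {self.line_id}: locus-2 genotype "
                f"{self.genotype_locus2!r} not in {GENOTYPES_LOCUS2}"
            )
        if self.population == "P1" and (
            self.genotype_locus1 != "aa" or self.genotype_locus2 != "bb"
        ):
            raise ValueError(f"line {self.line_id}: P1 must be aabb")
        if self.population == "P2" and (
            self.genotype_locus1 != "AA" or self.genotype_locus2 != "BB"
        ):
            raise ValueError(f"line {self.line_id}: P2 must be AABB")

    @property
    def genotype(self) -> str:
        """Combined two-locus genotype string, e.g. ``AaBb``."""
        return self.genotype_locus1 + self.genotype_locus2


def translate_cds(seq: str) -> str:
    """Translate a CDS codon-by-codon under the standard genetic code.

    Translation starts at position 1 and continues through internal stop
    codons, rendering them as ``*`` — required to represent the family's
    pseudogene member, whose reading frame is disrupted early.  Trailing
    1-2 bases that do not fill a codon are ignored.
    """
    if len(seq) < 3:
        raise ValueError(f"CDS of length {len(seq)} < 3 cannot be translated")
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate(to_stop=False))


def reverse_complement(seq: str) -> str:
    """Reverse complement; IUPAC degeneracy codes are complemented too."""
    return str(Seq(seq).reverse_complement())
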