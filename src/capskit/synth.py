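"""Synthetic study inputs: reference panels, clone libraries, amplicon
fixtures and segregating populations.

The generators emulate the dry-lab inputs of a two-locus high-oleic
rapeseed study: a four-member desaturase gene family cloned as a mixed
amplicon library from a mutant and a wild-type line, CAPS amplicons
whose digest patterns distinguish the alleles, and F2/BC1 populations
segregating for the two loss-of-function loci.  Defaults mirror the
study conditions: clone-group sizes 48/45/40/73 (mutant line, 206
clones) and 55/50/44/62 (wild type, 211), a per-base substitution error
of 0.3%, the two causal substitutions G316A (E106K) and G908A (G303E),
an F2 of 232 lines, and a phenotype model anchored at 63.1% oleic acid
for the double wild-type homozygote.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .core import FattyAcidProfile, PopulationLine, SequenceRecord
from .caps import BandObservation, CapsAssay, digest, render_gel
from .io import default_enzyme_table

__all__ = [
    "GROUP_NAMES",
    "MUTANT_CLONE_COUNTS",
    "WT_CLONE_COUNTS",
    "DEFAULT_PLANTED_SNPS",
    "CloneLibraryConfig",
    "PopulationConfig",
    "AmpliconFixtures",
    "make_reference_panel",
    "simulate_clone_library",
    "mutant_library_config",
    "wildtype_library_config",
    "make_amplicon_fixtures",
    "simulate_population",
    "simulate_band_observations",
]

GROUP_NAMES = ("FAD2-1", "FAD2-2", "FAD2-3", "FAD2-4")

#: clone-group sizes per line (sum 206 for the mutant, 211 for wild type)
MUTANT_CLONE_COUNTS = (48, 45, 40, 73)
WT_CLONE_COUNTS = (55, 50, 44, 62)

#: the two causal loss-of-function substitutions, (group, position, ref, alt)
DEFAULT_PLANTED_SNPS = (
    ("FAD2-1", 316, "G", "A"),
    ("FAD2-2", 908, "G", "A"),
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}

#: group-diagnostic 6-mers written at CDS positions 41-46 (all four
#: differ at every one of the six positions)
_ZONE_6MERS = {
    "FAD2-1": "CTCCTC",
    "FAD2-2": "AGAAGA",
    "FAD2-3": "GACGAC",
    "FAD2-4": "TCATCA",
}

_CDS_LENGTH = 1155  # 385 codons including the stop


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    """Random stop-free codons under the given generator."""
    codons = []
    while len(codons) < n_codons:
        c = "".join(chr(b) for b in rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    return codons


def make_reference_panel(seed: int = 0) -> list[SequenceRecord]:
    """Four ~1.2-kb CDS-like homolog references sharing >99% identity.

    All start with ATG and end with TGA.  Group identity is encoded in a
    distinct 6-mer at positions 41-46; the second group additionally
    carries C/C markers at 732/735.  The third member is a pseudogene:
    it has a 15-bp deletion and an in-frame premature stop near position
    164.  Conserved across the family, positions 313-318 spell CACGAG
    (His105-Glu106, a BssSI site) and 907-912 spell GGATTC (Gly303 plus
    a HinfI site at 908-912), so the default planted substitutions
    G316A and G908A reproduce E106K and G303E and each abolishes its
    enzyme's recognition site.
    """
    rng = np.random.default_rng(seed)
    codons = ["ATG"] + _random_cds(rng, 383) + ["TGA"]
    base = list("".join(codons))
    assert len(base) == _CDS_LENGTH

    # guard bases so the per-group edits below can never create a stop
    base[39] = "C"  # codon 14 starts C
    base[729] = "G"  # codon 244 starts G
    base[732] = "G"  # codon 245 starts G
    base[312:318] = "CACGAG"  # His105-Glu106; BssSI site
    base[906:912] = "GGATTC"  # Gly303-Phe304; HinfI site at 908-912
    base[731] = "A"  # position 732 (group marker default)
    base[734] = "G"  # position 735

    panel = []
    for name in GROUP_NAMES:
        seq = base.copy()
        seq[40:46] = _ZONE_6MERS[name]
        if name == "FAD2-2":
            seq[731] = "C"
            seq[734] = "C"
        if name == "FAD2-3":
            seq[165:168] = "TGA"  # premature stop at codon 56 (pos 166-168)
            del seq[600:615]  # the 15-bp deletion
        record = SequenceRecord(id=name, seq="".join(seq))
        panel.append(record)

    from .core import translate_cds  # local import avoids cycle at module load

    for rec in panel:
        aa = translate_cds(rec.seq)
        internal_stops = aa[:-1].count("*")
        if rec.id == "FAD2-3":
            assert internal_stops >= 1, "pseudogene must carry an early stop"
        else:
            assert internal_stops == 0, f"{rec.id}: unexpected internal stop"
    return panel


@dataclass(frozen=True)
class CloneLibraryConfig:
    """Configuration of one line's plasmid clone library."""

    line: str
    n_clones_per_group: tuple[int, int, int, int]
    per_base_error: float = 0.003
    planted_snps: tuple[tuple[str, int, str, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_base_error <= 0.05:
            raise ValueError("per_base_error must lie in [0, 0.05]")
        if any(n < 0 for n in self.n_clones_per_group):
            raise ValueError("clone counts must be non-negative")


def mutant_library_config(seed: int = 0) -> CloneLibraryConfig:
    """Default mutant-line library: 206 clones carrying both causal SNPs."""
    return CloneLibraryConfig(
        line="mutant",
        n_clones_per_group=MUTANT_CLONE_COUNTS,
        planted_snps=DEFAULT_PLANTED_SNPS,
        seed=seed,
    )


def wildtype_library_config(seed: int = 0) -> CloneLibraryConfig:
    """Default wild-type library: 211 clones, no planted SNPs."""
    return CloneLibraryConfig(
        line="wildtype",
        n_clones_per_group=WT_CLONE_COUNTS,
        seed=seed,
    )


def simulate_clone_library(
    config: CloneLibraryConfig, panel: Sequence[SequenceRecord]
) -> list[SequenceRecord]:
    """Draw clones per homolog group with planted SNPs and i.i.d.
    per-base substitution error.

    Each clone of group g is the group reference, with any planted SNP
    for g applied, then corrupted by substitutions at rate
    ``per_base_error`` (errors pick one of the three other bases
    uniformly).  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    clones: list[SequenceRecord] = []
    for ref, n in zip(panel, config.n_clones_per_group):
        template = np.frombuffer(ref.seq.encode(), dtype=np.uint8).copy()
        for group, pos, ref_base, alt_base in config.planted_snps:
            if group != ref.id:
                continue
            if chr(template[pos - 1]) != ref_base:
                raise ValueError(
                    f"planted SNP {group}:{pos}{ref_base}>{alt_base}: "
                    f"reference has {chr(template[pos - 1])}"
                )
            template[pos - 1] = ord(alt_base)
        if n == 0:
            continue
        mat = np.tile(template, (n, 1))
        if config.per_base_error > 0:
            mask = rng.random(mat.shape) < config.per_base_error
            if mask.any():
                # shift to one of the other three bases, uniformly
                idx = np.searchsorted(_BASES, mat[mask])
                shift = rng.integers(1, 4, size=mask.sum())
                mat[mask] = _BASES[(idx + shift) % 4]
        for k in range(n):
            clones.append(
                SequenceRecord(
                    id=f"{config.line}_{ref.id}_c{k:03d}",
                    seq=mat[k].tobytes().decode(),
                )
            )
    return clones


class AmpliconFixtures(NamedTuple):
    """Two WT/mutant CAPS amplicon pairs plus the enzymes that cut them."""

    locus1_wt: SequenceRecord
    locus1_mut: SequenceRecord
    locus2_wt: SequenceRecord
    locus2_mut: SequenceRecord
    enzymes: list  # RestrictionEnzyme entries (BssSI, HinfI)


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(_BASES, size=n)


def make_amplicon_fixtures(seed: int = 0) -> AmpliconFixtures:
    """Construct amplicon pairs reproducing the diagnostic band patterns.

    Locus 1: a 731-bp pair with a single BssSI site placed so the WT
    digest gives [295, 436]; the mutant substitution inside the site
    (mirroring G316A) leaves the 731-bp amplicon uncut.  Locus 2: a
    405-bp pair with three HinfI sites giving WT [61, 80, 58, 206]; the
    mutant substitution (mirroring G908A) abolishes the third site,
    fusing the last two fragments into 264 bp.  Background sequence is
    rejection-sampled until neither enzyme has any unintended site in
    either allele.
    """
    enzymes = default_enzyme_table()
    by_name = {e.name: e for e in enzymes}
    bsss, hinf = by_name["BssSI"], by_name["HinfI"]
    rng = np.random.default_rng(seed)

    def build_pair(length, placements, mut_edit, target_wt, target_mut, enzyme):
        while True:
            seq = _random_seq(rng, length)
            for start, motif in placements:
                seq[start : start + len(motif)] = np.frombuffer(
                    motif.encode(), dtype=np.uint8
                )
            wt = seq.tobytes().decode()
            pos, alt = mut_edit
            mut = wt[:pos] + alt + wt[pos + 1 :]
            ok = (
                digest(wt, enzyme).fragments == target_wt
                and digest(mut, enzyme).fragments == target_mut
            )
            other = hinf if enzyme is bsss else bsss
            ok = ok and not digest(wt, other).cut_positions
            ok = ok and not digest(mut, other).cut_positions
            if ok:
                return wt, mut

    wt1, mut1 = build_pair(
        731,
        [(294, "CACGAG")],
        (297, "A"),  # CACGAG -> CACAAG, the site's G like G316A
        (295, 436),
        (731,),
        bsss,
    )
    wt2, mut2 = build_pair(
        405,
        [(60, "GATTC"), (140, "GATTC"), (198, "GATTC")],
        (198, "A"),  # third site's leading G like G908A
        (61, 80, 58, 206),
        (61, 80, 264),
        hinf,
    )
    return AmpliconFixtures(
        locus1_wt=SequenceRecord("FAD2-1_amplicon_wt", wt1),
        locus1_mut=SequenceRecord("FAD2-1_amplicon_mut", mut1),
        locus2_wt=SequenceRecord("FAD2-2_amplicon_wt", wt2),
        locus2_mut=SequenceRecord("FAD2-2_amplicon_mut", mut2),
        enzymes=enzymes,
    )


@dataclass(frozen=True)
class PopulationConfig:
    """Two-locus segregating population and phenotype model.

    Genotype contributions to oleic acid are 0, ``a+d`` and ``2a`` for
    the wild-type homozygote, heterozygote and mutant homozygote (so the
    class-mean estimators recover ``a`` and ``d`` exactly in
    expectation), plus an epistasis term reaching ``i`` in the double
    mutant homozygote.  The oleic gain is drained from linoleic and
    linolenic acid in the proportions ``frac_c18_2``/``frac_c18_3``.
    """

    population: str = "F2"  # "F2" or "BC1"
    n_lines: int = 232
    mu0: float = 63.1  # AABB oleic baseline, %
    a1: float = 5.38
    d1: float = 0.95
    a2: float = 5.55
    d2: float = 0.65
    i: float = 0.0
    sigma: float = 2.0  # residual SD of oleic %, per line
    frac_c18_2: float = 0.72
    frac_c18_3: float = 0.28
    base_c18_2: float = 21.0  # AABB linoleic %, mean
    base_c18_3: float = 7.8  # AABB linolenic %
    sd_c18_2: float = 1.2
    sd_c18_3: float = 0.8
    recombination_fraction: float = 0.5  # loci on different chromosomes
    location: str = "Nanjing"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population not in ("F2", "BC1"):
            raise ValueError("population must be F2 or BC1")
        if self.population == "F2" and self.n_lines < 9:
            raise ValueError("an F2 needs at least 9 lines")
        if self.n_lines < 1:
            raise ValueError("n_lines must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if abs(self.frac_c18_2 + self.frac_c18_3 - 1.0) > 1e-9:
            raise ValueError("allocation fractions must sum to 1")
        if not 0.0 <= self.recombination_fraction <= 0.5:
            raise ValueError("recombination fraction must lie in [0, 0.5]")


_CONTRIB_GENO = {0: ("AA", "BB"), 1: ("Aa", "Bb"), 2: ("aa", "bb")}


def _gametes(rng: np.random.Generator, n: int, r: float) -> np.ndarray:
    """n F1 gametes as mutant-allele indicators, shape (n, 2 loci).

    The F1 is in coupling phase (one parent contributed both mutant
    alleles), so parental gametes have probability (1-r)/2 each and
    recombinants r/2.
    """
    types = np.array([[0, 0], [1, 1], [0, 1], [1, 0]])
    p = np.array([(1 - r) / 2, (1 - r) / 2, r / 2, r / 2])
    return types[rng.choice(4, size=n, p=p)]


def simulate_population(config: PopulationConfig) -> list[PopulationLine]:
    """Simulate an F2 (selfed F1) or BC1 (F1 x wild-type parent).

    Per-locus segregation is 1:2:1 in the F2 and 1:1 het:wild-type
    homozygote in the BC1 (so a BC1 contains only the AABB/AABb/AaBB/
    AaBb classes).  Fatty-acid rows are kept internally consistent: the
    oleic gain of mutant genotypes is removed from linoleic/linolenic
    (floored at 0.5%), and the five-component sum is confined to
    [90, 100] by adjusting the polyunsaturated pool.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_lines
    r = config.recombination_fraction
    maternal = _gametes(rng, n, r)
    if config.population == "F2":
        paternal = _gametes(rng, n, r)
    else:  # backcross to the wild-type (AABB) parent
        paternal = np.zeros((n, 2), dtype=int)
    counts = maternal + paternal  # mutant-allele count per locus

    contrib1 = np.choose(counts[:, 0], [0.0, config.a1 + config.d1, 2 * config.a1])
    contrib2 = np.choose(counts[:, 1], [0.0, config.a2 + config.d2, 2 * config.a2])
    epi = config.i * (counts[:, 0] / 2.0) * (counts[:, 1] / 2.0)
    delta_g = contrib1 + contrib2 + epi

    c18_1 = config.mu0 + delta_g + rng.normal(0, config.sigma, n)
    c18_2 = (
        config.base_c18_2
        - config.frac_c18_2 * delta_g
        + rng.normal(0, config.sd_c18_2, n)
    )
    c18_3 = (
        config.base_c18_3
        - config.frac_c18_3 * delta_g
        + rng.normal(0, config.sd_c18_3, n)
    )
    c18_2 = np.maximum(c18_2, 0.5)
    c18_3 = np.maximum(c18_3, 0.5)
    c16_0 = np.clip(rng.normal(3.6, 0.4, n), 0.1, None)
    c18_0 = np.clip(rng.normal(1.8, 0.3, n), 0.1, None)
    oil = np.clip(rng.normal(40.3, 1.2, n), 0.0, 100.0)
    c18_1 = np.clip(c18_1, 0.0, 100.0)

    # round to the 0.01% reported by GC, then confine the 5-component
    # sum to [90, 100] via the C18:2/C18:3 pool
    c16_0, c18_0, c18_1, c18_2, c18_3, oil = (
        np.round(a, 2) for a in (c16_0, c18_0, c18_1, c18_2, c18_3, oil)
    )
    total = c16_0 + c18_0 + c18_1 + c18_2 + c18_3
    excess = np.round(np.maximum(total - 100.0, 0.0), 2)
    give = np.minimum(excess, c18_2 - 0.5)
    c18_2 = np.round(c18_2 - give, 2)
    excess = np.round(excess - give, 2)
    give3 = np.minimum(excess, c18_3 - 0.5)
    c18_3 = np.round(c18_3 - give3, 2)
    # if both polyunsaturated floors bind, trim the oleic tail itself
    c18_1 = np.round(c18_1 - np.round(excess - give3, 2), 2)
    deficit = np.maximum(
        90.0 - (c16_0 + c18_0 + c18_1 + c18_2 + c18_3), 0.0
    )
    c18_2 = np.round(c18_2 + deficit, 2)

    lines = []
    for k in range(n):
        g1 = _CONTRIB_GENO[counts[k, 0]][0]
        g2 = _CONTRIB_GENO[counts[k, 1]][1]
        lines.append(
            PopulationLine(
                line_id=f"{config.population}_{config.location}_{k:04d}",
                population=config.population,
                location=config.location,
                genotype_locus1=g1,
                genotype_locus2=g2,
                profile=FattyAcidProfile(
                    c16_0=float(c16_0[k]),
                    c18_0=float(c18_0[k]),
                    c18_1=float(c18_1[k]),
                    c18_2=float(c18_2[k]),
                    c18_3=float(c18_3[k]),
                    oil=float(oil[k]),
                ),
            )
        )
    return lines


_CLASS_OF_LETTER = {
    "AA": "homWT", "Aa": "het", "aa": "homMUT",
    "BB": "homWT", "Bb": "het", "bb": "homMUT",
}


def simulate_band_observations(
    pop: Sequence[PopulationLine],
    assays: dict[int, CapsAssay],
    miscall_rate: float = 0.0,
    seed: int = 0,
) -> list[BandObservation]:
    """Emit the gel band pattern of each line's true genotype.

    ``assays`` maps locus number (1 or 2) to its CAPS assay.  With
    probability ``miscall_rate`` one band is dropped from a lane,
    emulating a weak or run-off band.
    """
    rng = np.random.default_rng(seed)
    out: list[BandObservation] = []
    for ln in pop:
        for locus, assay in sorted(assays.items()):
            letter = ln.genotype_locus1 if locus == 1 else ln.genotype_locus2
            if letter == "unknown":
                continue
            cls = _CLASS_OF_LETTER[letter]
            bands = [
                b.length for b in render_gel(assay.fragments_for(cls))
            ]
            if bands and rng.random() < miscall_rate:
                bands.pop(rng.integers(0, len(bands)))
            out.append(
                BandObservation(
                    line_id=ln.line_id,
                    locus=f"locus{locus}",
                    visible_bands=tuple(bands),
                )
            )
    return out
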