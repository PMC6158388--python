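"""CAPS assay design, in-silico restriction digestion and genotyping.

A CAPS (cleaved amplified polymorphic sequence) marker exploits a SNP
that creates or destroys a restriction site inside a locus-specific
amplicon: after digestion, the two alleles give different band patterns
on an agarose gel, and a heterozygote shows the union of both.  This
module scans IUPAC-degenerate recognition sites on both strands,
simulates the digest of linear amplicons, designs assays for a single
SNP, renders fragment lists through a simple gel co-migration model and
calls genotypes from observed band patterns.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from .core import IUPAC_CODES, RestrictionEnzyme, SequenceRecord, reverse_complement

__all__ = [
    "DigestResult",
    "CapsAssay",
    "BandObservation",
    "GelBand",
    "GENOTYPE_CLASSES",
    "scan_sites",
    "digest",
    "design_caps",
    "render_gel",
    "check_allele_specific_primer",
    "call_genotype",
    "genotype_code",
    "write_assays",
    "read_assays",
]

#: genotype classes at a single CAPS locus
GENOTYPE_CLASSES = ("homWT", "het", "homMUT")


def _site_regex(recognition: str) -> re.Pattern:
    parts = []
    for code in recognition:
        bases = sorted(IUPAC_CODES[code])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    # lookahead so overlapping occurrences are all found
    return re.compile("(?=" + "".join(parts) + ")")


def _matching_windows(seq: str, recognition: str) -> set[int]:
    """0-based start positions where the degenerate site matches."""
    return {m.start() for m in _site_regex(recognition).finditer(seq)}


def scan_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Top-strand cut positions of ``enzyme`` in a linear sequence.

    The recognition sequence is matched degenerately on both strands.  A
    forward match starting at 0-based ``i`` cuts after base
    ``i + cut_offset`` (positions are reported 1-based, i.e. the number
    of bases left of the cut); a reverse-orientation match mirrors the
    offset to ``i + len(site) - cut_offset``.  Windows matched in both
    orientations (palindromic sites) count once, with the forward cut.
    Cuts falling on or outside the molecule ends are discarded;
    positions are deduplicated and sorted.
    """
    n = len(seq)
    length = len(enzyme.recognition)
    fwd = _matching_windows(seq, enzyme.recognition)
    rev_raw = _matching_windows(reverse_complement(seq), enzyme.recognition)
    rev = {n - length - j for j in rev_raw}
    cuts = {i + enzyme.cut_offset for i in fwd}
    cuts |= {i + length - enzyme.cut_offset for i in rev - fwd}
    return sorted(c for c in cuts if 0 < c < n)


@dataclass(frozen=True)
class DigestResult:
    """Fragments of one linear molecule after complete digestion."""

    enzyme: str
    cut_positions: tuple[int, ...]  # ascending, 1-based top-strand cuts
    fragments: tuple[int, ...]  # bp, in amplicon order

    def __post_init__(self) -> None:
        if len(self.fragments) != len(self.cut_positions) + 1:
            raise ValueError("linear digest must give cuts + 1 fragments")
        if any(f <= 0 for f in self.fragments):
            raise ValueError("fragments must have positive length")


def digest(seq: str, enzyme: RestrictionEnzyme) -> DigestResult:
    """Complete digest of a linear amplicon.

    Fragment lengths are consecutive differences of the cut positions
    bounded by the molecule ends; their sum always equals the amplicon
    length.
    """
    cuts = scan_sites(seq, enzyme)
    bounds = [0, *cuts, len(seq)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    assert sum(fragments) == len(seq)
    return DigestResult(enzyme.name, tuple(cuts), fragments)


class GelBand(NamedTuple):
    """One visible band: mean length of its co-migrating fragments."""

    length: float
    fragments: tuple[int, ...]
    may_run_off: bool  # any member shorter than the visibility floor


def render_gel(
    fragments: Sequence[int],
    min_separation_bp: int = 30,
    min_visible_bp: int = 40,
) -> list[GelBand]:
    """Collapse a fragment list into the bands visible on an agarose gel.

    Fragments are clustered greedily in ascending order: a fragment
    within ``min_separation_bp`` of the previous one co-migrates into
    the same band, reported at the cluster's mean length (so 58/61/80 bp
    merge into one ~66 bp band while 206 vs 264 bp stay distinct).
    Fragments below ``min_visible_bp`` are flagged as possibly running
    off the gel but are retained.  Bands are returned in gel order
    (largest first).
    """
    if any(f <= 0 for f in fragments):
        raise ValueError("fragment lengths must be positive")
    if not fragments:
        return []
    ordered = sorted(fragments)
    clusters: list[list[int]] = [[ordered[0]]]
    for f in ordered[1:]:
        if f - clusters[-1][-1] <= min_separation_bp:
            clusters[-1].append(f)
        else:
            clusters.append([f])
    bands = [
        GelBand(
            length=sum(c) / len(c),
            fragments=tuple(c),
            may_run_off=any(f < min_visible_bp for f in c),
        )
        for c in clusters
    ]
    return sorted(bands, key=lambda b: -b.length)


@dataclass(frozen=True)
class CapsAssay:
    """A designed CAPS assay for one SNP locus.

    The heterozygote pattern is exactly the multiset union of the two
    homozygote patterns (both alleles are present in the template).
    """

    locus: str
    amplicon_wt: SequenceRecord
    amplicon_mut: SequenceRecord
    enzyme: RestrictionEnzyme
    snp_offset: int  # 1-based SNP position within the amplicon
    fragments_wt: tuple[int, ...]
    fragments_mut: tuple[int, ...]
    fragments_het: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.amplicon_wt) != len(self.amplicon_mut):
            raise ValueError(f"assay {self.locus}: amplicon lengths differ")
        diffs = [
            i + 1
            for i, (a, b) in enumerate(
                zip(self.amplicon_wt.seq, self.amplicon_mut.seq)
            )
            if a != b
        ]
        if diffs != [self.snp_offset]:
            raise ValueError(
                f"assay {self.locus}: amplicons must differ exactly at "
                f"snp_offset {self.snp_offset}, found differences at {diffs}"
            )
        n = len(self.amplicon_wt)
        if sum(self.fragments_wt) != n or sum(self.fragments_mut) != n:
            raise ValueError(f"assay {self.locus}: fragments do not sum to length")
        union = tuple(sorted(self.fragments_wt + self.fragments_mut))
        if not self.fragments_het:
            object.__setattr__(self, "fragments_het", union)
        elif tuple(sorted(self.fragments_het)) != union:
            raise ValueError(
                f"assay {self.locus}: het pattern must be the multiset "
                "union of the homozygote patterns"
            )

    def fragments_for(self, genotype_class: str) -> tuple[int, ...]:
        try:
            return {
                "homWT": self.fragments_wt,
                "het": self.fragments_het,
                "homMUT": self.fragments_mut,
            }[genotype_class]
        except KeyError:
            raise ValueError(f"unknown genotype class {genotype_class!r}")


@dataclass(frozen=True)
class BandObservation:
    """Bands read off a gel lane for one line at one locus, largest first."""

    line_id: str
    locus: str
    visible_bands: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.visible_bands):
            raise ValueError("band lengths must be positive")
        if list(self.visible_bands) != sorted(self.visible_bands, reverse=True):
            raise ValueError("bands must be sorted descending (gel order)")


def _differential_site_overlaps_snp(
    assay_wt: str, assay_mut: str, enzyme: RestrictionEnzyme, snp_offset: int
) -> bool:
    """True iff a recognition-site occurrence present in exactly one
    allele (either strand) spans the SNP position."""
    length = len(enzyme.recognition)
    n = len(assay_wt)

    def windows(seq: str) -> set[int]:
        fwd = _matching_windows(seq, enzyme.recognition)
        rev = {
            n - length - j
            for j in _matching_windows(reverse_complement(seq), enzyme.recognition)
        }
        return fwd | rev

    for start in windows(assay_wt) ^ windows(assay_mut):
        if start < snp_offset <= start + length:
            return True
    return False


def _detectability(assay: CapsAssay, min_separation_bp: int) -> float:
    """Heuristic ranking score: how far apart the allele-specific bands
    sit on the gel (larger = easier to score by eye)."""
    wt = [b.length for b in render_gel(assay.fragments_wt, min_separation_bp)]
    mut = [b.length for b in render_gel(assay.fragments_mut, min_separation_bp)]
    uniq_wt = [b for b in wt if all(abs(b - m) > min_separation_bp for m in mut)]
    uniq_mut = [b for b in mut if all(abs(b - w) > min_separation_bp for w in wt)]
    if not uniq_wt or not uniq_mut:
        return 0.0
    return min(abs(w - m) for w in uniq_wt for m in uniq_mut)


def design_caps(
    amplicon_wt: SequenceRecord,
    amplicon_mut: SequenceRecord,
    enzymes: Iterable[RestrictionEnzyme],
    min_separation_bp: int = 30,
) -> list[CapsAssay]:
    """Design CAPS assays for a single-SNP amplicon pair.

    One assay is produced per enzyme whose digest patterns differ
    between the alleles *and* whose differential recognition-site
    occurrence overlaps the SNP itself (so the pattern difference is
    caused by the SNP, not background variation).  Assays are returned
    ranked by decreasing gel detectability of the allele-specific bands.
    """
    if len(amplicon_wt) != len(amplicon_mut):
        raise ValueError("amplicons must be the same length")
    diffs = [
        i + 1
        for i, (a, b) in enumerate(zip(amplicon_wt.seq, amplicon_mut.seq))
        if a != b
    ]
    if len(diffs) != 1:
        raise ValueError(
            f"single-SNP designer: amplicons differ at {len(diffs)} positions"
        )
    snp_offset = diffs[0]

    assays = []
    for enz in enzymes:
        dig_wt = digest(amplicon_wt.seq, enz)
        dig_mut = digest(amplicon_mut.seq, enz)
        if not dig_wt.cut_positions and not dig_mut.cut_positions:
            continue
        if dig_wt.fragments == dig_mut.fragments:
            continue
        if not _differential_site_overlaps_snp(
            amplicon_wt.seq, amplicon_mut.seq, enz, snp_offset
        ):
            continue
        assays.append(
            CapsAssay(
                locus=amplicon_wt.id,
                amplicon_wt=amplicon_wt,
                amplicon_mut=amplicon_mut,
                enzyme=enz,
                snp_offset=snp_offset,
                fragments_wt=dig_wt.fragments,
                fragments_mut=dig_mut.fragments,
            )
        )
    return sorted(
        assays, key=lambda a: -_detectability(a, min_separation_bp)
    )


def check_allele_specific_primer(
    primer: str, template: SequenceRecord, position: int
) -> bool:
    """Would an allele-specific (ARMS) primer amplify from this template?

    The primer is aligned with its 3'-terminal base on ``position``
    (1-based) of the template's top strand.  Amplification requires an
    exact 3'-terminal match — the discriminating base — and at most one
    internal mismatch over the rest of the primer.
    """
    if len(primer) < 15:
        raise ValueError("allele-specific primers must be >= 15 nt")
    primer = primer.upper()
    start = position - len(primer)
    if start < 0 or position > len(template):
        return False
    window = template.seq[start:position]
    if primer[-1] != window[-1]:
        return False
    internal_mismatches = sum(a != b for a, b in zip(primer[:-1], window[:-1]))
    return internal_mismatches <= 1


def _pattern_match_score(
    observed: Sequence[float], expected: Sequence[float], tolerance_bp: int
) -> float | None:
    """Total deviation if patterns match band-for-band, else None."""
    if len(observed) != len(expected):
        return None
    obs = sorted(observed)
    exp = sorted(expected)
    devs = [abs(o - e) for o, e in zip(obs, exp)]
    if any(d > tolerance_bp for d in devs):
        return None
    return sum(devs)


def call_genotype(
    observed: BandObservation,
    assay: CapsAssay,
    tolerance_bp: int = 30,
    min_separation_bp: int = 30,
) -> str:
    """Call a genotype from observed gel bands.

    Observed bands are compared against the gel-rendered expectation for
    each genotype class; the unique best match (smallest total length
    deviation within ``tolerance_bp`` per band) wins, anything else is
    ``"ambiguous"``.
    """
    scores: dict[str, float] = {}
    for cls in GENOTYPE_CLASSES:
        expected = [
            b.length
            for b in render_gel(assay.fragments_for(cls), min_separation_bp)
        ]
        s = _pattern_match_score(observed.visible_bands, expected, tolerance_bp)
        if s is not None:
            scores[cls] = s
    if not scores:
        return "ambiguous"
    best = min(scores.values())
    winners = [c for c, s in scores.items() if s == best]
    return winners[0] if len(winners) == 1 else "ambiguous"


#: per-locus genotype letters used in population tables
_GENOTYPE_LETTERS = {
    ("locus1", "homWT"): "AA",
    ("locus1", "het"): "Aa",
    ("locus1", "homMUT"): "aa",
    ("locus2", "homWT"): "BB",
    ("locus2", "het"): "Bb",
    ("locus2", "homMUT"): "bb",
}


def genotype_code(locus: str, genotype_class: str) -> str:
    """Map a genotype class to its letter code (AA/Aa/aa or BB/Bb/bb)."""
    if genotype_class == "ambiguous":
        return "unknown"
    try:
        return _GENOTYPE_LETTERS[(locus, genotype_class)]
    except KeyError:
        raise ValueError(f"unknown locus/class {locus!r}/{genotype_class!r}")


def write_assays(assays: Sequence[CapsAssay], path) -> None:
    payload = [
        {
            "locus": a.locus,
            "enzyme": {
                "name": a.enzyme.name,
                "recognition": a.enzyme.recognition,
                "cut_offset": a.enzyme.cut_offset,
            },
            "amplicon_wt": {"id": a.amplicon_wt.id, "seq": a.amplicon_wt.seq},
            "amplicon_mut": {"id": a.amplicon_mut.id, "seq": a.amplicon_mut.seq},
            "snp_offset": a.snp_offset,
            "fragments_wt": list(a.fragments_wt),
            "fragments_mut": list(a.fragments_mut),
            "fragments_het": list(a.fragments_het),
        }
        for a in assays
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_assays(path) -> list[CapsAssay]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        CapsAssay(
            locus=item["locus"],
            amplicon_wt=SequenceRecord(**item["amplicon_wt"]),
            amplicon_mut=SequenceRecord(**item["amplicon_mut"]),
            enzyme=RestrictionEnzyme(**item["enzyme"]),
            snp_offset=item["snp_offset"],
            fragments_wt=tuple(item["fragments_wt"]),
            fragments_mut=tuple(item["fragments_mut"]),
            fragments_het=tuple(item["fragments_het"]),
        )
        for item in payload
    ]
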