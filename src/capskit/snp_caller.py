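"""Homoeolog-aware SNP calling from cloned amplicon libraries.

In an allotetraploid, a single primer pair amplifies all near-identical
copies of a gene family at once.  Individual plasmid clones of the mixed
amplicon are therefore a random sample across homolog groups, and SNP
calling between two lines must first bin each clone into its group.
Groups are recognized by *diagnostic signatures*: minimal sets of CDS
positions whose bases jointly distinguish one group's reference from
every other group in the panel.

A substitution is only reported when the two lines' per-group consensus
bases differ and the variant base is carried by more than five clones
(``min_support`` >= 6 by default) in the line carrying it, which guards
against recurrent PCR/sequencing errors in deep clone libraries.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .core import SequenceRecord, translate_cds

__all__ = [
    "HomologGroup",
    "GroupAssignment",
    "SnpCall",
    "Annotation",
    "ConsensusResult",
    "build_diagnostic_signatures",
    "assign_clone",
    "consensus_with_counts",
    "call_snps",
    "annotate_snp",
    "PipelineResult",
    "run_snp_pipeline",
    "snp_calls_to_frame",
    "write_snp_tsv",
    "write_snp_vcf",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def _coordinate_map(query: str, target: str) -> list[Optional[int]]:
    """For each 0-based target position, the aligned 0-based query
    position, or None where the query has a gap (global alignment)."""
    res = edlib.align(query, target, task="path", mode="NW")
    qpos = 0
    out: list[Optional[int]] = []
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        if op in "=X":
            out.extend(range(qpos, qpos + n))
            qpos += n
        elif op == "D":  # target-only columns: gap in query
            out.extend([None] * n)
        else:  # 'I': query-only, no target column
            qpos += n
    return out


def edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW")["editDistance"]


@dataclass(frozen=True)
class HomologGroup:
    """A homolog group: its reference CDS and diagnostic signature.

    ``diagnostic_signature`` maps 1-based positions in the group's own
    reference coordinates to the base expected there.
    """

    name: str
    reference: SequenceRecord
    diagnostic_signature: dict[int, str]

    def __post_init__(self) -> None:
        for pos, base in self.diagnostic_signature.items():
            if not 1 <= pos <= len(self.reference):
                raise ValueError(
                    f"group {self.name}: signature position {pos} outside "
                    f"reference (length {len(self.reference)})"
                )
            if self.reference.seq[pos - 1] != base:
                raise ValueError(
                    f"group {self.name}: signature base {base} at {pos} "
                    f"disagrees with reference"
                )


@dataclass(frozen=True)
class GroupAssignment:
    clone_id: str
    group: str  # group name or "unassigned"
    mismatches_to_signature: int
    edit_distance_to_reference: int
    fallback: bool = False  # True when assigned by edit distance only


class Annotation(NamedTuple):
    codon_index: int
    ref_aa: str
    alt_aa: str
    label: str


@dataclass(frozen=True)
class SnpCall:
    """A per-group substitution call between two lines."""

    group: str
    position: int  # 1-based CDS coordinate
    ref_base: str
    alt_base: str
    support_line1: int  # clones carrying alt_base in line 1
    support_line2: int
    codon_index: int
    ref_aa: str
    alt_aa: str
    label: str

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError(f"{self.group}:{self.position}: ref == alt")
        if self.codon_index != math.ceil(self.position / 3):
            raise ValueError(
                f"{self.group}:{self.position}: codon index "
                f"{self.codon_index} != ceil(position/3)"
            )
        expected = f"{self.ref_aa}{self.codon_index}{self.alt_aa}"
        if self.label != expected:
            raise ValueError(f"label {self.label!r} != {expected!r}")

    @property
    def synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa

    @property
    def dna_label(self) -> str:
        """Nucleotide-level name, e.g. ``G316A``."""
        return f"{self.ref_base}{self.position}{self.alt_base}"


def build_diagnostic_signatures(
    references: Sequence[SequenceRecord],
) -> list[HomologGroup]:
    """Derive a minimal diagnostic signature for each reference.

    References are placed on the coordinate frame of the longest one by
    global alignment (the panel's members differ by a handful of bases
    and, for the pseudogene member, a short deletion).  For each group,
    positions are scanned in ascending order and greedily added until
    the accumulated set distinguishes the group from every other member
    (first-position tie-break).  Two identical references make the panel
    unresolvable and raise ``ValueError``.
    """
    if len(references) < 2:
        raise ValueError("need at least two references to build a panel")
    for i in range(len(references)):
        for j in range(i + 1, len(references)):
            if references[i].seq == references[j].seq:
                raise ValueError(
                    "indistinguishable groups: references "
                    f"{references[i].id!r} and {references[j].id!r} are "
                    "identical"
                )

    frame = max(references, key=len)
    n_cols = len(frame)
    # per reference: aligned base per frame column ('-' for gaps), plus
    # frame column -> own 0-based coordinate
    aligned: list[str] = []
    own_coord: list[list[Optional[int]]] = []
    for ref in references:
        cmap = _coordinate_map(ref.seq, frame.seq)
        aligned.append(
            "".join("-" if q is None else ref.seq[q] for q in cmap)
        )
        own_coord.append(cmap)

    groups: list[HomologGroup] = []
    for gi, ref in enumerate(references):
        remaining = {j for j in range(len(references)) if j != gi}
        signature: dict[int, str] = {}
        for col in range(n_cols):
            if not remaining:
                break
            base = aligned[gi][col]
            if base == "-" or base not in _BASE_INDEX:
                continue  # diagnostic positions must be real bases
            hit = {j for j in remaining if aligned[j][col] != base}
            if hit:
                signature[own_coord[gi][col] + 1] = base
                remaining -= hit
        if remaining:
            names = ", ".join(references[j].id for j in sorted(remaining))
            raise ValueError(
                f"indistinguishable groups: {ref.id!r} cannot be separated "
                f"from {names}"
            )
        groups.append(
            HomologGroup(
                name=ref.id, reference=ref, diagnostic_signature=signature
            )
        )
    return groups


def _signature_mismatches(clone: SequenceRecord, group: HomologGroup) -> int:
    """Mismatch count of a clone against a group's diagnostic signature.

    Signature positions are compared at their literal CDS coordinates,
    anchored at the shared start codon.  This is exact for any position
    upstream of an indel (where panel diagnostics live: a global aligner
    would happily slide a gap into a divergent island and erase the very
    mismatches that are diagnostic).  N never matches; positions beyond
    the clone's end count as mismatches.
    """
    mism = 0
    for pos, base in group.diagnostic_signature.items():
        if pos > len(clone) or clone.seq[pos - 1] != base:
            mism += 1
    return mism


def assign_clone(
    clone: SequenceRecord, panel: Sequence[HomologGroup]
) -> GroupAssignment:
    """Assign one clone to its homolog group.

    The clone goes to the unique group whose full diagnostic signature
    it matches.  With no exact signature match it falls back to minimum
    edit distance against the references (flagged); ties in either path
    yield ``"unassigned"``.
    """
    mism = {g.name: _signature_mismatches(clone, g) for g in panel}
    exact = [g for g in panel if mism[g.name] == 0]
    if len(exact) == 1:
        g = exact[0]
        return GroupAssignment(
            clone_id=clone.id,
            group=g.name,
            mismatches_to_signature=0,
            edit_distance_to_reference=edit_distance(
                clone.seq, g.reference.seq
            ),
            fallback=False,
        )
    if len(exact) > 1:
        return GroupAssignment(clone.id, "unassigned", 0, -1)

    dists = {g.name: edit_distance(clone.seq, g.reference.seq) for g in panel}
    best = min(dists.values())
    winners = [g for g in panel if dists[g.name] == best]
    if len(winners) != 1:
        return GroupAssignment(clone.id, "unassigned", min(mism.values()), best)
    g = winners[0]
    return GroupAssignment(
        clone_id=clone.id,
        group=g.name,
        mismatches_to_signature=mism[g.name],
        edit_distance_to_reference=best,
        fallback=True,
    )


class ConsensusResult(NamedTuple):
    consensus: str
    counts: np.ndarray  # shape (L, 4), columns A/C/G/T; N excluded

    def base_count(self, position: int, base: str) -> int:
        """Clone count for ``base`` at a 1-based position."""
        return int(self.counts[position - 1, _BASE_INDEX[base]])


def _stack(clones: Sequence[SequenceRecord]) -> np.ndarray:
    lengths = {len(c) for c in clones}
    if len(lengths) != 1:
        raise ValueError(
            f"clones must be pre-aligned to equal length, got {sorted(lengths)}"
        )
    joined = "".join(c.seq for c in clones).encode("ascii")
    return np.frombuffer(joined, dtype=np.uint8).reshape(len(clones), -1)


def consensus_with_counts(
    clones: Sequence[SequenceRecord],
) -> ConsensusResult:
    """Per-position A/C/G/T counts and the plurality consensus.

    Clones must already share the group reference's coordinates (equal
    lengths).  N is excluded from the counts; count ties (and all-N
    columns) give consensus ``N``, where no SNP is callable.
    """
    if not clones:
        raise ValueError("cannot build a consensus from zero clones")
    mat = _stack(clones)
    counts = np.empty((mat.shape[1], 4), dtype=np.int64)
    for i, b in enumerate(_BASES):
        counts[:, i] = (mat == ord(b)).sum(axis=0)
    top = counts.max(axis=1)
    ties = (counts == top[:, None]).sum(axis=1) > 1
    cons = np.array(list(_BASES))[counts.argmax(axis=1)]
    cons[ties | (top == 0)] = "N"
    return ConsensusResult("".join(cons), counts)


def annotate_snp(
    position: int,
    ref_base: str,
    alt_base: str,
    reference: SequenceRecord,
) -> Annotation:
    """Codon-level annotation of a substitution.

    ``position`` is 1-based from the A of ATG; the affected codon index
    is ``ceil(position/3)`` and residues are numbered from the initiator
    Met, so position 316 falls in codon 106.
    """
    if ref_base == alt_base:
        raise ValueError(f"position {position}: ref and alt are both {ref_base}")
    if not 1 <= position <= len(reference):
        raise ValueError(f"position {position} outside reference")
    if reference.seq[position - 1] != ref_base:
        raise ValueError(
            f"position {position}: reference has "
            f"{reference.seq[position - 1]}, not {ref_base}"
        )
    codon_index = (position + 2) // 3
    start = (codon_index - 1) * 3
    codon = reference.seq[start : start + 3]
    if len(codon) < 3:
        raise ValueError(f"position {position}: incomplete trailing codon")
    mut = list(codon)
    mut[(position - 1) - start] = alt_base
    ref_aa = translate_cds(codon)
    alt_aa = translate_cds("".join(mut))
    return Annotation(codon_index, ref_aa, alt_aa, f"{ref_aa}{codon_index}{alt_aa}")


def call_snps(
    group: str,
    clones_line1: Sequence[SequenceRecord],
    clones_line2: Sequence[SequenceRecord],
    reference: SequenceRecord,
    min_support: int = 6,
    pooled: bool = False,
) -> list[SnpCall]:
    """Call substitutions between two lines within one homolog group.

    A call is emitted at position p iff the two lines' consensus bases
    differ there and the variant (non-reference) base is supported by at
    least ``min_support`` clones in the line carrying it ("more than
    five" occurrences).  With ``pooled=True`` support is counted across
    both lines combined.  Synonymous calls are emitted too — filtering
    them is a reporting choice, not the caller's.
    """
    if not clones_line1 or not clones_line2:
        raise ValueError("both clone sets must be non-empty")
    cons1 = consensus_with_counts(clones_line1)
    cons2 = consensus_with_counts(clones_line2)
    if not len(cons1.consensus) == len(cons2.consensus) == len(reference):
        raise ValueError("clone sets and reference disagree in length")

    calls: list[SnpCall] = []
    for p0, (b1, b2) in enumerate(zip(cons1.consensus, cons2.consensus)):
        if b1 == b2 or b1 not in _BASE_INDEX or b2 not in _BASE_INDEX:
            continue
        position = p0 + 1
        ref_base = reference.seq[p0]
        alt_base = b1 if b1 != ref_base else b2
        s1 = cons1.base_count(position, alt_base)
        s2 = cons2.base_count(position, alt_base)
        support = s1 + s2 if pooled else (s1 if b1 == alt_base else s2)
        if support < min_support:
            continue
        if ref_base not in _BASE_INDEX:
            continue  # reference N: not annotatable
        ann = annotate_snp(position, ref_base, alt_base, reference)
        calls.append(
            SnpCall(
                group=group,
                position=position,
                ref_base=ref_base,
                alt_base=alt_base,
                support_line1=s1,
                support_line2=s2,
                codon_index=ann.codon_index,
                ref_aa=ann.ref_aa,
                alt_aa=ann.alt_aa,
                label=ann.label,
            )
        )
    return calls


@dataclass(frozen=True)
class PipelineResult:
    """End-to-end SNP-calling output for a pair of clone libraries."""

    calls: tuple[SnpCall, ...]
    group_counts: dict  # group name -> (n clones line1, n clones line2)
    unassigned: tuple[str, ...]  # clone ids left unassigned


def run_snp_pipeline(
    clones_line1: Sequence[SequenceRecord],
    clones_line2: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    min_support: int = 6,
    pooled: bool = False,
) -> PipelineResult:
    """Bin both lines' clones into homolog groups and call SNPs per group.

    Groups with clones from only one line are skipped (nothing to
    compare); unassigned clones are reported, not errors.
    """
    panel = build_diagnostic_signatures(references)
    buckets: dict[str, tuple[list, list]] = {
        g.name: ([], []) for g in panel
    }
    unassigned: list[str] = []
    for which, clones in ((0, clones_line1), (1, clones_line2)):
        for clone in clones:
            a = assign_clone(clone, panel)
            if a.group == "unassigned":
                unassigned.append(clone.id)
                continue
            ref = next(g for g in panel if g.name == a.group).reference
            if len(clone) != len(ref):
                # indel-bearing clone: consensus coordinates undefined
                unassigned.append(clone.id)
                continue
            buckets[a.group][which].append(clone)
    calls: list[SnpCall] = []
    for g in panel:
        c1, c2 = buckets[g.name]
        if not c1 or not c2:
            continue
        calls.extend(
            call_snps(
                g.name, c1, c2, g.reference,
                min_support=min_support, pooled=pooled,
            )
        )
    return PipelineResult(
        calls=tuple(calls),
        group_counts={
            name: (len(c1), len(c2)) for name, (c1, c2) in buckets.items()
        },
        unassigned=tuple(unassigned),
    )


def snp_calls_to_frame(calls: Sequence[SnpCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": c.group,
                "position": c.position,
                "ref": c.ref_base,
                "alt": c.alt_base,
                "support_line1": c.support_line1,
                "support_line2": c.support_line2,
                "codon": c.codon_index,
                "label": c.label,
                "synonymous": c.synonymous,
            }
            for c in calls
        ],
        columns=[
            "group",
            "position",
            "ref",
            "alt",
            "support_line1",
            "support_line2",
            "codon",
            "label",
            "synonymous",
        ],
    )


def write_snp_tsv(calls: Sequence[SnpCall], path) -> None:
    snp_calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def write_snp_vcf(calls: Sequence[SnpCall], path) -> None:
    """Minimal VCF-like output: CHROM = group name, 1-based POS."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            fh.write(
                f"{c.group}\t{c.position}\t{c.dna_label}\t{c.ref_base}\t"
                f"{c.alt_base}\t.\tPASS\tAA_CHANGE={c.label}\n"
            )
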