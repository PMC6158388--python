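"""File I/O: FASTA clone libraries, restriction-enzyme tables and
population tables.

All formats are plain text.  The population table is a UTF-8 TSV with a
required header row::

    line_id  population  location  genotype_locus1  genotype_locus2
    c16_0  c18_0  c18_1  c18_2  c18_3  oil

``oil`` may be empty (not measured); genotypes may be ``unknown``.
The enzyme table is a three-column TSV: name, recognition, cut_offset.
"""

from __future__ import annotations

import math
from os import PathLike
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord as _BioRecord
from Bio.Seq import Seq

from .core import (
    FattyAcidProfile,
    PopulationLine,
    RestrictionEnzyme,
    SequenceRecord,
)

PathType = Union[str, PathLike]

POPULATION_COLUMNS = [
    "line_id",
    "population",
    "location",
    "genotype_locus1",
    "genotype_locus2",
    "c16_0",
    "c18_0",
    "c18_1",
    "c18_2",
    "c18_3",
    "oil",
]

ENZYME_COLUMNS = ["name", "recognition", "cut_offset"]


class FastaError(ValueError):
    """Malformed FASTA input."""


def _header_line_numbers(path: PathType) -> dict[str, int]:
    """Map record id -> 1-based line number of its header (first wins)."""
    numbers: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                rid = line[1:].split(None, 1)[0] if line[1:].strip() else ""
                numbers.setdefault(rid, lineno)
    return numbers


def read_fasta(path: PathType) -> list[SequenceRecord]:
    """Read a multi-FASTA file into :class:`SequenceRecord` objects.

    Sequences are upper-cased and U is mapped to T.  Empty files,
    duplicate ids and non-IUPAC characters raise :class:`FastaError`
    naming the offending record and its header line number.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    lines = _header_line_numbers(path)
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        lineno = lines.get(rec.id, 0)
        if rec.id in seen:
            raise FastaError(
                f"{path}: duplicate record id {rec.id!r} (line {lineno})"
            )
        seen.add(rec.id)
        try:
            records.append(SequenceRecord(id=rec.id, seq=seq))
        except ValueError as exc:
            raise FastaError(f"{path}: line {lineno}: {exc}") from exc
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathType,
                width: int = 70) -> None:
    bio = [
        _BioRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_enzyme_table(path: PathType) -> list[RestrictionEnzyme]:
    """Read a TSV of restriction enzymes (name, recognition, cut_offset)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(ENZYME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing enzyme columns {sorted(missing)}")
    return [
        RestrictionEnzyme(
            name=str(row["name"]),
            recognition=str(row["recognition"]).upper(),
            cut_offset=int(row["cut_offset"]),
        )
        for _, row in df.iterrows()
    ]


def default_enzyme_table() -> list[RestrictionEnzyme]:
    """The enzyme table shipped with the package (HinfI, BssSI/BssSαI)."""
    return read_enzyme_table(Path(__file__).parent / "data" / "enzymes.tsv")


def _profile_from_row(row: pd.Series, line_id: str) -> FattyAcidProfile:
    oil = row.get("oil")
    if oil is None or (isinstance(oil, float) and math.isnan(oil)):
        oil = None
    else:
        oil = float(oil)
    try:
        return FattyAcidProfile(
            c16_0=float(row["c16_0"]),
            c18_0=float(row["c18_0"]),
            c18_1=float(row["c18_1"]),
            c18_2=float(row["c18_2"]),
            c18_3=float(row["c18_3"]),
            oil=oil,
        )
    except ValueError as exc:
        raise ValueError(f"line {line_id}: {exc}") from exc


def read_population_table(path: PathType) -> list[PopulationLine]:
    """Read a population TSV into :class:`PopulationLine` objects."""
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str})
    required = set(POPULATION_COLUMNS) - {"oil"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    out: list[PopulationLine] = []
    for _, row in df.iterrows():
        line_id = str(row["line_id"])
        out.append(
            PopulationLine(
                line_id=line_id,
                population=str(row["population"]),
                location=str(row["location"]),
                genotype_locus1=str(row["genotype_locus1"]),
                genotype_locus2=str(row["genotype_locus2"]),
                profile=_profile_from_row(row, line_id),
            )
        )
    return out


def population_to_frame(pop: Iterable[PopulationLine]) -> pd.DataFrame:
    rows = []
    for ln in pop:
        p = ln.profile
        rows.append(
            {
                "line_id": ln.line_id,
                "population": ln.population,
                "location": ln.location,
                "genotype_locus1": ln.genotype_locus1,
                "genotype_locus2": ln.genotype_locus2,
                "c16_0": p.c16_0,
                "c18_0": p.c18_0,
                "c18_1": p.c18_1,
                "c18_2": p.c18_2,
                "c18_3": p.c18_3,
                "oil": p.oil,
            }
        )
    return pd.DataFrame(rows, columns=POPULATION_COLUMNS)


def write_population_table(pop: Iterable[PopulationLine],
                           path: PathType) -> None:
    population_to_frame(pop).to_csv(path, sep="\t", index=False)
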