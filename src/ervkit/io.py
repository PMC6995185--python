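"""Readers and writers for the interchange formats.

FASTA (loci, genomes, tRNA-PBS library, references), aligned FASTA (MSAs),
Newick trees, and tab-separated locus/feature/age tables. Sequences are
upper-cased on input with RNA ``U`` mapped to ``T``; anything outside
``{A,C,G,T,N,-}`` is rejected with the offending line number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Phylo, SeqIO

from .core import (
    AlignmentError,
    FastaFormatError,
    GenomicInterval,
    ProviralLocus,
)

_ALLOWED = frozenset("ACGTN-")

#: Fixed BED-like header of locus tables (coordinates are written 1-based
#: inclusive; `start`/`end` columns carry the rendered coordinates).
LOCUS_TABLE_COLUMNS = [
    "contig",
    "start",
    "end",
    "strand",
    "id",
    "class",
    "age",
    "subgroup",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of ``(id, sequence)`` tuples."""
    path = Path(path)
    try:
        records = [
            (rec.id, str(rec.seq).upper().replace("U", "T"))
            for rec in SeqIO.parse(path, "fasta")
        ]
    except ValueError as exc:  # leading junk before the first header
        raise FastaFormatError(f"{path}:1: {exc}") from exc
    if not records:
        raise FastaFormatError(f"{path}:1: no FASTA records found")
    seen: set[str] = set()
    for rid, seq in records:
        bad = set(seq) - _ALLOWED
        if bad:
            raise FastaFormatError(
                f"{path}:{_find_bad_line(path, bad)}: "
                f"illegal sequence characters {sorted(bad)} in record {rid!r}"
            )
        if rid in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
    return records


def _find_bad_line(path: Path, bad: set[str]) -> int:
    bad_upper = {c for c in bad} | {c.lower() for c in bad}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if line.startswith(">"):
            continue
        if set(line) & bad_upper:
            return lineno
    return 1


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, width: int = 70
) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA file; all rows must have equal length."""
    rows = read_fasta(path)
    ncols = len(rows[0][1])
    for rid, seq in rows:
        if len(seq) != ncols:
            raise AlignmentError(
                f"{path}: ragged alignment: row {rid!r} has length "
                f"{len(seq)}, expected {ncols}"
            )
    return rows


write_alignment = write_fasta


def write_newick(tree, path: str | Path) -> None:
    """Write a Bio.Phylo tree as Newick.

    Bootstrap supports are emitted as internal-node labels and branch
    lengths with at least 6 significant digits.
    """
    Phylo.write(tree, str(path), "newick", format_branch_length="%1.8g")


def read_newick(path: str | Path):
    return Phylo.read(str(path), "newick")


def write_locus_table(loci: Sequence[ProviralLocus], path: str | Path) -> None:
    """Write a TSV locus table with the fixed BED-like header.

    Coordinates are rendered 1-based inclusive.
    """
    rows = []
    for loc in loci:
        s1, e1 = loc.interval.to_1based()
        rows.append(
            {
                "contig": loc.interval.contig,
                "start": s1,
                "end": e1,
                "strand": loc.interval.strand,
                "id": loc.id,
                "class": loc.annotations.get("class", "."),
                "age": loc.annotations.get("age", "."),
                "subgroup": loc.annotations.get("subgroup", "."),
            }
        )
    pd.DataFrame(rows, columns=LOCUS_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_locus_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(LOCUS_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FastaFormatError(
            f"{path}: locus table missing columns {sorted(missing)}"
        )
    return df


def loci_from_table(
    table: pd.DataFrame, sequences: dict[str, str]
) -> list[ProviralLocus]:
    """Materialise ProviralLocus objects from a table plus id->sequence map."""
    loci = []
    for _, row in table.iterrows():
        loci.append(
            ProviralLocus(
                id=row["id"],
                species=str(row.get("species", ".")),
                interval=GenomicInterval.from_1based(
                    row["contig"], int(row["start"]), int(row["end"]), row["strand"]
                ),
                sequence=sequences[row["id"]],
            )
        )
    return loci


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
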