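"""Readers/writers for the formats the pipeline touches, and the shared record types.

Protein sequences are kept as plain upper-case strings over the 20 canonical
amino-acid letters.  Non-canonical letters (B, Z, J, U, O, X), stop marks and
stray gap characters in *unaligned* input are stripped and counted, because
every downstream descriptor is defined only over the canonical alphabet.
Gene tables locate genes by an integer order index along a replicon — the
neighborhood analyses work in units of genes, not base pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes, alphabetical.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

GAP = "-"


class FormatError(ValueError):
    """Malformed input file."""


class IntegrityError(ValueError):
    """Input violates a uniqueness/consistency constraint."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier, free-text description, residue string."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment: ≥2 equal-length gapped rows."""

    records: tuple[ProteinRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise FormatError("an alignment needs at least 2 sequences")
        width = len(self.records[0].sequence)
        for rec in self.records:
            if len(rec.sequence) != width:
                raise FormatError(
                    f"ragged alignment: record '{rec.id}' has length "
                    f"{len(rec.sequence)}, expected {width}"
                )

    @property
    def width(self) -> int:
        return len(self.records[0].sequence)

    def __len__(self) -> int:
        return len(self.records)

    def column(self, j: int) -> str:
        return "".join(rec.sequence[j] for rec in self.records)


@dataclass(frozen=True)
class GeneLocus:
    """A gene occurrence: genome, replicon, order index along the replicon, label."""

    genome_id: str
    replicon_id: str
    order_index: int
    gene_label: str


def sanitize_sequence(raw: str) -> tuple[str, int]:
    """Upper-case and strip non-canonical residues.

    Returns (clean sequence, number of characters removed).  Whitespace is
    dropped silently; anything else outside the canonical alphabet (B, Z, J,
    U, O, X, '*', '-', ...) counts as removed.
    """
    removed = 0
    kept: list[str] = []
    for ch in raw:
        if ch.isspace():
            continue
        up = ch.upper()
        if up in _CANONICAL_SET:
            kept.append(up)
        else:
            removed += 1
    return "".join(kept), removed


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a plain (unaligned) FASTA file into sanitized ProteinRecords.

    Non-canonical residues are removed and the total count logged.  Raises
    ``FileNotFoundError`` for a missing file, :class:`FormatError` for an
    empty file, an empty/duplicate id, or a record that is empty after
    sanitization.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    total_removed = 0
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not rec.id:
            raise FormatError(f"{path}: record {i} has an empty identifier")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id '{rec.id}'")
        seen.add(rec.id)
        clean, removed = sanitize_sequence(str(rec.seq))
        total_removed += removed
        if not clean:
            raise FormatError(
                f"{path}: record '{rec.id}' is empty after sanitization"
            )
        records.append(
            ProteinRecord(id=rec.id, sequence=clean, description=rec.description)
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if total_removed:
        logger.info(
            "read_fasta(%s): removed %d non-canonical residue(s) across %d records",
            path, total_removed, len(records),
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA (60-column wrapped)."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqrecs, str(Path(path)), "fasta")


def read_msa(path: str | Path) -> Msa:
    """Read an aligned FASTA file; '-' gaps preserved, all rows equal length."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[ProteinRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq).upper()
        bad = {c for c in seq if c != GAP and c not in _CANONICAL_SET}
        if bad:
            raise FormatError(
                f"{path}: record '{rec.id}' contains non-canonical symbol(s) "
                f"{sorted(bad)} in an alignment"
            )
        rows.append(ProteinRecord(id=rec.id, sequence=seq, description=rec.description))
    if not rows:
        raise FormatError(f"{path}: no FASTA records found")
    return Msa(records=tuple(rows))


def write_msa(msa: Msa, path: str | Path) -> None:
    write_fasta(msa.records, path)


_GENE_TABLE_COLUMNS = ["genome_id", "replicon_id", "order_index", "gene_label"]


def read_gene_table(path: str | Path) -> list[GeneLocus]:
    """Read a TSV gene table (genome_id, replicon_id, order_index, gene_label).

    order_index is a 0-based integer gene position along its replicon.
    Duplicate (genome, replicon, index) rows raise :class:`IntegrityError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != _GENE_TABLE_COLUMNS:
        raise FormatError(
            f"{path}: expected header {_GENE_TABLE_COLUMNS}, got {list(df.columns)}"
        )
    try:
        idx = df["order_index"].astype(int)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-integer order_index: {exc}") from exc
    if (idx < 0).any():
        raise FormatError(f"{path}: negative order_index")
    df = df.assign(order_index=idx)
    dup = df.duplicated(subset=["genome_id", "replicon_id", "order_index"])
    if dup.any():
        row = df[dup].iloc[0]
        raise IntegrityError(
            f"{path}: duplicate gene position "
            f"({row.genome_id}, {row.replicon_id}, {row.order_index})"
        )
    return [
        GeneLocus(r.genome_id, r.replicon_id, int(r.order_index), r.gene_label)
        for r in df.itertuples(index=False)
    ]


def write_gene_table(loci: Iterable[GeneLocus], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.genome_id, g.replicon_id, g.order_index, g.gene_label) for g in loci],
        columns=_GENE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
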