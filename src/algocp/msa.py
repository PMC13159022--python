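"""Aligned-FASTA ingestion, cleaning and columnarisation.

The cleaning step mirrors the usual pre-processing of database-derived
homologue collections: exact duplicates (compared on ungapped residue
strings, so re-alignments of the same sequence still deduplicate) and
fragmentary entries are removed before profile building. Columns are then
filtered by depth — only positions with enough aligned residues carry a
meaningful frequency signal.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import (
    ALLOWED_ALIGNMENT_CHARS,
    AMBIGUITY_CODES,
    AMINO_ACIDS,
    GAP,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence: identifier plus residue string (may contain
    gaps and ambiguity codes, stored uppercase)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty residue string")
        res = self.residues.upper()
        for pos, ch in enumerate(res):
            if ch not in ALLOWED_ALIGNMENT_CHARS:
                raise ValueError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos + 1}"
                )
        object.__setattr__(self, "residues", res)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class Alignment:
    """An MSA: ordered records, all of identical width."""

    records: tuple[SequenceRecord, ...]
    width: int = field(init=False)

    def __post_init__(self) -> None:
        records = tuple(self.records)
        if len(records) < 2:
            raise ValueError("alignment needs at least 2 records")
        width = len(records[0].residues)
        for rec in records:
            if len(rec.residues) != width:
                raise ValueError(
                    f"ragged alignment: record {rec.id!r} has length "
                    f"{len(rec.residues)}, expected {width}"
                )
        object.__setattr__(self, "records", records)
        object.__setattr__(self, "width", width)

    def __len__(self) -> int:
        return len(self.records)

    def column(self, index: int) -> str:
        return "".join(rec.residues[index] for rec in self.records)


@dataclass(frozen=True)
class AlignmentColumn:
    """One alignment position: the multiset of non-gap, non-ambiguous
    residues observed there. ``depth`` is the N of the frequency profile."""

    index: int
    residues: Counter

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("column index must be non-negative")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"column {self.index}: non-canonical residues {sorted(bad)}")

    @property
    def depth(self) -> int:
        return sum(self.residues.values())


def read_fasta_alignment(path) -> Alignment:
    """Parse an aligned FASTA file into an :class:`Alignment`.

    Residues are uppercased; unequal record lengths raise a
    "ragged alignment" error naming the offending record.
    """
    records = [
        SequenceRecord(id=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return Alignment(tuple(records))


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def clean_alignment(aln: Alignment, min_ungapped_fraction: float = 0.5) -> Alignment:
    """Drop duplicate and fragmentary records.

    Duplicates: a record whose ungapped string equals an earlier record's is
    removed (first occurrence kept). Fragments: ungapped length below
    ``min_ungapped_fraction`` x the median ungapped length. Idempotent.
    """
    if not 0 <= min_ungapped_fraction <= 1:
        raise ValueError("min_ungapped_fraction must lie in [0, 1]")
    seen: set[str] = set()
    deduped: list[SequenceRecord] = []
    n_dup = 0
    for rec in aln.records:
        key = rec.ungapped
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        deduped.append(rec)
    median_len = float(np.median([len(r.ungapped) for r in deduped]))
    threshold = min_ungapped_fraction * median_len
    kept = [r for r in deduped if len(r.ungapped) >= threshold]
    n_frag = len(deduped) - len(kept)
    logger.info(
        "clean_alignment: removed %d duplicate and %d fragmentary records (%d kept)",
        n_dup, n_frag, len(kept),
    )
    if len(kept) < 2:
        raise ValueError("alignment exhausted by cleaning (<2 records remain)")
    return Alignment(tuple(kept))


def extract_columns(aln: Alignment, min_residues: int = 50) -> list[AlignmentColumn]:
    """Columnarise an alignment, keeping positions with depth >= min_residues.

    Depth counts canonical residues only; gaps and ambiguity codes are
    excluded from the multiset and from N. Retained columns keep their
    original 0-based ``index`` so downstream reports can print 1-based
    alignment coordinates.
    """
    if min_residues < 1:
        raise ValueError("min_residues must be >= 1")
    retained: list[AlignmentColumn] = []
    dropped: list[tuple[int, int]] = []
    canonical = set(AMINO_ACIDS)
    for i in range(aln.width):
        counts = Counter(ch for ch in aln.column(i) if ch in canonical)
        depth = sum(counts.values())
        if depth >= min_residues:
            retained.append(AlignmentColumn(index=i, residues=counts))
        else:
            dropped.append((i, depth))
    if not retained:
        raise ValueError(
            f"no columns with >= {min_residues} residues (alignment width {aln.width})"
        )
    if dropped:
        logger.info("extract_columns: dropped %d/%d positions below depth %d",
                    len(dropped), aln.width, min_residues)
    return retained


def dropped_column_report(aln: Alignment, min_residues: int = 50) -> pd.DataFrame:
    """TSV-ready table of positions failing the depth filter
    (1-based original_position, depth, reason)."""
    canonical = set(AMINO_ACIDS)
    rows = []
    for i in range(aln.width):
        depth = sum(1 for ch in aln.column(i) if ch in canonical)
        if depth < min_residues:
            rows.append({"original_position": i + 1, "depth": depth,
                         "reason": f"depth<{min_residues}"})
    return pd.DataFrame(rows, columns=["original_position", "depth", "reason"])
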