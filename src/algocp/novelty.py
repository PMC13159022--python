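"""Sequence-novelty profiling of designed variants.

Given a designed sequence, a reference (e.g. the natural template) and the
columnarised input MSA in the same coordinate frame, every substitution is
annotated with:

* rarity — the fraction of MSA residues at that column equal to the query
  residue (flags at <5% and <1% by default);
* evolutionary conservativeness — BLOSUM62 score, with scores <= 0 treated
  as non-conservative;
* physicochemical divergence — Grantham distance, with >= 43 flagged as
  divergent, placed in context by its percentile among amino-acid pairings.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .alphabet import AMINO_ACIDS, AA_INDEX, validate_sequence
from .msa import AlignmentColumn

_BLOSUM62 = None
_GRANTHAM: pd.DataFrame | None = None

# Flag thresholds (configurable per call): strict < for rarity, <=0
# non-conservative, >=43 divergent.
RARE_5PCT = 0.05
RARE_1PCT = 0.01
NON_CONSERVATIVE_MAX = 0
DIVERGENT_MIN = 43


def _blosum():
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def _grantham() -> pd.DataFrame:
    global _GRANTHAM
    if _GRANTHAM is None:
        with resources.files("algocp.data").joinpath("grantham.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#").set_index("aa")
        _GRANTHAM = df.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)].astype(int)
    return _GRANTHAM


def _check_canonical(a: str, b: str) -> None:
    for res in (a, b):
        if res not in AA_INDEX:
            raise ValueError(f"non-canonical residue {res!r}")


def blosum62_score(a: str, b: str) -> int:
    """Symmetric BLOSUM62 half-bit score for a residue pair."""
    _check_canonical(a, b)
    return int(_blosum()[a, b])


def grantham_distance(a: str, b: str) -> int:
    """Grantham (1974) physicochemical distance; zero on the diagonal."""
    _check_canonical(a, b)
    return int(_grantham().loc[a, b])


def grantham_pair_distances(include_self: bool = False) -> np.ndarray:
    """All unordered pair distances: 190 distinct substitutions, or 210
    pairings when identical pairs are included."""
    m = _grantham().to_numpy()
    iu = np.triu_indices(len(AMINO_ACIDS), k=0 if include_self else 1)
    return m[iu]


def grantham_percentile(d: float, include_self: bool = False) -> float:
    """Percentile rank of a distance among amino-acid pairings.

    Midpoint convention for ties: 100·(#pairs < d + 0.5·#pairs == d)/#pairs.
    Defaults to the 190 distinct substitutions (identical pairs excluded).
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    vals = grantham_pair_distances(include_self)
    less = (vals < d).sum()
    equal = (vals == d).sum()
    return float(100.0 * (less + 0.5 * equal) / vals.size)


def grantham_median(include_self: bool = True) -> float:
    """The 50th-percentile Grantham distance over amino-acid pairings.

    Over *all* pairings of the full 20x20 matrix (both orderings, diagonal
    included — the default) the median is 96, the boundary used to call a
    substitution moderately vs. extremely divergent.
    """
    m = _grantham().to_numpy()
    vals = m.ravel() if include_self else grantham_pair_distances(False)
    return float(np.median(vals))


def pairwise_identity(a: str, b: str) -> float:
    """Percent identical positions between two equal-length sequences,
    reported to 2 decimals."""
    a = validate_sequence(a, context="pairwise_identity")
    b = validate_sequence(b, context="pairwise_identity")
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    matches = sum(x == y for x, y in zip(a, b))
    return round(100.0 * matches / len(a), 2)


@dataclass(frozen=True)
class VariationRecord:
    """One query-vs-reference substitution with its annotations.
    ``position`` is 1-based in the shared design frame."""

    position: int
    ref_residue: str
    query_residue: str
    msa_frequency: float
    blosum62_score: int
    grantham_distance: int
    rare_5pct: bool
    rare_1pct: bool
    non_conservative: bool
    divergent: bool


def variation_rarity(
    query: str,
    reference: str,
    msa_columns: Sequence[AlignmentColumn],
    rare_threshold: float = RARE_5PCT,
    very_rare_threshold: float = RARE_1PCT,
    blosum_max: int = NON_CONSERVATIVE_MAX,
    grantham_min: int = DIVERGENT_MIN,
) -> list[VariationRecord]:
    """Annotate every position where query differs from reference.

    Rarity is the query residue's frequency in the matching MSA column
    (canonical residues only); thresholds are strict ``<`` comparisons.
    Query, reference and the retained-column list must share one
    coordinate frame (equal lengths).
    """
    query = validate_sequence(query, context="query")
    reference = validate_sequence(reference, context="reference")
    if not (len(query) == len(reference) == len(msa_columns)):
        raise ValueError(
            f"coordinate mismatch: query {len(query)}, reference {len(reference)}, "
            f"columns {len(msa_columns)}"
        )
    records = []
    for i, (q, ref) in enumerate(zip(query, reference)):
        if q == ref:
            continue
        col = msa_columns[i]
        freq = col.residues.get(q, 0) / col.depth if col.depth else 0.0
        bl = blosum62_score(ref, q)
        gd = grantham_distance(ref, q)
        records.append(
            VariationRecord(
                position=i + 1,
                ref_residue=ref,
                query_residue=q,
                msa_frequency=freq,
                blosum62_score=bl,
                grantham_distance=gd,
                rare_5pct=freq < rare_threshold,
                rare_1pct=freq < very_rare_threshold,
                non_conservative=bl <= blosum_max,
                divergent=gd >= grantham_min,
            )
        )
    return records


@dataclass(frozen=True)
class NoveltyReport:
    records: tuple[VariationRecord, ...]
    counts: dict
    median_grantham: float | None
    identity_percent: float | None = None


def summarize_novelty(
    records: Sequence[VariationRecord],
    subset_filter: Callable[[VariationRecord], bool] | None = None,
    identity_percent: float | None = None,
) -> NoveltyReport:
    """Flag counts plus the median Grantham distance over a filtered subset
    (defaults to all records; empty subset reports None)."""
    records = tuple(records)
    counts = {
        "n_variations": len(records),
        "rare_5pct": sum(r.rare_5pct for r in records),
        "rare_1pct": sum(r.rare_1pct for r in records),
        "non_conservative": sum(r.non_conservative for r in records),
        "divergent": sum(r.divergent for r in records),
    }
    subset = [r for r in records if subset_filter is None or subset_filter(r)]
    median = float(np.median([r.grantham_distance for r in subset])) if subset else None
    return NoveltyReport(records, counts, median, identity_percent)


def records_to_frame(records: Sequence[VariationRecord]) -> pd.DataFrame:
    """TSV-ready table of variation records."""
    return pd.DataFrame([r.__dict__ for r in records])
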