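"""Trio binning: classify long reads by parent of origin with parental-unique k-mers.

Short reads from each parent yield k-mer count tables (k = 21 by default).
k-mers seen in one parent (at or above a noise threshold) and absent from the
other are that parent's markers.  Each long read from the offspring is scanned
for marker hits; the read goes to the parent with the strictly higher score,
and reads with tied scores -- including reads carrying no markers at all, as
happens for short reads from homozygous regions -- stay unassigned.

All k-mers are canonicalized (lexicographic minimum of the k-mer and its
reverse complement) so that classification is strand-independent.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io import FormatError

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def iter_canonical_kmers(seq: str, k: int) -> Iterable[str]:
    """Canonical k-mers at every position of ``seq``; k-mers with non-ACGT skipped."""
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if _VALID.issuperset(kmer):
            yield canonical(kmer)


def count_kmers(seqs: Iterable[str], k: int = 21) -> Counter:
    """Canonical k-mer counts over sequences.  Test-scale in-memory counter,
    not a replacement for a k-mer counting tool on real read sets."""
    counts: Counter = Counter()
    for seq in seqs:
        counts.update(iter_canonical_kmers(seq, k))
    return counts


# ---------------------------------------------------------------------------
# Marker sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParentalMarkerSet:
    """k-mers unique to one parent's short-read data."""

    parent_label: str
    k: int
    markers: frozenset
    min_count_used: int

    def __len__(self):
        return len(self.markers)


def _check_k(counts: Mapping[str, int], k: int, which: str) -> None:
    for kmer in counts:
        if len(kmer) != k:
            raise FormatError(
                f"{which}: k-mer {kmer!r} has length {len(kmer)}, expected k={k}"
            )


def build_marker_sets(
    kmer_counts_p1: Mapping[str, int],
    kmer_counts_p2: Mapping[str, int],
    k: int = 21,
    min_count: int = 5,
    labels: tuple[str, str] = ("parent1", "parent2"),
) -> tuple[ParentalMarkerSet, ParentalMarkerSet]:
    """Parent-unique marker sets from two canonical k-mer count tables.

    A k-mer is a marker of parent i when its count there is >= ``min_count``
    (suppressing sequencing-error k-mers) and it is entirely absent from the
    other parent.  The two sets are disjoint by construction.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    _check_k(kmer_counts_p1, k, labels[0])
    _check_k(kmer_counts_p2, k, labels[1])
    m1 = frozenset(
        m for m, c in kmer_counts_p1.items() if c >= min_count and kmer_counts_p2.get(m, 0) == 0
    )
    m2 = frozenset(
        m for m, c in kmer_counts_p2.items() if c >= min_count and kmer_counts_p1.get(m, 0) == 0
    )
    if not m1 and not m2:
        log.warning("no parent-unique markers found (empty or identical count tables)")
    return (
        ParentalMarkerSet(labels[0], k, m1, min_count),
        ParentalMarkerSet(labels[1], k, m2, min_count),
    )


def read_kmer_counts(path) -> dict[str, int]:
    """2-column TSV (kmer, count) -> dict.  k-mers are canonicalized on read."""
    counts: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 'kmer<TAB>count'")
            kmer = canonical(parts[0].upper())
            counts[kmer] = counts.get(kmer, 0) + int(parts[1])
    return counts


# ---------------------------------------------------------------------------
# Read classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinnedRead:
    """One long read with its parental marker hit counts and bin decision."""

    read_id: str
    count_p1: int
    count_p2: int
    bin: str  # "parent1" | "parent2" | "unassigned"


def classify_read(
    sequence: str,
    markers1: ParentalMarkerSet,
    markers2: ParentalMarkerSet,
    normalize: bool = False,
    read_id: str = "",
) -> BinnedRead:
    """Assign one read to a parental bin by marker k-mer hits.

    Hits are counted per position (a marker occurring twice counts twice,
    preserving dosage).  With ``normalize=True`` each count is divided by its
    marker-set size before comparison, compensating for unequal parental
    heterozygosity.  Strictly higher score wins; ties -- including the 0/0
    case of a read lacking parent-specific k-mers -- are unassigned.
    """
    if markers1.k != markers2.k:
        raise FormatError(f"marker sets disagree on k: {markers1.k} vs {markers2.k}")
    k = markers1.k
    c1 = c2 = 0
    m1, m2 = markers1.markers, markers2.markers
    for kmer in iter_canonical_kmers(sequence, k):
        if kmer in m1:
            c1 += 1
        elif kmer in m2:
            c2 += 1
    if normalize:
        s1 = c1 / len(m1) if m1 else 0.0
        s2 = c2 / len(m2) if m2 else 0.0
    else:
        s1, s2 = c1, c2
    if s1 > s2:
        bin_ = markers1.parent_label
    elif s2 > s1:
        bin_ = markers2.parent_label
    else:
        bin_ = "unassigned"
    return BinnedRead(read_id, c1, c2, bin_)


def bin_reads(
    reads: Iterable[tuple[str, str]],
    markers1: ParentalMarkerSet,
    markers2: ParentalMarkerSet,
    normalize: bool = False,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Classify a read set; returns (per-read table, fraction per bin).

    ``reads`` yields ``(read_id, sequence)``.  Summary fractions sum to 1
    (an empty read set yields an empty summary).
    """
    records = [
        classify_read(seq, markers1, markers2, normalize=normalize, read_id=rid)
        for rid, seq in reads
    ]
    df = pd.DataFrame(
        [(r.read_id, r.count_p1, r.count_p2, r.bin) for r in records],
        columns=["read_id", "count_p1", "count_p2", "bin"],
    )
    summary: dict[str, float] = {}
    if len(df):
        for label in (markers1.parent_label, markers2.parent_label, "unassigned"):
            summary[label] = float((df["bin"] == label).mean())
    return df, summary
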