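"""Hi-C read-pair haplotype assignment by alignment score.

Each Hi-C pair is aligned to both haplotype assemblies.  The score of a pair
against one haplotype is the sum over its two ends of percent identity times
match length, with unmapped ends contributing 0.  The pair is assigned to the
haplotype with the strictly higher score; pairs with tied scores come from
homozygous regions and go to both haplotypes, so that neither scaffolding
input set loses contact information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

TIE_TOL = 1e-9  # absolute score tolerance below which a pair counts as tied


@dataclass(frozen=True)
class EndAlignment:
    """Alignment summary of one read end against one haplotype."""

    mapped: bool
    identity: float = 0.0  # fraction in [0, 1]
    match_length: int = 0  # aligned bases

    def __post_init__(self):
        if self.mapped:
            if not (0.0 <= self.identity <= 1.0):
                raise ValueError(f"identity {self.identity} outside [0, 1]")
            if self.match_length < 0:
                raise ValueError("match_length must be >= 0")


@dataclass(frozen=True)
class PairScore:
    pair_id: str
    score_hapA: float
    score_hapB: float
    assignment: str  # "A" | "B" | "both"

    @property
    def informative(self) -> bool:
        """False when both haplotype scores are 0 (all ends unmapped)."""
        return max(self.score_hapA, self.score_hapB) > 0.0


def end_score(end: EndAlignment) -> float:
    """identity x match_length for a mapped end, 0 for an unmapped end."""
    if not end.mapped:
        return 0.0
    return end.identity * end.match_length


def identity_from_alignment(aligned_len: int, edit_distance: int) -> float:
    """Identity fraction from aligned length and an NM-style edit distance."""
    if aligned_len == 0:
        return 0.0
    if not (0 <= edit_distance <= aligned_len):
        raise ValueError("edit_distance must lie in [0, aligned_len]")
    return (aligned_len - edit_distance) / aligned_len


def score_pair(
    endsA: Sequence[EndAlignment],
    endsB: Sequence[EndAlignment],
    pair_id: str = "",
) -> PairScore:
    """Score one pair against both haplotypes and decide its assignment.

    ``endsA``/``endsB`` are the two end alignments of the same pair against
    haplotype A and B respectively.  Scores within ``TIE_TOL`` of each other
    are ties (assigned "both"), avoiding spurious decisions from float noise.
    """
    if len(endsA) != 2 or len(endsB) != 2:
        raise ValueError("each haplotype needs exactly two end alignments")
    sa = end_score(endsA[0]) + end_score(endsA[1])
    sb = end_score(endsB[0]) + end_score(endsB[1])
    if sa > sb + TIE_TOL:
        assignment = "A"
    elif sb > sa + TIE_TOL:
        assignment = "B"
    else:
        assignment = "both"
    return PairScore(pair_id, sa, sb, assignment)


def score_pairs_table(table: pd.DataFrame) -> list[PairScore]:
    """Score every pair in a per-end alignment summary table.

    Expected columns: ``pair_id, end, haplotype, mapped`` plus either
    ``identity, match_length`` or ``aligned_len, edit_distance`` (identity is
    then derived).  ``haplotype`` takes values "A"/"B"; ``end`` 1/2.  An end
    absent from the table counts as unmapped.
    """
    df = table.copy()
    if "identity" not in df.columns:
        df["identity"] = [
            identity_from_alignment(al, nm)
            for al, nm in zip(df["aligned_len"], df["edit_distance"])
        ]
        df["match_length"] = df["aligned_len"]
    out = []
    unmapped = EndAlignment(mapped=False)
    for pair_id, grp in df.groupby("pair_id", sort=False):
        ends = {"A": [unmapped, unmapped], "B": [unmapped, unmapped]}
        for row in grp.itertuples(index=False):
            ends[str(row.haplotype)][int(row.end) - 1] = EndAlignment(
                mapped=bool(row.mapped),
                identity=float(row.identity) if row.mapped else 0.0,
                match_length=int(row.match_length) if row.mapped else 0,
            )
        out.append(score_pair(ends["A"], ends["B"], pair_id=str(pair_id)))
    return out


def partition_pairs(
    pair_scores: Iterable[PairScore],
) -> tuple[list[str], list[str], dict]:
    """Split scored pairs into the per-haplotype sets used for scaffolding.

    Pairs assigned A appear only in A's set, B only in B's, ties in both.
    ``stats`` reports counts per class and the informative fraction (pairs
    with at least one mapped end on some haplotype).
    """
    set_a: list[str] = []
    set_b: list[str] = []
    n = {"A": 0, "B": 0, "both": 0, "uninformative": 0}
    total = 0
    for ps in pair_scores:
        total += 1
        n[ps.assignment] += 1
        if not ps.informative:
            n["uninformative"] += 1
        if ps.assignment in ("A", "both"):
            set_a.append(ps.pair_id)
        if ps.assignment in ("B", "both"):
            set_b.append(ps.pair_id)
    stats = {
        "n_pairs": total,
        "n_A": n["A"],
        "n_B": n["B"],
        "n_both": n["both"],
        "n_uninformative": n["uninformative"],
        "informative_fraction": (total - n["uninformative"]) / total if total else float("nan"),
    }
    return set_a, set_b, stats


def pairs_table_from_sam(sam_path_hapA, sam_path_hapB) -> pd.DataFrame:
    """Thin converter: two name-matched SAM files -> per-end score table.

    Only primary alignments are scored (secondary/supplementary records are
    skipped); identity derives from the NM tag over aligned (M/=/X) bases.
    Read names are pair ids; first/second-of-pair flags give the end number.
    Alignment itself is upstream of this package.
    """
    import pysam  # optional converter; core pipeline consumes TSVs

    rows = []
    for hap, path in (("A", sam_path_hapA), ("B", sam_path_hapB)):
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for rec in fh:
                if rec.is_secondary or rec.is_supplementary:
                    continue
                end = 2 if rec.is_read2 else 1
                if rec.is_unmapped:
                    rows.append((rec.query_name, end, hap, False, 0, 0))
                    continue
                aligned = sum(
                    ln for op, ln in (rec.cigartuples or []) if op in (0, 7, 8)
                )
                nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                rows.append((rec.query_name, end, hap, True, aligned, min(nm, aligned)))
    df = pd.DataFrame(
        rows, columns=["pair_id", "end", "haplotype", "mapped", "aligned_len", "edit_distance"]
    )
    return df
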