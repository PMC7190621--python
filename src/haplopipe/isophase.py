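"""SNP calling, phasing and allele-specific expression from full-length reads.

Full-length non-concatamer (FLNC) transcript reads of all isoforms of a gene
are piled up over the gene's candidate positions.  Substitution SNPs are
called per position with a one-sided Fisher exact test of the minor-base count
against an expected sequencing-error pseudo-sample, Bonferroni-corrected over
the positions tested in the gene at a cut-off of 0.01.  Reads are then phased
by their allele strings over the significant SNPs: the two most frequent
complete strings define the haplotypes, remaining reads join the unique
compatible haplotype or stay ambiguous.  Haplotype-specific counts are
demultiplexed per tissue, normalized to transcripts per million (TPM), and the
maternal-allele proportion m/(m+p) quantifies allelic imbalance, screened per
tissue with a Shapiro-Wilk test on the per-gene proportion distribution.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Alignment filtering
# ---------------------------------------------------------------------------

def filter_transcript_alignments(
    records: pd.DataFrame,
    min_coverage: float = 0.99,
    min_identity: float = 0.95,
) -> pd.DataFrame:
    """Keep transcript alignments with coverage >= 99% and identity >= 95%.

    Both gates are inclusive; ``records`` needs ``coverage`` and ``identity``
    columns as fractions.
    """
    keep = (records["coverage"] >= min_coverage) & (records["identity"] >= min_identity)
    return records[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Fisher test and SNP calling
# ---------------------------------------------------------------------------

def fisher_one_sided(table) -> float:
    """One-sided (greater) Fisher exact p-value for a 2x2 count table.

    For ``[[a, b], [c, d]]`` this is the exact hypergeometric tail
    P(X >= a) with margins fixed.  Cells must be non-negative integers and
    at least one margin positive.
    """
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError(f"table cells must be non-negative integers: {cells}")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    if n == 0:
        raise ValueError("all margins are zero")
    return float(stats.hypergeom.sf(a - 1, n, a + b, a + c))


@dataclass(frozen=True)
class SnpCall:
    """A tested pileup position (gene-local, 0-based)."""

    position: int
    ref_base: str
    alt_base: str
    counts: dict = field(hash=False)
    p_value: float
    p_adjusted: float
    significant: bool

    @property
    def coverage(self) -> int:
        return sum(self.counts.values())


def pileup_from_reads(flnc: pd.DataFrame) -> list[Counter]:
    """Per-position base counts from FLNC allele strings of one gene.

    Position ``i`` of each string is the read's base at the gene's i-th
    candidate position; ``-`` (position not covered by the read) is skipped.
    """
    strings = flnc["alleles"].tolist()
    if not strings:
        return []
    width = len(strings[0])
    if any(len(s) != width for s in strings):
        raise ValueError("allele strings of one gene must share one length")
    pile = [Counter() for _ in range(width)]
    for s in strings:
        for i, base in enumerate(s):
            if base in _BASES:
                pile[i][base] += 1
    return pile


def call_snps(
    pileup: list[Counter],
    p_err: float = 0.005,
    alpha: float = 0.01,
) -> list[SnpCall]:
    """Call substitution SNPs from a per-position pileup.

    A position with at least two observed bases is tested: the count m of the
    second-most-frequent base out of coverage N is compared against an
    expected-error pseudo-sample via a one-sided Fisher test on
    ``[[m, N-m], [round(p_err*N), N-round(p_err*N)]]``.  Bonferroni
    correction runs over the positions tested within the gene; a call is
    significant when the adjusted p-value is below ``alpha``.  Monomorphic
    positions are not tested and do not enter the correction.
    """
    tested = [
        (pos, counts)
        for pos, counts in enumerate(pileup)
        if sum(counts.values()) > 0 and len([b for b, c in counts.items() if c > 0]) >= 2
    ]
    n_tests = len(tested)
    calls: list[SnpCall] = []
    for pos, counts in tested:
        (ref, _), (alt, m) = counts.most_common(2)
        cov = sum(counts.values())
        e = int(round(p_err * cov))
        p = fisher_one_sided([[m, cov - m], [e, cov - e]])
        p_adj = min(1.0, p * n_tests)
        calls.append(
            SnpCall(
                position=pos,
                ref_base=ref,
                alt_base=alt,
                counts=dict(counts),
                p_value=p,
                p_adjusted=p_adj,
                significant=bool(p_adj < alpha),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Phasing
# ---------------------------------------------------------------------------

@dataclass
class PhasingResult:
    snp_positions: list[int]
    hap1: str
    hap2: str | None  # None when only one complete allele string exists
    assignments: dict[str, str]  # read_id -> "hap1" | "hap2" | "ambiguous"

    @property
    def n_ambiguous(self) -> int:
        return sum(1 for v in self.assignments.values() if v == "ambiguous")


def _compatible(substring: str, hap: str) -> bool:
    return all(s == "-" or s == h for s, h in zip(substring, hap))


def phase_reads(flnc: pd.DataFrame, snp_calls: list[SnpCall]) -> PhasingResult:
    """Infer the two haplotype allele strings and assign every read.

    The allele strings of reads restricted to the significant SNP positions
    vote: the two most frequent complete strings (no missing positions)
    become hap1 (more frequent; lexicographic tie-break) and hap2.  Reads --
    including partially covering ones -- are assigned to the unique
    compatible haplotype; reads compatible with both (covering only positions
    where the haplotypes agree) or with neither (sequencing errors) are
    ambiguous.  Requires at least one significant SNP.
    """
    sig = [c.position for c in snp_calls if c.significant]
    if not sig:
        raise ValueError("phasing requires >= 1 significant SNP")
    subs = {
        r.read_id: "".join(r.alleles[p] for p in sig) for r in flnc.itertuples(index=False)
    }
    complete = Counter(s for s in subs.values() if "-" not in s)
    ranked = sorted(complete.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) < 2:
        log.warning("fewer than 2 distinct complete allele strings; single haplotype")
        hap1 = ranked[0][0] if ranked else ""
        hap2 = None
    else:
        hap1, hap2 = ranked[0][0], ranked[1][0]
    assignments: dict[str, str] = {}
    for rid, s in subs.items():
        cands = [
            name
            for name, hap in (("hap1", hap1), ("hap2", hap2))
            if hap is not None and hap != "" and _compatible(s, hap)
        ]
        assignments[rid] = cands[0] if len(cands) == 1 else "ambiguous"
    return PhasingResult(snp_positions=sig, hap1=hap1, hap2=hap2, assignments=assignments)


# ---------------------------------------------------------------------------
# Demultiplexing and normalization
# ---------------------------------------------------------------------------

def demultiplex(
    assignments: dict[str, str],
    flnc: pd.DataFrame,
    hap_labels: tuple[str, str] = ("hap1", "hap2"),
) -> tuple[pd.DataFrame, dict]:
    """Haplotype-specific FLNC counts per (gene, isoform, haplotype, tissue).

    Ambiguous reads are excluded from haplotype-specific counts (conservative;
    they are reported, not fractionally split).  Count conservation holds:
    hap1 + hap2 + ambiguous = total reads per gene.
    """
    df = flnc.copy()
    df["haplotype"] = df["read_id"].map(assignments)
    assigned = df[df["haplotype"].isin(["hap1", "hap2"])].copy()
    assigned["haplotype"] = assigned["haplotype"].map(
        {"hap1": hap_labels[0], "hap2": hap_labels[1]}
    )
    counts = (
        assigned.groupby(["gene_id", "isoform_id", "haplotype", "tissue"], sort=True)
        .size()
        .reset_index(name="count")
    )
    stats_out = {
        "n_reads": int(len(df)),
        "n_hap1": int((df["haplotype"] == "hap1").sum()),
        "n_hap2": int((df["haplotype"] == "hap2").sum()),
        "n_ambiguous": int((df["haplotype"] == "ambiguous").sum()),
        "per_tissue_totals": df.groupby("tissue").size().to_dict(),
    }
    return counts, stats_out


def tpm_normalize(abundance: pd.DataFrame, count_col: str = "count") -> pd.DataFrame:
    """Add a ``tpm`` column: count / per-tissue total * 1e6.

    Per tissue, TPM values sum to 1e6 (exactly in rational arithmetic; to
    within float rounding in the returned float64 column).  A tissue with a
    zero total gets TPM 0 with a warning.
    """
    out = abundance.copy()
    totals = out.groupby("tissue")[count_col].transform("sum")
    tpm = np.zeros(len(out))
    nonzero = totals.to_numpy() > 0
    tpm[nonzero] = out[count_col].to_numpy()[nonzero] * 1e6 / totals.to_numpy()[nonzero]
    if (~nonzero).any():
        log.warning("tpm_normalize: tissue with zero total counts; TPM set to 0")
    out["tpm"] = tpm
    return out


def allelic_proportion(tpm_maternal: float, tpm_paternal: float) -> float:
    """Maternal-allele proportion m/(m+p); NaN when both alleles are silent.

    Swapping the labels maps a proportion p to 1 - p exactly.
    """
    total = tpm_maternal + tpm_paternal
    if total == 0:
        return float("nan")
    return tpm_maternal / total


# ---------------------------------------------------------------------------
# Imbalance screen and concordance
# ---------------------------------------------------------------------------

def tissue_imbalance_test(proportions, alpha: float = 0.01) -> tuple[float, float, bool]:
    """Shapiro-Wilk screen of per-gene allelic proportions in one tissue.

    Balanced expression concentrates proportions symmetrically around 0.5;
    strong allele-specific expression produces heavy shoulders or spikes near
    0 and 1 that the normality test rejects.  The test is a screen, not a
    per-gene call.  Requires >= 3 finite proportions.  Returns
    ``(W, p_value, flagged)`` with ``flagged = p < alpha``.
    """
    arr = np.asarray(proportions, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) < 3:
        raise ValueError("Shapiro-Wilk screen needs >= 3 finite proportions")
    w, p = stats.shapiro(arr)
    return float(w), float(p), bool(p < alpha)


def snp_concordance(
    iso_snps,
    wgs_snps,
    rnaseq_snps,
    coverage: dict,
    min_cov: int = 40,
) -> dict:
    """Venn-region counts of SNP positions across three callers.

    All three sets are first restricted to positions covered by at least
    ``min_cov`` full-length reads (``coverage`` maps position -> read count;
    positions absent from it count as uncovered).  Returns the seven Venn
    region counts plus ``concordance``, the fraction of retained long-read
    SNPs confirmed by both short-read callers.
    """
    def covered(snps):
        return {p for p in snps if coverage.get(p, 0) >= min_cov}

    iso, wgs, rna = covered(iso_snps), covered(wgs_snps), covered(rnaseq_snps)
    out = {
        "iso_only": len(iso - wgs - rna),
        "wgs_only": len(wgs - iso - rna),
        "rnaseq_only": len(rna - iso - wgs),
        "iso_wgs": len((iso & wgs) - rna),
        "iso_rnaseq": len((iso & rna) - wgs),
        "wgs_rnaseq": len((wgs & rna) - iso),
        "triple": len(iso & wgs & rna),
    }
    out["n_iso"] = len(iso)
    out["concordance"] = out["triple"] / len(iso) if iso else float("nan")
    return out
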