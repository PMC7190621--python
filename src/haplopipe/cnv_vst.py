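"""Copy-number differentiation between two populations from windowed read depth.

Windowed depth "levels" (normalized so that the diploid state sits at 1.0, as
produced by read-depth segmentation tools) are converted to copy numbers by
multiplying by two, aggregated per gene, and compared between a taurine and an
indicine population with the Vst statistic,

    Vst = (Vt - Vs) / Vt,

where Vt is the variance of copy number across all individuals and Vs is the
population-size-weighted mean of the within-population variances.  Vst behaves
like Fst on a continuous copy-number value: 0 for undifferentiated genes, 1
when the populations are internally homogeneous but different from each other.

Genes are called copy-number differentiated when Vst > 0.3 and the absolute
difference in mean copy number between populations exceeds 3 copies; a looser
"plot set" at a difference of at least 1.5 copies is reported alongside, as is
the empirical top-1% Vst quantile (the fixed 0.3 cut-off is equivalent to the
top 1% only on data where that happens to hold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Container
# ---------------------------------------------------------------------------

@dataclass
class CopyNumberMatrix:
    """Individuals x windows of diploid-scaled depth levels.

    ``levels[i, j]`` is the normalized depth level of individual ``i`` in
    window ``j`` (1.0 = diploid).  ``windows`` has 1-based closed columns
    ``chrom, start, end``, sorted and non-overlapping within a chromosome.
    """

    individuals: list[str]
    populations: list[str]
    windows: pd.DataFrame
    levels: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=float)
        n_ind, n_win = self.levels.shape
        if n_ind != len(self.individuals) or n_ind != len(self.populations):
            raise ValueError("levels shape does not match individual labels")
        if n_win != len(self.windows):
            raise ValueError("levels shape does not match window table")
        if (self.levels < 0).any():
            raise ValueError("depth levels must be non-negative")
        for _, grp in self.windows.groupby("chrom", sort=False):
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            if (s > e).any():
                raise ValueError("window start > end")
            if len(grp) > 1 and (s[1:] <= e[:-1]).any():
                raise ValueError("windows overlap or are unsorted")

    def copy_numbers(self) -> np.ndarray:
        """Copy-number matrix (levels scaled to the diploid baseline of 2)."""
        return depth_to_cn(self.levels)

    # -- on-disk long format: individual, population, chrom, start, end, level
    def to_tsv(self, path) -> None:
        n_ind = len(self.individuals)
        n_win = len(self.windows)
        df = pd.DataFrame(
            {
                "individual": np.repeat(self.individuals, n_win),
                "population": np.repeat(self.populations, n_win),
                "chrom": np.tile(self.windows["chrom"].to_numpy(), n_ind),
                "start": np.tile(self.windows["start"].to_numpy(), n_ind),
                "end": np.tile(self.windows["end"].to_numpy(), n_ind),
                "level": self.levels.ravel(),
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CopyNumberMatrix":
        df = pd.read_csv(path, sep="\t")
        ind = df["individual"].drop_duplicates().tolist()
        pops = df.drop_duplicates("individual").set_index("individual")["population"]
        first = df[df["individual"] == ind[0]]
        windows = first[["chrom", "start", "end"]].reset_index(drop=True)
        levels = df["level"].to_numpy().reshape(len(ind), len(windows))
        return cls(ind, [pops[i] for i in ind], windows, levels)


# ---------------------------------------------------------------------------
# Copy-number arithmetic
# ---------------------------------------------------------------------------

def depth_to_cn(levels):
    """Diploid-scaled depth level -> copy number: cn = 2 * level."""
    return 2.0 * np.asarray(levels, dtype=float)


def _overlap_len(s1, e1, s2, e2):
    """bp overlap of two 1-based closed intervals (vectorizable)."""
    return np.maximum(0, np.minimum(e1, e2) - np.maximum(s1, s2) + 1)


def gene_copy_number(cnm: CopyNumberMatrix, gene_interval) -> np.ndarray:
    """Per-individual copy number of one gene.

    ``gene_interval`` is ``(chrom, start, end)``, 1-based closed.  The gene
    value is the overlap-length-weighted mean of the copy numbers of the
    windows it intersects, which makes the aggregate robust to window
    boundaries cutting through the gene.

    Raises ``ValueError`` if the gene overlaps no window.
    """
    chrom, gstart, gend = gene_interval
    w = cnm.windows
    on_chrom = (w["chrom"] == chrom).to_numpy()
    ov = np.zeros(len(w))
    ov[on_chrom] = _overlap_len(
        w["start"].to_numpy()[on_chrom], w["end"].to_numpy()[on_chrom], gstart, gend
    )
    if ov.sum() == 0:
        raise ValueError(f"gene {chrom}:{gstart}-{gend} overlaps no depth window")
    weights = ov / ov.sum()
    return cnm.copy_numbers() @ weights


# ---------------------------------------------------------------------------
# Vst
# ---------------------------------------------------------------------------

def vst(values, labels, ddof: int = 0) -> float:
    """Between-population differentiation of a continuous value.

    Vst = (Vt - Vs)/Vt with Vt the variance of all values and
    Vs = (n1*V1 + n2*V2)/(n1 + n2) the size-weighted mean within-population
    variance.  Population variance (ddof=0) is the default convention; ddof
    is exposed for sensitivity checks.  Vt = 0 (no variation at all) is
    defined as Vst = 0.  Requires exactly two populations with >= 2 members
    each.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"vst requires exactly 2 populations, got {len(groups)}")
    g1 = values[labels == groups[0]]
    g2 = values[labels == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each population needs >= 2 individuals")
    vt = values.var(ddof=ddof)
    if vt == 0.0:
        return 0.0
    vs = (len(g1) * g1.var(ddof=ddof) + len(g2) * g2.var(ddof=ddof)) / (len(g1) + len(g2))
    return float((vt - vs) / vt)


def call_differentiated_genes(
    cnm: CopyNumberMatrix,
    genes: pd.DataFrame,
    vst_threshold: float = 0.3,
    diff_threshold: float = 3.0,
    plot_diff_threshold: float = 1.5,
    ddof: int = 0,
) -> pd.DataFrame:
    """Per-gene Vst between the two populations with the fixed call rule.

    ``genes`` needs columns ``gene_id, chrom, start, end`` (1-based closed).
    A gene is ``called`` when Vst > vst_threshold and the absolute difference
    of population mean copy numbers > diff_threshold; ``in_plot_set`` uses
    the softer >= plot_diff_threshold difference.  Genes overlapping no depth
    window are skipped with a warning.  The returned frame carries the
    empirical top-1% Vst quantile in ``.attrs["vst_top1pct"]``.
    """
    labels = np.asarray(cnm.populations)
    pops = pd.unique(labels)
    if len(pops) != 2:
        raise ValueError("copy-number matrix must carry exactly 2 populations")
    rows = []
    for g in genes.itertuples(index=False):
        try:
            cn = gene_copy_number(cnm, (g.chrom, g.start, g.end))
        except ValueError:
            log.warning("gene %s overlaps no depth window; skipped", g.gene_id)
            continue
        m1 = float(cn[labels == pops[0]].mean())
        m2 = float(cn[labels == pops[1]].mean())
        v = vst(cn, labels, ddof=ddof)
        diff = abs(m1 - m2)
        rows.append(
            {
                "gene_id": g.gene_id,
                "vst": v,
                "mean_cn_pop1": m1,
                "mean_cn_pop2": m2,
                "cn_diff": diff,
                "called": bool(v > vst_threshold and diff > diff_threshold),
                "in_plot_set": bool(v > vst_threshold and diff >= plot_diff_threshold),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "vst", "mean_cn_pop1", "mean_cn_pop2",
            "cn_diff", "called", "in_plot_set",
        ],
    )
    out.attrs["populations"] = list(pops)
    out.attrs["vst_top1pct"] = float(np.quantile(out["vst"], 0.99)) if len(out) else float("nan")
    return out


# ---------------------------------------------------------------------------
# SV depth-support filter
# ---------------------------------------------------------------------------

def filter_large_svs(
    svs: pd.DataFrame,
    cnm: CopyNumberMatrix,
    length_threshold: int = 1_000_000,
    deviation_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop very large SV calls lacking read-depth support.

    An SV longer than ``length_threshold`` is a likely false positive unless
    its span shows aberrant read depth: it is kept only if the mean copy
    number across the span deviates from the diploid 2 by at least
    ``deviation_threshold`` in at least one individual.  Shorter SVs pass
    through untouched.  ``svs`` needs columns ``chrom, start, end``
    (1-based closed).  Returns ``(kept, removed)``.
    """
    keep_mask = []
    for sv in svs.itertuples(index=False):
        length = sv.end - sv.start + 1
        if length <= length_threshold:
            keep_mask.append(True)
            continue
        try:
            cn = gene_copy_number(cnm, (sv.chrom, sv.start, sv.end))
        except ValueError:
            log.warning(
                "SV %s:%d-%d exceeds %d bp but overlaps no depth window; removed",
                sv.chrom, sv.start, sv.end, length_threshold,
            )
            keep_mask.append(False)
            continue
        keep_mask.append(bool(np.abs(cn - 2.0).max() >= deviation_threshold))
    keep_mask = np.asarray(keep_mask, dtype=bool)
    return svs[keep_mask].reset_index(drop=True), svs[~keep_mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# CNVR intersection
# ---------------------------------------------------------------------------

def _merge_intervals(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Merge 1-based closed intervals per chromosome -> {chrom: (k, 2) array}."""
    merged: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        iv = grp[["start", "end"]].sort_values("start").to_numpy()
        out = []
        cs, ce = iv[0]
        for s, e in iv[1:]:
            if s <= ce + 1:
                ce = max(ce, e)
            else:
                out.append((cs, ce))
                cs, ce = s, e
        out.append((cs, ce))
        merged[chrom] = np.asarray(out)
    return merged


def _total_bp(merged: dict[str, np.ndarray]) -> int:
    return int(sum((iv[:, 1] - iv[:, 0] + 1).sum() for iv in merged.values()))


def _intersect_bp(a: dict[str, np.ndarray], b: dict[str, np.ndarray]) -> int:
    total = 0
    for chrom, av in a.items():
        if chrom not in b:
            continue
        bv = b[chrom]
        i = j = 0
        while i < len(av) and j < len(bv):
            s = max(av[i, 0], bv[j, 0])
            e = min(av[i, 1], bv[j, 1])
            if s <= e:
                total += int(e - s + 1)
            if av[i, 1] < bv[j, 1]:
                i += 1
            else:
                j += 1
    return total


def _overlaps_any(region, merged: dict[str, np.ndarray]) -> bool:
    chrom, s, e = region
    iv = merged.get(chrom)
    if iv is None:
        return False
    k = np.searchsorted(iv[:, 0], e, side="right")
    return bool(k > 0 and iv[:k, 1].max() >= s)


def cnvr_intersection(region_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Base-pair-resolution sharing of CNV regions between named sets.

    All sets must be on one coordinate system (liftover is upstream).  For
    each set, the bp covered by it alone (``unique_bp``) and by it and at
    least one other set (``shared_bp``) are reported, together with region
    counts under any-overlap counting.  ``unique_bp + shared_bp == total_bp``
    per set by construction.
    """
    merged = {name: _merge_intervals(df) for name, df in region_sets.items()}
    rows = []
    for name, df in region_sets.items():
        own = merged[name]
        others = [merged[o] for o in region_sets if o != name]
        if others:
            union_others = _merge_intervals(
                pd.concat(
                    [region_sets[o][["chrom", "start", "end"]] for o in region_sets if o != name],
                    ignore_index=True,
                )
            )
            shared = _intersect_bp(own, union_others)
            n_shared = sum(
                _overlaps_any((r.chrom, r.start, r.end), union_others)
                for r in df.itertuples(index=False)
            )
        else:
            shared, n_shared = 0, 0
        total = _total_bp(own)
        rows.append(
            {
                "set": name,
                "total_bp": total,
                "shared_bp": shared,
                "unique_bp": total - shared,
                "unique_fraction": (total - shared) / total if total else float("nan"),
                "n_regions": len(df),
                "n_regions_shared": n_shared,
            }
        )
    return pd.DataFrame(rows).set_index("set")
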