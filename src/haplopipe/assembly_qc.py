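"""Assembly QC: recombination-map order validation, breakpoint refinement, and
sequence-level checks (gap runs, telomeric repeats, satellite blocks, repeat
filtering).

Scaffold order is validated against a recombination map by checking that probe
coordinates on a scaffold are monotone in map rank, in whichever orientation
fits better.  One mismatched probe in any window of three consecutive
map-ordered probes is tolerated (isolated mis-mapped probes are expected from
mapping ambiguity); clustered violations count as errors.  A scaffold carrying
probes of more than one map chromosome is an inter-chromosomal fusion, and
every chromosome switch along the scaffold is one error at the junction.

Coordinates throughout this module are 1-based and closed on both ends
(recombination-map and RepeatMasker convention); BED conversion lives in
:mod:`haplopipe.io`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Recombination map types
# ---------------------------------------------------------------------------

@dataclass
class RecombMap:
    """Ordered probe list per chromosome: columns ``chromosome, rank, probe_id``."""

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if t["probe_id"].duplicated().any():
            raise ValueError("duplicate probe ids in recombination map")
        for chrom, grp in t.groupby("chromosome", sort=False):
            ranks = grp["rank"].to_numpy()
            if len(ranks) > 1 and not (np.diff(ranks) > 0).all():
                raise ValueError(f"map ranks not strictly increasing on {chrom}")

    def lookup(self) -> dict[str, tuple[str, int]]:
        """probe_id -> (chromosome, rank)."""
        return {
            r.probe_id: (r.chromosome, int(r.rank))
            for r in self.table.itertuples(index=False)
        }


@dataclass(frozen=True)
class ProbePlacement:
    """One recombination-map probe located on a scaffold (1-based coordinate)."""

    probe_id: str
    scaffold_id: str
    coordinate: int

    def __post_init__(self):
        if self.coordinate < 1:
            raise ValueError("placement coordinate must be >= 1")


# ---------------------------------------------------------------------------
# Order validation
# ---------------------------------------------------------------------------

def _run_cost(L: int, f: int, p: int, final: bool) -> tuple[int, int, int]:
    """Cost and new flags for a run of ``L`` consecutive deleted probes.

    ``f``: the run immediately before the current kept probe was non-empty.
    ``p``: that run was a singleton whose isolation still depends on this run.
    Isolated singleton deletions are free; every member of a cluster (two
    deleted probes within two map positions of each other) costs 1.
    """
    if L == 0:
        # empty run: a pending singleton on the left is isolated after all
        return 0, 0, 0
    if L == 1:
        add = 1 if p else 0  # pending singleton gains a neighbour two away
        if f:
            return add + 1, 1, 0  # left-adjacent run non-empty: charged now
        return add, 1, (0 if final else 1)  # isolation awaits the next run
    # L >= 2: every member of the cluster counts
    return L + (1 if p else 0), 1, 0


def _min_violations(x) -> tuple[int, list[int]]:
    """Minimum tolerated-error count to make ``x`` strictly increasing.

    Exact dynamic program over (last kept index, flags) minimizing the number
    of non-isolated deleted probes; O(n^2).  Returns the count and the
    0-based indices of the charged (non-isolated) deletions of one optimum.
    """
    n = len(x)
    if n <= 1:
        return 0, []
    # states[b] maps (f, p) -> (cost, parent (b', f', p'))
    states: dict[int, dict[tuple[int, int], tuple[int, tuple | None]]] = {
        -1: {(0, 0): (0, None)}
    }
    best_final: tuple[int, tuple | None] = (n + 1, None)
    for b in range(-1, n):
        if b not in states:
            continue
        xb = -np.inf if b == -1 else x[b]
        for (f, p), (cost, _) in list(states[b].items()):
            # close with the suffix run
            add, _, _ = _run_cost(n - 1 - b, f, p, final=True)
            if cost + add < best_final[0]:
                best_final = (cost + add, (b, f, p))
            for m in range(b + 1, n):
                if x[m] <= xb:
                    continue
                add, nf, np_ = _run_cost(m - b - 1, f, p, final=False)
                entry = states.setdefault(m, {})
                old = entry.get((nf, np_))
                if old is None or cost + add < old[0]:
                    entry[(nf, np_)] = (cost + add, (b, f, p))
    cost = best_final[0]
    # backtrack the kept set to report which deletions were charged
    kept = []
    key = best_final[1]
    while key is not None and key[0] != -1:
        b, f, p = key
        kept.append(b)
        key = states[b][(f, p)][1]
    deleted = sorted(set(range(n)) - set(kept))
    dset = set(deleted)
    charged = [i for i in deleted if any(j in dset for j in (i - 2, i - 1, i + 1, i + 2))]
    return cost, charged


@dataclass
class ScaffoldCheck:
    scaffold_id: str
    chromosomes: list[str]
    error_count: int
    error_probes: list[str]
    orientation: dict[str, str] = field(default_factory=dict)
    fusion_junctions: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class ValidationReport:
    per_scaffold: dict[str, ScaffoldCheck]

    @property
    def total_errors(self) -> int:
        return sum(c.error_count for c in self.per_scaffold.values())

    @property
    def error_probes(self) -> list[str]:
        out: list[str] = []
        for c in self.per_scaffold.values():
            out.extend(c.error_probes)
        return out


def validate_scaffold_order(
    rmap: RecombMap,
    placements: pd.DataFrame,
    window: int = 3,
    tolerance: int = 1,
) -> ValidationReport:
    """Check scaffold probe order against the recombination map.

    ``placements`` needs columns ``probe_id, scaffold_id, coordinate`` with
    one placement per probe (multi-mappers are dropped upstream).  Per
    scaffold and chromosome the orientation (coordinates increasing or
    decreasing with map rank) minimizing violations is chosen; an isolated
    out-of-order probe is forgiven, while two mismatches within any window of
    three consecutive map-ordered probes both count as errors.  Chromosome
    switches along a multi-chromosome scaffold each count as one fusion error.

    Only the published tolerance rule (window=3, tolerance=1) is supported.
    """
    if (window, tolerance) != (3, 1):
        raise NotImplementedError("only window=3, tolerance=1 is supported")
    lookup = rmap.lookup()
    missing = [p for p in placements["probe_id"] if p not in lookup]
    if missing:
        raise ValueError(f"placed probes absent from map: {missing[:5]}")
    if placements["probe_id"].duplicated().any():
        raise ValueError("multiple placements for one probe; deduplicate upstream")

    report: dict[str, ScaffoldCheck] = {}
    for scaffold_id, grp in placements.groupby("scaffold_id", sort=False):
        chroms = [lookup[p][0] for p in grp["probe_id"]]
        check = ScaffoldCheck(
            scaffold_id=str(scaffold_id),
            chromosomes=sorted(set(chroms)),
            error_count=0,
            error_probes=[],
        )
        # fusion detection: chromosome switches along the scaffold coordinate
        by_coord = grp.assign(_chrom=chroms).sort_values("coordinate")
        cseq = by_coord["_chrom"].tolist()
        pseq = by_coord["probe_id"].tolist()
        for i in range(len(cseq) - 1):
            if cseq[i] != cseq[i + 1]:
                check.fusion_junctions.append((pseq[i], pseq[i + 1]))
                check.error_count += 1
                check.error_probes.append(pseq[i + 1])
        # per-chromosome monotonicity with single-probe forgiveness
        for chrom, sub in by_coord.groupby("_chrom", sort=False):
            ordered = sub.assign(_rank=[lookup[p][1] for p in sub["probe_id"]]).sort_values(
                "_rank"
            )
            coords = ordered["coordinate"].to_numpy()
            ids = ordered["probe_id"].tolist()
            fwd, fwd_pos = _min_violations(coords)
            rev, rev_pos = _min_violations(-coords)
            if fwd <= rev:
                cost, pos, orient = fwd, fwd_pos, "+"
            else:
                cost, pos, orient = rev, rev_pos, "-"
            check.orientation[str(chrom)] = orient
            check.error_count += cost
            check.error_probes.extend(ids[i] for i in pos)
        report[str(scaffold_id)] = check
    return ValidationReport(per_scaffold=report)


# ---------------------------------------------------------------------------
# Breakpoint refinement
# ---------------------------------------------------------------------------

def refine_breakpoint(coverage, approx_pos: int, search_radius: int) -> int:
    """Move an approximate breakpoint to the local short-read coverage minimum.

    Optical-map breakpoints are imprecise; the refined position is the
    1-based position of minimum coverage within ``approx_pos +/- search_radius``
    (clipped to the array with a warning).  Ties break toward ``approx_pos``,
    then leftward.
    """
    coverage = np.asarray(coverage)
    n = len(coverage)
    if not (0 < approx_pos <= n):
        raise ValueError(f"approx_pos {approx_pos} outside coverage array of length {n}")
    if search_radius < 1:
        raise ValueError("search_radius must be >= 1")
    lo = approx_pos - search_radius
    hi = approx_pos + search_radius
    if lo < 1 or hi > n:
        log.warning("refine_breakpoint: window [%d, %d] clipped to [1, %d]", lo, hi, n)
        lo, hi = max(1, lo), min(n, hi)
    positions = np.arange(lo, hi + 1)
    window = coverage[lo - 1 : hi]
    order = sorted(
        range(len(window)),
        key=lambda i: (window[i], abs(int(positions[i]) - approx_pos), positions[i]),
    )
    return int(positions[order[0]])


# ---------------------------------------------------------------------------
# Gaps and telomeres
# ---------------------------------------------------------------------------

def count_gaps(sequence: str, min_run: int = 1) -> tuple[list[tuple[int, int]], int]:
    """Maximal N-runs of length >= ``min_run`` as 1-based closed intervals."""
    gaps = [
        (m.start() + 1, m.end())
        for m in re.finditer("[Nn]+", sequence)
        if m.end() - m.start() >= min_run
    ]
    return gaps, len(gaps)


def find_telomeres(
    sequence: str,
    motif: str = "TTAGGG",
    min_consecutive: int = 2,
    end_window: int = 1_000_000,
) -> tuple[bool, bool, list[tuple[int, int, str]]]:
    """Detect telomeric tandem repeat runs near the sequence ends.

    Both strands are searched for at least ``min_consecutive`` exact tandem
    copies of ``motif``.  An end is flagged when a qualifying run has its
    near boundary within ``end_window`` bp of that end (so that
    reverse-complementing the sequence swaps the two flags exactly).
    Returns ``(has_left, has_right, runs)`` with runs as
    ``(start, end, strand)`` in 1-based closed coordinates.
    """
    from .trio_binning import revcomp

    seq = sequence.upper()
    n = len(seq)
    runs: list[tuple[int, int, str]] = []
    for strand, m in (("+", motif.upper()), ("-", revcomp(motif.upper()))):
        pat = re.compile(f"(?:{re.escape(m)}){{{min_consecutive},}}")
        runs.extend((mt.start() + 1, mt.end(), strand) for mt in pat.finditer(seq))
    runs.sort()
    has_left = any(start - 1 <= end_window for start, _end, _s in runs)
    has_right = any(n - end <= end_window for _start, end, _s in runs)
    return has_left, has_right, runs


# ---------------------------------------------------------------------------
# Repeat tables
# ---------------------------------------------------------------------------

def satellite_blocks(
    repeats: pd.DataFrame,
    family_filter: str = "Satellite",
    merge_gap: int = 100,
) -> tuple[pd.DataFrame, int]:
    """Merge runs of same-family repeat units into blocks and count them.

    A centromeric satellite array is annotated as many consecutive repeat
    units; units of a family matching ``family_filter`` (prefix match) that
    are separated by at most ``merge_gap`` bp are scored as one block.
    ``repeats`` needs columns ``sequence_id, start, end, family``.
    Returns ``(blocks, count)`` with block spans and unit counts.
    """
    sel = repeats[repeats["family"].astype(str).str.startswith(family_filter)]
    rows = []
    for seq_id, grp in sel.groupby("sequence_id", sort=False):
        iv = grp[["start", "end"]].sort_values("start").to_numpy()
        if len(iv) == 0:
            continue
        cs, ce, units = int(iv[0, 0]), int(iv[0, 1]), 1
        for s, e in iv[1:]:
            if s - ce - 1 <= merge_gap:
                ce = max(ce, int(e))
                units += 1
            else:
                rows.append((seq_id, cs, ce, units))
                cs, ce, units = int(s), int(e), 1
        rows.append((seq_id, cs, ce, units))
    blocks = pd.DataFrame(rows, columns=["sequence_id", "start", "end", "n_units"])
    return blocks, len(blocks)


def centromere_proximity(
    blocks: pd.DataFrame,
    sequence_length: int,
    end_window: int = 100_000,
) -> tuple[bool, bool]:
    """Whether any satellite block overlaps either terminal ``end_window``."""
    if len(blocks) == 0:
        return False, False
    s = blocks["start"].to_numpy()
    e = blocks["end"].to_numpy()
    left = bool((s <= end_window).any())
    right = bool((e >= sequence_length - end_window + 1).any())
    return left, right


DEFAULT_MIN_LENGTH_BY_FAMILY = {"LINE": 2500, "Satellite": 10000}


def filter_repeats(
    repeats: pd.DataFrame,
    min_identity: float = 0.60,
    min_length_by_family: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Drop low-identity and short repeat annotations.

    Matches at identity <= ``min_identity`` are removed (the published rule
    filters repeats at <= 60% identity).  Per-family length gates follow the
    longest matching family prefix in ``min_length_by_family`` (defaults:
    LINE families > 2.5 kb, satellite/centromeric > 10 kb; other families
    unconstrained); intervals with span <= the gate are dropped.
    """
    gates = DEFAULT_MIN_LENGTH_BY_FAMILY if min_length_by_family is None else min_length_by_family

    def min_len(family: str) -> int:
        best = 0
        best_key_len = -1
        for key, val in gates.items():
            if family.startswith(key) and len(key) > best_key_len:
                best, best_key_len = val, len(key)
        return best

    lengths = repeats["end"] - repeats["start"] + 1
    keep = (repeats["identity"] > min_identity) & (
        lengths > repeats["family"].astype(str).map(min_len)
    )
    return repeats[keep].reset_index(drop=True)
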