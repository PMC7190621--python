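"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the data shapes of a trio-sequenced F1 hybrid study:
a diploid genome pair diverging by planted SNPs, error-bearing long reads of
known haplotype, Hi-C pair alignment summaries, windowed depth matrices for
two populations with planted per-gene copy numbers, FLNC transcript reads with
planted allelic ratios per tissue, and recombination-map probe placements with
injected order violations.  Every record id receives exactly one truth entry,
and every generator is deterministic given its parameters and seed.

The error model is substitution-only (no indels): every downstream statistic
in this package consumes base identity, marker hits, or allele strings, none
of which require indel realism.  Hi-C pair loci are sampled uniformly with no
contact-distance decay, since only the haplotype-scoring stage is tested here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly_qc import RecombMap
from .cnv_vst import CopyNumberMatrix

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_ALPH = "ACGT"


class ParameterError(ValueError):
    """A generator parameter is outside its documented range."""


@dataclass
class SimTruth:
    """Ground truth for one generated dataset.

    ``haplotype_of_read`` labels reads/pairs ("A"/"B" for genomic reads,
    "maternal"/"paternal" for FLNC reads); ``snp_positions`` holds 0-based
    ``(position, alleleA, alleleB)``; ``gene_copy_numbers`` is per individual
    per gene; ``allelic_ratio`` is the maternal-transcript fraction per gene
    per tissue; ``probe_truth`` records intended probe order and injected
    violations.  ``extra`` carries generator-specific detail (read intervals,
    per-pair SNP overlap, haplotype allele strings).
    """

    seed: int
    haplotype_of_read: dict = field(default_factory=dict)
    snp_positions: list = field(default_factory=list)
    gene_copy_numbers: dict = field(default_factory=dict)
    allelic_ratio: dict = field(default_factory=dict)
    probe_truth: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        for gene, per_tissue in self.allelic_ratio.items():
            for tissue, r in per_tissue.items():
                if not (0.0 <= r <= 1.0):
                    raise ValueError(f"allelic ratio {r} for {gene}/{tissue} outside [0,1]")
        for ind, genes in self.gene_copy_numbers.items():
            for gene, cn in genes.items():
                if cn < 0:
                    raise ValueError(f"negative copy number {cn} for {ind}/{gene}")

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "haplotype_of_read": self.haplotype_of_read,
            "snp_positions": self.snp_positions,
            "gene_copy_numbers": self.gene_copy_numbers,
            "allelic_ratio": self.allelic_ratio,
            "probe_truth": self.probe_truth,
            "extra": self.extra,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, default=_jsonable)
            fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(len(arr), 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        out[arr == b] = i
    if (out == 255).any():
        raise ParameterError("sequence contains non-ACGT characters")
    return out


def _substitute(codes: np.ndarray, rng: np.random.Generator, error_rate: float) -> np.ndarray:
    """Apply substitution errors in place-free fashion; returns a new array."""
    if error_rate == 0:
        return codes
    n_err = rng.binomial(len(codes), error_rate)
    if n_err == 0:
        return codes
    pos = rng.choice(len(codes), size=n_err, replace=False)
    shift = rng.integers(1, 4, size=n_err, dtype=np.uint8)
    out = codes.copy()
    out[pos] = (out[pos] + shift) % 4
    return out


# ---------------------------------------------------------------------------
# Diploid genome
# ---------------------------------------------------------------------------

def gen_diploid_genome(length_bp: int, snp_rate: float, seed: int):
    """A haplotype pair differing at Poisson(snp_rate * length) planted SNPs.

    Returns ``(seqA, seqB, truth)``; truth records each SNP as
    ``(0-based position, alleleA, alleleB)``.
    """
    if length_bp < 1000:
        raise ParameterError("length_bp must be >= 1000")
    if not (0.0 <= snp_rate <= 0.05):
        raise ParameterError("snp_rate must lie in [0, 0.05]")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, length_bp, dtype=np.uint8)
    n_snp = min(int(rng.poisson(snp_rate * length_bp)), length_bp)
    pos = np.sort(rng.choice(length_bp, size=n_snp, replace=False)) if n_snp else np.array([], int)
    codes_b = codes.copy()
    if n_snp:
        shift = rng.integers(1, 4, size=n_snp, dtype=np.uint8)
        codes_b[pos] = (codes_b[pos] + shift) % 4
    truth = SimTruth(
        seed=seed,
        snp_positions=[
            (int(p), _ALPH[codes[p]], _ALPH[codes_b[p]]) for p in pos
        ],
    )
    return _decode(codes), _decode(codes_b), truth


# ---------------------------------------------------------------------------
# Long reads
# ---------------------------------------------------------------------------

def gen_long_reads(
    seqA: str,
    seqB: str,
    n_reads: int,
    mean_len: int,
    error_rate: float,
    seed: int,
    length_sd: float | None = None,
):
    """Long reads drawn uniformly from the two haplotypes with substitution errors.

    Read lengths follow a normal around ``mean_len`` (sd defaults to 10% of
    the mean), clipped to the genome.  Returns ``(reads, truth)`` with reads
    as ``(read_id, sequence)``; truth labels each read "A"/"B" and records
    its 0-based half-open source interval in ``extra["read_intervals"]``.
    """
    if n_reads <= 0:
        raise ParameterError("n_reads must be > 0")
    if not (0.0 <= error_rate <= 0.2):
        raise ParameterError("error_rate must lie in [0, 0.2]")
    rng = np.random.default_rng(seed)
    arr = {"A": _encode(seqA), "B": _encode(seqB)}
    L = len(seqA)
    if length_sd is None:
        length_sd = 0.1 * mean_len
    lengths = np.clip(
        np.rint(rng.normal(mean_len, length_sd, n_reads)).astype(int), 50, L
    )
    haps = np.where(rng.integers(0, 2, n_reads) == 0, "A", "B")
    reads = []
    truth = SimTruth(seed=seed)
    intervals = {}
    for i in range(n_reads):
        rid = f"read_{i:05d}"
        ln = int(lengths[i])
        start = int(rng.integers(0, L - ln + 1))
        codes = _substitute(arr[haps[i]][start : start + ln], rng, error_rate)
        reads.append((rid, _decode(codes)))
        truth.haplotype_of_read[rid] = str(haps[i])
        intervals[rid] = (str(haps[i]), start, start + ln)
    truth.extra["read_intervals"] = intervals
    return reads, truth


# ---------------------------------------------------------------------------
# Hi-C pairs
# ---------------------------------------------------------------------------

def gen_hic_pairs(
    seqA: str,
    seqB: str,
    n_pairs: int,
    end_len: int,
    error_rate: float,
    seed: int,
    unmapped_rate: float = 0.0,
):
    """Hi-C pairs of known haplotype as a per-end alignment summary table.

    Each pair is sampled from one haplotype; its two end loci are uniform and
    independent (contact-distance decay is irrelevant to haplotype scoring).
    For every end and candidate haplotype the table reports
    ``(mapped, identity, match_length)`` where identity is the exact base
    identity of the (error-bearing) end sequence against that haplotype at
    the end's true locus.  Ends are flagged unmapped (on both haplotypes) at
    ``unmapped_rate``.  Truth records the pair haplotype and, in
    ``extra["pair_snp_overlap"]``, how many planted SNPs the pair's ends span.
    """
    if n_pairs <= 0:
        raise ParameterError("n_pairs must be > 0")
    if end_len < 36:
        raise ParameterError("end_len must be >= 36")
    if not (0.0 <= error_rate <= 0.2):
        raise ParameterError("error_rate must lie in [0, 0.2]")
    if not (0.0 <= unmapped_rate <= 1.0):
        raise ParameterError("unmapped_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    a, b = _encode(seqA), _encode(seqB)
    if len(a) != len(b):
        raise ParameterError("haplotypes must have equal length (substitution divergence)")
    L = len(a)
    snp_cum = np.concatenate([[0], np.cumsum(a != b)])  # SNPs in [i, j) = cum[j]-cum[i]
    rows = []
    truth = SimTruth(seed=seed)
    overlap = {}
    for i in range(n_pairs):
        pid = f"pair_{i:05d}"
        hap = "A" if rng.integers(0, 2) == 0 else "B"
        src = a if hap == "A" else b
        windows = []
        for end in (1, 2):
            start = int(rng.integers(0, L - end_len + 1))
            windows.append((start, start + end_len))
            end_codes = _substitute(src[start : start + end_len], rng, error_rate)
            mapped = bool(rng.random() >= unmapped_rate)
            id_a = float(np.mean(end_codes == a[start : start + end_len]))
            id_b = float(np.mean(end_codes == b[start : start + end_len]))
            rows.append((pid, end, "A", mapped, id_a if mapped else 0.0, end_len))
            rows.append((pid, end, "B", mapped, id_b if mapped else 0.0, end_len))
        truth.haplotype_of_read[pid] = hap
        (s1, e1), (s2, e2) = sorted(windows)
        n_snps = int(snp_cum[e1] - snp_cum[s1])
        s2_eff = max(s2, e1)  # avoid double-counting an overlap of the two ends
        n_snps += int(snp_cum[max(e2, s2_eff)] - snp_cum[s2_eff])
        overlap[pid] = n_snps
    truth.extra["pair_snp_overlap"] = overlap
    table = pd.DataFrame(
        rows, columns=["pair_id", "end", "haplotype", "mapped", "identity", "match_length"]
    )
    return table, truth


# ---------------------------------------------------------------------------
# Depth matrices
# ---------------------------------------------------------------------------

def make_gene_grid(
    n_genes: int,
    windows_per_gene: int = 5,
    gap_windows: int = 1,
    window_size: int = 1000,
) -> tuple[pd.DataFrame, int]:
    """Evenly spaced genes aligned to the window grid.

    Returns ``(gene_table, n_windows)`` where genes occupy
    ``windows_per_gene`` consecutive windows separated by ``gap_windows``
    background windows.
    """
    rows = []
    w = 0
    for g in range(n_genes):
        w += gap_windows
        start = w * window_size + 1
        end = (w + windows_per_gene) * window_size
        rows.append((f"gene_{g:04d}", "chr1", start, end))
        w += windows_per_gene
    w += gap_windows
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"]), w


def gen_depth_matrix(
    n_pop1: int,
    n_pop2: int,
    n_windows: int,
    gene_table: pd.DataFrame,
    cn_assignments: dict,
    noise_sd: float,
    seed: int,
    window_size: int = 1000,
    populations: tuple[str, str] = ("taurine", "indicine"),
):
    """Windowed depth levels for two populations with planted gene copy numbers.

    Background windows sit at the diploid level 1.0 plus Gaussian noise;
    windows fully inside a gene listed in ``cn_assignments``
    (``gene_id -> (cn_pop1, cn_pop2)``) sit at cn/2 plus noise.  Unlisted
    genes stay diploid.  Truth records every individual's copy number for
    every gene in ``gene_table``.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if n_pop1 < 1 or n_pop2 < 1 or n_windows < 1:
        raise ParameterError("population sizes and n_windows must be >= 1")
    for gid, (c1, c2) in cn_assignments.items():
        if c1 < 0 or c2 < 0:
            raise ParameterError(f"negative copy number planted for {gid}")
    rng = np.random.default_rng(seed)
    individuals = [f"{populations[0]}_{i:03d}" for i in range(n_pop1)] + [
        f"{populations[1]}_{i:03d}" for i in range(n_pop2)
    ]
    labels = [populations[0]] * n_pop1 + [populations[1]] * n_pop2
    starts = np.arange(n_windows) * window_size + 1
    windows = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + window_size - 1}
    )
    cn = np.full((len(individuals), n_windows), 2.0)
    truth = SimTruth(seed=seed)
    truth.gene_copy_numbers = {ind: {} for ind in individuals}
    for g in gene_table.itertuples(index=False):
        inside = (windows["chrom"] == g.chrom).to_numpy()
        inside &= (windows["start"].to_numpy() >= g.start) & (
            windows["end"].to_numpy() <= g.end
        )
        c1, c2 = cn_assignments.get(g.gene_id, (2, 2))
        for i, ind in enumerate(individuals):
            c = c1 if labels[i] == populations[0] else c2
            cn[i, inside] = float(c)
            truth.gene_copy_numbers[ind][g.gene_id] = int(c)
    levels = cn / 2.0 + rng.normal(0.0, noise_sd, cn.shape) if noise_sd > 0 else cn / 2.0
    levels = np.clip(levels, 0.0, None)
    cnm = CopyNumberMatrix(individuals, labels, windows, levels)
    return cnm, truth


# ---------------------------------------------------------------------------
# FLNC transcript reads
# ---------------------------------------------------------------------------

def make_snp_table(gene_ids, n_snps: int, seed: int) -> dict:
    """Random per-gene SNP tables: ``gene -> [(gene-local position, alleleM, alleleP)]``.

    Maternal and paternal alleles differ at every candidate position.
    """
    rng = np.random.default_rng(seed)
    table = {}
    for gid in gene_ids:
        rows = []
        for j in range(n_snps):
            m = int(rng.integers(0, 4))
            p = (m + int(rng.integers(1, 4))) % 4
            rows.append((j, _ALPH[m], _ALPH[p]))
        table[gid] = rows
    return table


def gen_flnc_reads(
    gene_models: dict,
    snp_table: dict,
    ratio_per_tissue,
    n_reads_per_tissue,
    error_rate: float,
    seed: int,
    missing_rate: float = 0.0,
):
    """FLNC reads per gene, isoform and tissue with planted allelic ratios.

    ``gene_models`` maps gene id -> list of isoform ids; ``snp_table`` maps
    gene id -> [(position, alleleM, alleleP)]; ``ratio_per_tissue`` is either
    ``{tissue: maternal_fraction}`` applied to all genes or
    ``{gene: {tissue: fraction}}``.  Each read carries its haplotype's allele
    string over the gene's candidate positions, with per-base substitution
    errors at ``error_rate`` and positions masked to ``-`` at
    ``missing_rate``.  Truth records the planted ratios, each read's
    haplotype, and the two haplotype strings per gene in
    ``extra["haplotype_strings"]``.
    """
    if not (0.0 <= error_rate <= 0.2):
        raise ParameterError("error_rate must lie in [0, 0.2]")
    if not (0.0 <= missing_rate <= 1.0):
        raise ParameterError("missing_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    first = next(iter(ratio_per_tissue.values()))
    per_gene = isinstance(first, dict)
    rows = []
    truth = SimTruth(seed=seed)
    truth.extra["haplotype_strings"] = {}
    for gid, isoforms in gene_models.items():
        snps = snp_table[gid]
        mat = "".join(s[1] for s in snps)
        pat = "".join(s[2] for s in snps)
        truth.extra["haplotype_strings"][gid] = (mat, pat)
        ratios = ratio_per_tissue[gid] if per_gene else ratio_per_tissue
        truth.allelic_ratio[gid] = {}
        for tissue, r in ratios.items():
            if not (0.0 <= r <= 1.0):
                raise ParameterError(f"allelic ratio {r} outside [0, 1]")
            n = (
                n_reads_per_tissue[tissue]
                if isinstance(n_reads_per_tissue, dict)
                else n_reads_per_tissue
            )
            if n <= 0:
                raise ParameterError("n_reads_per_tissue must be > 0")
            truth.allelic_ratio[gid][tissue] = float(r)
            for i in range(n):
                rid = f"{gid}_{tissue}_{i:05d}"
                maternal = bool(rng.random() < r)
                template = mat if maternal else pat
                bases = []
                for base in template:
                    if missing_rate and rng.random() < missing_rate:
                        bases.append("-")
                        continue
                    if error_rate and rng.random() < error_rate:
                        base = _ALPH[(_ALPH.index(base) + int(rng.integers(1, 4))) % 4]
                    bases.append(base)
                rows.append(
                    (
                        rid,
                        gid,
                        isoforms[int(rng.integers(0, len(isoforms)))],
                        tissue,
                        "".join(bases),
                    )
                )
                truth.haplotype_of_read[rid] = "maternal" if maternal else "paternal"
    table = pd.DataFrame(
        rows, columns=["read_id", "gene_id", "isoform_id", "tissue", "alleles"]
    )
    truth.validate()
    return table, truth


# ---------------------------------------------------------------------------
# Recombination-map probe cases
# ---------------------------------------------------------------------------

SCENARIOS = ("perfect", "single_transposition", "fusion", "reversal", "random_k_violations")


def gen_probe_case(n_probes: int, scenario: str, seed: int):
    """A recombination map plus probe placements for one validation scenario.

    Scenarios: ``perfect`` (placements monotone in map order),
    ``single_transposition`` (one probe displaced past its neighbour --
    forgivable), ``fusion`` (two map chromosomes concatenated on one
    scaffold), ``reversal`` (a block of >= 4 probes reversed), and
    ``random_k_violations`` (k isolated, forgivable transpositions).
    Returns ``(RecombMap, placements, truth)``.
    """
    if scenario not in SCENARIOS:
        raise ParameterError(f"unknown scenario {scenario!r}; pick one of {SCENARIOS}")
    if n_probes < 8:
        raise ParameterError("n_probes must be >= 8")
    rng = np.random.default_rng(seed)

    def chrom_coords(n):
        return 1000 + np.cumsum(rng.integers(1_000, 50_000, n))

    ids = [f"chr1_p{i:03d}" for i in range(n_probes)]
    map_rows = [("chr1", i + 1, pid) for i, pid in enumerate(ids)]
    coords = chrom_coords(n_probes)
    truth = SimTruth(seed=seed)
    truth.probe_truth = {"scenario": scenario, "violations": [], "map_order": list(ids)}

    if scenario == "single_transposition":
        i = int(rng.integers(1, n_probes - 3))
        coords = coords.copy()
        coords[i] = (coords[i + 1] + coords[i + 2]) // 2
        truth.probe_truth["violations"] = [ids[i]]
    elif scenario == "reversal":
        blen = min(max(4, n_probes // 5), n_probes - 2)
        s = int(rng.integers(1, n_probes - blen))
        coords = coords.copy()
        coords[s : s + blen] = coords[s : s + blen][::-1]
        truth.probe_truth["violations"] = ids[s : s + blen]
        truth.probe_truth["block"] = [int(s), int(s + blen)]
    elif scenario == "random_k_violations":
        k = max(1, n_probes // 10)
        candidates = np.arange(1, n_probes - 3)
        chosen: list[int] = []
        rng.shuffle(candidates)
        for c in candidates:
            if all(abs(c - x) > 4 for x in chosen):
                chosen.append(int(c))
            if len(chosen) == k:
                break
        coords = coords.copy()
        for i in sorted(chosen):
            coords[i] = (coords[i + 1] + coords[i + 2]) // 2
        truth.probe_truth["violations"] = [ids[i] for i in sorted(chosen)]

    placements = pd.DataFrame(
        {"probe_id": ids, "scaffold_id": "scaf1", "coordinate": coords.astype(int)}
    )

    if scenario == "fusion":
        ids2 = [f"chr2_p{i:03d}" for i in range(n_probes)]
        map_rows += [("chr2", i + 1, pid) for i, pid in enumerate(ids2)]
        offset = int(coords[-1]) + 10_000
        coords2 = offset + chrom_coords(n_probes)
        placements = pd.concat(
            [
                placements,
                pd.DataFrame(
                    {"probe_id": ids2, "scaffold_id": "scaf1", "coordinate": coords2.astype(int)}
                ),
            ],
            ignore_index=True,
        )
        truth.probe_truth["violations"] = [ids[-1], ids2[0]]
        truth.probe_truth["junction"] = (ids[-1], ids2[0])

    rmap = RecombMap(pd.DataFrame(map_rows, columns=["chromosome", "rank", "probe_id"]))
    return rmap, placements, truth
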