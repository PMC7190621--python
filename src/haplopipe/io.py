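"""Readers and writers for the on-disk formats used across the pipeline.

Coordinate convention: in memory, genomic intervals are 1-based and closed on
both ends, matching recombination-map probe tables and RepeatMasker output.
BED files are 0-based half-open on disk; the conversion happens here and
nowhere else.  Sequence-string indices (SNP positions inside a simulated
genome, read offsets) are plain 0-based Python indices.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """An input file violates its expected on-disk format."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{id: sequence}``.

    Sequences are uppercased on read (lowercase soft-masking is not
    meaningful to any downstream stage); an empty file yields an empty dict.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(1)
    if head and head != ">":
        raise FormatError(f"{path}:1: expected FASTA header line starting with '>'")
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        s = str(rec.seq)
        if any(c.islower() for c in s):
            log.info("read_fasta: lowercase bases in %r uppercased", rec.id)
            s = s.upper()
        seqs[rec.id] = s
    return seqs


def write_fasta(seqs, path, width: int = 80) -> None:
    """Write ``{id: sequence}`` (or an iterable of ``(id, sequence)``) as FASTA."""
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=str(name), description="") for name, s in items]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(records)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read BED (0-based half-open) into the internal 1-based closed convention.

    Returns a DataFrame with columns ``chrom, start, end, name`` (name may be
    empty).  ``start >= end`` on disk is a format error.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: fewer than 3 BED columns")
            try:
                chrom, s0, e0 = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer BED coordinate") from exc
            if s0 < 0 or s0 >= e0:
                raise FormatError(f"{path}:{ln}: invalid BED interval {s0}-{e0}")
            name = parts[3] if len(parts) > 3 else ""
            rows.append((chrom, s0 + 1, e0, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write internal 1-based closed intervals as a BED file (0-based half-open)."""
    cols = ["chrom", "start", "end"]
    out = intervals.copy()
    out["start"] = out["start"].astype(int) - 1
    out["end"] = out["end"].astype(int)
    if "name" in out.columns and out["name"].astype(str).str.len().gt(0).any():
        cols.append("name")
    out[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# VCF-lite
# ---------------------------------------------------------------------------

def read_vcf_lite(path) -> list[tuple[str, int, str, str]]:
    """Read a minimal VCF into ``[(chrom, pos, ref, alt), ...]``.

    INFO/FORMAT/sample columns are ignored; multi-allelic records are split
    into one entry per ALT allele.  Positions are 1-based as in VCF.
    """
    path = Path(path)
    snps: list[tuple[str, int, str, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{ln}: fewer than 5 VCF columns")
            chrom, pos, _id, ref, alt = parts[:5]
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer POS") from exc
            for a in alt.split(","):
                if a and a != ".":
                    snps.append((chrom, pos_i, ref, a))
    return snps


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, command: str, params: dict, seed, inputs=()) -> None:
    """Write a JSON run manifest: package version, config, seed, input digests.

    No timestamp is recorded so that reruns with identical configuration
    produce byte-identical output trees.
    """
    from . import __version__

    manifest = {
        "package": "haplopipe",
        "version": __version__,
        "command": command,
        "params": {k: _jsonable(v) for k, v in params.items()},
        "seed": seed,
        "inputs": {str(p): sha256_of(p) for p in inputs},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(v):
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
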