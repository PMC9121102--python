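"""Small-RNA read preparation: clean, filter, collapse, map, summarise.

Reads arrive pre-trimmed of sequencing adapters (vendor trimming is out of
scope); cleaning removes polyA tails (>= 8 terminal A by default), then
length-filters to 18-30 nt. The 19-25 nt subset feeds miRNA prediction.
Reads matching a supplied non-coding RNA set (tRNA/rRNA/snRNA/snoRNA) with
at most one mismatch on either strand are discarded. Unique sequences carry
per-library counts throughout; mapping to the genome is exact-match (miRNA
quantification uses exact reads) and reports all occurrences on both strands.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import iter_fastq, revcomp, write_fasta

logger = logging.getLogger(__name__)

__all__ = [
    "load_libraries",
    "clean_reads",
    "select_prediction_set",
    "filter_ncrna",
    "collapse_unique",
    "map_reads",
    "length_distribution",
    "write_collapsed_fasta",
]


def load_libraries(paths: dict[str, str | Path]) -> pd.DataFrame:
    """Read FASTQ libraries into a unique-sequence x library count matrix."""
    return collapse_unique(
        {lib: (seq for _t, seq in iter_fastq(p)) for lib, p in paths.items()}
    )


def collapse_unique(seqs_by_lib: dict) -> pd.DataFrame:
    """Collapse to unique sequences; column sums equal input read counts."""
    cols = {}
    for lib, seqs in seqs_by_lib.items():
        s = pd.Series(list(seqs), dtype="object")
        cols[lib] = s.value_counts() if len(s) else pd.Series(dtype="int64")
        if len(s) == 0:
            logger.warning("library %s is empty", lib)
    df = pd.DataFrame(cols).fillna(0).astype(np.int64)
    df.index.name = "seq"
    return df


def clean_reads(
    counts: pd.DataFrame,
    min_len: int = 18,
    max_len: int = 30,
    polya_min: int = 8,
) -> pd.DataFrame:
    """Trim >= ``polya_min`` terminal A, then keep lengths in [min_len, max_len]."""
    if len(counts) == 0:
        logger.warning("no reads to clean")
        return counts
    idx = counts.index.to_series()
    stripped = idx.str.replace("A+$", "", regex=True)
    n_tail = idx.str.len() - stripped.str.len()
    trimmed = stripped.where(n_tail >= polya_min, idx)
    out = counts.groupby(trimmed.to_numpy()).sum()
    lens = out.index.str.len()
    out = out[(lens >= min_len) & (lens <= max_len)]
    out.index.name = "seq"
    if (out.sum(axis=0) == 0).any():
        logger.warning("some libraries are empty after cleaning")
    return out


def select_prediction_set(counts: pd.DataFrame, min_len: int = 19, max_len: int = 25) -> pd.DataFrame:
    """The 19-25 nt clean reads used for miRNA prediction."""
    lens = counts.index.str.len()
    out = counts[(lens >= min_len) & (lens <= max_len)]
    if len(out) == 0:
        logger.warning("prediction set is empty")
    return out


def _one_mismatch_variants(seq: str):
    for i, c in enumerate(seq):
        for b in "ACGT":
            if b != c:
                yield seq[:i] + b + seq[i + 1 :]


def filter_ncrna(
    counts: pd.DataFrame,
    ncrna: dict[str, str],
    max_mm: int = 1,
    min_len: int = 18,
    max_len: int = 30,
) -> pd.DataFrame:
    """Drop reads aligning full-length, ungapped, to any ncRNA (either
    strand) with at most ``max_mm`` mismatches."""
    if not ncrna:
        raise ValueError("ncRNA reference set is empty")
    if max_mm <= 1:
        bad: set[str] = set()
        for seq in ncrna.values():
            for strand_seq in (seq.upper(), revcomp(seq.upper())):
                for L in range(min_len, min(max_len, len(strand_seq)) + 1):
                    for i in range(len(strand_seq) - L + 1):
                        sub = strand_seq[i : i + L]
                        bad.add(sub)
                        if max_mm == 1:
                            bad.update(_one_mismatch_variants(sub))
        keep = ~counts.index.isin(bad)
    else:  # small-input fallback: direct Hamming scan
        def hits(read: str) -> bool:
            for seq in ncrna.values():
                for s in (seq.upper(), revcomp(seq.upper())):
                    for i in range(len(s) - len(read) + 1):
                        if sum(a != b for a, b in zip(read, s[i : i + len(read)])) <= max_mm:
                            return True
            return False

        keep = ~counts.index.to_series().map(hits).to_numpy()
    return counts[keep]


def map_reads(
    seqs,
    genome: dict[str, str],
    max_mm: int = 0,
    k: int = 18,
) -> pd.DataFrame:
    """Exact-match alignments of unique sequences to both genome strands.

    Returns rows (seq, chrom, start, end, strand); ``start``/``end`` are
    0-based half-open plus-strand genome coordinates; minus-strand hits mean
    the reverse complement of the genome interval equals the read.
    """
    if max_mm != 0:
        return _map_reads_brute(seqs, genome, max_mm)
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in genome.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((chrom, i))
    rows = []
    for read in seqs:
        L = len(read)
        if L < k:
            logger.warning("read shorter than index k=%d skipped: %s", k, read)
            continue
        if L > max(len(s) for s in genome.values()):
            logger.warning("read longer than every chromosome skipped")
            continue
        for strand, query in (("+", read), ("-", revcomp(read))):
            for chrom, i in index.get(query[:k], ()):
                if genome[chrom][i : i + L] == query:
                    rows.append((read, chrom, i, i + L, strand))
    return pd.DataFrame(rows, columns=["seq", "chrom", "start", "end", "strand"])


def _map_reads_brute(seqs, genome, max_mm):
    rows = []
    for read in seqs:
        L = len(read)
        for strand in "+-":
            for chrom, gseq in genome.items():
                q = read if strand == "+" else revcomp(read)
                for i in range(len(gseq) - L + 1):
                    if sum(a != b for a, b in zip(q, gseq[i : i + L])) <= max_mm:
                        rows.append((read, chrom, i, i + L, strand))
    return pd.DataFrame(rows, columns=["seq", "chrom", "start", "end", "strand"])


def length_distribution(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Per-library read-length histograms.

    Returns (clean_hist, unique_hist, mode) where ``clean_hist`` weights each
    sequence by its read count, ``unique_hist`` counts each unique sequence
    once, and ``mode`` is the per-library modal length of the clean histogram
    (ties broken toward the smallest length).
    """
    lens = counts.index.str.len()
    clean = counts.groupby(lens.to_numpy()).sum()
    clean.index.name = "length"
    uniq = (counts > 0).groupby(lens.to_numpy()).sum()
    uniq.index.name = "length"
    mode = clean.idxmax(axis=0)  # idxmax returns the first (smallest) length
    return clean, uniq, mode


def write_collapsed_fasta(path: str | Path, counts: pd.DataFrame) -> None:
    """Collapsed FASTA with headers ``seq{i}_x{total count}``."""
    totals = counts.sum(axis=1)
    write_fasta(
        path,
        ((f"seq{i + 1}_x{int(c)}", s) for i, (s, c) in enumerate(totals.items())),
    )
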