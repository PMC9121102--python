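"""Expression quantification: miRNA RPM, transcript FPKM, pattern classes.

RPM counts reads anchored at annotated mature miRNA positions (same strand,
start and end each within ``max_shift`` nt) against the library's total
genome-mapped reads. FPKM is fragments / (kb of transcript x millions of
mapped fragments). Tissue-level matrices are replicate means; miRNAs are then
partitioned into four expression patterns by the 100/10 RPM cutoffs:
housekeeping (>= high in every tissue), tissue-specific (>= high in exactly
one), low (< low everywhere), intermediate (the rest).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "quantify_mirna_rpm",
    "quantify_fpkm",
    "average_by_tissue",
    "classify_patterns",
    "ddct",
    "write_matrix",
    "read_matrix",
]


def quantify_mirna_rpm(
    alignments: pd.DataFrame,
    counts: pd.DataFrame,
    loci: pd.DataFrame,
    totals: pd.Series,
    max_shift: int = 2,
) -> pd.DataFrame:
    """RPM per annotated mature miRNA per library.

    Parameters
    ----------
    alignments : rows (seq, chrom, start, end, strand) of unique-read hits.
    counts : unique sequence x library count matrix.
    loci : annotated loci with mature coordinates (locus_id, chrom, strand,
        mature_start, mature_end).
    totals : total genome-mapped reads per library (the RPM denominator).
    max_shift : maximum start/end offset (inclusive) for a read to count as
        the mature miRNA.
    """
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero mapped reads in libraries {bad}; RPM undefined")
    out = pd.DataFrame(0.0, index=loci["locus_id"], columns=totals.index)
    if len(alignments) == 0:
        return out
    aln = alignments
    for _, loc in loci.iterrows():
        sel = aln[
            (aln["chrom"] == loc["chrom"])
            & (aln["strand"] == loc["strand"])
            & (aln["start"] - loc["mature_start"]).abs().le(max_shift)
            & (aln["end"] - loc["mature_end"]).abs().le(max_shift)
        ]
        if len(sel):
            c = counts.loc[sel["seq"].unique()].sum(axis=0)
            out.loc[loc["locus_id"]] = c
    return out.div(totals, axis=1) * 1e6


def quantify_fpkm(
    counts: pd.DataFrame, lengths: pd.Series, totals: pd.Series | None = None
) -> pd.DataFrame:
    """FPKM = count / (length_kb x total_fragments_millions)."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all transcripts need a positive length for FPKM")
    if totals is None:
        totals = counts.sum(axis=0)
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


def average_by_tissue(matrix: pd.DataFrame, samples: pd.DataFrame,
                      tissues: list[str] | None = None) -> pd.DataFrame:
    """Arithmetic replicate mean per tissue; columns ordered as ``tissues``."""
    lib_tissue = samples.set_index("lib_id")["tissue"]
    if tissues is None:
        tissues = list(dict.fromkeys(lib_tissue))
    missing = [t for t in tissues if t not in set(lib_tissue)]
    if missing:
        raise ValueError(f"no replicates for tissues {missing}")
    grouped = matrix.T.groupby(lib_tissue.reindex(matrix.columns)).mean().T
    return grouped[tissues]


def classify_patterns(
    tissue_matrix: pd.DataFrame, high_cut: float = 100.0, low_cut: float = 10.0
) -> pd.DataFrame:
    """Partition miRNAs into the four expression patterns (see module doc)."""
    vals = tissue_matrix.to_numpy(dtype=float)
    n_high = (vals >= high_cut).sum(axis=1)
    all_low = (vals < low_cut).all(axis=1)
    cls = np.where(
        n_high == vals.shape[1], "housekeeping",
        np.where(n_high == 1, "tissue_specific",
                 np.where(all_low, "low", "intermediate")),
    )
    peak = tissue_matrix.columns.to_numpy()[np.argmax(vals, axis=1)]
    return pd.DataFrame(
        {
            "pattern_class": cls,
            "peak_tissue": np.where(cls == "tissue_specific", peak, ""),
        },
        index=tissue_matrix.index,
    )


def ddct(ct_target: float, ct_ref: float, ct_target_cal: float, ct_ref_cal: float) -> float:
    """Relative expression by the 2^-ddCt method."""
    ddct_val = (ct_target - ct_ref) - (ct_target_cal - ct_ref_cal)
    return float(2.0 ** (-ddct_val))


# --------------------------------------------------------------------------
# matrix I/O: TSV with a two-line header (library ids, then tissue labels)
# --------------------------------------------------------------------------

def write_matrix(path: str | Path, matrix: pd.DataFrame, samples: pd.DataFrame) -> None:
    tissue = samples.set_index("lib_id")["tissue"].reindex(matrix.columns)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(map(str, matrix.columns)) + "\n")
        fh.write("tissue\t" + "\t".join(tissue.astype(str)) + "\n")
    matrix.to_csv(path, sep="\t", header=False, mode="a", float_format="%.6g")


def read_matrix(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a two-line-header matrix; returns (matrix, samples)."""
    with open(path) as fh:
        libs = fh.readline().rstrip("\n").split("\t")[1:]
        tissues = fh.readline().rstrip("\n").split("\t")[1:]
    mat = pd.read_csv(path, sep="\t", skiprows=2, header=None, index_col=0)
    mat.index.name = "id"
    mat.columns = libs
    reps: dict[str, int] = {}
    rows = []
    for lib, t in zip(libs, tissues):
        reps[t] = reps.get(t, 0) + 1
        rows.append({"lib_id": lib, "tissue": t, "replicate": reps[t]})
    return mat, pd.DataFrame(rows)
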