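"""Expression-correlation and enrichment statistics.

Pearson correlation between tissue-averaged miRNA and target profiles with a
Student t-test on n-2 degrees of freedom (n = 7 tissues); the summary of
interest is the fraction of miRNA-target pairs with r < 0. Annotation-term
enrichment is the upper-tail hypergeometric probability (equivalently a
one-sided Fisher exact test) with optional Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["correlate_pairs", "negative_fraction", "enrich"]


def correlate_pairs(
    mirna_tissue: pd.DataFrame,
    target_tissue: pd.DataFrame,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson r and two-sided p per (mirna_id, transcript_id) pair.

    Both matrices must share an identical tissue column ordering. Pairs with
    a constant profile on either side get ``defined = False`` and are
    excluded from downstream summaries.
    """
    if list(mirna_tissue.columns) != list(target_tissue.columns):
        raise ValueError("tissue column ordering differs between matrices")
    rows = []
    for _, p in pairs.iterrows():
        mid, tid = p["mirna_id"], p["transcript_id"]
        if mid not in mirna_tissue.index or tid not in target_tissue.index:
            continue
        x = mirna_tissue.loc[mid].to_numpy(dtype=float)
        y = target_tissue.loc[tid].to_numpy(dtype=float)
        n = len(x)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"mirna_id": mid, "transcript_id": tid, "r": np.nan,
                         "t": np.nan, "p": np.nan, "n": n, "defined": False})
            continue
        r, pval = sps.pearsonr(x, y)
        t = r * np.sqrt((n - 2) / (1 - r**2)) if abs(r) < 1 else np.inf * np.sign(r)
        rows.append({"mirna_id": mid, "transcript_id": tid, "r": float(r),
                     "t": float(t), "p": float(pval), "n": n, "defined": True})
    return pd.DataFrame(
        rows, columns=["mirna_id", "transcript_id", "r", "t", "p", "n", "defined"]
    )


def negative_fraction(records: pd.DataFrame) -> tuple[float, int, int]:
    """(fraction with r < 0, negative count, defined count)."""
    defined = records[records["defined"].astype(bool)]
    if len(defined) == 0:
        raise ValueError("no defined correlation records")
    neg = int((defined["r"] < 0).sum())
    return neg / len(defined), neg, len(defined)


def enrich(
    selection: set[str],
    term_genes: dict[str, set[str]],
    universe: set[str],
    adjust: bool = True,
) -> pd.DataFrame:
    """Hypergeometric (one-sided Fisher) enrichment per term.

    p = P[X >= k] with X ~ Hypergeom(N=|universe|, K=|term|, n=|selection|).
    Terms with no overlap are omitted; BH-adjusted p is computed over the
    reported terms when ``adjust``.
    """
    stray = selection - universe
    if stray:
        raise ValueError(f"selection genes outside the universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(selection)
    rows = []
    for term, genes in term_genes.items():
        g = genes & universe
        k = len(g & selection)
        if k == 0:
            continue
        K = len(g)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": N, "p_hyper": p})
    df = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p_hyper"])
    if adjust and len(df):
        df = df.sort_values("p_hyper").reset_index(drop=True)
        m = len(df)
        raw = df["p_hyper"].to_numpy() * m / (np.arange(m) + 1)
        df["p_adj"] = np.minimum.accumulate(raw[::-1])[::-1].clip(max=1.0)
    return df
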