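"""High-confidence miRNA locus annotation from mapped small-RNA reads.

Implements the current plant miRNA annotation checklist on candidate hairpin
windows excised around read stacks:

* the mature:star duplex has at most 5 mismatched mature bases,
* asymmetric internal loops/bulges are at most 3 nt,
* the precursor spans at most 300 nt,
* the duplex shows 2-nt 3' overhangs (the star arm is placed accordingly),
* the mature read is 19-25 nt (20-24 flagged high-confidence length),
* star reads exist at the predicted star coordinates (+-1 nt), and
* precision (fraction of locus reads from the mature + star positions)
  is at least 0.75.

Candidates are seeded from abundant unique reads; windows whose read
composition cannot possibly reach the precision threshold are rejected
before folding (an upper bound, so no passing locus is ever lost).
Conservation is classified against a reference mature catalogue with species
and lineage tags; families are inherited from the catalogue or grouped by
single-linkage among novel matures; genomic clusters and synteny-block
anchoring follow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median_low

import numpy as np
import pandas as pd

from .fold import fold as nussinov_fold
from .fold import pair_table
from .seqio import revcomp, to_rna

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationConfig",
    "CriteriaReport",
    "extract_candidate_precursors",
    "evaluate_criteria",
    "annotate_loci",
    "classify_conservation",
    "assign_family",
    "assign_ids",
    "detect_clusters",
    "anchor_synteny",
    "parse_catalogue",
    "loci_to_gff3",
]

_CRITERIA_ORDER = [
    "duplex_mismatches", "asym_bulge", "precursor_len", "mature_len", "star", "precision",
]


@dataclass
class AnnotationConfig:
    flank: int = 250
    max_precursor: int = 300
    max_duplex_mismatches: int = 5
    max_asym_bulge: int = 3
    min_precision: float = 0.75
    min_star_reads: int = 1
    star_tol: int = 1
    mature_len: tuple[int, int] = (19, 25)
    hc_len: tuple[int, int] = (20, 24)
    min_stack_count: int = 3
    merge_dist: int = 100
    id_prefix: str = "Sit"


@dataclass
class CriteriaReport:
    duplex_mismatches: int = 0
    max_asym_bulge: int = 0
    overhang_3p: tuple[int, int] = (2, 2)
    precursor_len: int = 0
    mature_len: int = 0
    precision: float = 0.0
    star_read_count: int = 0
    checks: dict = field(default_factory=dict)
    passed: bool = False
    first_fail: str = ""


# --------------------------------------------------------------------------
# candidate extraction
# --------------------------------------------------------------------------

def extract_candidate_precursors(
    alignments: pd.DataFrame,
    counts: pd.Series,
    genome: dict[str, str],
    config: AnnotationConfig | None = None,
) -> list[dict]:
    """Excise candidate precursor windows around abundant read stacks.

    ``alignments`` are prediction-set (19-25 nt) hits; ``counts`` maps unique
    sequence to pooled read count. One window per seed cluster: seeds are
    unique reads with pooled count >= ``min_stack_count``; seeds within
    ``merge_dist`` on one strand merge, anchored at the most abundant seed;
    windows extend ``flank`` nt each side and are clipped at chromosome ends
    (minus-strand windows are reverse-complemented).
    """
    cfg = config or AnnotationConfig()
    aln = alignments.copy()
    aln["count"] = counts.reindex(aln["seq"]).to_numpy()
    seeds = aln[aln["count"] >= cfg.min_stack_count]
    windows: list[dict] = []
    for (chrom, strand), grp in seeds.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values(["start", "end", "seq"])
        starts = grp["start"].to_numpy()
        cluster_break = np.concatenate(([True], np.diff(starts) > cfg.merge_dist))
        cluster_id = np.cumsum(cluster_break)
        for _, cl in grp.groupby(cluster_id):
            peak = cl.sort_values(["count", "start"], ascending=[False, True]).iloc[0]
            ws = max(0, int(peak["start"]) - cfg.flank)
            we = min(len(genome[chrom]), int(peak["end"]) + cfg.flank)
            seq = genome[chrom][ws:we]
            if strand == "-":
                seq = revcomp(seq)
            windows.append(
                {
                    "chrom": chrom,
                    "strand": strand,
                    "start": ws,
                    "end": we,
                    "seq": to_rna(seq),
                    "peak_start": int(peak["start"]),
                    "peak_end": int(peak["end"]),
                }
            )
    return windows


def _precision_upper_bound(reads: pd.DataFrame) -> float:
    """Upper bound on attainable precision: the two largest read-position
    groups (mature candidate +-2 and any other group +-2) over all reads."""
    if len(reads) == 0:
        return 0.0
    counts = reads["count"].to_numpy(dtype=float)
    ws = reads["ws"].to_numpy()
    total = counts.sum()
    peak = ws[int(np.argmax(counts))]
    m_mask = np.abs(ws - peak) <= 2
    m = counts[m_mask].sum()
    rest = counts[~m_mask]
    s = 0.0
    if rest.size:
        o_ws = ws[~m_mask][int(np.argmax(rest))]
        s = counts[~m_mask][np.abs(ws[~m_mask] - o_ws) <= 2].sum()
    return float((m + s) / total)


# --------------------------------------------------------------------------
# criteria evaluation
# --------------------------------------------------------------------------

def evaluate_criteria(
    window: dict,
    structure: str,
    reads: pd.DataFrame,
    config: AnnotationConfig | None = None,
) -> tuple[CriteriaReport, dict | None]:
    """Apply the annotation checklist to a folded window.

    ``reads`` must be in window coordinates (columns seq, ws, we, count; see
    :func:`_window_reads`). Returns the criteria report and, when all checks
    pass, the locus record (window + precursor/mature/star geometry).
    """
    cfg = config or AnnotationConfig()
    if len(structure) != len(window["seq"]):
        raise ValueError("structure length does not match window length")
    rep = CriteriaReport()
    if len(reads) == 0:
        rep.first_fail = "star"
        return rep, None
    reads = reads.sort_values(["count", "ws"], ascending=[False, True])
    mature = reads.iloc[0]
    ms, me = int(mature["ws"]), int(mature["we"])
    rep.mature_len = me - ms

    pt = pair_table(structure)
    duplex_hi = me - 2  # mature 3' 2-nt overhang is outside the duplex
    paired = [(i, int(pt[i])) for i in range(ms, duplex_hi) if pt[i] >= 0]
    rep.duplex_mismatches = (duplex_hi - ms) - len(paired)
    asym = 0
    for (i1, j1), (i2, j2) in zip(paired, paired[1:]):
        gm = i2 - i1 - 1
        gs = abs(j1 - j2) - 1
        asym = max(asym, abs(gm - gs))
    rep.max_asym_bulge = asym

    star_found = bool(paired)
    ss = se = -1
    if star_found:
        ss = median_low([j - (duplex_hi - 1 - i) for i, j in paired])
        se = median_low([j + (i - ms) for i, j in paired]) + 3
        ss, se = min(ss, se - 1), max(se, ss + 1)
    pstart, pend = (min(ms, ss), max(me, se)) if star_found else (ms, me)
    rep.precursor_len = pend - pstart

    ws_arr = reads["ws"].to_numpy()
    we_arr = reads["we"].to_numpy()
    cnt = reads["count"].to_numpy(dtype=float)
    star_mask = np.zeros(len(reads), dtype=bool)
    if star_found:
        star_mask = (np.abs(ws_arr - ss) <= cfg.star_tol) & (np.abs(we_arr - se) <= cfg.star_tol)
    rep.star_read_count = int(cnt[star_mask].sum())
    mature_mask = (np.abs(ws_arr - ms) <= 2) & (np.abs(we_arr - me) <= 2)
    locus_mask = (we_arr > pstart) & (ws_arr < pend)
    star_grp = (np.abs(ws_arr - ss) <= 2) & (np.abs(we_arr - se) <= 2) if star_found else star_mask
    total = cnt[locus_mask].sum()
    rep.precision = float(cnt[mature_mask | star_grp].sum() / total) if total else 0.0

    rep.checks = {
        "duplex_mismatches": rep.duplex_mismatches <= cfg.max_duplex_mismatches,
        "asym_bulge": rep.max_asym_bulge <= cfg.max_asym_bulge,
        "precursor_len": rep.precursor_len <= cfg.max_precursor,
        "mature_len": cfg.mature_len[0] <= rep.mature_len <= cfg.mature_len[1],
        "star": star_found and rep.star_read_count >= cfg.min_star_reads,
        "precision": rep.precision >= cfg.min_precision,
    }
    rep.passed = all(rep.checks.values())
    rep.first_fail = next((c for c in _CRITERIA_ORDER if not rep.checks[c]), "")
    if not rep.passed:
        return rep, None

    locus = {
        "chrom": window["chrom"],
        "strand": window["strand"],
        "w_precursor": (pstart, pend),
        "w_mature": (ms, me),
        "w_star": (ss, se),
        "mature_seq": window["seq"][ms:me],
        "star_seq": window["seq"][ss:se],
        "structure": structure[pstart:pend],
        "precursor_seq": window["seq"][pstart:pend],
        "hc_length": cfg.hc_len[0] <= rep.mature_len <= cfg.hc_len[1],
    }
    return rep, locus


def _to_genome(window: dict, a: int, b: int) -> tuple[int, int]:
    if window["strand"] == "+":
        return window["start"] + a, window["start"] + b
    return window["end"] - b, window["end"] - a


def annotate_loci(
    alignments: pd.DataFrame,
    counts: pd.DataFrame | pd.Series,
    genome: dict[str, str],
    config: AnnotationConfig | None = None,
    folder=nussinov_fold,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run extraction, folding and criteria evaluation over the genome.

    Returns (loci, rejected): ``loci`` rows describe passing loci in genome
    coordinates; ``rejected`` records each evaluated-but-failed window with
    its first failing criterion.
    """
    cfg = config or AnnotationConfig()
    pooled = counts.sum(axis=1) if isinstance(counts, pd.DataFrame) else counts
    windows = extract_candidate_precursors(alignments, pooled, genome, cfg)
    # sorted per-strand arrays make per-window read lookup O(log n)
    arrays: dict[tuple, tuple] = {}
    aln_counts = pooled.reindex(alignments["seq"]).to_numpy(dtype=float)
    for (chrom, strand), grp_idx in alignments.groupby(["chrom", "strand"]).indices.items():
        order = grp_idx[np.argsort(alignments["start"].to_numpy()[grp_idx], kind="stable")]
        arrays[(chrom, strand)] = (
            alignments["start"].to_numpy()[order],
            alignments["end"].to_numpy()[order],
            aln_counts[order],
            alignments["seq"].to_numpy()[order],
        )
    loci_rows, rej_rows = [], []
    seen = set()
    for w in windows:
        starts, ends, cnts, seqs = arrays.get((w["chrom"], w["strand"]), (None,) * 4)
        if starts is None:
            continue
        lo = np.searchsorted(starts, w["start"], side="left")
        hi = np.searchsorted(starts, w["end"], side="left")
        inside = ends[lo:hi] <= w["end"]
        g_starts, g_ends = starts[lo:hi][inside], ends[lo:hi][inside]
        g_cnts, g_seqs = cnts[lo:hi][inside], seqs[lo:hi][inside]
        if w["strand"] == "+":
            ws_arr, we_arr = g_starts - w["start"], g_ends - w["start"]
        else:
            ws_arr, we_arr = w["end"] - g_ends, w["end"] - g_starts
        reads = pd.DataFrame(
            {"seq": g_seqs, "ws": ws_arr, "we": we_arr, "count": g_cnts}
        )
        if _precision_upper_bound(reads) < cfg.min_precision:
            rej_rows.append(
                {"chrom": w["chrom"], "strand": w["strand"], "start": w["start"],
                 "end": w["end"], "first_fail": "precision"}
            )
            continue
        structure = folder(w["seq"])
        rep, locus = evaluate_criteria(w, structure, reads, cfg)
        if locus is None:
            rej_rows.append(
                {"chrom": w["chrom"], "strand": w["strand"], "start": w["start"],
                 "end": w["end"], "first_fail": rep.first_fail}
            )
            continue
        ms, me = _to_genome(w, *locus["w_mature"])
        key = (w["chrom"], w["strand"], ms, me)
        if key in seen:
            continue
        seen.add(key)
        ps, pe = _to_genome(w, *locus["w_precursor"])
        ss, se = _to_genome(w, *locus["w_star"])
        loci_rows.append(
            {
                "chrom": w["chrom"],
                "strand": w["strand"],
                "precursor_start": ps,
                "precursor_end": pe,
                "mature_start": ms,
                "mature_end": me,
                "star_start": ss,
                "star_end": se,
                "mature_seq": locus["mature_seq"],
                "star_seq": locus["star_seq"],
                "precursor_seq": locus["precursor_seq"],
                "structure": locus["structure"],
                "hc_length": locus["hc_length"],
                "duplex_mismatches": rep.duplex_mismatches,
                "max_asym_bulge": rep.max_asym_bulge,
                "precursor_len": rep.precursor_len,
                "precision": rep.precision,
                "star_read_count": rep.star_read_count,
            }
        )
    loci = pd.DataFrame(loci_rows)
    if len(loci):
        loci = loci.sort_values(["chrom", "precursor_start"]).reset_index(drop=True)
    return loci, pd.DataFrame(rej_rows)


# --------------------------------------------------------------------------
# conservation, families, ids
# --------------------------------------------------------------------------

def parse_catalogue(records: list[tuple[str, str, str]]) -> pd.DataFrame:
    """Catalogue FASTA records (id, description, seq) -> tidy table."""
    rows = []
    for rid, desc, seq in records:
        attrs = dict(
            f.split("=", 1) for f in desc.split() if "=" in f
        )
        if "lineage" not in attrs:
            raise ValueError(f"catalogue entry {rid} lacks a lineage tag")
        rows.append(
            {
                "ref_id": rid,
                "species": attrs.get("species", rid.split("-")[0]),
                "lineage": attrs["lineage"],
                "family": attrs.get("family", rid.split("-", 1)[-1]),
                "seq": to_rna(seq),
            }
        )
    return pd.DataFrame(rows)


def _shifted_mismatches(a: str, b: str, max_shift: int = 2) -> int:
    """Minimum mismatch count over end shifts up to ``max_shift`` nt."""
    best = len(a) + len(b)
    for shift in range(-max_shift, max_shift + 1):
        if shift >= 0:
            ov = min(len(a) - shift, len(b))
            mm = sum(a[shift + i] != b[i] for i in range(ov))
        else:
            ov = min(len(a), len(b) + shift)
            mm = sum(a[i] != b[-shift + i] for i in range(ov))
        if ov >= max(len(a), len(b)) - abs(shift) - max_shift:
            best = min(best, mm)
    return best


def classify_conservation(
    mature_seq: str,
    catalogue: pd.DataFrame,
    max_mm: int = 2,
    max_shift: int = 2,
) -> tuple[str, str]:
    """(conservation_class, best-hit family) for one mature sequence.

    Hits in any non-Poaceae species -> conserved; hits restricted to Poaceae
    -> poaceae_specific; no hit within ``max_mm`` mismatches (allowing
    <= ``max_shift``-nt terminal shifts) -> species_specific.
    """
    q = to_rna(mature_seq)
    hits = []
    for _, row in catalogue.iterrows():
        mm = _shifted_mismatches(q, row["seq"], max_shift)
        if mm <= max_mm:
            hits.append((mm, row["lineage"], row["family"]))
    if not hits:
        return "species_specific", ""
    hits.sort()
    if any(lineage != "Poaceae" for _mm, lineage, _f in hits):
        return "conserved", hits[0][2]
    return "poaceae_specific", hits[0][2]


def assign_family(
    loci: pd.DataFrame, catalogue: pd.DataFrame, max_mm: int = 2
) -> pd.DataFrame:
    """Attach conservation class and family labels to annotated loci.

    Catalogued matures inherit the reference family; unmatched loci group by
    single-linkage at <= ``max_mm`` mismatches among themselves and receive
    miRN0001... family names in genomic order.
    """
    loci = loci.copy()
    cons, fams = [], []
    for seq in loci["mature_seq"]:
        c, f = classify_conservation(seq, catalogue, max_mm=max_mm)
        cons.append(c)
        fams.append(f)
    loci["conservation_class"] = cons
    loci["family"] = fams

    novel = loci.index[loci["family"] == ""].tolist()
    parent = {i: i for i in novel}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ai in range(len(novel)):
        for bi in range(ai + 1, len(novel)):
            a, b = novel[ai], novel[bi]
            if _shifted_mismatches(loci.at[a, "mature_seq"], loci.at[b, "mature_seq"]) <= max_mm:
                parent[find(a)] = find(b)
    groups: dict[int, list[int]] = {}
    for i in novel:
        groups.setdefault(find(i), []).append(i)
    ordered = sorted(groups.values(), key=lambda g: min(g))
    for n, members in enumerate(ordered, start=1):
        for i in members:
            loci.at[i, "family"] = f"miRN{n:04d}"
    return loci


def assign_ids(loci: pd.DataFrame, prefix: str = "Sit") -> pd.DataFrame:
    """Stable ids: ``{prefix}-{family}{letter}`` in genomic order per family."""
    loci = loci.sort_values(["chrom", "precursor_start"]).reset_index(drop=True)
    ids = [""] * len(loci)
    for fam, grp in loci.groupby("family", sort=False):
        multi = len(grp) > 1
        for k, i in enumerate(grp.index):
            suffix = chr(ord("a") + k) if multi else ""
            ids[i] = f"{prefix}-{fam}{suffix}"
    loci["locus_id"] = ids
    return loci


# --------------------------------------------------------------------------
# clusters and synteny
# --------------------------------------------------------------------------

def detect_clusters(loci: pd.DataFrame, max_gap: int = 10_000) -> pd.DataFrame:
    """Chain loci whose consecutive start-to-start distance is < ``max_gap``
    (strict); report clusters with >= 2 members."""
    rows = []
    n = 0
    for chrom, grp in loci.groupby("chrom", sort=True):
        grp = grp.sort_values("precursor_start")
        members: list[str] = []
        last = None
        for _, r in grp.iterrows():
            if last is not None and r["precursor_start"] - last < max_gap:
                members.append(r["locus_id"])
            else:
                if len(members) >= 2:
                    n += 1
                    rows.append({"cluster_id": f"C{n:02d}", "chrom": chrom,
                                 "members": ",".join(members), "n": len(members)})
                members = [r["locus_id"]]
            last = r["precursor_start"]
        if len(members) >= 2:
            n += 1
            rows.append({"cluster_id": f"C{n:02d}", "chrom": chrom,
                         "members": ",".join(members), "n": len(members)})
    return pd.DataFrame(rows, columns=["cluster_id", "chrom", "members", "n"])


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def anchor_synteny(loci: pd.DataFrame, blocks: pd.DataFrame) -> pd.DataFrame:
    """Anchor loci into collinearity block pairs; mark syntenic family pairs.

    A locus anchors to a block side when its precursor overlaps it by >= 1 bp;
    two same-family loci anchored to the two sides of one block pair are a
    syntenic pair.
    """
    req = {"block_id", "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"}
    missing = req - set(blocks.columns)
    if missing:
        raise ValueError(f"synteny block table lacks columns {sorted(missing)}")
    anchors = []
    for _, loc in loci.iterrows():
        for _, blk in blocks.iterrows():
            for side in ("a", "b"):
                if loc["chrom"] == blk[f"chrom_{side}"] and _overlaps(
                    loc["precursor_start"], loc["precursor_end"],
                    int(blk[f"start_{side}"]), int(blk[f"end_{side}"]),
                ):
                    anchors.append(
                        {"locus_id": loc["locus_id"], "family": loc["family"],
                         "block_id": blk["block_id"], "side": side}
                    )
    df = pd.DataFrame(anchors, columns=["locus_id", "family", "block_id", "side"])
    df["partner_locus_id"] = ""
    df["syntenic_pair"] = False
    for (block, fam), grp in df.groupby(["block_id", "family"]):
        sides = set(grp["side"])
        if sides == {"a", "b"}:
            a_ids = grp.loc[grp["side"] == "a", "locus_id"]
            b_ids = grp.loc[grp["side"] == "b", "locus_id"]
            for ai, bi in zip(a_ids, b_ids):
                df.loc[(df["locus_id"] == ai) & (df["block_id"] == block),
                       ["partner_locus_id", "syntenic_pair"]] = [bi, True]
                df.loc[(df["locus_id"] == bi) & (df["block_id"] == block),
                       ["partner_locus_id", "syntenic_pair"]] = [ai, True]
    return df


def loci_to_gff3(loci: pd.DataFrame) -> list[dict]:
    """miRBase-dialect GFF3 rows (primary transcript + mature miRNA)."""
    rows = []
    for _, r in loci.iterrows():
        rows.append(
            {"seqid": r["chrom"], "type": "miRNA_primary_transcript",
             "start": r["precursor_start"], "end": r["precursor_end"],
             "strand": r["strand"], "attributes": {"ID": r["locus_id"]}}
        )
        rows.append(
            {"seqid": r["chrom"], "type": "miRNA",
             "start": r["mature_start"], "end": r["mature_end"],
             "strand": r["strand"],
             "attributes": {"ID": r["locus_id"] + ".mature",
                            "Derives_from": r["locus_id"]}}
        )
    return rows
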