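"""TF -> miRNA -> target regulatory network construction.

Promoters are the 2,000 nt upstream of each pre-miRNA and target transcript
(strand-aware, truncated at contig edges with the actual length recorded).
Binding sites come from a position-weight-matrix scan: log2-odds scores
against a 0-order background, both strands, with an exact score p-value from
dynamic programming over the per-column score distributions (scores are
quantised to a fixed grid, and the p-value is exact for the quantised
score). A window is a hit when its score p-value is at most ``p_cut``
(1e-4 by default).

Edges: TMI (TF -> miRNA) from hits on pre-miRNA promoters, TTI (TF ->
target) from hits on gene promoters, MTI (miRNA -> target) from the target-
interaction dataset (overall or overlap). Cascades are TMI+MTI chains;
feed-forward loops (FFLs) are cascades whose TF also hits the target's
promoter. Self-edges (tf == gene) are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .seqio import revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "Pwm",
    "read_pwms",
    "extract_promoters",
    "scan_motifs",
    "score_pvalues",
    "build_edges",
    "enumerate_motifs",
    "export_network",
]

_SCALE = 1000  # score quantisation: integer grid of 1/1000 bits


@dataclass
class Pwm:
    motif_id: str
    tf_family: str
    matrix: np.ndarray                      # L x 4 probabilities (A C G T)
    background: np.ndarray = None
    pseudocount: float = 1e-3

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 4:
            raise ValueError("PWM must be L x 4 with L >= 4")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("PWM columns must each sum to 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def int_scores(self) -> np.ndarray:
        """Quantised log2-odds scores, shape L x 4 (int64)."""
        p = self.matrix + self.pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        s = np.log2(p / self.background)
        return np.round(s * _SCALE).astype(np.int64)


def read_pwms(path) -> list[Pwm]:
    """Read motifs in JASPAR-style tab format or MEME minimal format."""
    text = open(path).read()
    if "MEME version" in text:
        return _read_meme(text)
    pwms = []
    block: list[str] = []
    header = None
    for line in text.splitlines() + [">"]:
        if line.startswith(">"):
            if header is not None and block:
                pwms.append(_jaspar_block(header, block))
            header, block = line[1:].strip(), []
        elif line.strip():
            block.append(line)
    return pwms


def _jaspar_block(header: str, lines: list[str]) -> Pwm:
    fields = header.split()
    motif_id = fields[0]
    family = fields[1] if len(fields) > 1 else motif_id
    rows = {}
    for ln in lines:
        parts = ln.replace("[", " ").replace("]", " ").split()
        rows[parts[0].upper()] = [float(x) for x in parts[1:]]
    mat = np.array([rows[b] for b in "ACGT"]).T
    mat = mat / mat.sum(axis=1, keepdims=True)
    return Pwm(motif_id=motif_id, tf_family=family, matrix=mat)


def _read_meme(text: str) -> list[Pwm]:
    pwms = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        if lines[i].startswith("MOTIF"):
            parts = lines[i].split()
            motif_id = parts[1]
            family = parts[2] if len(parts) > 2 else motif_id
            while i < len(lines) and not lines[i].startswith("letter-probability"):
                i += 1
            i += 1
            rows = []
            while i < len(lines) and lines[i].strip() and not lines[i].startswith("MOTIF"):
                vals = lines[i].split()
                if len(vals) == 4:
                    rows.append([float(v) for v in vals])
                    i += 1
                else:
                    break
            mat = np.array(rows)
            mat = mat / mat.sum(axis=1, keepdims=True)
            pwms.append(Pwm(motif_id=motif_id, tf_family=family, matrix=mat))
        else:
            i += 1
    return pwms


# --------------------------------------------------------------------------
# promoters
# --------------------------------------------------------------------------

def extract_promoters(
    features: pd.DataFrame,
    genome: dict[str, str],
    upstream: int = 2000,
) -> pd.DataFrame:
    """Strand-aware upstream sequence per feature.

    ``features`` rows need (id, chrom, strand, start, end) with 0-based
    half-open coordinates. Plus strand: [start-upstream, start); minus
    strand: [end, end+upstream) reverse-complemented. Truncation at contig
    edges is recorded in ``length``.
    """
    rows = []
    for _, f in features.iterrows():
        strand = f.get("strand")
        if strand not in ("+", "-"):
            raise ValueError(f"feature {f.get('id')} lacks a strand")
        chrom_seq = genome[f["chrom"]]
        if strand == "+":
            a, b = max(0, int(f["start"]) - upstream), int(f["start"])
            seq = chrom_seq[a:b]
        else:
            a, b = int(f["end"]), min(len(chrom_seq), int(f["end"]) + upstream)
            seq = revcomp(chrom_seq[a:b])
        rows.append(
            {"id": f["id"], "chrom": f["chrom"], "strand": strand,
             "start": a, "end": b, "length": len(seq), "seq": seq}
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# scanning with exact score p-values
# --------------------------------------------------------------------------

def score_pvalues(pwm: Pwm) -> tuple[np.ndarray, np.ndarray, int]:
    """(scores, pvalues, offset) of the exact quantised score distribution.

    ``pvalues[s - offset]`` is P[S >= s] for a random word under the 0-order
    background; computed by convolving per-column score distributions.
    """
    S = pwm.int_scores()
    lo = int(S.min(axis=1).sum())
    hi = int(S.max(axis=1).sum())
    dist = np.zeros(hi - lo + 1)
    dist[-lo if lo < 0 else 0] = 0.0
    # start with a point mass at score 0 located at index -lo
    dist = np.zeros(hi - lo + 1)
    dist[0 - lo] = 1.0
    cur_lo = 0
    for col in range(pwm.length):
        new = np.zeros_like(dist)
        for b in range(4):
            s = int(S[col, b])
            w = float(pwm.background[b])
            if s >= 0:
                new[s:] += w * dist[: len(dist) - s if s else len(dist)]
            else:
                new[:s] += w * dist[-s:]
        dist = new
    tail = np.cumsum(dist[::-1])[::-1]
    scores = np.arange(lo, hi + 1)
    return scores, tail, lo


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def _encode_dna(seq: str) -> np.ndarray:
    return np.array([_BASE_IDX.get(c, -1) for c in seq.upper()], dtype=np.int64)


def scan_motifs(
    promoters: pd.DataFrame,
    pwms: list[Pwm],
    p_cut: float = 1e-4,
) -> pd.DataFrame:
    """Scan each promoter with each PWM on both strands.

    Returns hits (id, motif_id, tf_family, offset, strand, score_bits,
    pvalue); ``offset`` indexes the promoter sequence as given (5'->3'
    relative to the gene).
    """
    rows = []
    for pwm in pwms:
        S = pwm.int_scores()
        L = pwm.length
        scores, tail, lo = score_pvalues(pwm)
        # minimal integer score whose p-value is <= p_cut
        ok = tail <= p_cut
        if not ok.any():
            continue
        threshold = int(scores[ok.argmax()])
        for _, prom in promoters.iterrows():
            seq = prom["seq"]
            if len(seq) < L:
                continue
            codes = _encode_dna(seq)
            valid = codes >= 0
            for strand in "+-":
                c = codes if strand == "+" else (3 - codes[::-1]) % 4
                v = valid if strand == "+" else valid[::-1]
                n = len(c) - L + 1
                win = np.zeros(n, dtype=np.int64)
                bad = np.zeros(n, dtype=bool)
                for j in range(L):
                    win += S[j, c[j : j + n]]
                    bad |= ~v[j : j + n]
                hit_idx = np.nonzero((win >= threshold) & ~bad)[0]
                for o in hit_idx:
                    s_int = int(win[o])
                    offset = int(o) if strand == "+" else len(seq) - L - int(o)
                    rows.append(
                        {
                            "id": prom["id"],
                            "motif_id": pwm.motif_id,
                            "tf_family": pwm.tf_family,
                            "offset": offset,
                            "strand": strand,
                            "score_bits": s_int / _SCALE,
                            "pvalue": float(tail[s_int - lo]),
                        }
                    )
    cols = ["id", "motif_id", "tf_family", "offset", "strand", "score_bits", "pvalue"]
    return pd.DataFrame(rows, columns=cols)


# --------------------------------------------------------------------------
# edges and motif enumeration
# --------------------------------------------------------------------------

def build_edges(
    mirna_hits: pd.DataFrame,
    gene_hits: pd.DataFrame,
    interactions: pd.DataFrame,
    tf_map: pd.DataFrame,
    known_genes: set[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Typed edge sets TMI / MTI / TTI (deduplicated, self-edges dropped).

    ``tf_map`` maps tf_gene -> pwm_id; every TF carrying a motif that hits a
    promoter contributes an edge. TFs absent from ``known_genes`` are kept
    with an ``external_tf`` flag and a warning.
    """
    motif_tfs: dict[str, list[str]] = {}
    for _, r in tf_map.iterrows():
        motif_tfs.setdefault(r["pwm_id"], []).append(r["tf_gene"])

    def expand(hits: pd.DataFrame, kind: str) -> pd.DataFrame:
        recs = {}
        for _, h in hits.iterrows():
            for tf in motif_tfs.get(h["motif_id"], ()):
                if kind == "TTI" and tf == h["id"]:
                    continue  # self-loop rule
                key = (tf, h["id"])
                rec = recs.setdefault(
                    key, {"source": tf, "target": h["id"], "type": kind,
                          "n_sites": 0, "best_p": np.inf}
                )
                rec["n_sites"] += 1
                rec["best_p"] = min(rec["best_p"], h["pvalue"])
        df = pd.DataFrame(
            list(recs.values()),
            columns=["source", "target", "type", "n_sites", "best_p"],
        )
        if known_genes is not None and len(df):
            df["external_tf"] = ~df["source"].isin(known_genes)
            if df["external_tf"].any():
                logger.warning("%d TFs absent from the gene set", df["external_tf"].sum())
        return df

    tmi = expand(mirna_hits, "TMI")
    tti = expand(gene_hits, "TTI")
    mti = interactions[["mirna_id", "transcript_id"]].drop_duplicates()
    mti = mti.rename(columns={"mirna_id": "source", "transcript_id": "target"})
    mti["type"] = "MTI"
    return {"TMI": tmi, "MTI": mti.reset_index(drop=True), "TTI": tti}


def enumerate_motifs(
    tmi: pd.DataFrame, mti: pd.DataFrame, tti: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """All (tf, mirna, gene) cascade motifs and the FFL subset, with counts.

    cascade(t, m, g) <=> TMI(t, m) and MTI(m, g); FFL additionally needs
    TTI(t, g). FFLs are a subset of cascades by construction.
    """
    tmi_pairs = set(zip(tmi["source"], tmi["target"])) if len(tmi) else set()
    mti_by_m: dict[str, list[str]] = {}
    for s, t in zip(mti["source"], mti["target"]):
        mti_by_m.setdefault(s, []).append(t)
    tti_pairs = set(zip(tti["source"], tti["target"])) if len(tti) else set()
    cascades, ffls = [], []
    for t, m in sorted(tmi_pairs):
        for g in sorted(set(mti_by_m.get(m, ()))):
            cascades.append((t, m, g))
            if (t, g) in tti_pairs:
                ffls.append((t, m, g))
    cas = pd.DataFrame(cascades, columns=["tf", "mirna", "gene"])
    ffl = pd.DataFrame(ffls, columns=["tf", "mirna", "gene"])
    counts = {
        "n_tmi": int(len(tmi_pairs)),
        "n_mti": int(len(mti.drop_duplicates())) if len(mti) else 0,
        "n_tti": int(len(tti_pairs)),
        "n_cascades": len(cas),
        "n_ffls": len(ffl),
    }
    assert counts["n_ffls"] <= counts["n_cascades"]
    return cas, ffl, counts


def export_network(
    edges: dict[str, pd.DataFrame],
    outdir,
    prefix: str = "network",
) -> dict[str, str]:
    """Write SIF, node-attribute TSV and GraphML; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = nx.MultiDiGraph()
    kind_of: dict[str, str] = {}
    for etype, df in edges.items():
        for _, r in df.iterrows():
            g.add_edge(r["source"], r["target"], type=etype)
            if etype == "TMI":
                kind_of[r["source"]] = "TF"
                kind_of.setdefault(r["target"], "miRNA")
            elif etype == "MTI":
                kind_of[r["source"]] = "miRNA"
                kind_of.setdefault(r["target"], "target")
            else:
                kind_of[r["source"]] = "TF"
                kind_of.setdefault(r["target"], "target")
    nx.set_node_attributes(g, kind_of, "kind")
    sif = outdir / f"{prefix}.sif"
    with open(sif, "w") as fh:
        for u, v, d in sorted(g.edges(data=True), key=lambda e: (e[2]["type"], e[0], e[1])):
            fh.write(f"{u}\t{d['type']}\t{v}\n")
    nodes = outdir / f"{prefix}.nodes.tsv"
    pd.DataFrame(
        [{"node": n, "kind": k} for n, k in sorted(kind_of.items())]
    ).to_csv(nodes, sep="\t", index=False)
    gml = outdir / f"{prefix}.graphml"
    nx.write_graphml(g, gml)
    return {"sif": str(sif), "nodes": str(nodes), "graphml": str(gml)}
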