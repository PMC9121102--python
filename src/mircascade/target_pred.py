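"""miRNA target prediction over a transcriptome.

Two complementary scoring families stand behind a common method interface:

* expectation score E: cumulative penalties over the antiparallel
  miRNA:site alignment (mismatch 1.0, G:U wobble 0.5, each bulged nucleotide
  2.0; all penalties doubled at miRNA positions 2-13 counted 1-based from
  the 5' end). Targets need E < 3.0. E = 0 iff the site is a perfect
  complement.
* duplex-energy ratio: a simplified pair-energy model (GC -3, AU -2, GU -1,
  arbitrary units) gives the minimum free energy (MFE) of the candidate
  duplex and the minimum duplex energy (MDE) of the perfectly paired miRNA;
  sites pass at MFE/MDE >= 0.75.

Alignments are ungapped or carry a single interior bulge on either strand
(site one nucleotide longer or shorter than the miRNA); the reported score
is the exact minimum over that alignment space. The integration rule builds
the overall dataset (union of every method plus degradome confirmations) and
the overlap dataset (degradome confirmations plus pairs predicted by at
least two computational methods).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import to_rna

__all__ = [
    "TargetConfig",
    "expectation_score",
    "hybrid_ratio",
    "duplex_energies",
    "scan_transcriptome",
    "scan_hybrid",
    "integrate_methods",
]

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_SEP = 4  # transcript separator in concatenated scans

_COMPLEMENT = {(0, 3), (3, 0), (1, 2), (2, 1)}
_WOBBLE = {(2, 3), (3, 2)}


@dataclass
class TargetConfig:
    mismatch_penalty: float = 1.0
    wobble_penalty: float = 0.5
    bulge_penalty: float = 2.0
    seed_start: int = 2          # 1-based miRNA positions with doubled weight
    seed_end: int = 13
    e_cutoff: float = 3.0
    ratio_cutoff: float = 0.75
    pair_energy: dict = field(
        default_factory=lambda: {"GC": -3.0, "AU": -2.0, "GU": -1.0}
    )

    def weight(self, pos1: int) -> float:
        return 2.0 if self.seed_start <= pos1 <= self.seed_end else 1.0


def _encode(seq: str) -> np.ndarray:
    rna = to_rna(seq)
    try:
        return np.array([_CODE[c] for c in rna], dtype=np.int8)
    except KeyError:
        bad = next(c for c in rna if c not in _CODE)
        raise ValueError(f"non-ACGU(T) character {bad!r} in sequence")


def _pair_penalty(cfg: TargetConfig, mb: int, sb: int) -> float:
    if (mb, sb) in _COMPLEMENT:
        return 0.0
    if (mb, sb) in _WOBBLE:
        return cfg.wobble_penalty
    return cfg.mismatch_penalty


def _pair_energy(cfg: TargetConfig, mb: int, sb: int) -> float:
    if (mb, sb) in _COMPLEMENT:
        return cfg.pair_energy["GC"] if mb in (1, 2) else cfg.pair_energy["AU"]
    if (mb, sb) in _WOBBLE:
        return cfg.pair_energy["GU"]
    return 0.0


def _alignments(L: int, Ls: int):
    """Yield (pairs, bulge) for the allowed alignment space.

    ``pairs`` is a list of (miRNA index, site index); ``bulge`` is
    ("site", k) / ("mirna", q) or None. Site indices are 5'->3' on the
    transcript; the duplex is antiparallel.
    """
    if Ls == L:
        yield [(i, L - 1 - i) for i in range(L)], None
    elif Ls == L + 1:
        for k in range(1, Ls - 1):  # interior site bulge
            pairs = []
            for j in range(Ls):
                if j == k:
                    continue
                i = L - j if j > k else L - 1 - j
                pairs.append((i, j))
            yield pairs, ("site", k)
    elif Ls == L - 1:
        for q in range(1, L - 1):  # interior miRNA bulge
            pairs = []
            for j in range(Ls):
                i = L - 2 - j if j >= L - 1 - q else L - 1 - j
                pairs.append((i, j))
            yield pairs, ("mirna", q)
    else:
        raise ValueError("site length must be within 1 nt of the miRNA length")


def expectation_score(mirna_seq: str, site_seq: str, config: TargetConfig | None = None) -> float:
    """Minimum expectation penalty E over the allowed alignments."""
    cfg = config or TargetConfig()
    m, s = _encode(mirna_seq), _encode(site_seq)
    L, Ls = len(m), len(s)
    best = np.inf
    for pairs, bulge in _alignments(L, Ls):
        e = sum(
            cfg.weight(i + 1) * _pair_penalty(cfg, int(m[i]), int(s[j]))
            for i, j in pairs
        )
        if bulge is not None:
            kind, pos = bulge
            pos1 = min(max(L - pos, 1), L) if kind == "site" else pos + 1
            e += cfg.bulge_penalty * cfg.weight(pos1)
        best = min(best, e)
    return float(best)


def duplex_energies(mirna_seq: str, site_seq: str, config: TargetConfig | None = None):
    """(MFE, MDE): best attainable duplex energy of the site, and the energy
    of the perfectly paired miRNA."""
    cfg = config or TargetConfig()
    m, s = _encode(mirna_seq), _encode(site_seq)
    mde = sum(
        cfg.pair_energy["GC"] if b in (1, 2) else cfg.pair_energy["AU"] for b in m
    )
    if mde == 0:
        raise ValueError("miRNA cannot pair at all; MFE/MDE undefined")
    mfe = min(
        sum(_pair_energy(cfg, int(m[i]), int(s[j])) for i, j in pairs)
        for pairs, _b in _alignments(len(m), len(s))
    )
    return float(mfe), float(mde)


def hybrid_ratio(mirna_seq: str, site_seq: str, config: TargetConfig | None = None):
    """MFE/MDE ratio and whether it passes the cutoff."""
    cfg = config or TargetConfig()
    mfe, mde = duplex_energies(mirna_seq, site_seq, cfg)
    ratio = mfe / mde
    return float(ratio), bool(ratio >= cfg.ratio_cutoff)


# --------------------------------------------------------------------------
# vectorised transcriptome scans
# --------------------------------------------------------------------------

def _concat_transcripts(transcripts: dict[str, str]):
    ids, codes, bounds = [], [], []
    pos = 0
    parts = []
    for tid, seq in transcripts.items():
        c = _encode(seq)
        ids.append(tid)
        parts.append(c)
        parts.append(np.full(1, _SEP, dtype=np.int8))
        bounds.append((pos, pos + len(c)))
        pos += len(c) + 1
    codes = np.concatenate(parts) if parts else np.zeros(0, dtype=np.int8)
    return ids, codes, bounds


def _slot_matrix(cfg: TargetConfig, m: np.ndarray, mirna_index, weighted: bool,
                 big: float) -> np.ndarray:
    """M[j, b] = penalty/energy of site base b at window slot j."""
    L = len(mirna_index)
    M = np.empty((L, 5))
    for j, i in enumerate(mirna_index):
        for b in range(4):
            if weighted:
                M[j, b] = cfg.weight(i + 1) * _pair_penalty(cfg, int(m[i]), b)
            else:
                M[j, b] = _pair_energy(cfg, int(m[i]), b)
        M[j, 4] = big
    return M


def _window_scores(codes: np.ndarray, M: np.ndarray) -> np.ndarray:
    """score[o] = sum_j M[j, codes[o + j]] for all offsets."""
    L = M.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.zeros(0)
    out = np.zeros(n)
    for j in range(L):
        out += M[j, codes[j : j + n]]
    return out


def _bulge_scores(codes: np.ndarray, M_pre: np.ndarray, M_post: np.ndarray,
                  extra: np.ndarray, skip_split: bool) -> np.ndarray:
    """Minimum over interior split positions of prefix/suffix scores.

    Window length W = M_pre.shape[0]; for split k, slots j < k score by
    M_pre, slots j > k (or j >= k when ``skip_split`` is False) by M_post,
    plus ``extra[k]``. ``skip_split=True`` models a bulged (unpaired) site
    slot at k; ``False`` models a miRNA-side bulge between site slots.
    """
    W = M_pre.shape[0]
    n = len(codes) - W + 1
    if n <= 0:
        return np.zeros(0)
    pre = np.zeros(n)
    sufs = [np.zeros(n)]
    for j in range(W - 1, -1, -1):
        sufs.append(sufs[-1] + M_post[j, codes[j : j + n]])
    sufs.reverse()  # sufs[k] = sum over slots j >= k of M_post
    best = np.full(n, np.inf)
    for k in range(1, W - 1 if skip_split else W - 0):
        pre = pre + M_pre[k - 1, codes[k - 1 : k - 1 + n]]
        if not np.isfinite(extra[k]):
            continue
        suf = sufs[k + 1] if skip_split else sufs[k]
        np.minimum(best, pre + suf + extra[k], out=best)
    return best


def _collect_hits(ids, bounds, scores_by_len, keep_mask_fn, better):
    """Reduce per-offset scores to the best site per (transcript) window set."""
    hits = []
    for tid, (lo, hi) in zip(ids, bounds):
        best = None
        for W, scores in scores_by_len.items():
            o_lo, o_hi = lo, hi - W + 1
            if o_hi <= o_lo:
                continue
            seg = scores[o_lo:o_hi]
            o = int(np.argmin(seg) if better == "min" else np.argmax(seg))
            val = float(seg[o])
            if not keep_mask_fn(val):
                continue
            if best is None or (better == "min" and val < best[0]) or (
                better == "max" and val > best[0]
            ):
                best = (val, o, W)
        if best is not None:
            val, o, W = best
            hits.append({"transcript_id": tid, "site_start": o, "site_end": o + W,
                         "score": val})
    return hits


def scan_transcriptome(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    e_cutoff: float | None = None,
    config: TargetConfig | None = None,
) -> pd.DataFrame:
    """Expectation-method scan: best site with E < cutoff per miRNA-transcript
    pair (overlapping candidate windows merge to the minimum-E site)."""
    cfg = config or TargetConfig()
    cutoff = cfg.e_cutoff if e_cutoff is None else e_cutoff
    ids, codes, bounds = _concat_transcripts(transcripts)
    rows = []
    for mid, mseq in mirnas.items():
        m = _encode(mseq)
        L = len(m)
        big = 1e9
        M1 = _slot_matrix(cfg, m, [L - 1 - j for j in range(L)], True, big)
        scores = {L: _window_scores(codes, M1)}
        # site bulge at slot k: window W=L+1; j<k pairs miRNA L-1-j, j>k pairs L-j
        M_sb_pre = np.vstack([M1, M1[-1:]])
        M_sb_post = _slot_matrix(
            cfg, m, [L - j if 1 <= j <= L else 0 for j in range(L + 1)], True, big
        )
        extra_sb = np.array(
            [cfg.bulge_penalty * cfg.weight(min(max(L - k, 1), L)) for k in range(L + 1)]
        )
        scores[L + 1] = _bulge_scores(codes, M_sb_pre, M_sb_post, extra_sb, True)
        # miRNA bulge at q = L-1-k: window W=L-1; j<k pairs L-1-j, j>=k pairs L-2-j
        if L - 1 >= 4:
            M_mb_pre = M1[: L - 1]
            M_mb_post = _slot_matrix(
                cfg, m, [max(L - 2 - j, 0) for j in range(L - 1)], True, big
            )
            extra_m = np.array(
                [cfg.bulge_penalty * cfg.weight(L - k) if 1 <= L - 1 - k <= L - 2 else np.inf
                 for k in range(L - 1)]
            )
            scores[L - 1] = _bulge_scores(codes, M_mb_pre, M_mb_post, extra_m, False)
        for h in _collect_hits(ids, bounds, scores, lambda v: v < cutoff, "min"):
            h["mirna_id"] = mid
            h["expectation_E"] = h.pop("score")
            rows.append(h)
    cols = ["mirna_id", "transcript_id", "site_start", "site_end", "expectation_E"]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def scan_hybrid(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    ratio_cutoff: float | None = None,
    config: TargetConfig | None = None,
) -> pd.DataFrame:
    """Energy-method scan: best MFE/MDE ratio per pair, kept at >= cutoff."""
    cfg = config or TargetConfig()
    cutoff = cfg.ratio_cutoff if ratio_cutoff is None else ratio_cutoff
    ids, codes, bounds = _concat_transcripts(transcripts)
    rows = []
    for mid, mseq in mirnas.items():
        m = _encode(mseq)
        L = len(m)
        mde = sum(
            cfg.pair_energy["GC"] if b in (1, 2) else cfg.pair_energy["AU"] for b in m
        )
        if mde == 0:
            raise ValueError(f"miRNA {mid} cannot pair; MDE undefined")
        big = 1e9  # separators force a hugely positive (failing) energy
        M1 = _slot_matrix(cfg, m, [L - 1 - j for j in range(L)], False, big)
        energy = _window_scores(codes, M1)
        ratios = {L: energy / mde}
        for h in _collect_hits(ids, bounds, ratios, lambda v: v >= cutoff, "max"):
            h["mirna_id"] = mid
            h["ratio"] = h.pop("score")
            h["mfe"] = h["ratio"] * mde
            h["mde"] = float(mde)
            rows.append(h)
    cols = ["mirna_id", "transcript_id", "site_start", "site_end", "mfe", "mde", "ratio"]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


# --------------------------------------------------------------------------
# integration
# --------------------------------------------------------------------------

def integrate_methods(
    method_hits: dict[str, pd.DataFrame],
    degradome_pairs: pd.DataFrame | None = None,
    min_methods: int = 2,
) -> pd.DataFrame:
    """Combine per-method predictions and degradome confirmations.

    overall = union of all computational methods and degradome pairs;
    overlap = degradome pairs plus pairs predicted by >= ``min_methods``
    computational methods.
    """
    if len(method_hits) < min_methods:
        raise ValueError(f"need >= {min_methods} computational methods configured")
    frames = []
    for name, df in method_hits.items():
        d = df.copy()
        d["method"] = name
        frames.append(d)
    allhits = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["mirna_id", "transcript_id", "method"]
    )
    key = ["mirna_id", "transcript_id"]
    agg: dict[tuple, dict] = {}
    for _, r in allhits.iterrows():
        k = (r["mirna_id"], r["transcript_id"])
        rec = agg.setdefault(
            k, {"mirna_id": k[0], "transcript_id": k[1], "methods": set(),
                "site_start": -1, "site_end": -1, "expectation_E": np.nan,
                "ratio": np.nan, "degradome_category": -1}
        )
        rec["methods"].add(r["method"])
        if r.get("site_start", -1) >= 0 and rec["site_start"] < 0:
            rec["site_start"], rec["site_end"] = int(r["site_start"]), int(r["site_end"])
        if "expectation_E" in r and pd.notna(r.get("expectation_E")):
            rec["site_start"], rec["site_end"] = int(r["site_start"]), int(r["site_end"])
            rec["expectation_E"] = float(r["expectation_E"])
        if "ratio" in r and pd.notna(r.get("ratio")):
            rec["ratio"] = float(r["ratio"])
    if degradome_pairs is not None and len(degradome_pairs):
        for _, r in degradome_pairs.iterrows():
            k = (r["mirna_id"], r["transcript_id"])
            rec = agg.setdefault(
                k, {"mirna_id": k[0], "transcript_id": k[1], "methods": set(),
                    "site_start": int(r.get("site_start", -1)),
                    "site_end": int(r.get("site_end", -1)),
                    "expectation_E": np.nan, "ratio": np.nan,
                    "degradome_category": -1}
            )
            rec["methods"].add("degradome")
            rec["degradome_category"] = int(r["category"])
    rows = []
    for rec in agg.values():
        methods = rec.pop("methods")
        comp = methods - {"degradome"}
        rec["methods"] = ",".join(sorted(methods))
        rec["in_overall"] = True
        rec["in_overlap"] = ("degradome" in methods) or (len(comp) >= min_methods)
        rows.append(rec)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["mirna_id", "transcript_id"]).reset_index(drop=True)
    return out
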