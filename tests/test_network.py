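"""Promoter extraction, PWM scanning with exact p-values, edges and FFLs."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mircascade import network as nw
from mircascade.seqio import revcomp
from conftest import brute_force_ffls


def _pwm(consensus="ACGTACGT", p=0.91):
    mat = np.full((len(consensus), 4), (1 - p) / 3)
    for j, b in enumerate(consensus):
        mat[j, "ACGT".index(b)] = p
    return nw.Pwm(motif_id="M1", tf_family="WRKY", matrix=mat)


def test_pwm_validation():
    with pytest.raises(ValueError, match="sum"):
        nw.Pwm("M", "F", np.full((6, 4), 0.3))
    with pytest.raises(ValueError, match="L >= 4"):
        nw.Pwm("M", "F", np.full((2, 4), 0.25))


@pytest.mark.parametrize(
    "feat,expected",
    [
        ({"id": "g", "chrom": "c", "strand": "+", "start": 5000, "end": 6000},
         (3000, 5000, 2000)),
        ({"id": "g", "chrom": "c", "strand": "+", "start": 500, "end": 900},
         (0, 500, 500)),
        ({"id": "g", "chrom": "c", "strand": "-", "start": 1000, "end": 2000},
         (2000, 4000, 2000)),
    ],
)
def test_extract_promoters_coordinates(feat, expected):
    rng = np.random.default_rng(0)
    genome = {"c": "".join(rng.choice(list("ACGT"), size=8000))}
    out = nw.extract_promoters(pd.DataFrame([feat]), genome)
    row = out.iloc[0]
    assert (row["start"], row["end"], row["length"]) == expected
    if feat["strand"] == "-":
        assert row["seq"] == revcomp(genome["c"][row["start"]: row["end"]])


def test_extract_promoters_requires_strand():
    with pytest.raises(ValueError, match="strand"):
        nw.extract_promoters(
            pd.DataFrame([{"id": "g", "chrom": "c", "strand": ".",
                           "start": 10, "end": 20}]),
            {"c": "A" * 100},
        )


@pytest.mark.parametrize("L", [4, 6, 8])
def test_score_pvalues_match_exhaustive_enumeration(L):
    rng = np.random.default_rng(L)
    mat = rng.dirichlet(np.ones(4) * 0.4, size=L)
    pwm = nw.Pwm("M", "F", mat)
    scores, tail, lo = nw.score_pvalues(pwm)
    S = pwm.int_scores()
    bg = pwm.background
    # enumerate all 4^L words, accumulate exact tail probabilities
    word_scores = {}
    for word in itertools.product(range(4), repeat=L):
        s = int(sum(S[j, b] for j, b in enumerate(word)))
        p = float(np.prod([bg[b] for b in word]))
        word_scores[s] = word_scores.get(s, 0.0) + p
    for s_query in sorted(word_scores):
        expect = sum(p for s, p in word_scores.items() if s >= s_query)
        got = tail[s_query - lo]
        assert got == pytest.approx(expect, rel=1e-9)


def test_scan_finds_planted_consensus_with_max_score():
    pwm = _pwm("TTGACCAA")
    rng = np.random.default_rng(7)
    seq = list(rng.choice(list("ACGT"), size=400))
    seq[150:158] = list("TTGACCAA")
    seq[300:308] = list(revcomp("TTGACCAA"))
    proms = pd.DataFrame([{"id": "p1", "seq": "".join(seq)}])
    hits = nw.scan_motifs(proms, [pwm], p_cut=1e-4)
    fwd = hits[(hits.strand == "+") & (hits.offset == 150)]
    rev = hits[(hits.strand == "-") & (hits.offset == 300)]
    assert len(fwd) == 1 and len(rev) == 1
    assert fwd.iloc[0]["score_bits"] == hits["score_bits"].max()


def test_scan_false_positive_rate_respects_p_cut():
    pwm = _pwm("TTGACCAAGG", p=0.97)
    rng = np.random.default_rng(123)
    n_windows = 0
    n_hits = 0
    for i in range(40):
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        hits = nw.scan_motifs(pd.DataFrame([{"id": f"p{i}", "seq": seq}]),
                              [pwm], p_cut=1e-4)
        n_windows += 2 * (2000 - pwm.length + 1)
        n_hits += len(hits)
    # expected <= p_cut per window; allow generous binomial slack
    assert n_hits <= 1e-4 * n_windows + 4 * np.sqrt(1e-4 * n_windows) + 3


def test_build_edges_dedup_and_self_loop():
    hits_m = pd.DataFrame(
        [{"id": "mir156", "motif_id": "M1", "tf_family": "F",
          "offset": 5, "strand": "+", "score_bits": 9.0, "pvalue": 1e-6},
         {"id": "mir156", "motif_id": "M1", "tf_family": "F",
          "offset": 80, "strand": "-", "score_bits": 8.0, "pvalue": 1e-5}]
    )
    hits_g = pd.DataFrame(
        [{"id": "tf1", "motif_id": "M1", "tf_family": "F",
          "offset": 3, "strand": "+", "score_bits": 9.0, "pvalue": 1e-6},
         {"id": "g2", "motif_id": "M1", "tf_family": "F",
          "offset": 3, "strand": "+", "score_bits": 9.0, "pvalue": 1e-6}]
    )
    inter = pd.DataFrame([{"mirna_id": "mir156", "transcript_id": "g2"}])
    tf_map = pd.DataFrame([{"tf_gene": "tf1", "pwm_id": "M1"}])
    edges = nw.build_edges(hits_m, hits_g, inter, tf_map, known_genes={"tf1", "g2"})
    assert len(edges["TMI"]) == 1                      # two sites, one edge
    assert edges["TMI"].iloc[0]["n_sites"] == 2
    assert list(edges["TTI"]["target"]) == ["g2"]      # tf1 -> tf1 dropped
    assert len(edges["MTI"]) == 1


def test_enumerate_motifs_worked_example():
    tmi = pd.DataFrame({"source": ["T1", "T2"], "target": ["m1", "m1"]})
    mti = pd.DataFrame({"source": ["m1", "m1"], "target": ["g1", "g2"]})
    tti = pd.DataFrame({"source": ["T1"], "target": ["g1"]})
    cas, ffl, counts = nw.enumerate_motifs(tmi, mti, tti)
    assert counts["n_cascades"] == 4 and counts["n_ffls"] == 1
    assert tuple(ffl.iloc[0]) == ("T1", "m1", "g1")
    _c2, f2, c2 = nw.enumerate_motifs(tmi, mti, tti.iloc[0:0])
    assert c2["n_cascades"] == 4 and c2["n_ffls"] == 0


def test_enumeration_matches_brute_force_on_random_graphs():
    rng = np.random.default_rng(31)
    for _ in range(12):
        tfs = [f"T{i}" for i in range(int(rng.integers(3, 15)))]
        ms = [f"m{i}" for i in range(int(rng.integers(3, 20)))]
        gs = [f"g{i}" for i in range(int(rng.integers(5, 60)))]
        tmi = {(t, m) for t in tfs for m in ms if rng.random() < 0.2}
        mti = {(m, g) for m in ms for g in gs if rng.random() < 0.1}
        tti = {(t, g) for t in tfs for g in gs if rng.random() < 0.1}
        cas, ffl, counts = nw.enumerate_motifs(
            pd.DataFrame(list(tmi), columns=["source", "target"]),
            pd.DataFrame(list(mti), columns=["source", "target"]),
            pd.DataFrame(list(tti), columns=["source", "target"]),
        )
        bc, bf = brute_force_ffls(tmi, mti, tti)
        assert set(map(tuple, cas.to_numpy())) == bc
        assert set(map(tuple, ffl.to_numpy())) == bf
        assert counts["n_ffls"] <= counts["n_cascades"]


def test_export_roundtrip(tmp_path):
    edges = {
        "TMI": pd.DataFrame([{"source": "T1", "target": "m1"}]),
        "MTI": pd.DataFrame([{"source": "m1", "target": "g1"}]),
        "TTI": pd.DataFrame([{"source": "T1", "target": "g1"}]),
    }
    paths = nw.export_network(edges, tmp_path)
    sif_lines = open(paths["sif"]).read().strip().split("\n")
    assert len(sif_lines) == 3  # one FFL = one line per edge type
    g = nx.read_graphml(paths["graphml"])
    got = sorted((u, v, d["type"]) for u, v, d in g.edges(data=True))
    assert got == [("T1", "g1", "TTI"), ("T1", "m1", "TMI"), ("m1", "g1", "MTI")]
    empty = nw.export_network({"TMI": edges["TMI"].iloc[0:0],
                               "MTI": edges["MTI"].iloc[0:0],
                               "TTI": edges["TTI"].iloc[0:0]}, tmp_path, "empty")
    assert open(empty["sif"]).read() == ""
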