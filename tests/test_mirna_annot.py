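"""Annotation criteria, conservation, families, clusters and synteny."""

import numpy as np
import pandas as pd
import pytest

from mircascade import mirna_annot as ma
from mircascade.fold import fold
from mircascade.seqio import to_rna

RNA_COMP = str.maketrans("ACGU", "UGCA")


def rna_revcomp(s):
    return s.translate(RNA_COMP)[::-1]


def make_window(mature="ACCACAAACAACCCACCCAC" + "A", star_edit=None, flank=60):
    """A synthetic hairpin window with A/C flanks and a perfect duplex."""
    rng = np.random.default_rng(0)
    loop = "CAACACAAC"
    core = list(rna_revcomp(mature[:19]))
    if star_edit:
        star_edit(core)
    star = "".join(core) + "CC"
    fl = lambda n: "".join(rng.choice(["A", "C"], size=n))  # noqa: E731
    pre = mature + loop + star
    seq = fl(flank) + pre + fl(flank)
    window = {"chrom": "c1", "strand": "+", "start": 0, "end": len(seq), "seq": seq}
    ms = flank
    reads = pd.DataFrame(
        {
            "seq": [mature, star],
            "ws": [ms, ms + len(mature) + len(loop)],
            "we": [ms + len(mature), ms + len(pre)],
            "count": [40.0, 12.0],
        }
    )
    return window, reads, ms


def test_evaluate_criteria_passes_clean_hairpin():
    window, reads, ms = make_window()
    rep, locus = ma.evaluate_criteria(window, fold(window["seq"]), reads)
    assert rep.passed and locus is not None
    assert rep.duplex_mismatches == 0 and rep.max_asym_bulge == 0
    assert rep.precision == 1.0 and rep.star_read_count == 12
    assert locus["w_mature"] == (ms, ms + 21)


def test_evaluate_criteria_rejects_six_mismatches():
    def edit(core):
        for i in (2, 5, 8, 11, 14, 16):
            core[18 - i] = "A"

    window, reads, _ = make_window(star_edit=edit)
    rep, locus = ma.evaluate_criteria(window, fold(window["seq"]), reads)
    assert locus is None
    assert rep.first_fail == "duplex_mismatches"
    assert rep.duplex_mismatches > 5


def test_evaluate_criteria_rejects_missing_star_reads():
    window, reads, _ = make_window()
    rep, locus = ma.evaluate_criteria(window, fold(window["seq"]), reads.iloc[:1])
    assert locus is None and rep.first_fail == "star"


def test_evaluate_criteria_precursor_length_limit():
    window, reads, _ = make_window()
    cfg = ma.AnnotationConfig(max_precursor=40)
    rep, locus = ma.evaluate_criteria(window, fold(window["seq"]), reads, cfg)
    assert locus is None and rep.first_fail == "precursor_len"


def test_extract_windows_clip_at_chromosome_start():
    genome = {"c1": "ACGT" * 400}
    aln = pd.DataFrame(
        {"seq": ["ACGTACGTACGTACGTACGTA"], "chrom": ["c1"], "start": [100],
         "end": [121], "strand": ["+"]}
    )
    counts = pd.Series({"ACGTACGTACGTACGTACGTA": 10})
    wins = ma.extract_candidate_precursors(aln, counts, genome)
    assert wins[0]["start"] == 0 and wins[0]["end"] == 121 + 250
    # interior stack: plain +-250 window
    aln2 = aln.assign(start=1000, end=1021)
    wins2 = ma.extract_candidate_precursors(aln2, counts, genome)
    assert (wins2[0]["start"], wins2[0]["end"]) == (750, 1271)


@pytest.mark.parametrize(
    "entries,expected",
    [
        ([("osa", "Poaceae"), ("ath", "nonPoaceae")], "conserved"),
        ([("osa", "Poaceae"), ("zma", "Poaceae")], "poaceae_specific"),
        ([], "species_specific"),
    ],
)
def test_classify_conservation(entries, expected):
    q = "ACCACAAACAACCCACCCACA"
    cat = pd.DataFrame(
        [
            {"ref_id": f"{sp}-miR1", "species": sp, "lineage": lin,
             "family": "miR1", "seq": q}
            for sp, lin in entries
        ],
        columns=["ref_id", "species", "lineage", "family", "seq"],
    )
    cls, fam = ma.classify_conservation(q, cat)
    assert cls == expected


def test_conservation_three_mismatches_is_specific():
    q = "ACCACAAACAACCCACCCACA"
    far = list(q)
    for i in (3, 9, 15):
        far[i] = "C" if far[i] == "A" else "A"
    cat = pd.DataFrame(
        [{"ref_id": "ath-miR1", "species": "ath", "lineage": "nonPoaceae",
          "family": "miR1", "seq": "".join(far)}]
    )
    assert ma.classify_conservation(q, cat)[0] == "species_specific"


def test_catalogue_without_lineage_is_an_error():
    with pytest.raises(ValueError, match="lineage"):
        ma.parse_catalogue([("x-miR9", "x-miR9 species=x family=miR9", "ACGU" * 5)])


def brute_transitive_groups(seqs, max_mm=2):
    n = len(seqs)
    groups = [{i} for i in range(n)]
    changed = True
    while changed:
        changed = False
        for a in range(n):
            for b in range(n):
                ga = next(g for g in groups if a in g)
                gb = next(g for g in groups if b in g)
                if ga is not gb and ma._shifted_mismatches(seqs[a], seqs[b]) <= max_mm:
                    groups.remove(gb)
                    ga |= gb
                    changed = True
    return {frozenset(g) for g in groups}


def test_assign_family_matches_transitive_closure():
    rng = np.random.default_rng(3)
    bases = ["".join(rng.choice(["A", "C"], size=21)) for _ in range(6)]
    seqs = []
    for b in bases:
        seqs.append(b)
        m = list(b)
        m[5] = "C" if m[5] == "A" else "A"
        seqs.append("".join(m))
    loci = pd.DataFrame(
        {
            "chrom": ["c1"] * len(seqs),
            "strand": ["+"] * len(seqs),
            "precursor_start": np.arange(len(seqs)) * 1000,
            "precursor_end": np.arange(len(seqs)) * 1000 + 100,
            "mature_seq": seqs,
        }
    )
    cat = pd.DataFrame(columns=["ref_id", "species", "lineage", "family", "seq"])
    out = ma.assign_family(loci, cat)
    got = {
        frozenset(out.index[out["family"] == f]) for f in out["family"].unique()
    }
    assert got == brute_transitive_groups(seqs)
    assert all(out["conservation_class"] == "species_specific")
    assert out["family"].str.match(r"miRN\d{4}").all()


def _cluster_loci(starts, chrom="c1"):
    return pd.DataFrame(
        {
            "locus_id": [f"L{s}" for s in starts],
            "chrom": [chrom] * len(starts),
            "precursor_start": starts,
            "precursor_end": [s + 100 for s in starts],
        }
    )


def test_detect_clusters_examples_and_boundary():
    out = ma.detect_clusters(_cluster_loci([1000, 9000, 25000]))
    assert len(out) == 1 and out.iloc[0]["members"] == "L1000,L9000"
    assert len(ma.detect_clusters(_cluster_loci([0, 10_000]))) == 0  # strict <


def test_detect_clusters_order_invariant():
    starts = [50_000, 1000, 9000, 120_000, 125_000]
    a = ma.detect_clusters(_cluster_loci(starts))
    b = ma.detect_clusters(_cluster_loci(sorted(starts)))
    assert sorted(a["members"]) != [] and len(a) == len(b)
    assert sorted(tuple(sorted(m.split(","))) for m in a["members"]) == sorted(
        tuple(sorted(m.split(","))) for m in b["members"]
    )


def test_anchor_synteny_against_interval_oracle():
    rng = np.random.default_rng(8)
    loci = pd.DataFrame(
        {
            "locus_id": [f"L{i}" for i in range(30)],
            "family": [f"fam{i % 5}" for i in range(30)],
            "chrom": rng.choice(["c1", "c2"], size=30),
            "precursor_start": rng.integers(0, 50_000, size=30),
        }
    )
    loci["precursor_end"] = loci["precursor_start"] + 120
    blocks = pd.DataFrame(
        {
            "block_id": [f"B{i}" for i in range(8)],
            "chrom_a": rng.choice(["c1", "c2"], size=8),
            "start_a": rng.integers(0, 45_000, size=8),
            "chrom_b": rng.choice(["c1", "c2"], size=8),
            "start_b": rng.integers(0, 45_000, size=8),
        }
    )
    blocks["end_a"] = blocks["start_a"] + 6000
    blocks["end_b"] = blocks["start_b"] + 6000
    blocks["orientation"] = "+"
    anchors = ma.anchor_synteny(loci, blocks)
    for _, loc in loci.iterrows():
        for _, blk in blocks.iterrows():
            for side in ("a", "b"):
                expect = (
                    loc["chrom"] == blk[f"chrom_{side}"]
                    and loc["precursor_start"] < blk[f"end_{side}"]
                    and blk[f"start_{side}"] < loc["precursor_end"]
                )
                got = (
                    (anchors["locus_id"] == loc["locus_id"])
                    & (anchors["block_id"] == blk["block_id"])
                    & (anchors["side"] == side)
                ).any()
                assert got == expect
    # syntenic pairs require same family on the two sides of one block
    for _, row in anchors[anchors["syntenic_pair"]].iterrows():
        partner = anchors[
            (anchors["locus_id"] == row["partner_locus_id"])
            & (anchors["block_id"] == row["block_id"])
        ]
        assert len(partner) and partner.iloc[0]["family"] == row["family"]


def test_malformed_block_table_errors():
    loci = _cluster_loci([100])
    loci["family"] = "f"
    with pytest.raises(ValueError, match="columns"):
        ma.anchor_synteny(loci, pd.DataFrame({"block_id": ["B1"]}))
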