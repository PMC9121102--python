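"""Expectation scoring, energy ratios, scans and dataset integration."""

import numpy as np
import pandas as pd
import pytest

from mircascade import target_pred as tp

RNA_COMP = str.maketrans("ACGU", "UGCA")


def rc(s):
    return s.translate(RNA_COMP)[::-1]


MIRNA = "UGACAGAAGAGAGUGAGCACA"  # 21 nt


def test_perfect_complement_scores_zero():
    assert tp.expectation_score(MIRNA, rc(MIRNA)) == 0.0


def _force_mismatch(mirna: str, site: list[str], pos1: int) -> None:
    """Make the site base opposite 1-based miRNA position ``pos1`` a plain
    mismatch (identical base: never complementary, never a G:U wobble)."""
    site[len(mirna) - pos1] = mirna[pos1 - 1]


def test_single_wobble_in_seed_scores_one():
    # G:U inside the seed (position 9): wobble 0.5 doubled to 1.0
    site = list(rc(MIRNA))
    pos1 = 9
    j = len(MIRNA) - pos1
    assert MIRNA[pos1 - 1] == "G" and site[j] == "C"
    site[j] = "U"
    assert tp.expectation_score(MIRNA, "".join(site)) == 1.0


def test_two_mismatches_outside_seed_score_two():
    site = list(rc(MIRNA))
    for pos1 in (15, 18):
        _force_mismatch(MIRNA, site, pos1)
    assert tp.expectation_score(MIRNA, "".join(site)) == 2.0


def test_expectation_increases_when_match_becomes_mismatch():
    site = list(rc(MIRNA))
    base = tp.expectation_score(MIRNA, "".join(site))
    _force_mismatch(MIRNA, site, 18)
    assert tp.expectation_score(MIRNA, "".join(site)) > base


def test_site_length_constraint():
    with pytest.raises(ValueError):
        tp.expectation_score(MIRNA, rc(MIRNA)[:-3])


def test_hybrid_ratio_worked_example():
    # 21-nt miRNA with 12 G/C and 9 A/U: MDE = -(12*3 + 9*2) = -54; losing
    # one A:U pair gives MFE -52 and ratio 52/54
    m = "G" * 6 + "C" * 6 + "A" * 5 + "U" * 4
    assert sum(b in "GC" for b in m) == 12
    site = list(rc(m))
    j = len(m) - 15  # miRNA position 15 is an A
    assert m[14] == "A"
    site[j] = "C"  # A:C cannot pair -> loses -2
    mfe, mde = tp.duplex_energies(m, "".join(site))
    assert mde == -54.0 and mfe == -52.0
    ratio, ok = tp.hybrid_ratio(m, "".join(site))
    assert ok and abs(ratio - 52 / 54) < 1e-12


def test_hybrid_ratio_boundaries():
    ratio, ok = tp.hybrid_ratio(MIRNA, rc(MIRNA))
    assert ratio == 1.0 and ok
    # destroy roughly half the pairing energy -> fail
    site = list(rc(MIRNA))
    for j in range(0, len(site), 2):
        site[j] = "A" if site[j] != "A" else "C"
    ratio2, ok2 = tp.hybrid_ratio(MIRNA, "".join(site))
    assert ratio2 < 0.75 and not ok2


def test_undefined_ratio_for_unpairable_mirna():
    cfg = tp.TargetConfig(pair_energy={"GC": -3.0, "AU": 0.0, "GU": -1.0})
    with pytest.raises(ValueError):
        tp.duplex_energies("A" * 21, "U" * 21, cfg)


def brute_scan(mirna, transcripts, cutoff):
    hits = []
    L = len(mirna)
    for tid, seq in transcripts.items():
        best = None
        for W in (L - 1, L, L + 1):
            for o in range(len(seq) - W + 1):
                e = tp.expectation_score(mirna, seq[o : o + W])
                if e < cutoff and (best is None or e < best[0]):
                    best = (e, o, W)
        if best:
            hits.append((tid, best[0]))
    return dict(hits)


def test_scan_agrees_with_per_window_scoring():
    rng = np.random.default_rng(21)
    mirna = "".join(rng.choice(list("ACGU"), size=21))
    transcripts = {
        f"t{i}": "".join(rng.choice(list("ACGU"), size=150)) for i in range(4)
    }
    # plant a near-perfect site (one mismatch) in t0
    site = list(rc(mirna))
    site[5] = {"A": "G", "C": "U", "G": "A", "U": "C"}[site[5]]
    s = transcripts["t0"]
    transcripts["t0"] = s[:60] + "".join(site) + s[60 + 21 :]
    cutoff = 6.0  # loose cutoff so random hits exercise the comparison
    got = tp.scan_transcriptome({"m": mirna}, transcripts, e_cutoff=cutoff)
    got_map = dict(zip(got["transcript_id"], got["expectation_E"]))
    expected = brute_scan(mirna, transcripts, cutoff)
    assert got_map.keys() == expected.keys()
    for tid in expected:
        assert got_map[tid] == pytest.approx(expected[tid])


def test_scan_cutoff_is_strict():
    site = list(rc(MIRNA))
    # three plain mismatches outside the seed: E = 3.0 exactly
    for pos1 in (15, 17, 19):
        _force_mismatch(MIRNA, site, pos1)
    seq = "A" * 30 + "".join(site) + "A" * 30
    assert tp.expectation_score(MIRNA, "".join(site)) == 3.0
    out = tp.scan_transcriptome({"m": MIRNA}, {"t": seq}, e_cutoff=3.0)
    assert len(out) == 0
    out2 = tp.scan_transcriptome({"m": MIRNA}, {"t": seq}, e_cutoff=3.01)
    assert len(out2) == 1 and out2.iloc[0]["expectation_E"] == 3.0


def test_integration_rule():
    e = pd.DataFrame(
        [{"mirna_id": "m1", "transcript_id": "g1", "site_start": 5,
          "site_end": 26, "expectation_E": 1.0},
         {"mirna_id": "m2", "transcript_id": "g3", "site_start": 2,
          "site_end": 23, "expectation_E": 2.0}]
    )
    h = pd.DataFrame(
        [{"mirna_id": "m1", "transcript_id": "g1", "site_start": 5,
          "site_end": 26, "mfe": -50.0, "mde": -54.0, "ratio": 0.9}]
    )
    deg = pd.DataFrame(
        [{"mirna_id": "m4", "transcript_id": "g9", "site_start": 1,
          "site_end": 22, "category": 0}]
    )
    out = tp.integrate_methods({"expectation": e, "hybrid": h}, deg)
    rec = out.set_index(["mirna_id", "transcript_id"])
    assert rec.loc[("m1", "g1"), "in_overlap"]          # two methods
    assert not rec.loc[("m2", "g3"), "in_overlap"]      # one method only
    assert rec.loc[("m2", "g3"), "in_overall"]
    assert rec.loc[("m4", "g9"), "in_overlap"]          # degradome alone
    assert (out["in_overall"] | ~out["in_overlap"]).all()  # overlap => overall


def test_integration_needs_two_methods():
    with pytest.raises(ValueError):
        tp.integrate_methods({"expectation": pd.DataFrame()}, None)
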