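"""RPM/FPKM arithmetic, tissue averaging, pattern classes, 2^-ddCt."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mircascade import expression as ex

TISSUES = ["RS", "SS", "LS", "RG", "SG", "LG", "P"]


def _loci_df():
    return pd.DataFrame(
        [{"locus_id": "L1", "chrom": "c1", "strand": "+",
          "mature_start": 100, "mature_end": 121}]
    )


def _aln(start, end, seq="M1", strand="+"):
    return {"seq": seq, "chrom": "c1", "start": start, "end": end, "strand": strand}


def test_rpm_arithmetic_and_shift_rule():
    aln = pd.DataFrame([_aln(100, 121), _aln(101, 122, "M2"), _aln(103, 124, "M3")])
    counts = pd.DataFrame({"lib": {"M1": 100, "M2": 7, "M3": 999}})
    totals = pd.Series({"lib": 1_000_000})
    rpm = ex.quantify_mirna_rpm(aln, counts, _loci_df(), totals)
    # exact + 1-nt shift count; the 3-nt shift does not
    assert rpm.loc["L1", "lib"] == pytest.approx(107.0)


def test_rpm_requires_mapped_reads():
    with pytest.raises(ValueError, match="zero mapped"):
        ex.quantify_mirna_rpm(
            pd.DataFrame([_aln(100, 121)]),
            pd.DataFrame({"lib": {"M1": 1}}),
            _loci_df(),
            pd.Series({"lib": 0}),
        )


def test_rpm_wrong_strand_not_counted():
    aln = pd.DataFrame([_aln(100, 121, strand="-")])
    counts = pd.DataFrame({"lib": {"M1": 50}})
    rpm = ex.quantify_mirna_rpm(aln, counts, _loci_df(), pd.Series({"lib": 1000}))
    assert rpm.loc["L1", "lib"] == 0.0


def test_fpkm_arithmetic():
    counts = pd.DataFrame({"s1": {"t1": 200, "t2": 0}})
    lengths = pd.Series({"t1": 2000, "t2": 500})
    out = ex.quantify_fpkm(counts, lengths, pd.Series({"s1": 10_000_000}))
    assert out.loc["t1", "s1"] == pytest.approx(10.0)
    assert out.loc["t2", "s1"] == 0.0


def test_fpkm_toy_table_matches_hand_computation():
    rng = np.random.default_rng(2)
    counts = pd.DataFrame(rng.integers(0, 500, size=(3, 3)),
                          index=list("abc"), columns=list("xyz"))
    lengths = pd.Series({"a": 1000, "b": 1500, "c": 700})
    totals = pd.Series({"x": 1e6, "y": 2e6, "z": 5e5})
    out = ex.quantify_fpkm(counts, lengths, totals)
    for g in "abc":
        for s in "xyz":
            expect = counts.loc[g, s] / (lengths[g] / 1e3) / (totals[s] / 1e6)
            assert out.loc[g, s] == pytest.approx(expect)


def test_fpkm_zero_length_errors():
    with pytest.raises(ValueError):
        ex.quantify_fpkm(pd.DataFrame({"s": {"t": 5}}), pd.Series({"t": 0}))


def test_average_by_tissue():
    mat = pd.DataFrame({"T1_1": {"g": 10.0}, "T1_2": {"g": 20.0}, "T2_1": {"g": 7.0}})
    samples = pd.DataFrame(
        [{"lib_id": "T1_1", "tissue": "T1", "replicate": 1},
         {"lib_id": "T1_2", "tissue": "T1", "replicate": 2},
         {"lib_id": "T2_1", "tissue": "T2", "replicate": 1}]
    )
    out = ex.average_by_tissue(mat, samples)
    assert out.loc["g", "T1"] == 15.0 and out.loc["g", "T2"] == 7.0
    with pytest.raises(ValueError, match="T9"):
        ex.average_by_tissue(mat, samples, tissues=["T1", "T9"])


def test_pattern_examples():
    m = pd.DataFrame(
        [
            [150, 200, 120, 300, 110, 101, 100],   # housekeeping (>=100 everywhere)
            [500, 5, 5, 5, 5, 5, 5],               # tissue-specific, peak RS
            [9, 9, 9, 9, 9, 9, 9],                 # low
            [50, 20, 9, 9, 9, 9, 9],               # intermediate
        ],
        columns=TISSUES, index=["h", "t", "l", "i"],
    )
    out = ex.classify_patterns(m)
    assert out.loc["h", "pattern_class"] == "housekeeping"
    assert out.loc["t", "pattern_class"] == "tissue_specific"
    assert out.loc["t", "peak_tissue"] == "RS"
    assert out.loc["l", "pattern_class"] == "low"
    assert out.loc["i", "pattern_class"] == "intermediate"


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.lists(st.floats(0, 1000, allow_nan=False), min_size=7, max_size=7),
        min_size=1, max_size=12,
    )
)
def test_pattern_classes_partition(rows):
    m = pd.DataFrame(rows, columns=TISSUES)
    out = ex.classify_patterns(m)
    assert set(out["pattern_class"]) <= {
        "housekeeping", "tissue_specific", "low", "intermediate"
    }
    assert len(out) == len(m)  # every miRNA gets exactly one class


def test_pattern_degenerate_high_cut():
    m = pd.DataFrame([[500.0] * 7, [1.0] * 7], columns=TISSUES)
    out = ex.classify_patterns(m, high_cut=np.inf)
    assert set(out["pattern_class"]) <= {"low", "intermediate"}


def test_rpm_scaling_invariance():
    aln = pd.DataFrame([_aln(100, 121)])
    loci = _loci_df()
    c1 = pd.DataFrame({"lib": {"M1": 100}})
    r1 = ex.quantify_mirna_rpm(aln, c1, loci, pd.Series({"lib": 10_000}))
    r2 = ex.quantify_mirna_rpm(aln, 2 * c1, loci, pd.Series({"lib": 20_000}))
    pd.testing.assert_frame_equal(r1, r2)


@pytest.mark.parametrize(
    "args,expected",
    [((20.0, 18.0, 22.0, 20.0), 1.0),    # ddCt = 0
     ((22.0, 18.0, 20.0, 18.0), 0.25),   # ddCt = 2
     ((19.0, 18.0, 20.0, 18.0), 2.0)],   # ddCt = -1
)
def test_ddct(args, expected):
    assert ex.ddct(*args) == pytest.approx(expected)


def test_matrix_roundtrip(tmp_path):
    mat = pd.DataFrame({"A_1": {"x": 1.5}, "A_2": {"x": 2.0}, "B_1": {"x": 0.0}})
    samples = pd.DataFrame(
        [{"lib_id": "A_1", "tissue": "A", "replicate": 1},
         {"lib_id": "A_2", "tissue": "A", "replicate": 2},
         {"lib_id": "B_1", "tissue": "B", "replicate": 1}]
    )
    p = tmp_path / "m.tsv"
    ex.write_matrix(p, mat, samples)
    mat2, samples2 = ex.read_matrix(p)
    pd.testing.assert_frame_equal(mat, mat2, check_dtype=False, check_names=False)
    assert list(samples2["tissue"]) == ["A", "A", "B"]
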