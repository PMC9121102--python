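"""Shared fixtures: one full default-condition pipeline run per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mircascade import syndata as sd
from mircascade.pipeline import PipelineConfig, run_all

SMALL_SIM = dict(
    chrom_len=250_000, n_transcripts=120, n_free_targets=60, block_size=10,
    depth_per_lib=20_000, mrna_depth=2_000_000,
)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default synthetic study (seed 42)."""
    out = tmp_path_factory.mktemp("default_run")
    cfg = PipelineConfig(seed=42, out_dir=str(out))
    manifest = run_all(cfg)
    truth = sd.load_truth(out / "sim")
    return {"out": out, "manifest": manifest, "truth": truth, "config": cfg}


@pytest.fixture(scope="session")
def small_truth():
    """In-memory reduced synthetic genome (no reads)."""
    cfg = sd.SimulationConfig(seed=11, **SMALL_SIM)
    return sd.make_genome(cfg)


def match_loci_to_truth(loci: pd.DataFrame, truth_loci: pd.DataFrame) -> pd.Series:
    """Truth id per annotated locus (mature anchor within 2 nt), '' if none."""
    out = []
    for _, row in loci.iterrows():
        m = truth_loci[
            (truth_loci["chrom"] == row["chrom"])
            & (truth_loci["strand"] == row["strand"])
            & ((truth_loci["mature_start"] - row["mature_start"]).abs() <= 2)
        ]
        out.append(m.iloc[0]["truth_id"] if len(m) else "")
    return pd.Series(out, index=loci.index)


def brute_force_ffls(tmi, mti, tti):
    """Triple-loop cascade/FFL enumeration used as the counting oracle."""
    tmi_s = set(tmi)
    mti_s = set(mti)
    tti_s = set(tti)
    tfs = {t for t, _ in tmi_s}
    mirnas = {m for _, m in tmi_s} | {m for m, _ in mti_s}
    genes = {g for _, g in mti_s} | {g for _, g in tti_s}
    cascades, ffls = set(), set()
    for t in tfs:
        for m in mirnas:
            for g in genes:
                if (t, m) in tmi_s and (m, g) in mti_s:
                    cascades.add((t, m, g))
                    if (t, g) in tti_s:
                        ffls.add((t, m, g))
    return cascades, ffls
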