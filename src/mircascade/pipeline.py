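"""End-to-end orchestration of the miRNA regulatory-network analysis.

``run_all`` executes: simulate (optional) -> small-RNA preparation -> miRNA
annotation -> target prediction + degradome confirmation -> expression
quantification -> correlation statistics -> co-expression modules ->
TF/miRNA/target network, writing per-stage tables plus a run manifest with
parameter snapshots, output hashes and wall times. All randomness derives
from the single configured seed, so a repeated run reproduces identical
output hashes (wall times excluded).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpress as cx
from . import degradome as dg
from . import expression as ex
from . import mirna_annot as ma
from . import network as nw
from . import srna_prep as sp
from . import stats as st
from . import syndata as sd
from . import target_pred as tp
from .seqio import read_fasta, sha256_file, write_gff3
from .seqio import read_fasta_with_desc, to_rna

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "validate", "run_all"]

STAGES = [
    "simulate", "srna_prep", "mirna_annot", "target_pred", "degradome",
    "expression", "stats", "coexpress", "network",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    seed: int = 42
    out_dir: str = "mircascade_run"
    input_dir: str = ""              # existing syndata-layout inputs; empty = simulate
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    simulation: sd.SimulationConfig = field(default_factory=sd.SimulationConfig)
    annotation: ma.AnnotationConfig = field(default_factory=ma.AnnotationConfig)
    targets: tp.TargetConfig = field(default_factory=tp.TargetConfig)
    coexpression: cx.CoexpressionConfig = field(default_factory=cx.CoexpressionConfig)
    min_len: int = 18
    max_len: int = 30
    pred_min_len: int = 19
    pred_max_len: int = 25
    ncrna_max_mm: int = 1
    conservation_max_mm: int = 2
    cluster_max_gap: int = 10_000
    rpm_max_shift: int = 2
    pattern_high_cut: float = 100.0
    pattern_low_cut: float = 10.0
    degradome_keep: tuple[int, ...] = (0, 1)
    mti_dataset: str = "overlap"     # which dataset feeds MTI edges
    promoter_len: int = 2000
    motif_p_cut: float = 1e-4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(open(path)) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sub = {
            "simulation": sd.SimulationConfig,
            "annotation": ma.AnnotationConfig,
            "targets": tp.TargetConfig,
            "coexpression": cx.CoexpressionConfig,
        }
        kwargs = {}
        for key, val in raw.items():
            if key in sub:
                known = {f.name for f in dataclasses.fields(sub[key])}
                bad = set(val) - known
                if bad:
                    raise ValueError(f"unknown keys in {key}: {sorted(bad)}")
                kwargs[key] = sub[key](**val)
            elif key in {f.name for f in dataclasses.fields(cls)}:
                kwargs[key] = val
            else:
                raise ValueError(f"unknown configuration key {key!r}")
        cfg = cls(**kwargs)
        cfg.simulation.seed = cfg.seed
        return cfg


def validate(config: PipelineConfig) -> list[str]:
    """Aggregate every configuration problem into one report (empty = ok)."""
    errors: list[str] = []
    try:
        config.simulation.validate()
    except ValueError as exc:
        errors.append(str(exc))
    if config.coexpression.beta < 1:
        errors.append(f"soft power beta must be >= 1, got {config.coexpression.beta}")
    if not 0 < config.coexpression.cut_height <= 1:
        errors.append("cut_height must be in (0, 1]")
    if config.targets.e_cutoff <= 0:
        errors.append("expectation cutoff must be positive")
    if not 0 < config.targets.ratio_cutoff <= 1:
        errors.append("MFE/MDE ratio cutoff must be in (0, 1]")
    if config.mti_dataset not in ("overall", "overlap"):
        errors.append("mti_dataset must be 'overall' or 'overlap'")
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        errors.append(f"unknown stages {sorted(unknown)}")
    if config.input_dir:
        need = ["genome.fa", "transcripts.fa", "ncrna.fa", "catalogue.fa",
                "pwms.motifs", "tf_list.tsv", "synteny_blocks.tsv"]
        for f in need:
            if not (Path(config.input_dir) / f).exists():
                errors.append(f"missing input file {f} in {config.input_dir}")
    return errors


def run_all(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest dict."""
    errors = validate(config)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "hashes": {}, "summary": {}}
    ctx: dict = {}

    def record(stage: str, t0: float, params: dict, files: list[Path]) -> None:
        entry = {
            "stage": stage,
            "wall_time_s": round(time.time() - t0, 3),
            "params": params,
            "outputs": {},
        }
        for f in files:
            h = sha256_file(f)
            entry["outputs"][f.name] = h
            manifest["hashes"][f.name] = h
        manifest["stages"].append(entry)

    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        try:
            files = _STAGE_FUNCS[stage](config, out, ctx)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        params = _stage_params(config, stage)
        record(stage, t0, params, files)
    manifest["summary"] = ctx.get("summary", {})
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _stage_params(config: PipelineConfig, stage: str) -> dict:
    if stage == "simulate":
        return dataclasses.asdict(config.simulation)
    if stage == "mirna_annot":
        return dataclasses.asdict(config.annotation)
    if stage == "target_pred":
        d = dataclasses.asdict(config.targets)
        return d
    if stage == "coexpress":
        return dataclasses.asdict(config.coexpression)
    return {
        k: getattr(config, k)
        for k in ("min_len", "max_len", "pred_min_len", "pred_max_len",
                  "ncrna_max_mm", "rpm_max_shift", "pattern_high_cut",
                  "pattern_low_cut", "motif_p_cut", "mti_dataset")
    }


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _indir(config: PipelineConfig, out: Path) -> Path:
    return Path(config.input_dir) if config.input_dir else out / "sim"


def _stage_simulate(config: PipelineConfig, out: Path, ctx: dict) -> list[Path]:
    if config.input_dir:
        return []
    simdir = out / "sim"
    truth = sd.simulate(config.simulation, simdir)
    ctx["truth"] = truth
    return sorted(simdir.glob("*"))


def _stage_srna_prep(config: PipelineConfig, out: Path, ctx: dict) -> list[Path]:
    indir = _indir(config, out)
    fastqs = sorted(indir.glob("srna_*.fastq"))
    libs = {p.stem.replace("srna_", ""): p for p in fastqs}
    raw = sp.load_libraries(libs)
    clean = sp.clean_reads(raw, config.min_len, config.max_len)
    hist_clean, hist_uniq, mode = sp.length_distribution(clean)
    ncrna = read_fasta(indir / "ncrna.fa")
    kept = sp.filter_ncrna(clean, ncrna, max_mm=config.ncrna_max_mm)
    genome = read_fasta(indir / "genome.fa")
    aln = sp.map_reads(kept.index, genome)
    mapped_seqs = pd.Index(aln["seq"].unique())
    totals = kept.loc[kept.index.intersection(mapped_seqs)].sum(axis=0)
    pred = sp.select_prediction_set(kept, config.pred_min_len, config.pred_max_len)
    pred_aln = aln[aln["seq"].isin(set(pred.index))]
    ctx.update(
        genome=genome, clean=kept, alignments=aln, pred=pred,
        pred_aln=pred_aln, totals=totals,
    )
    hist_clean.to_csv(out / "length_hist_clean.tsv", sep="\t")
    hist_uniq.to_csv(out / "length_hist_unique.tsv", sep="\t")
    mode.rename("modal_length").to_csv(out / "length_mode.tsv", sep="\t")
    sp.write_collapsed_fasta(out / "collapsed.fa", kept)
    return [out / "length_hist_clean.tsv", out / "length_hist_unique.tsv",
            out / "length_mode.tsv", out / "collapsed.fa"]


def _stage_mirna_annot(config: PipelineConfig, out: Path, ctx: dict) -> list[Path]:
    indir = _indir(config, out)
    loci, rejected = ma.annotate_loci(
        ctx["pred_aln"], ctx["pred"], ctx["genome"], config.annotation
    )
    catalogue = ma.parse_catalogue(read_fasta_with_desc(indir / "catalogue.fa"))
    loci = ma.assign_family(loci, catalogue, max_mm=config.conservation_max_mm)
    loci = ma.assign_ids(loci, prefix=config.annotation.id_prefix)
    clusters = ma.detect_clusters(loci, max_gap=config.cluster_max_gap)
    blocks = pd.read_csv(indir / "synteny_blocks.tsv", sep="\t")
    anchors = ma.anchor_synteny(loci, blocks)
    ctx.update(loci=loci, clusters=clusters, anchors=anchors)
    loci.drop(columns=["precursor_seq", "structure"]).to_csv(
        out / "loci.tsv", sep="\t", index=False
    )
    with open(out / "loci_structures.txt", "w") as fh:
        for _, r in loci.iterrows():
            fh.write(f">{r['locus_id']}\n{r['precursor_seq']}\n{r['structure']}\n")
    write_gff3(out / "loci.gff3", ma.loci_to_gff3(loci))
    rejected.to_csv(out / "rejected_candidates.tsv", sep="\t", index=False)
    clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)
    anchors.to_csv(out / "synteny_anchors.tsv", sep="\t", index=False)
    ctx.setdefault("summary", {}).update(
        n_loci=int(len(loci)),
        n_families=int(loci["family"].nunique()),
        n_clusters=int(len(clusters)),
        n_syntenic_pairs=int(anchors["syntenic_pair"].sum() // 2) if len(anchors) else 0,
        conservation_counts=loci["conservation_class"].value_counts().to_dict(),
    )
    return [out / "loci.tsv", out / "loci.gff3", out / "loci_structures.txt",
            out / "rejected_candidates.tsv", out / "clusters.tsv",
            out / "synteny_anchors.tsv"]


def _stage_target_pred(config: PipelineConfig, out: Path, ctx: dict) -> list[Path]:
    indir = _indir(config, out)
    transcripts = read_fasta(indir / "transcripts.fa")
    mirnas = {
        r["locus_id"]: to_rna(r["mature_seq"]) for _, r in ctx["loci"].iterrows()
    }
    expect = tp.scan_transcriptome(mirnas, transcripts, config=config.targets)
    hybrid = tp.scan_hybrid(mirnas, transcripts, config=config.targets)
    ctx.update(transcripts=transcripts, expect=expect, hybrid=hybrid)
    expect.to_csv(out / "hits_expectation.tsv", sep="\t", index=False)
    hybrid.to_csv(out / "hits_hybrid.tsv", sep="\t", index=False)
    return [out / "hits_expectation.tsv", out / "hits_hybrid.tsv"]


def _stage_degradome(config: PipelineConfig, out: Path, ctx: dict) -> list[Path]:
    indir = _indir(config, out)
    tags = dg.load_tags(sorted(indir.glob("pare_*.fasta")))
    profiles = dg.build_density(tags, ctx["transcripts"])
    candidates = pd.concat(
        [ctx["expect"][["mirna_id", "transcript_id", "site_start", "site_end"]],
         ctx["hybrid"][["mirna_id", "transcript_id", "site_start", "site_end"]]],
        ignore_index=True,
    ).drop_duplicates(["mirna_id", "transcript_id"])
    calls = dg.confirm_pairs(candidates, profiles, keep=set(config.degradome_keep))
    confirmed = calls[calls["confirmed"]]
    interactions = tp.integrate_methods(
        {"expectation": ctx["expect"], "hybrid": ctx["hybrid"]},
        confirmed.rename(columns={"position": "cleavage_pos"}),
    )
    ctx.update(interactions=interactions, degradome_calls=calls)
    dens_rows = []
    for tid, prof in sorted(profiles.items()):
        for pos in np.nonzero(prof)[0]:
            dens_rows.append({"transcript_id": tid, "position": int(pos),
                              "depth": int(prof[pos])})
    pd.DataFrame(dens_rows).to_csv(out / "density.tsv", sep="\t", index=False)
    calls.to_csv(out / "degradome_calls.tsv", sep="\t", index=False)
    interactions.to_csv(out / "interactions.tsv", sep="\t", index=False)
    ctx.setdefault("summary", {}).update(
        n_interactions_overall=int(interactions["in_overall"].sum()),
        n_interactions_overlap=int(interactions["in_overlap"].sum()),
        n_targets_overall=int(interactions["transcript_id"].nunique()),
        n_degradome_confirmed=int(len(confirmed)),
    )
    return [out / "density.tsv", out / "degradome_calls.tsv", out / "interactions.tsv"]


def _stage_expression(config: PipelineConfig, out: Path, ctx: dict) -> list[Path]:
    indir = _indir(config, out)
    loci = ctx["loci"]
    rpm = ex.quantify_mirna_rpm(
        ctx["pred_aln"], ctx["pred"], loci, ctx["totals"],
        max_shift=config.rpm_max_shift,
    )
    counts = pd.read_csv(indir / "mrna_counts.tsv", sep="\t", index_col=0)
    transcripts = ctx["transcripts"]
    lengths = pd.Series({t: len(s) for t, s in transcripts.items()})
    totals = None
    totals_path = indir / "mrna_totals.tsv"
    if totals_path.exists():
        tdf = pd.read_csv(totals_path, sep="\t")
        totals = tdf.set_index("lib_id")["total_fragments"].reindex(counts.columns)
    fpkm = ex.quantify_fpkm(counts, lengths, totals)
    s_samples = sd.srna_samples(config.simulation)
    m_samples = sd.mrna_samples(config.simulation)
    tissues = list(config.simulation.tissues)
    rpm_t = ex.average_by_tissue(rpm, s_samples, tissues)
    fpkm_t = ex.average_by_tissue(fpkm, m_samples, tissues)
    patterns = ex.classify_patterns(rpm_t, config.pattern_high_cut, config.pattern_low_cut)
    ctx.update(rpm=rpm, fpkm=fpkm, rpm_t=rpm_t, fpkm_t=fpkm_t,
               patterns=patterns, s_samples=s_samples, m_samples=m_samples)
    ex.write_matrix(out / "mirna_rpm.tsv", rpm, s_samples)
    ex.write_matrix(out / "target_fpkm.tsv", fpkm, m_samples)
    patterns.to_csv(out / "patterns.tsv", sep="\t")
    ctx.setdefault("summary", {}).update(
        pattern_counts=patterns["pattern_class"].value_counts().to_dict()
    )
    return [out / "mirna_rpm.tsv", out / "target_fpkm.tsv", out / "patterns.tsv"]


def _stage_stats(config: PipelineConfig, out: Path, ctx: dict) -> list[Path]:
    inter = ctx["interactions"]
    pairs = inter[inter["in_overlap"]] if config.mti_dataset == "overlap" else inter
    records = st.correlate_pairs(ctx["rpm_t"], ctx["fpkm_t"], pairs)
    frac, neg, total = st.negative_fraction(records)
    ctx.update(correlations=records)
    records.to_csv(out / "correlations.tsv", sep="\t", index=False)
    ctx.setdefault("summary", {}).update(
        negative_fraction=round(float(frac), 4),
        n_negative=neg, n_correlated=total,
    )
    return [out / "correlations.tsv"]


def _stage_coexpress(config: PipelineConfig, out: Path, ctx: dict) -> list[Path]:
    inter = ctx["interactions"]
    targets = sorted(inter.loc[inter["in_overall"], "transcript_id"].unique())
    expr = np.log2(ctx["fpkm"].loc[ctx["fpkm"].index.intersection(targets)] + 1.0)
    expr = cx.filter_genes(expr, config.coexpression.max_missing)
    adj = cx.adjacency(expr, beta=config.coexpression.beta)
    tom = cx.topological_overlap(adj)
    modules = cx.detect_modules(tom, config.coexpression)
    eig = cx.module_eigengene(expr, modules)
    mt = cx.module_trait(eig, ctx["m_samples"], config.coexpression,
                         list(config.simulation.tissues))
    hubs = cx.kme_hubs(expr, modules, eig, config.coexpression.n_hubs)
    traced = {}
    for mod in eig.index:
        sub, degree = cx.trace_module_mirnas(
            set(modules.index[modules == mod]), inter[inter["in_overall"]]
        )
        traced[mod] = degree
    ctx.update(modules=modules, eigengenes=eig, module_trait=mt, hubs=hubs)
    modules.rename("module").to_csv(out / "modules.tsv", sep="\t")
    eig.to_csv(out / "eigengenes.tsv", sep="\t")
    mt.to_csv(out / "module_trait.tsv", sep="\t", index=False)
    hubs.to_csv(out / "hubs.tsv", sep="\t", index=False)
    ctx.setdefault("summary", {}).update(
        n_modules=int(len(eig)),
        n_modules_retained=int(mt.groupby("module")["retained"].any().sum()) if len(mt) else 0,
    )
    return [out / "modules.tsv", out / "eigengenes.tsv", out / "module_trait.tsv",
            out / "hubs.tsv"]


def _stage_network(config: PipelineConfig, out: Path, ctx: dict) -> list[Path]:
    indir = _indir(config, out)
    genome = ctx["genome"]
    loci = ctx["loci"]
    inter = ctx["interactions"]
    dataset = inter[inter["in_overlap"]] if config.mti_dataset == "overlap" else inter
    mir_feats = loci.rename(columns={"locus_id": "id"})[
        ["id", "chrom", "strand", "precursor_start", "precursor_end"]
    ].rename(columns={"precursor_start": "start", "precursor_end": "end"})
    tx_truth = pd.read_csv(indir / "truth_transcripts.tsv", sep="\t")
    target_ids = set(dataset["transcript_id"])
    gene_feats = tx_truth[tx_truth["transcript_id"].isin(target_ids)].rename(
        columns={"transcript_id": "id"}
    )[["id", "chrom", "strand", "start", "end"]]
    mir_proms = nw.extract_promoters(mir_feats, genome, config.promoter_len)
    gene_proms = nw.extract_promoters(gene_feats, genome, config.promoter_len)
    pwms = nw.read_pwms(indir / "pwms.motifs")
    mir_hits = nw.scan_motifs(mir_proms, pwms, p_cut=config.motif_p_cut)
    gene_hits = nw.scan_motifs(gene_proms, pwms, p_cut=config.motif_p_cut)
    tf_map = pd.read_csv(indir / "tf_list.tsv", sep="\t")
    edges = nw.build_edges(mir_hits, gene_hits, dataset, tf_map,
                           known_genes=set(tx_truth["transcript_id"]))
    cascades, ffls, counts = nw.enumerate_motifs(edges["TMI"], edges["MTI"], edges["TTI"])
    paths = nw.export_network(edges, out)
    cascades.to_csv(out / "cascades.tsv", sep="\t", index=False)
    ffls.to_csv(out / "ffls.tsv", sep="\t", index=False)
    for etype, df in edges.items():
        df.to_csv(out / f"edges_{etype.lower()}.tsv", sep="\t", index=False)
    ctx.setdefault("summary", {}).update(counts)
    return [out / "cascades.tsv", out / "ffls.tsv", Path(paths["sif"]),
            Path(paths["nodes"]), Path(paths["graphml"]),
            *[out / f"edges_{e.lower()}.tsv" for e in edges]]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "srna_prep": _stage_srna_prep,
    "mirna_annot": _stage_mirna_annot,
    "target_pred": _stage_target_pred,
    "degradome": _stage_degradome,
    "expression": _stage_expression,
    "stats": _stage_stats,
    "coexpress": _stage_coexpress,
    "network": _stage_network,
}
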