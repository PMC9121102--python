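"""Synthetic study generator: toy genome, reads, expression, motifs, truth.

Emulates the design of a seven-tissue small-RNA / mRNA / PARE survey of a
cereal genome: 14 sRNA libraries (7 tissues x 2 replicates), 21 mRNA
libraries (7 x 3), 7 PARE libraries (7 x 1). The genome carries planted
miRNA hairpins that satisfy the plant annotation criteria, decoy hairpins
that each violate exactly one named criterion, protein-coding transcripts
with 2,000-nt promoters (some carrying planted TF motifs), miRNA target
sites with cleavage positions, and block-structured tissue expression with
miRNA -> target repression. Every planted entity is recorded in machine-
checkable truth tables so each downstream stage can be scored exactly.

Design notes
------------
* Hairpin arms use complementary two-letter alphabets (mature A/C, star G/U)
  and A/C-only flanks, so the maximum-base-pairing structure of an excised
  window is essentially unique and flanking sequence cannot invade the stem.
* Counts are Gamma-Poisson (i.e. negative binomial): one Gamma-distributed
  latent mean per entity and library is shared between the continuous
  expression matrices and the Poisson read counts, so read-derived RPM and
  the matrices agree in expectation.
* One RNG stream per output file / component, derived from the master seed
  by stable labels, so outputs are byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import rng_for
from .seqio import revcomp, to_dna, to_rna, write_fasta, write_fastq, write_gff3

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "make_genome",
    "simulate_srna_reads",
    "simulate_degradome_reads",
    "simulate_mrna_counts",
    "simulate_expression_matrices",
    "simulate",
    "load_truth",
]

TISSUES = ("RS", "SS", "LS", "RG", "SG", "LG", "P")

# read-length distribution of the background small-RNA population (18..30 nt),
# peaked at 24 nt as in typical plant libraries dominated by siRNAs
_BG_LEN = np.arange(18, 31)
_BG_LEN_P = np.array(
    [0.015, 0.03, 0.04, 0.06, 0.07, 0.10, 0.30, 0.14, 0.08, 0.06, 0.045, 0.035, 0.025]
)

_RNA_COMP = str.maketrans("ACGU", "UGCA")


def _rna_revcomp(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study (defaults are the study conditions)."""

    seed: int = 42
    n_chrom: int = 2
    chrom_len: int = 500_000
    n_true_loci: int = 30
    n_decoy_loci: int = 10
    n_transcripts: int = 300
    tissues: tuple[str, ...] = TISSUES
    srna_reps: int = 2
    mrna_reps: int = 3
    pare_reps: int = 1
    depth_per_lib: int = 120_000
    mrna_depth: int = 20_000_000
    pare_depth_per_site: float = 15.0
    nb_dispersion: float = 0.08
    repression_strength: float = 0.9
    n_pwms: int = 6
    pwm_length: int = 8
    n_tf_genes: int = 40
    promoter_plant_rate: float = 0.4
    n_blocks: int = 3
    block_size: int = 25
    n_free_targets: int = 200
    promoter_len: int = 2000
    flank_len: int = 300

    def validate(self) -> None:
        if self.n_true_loci < 1:
            raise ValueError("n_true_loci must be >= 1")
        for name in ("repression_strength", "promoter_plant_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if len(self.tissues) != 7:
            raise ValueError("exactly 7 tissue labels are expected")
        needed = self.n_blocks * self.block_size + self.n_free_targets
        if self.n_transcripts < needed:
            raise ValueError(
                f"n_transcripts={self.n_transcripts} cannot host "
                f"{self.n_blocks}x{self.block_size} block genes plus "
                f"{self.n_free_targets} free targets"
            )


@dataclass
class TruthTable:
    """All planted entities, keyed consistently across tables."""

    loci: pd.DataFrame          # true loci and decoys (is_decoy, violation)
    transcripts: pd.DataFrame
    target_sites: pd.DataFrame  # mirna truth id, transcript, site, cleavage pos
    tf_sites: pd.DataFrame
    synteny_blocks: pd.DataFrame
    tf_map: pd.DataFrame        # tf gene -> pwm
    pwms: list[dict]
    catalogue: list[tuple[str, str, str]]   # (id, description, mature RNA)
    ncrna: list[tuple[str, str]]
    genome: dict[str, str]
    config: SimulationConfig


# --------------------------------------------------------------------------
# planted design: families, conservation, placement plan, expression classes
# --------------------------------------------------------------------------

# (family, n_members, conservation). Totals: 16 conserved, 6 poaceae, 8 novel.
_FAMILY_PLAN = [
    ("miR395", 3, "conserved"),
    ("miR2275", 2, "poaceae_specific"),
    ("miR156", 2, "conserved"),
    ("miR166", 3, "conserved"),
    ("miR167", 2, "conserved"),
    ("miR172", 2, "conserved"),
    ("miR396", 2, "conserved"),
    ("miR408", 1, "conserved"),
    ("miR827", 1, "conserved"),
    ("miR1432", 2, "poaceae_specific"),
    ("miR5179", 2, "poaceae_specific"),
    ("NOV1", 2, "species_specific"),
    ("NOV2", 2, "species_specific"),
    ("NOV3", 2, "species_specific"),
    ("NOV4", 2, "species_specific"),
]

# families whose members are placed back-to-back (genomic miRNA clusters)
_CLUSTER_FAMILIES = {"miR395", "miR2275"}
# families whose two members are split across chromosomes and wrapped in a
# collinearity block pair (syntenic duplicates)
_SYNTENY_FAMILIES = ("miR156", "miR396")

_DECOY_VIOLATIONS = [
    "duplex_mismatches", "duplex_mismatches", "duplex_mismatches",
    "asym_bulge", "asym_bulge", "asym_bulge",
    "star", "star",
    "precision", "precision",
]


def _mature_pool(rng: np.random.Generator, n_fam: int, length: int = 21) -> list[str]:
    """Family base matures over the A/C alphabet, mutually distant."""
    out: list[str] = []
    while len(out) < n_fam:
        cand = "".join(rng.choice(["A", "C"], size=length))
        if all(sum(a != b for a, b in zip(cand, s)) > 6 for s in out):
            out.append(cand)
    return out


def _member_mature(rng: np.random.Generator, base: str) -> str:
    """A family member: the base with at most one A<->C substitution."""
    s = list(base)
    if rng.random() < 0.7:
        i = int(rng.integers(2, len(s) - 3))
        s[i] = "C" if s[i] == "A" else "A"
    return "".join(s)


def _make_hairpin(rng: np.random.Generator, mature: str, violation: str | None):
    """Return (precursor RNA, mature ivl, star ivl) in precursor coordinates.

    Layout 5'->3': mature (5' arm) | loop | star (3' arm), with canonical
    2-nt 3' overhangs on both duplex ends.
    """
    loop = "".join(rng.choice(["C", "A"], size=9))
    core = list(_rna_revcomp(mature[:19]))  # core[k] pairs mature[18-k]
    if violation == "duplex_mismatches":
        for i in (2, 5, 8, 11, 14, 16):     # 6 isolated mismatches, > limit of 5
            core[18 - i] = "A"
    elif violation == "asym_bulge":
        core = core[:10] + ["A"] * 4 + core[10:]  # 4-nt bulge, > limit of 3
    star = "".join(core) + "CC"             # CC: inert 3' overhang
    pre = mature + loop + star
    m_ivl = (0, len(mature))
    s_ivl = (len(mature) + len(loop), len(pre))
    return pre, m_ivl, s_ivl


def _expression_classes(n_true: int, tissues: tuple[str, ...]) -> list[tuple[str, str]]:
    """(pattern_class, peak_tissue) per true locus, in locus order."""
    peaks = ["SS", "SG", "SG", "P", "P", "RS", "LG", "RG", "LG", "SS"]
    classes: list[tuple[str, str]] = []
    classes += [("housekeeping", "")] * 5
    classes += [("tissue_specific", p) for p in peaks]
    classes += [("low", "")] * 4
    while len(classes) < n_true:
        classes.append(("intermediate", ""))
    return classes[:n_true]


def _cassette_to_genome(offset: int, length: int, strand: str, a: int, b: int):
    """Map cassette-space interval [a, b) to genome coordinates."""
    if strand == "+":
        return offset + a, offset + b
    return offset + length - b, offset + length - a


def _oriented_slice(genome: dict[str, str], chrom: str, start: int, end: int, strand: str) -> str:
    s = genome[chrom][start:end]
    return revcomp(s) if strand == "-" else s


def _shifted_interval(start: int, end: int, strand: str, d5: int, d3: int):
    """Shift an interval by (d5, d3) measured in transcription orientation."""
    if strand == "+":
        return start + d5, end + d3
    return start - d3, end - d5


# --------------------------------------------------------------------------
# genome construction
# --------------------------------------------------------------------------

def make_genome(config: SimulationConfig, outdir: str | Path | None = None) -> TruthTable:
    """Build the toy genome, annotation and truth tables.

    Raises a sizing error naming the constraint if the configured chromosomes
    cannot host the requested loci and transcripts.
    """
    config.validate()
    cfg = config
    rng = rng_for(cfg.seed, "genome")
    P, F = cfg.promoter_len, cfg.flank_len

    # ---- locus specifications --------------------------------------------
    fam_names = [f for f, _, _ in _FAMILY_PLAN]
    bases = dict(zip(fam_names, _mature_pool(rng, len(fam_names))))
    loci_specs: list[dict] = []
    for fam, n, cons in _FAMILY_PLAN:
        for k in range(n):
            loci_specs.append(
                {
                    "truth_id": f"TL{len(loci_specs) + 1:03d}",
                    "family": fam,
                    "conservation": cons,
                    "mature": bases[fam] if k == 0 else _member_mature(rng, bases[fam]),
                    "is_decoy": False,
                    "violation": "",
                }
            )
    loci_specs = loci_specs[: cfg.n_true_loci]
    classes = _expression_classes(len(loci_specs), cfg.tissues)
    for spec, (cls, peak) in zip(loci_specs, classes):
        spec["pattern_class"] = cls
        spec["peak_tissue"] = peak

    decoy_pool = _mature_pool(rng, cfg.n_decoy_loci + len(fam_names))[len(fam_names):]
    for d in range(cfg.n_decoy_loci):
        loci_specs.append(
            {
                "truth_id": f"TD{d + 1:03d}",
                "family": "",
                "conservation": "",
                "mature": decoy_pool[d],
                "is_decoy": True,
                "violation": _DECOY_VIOLATIONS[d % len(_DECOY_VIOLATIONS)],
                "pattern_class": "decoy",
                "peak_tissue": "",
            }
        )

    # ---- transcript roles -------------------------------------------------
    n_block = cfg.n_blocks * cfg.block_size
    roles = (
        [f"block{b + 1}" for b in range(cfg.n_blocks) for _ in range(cfg.block_size)]
        + ["free"] * cfg.n_free_targets
        + ["none"] * (cfg.n_transcripts - n_block - cfg.n_free_targets)
    )
    true_ids = [s["truth_id"] for s in loci_specs if not s["is_decoy"]]
    hk_ids = [s["truth_id"] for s in loci_specs
              if s.get("pattern_class") == "housekeeping"]
    regulators: list[str] = []
    for i, role in enumerate(roles):
        if role.startswith("block"):
            # one shared housekeeping regulator per block: the module is
            # co-regulated, so repression shifts the whole block coherently
            regulators.append(hk_ids[(int(role[5:]) - 1) % len(hk_ids)])
        elif role == "free":
            regulators.append(true_ids[i % len(true_ids)])
        else:
            regulators.append("")

    # ---- placement plan ---------------------------------------------------
    # clusters first (members back-to-back), then singles interleaved with
    # transcripts so that unrelated loci sit > 10 kb apart.
    order: list[dict] = []
    placed = set()
    for fam in sorted(_CLUSTER_FAMILIES):
        group = [s for s in loci_specs if s["family"] == fam]
        for g in group:
            g["cluster"] = fam
            placed.add(g["truth_id"])
        order.append({"kind": "cluster", "loci": group})
    singles = [s for s in loci_specs if s["truth_id"] not in placed]
    for s in singles:
        s["cluster"] = ""
        order.append({"kind": "locus", "loci": [s]})

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    cursors = {c: 0 for c in chrom_names}
    parts: dict[str, list[str]] = {c: [] for c in chrom_names}

    def _emit(chrom: str, seq: str) -> int:
        start = cursors[chrom]
        if start + len(seq) > cfg.chrom_len:
            raise ValueError(
                f"chrom_len={cfg.chrom_len} too short to host the requested "
                f"loci/transcripts on {chrom} (needs >= {start + len(seq)})"
            )
        parts[chrom].append(seq)
        cursors[chrom] = start + len(seq)
        return start

    # split synteny families across chromosomes explicitly
    chrom_of: dict[str, str] = {}
    for fam in _SYNTENY_FAMILIES:
        members = [s for s in loci_specs if s["family"] == fam][:2]
        if len(members) == 2 and cfg.n_chrom >= 2:
            chrom_of[members[0]["truth_id"]] = chrom_names[0]
            chrom_of[members[1]["truth_id"]] = chrom_names[1]

    loci_rows: list[dict] = []
    tx_rows: list[dict] = []
    tf_site_rows: list[dict] = []
    site_rows: list[dict] = []

    pwms = _make_pwms(rng, cfg)
    tx_iter = iter(range(cfg.n_transcripts))
    tx_lengths = rng.integers(420, 680, size=cfg.n_transcripts)
    tf_genes = sorted(rng.choice(cfg.n_transcripts, size=cfg.n_tf_genes, replace=False))
    tf_pwm = {f"g{g + 1:04d}": pwms[i % len(pwms)]["motif_id"] for i, g in enumerate(tf_genes)}
    tf_gene_ids = set(tf_pwm)

    def _random_dna(n: int) -> str:
        return "".join(rng.choice(["A", "C", "G", "T"], size=n))

    def _promoter(owner: str, lo: int, hi: int) -> str:
        """A 2000-nt promoter; motifs planted at rate promoter_plant_rate."""
        seq = list(_random_dna(P))
        if rng.random() < cfg.promoter_plant_rate:
            pwm = pwms[int(rng.integers(0, len(pwms)))]
            L = len(pwm["consensus"])
            off = int(rng.integers(lo, hi - L))
            strand = "+" if rng.random() < 0.5 else "-"
            word = pwm["consensus"] if strand == "+" else revcomp(pwm["consensus"])
            seq[off : off + L] = list(word)
            tf_site_rows.append(
                {
                    "pwm_id": pwm["motif_id"],
                    "owner_id": owner,
                    # offset within the upstream-2000 window actually extracted
                    "offset": off - (lo - 20),
                    "strand": strand,
                }
            )
        return "".join(seq)

    def _place_locus(spec: dict, chrom: str) -> None:
        hp_rng = rng_for(cfg.seed, f"hairpin/{spec['truth_id']}")
        pre, m_ivl, s_ivl = _make_hairpin(hp_rng, spec["mature"], spec["violation"] or None)
        strand = "+" if (len(loci_rows) % 2 == 0) else "-"
        flank = lambda n: "".join(hp_rng.choice(["A", "C"], size=n))  # noqa: E731
        # locus promoter motifs are restricted to the part of the cassette
        # promoter that falls inside the upstream-2000 extraction window and
        # outside the ±250-nt folding window around the mature stack.
        prom = _promoter(spec["truth_id"], F + 20, P - 260)
        cassette = prom + flank(F) + to_dna(pre) + flank(F)
        Lc = len(cassette)
        offset = _emit(chrom, revcomp(cassette) if strand == "-" else cassette)
        pre_a, pre_b = P + F, P + F + len(pre)
        g = lambda a, b: _cassette_to_genome(offset, Lc, strand, a, b)  # noqa: E731
        ps, pe = g(pre_a, pre_b)
        ms, me = g(pre_a + m_ivl[0], pre_a + m_ivl[1])
        ss, se = g(pre_a + s_ivl[0], pre_a + s_ivl[1])
        loci_rows.append(
            {
                **{k: spec[k] for k in (
                    "truth_id", "family", "conservation", "is_decoy", "violation",
                    "pattern_class", "peak_tissue", "cluster",
                )},
                "chrom": chrom,
                "strand": strand,
                "precursor_start": ps,
                "precursor_end": pe,
                "mature_start": ms,
                "mature_end": me,
                "star_start": ss,
                "star_end": se,
                "mature_seq": spec["mature"],
                "star_seq": pre[s_ivl[0]: s_ivl[1]],
                "precursor_seq": pre,
            }
        )

    def _place_transcript(idx: int, chrom: str) -> None:
        gid = f"g{idx + 1:04d}"
        L = int(tx_lengths[idx])
        strand = "+" if idx % 2 == 0 else "-"
        body = list(_random_dna(L))
        role, reg = roles[idx], regulators[idx]
        site_info = None
        if reg:
            mat = next(s for s in loci_specs if s["truth_id"] == reg)["mature"]
            site = list(revcomp(to_dna(mat)))
            # one mismatch opposite a 3'-half miRNA position keeps E = 1 < 3
            # and makes the site inexact so mature reads do not multimap here
            mm_pos = int(rng.integers(15, 19))  # 1-based miRNA position 15..18
            j = len(mat) - mm_pos
            site[j] = "G" if mat[mm_pos - 1] == "A" else "T"
            off = int(rng.integers(60, L - len(site) - 60))
            body[off : off + len(site)] = site
            cleav = off + len(site) - 10  # nucleotide opposite miRNA position 10
            site_info = (reg, gid, off, off + len(site), cleav)
        prom = _promoter(gid, 20, 1980)
        cassette = prom + "".join(body) + _random_dna(100)
        Lc = len(cassette)
        offset = _emit(chrom, revcomp(cassette) if strand == "-" else cassette)
        bs, be = _cassette_to_genome(offset, Lc, strand, P, P + L)
        pr_s, pr_e = _cassette_to_genome(offset, Lc, strand, 0, P)
        tx_rows.append(
            {
                "transcript_id": gid,
                "chrom": chrom,
                "strand": strand,
                "start": bs,
                "end": be,
                "length": L,
                "promoter_start": pr_s,
                "promoter_end": pr_e,
                "role": role,
                "regulator": reg,
                "is_tf": gid in tf_gene_ids,
                "pwm_id": tf_pwm.get(gid, ""),
                "seq": "".join(body),
            }
        )
        if site_info:
            site_rows.append(
                dict(zip(("mirna_truth_id", "transcript_id", "site_start",
                          "site_end", "cleavage_pos"), site_info))
            )

    # interleave: each locus group followed by a handful of transcripts
    chrom_cycle = 0
    for group in order:
        chrom = chrom_of.get(group["loci"][0]["truth_id"], chrom_names[chrom_cycle % cfg.n_chrom])
        chrom_cycle += 1
        for spec in group["loci"]:
            _place_locus(spec, chrom_of.get(spec["truth_id"], chrom))
        for _ in range(4):
            idx = next(tx_iter, None)
            if idx is not None:
                _place_transcript(idx, chrom_names[chrom_cycle % cfg.n_chrom])
                chrom_cycle += 1
    for idx in tx_iter:
        _place_transcript(idx, chrom_names[chrom_cycle % cfg.n_chrom])
        chrom_cycle += 1

    # pad chromosomes with random background
    for c in chrom_names:
        pad = cfg.chrom_len - cursors[c]
        if pad > 0:
            parts[c].append(_random_dna(pad))
    genome = {c: "".join(parts[c]) for c in chrom_names}

    loci = pd.DataFrame(loci_rows)
    transcripts = pd.DataFrame(tx_rows)
    blocks = _make_synteny_blocks(loci, transcripts, cfg)
    catalogue = _make_catalogue(rng, loci)
    ncrna = [(f"ncRNA_{i + 1}", _random_dna(int(rng.integers(80, 150))))
             for i in range(6)]

    truth = TruthTable(
        loci=loci,
        transcripts=transcripts,
        target_sites=pd.DataFrame(site_rows),
        tf_sites=pd.DataFrame(tf_site_rows),
        synteny_blocks=blocks,
        tf_map=pd.DataFrame(
            [{"tf_gene": g, "pwm_id": p} for g, p in sorted(tf_pwm.items())]
        ),
        pwms=pwms,
        catalogue=catalogue,
        ncrna=ncrna,
        genome=genome,
        config=cfg,
    )
    if outdir is not None:
        _write_genome_files(truth, Path(outdir))
    return truth


def _make_pwms(rng: np.random.Generator, cfg: SimulationConfig) -> list[dict]:
    families = ["WRKY", "MYB", "ERF", "NAC", "SBP", "AP2", "bZIP", "C2H2"]
    pwms = []
    for i in range(cfg.n_pwms):
        consensus = "".join(rng.choice(["A", "C", "G", "T"], size=cfg.pwm_length))
        mat = np.full((cfg.pwm_length, 4), 0.03)
        for j, b in enumerate(consensus):
            mat[j, "ACGT".index(b)] = 0.91
        pwms.append(
            {
                "motif_id": f"M{i + 1:03d}",
                "tf_family": families[i % len(families)],
                "matrix": mat,
                "consensus": consensus,
            }
        )
    return pwms


def _make_synteny_blocks(loci: pd.DataFrame, transcripts: pd.DataFrame,
                         cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    bid = 0
    for fam in _SYNTENY_FAMILIES:
        mem = loci[(loci["family"] == fam) & (~loci["is_decoy"])].head(2)
        if len(mem) < 2 or mem.iloc[0]["chrom"] == mem.iloc[1]["chrom"]:
            continue
        bid += 1
        a, b = mem.iloc[0], mem.iloc[1]
        rows.append(
            {
                "block_id": f"B{bid:03d}",
                "chrom_a": a["chrom"],
                "start_a": max(0, int(a["precursor_start"]) - 3000),
                "end_a": int(a["precursor_end"]) + 3000,
                "chrom_b": b["chrom"],
                "start_b": max(0, int(b["precursor_start"]) - 3000),
                "end_b": int(b["precursor_end"]) + 3000,
                "orientation": "+",
            }
        )
    # one block anchoring a single locus (no partner) and one empty block
    single = loci[(~loci["is_decoy"]) & (loci["family"] == "miR408")]
    if len(single):
        s = single.iloc[0]
        bid += 1
        rows.append(
            {
                "block_id": f"B{bid:03d}",
                "chrom_a": s["chrom"],
                "start_a": max(0, int(s["precursor_start"]) - 2000),
                "end_a": int(s["precursor_end"]) + 2000,
                "chrom_b": s["chrom"],
                "start_b": cfg.chrom_len - 9000,
                "end_b": cfg.chrom_len - 1000,
                "orientation": "+",
            }
        )
    bid += 1
    rows.append(
        {
            "block_id": f"B{bid:03d}",
            "chrom_a": "chr1", "start_a": cfg.chrom_len - 5000, "end_a": cfg.chrom_len - 1000,
            "chrom_b": "chr2" if cfg.n_chrom > 1 else "chr1",
            "start_b": cfg.chrom_len - 5000, "end_b": cfg.chrom_len - 1000,
            "orientation": "+",
        }
    )
    return pd.DataFrame(rows)


def _make_catalogue(rng: np.random.Generator, loci: pd.DataFrame) -> list:
    """A reference mature catalogue with species and lineage tags."""
    recs = []
    seen = set()
    for _, row in loci[~loci["is_decoy"]].iterrows():
        fam, cons = row["family"], row["conservation"]
        if fam in seen or cons == "species_specific":
            continue
        seen.add(fam)
        species = [("osa", "Poaceae"), ("zma", "Poaceae")]
        if cons == "conserved":
            species.append(("ath", "nonPoaceae"))
        for sp, lineage in species:
            seq = list(row["mature_seq"])
            if rng.random() < 0.5:  # catalogue orthologue differs by <= 1 nt
                i = int(rng.integers(2, len(seq) - 2))
                seq[i] = "C" if seq[i] == "A" else "A"
            recs.append(
                (
                    f"{sp}-{fam}",
                    f"{sp}-{fam} species={sp} lineage={lineage} family={fam}",
                    "".join(seq),
                )
            )
    return recs


# --------------------------------------------------------------------------
# expression model
# --------------------------------------------------------------------------

def _tissue_means(truth: TruthTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent per-tissue mean RPM (loci incl. decoys) and FPKM (transcripts)."""
    cfg = truth.config
    rng = rng_for(cfg.seed, "tissue_means")
    tissues = list(cfg.tissues)
    m_rows = {}
    for _, row in truth.loci.iterrows():
        cls = row["pattern_class"]
        if cls == "housekeeping":
            prof = rng.uniform(150, 400, size=7)
        elif cls == "tissue_specific":
            prof = rng.uniform(1, 6, size=7)
            prof[tissues.index(row["peak_tissue"])] = rng.uniform(300, 600)
        elif cls == "low":
            prof = rng.uniform(3, 5, size=7)
        elif cls == "decoy":
            prof = rng.uniform(25, 60, size=7)
        else:
            prof = rng.uniform(15, 60, size=7)
        m_rows[row["truth_id"]] = prof
    mirna = pd.DataFrame(m_rows, index=tissues).T

    # block contrast is kept well above the worst-case repression modulation
    # (~6x) so planted modules stay coherent after miRNA-driven modulation
    block_profiles = {}
    block_peaks = ["RS", "LG", "P"]
    for b in range(cfg.n_blocks):
        prof = np.full(7, 12.0)
        prof[tissues.index(block_peaks[b % len(block_peaks)])] = 1000.0
        block_profiles[f"block{b + 1}"] = prof

    rep = cfg.repression_strength
    z = mirna.div(mirna.max(axis=1), axis=0)
    t_rows = {}
    for _, row in truth.transcripts.iterrows():
        role, reg = row["role"], row["regulator"]
        if role.startswith("block"):
            base = block_profiles[role] * rng.uniform(0.6, 1.8)
        else:
            base = np.full(7, rng.uniform(20, 120))
        if reg:
            base = base * (1.0 - rep * z.loc[reg].to_numpy())
        t_rows[row["transcript_id"]] = np.maximum(base, 0.05)
    fpkm = pd.DataFrame(t_rows, index=tissues).T
    return mirna, fpkm


def srna_samples(cfg: SimulationConfig) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"lib_id": f"{t}_{r + 1}", "tissue": t, "replicate": r + 1}
            for t in cfg.tissues
            for r in range(cfg.srna_reps)
        ]
    )


def mrna_samples(cfg: SimulationConfig) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"lib_id": f"{t}_m{r + 1}", "tissue": t, "replicate": r + 1}
            for t in cfg.tissues
            for r in range(cfg.mrna_reps)
        ]
    )


def _realized(truth: TruthTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-library latent means: Gamma(1/d, d) x tissue mean (shared with reads)."""
    cfg = truth.config
    mirna_t, fpkm_t = _tissue_means(truth)
    d = cfg.nb_dispersion
    rng = rng_for(cfg.seed, "realized_expression")
    s_samp, m_samp = srna_samples(cfg), mrna_samples(cfg)
    g = rng.gamma(1.0 / d, d, size=(len(mirna_t), len(s_samp)))
    mirna = pd.DataFrame(
        mirna_t[ [*s_samp["tissue"]] ].to_numpy() * g,
        index=mirna_t.index, columns=s_samp["lib_id"],
    )
    g2 = rng.gamma(1.0 / d, d, size=(len(fpkm_t), len(m_samp)))
    fpkm = pd.DataFrame(
        fpkm_t[ [*m_samp["tissue"]] ].to_numpy() * g2,
        index=fpkm_t.index, columns=m_samp["lib_id"],
    )
    return mirna, fpkm


def simulate_expression_matrices(truth: TruthTable):
    """miRNA RPM matrix (true loci x 14) and transcript FPKM matrix (x 21).

    Values are the realized per-library latent means of the Gamma-Poisson
    count model, so they match read-derived RPM/FPKM in expectation.
    """
    mirna, fpkm = _realized(truth)
    true_idx = truth.loci.loc[~truth.loci["is_decoy"], "truth_id"]
    return mirna.loc[true_idx], fpkm


# --------------------------------------------------------------------------
# read simulation
# --------------------------------------------------------------------------

def _background_space(truth: TruthTable) -> list[tuple[str, int, int]]:
    """Genome intervals outside locus cassettes (promoter+flanks+hairpin)."""
    cfg = truth.config
    masks: dict[str, list[tuple[int, int]]] = {c: [] for c in truth.genome}
    for _, r in truth.loci.iterrows():
        lo = min(r["precursor_start"], r["star_start"], r["mature_start"])
        hi = max(r["precursor_end"], r["star_end"], r["mature_end"])
        masks[r["chrom"]].append((lo - cfg.flank_len - cfg.promoter_len, hi + cfg.flank_len))
    allowed = []
    for chrom, seq in truth.genome.items():
        pos = 0
        for lo, hi in sorted(masks[chrom]):
            if lo - 35 > pos:
                allowed.append((chrom, pos, lo - 35))
            pos = max(pos, hi + 35)
        if pos < len(seq) - 35:
            allowed.append((chrom, pos, len(seq) - 35))
    return allowed


def simulate_srna_reads(truth: TruthTable, outdir: str | Path) -> dict[str, Path]:
    """Emit the 14 small-RNA FASTQ libraries (pre-trimmed reads)."""
    cfg = truth.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mirna_lam, _ = _realized(truth)
    samples = srna_samples(cfg)
    genome = truth.genome
    space = _background_space(truth)
    space_len = np.array([b - a for _, a, b in space])
    space_cum = np.cumsum(space_len)
    total_space = int(space_cum[-1])

    paths = {}
    for _, lib in samples.iterrows():
        lib_id = lib["lib_id"]
        rng = rng_for(cfg.seed, f"srna/{lib_id}")
        reads: list[str] = []
        scale = cfg.depth_per_lib / 1e6

        for _, r in truth.loci.iterrows():
            lam = float(mirna_lam.loc[r["truth_id"], lib_id]) * scale
            n_mat = rng.poisson(lam)
            n_star = rng.poisson(lam / 3.5)
            if r["violation"] == "star":
                n_star = 0
            strand = r["strand"]
            ms, me = int(r["mature_start"]), int(r["mature_end"])
            n_exact = rng.binomial(n_mat, 0.8)
            n_up = rng.binomial(n_mat - n_exact, 0.5)
            n_dn = n_mat - n_exact - n_up
            for n, (d5, d3) in ((n_exact, (0, 0)), (n_up, (-1, -1)), (n_dn, (1, 1))):
                if n:
                    a, b = _shifted_interval(ms, me, strand, d5, d3)
                    reads += [_oriented_slice(genome, r["chrom"], a, b, strand)] * int(n)
            if n_star:
                reads += [to_dna(r["star_seq"])] * int(n_star)
            if r["violation"] == "precision":
                n_loop = rng.poisson(lam * 0.7)
                if n_loop:
                    a, b = _shifted_interval(
                        int(r["precursor_start"]), int(r["precursor_start"]) + 21,
                        strand, 6, 6,
                    )
                    reads += [_oriented_slice(genome, r["chrom"], a, b, strand)] * int(n_loop)

        # ncRNA-derived fragments (to be removed by the Rfam-style filter)
        n_nc = int(0.015 * cfg.depth_per_lib)
        nc_seqs = [s for _, s in truth.ncrna]
        for _ in range(n_nc):
            s = nc_seqs[int(rng.integers(0, len(nc_seqs)))]
            ln = int(rng.integers(19, 25))
            st = int(rng.integers(0, len(s) - ln))
            frag = list(s[st : st + ln])
            if rng.random() < 0.3:  # one mismatch still has to be filtered
                i = int(rng.integers(0, ln))
                frag[i] = "ACGT"[int(rng.integers(0, 4))]
            reads.append("".join(frag))

        # junk: polyA-tailed, too-short and too-long fragments
        n_junk = int(0.005 * cfg.depth_per_lib)
        for j in range(n_junk):
            if j % 3 == 0:
                core = "".join(rng.choice(["A", "C", "G", "T"], size=21))
                reads.append(core + "A" * 10)
            elif j % 3 == 1:
                reads.append("".join(rng.choice(["A", "C", "G", "T"], size=int(rng.integers(14, 18)))))
            else:
                reads.append("".join(rng.choice(["A", "C", "G", "T"], size=int(rng.integers(31, 35)))))

        # genomic background, uniform position, 24-nt peaked length
        n_bg = max(0, cfg.depth_per_lib - len(reads))
        pos = rng.integers(0, total_space, size=n_bg)
        lens = rng.choice(_BG_LEN, size=n_bg, p=_BG_LEN_P)
        strands = rng.random(n_bg) < 0.5
        idx = np.searchsorted(space_cum, pos, side="right")
        offs = pos - np.concatenate(([0], space_cum[:-1]))[idx]
        for i in range(n_bg):
            chrom, a, _b = space[int(idx[i])]
            st = a + int(offs[i])
            s = genome[chrom][st : st + int(lens[i])]
            reads.append(revcomp(s) if strands[i] else s)

        path = outdir / f"srna_{lib_id}.fastq"
        write_fastq(path, ((f"{lib_id}.r{i}", s) for i, s in enumerate(reads)))
        paths[lib_id] = path
    return paths


def simulate_degradome_reads(truth: TruthTable, outdir: str | Path) -> dict[str, Path]:
    """Emit 7 PARE 5'-tag FASTA libraries (one per tissue)."""
    cfg = truth.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tx_seq = dict(zip(truth.transcripts["transcript_id"], truth.transcripts["seq"]))
    paths = {}
    for tissue in cfg.tissues:
        rng = rng_for(cfg.seed, f"pare/{tissue}")
        recs = []
        for _, s in truth.target_sites.iterrows():
            n = rng.poisson(cfg.pare_depth_per_site)
            seq = tx_seq[s["transcript_id"]]
            c = int(s["cleavage_pos"])
            tag = seq[c : c + 20]
            if len(tag) >= 15:
                recs += [(f"{tissue}.t{len(recs) + k}", tag) for k in range(n)]
        # sparse background degradation tags (depth 1 at random positions)
        for gid, seq in tx_seq.items():
            for _ in range(int(rng.poisson(2.0))):
                c = int(rng.integers(0, max(1, len(seq) - 20)))
                recs.append((f"{tissue}.b{len(recs)}", seq[c : c + 20]))
        path = outdir / f"pare_{tissue}.fasta"
        write_fasta(path, recs)
        paths[tissue] = path
    return paths


def simulate_mrna_counts(truth: TruthTable, outdir: str | Path | None = None) -> pd.DataFrame:
    """Fragment-count table (transcripts x 21 mRNA libraries), NB-distributed."""
    cfg = truth.config
    _, fpkm_lam = _realized(truth)
    lengths = truth.transcripts.set_index("transcript_id")["length"]
    rng = rng_for(cfg.seed, "mrna_counts")
    lam = fpkm_lam.mul(lengths / 1000.0, axis=0) * (cfg.mrna_depth / 1e6)
    counts = pd.DataFrame(
        rng.poisson(lam.to_numpy()), index=fpkm_lam.index, columns=fpkm_lam.columns
    )
    if outdir is not None:
        counts.to_csv(Path(outdir) / "mrna_counts.tsv", sep="\t")
        totals = pd.DataFrame(
            {"lib_id": counts.columns, "total_fragments": cfg.mrna_depth}
        )
        totals.to_csv(Path(outdir) / "mrna_totals.tsv", sep="\t", index=False)
    return counts


# --------------------------------------------------------------------------
# file emission / loading
# --------------------------------------------------------------------------

def _write_genome_files(truth: TruthTable, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "genome.fa", truth.genome.items())
    rows = []
    for _, t in truth.transcripts.iterrows():
        attrs = {"ID": t["transcript_id"], "role": t["role"] or "none"}
        rows.append(
            {"seqid": t["chrom"], "type": "gene", "start": t["start"],
             "end": t["end"], "strand": t["strand"],
             "attributes": {"ID": t["transcript_id"] + ".g", **{}}}
        )
        rows.append(
            {"seqid": t["chrom"], "type": "mRNA", "start": t["start"],
             "end": t["end"], "strand": t["strand"], "attributes": attrs}
        )
    write_gff3(outdir / "genes.gff3", rows)
    write_fasta(
        outdir / "transcripts.fa",
        zip(truth.transcripts["transcript_id"], truth.transcripts["seq"]),
    )
    write_fasta(outdir / "ncrna.fa", truth.ncrna)
    write_fasta(
        outdir / "catalogue.fa",
        ((desc, to_dna(seq)) for _i, desc, seq in truth.catalogue),
    )
    _write_pwms(outdir / "pwms.motifs", truth.pwms)
    truth.tf_map.to_csv(outdir / "tf_list.tsv", sep="\t", index=False)
    truth.synteny_blocks.to_csv(outdir / "synteny_blocks.tsv", sep="\t", index=False)
    loci = truth.loci.drop(columns=["precursor_seq"])
    loci.to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)
    truth.transcripts.drop(columns=["seq"]).to_csv(
        outdir / "truth_transcripts.tsv", sep="\t", index=False
    )
    truth.target_sites.to_csv(outdir / "truth_target_sites.tsv", sep="\t", index=False)
    truth.tf_sites.to_csv(outdir / "truth_tf_sites.tsv", sep="\t", index=False)
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(truth.config), fh, indent=1, default=list)


def _write_pwms(path: Path, pwms: list[dict]) -> None:
    """JASPAR-style tab format: a header line then four base rows of counts."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p['motif_id']} {p['tf_family']}\n")
            counts = np.round(p["matrix"] * 100).astype(int)
            for bi, base in enumerate("ACGT"):
                fh.write(base + "\t" + "\t".join(str(c) for c in counts[:, bi]) + "\n")


def simulate(config: SimulationConfig, outdir: str | Path) -> TruthTable:
    """Run the whole generator and write every input + truth file to outdir."""
    outdir = Path(outdir)
    truth = make_genome(config, outdir)
    simulate_srna_reads(truth, outdir)
    simulate_degradome_reads(truth, outdir)
    simulate_mrna_counts(truth, outdir)
    mirna_rpm, fpkm = simulate_expression_matrices(truth)
    from .expression import write_matrix  # local import to avoid cycle

    write_matrix(outdir / "mirna_rpm_matrix.tsv", mirna_rpm, srna_samples(config))
    write_matrix(outdir / "fpkm_matrix.tsv", fpkm, mrna_samples(config))
    return truth


def load_truth(outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Load the written truth tables (no genome) for scoring."""
    outdir = Path(outdir)
    return {
        "loci": pd.read_csv(outdir / "truth_loci.tsv", sep="\t").fillna(""),
        "transcripts": pd.read_csv(outdir / "truth_transcripts.tsv", sep="\t").fillna(""),
        "target_sites": pd.read_csv(outdir / "truth_target_sites.tsv", sep="\t"),
        "tf_sites": pd.read_csv(outdir / "truth_tf_sites.tsv", sep="\t"),
        "synteny_blocks": pd.read_csv(outdir / "synteny_blocks.tsv", sep="\t"),
    }
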