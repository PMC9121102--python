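# Methods

This note records the models behind each stage, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the places
where a genuinely open design choice was made.

## Study design emulated by the generator

The generator (`mircascade.syndata`) emulates a seven-tissue survey of a
small cereal genome: roots, stems and leaves at the shooting stage (RS, SS,
LS), roots, stems, flag leaves and panicles at the grain-filling stage (RG,
SG, LG, P); two small-RNA replicates, three mRNA replicates and one PARE
library per tissue — 42 libraries in all. Defaults (all `SimulationConfig`
fields): 2 chromosomes × 500 kb, 30 true miRNA loci and 10 decoys, 300
protein-coding transcripts with 2,000-nt promoters, 120,000 reads per sRNA
library, 20 M fragments per mRNA library, Gamma-Poisson dispersion 0.08,
repression strength 0.9, six 8-nt PWMs planted in 40% of promoters.

### Planted hairpins

Each true locus is a 5′-arm mature (21 nt), a 9-nt loop and a star arm with
canonical 2-nt 3′ overhangs. Mature sequences use the A/C alphabet and star
arms the complementary G/U alphabet, with A/C-only 300-nt flanks; this makes
the intended stem essentially the unique maximum-base-pairing structure of
an excised window, which is what lets a base-pair-count folder (rather than
a thermodynamic one) drive annotation. Hairpins alternate genome strands.
Loci unrelated by design sit > 10 kb apart (four transcript cassettes are
interleaved between them); two families are laid out back-to-back to plant
genomic clusters, and two families are split across chromosomes inside
planted collinearity blocks to create syntenic pairs.

Decoys each violate one criterion: six isolated duplex mismatches (> 5), a
4-nt star-side bulge (> 3 nt asymmetry), no star reads, or planted
loop-spanning reads that push precision below 0.75. A precursor-length
violation is *not* plantable: with the ±250-nt excision window a star more
than ~250 nt from the mature falls outside the window and fails the star
criterion first, so that check is exercised synthetically in unit tests
instead.

### Expression and reads

Latent per-tissue mean RPM per miRNA follows its expression class:
housekeeping U(150, 400) in every tissue, tissue-specific U(300, 600) in
one tissue and U(1, 6) elsewhere, intermediate U(15, 60), low U(3, 5)
(kept well under the low cutoff of 10 so the class survives replicate
noise). Per-library means are the tissue mean times a Gamma(1/d, d)
multiplier (d = 0.08), and read counts are Poisson around them — i.e.
counts are exactly negative-binomial while the continuous expression
matrices share the same latent means, so read-derived RPM and the matrices
agree in expectation. Mature reads are emitted 80% exact and 20% with 1-nt
end wobble; star reads at 1/3.5 of the mature level; background reads are
drawn uniformly from the non-locus genome with a designed 24-nt length mode
(siRNA-like), plus small ncRNA-derived and junk (polyA-tailed, too-short,
too-long) fractions.

Transcripts: three co-expression blocks of 25 genes (peaks in RS, LG and P;
within-block profile 1000 vs 12 FPKM), 200 "free" target genes with flat
baselines U(20, 120), and 25 untargeted genes. Every targeted gene carries
one planted site — the reverse complement of its regulator's mature with
one mismatch opposite miRNA positions 15–18 (E = 1, so prediction still
succeeds but reads cannot multi-map into sites). Target FPKM means follow
E[target] = base(t) · (1 − repression · z(t)) with z the regulator's
tissue profile normalised to its maximum. Each block shares a single
housekeeping regulator, so repression shifts the whole block coherently and
planted modules survive modulation; the block contrast (~83×) is kept above
the worst-case modulation (~6×) for the same reason. The 200 free pairs are
the correlation panel: with repression 0 their correlations are symmetric
around zero (block pairs are excluded from that symmetry check because one
regulator per block leaves only three effective draws). PARE libraries put
~15 tags per library at each planted cleavage position (site end − 10)
plus sparse depth-1 background.

What the generator does *not* emulate: sequencing errors and quality
scores, adapter contamination (reads are emitted pre-trimmed), isoforms and
splicing, multi-mapping sRNA families beyond the planted ones, 3′-arm
matures, and any real genome's repeat structure. Passing tests therefore
show that the computations are correct under the stated generative model,
not that the pipeline is robust to artifacts absent from it.

## Folding

`fold.fold` maximises the number of {GC, AU, GU} pairs with hairpin loops
≥ 3 nt (Nussinov recursion, O(n³), JIT-compiled). Maximum-pair structures
are massively degenerate, so among them the traceback returns a structure
with the largest number of *stacked* pairs, preferring helix continuation
and leaving terminal bases unpaired on remaining ties. This plays the role
stacking energies play in thermodynamic folders and is what keeps a
designed stem intact instead of scattering equivalent pairs over flanking
sequence; the reported pair count is still exactly the Nussinov optimum
(checked against an independent enumeration in the tests). Pre-computed
dot-bracket structures from any external folder can be supplied instead;
`validate_structure` checks balance, pairability and the loop constraint.

## Annotation

Candidate windows are seeded by unique 19–25-nt reads with pooled count ≥ 3
(`min_stack_count`); seeds within 100 nt on one strand merge, anchored at
the most abundant read, and the window is the anchor ± 250 nt. Before
folding, a window is discarded if even its two largest read-position groups
could not reach precision 0.75 — an upper bound, so no passing locus is
lost; this is what keeps the dense siRNA-like background from being folded
at all. After folding, the mature is the most abundant read (ties: 5′-most),
the star interval is projected from the duplex pair table assuming 2-nt 3′
overhangs (median over paired positions, robust to a few lost pairs), and
the checklist is applied in a fixed order (duplex mismatches, asymmetric
bulge, precursor length, mature length, star evidence, precision); the
first failing criterion is logged per rejected window. Mismatches are
counted on the mature strand (unpaired mature bases in the duplex region,
3′ overhang excluded) and bulge asymmetry as |gap_mature − gap_star| per
internal loop, so a star-side bulge violates only the asymmetry limit.

Conservation matching allows ≤ 2 mismatches with terminal shifts up to
2 nt (the shift tolerance is an interpretation of "2 nt contiguous
nucleotides matched"; it is config-exposed). Families come from the best
catalogue hit or, for novel matures, single-linkage grouping at ≤ 2
mismatches, named miRN0001… in genomic order with letter suffixes per
member. Clusters chain loci with start-to-start distance strictly < 10 kb.
Synteny anchoring is ≥ 1-bp overlap with either side of a supplied block
pair; a syntenic pair is two same-family loci on the two sides of one pair.

## Target prediction and degradome

The expectation score uses the classic plant penalty scheme (mismatch 1.0,
G:U 0.5, bulged nucleotide 2.0, all doubled at miRNA positions 2–13,
1-based from the 5′ end); alignments are ungapped or carry one interior
bulge on either strand, and the score is the exact minimum over that space
(the vectorised transcriptome scan is tested against per-window scoring).
One best site per miRNA–transcript pair is reported at E < 3.0 (strict).
The energy method scores the same duplexes with GC −3 / AU −2 / GU −1
(arbitrary units; config) and passes at MFE/MDE ≥ 0.75, where MDE is the
perfectly paired miRNA. Two scoring families stand behind the method
interface; the "≥ 2 computational methods" overlap rule operates over
configured methods. Re-implementing four near-identical third-party
scorers would add no coverage — the integration rule is the computation
that matters here.

Degradome tags map exact-match (prefix index, ≥ 15 nt); multi-transcript
tags increment every hit. The seven libraries are pooled into one density
per transcript. Categories follow the standard convention with the median
taken over positions with ≥ 1 read: depth 1 → 4; ≤ median → 3; < max → 2;
= max → 1, or 0 if the maximum is unique. The expected cleavage position is
`site_end − 10` (the nucleotide opposite miRNA position 10); the offset is
config-exposed since conventions differ by one. Categories {0, 1} confirm.

## Expression, correlation, modules, network

RPM counts reads matching an annotated mature's strand with start and end
each within 2 nt (inclusive; "less than 2-nt shift" is ambiguous and the
inclusive reading is the default), against all genome-mapped reads of the
library. FPKM uses supplied library totals when present (the simulated
libraries state 20 M fragments), else column sums. Pattern classes
partition by the 100/10 cutoffs as: housekeeping ≥ 100 everywhere;
tissue-specific ≥ 100 in exactly one tissue; low < 10 everywhere;
intermediate otherwise — the minimal partition consistent with the named
patterns and both cutoffs.

Correlations use the 7 tissue means (replicates averaged first), Pearson r
with a two-sided t-test on 5 degrees of freedom; zero-variance profiles are
flagged undefined and excluded from the negative fraction. Enrichment is
the upper-tail hypergeometric probability (identical to a one-sided Fisher
exact test) with optional Benjamini–Hochberg adjustment.

Co-expression runs on log2(FPKM + 1) of the overall target set over all 21
mRNA samples (module–trait p-values need sample-level replication).
Adjacency is unsigned |cor|^β with β = 8; TOM is the standard unsigned
formula; modules come from average-linkage clustering on 1 − TOM with a
*static* cut at height 0.9 (deterministic and dependency-free, unlike the
usual dynamic cut; the height is config-exposed and the degenerate cut
height 0 sends everything to grey). Clusters under 5 genes pool into grey.
Eigengenes are the first principal component of the standardised module
matrix, sign-oriented to the module mean profile so module–trait signs are
deterministic. Traits are one-hot tissue indicators over samples; modules
are retained at |r| ≥ 0.75 and P < 0.01 (the ≥ reading of the threshold).
kME is the gene–eigengene correlation, hubs the top 9 with ties broken by
gene id.

Promoters are the strand-aware upstream 2,000 nt, truncated (not padded) at
contig edges so scan statistics stay honest. PWM scores are log₂-odds
against a 0-order background with a 1e-3 pseudocount, quantised to a
1/1000-bit integer grid; the score p-value is exact for the quantised score
(dynamic programming over per-column score distributions, verified against
4^L word enumeration) and a window is a hit at p ≤ 1e-4 on either strand.
TMI/TTI edges deduplicate multiple sites into one edge with an evidence
count; tf = gene self-edges are dropped so motifs stay acyclic. Cascades
and FFLs are enumerated exactly; FFLs ⊆ cascades is asserted every run.
MTI edges come from the overlap dataset by default (config: overall).

## Reproducibility and scale

Every random draw comes from a stream derived from the master seed and a
stable label (one stream per library/component), so a fixed seed reproduces
all outputs byte-for-byte; the run manifest records parameter snapshots and
SHA-256 hashes per output. Default problem sizes (1 Mb genome, 1.7 M reads,
300 transcripts) were chosen so a full run takes about a minute on one CPU
while keeping, e.g., low-expressed miRNAs above the read floor needed for
star-read evidence; the reduced configuration used for determinism tests
shrinks depth and transcript count further.

## Known limitations

The folder is a base-pairing model, not a thermodynamic one; annotation of
real genomes should plug in external structures. The internal read mapper
is exact-match (mismatch tolerance exists only in the ncRNA filter), which
matches how mature miRNAs are quantified but is not a general aligner. The
expectation/energy scorers are representative of their families, not
re-implementations of any specific external tool, so hit lists on real data
will differ from any one of them. Collinearity blocks, GO/KEGG annotation
tables and PWM collections are inputs, not computed here. The static tree
cut can split very close modules where a dynamic cut would merge them.
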