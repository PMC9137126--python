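# Methods

`pgscreen` implements the computational workflow of a paired-guide (pgRNA)
CRISPR-Cas9 deletion screen for genes modulating a cellular transition — the
motivating system is the transdifferentiation of human BLaER1 pre-B cells
into macrophages, read out by FACS-sorting "delayed" versus "differentiated"
cell fractions. This note records the models, parameter choices and numerical
conventions, and what the synthetic data do and do not establish.

## Candidate nomination from time-course expression

Input: two biological replicates of FPKM matrices over 12 timepoints
(0, 3, 6, 9, 12, 18, 24, 36, 48, 72, 120, 168 h).

Filters, per replicate:

* protein-coding genes: mean FPKM >= 1 and max/min fold change >= 4 along
  the profile;
* lncRNAs: mean FPKM >= 0.1, fold >= 2, and >= 1 FPKM in at least one
  timepoint; additionally the TSS must be isolated — no other gene body
  within +-5 kb on the same strand or +-50 bp on the opposite strand
  (closed windows against half-open gene bodies, so a gene starting exactly
  60 bp past the TSS on the opposite strand is clear).

Fold change uses the profile minimum clamped to the log pseudocount (0.01)
when zero; the pseudocount also guards the log10 transform. Both choices
preserve ranking among lowly expressed genes without producing infinities.

Retained genes are z-scored on log10(FPKM + 0.01) across their 12 timepoints
(genes with numerically zero variance are dropped — their z-score is
undefined) and clustered per replicate with k-means (scikit-learn, fixed
seed, 10 restarts, squared Euclidean; defaults k = 36 for protein-coding,
16 for lncRNA). Cluster centroids are classified automatically rather than
by visual inspection, with explicit thresholds in z-units:

* **upregulated**: z(last) − z(first) >= 1.0 and the last timepoint is the
  centroid maximum within 0.1;
* **peaking**: internal argmax with a rise >= 1.0 before the peak and a fall
  >= 1.0 after it;
* otherwise **other**.

The final candidate list intersects the peaking-or-upregulated gene sets of
the two replicates. All thresholds are exposed in `SelectionParams`.

## Paired-guide library design

Candidate guides are all 20-mers followed by an NGG PAM, both strands. The
Cas9 blunt cut is fixed 3 bp 5' of the PAM (between protospacer positions
17/18) — the universal convention. On-target scores come from a pluggable
scorer over the 30-nt context (4 nt upstream + protospacer + PAM + 3 nt
downstream); the default is a documented deterministic position-weight
surrogate (fixed nucleotide weights plus a GC-distance penalty, rescaled to
[0, 1]). It ranks guides reproducibly but is not a trained activity model;
substitute any callable for production designs.

Off-target filtering scans the whole genome (both strands, NGG-adjacent
sites only) for sites within Hamming distance 0–4 of the protospacer,
excluding the on-target locus, and applies per-distance ceilings — default
(0, 0, 0, unlimited, unlimited), i.e. no site up to 2 mismatches.

Protein-coding targets: guides are drawn from the first coding exon of the
supplied isoform (longest-CDS convention if the caller does not choose),
paired in all cut1 < cut2 combinations, and ranked by (a) earlier ORF
location — implemented as the lower ORF-exon index of the pair, which is
what makes the exon-window expansion meaningful, (b) higher summed pair
score, (c) out-of-frame deletion (length not divisible by 3) before
in-frame, with a deterministic (start1, start2) tie-break. Pairs are
accepted greedily under the 50-bp separation rule; when the first exon
cannot host the requested designs (default 10 per target) the window extends
to exons 2 and 3. The 50-bp rule is enforced in both readings — every two
cut sites among a target's accepted designs are >= 50 bp apart, which
subsumes the within-pair reading — because the source phrasing admits both.

lncRNA targets: a symmetric window around the TSS grows through 500, 1000,
2000, 3000, 4000, 5000 bp; every accepted pair must straddle the TSS
(cut1 < TSS < cut2); guides overlapping any protein-coding gene body are
discarded; each window expansion relaxes the off-target ceiling by allowing
one more 2-mismatch site (exact and 1-mismatch duplicates are never
tolerated).

Controls: positive-control genes are designed like protein-coding targets at
the requested depth; negative controls are guide pairs inside intergenic
regions sampled uniformly (seeded) from annotation-free stretches >= 1 kb
from every gene. Each construct is emitted as a 165-nt insert-1 cloning
oligo: 25-nt arm + protospacer-1 (20) + 75-nt central cloning site (with
EcoRI/BamHI sites) + protospacer-2 (20) + 25-nt arm. The arm sequences are
synthetic placeholders — structurally faithful (total length, two targeting
regions, central cloning site) but not the published vector arms, which the
design table's round-trip parser treats as pure coordinates anyway.

Guides must lie within a single exon (no junction-spanning guides): designs
are validated against the genomic sequence, and a spliced-CDS guide would
not match the genome.

## Read structure and quantification

Each construct's guide-1 segment is stored as 21 nt ("G" + protospacer, the
transcription-start G of the U6 cassette); guide-2 as its 20-nt protospacer.
Read 2 carries a 0–7-nt stagger prefix (emulating staggered amplification
primers that desynchronise the constant region on the flow cell), vector
context, the "ACCG" cloning anchor and the guide-1 segment, with the anchor
match start constrained to positions 15–55 (1-based). Read 1 carries vector
context, the "AAAC" anchor and the reverse complement of the guide-2
protospacer, anchor start within 100–150. Extraction takes the 21 nt after
the first in-window "ACCG" on read 2 and the 20 nt after the first in-window
"AAAC" on read 1, reverse-complements the latter, and fuses them; fused
sequences shorter than 20 nt are discarded. Orientation convention: the
guide-2 site is sequenced on the opposite strand, so the reference record is
guide1(21) + guide2-protospacer(20) = 41 nt and the extraction's reverse
complement restores exactly that — the error-free round trip is the identity.

Duplicate constructs (identical fused sequence) collapse into one reference
record whose id joins the source construct ids; counts are reported at that
merged granularity by default (a per-source split is available).

Assignment is an exact Hamming scan (no indels) against all 41-nt records:
a fused read is assigned to the unique record at minimal distance within the
mismatch budget, called multimapped on a tie at the minimum, unmapped
beyond the budget; sub-41-nt survivors are compared against reference
prefixes (a declared surrogate for soft-clipped alignment). This replaces
the original spliced-aligner step: with fixed-length references and
substitution-only errors the two are equivalent, which the test suite
enforces against a brute-force oracle rather than by imitating aligner
internals. Defaults: 2 mismatches for synthetic data; 13 is the documented
setting for real screen data (where a long primer-to-guide distance inflates
the guide-2 error rate and 13 mismatches keeps multimapping below 1%).

Accounting identities are maintained per sample: pairs = fused + no_anchor1
+ no_anchor2 + too_short, and fused = assigned + unmapped + multimapped.

## DDE analysis and candidate calling

Constructs need >= 5 counts in the replicate's own T0 sample (a pooled T0 is
accepted and applied to both replicates). The differentiation-delaying
effect is DDE = delayed count / differentiated count, computed independently
per replicate at T3 and T6. Zero denominators yield +inf under the default
"raw" policy: such constructs are excluded from percentile estimation but
always count as hits; an additive-pseudocount policy is available and the
policy in force is recorded in the output metadata. The T0 filter makes
zeros rare in practice.

Per (replicate, timepoint) stratum the hit threshold is the 90th percentile
(linear interpolation between order statistics) of the finite DDE values;
hits lie strictly above it. A target is called at a timepoint when at least
2 *identical* constructs are hits in both replicates; the final call is the
union over T3 and T6 (an intersection variant is a config switch). Decile
thresholds of the replicate-mean DDE are reported alongside, since headline
threshold values for such screens are usually quoted on that scale. No
multiple-testing correction is applied: the procedure is rank/threshold
based, not p-value based, and adding one would change the published
semantics.

QC: within positive-control and intergenic-control sets, the
between-replicate Spearman correlation of DDE per timepoint plus median DDE
(the expected signature: large, correlated DDE for positive controls;
uncorrelated, near-1 DDE for intergenic controls).

## Synthetic data: what it emulates, what it does not

The generator is deterministic given its config (fixed RNG streams; gzip
members written with zeroed timestamps, so identical configs give
byte-identical files).

* **Time course**: per-gene templates for the four planted classes, in FPKM:
  upregulated 0.5 -> 4.0 log-linear (8-fold; lncRNA scale 0.15 -> 1.5),
  peaking with the maximum at 36 h, flat at the geometric midpoint, down the
  reverse of up; a per-gene baseline jitter of +-0.1 decades shared between
  replicates; replicate noise is Gaussian with sd 0.1 on log10(FPKM + 0.01)
  (matching the log-scale z-scoring used downstream; the 8-fold template
  clears the 4-fold filter with a wide noise margin). Flat genes carry no
  signal, so z-scoring turns them into random unit-variance vectors; a few
  therefore co-cluster with signal classes (adjusted Rand ~0.83–0.92 at
  these settings), which is why class recovery is asserted on the
  peaking/upregulated selection, where it is complete.
* **Counts**: negative binomial via Gamma-Poisson with mean = depth (100
  reads/construct by default) times the construct's delayed-fraction fold,
  dispersion alpha = 0.2 (var = m + alpha m^2), the standard over-dispersion
  model for pooled screens. Spiked targets draw per-construct folds once
  from a log-normal centred on the configured fold with ln-sd 1.0, shared
  across replicates and timepoints. That heterogeneity is what makes
  replicate DDE values correlate for true effects: the ln-DDE measurement
  noise variance is ~2(1/depth + alpha) = 0.42 at the default depth and
  dispersion, so construct-level variance sigma^2 gives an expected
  between-replicate correlation sigma^2 / (sigma^2 + 0.42); sigma = 1.0
  reproduces the clearly-correlated (rho ~ 0.7) positive-control regime.
  With identical folds for every construct the correlation would be ~0
  regardless of effect size.
* **Reads**: exact protocol geometry (anchors, windows, stagger, 150-bp
  pairs; read length configurable, e.g. 125 bp for plasmid-pool QC runs),
  uniform per-base substitution errors (default 0.1%). Not modelled: base
  quality realism, indels, PCR duplicates, chimeric reads, FACS gating
  noise. Passing tests therefore demonstrate correctness of the extraction/
  assignment/statistics machinery under the protocol's read structure, not
  robustness to every artefact of real sequencing.

## Problem sizes and numerical conventions

The planted-effect study uses 10 spiked targets (fold 5, 10 designs each)
among 200 null targets at depth 100 — about 2.4 M read pairs over the ten
sorted samples (per-replicate T0 plus T3/T6 x delayed/differentiated x 2
replicates) — chosen as the smallest screen in which decile calling has
stable behaviour. Profile recovery uses 40 genes per class at noise sd 0.1.
Coordinates are 0-based half-open in memory, GTF 1-based on disk, converted
only at I/O boundaries. Percentiles use linear interpolation; k-means uses a
fixed seed with 10 restarts; all simulation randomness flows from a single
config seed through named substreams.

## Known limitations

* The surrogate on-target scorer ranks deterministically but has no measured
  activity validity; plug in a trained scorer for real designs.
* Off-target scanning considers NGG PAMs only (matching the protospacer
  definition used for design) and Hamming distance (no bulges).
* Frame status for a deletion is computed from the genomic cut-site distance,
  which equals the spliced-ORF distance only while both cuts lie in the same
  exon window; multi-exon deletions also remove intronic sequence and may
  additionally disrupt splicing, which is not modelled.
* Reproducing a published screen's exact thresholds and candidate lists
  requires its real sequencing data and design table, which are external
  downloads; the package reproduces the procedure and validates it on
  synthetic data with known truth.
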