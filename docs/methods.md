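# Methods

This note records the models and procedures implemented in `lncmap`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions.

## Coordinates and formats

All internal coordinates are 0-based half-open; GTF (1-based inclusive) and
BLAST tabular coordinates are converted at the file boundary, and
reverse-strand query coordinates in chain files are flipped to the forward
strand at parse time. Writers emit a canonical byte layout so that
`write(read(x))` is byte-identical for generator-emitted files; this makes
round-trip corruption detectable by hashing.

## Discovery filter

The filter applies six steps in a fixed order and records, for each removed
transcript, the **first** step that fired: (1) multi-exon requirement,
(2) same-strand exon overlap with annotation, (3) exonic length < 200 nt,
(4) coding potential, (5) structural-ncRNA homology, (6) retention and
positional classification. Choices that were genuinely open:

- **Coding verdict = union over callers.** Upstream tools (e.g. CNCI, CPC)
  each emit a verdict; removing a transcript when *any* caller says coding
  is the stringent reading appropriate for a high-confidence catalogue. The
  missing-verdict behavior is configurable (`error` default,
  `treat-as-noncoding` optional).
- **Overlap test: ≥ 1 nt of exon–exon overlap on the same strand.** The
  strictest testable rule; annotated lncRNAs bypass this step and are
  flagged `novel=False`.
- **Category precedence antisense > intronic > cis-regulatory >
  intergenic.** The four categories must be mutually exclusive; this order
  resolves transcripts that are simultaneously antisense to one gene and
  near another. The strand relation of cis-regulatory lncRNAs is recorded
  as metadata rather than used for sub-classification.
- **"Within 2 kb" is measured span-to-span** (transcript span to gene
  span, either side, either strand), not TSS-only.

## Expression metrics

RPKM is computed on fragments (read pairs): `count / (exonic kb) /
(library size / 10⁶)`. SNP density is per exonic kb (not genomic span),
since variants are attributed to transcribed sequence. Sample clustering
uses average linkage on `1 − Pearson r` of `log₂(RPKM + 1)`; the
pseudocount-1 transform is the conventional variance stabilizer and is
configurable. Zero-variance samples are rejected by name.

## Jensen-Shannon specificity

For profile `e` over `n` tissues, `p = e/Σe`, the per-tissue score against
the extreme pattern `q_t` (all mass in tissue `t`) is `1 − √JSD(p, q_t)`
with JSD in bits; base-2 logs make the score lie exactly in [0, 1], with 1
iff expression is confined to one tissue. The two KL terms collapse to
closed forms in `p_t`:

    KL(p‖m) = (1 − p_t) + p_t log₂(2p_t/(p_t+1)),   KL(q_t‖m) = log₂(2/(p_t+1)),

which is what the vectorized implementation evaluates; a direct-summation
JSD is kept in the test suite as the oracle (agreement ≤ 1e−12). Reference
values: a uniform 2-tissue profile scores 1 − √0.31128 ≈ 0.4421 and a
uniform 11-tissue profile ≈ 0.1201.

Tissue association uses raw-RPKM Z scores across tissues (sample SD, n−1)
with the conjunctive rule Z ≥ 1.5 **and** RPKM ≥ 0.5; transcripts
associated with any skeletal-muscle developmental stage are merged to a
single "skeletal_muscle" label. Muscle merging applies only to
association — the JS score always sees all 11 samples.

**A calibration caveat recorded deliberately:** for a *flat* profile with
exchangeable noise, the maximum studentized residual of 11 values exceeds
1.5 roughly half the time, independent of the noise scale (Z is
scale-free). The association rule therefore has an irreducible
false-positive rate on non-specific transcripts; it is excellent at
*finding* planted specific transcripts (recall 1 in the end-to-end report)
but over-counts specificity among flat profiles. Accordingly, the planted
fraction-recovery test classifies by JS score (≥ 0.5), where recovery is
exact, and the end-to-end report asserts association **recall** and
best-tissue accuracy while *reporting* the flat-profile association rate
without asserting it.

## Conservation

Genome-alignment conservation is the fraction of a transcript's **exonic**
nucleotides inside the union of chain target blocks, each base counted at
most once however many chains cover it ("uniquely intersected" read as
unique per-base counting; the alternative single-chain reading is noted but
not implemented). Exonic rather than genomic-span counting is the
sequence-faithful reading and is configurable (`span_based=True`). The
four-way class uses ≥ 0.5 per species: both → conserved in all three
genomes, exactly one → pairwise, neither → species-specific.
Transcript-level homology merges the query intervals of all BLAST hits
(union, not best-single-hit; configurable) and requires ≥ 20 % query
coverage. All threshold comparisons are ≥.

The specificity-by-conservation comparison reports per-class JS
distributions and a two-sided Mann–Whitney test between the fully conserved
and species-specific classes, skipped when a class has fewer than two
members.

## Differential expression without replicates

With a single library per condition, counts are modeled as binomial draws
with a shared per-transcript probability: `C₁ ~ Bin(n₁, p)`,
`C₂ ~ Bin(n₂, p)`. On the MA plane the delta method gives, conditional on
`A`,

    E[M|A] = log₂(n₁/n₂)
    Var[M|A] = 4(1−p̂)√(n₁n₂) / (ln²2 · (n₁+n₂) · 2^A),   p̂ = 2^A/√(n₁n₂).

Because the source describes the method only by name, these moments are
treated as *implementation-verified*: the test suite simulates binomial
pairs, stratifies by A, and checks the empirical conditional mean and
variance against the formulas (the simulation is the contract). Under the
null at 10,000 genes the p < 0.05 fraction is 0.05 ± 0.01.

Conventions: zero counts are replaced by a pseudocount of 1 before logs;
transcripts with zero counts in both libraries are excluded; the reported
fold change is the library-size-normalized `log₂FC = M − log₂(n₁/n₂)`, so
the FC ≥ 2 ∧ q < 0.05 call rule is depth-independent. Note that the
binomial model excludes biological variance: on overdispersed data the z
statistics are anti-conservative and the fold-change threshold becomes the
effective gate, which is visible in the end-to-end report as perfect recall
with moderate precision on negative-binomial counts.

Neighbor analysis pairs each intergenic lncRNA with the nearest coding gene
on its chromosome (span-to-span distance) and each intragenic lncRNA with
its overlapped gene; Pearson r is computed on `log₂(RPKM+1)` across
samples, and lncRNAs with no same-chromosome gene are skipped and counted.

## Co-expression network

The network is **unsigned**: `a_ij = |cor(x_i, x_j)|^β`, unit diagonal.
The soft threshold is the smallest candidate power whose scale-free fit
index (signed R² of the log–log degree-distribution regression, 10 bins)
reaches 0.8, falling back to β = 6 with a warning — 6 being the
conventional choice for unsigned networks of this size. Topological
overlap is the standard unsigned form

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

checked against a literal triple loop to 1e−10. Modules come from
average-linkage clustering of 1 − TOM with a **static cut** at 0.99 × the
maximum merge height and a minimum module size (default 30); clusters below
the minimum are "unassigned", and labels are M1, M2, … by decreasing size.
The static cut replaces the dynamic tree-cut algorithm deliberately: the
dynamic variant has many unstated parameters, and on separated blocks the
two are equivalent — the contract here is module *recovery* (ARI against
planted truth), not label identity; cut height and minimum size are exposed.

Eigengenes are the first principal component of the module's standardized
member profiles (unit norm, sign oriented to correlate positively with the
module's average profile); kME is each member's correlation with its
module eigengene, and hubs are |kME| ≥ 0.9 (the conventional membership
cutoff; configurable). Module–trait relevance is the Pearson correlation of
each eigengene with the binary muscle vector (muscle samples 1, others 0),
with a two-sided t-test p. Guilt-by-association takes the coding genes
whose correlation with a lncRNA is significant at BH-adjusted p < 0.05,
declines to assess lncRNAs with fewer than 30 such genes, and otherwise
runs hypergeometric enrichment against all coding genes in the network —
the analysis-stage background, which avoids composition bias relative to a
whole-genome background.

## Hypergeometric enrichment

Upper tail only (over-representation); p-values are exact hypergeometric
tails, BH-adjusted across the tested terms, with fold = (k/n)/(K/N). The
term map is assumed pre-propagated; no GO-DAG handling.

## Synthetic data: what it emulates, and what it does not

The generator lays out a miniature genome (one chromosome per 50
protein-coding genes, 12 kb gene spacing, 4-exon genes over 3 kb spans) in
which every planted feature's geometry is constructable by design:
intergenic lncRNAs sit ≥ 2 kb from all genes, antisense lncRNAs overlap a
host exon on the opposite strand, intronic lncRNAs sit wholly inside an
intron, cis-regulatory lncRNAs sit 500 bp–1.3 kb from a gene end, and each
decoy class (mono-exonic, < 200 nt, coding-flagged, same-strand
annotated-overlap) trips exactly one filter step. Defaults: 200 coding
genes, 20 lncRNAs per category, 10 decoys per class, 5 known lncRNAs,
seed 42.

Expression is drawn over the 11-sample panel (9 organs + skeletal muscle at
3 postnatal stages): counts are negative binomial with mean =
RPKM × exonic kb × library millions (default library 2 × 10⁷ pairs,
dispersion 0.05 — a standard bulk RNA-seq scale; the model is Poisson in
the dispersion → 0 limit, which is how the test suite checks the
replicate-free DE test under its own sampling assumption). Half the
lncRNAs are tissue-specific (organ-restricted, or restricted to one muscle
stage with low expression at the other stages), half ubiquitous; half the
ubiquitous ones are stage-differential with a planted log₂FC of 2 at day 0.
Each intergenic lncRNA's nearest gene tracks the lncRNA's profile, planting
the positive neighbor correlation. A separate 30-sample panel (the 11
tissues plus extra samples, 5 muscle in total) carries three 50-gene
modules at within-correlation 0.8, one tied to the muscle trait, each with
a hallmark GO term carried by ~80 % of its coding members. Conservation is
planted per transcript as a four-way class with exact covered fractions
realized by laying chain blocks over exon prefixes; species-specific
transcripts receive no blocks at all.

Not emulated: raw reads and alignment, splice-graph structure, the pooled
mixed libraries of a real body-map design, sequence-level homology (hit
tables are planted, not aligned), batch structure among the 30 network
samples, and biological replicates. Consequently a passing suite
demonstrates correctness of the *analysis* — coordinate arithmetic,
thresholds, statistics, recovery under the stated noise model — not
robustness to assembly artifacts or batch effects in real data.

## Problem sizes and numerics

Test and acceptance problem sizes were chosen so the full suite runs in
seconds on one core while keeping Monte-Carlo error well inside the
asserted tolerances: 10,000 genes for DE calibration, 1,000 random cases
for per-base oracles, 100 seeds for trait-module ranking, 150 × 30 for
module recovery. Ties in the JS argmax go to the lexicographically smallest
label and are flagged; eigengene signs are fixed by the average-profile
convention; BH is the standard step-up (via `scipy`); all random draws use
`numpy.random.default_rng` with explicit seeds, and the generator is
byte-deterministic given its seed.
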