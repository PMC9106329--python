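# Methods

This note documents the statistical models, numerical choices and known
limitations of the `plasmascreen` pipeline: a pooled CRISPR knockout
screen analysis for plasma-cell (CD138+) accumulation, and a companion
m6A-eCLIP crosslink-site analysis. All empirical statements below are
computed by the test suite or by `scripts/acceptance.py`; nothing here is
quoted from external results.

## Screen arm

### Read counting

Screen reads carry the 19-nt protospacer immediately 5' of the constant
sgRNA scaffold. We locate the first occurrence of the scaffold anchor
`GTTTAAGAGCTAT` in each read and take the 19 bases preceding it; the
19-mer is assigned to a guide by exact dictionary lookup (equivalent to
zero-mismatch alignment against a protospacer "genome", without the
aligner). Reads with no anchor, fewer than 19 preceding bases, an `N` in
the extracted window, or no exact match are left unassigned. When the
anchor occurs more than once, the first occurrence is used — an arbitrary
but deterministic convention. No quality filtering is applied. Protospacer
collisions within a library are rejected at load time because exact
assignment would be ambiguous.

### Normalization

The counting-depth model is median-of-ratios (as in DESeq), restricted to
the non-targeting (NT) control guides: the size factor of a sample is the
median over NT guides (with nonzero counts in every sample) of
count / per-guide geometric mean. NT guides are the designated null set
of the screen, so anchoring size factors on them keeps the null centred
even when many targeting guides shift in one direction — the main failure
mode of total-count scaling in selection screens. A `normalization="total"`
fallback exists for libraries with too few usable NT guides (< 20).

### Mean–variance null and sgRNA tests

For a tested sample pair, each NT guide contributes a mean
mu = (x1+x2)/2 and a variance proxy (x1−x2)²/2 (the unbiased two-point
variance estimate under a shared mean; this uses the paired-condition
difference itself because the screen design has no replicates). Guides are
split into equal-occupancy mean bins (>= 5 per bin, at most 20 bins), and
the super-Poisson excess of bin-averaged variance over the bin mean
(floored at 0.01 to keep logs finite in the Poisson-like regime) is
regressed on the bin mean in log2–log2 space. The fitted power law gives

    var(mu) = mu + k * mu^b,   k = 2^intercept >= 0,  b = slope,

i.e. a negative-binomial-shaped variance function with Poisson lower
bound. Per guide, the null for the treatment count is NB with mean equal
to the (pseudocount-floored) control value and variance from the model;
when the predicted variance does not exceed the mean, exact Poisson tails
are used (the NB parameterisation degenerates there). Both one-sided tail
probabilities are computed: P(X >= t) for enrichment, P(X <= t) for
depletion, with t the rounded normalized treatment count. Each direction
is ranked independently: ascending p, ties broken by |LFC| descending and
then guide id, so ranks are a deterministic permutation.

LFCs use a symmetric pseudocount of 0.5: lfc = log2((t+0.5)/(c+0.5)).

### Gene scores: alpha-RRA

Guides with direction p below `alpha_select` (default 0.05, the screen's
significance convention) are "selected". With normalized ranks
u = rank / N_total, the gene score is

    rho = min_{k=1..j} P( Beta(k, m−k+1) <= u_(k) ),

the smallest probability that the k-th best of m uniform ranks would be
as extreme as the gene's k-th selected guide; j is the number of selected
guides, and rho = 1 when none is selected. Beta(k, m−k+1) is the exact
distribution of the k-th order statistic of m uniforms. A vectorised
incomplete-beta implementation scores tens of thousands of permuted guide
sets per second; the test suite checks it against a direct Beta-CDF
brute force to 1e-12.

### Permutation p-values, FDR, z-scores, hit rule

Gene p-values come from randomizing the guide-to-gene allocation:
for each gene size m, `n_permutations` (default 10,000) random m-guide
sets are drawn without replacement from all targeting guides and scored;
draws are pooled across genes of identical size. The p-value is the
add-one estimator (1 + #{null <= observed}) / (1 + n_permutations), so it
is floored at 1/(n+1). Benjamini–Hochberg adjustment is applied within
each direction separately (positive and negative enrichment are computed
independently); each gene is then reported in its better direction —
smaller permutation p, ties broken by smaller RRA score.

The gene effect size is the median LFC of the gene's guides whose LFC
sign matches the reported direction; genes with no same-direction guide
are flagged and given LFC = z = 0. The z-score standardises the gene LFC
against the NT-control LFC distribution (mean and sample SD over NT guide
LFCs). A pseudo-gene reference — median LFCs of random 10-guide NT groups
— is available via `nt_reference="pseudo"`; the guide-level reference is
the default and is deliberately conservative (guide-level spread exceeds
median-of-10 spread, so z magnitudes shrink).

A gene is a hit when |z| >= 2 **and** FDR < 0.05 (z boundary inclusive,
FDR strict).

### Two-screen classification

With accumulation LFC defined as CD138+ over CD138−, knocking out a
differentiation promoter depletes its guides from the CD138+ gate, so:
accumulation hit and not expansion hit with z <= −2 → promoter of
accumulation; with z >= +2 → limiter; expansion-only hit → expansion
regulator; hit in both → pleiotropic; otherwise none. A `flip_sign` flag
inverts the convention for comparisons run the other way around. The five
classes partition the gene set; negating every accumulation z exactly
swaps the promote and limit tallies (a tested symmetry).

## m6A arm

### Feature hierarchy

Transcript models come from an Ensembl-dialect GTF (parsed with gffutils;
1-based closed coordinates converted to 0-based half-open internally).
UTRs are derived as exonic sequence outside the genomic CDS span, 5' vs
3' resolved by strand; introns are the gaps between sorted exons. A site
(point) or cluster (interval, any overlap) is a candidate for every
same-strand overlapping (transcript, feature) pair — eCLIP is
strand-specific, so opposite-strand overlap never counts. Candidates are
ordered lexicographically:

1. coding transcript first;
2. transcript support level (TSL) < 4 first (absent TSL counts as not
   < 4, the conservative reading);
3. feature type: CDS > 3'UTR > 5'UTR > intron > non-coding exon >
   non-coding intron;
4. lower TSL first (absent last), then CCDS-flagged first;
5. transcript id ascending — a final deterministic tie-break, so the
   total order has no ties and assignment is independent of input order.

The best candidate wins; no candidate means intergenic. A brute-force
candidate enumeration over dense stacks of overlapping transcripts is the
oracle for this ordering in the tests. Transcripts are grouped by where
their sites fall: only 3'UTR, only CDS, both, or other.

### Motif enrichment

The 5 bases centred on a site (pos−2..pos+2, the only symmetric reading)
are read on the site's strand; windows off the chromosome end or
containing non-ACGT characters are unscorable and dropped. Control sites
are drawn in n_sets = 100 feature-matched sets: for every observed genic
site with feature F, each control set receives one position uniform over
the pooled feature-F territory of genes containing at least one observed
site — genes are hit with probability proportional to their feature-F
length, the least-informative density. Observed intergenic sites have no
gene territory and are excluded with a warning; a feature with zero
territory among site-bearing genes falls back to all genes. Per 5-mer,

    z = (obs − mean over control sets) / SD over control sets,

with the sample (n−1) SD; zero-SD cells give z = 0 when the observation
matches the control mean and a flagged ±inf otherwise. Count conservation
(per-set 5-mer counts summing to scorable sites) is tested, as is
invariance of the whole table under reverse-complementing the genome and
flipping strands.

The controls preserve the *feature* distribution but not per-gene site
counts; a per-gene-preserving variant would narrow the null further and
could be added, but feature matching is what the z-score definition above
requires.

### Metagene profile

One representative transcript per gene (longest CDS, ties by transcript
id, to avoid double-counting genes in the average). The genomic CDS span
is scaled to 100 body bins; 1 kb of genomic flank on each side is split
into 10-bp bins (100 bins per flank, 300 total). A bin's value is 1 if
any same-strand cluster overlaps its genomic interval, else 0 — the
maximum of an indicator with zeros kept — and the profile is the per-bin
mean over genes, so values lie in [0, 1]. Rows are oriented 5'→3', which
places the stop codon at body-bin boundary 199/200; stop-proximal signal
therefore peaks in the terminal body decile or the first downstream flank
bins.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions the analyses are validated under.

* **Library**: 1213 RBP genes and 72 positive-control genes at 10 guides
  per gene plus 500 non-targeting guides — 13,350 guides — with distinct
  uniform-random 19-mers.
* **Plasmid representation**: per-guide log2 abundance ~ Normal(0,
  sigma), sigma = 0.78. The selection rule for sigma is the library QC
  statement that >= 98.8% of guides sit inside a 16-fold abundance range:
  sigma = 0.78 puts the expected central-window coverage at 99.0%, about
  two binomial standard deviations above the 98.8% line at n = 13,350, so
  the property holds robustly for any seed (sigma = 0.79 would sit on the
  line in expectation and fail for roughly half of seeds).
* **Counts**: negative binomial with a single dispersion phi = 0.05
  (var = mu + phi mu²), the standard pooled-screen noise model and the
  same family the mean-variance null fits; mean depth 500 reads per guide
  (a desk-scale stand-in for the screen's > 1000x cell representation —
  500x keeps every validation property while halving runtimes). Planted
  effects are log2 multipliers applied to a configurable fraction
  (penetrance) of a gene's guides: expansion effects multiply the day8
  (and downstream sorted) means, accumulation effects multiply only the
  CD138+ mean, so each comparison's guide LFC recovers its planted effect.
* **Reads**: prefix (0–6 random nt) + protospacer + scaffold + random
  padding to 60 nt, constant quality, shuffled order — the exact inverse
  of the counting step, which recovers counts bit-exactly.
* **Toy transcriptome**: random-sequence chromosomes; ~80% coding genes
  with 2–5 exons (150–400 bp), introns of 80–300 bp, derivable UTRs
  (5'UTR 30–79 nt, 3'UTR 100–199 nt) and in-frame CDS lengths; TSL drawn
  from 1–5 or absent; CCDS flags on half the coding genes; strands
  alternate. Crosslink sites are planted over exonic territory with a
  configurable fraction carrying GGACT edited into the genome
  (transcript-strand oriented) and a configurable fraction within 100 nt
  of a stop codon; 5-mer windows of distinct sites never overlap (edits
  would otherwise corrupt neighbouring planted motifs). Clusters are
  ±20 nt windows around sites.

What the generator does **not** emulate: PCR jackpotting and
amplification bias, guide-efficiency heterogeneity beyond binary
penetrance, immunoprecipitation background reads, isochore/GC structure,
overlapping gene loci (overlap handling is exercised by constructed
fixtures instead), and real DRACH degeneracy (a single planted 5-mer
stands in for the motif family). Passing tests therefore demonstrate the
statistics behave correctly under their own model assumptions, not that
real screens are free of these artefacts.

## Problem sizes and numerical conventions

Validation runs use scaled-down instances chosen to exercise every code
path: null and planted screens of 5,000 guides (450 genes × 10 + 500 NT)
at depth 500 with 10,000 permutations; 12–20-gene toy transcriptomes with
150–200 sites and 100 control sets. Determinism: every stochastic step
consumes an explicit `numpy.random.Generator` seeded from the
configuration; identical config + seed yields byte-identical tables
(tested). Degenerate inputs are errors, not silent defaults: empty
libraries, too few NT guides (< 20), zero NT LFC spread, p-values outside
[0, 1], CDS outside exons, unknown chromosomes, and empty observed k-mer
sets all raise with specific messages.

## Known limitations

* No replicate-aware dispersion shrinkage, MLE-style joint modelling,
  copy-number correction, or paired designs; the variance model assumes
  the two compared samples share the NT null.
* The NB tail test treats the control value as the known null mean,
  ignoring its own sampling noise; with 500 NT guides and equal-occupancy
  binning this is conservative at the depths simulated.
* Real-data outputs will not be bit-identical to other screen toolchains:
  normalization anchor, permutation count and tie-breaking conventions
  all differ between implementations.
* The hierarchy's "TSL < 4 before feature type" step means a
  low-confidence CDS can lose to a high-confidence intron only across
  transcripts of different support; within a transcript the feature order
  governs.
* Metagene scaling uses the genomic CDS span (introns included), matching
  the scale-regions convention of coverage-matrix tools, not a
  spliced-transcript coordinate system.
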