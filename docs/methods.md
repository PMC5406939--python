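# Methods

This note describes the models and procedures implemented in `epiril`, the
assumptions behind them, and the choices made where the design was open.

## Coordinate and data conventions

All in-memory coordinates are 0-based, half-open. A CG dinucleotide is
indexed by the position of its forward-strand C; the reverse-strand C sits
at `pos + 1`. Cytosine count tables carry one record per cytosine per
strand (chrom, pos, strand, methylated reads, unmethylated reads,
context); on disk they use the Bismark cytosine-report dialect with
1-based positions. Methylation level of any set of records is always the
*weighted* level, Σ methylated reads / Σ total reads.

## Symmetric-CG processing

CG methylation is maintained symmetrically by the maintenance
methyltransferase, so the two cytosines of a CG are treated as one record.
For every CG with data on both strands a two-sided Fisher's exact test
compares the strand counts; p values are Benjamini–Hochberg corrected
across all CGs tested in the sample, and a site with corrected p < 0.05
**and** an absolute strand-level difference strictly greater than 0.40 is
censored as inconsistent. All other both-strand sites pool their counts.
Sites with data on one strand only are flagged and excluded from CG-level
analyses (the record is kept, with its own level, for inspection). Whether
the correction runs per sample or globally is not determined by the source
procedure; per sample is the default and the function operates on one
sample's table at a time. Cytosines whose position (either position, for a
merged CG) coincides with a known SNP between the parental strains are
censored to avoid genotype-driven artifacts.

Under a null simulation (both strands share the true level, depth 20 per
strand, 10^5 sites) the censored-inconsistent fraction is far below the
0.2% working bound, dominated by the BH correction.

## Genotype reconstruction

Reads are assigned to a parent by the SNP alleles they overlap: agreement
of all informative SNPs gives a parental label, disagreement gives
`conflicted`, no informative SNP gives `uninformative`; a base matching
neither allele at a SNP is ignored as a sequencing error. Mean per-base
depth of parent1-/parent2-assigned reads is tabulated in non-overlapping
200-bp windows and smoothed with a centered moving average of 51 windows
(truncated at chromosome edges — truncation rather than padding is the
simplest unbiased choice). Window calls follow fixed thresholds: with
smoothed depths `s1`, `s2`, a window with `s1 + s2 >= 2` is `hom1` when
`s1 > 1.5·s2` and `s1 − s2 > 2` (mirror for `hom2`), `het` when
`|s1 − s2| < 2` and `s1 + s2 > 2`, otherwise `undetermined`. A window
whose depth difference is exactly 2 is deliberately undetermined: the
heterozygous rule uses a strict `< 2` and the homozygous rules a strict
`> 2`. Data-free windows tile as undetermined so regions always tile the
chromosome.

Adjacent same-call windows merge into regions; then, iteratively, any
region shorter than 2 kb whose nearest *large* (≥ 2 kb) neighbors on both
sides agree is relabeled to that call and regions re-merge, until a fixed
point. Taking the nearest large neighbors (skipping intervening small
regions) is what lets a run of several small fragments between two long
homozygous blocks collapse in a couple of passes; each pass strictly
reduces the region count, so the iteration provably terminates. Only the
ratio criterion is invariant to rescaling both depth tracks; the
absolute-difference criteria are not, which is why depth is defined as
mean per-base read depth (not read count), keeping the `> 2` thresholds
meaningful at moderate coverage.

At the recovery conditions used in the tests (mosaic blocks of mean 2 Mb,
depth 10, 5% read misassignment, three 20-Mb chromosomes) the caller
recovers ≥ 99% of bases; the residual loss is the smoothing-width
transition zone around each breakpoint, whose midpoint lands within about
two windows of the true breakpoint.

## Differential cytosines and epimutation rates

Differential methylation between two samples, each with two sibling
biological replicates, is called per cytosine from all four replicate
pairings. Within a pairing, sites with at least 5 reads in every table are
tested with a two-sided Fisher's exact test, BH-corrected across the
sites of that pairing (the correction is per pairing, mirroring per-
comparison correction); a pairing scores +1/−1 only when the corrected
p < 0.05 and the level difference exceeds the context threshold (0.40 for
CG and CHG, 0.20 for CHH, strictly greater). The overall significance
score is the sum over the four pairings, in [−4, 4]; a site with score ≥ 3
is called more methylated in sample 1, ≤ −3 in sample 2. Replicates are
never pooled in the default path.

Dynamic genic sites are computed per parental genotype: only CGs inside
homozygous regions of that call, between a gene's TSS and TTS, and whose
dinucleotide does not intersect an annotated TE are compared against the
matching parent. Per-CG TE exclusion (rather than excluding whole genes
containing a TE) is the default; a whole-gene mode is a one-line filter
away for users who prefer it. Gains are RIL-higher calls among sites with
pooled parent level ≤ 0.60 (the *potential gain* set — only such sites can
show a >40-point increase); losses mirror with parent level ≥ 0.40.
Rates are `100 · |observed| / |potential|` per direction, with the
loss/gain ratio flagged undefined when no gains are observed. Overlap
between dynamic-site sets of independent lines is scored with the
upper-tail hypergeometric probability of the observed intersection.

The vectorized Fisher test is computed from the hypergeometric pmf over
each table's support (summing all outcomes no more probable than the
observed one, with the same relative tolerance scipy uses); it matches
both `scipy.stats.fisher_exact` and full enumeration to ~1e-15.

## Variability classification

Per-strain levels of a CG (strains with ≥ 5 reads; the site needs
qualifying data in at least ⌈0.676 × panel⌉ strains, the 627-of-927 rule
rescaled to any panel size) are binned into five equal bins — lo, medlo,
med, medhi, hi — left-closed, right-open, last bin closed, so a level of
exactly 0.20 falls in medlo. Local maxima holding at least 5% of strains
are peaks; runs of exactly equal adjacent bins collapse to one plateau
peak reported at the leftmost bin. One peak gives a unimodal category,
two bimodal, three trimodal; a category is *sharp* when the peak bins hold
at least 90% of the density, else *inter* (the original sharp/inter
boundary is not printed in the source text; 0.90 is the package default
and configurable). Bimodal subcategories compare the two peak-bin
proportions: *mostly* when the higher is more than 4× the lower, *biased*
when more than 1.5×, else *similar* — both strictly. The six classes
group as: unimodal lo/medlo → invariant low; hi/medhi → invariant high;
unimodal med → distributed (an intermediate-centered site is not
invariant); bimodal mostly-lo/medlo → bimodal low, mostly-hi/medhi →
bimodal high, everything biased/similar (and mostly-med) → bimodal med;
trimodal and the rest → distributed. The three-class variant for small
panels (e.g. five or seven inbred lines, keeping sites missing in at most
one strain) merges the bimodal classes with distributed into a single
*variable* class.

On synthetic 50-strain panels with per-strain noise σ = 0.05 the
classifier recovers ~94% of generating classes; the dominant confusion is
bimodal → invariant when the minor mode (10% of strains) drifts below the
5%-of-strains peak floor, an inherent property of the rule at 50 strains
that vanishes at panel sizes in the hundreds.

## Spatial statistics

Physical clustering of a site set is summarized by f100, the fraction of
within-chromosome nearest-neighbor distances ≤ 100 bp (chromosome
singletons contribute no distance; distances are pooled globally across
chromosomes). The null draws N = 1000 equal-size subsets of the eligible
background without replacement; the z-score of the observed f100 against
the resampled mean/s.d. gives an upper-tail normal p, and an empirical
permutation p (`(1 + #{resamples ≥ observed}) / (N + 1)`) is reported
alongside, since the normal approximation is what produces the very large
z values while the empirical p is bounded by the resample count. Under
the null (the "true" set itself a random subset), 200 seeded runs give a
z distribution with mean ≈ 0 and s.d. ≈ 1.

Ends metaplots average a positional track in fixed-width bins around
feature 5′ and 3′ ends, strand-oriented (minus-strand features mirrored),
dropping inside bins that cross a feature's midpoint. Relative-rate
profiles divide, per bin, the count of true sites by the count of
potential sites, with a companion profile from an equal-size random draw
of the potential set; empty-potential bins are missing. Sequence
composition (GC fraction, CG-dinucleotide count in a 200-bp window
centered on the site) is tested by drawing 10,000 equal-size background
subsets and counting permuted means above/below the observed mean; a tail
count below 100 flags significance. The 100/10,000 cutoff corresponds to
an empirical p of 0.01 per tail; both the cutoff and the reported
empirical p are exposed rather than a single nominal level. Small-RNA
association of a CG is the mean RPM over its two positions, flagged at
≥ 1 RPM.

## Prediction framework

For a direction (gain: parent level ≤ 0.60; loss: ≥ 0.40) every eligible
genic CG receives a predictor vector. Registered predictors: local CG,
CHG and CHH methylation (mean over the 200-bp window centered on the
site, excluding the focal site itself — exclusion avoids leaking the
outcome into its own predictor), methylation level of the other parent,
cross-strain variability class (one-hot of the six classes by default),
sRNA RPM from each parent, GC content, CG density, presence of the TGCWR
and RCATW motifs (IUPAC, either strand, within ±100 bp), expression of
the containing gene, and a seeded pure-noise calibration predictor.
Observed zeros are values, never missing; only methylation-derived
predictors can be missing.

The evaluation protocol per model and repeat: drop rows missing any of
the model's predictors; thin sites by seeded random-order greedy
selection so no two retained sites are within 200 bp (reducing the strong
spatial autocorrelation of neighboring CGs); keep all successes and draw
an equal number of failures without replacement (so 50% is the chance
line by construction); fit a maximum-likelihood logit; score a second,
independently drawn balanced subset as percent correct at the 0.5
probability cutoff. Non-convergence or perfect separation falls back to a
small quadratic (ridge) penalty on the coefficients, flagged in the
output. Train and test draws may share successes, as the protocol's
wording permits; a strict-disjoint variant is a two-line change but is
not the default. At small cell sizes this overlap leaks a little accuracy
into even a pure-noise model, which is why battery-scale runs use a
cohort large enough for ≳ 60 successes per cell (noise median ≈ 51%).

The 26-model grid ships with the nine text-anchored models (1 = local CG,
2–3 = local CHG/CHH, 4 = other parent, 11 = variability, 12–13 = sRNAs,
17 = other parent + variability, 26 = all predictors) marked
authoritative and the remaining rows as plausible reconstructions; the
grid is a plain mapping so a fully transcribed table can be substituted.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the study data: two parents
with divergent gene-body methylation (a configurable fraction of
parent-1-methylated genes unmethylated in parent 2, and a small reciprocal
set), binomial read counts at Poisson depths independently per strand and
replicate (replicates share true levels but not noise, like sibling
plants), RIL mosaics with exponential segment lengths, allele-tagged
window depths with a misassignment fraction, and sRNA clusters that
overlap a configurable fraction of gain sites of the *opposite* parental
origin, mimicking the trans-sRNA association qualitatively.

Dynamic sites are planted among eligible genic CGs (gain: parent ≤ 0.6;
loss: ≥ 0.4) with probability = base rate × 15 when the surrounding
200 bp has mean methylation in [0.2, 0.8], flipping the site by at least
40 points (gain → parent + 0.5 capped at 1). The true generative process
of epimutations is unknown — the source study only observes associations —
so this enrichment model is a testing device that makes the planted
signal recoverable, not a biological claim. Defaults (depth 20 per
strand, gain rate 0.01, loss rate 0.01, enrichment 15) put the dynamic
fraction of genic CGs at ~3.5% and the local-methylation model's battery
accuracy in the low 70s, inside the regimes the study reports (1–4%
dynamic sites; ~82% accuracy for the strongest predictors at full scale).
The "distributed" panel archetype is generated as a trimodal mixture
(modes near 0.1/0.5/0.9): a flat histogram would collapse to a single
plateau peak under the peak rule and be labelled invariant, so trimodal
is the stable generator of that class. Panel missingness is completely at
random — the simplest null consistent with a pure coverage filter.

Not emulated: read-level sequences and alignment (no FASTQ), bisulfite
conversion failure, PCR duplicates, copy-number differences between
strains, non-independence of neighboring sites beyond the planted
enrichment, and population structure in the strain panel. Tests passing
on this generator therefore validate the *procedures* — error control,
recovery, calibration, bookkeeping — not the biological conclusions on
real data.

## Problem sizes and numerics

Default study-condition sizes, chosen to exercise every stage at
desk scale: two 400-kb chromosomes with 120 genes (~8,000 CG
dinucleotides) for unit-level work; three 20-Mb chromosomes for genotype
recovery; 10^5 CGs for the differential caller's null and power checks;
6,000 sites × 50 strains for the panel; a 2 × 1.6-Mb, 480-gene cohort
with two RILs for the prediction battery (100 accuracy values per model
from 4 cells × 25 repeats, the same count as 10 RILs × 10 repeats).
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical config and seed give byte-identical
outputs. Ties and degenerate inputs: empty 2×2 tables give p = 1; a zero
resampling s.d. flags the clustering result degenerate instead of
dividing by zero; equal peak heights classify as "similar" with the
leftmost location; constant predictors are flagged degenerate but still
scored.
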