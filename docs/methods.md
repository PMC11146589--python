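# Methods

## Overview

`duetsnv` calls somatic SNVs from a matched tumor–normal pair in two stages.
The *calling* stage traverses both BAMs chunk by chunk, prefilters read
bases, fits per-sample error rates, estimates per-site equilibrium allele
frequencies (π) in the tumor, and emits candidate variants. The *tiering*
stage filters candidates by the normal/tumor VAF ratio, labels them against
dbSNP, fits a noise model to the π_alt values (Gaussian mixture for
whole-genome runs, Beta for whole-exome runs), derives tier cutoffs as upper
quantiles of the noise model, and writes a tiered VCF.

## Deterministic chunk-parallel traversal

`plan_chunks` splits each contig into an exact, ordered, disjoint cover of
half-open windows (default 50 kb). Up to `n_workers` chunks are processed
concurrently; every worker opens its own file handles, counts only bases
whose reference position falls inside its own window (so boundary-spanning
reads contribute to each position exactly once), and results are merged in
strict chunk-index order. Consequently the output is invariant to both
`n_workers` and `chunk_size` — the contract the tests verify byte for byte
on the final VCF and exactly on per-site counts against a brute-force
pileup.

Prefiltering drops reads flagged duplicate/secondary/supplementary/QC-fail/
unmapped, reads with mapping quality below 1, and bases that are `N` or
below base quality 5. Thresholds are inclusive and configurable
(`EngineConfig`); these defaults are conventional pileup hygiene. The
simulator emits single-end ungapped reads, but counting goes through the
aligned-pairs interface, so gapped alignments from real BAMs are handled
(insertions/soft clips contribute nothing; deleted positions are skipped).
Mate-overlap double counting is not an issue for single-end fixtures and is
out of scope for the bundled simulator.

## Per-site model

**Error model.** Each sample gets one scalar substitution rate *e*,
estimated as pooled mismatching/total filtered bases over "quiet" sites —
sites with fewer tumor alt reads than the candidate threshold and a normal
non-reference fraction ≤ 0.1 (to exclude germline heterozygotes). The rate
is clamped to [1e-4, 0.1]; under 1000 observations the floor is used with a
warning.

**Equilibrium frequencies.** At a site with filtered counts n = (n_A, n_C,
n_G, n_T), reads are modeled as draws from P(b) = (1−e)·π_b + (e/3)(1−π_b).
π is the MAP under a symmetric Dirichlet prior with concentration 1 + 1e-3
(a light pseudo-count that keeps zero-count alleles identifiable), computed
by an EM fixed point on the latent true allele. The objective is strictly
concave on the simplex, so the fixed point is the unique optimum; tests
compare it against an exhaustive coarse-to-fine simplex grid search at
resolution 1e-3 and require agreement within L∞ 2e-3 on random count
vectors.

**Candidate emission.** The non-reference allele with the highest tumor π is
the single candidate allele per site. It is emitted iff it has ≥ 3 tumor
reads, π_alt ≥ 0.005, and the normal is compatible with homozygous
reference: alt reads ≤ 2 and normal VAF ≤ 0.05. All four thresholds are
config-exposed. The normal-VAF bound is deliberately placed at the same
scale as the downstream VAF-ratio cutoff: a tighter bound (e.g. 0.03) would
reject any site where a 30× normal carries a single high-quality error read
(VAF 1/30 ≈ 0.033), vetoing several percent of true somatic variants at a
0.5% error rate.

## Tiering

**VAF-ratio filter.** A candidate survives iff normal_vaf / tumor_vaf ≤
0.05. This is the one numeric rule inherited unchanged from the published
method. Note its interaction with sequencing error: a single error read
supporting the alt allele in a normal of depth *d* vetoes every candidate
with tumor VAF < 20/*d*. With uniform-quality synthetic errors at 0.5% this
is the dominant source of false negatives on the fixtures; in real data
error bases concentrate at low base qualities and are largely removed by
the prefilter, so the veto is rarer.

**Noise model and cutoffs.** WGS mode fits a two-component 1-D Gaussian
mixture to the surviving π_alt values by EM: 50 restarts with means drawn
uniformly from the data range using seeds spawned deterministically from
the run seed, convergence at |Δ log-likelihood| < 1e-6 or 1000 iterations,
variances floored at 1e-6, and the best final log-likelihood wins. The
log-likelihood is asserted non-decreasing at every iteration — a violated
assertion is a bug, not a warning. A degenerate all-identical input
collapses both components onto the value at the variance floor. Fewer than
10 values is an error directing the user to WES mode, which fits a Beta
distribution by maximum likelihood (method-of-moments start, Nelder–Mead
over log-shape parameters; values clipped away from {0,1} by 1e-6).

Tier cutoffs are upper quantiles of the noise model (the lower-mean Gaussian
component, or the Beta itself) at levels PASS: 0.9999, Tier1: 0.999,
Tier2: 0.995, Tier3: 0.99, Tier4: 0.98. The published tier rule is not
public; this realization expresses "a call is at least tier *k* if its
π_alt exceeds what background noise would produce with probability
1 − level" and is fully configurable. Cutoffs are monotone by construction.

**dbSNP.** Membership is looked up in a bgzip-compressed, tabix-indexed
VCF; by default a match requires position, REF and ALT (position-only
matching is a switch, since the original tool's granularity is not
documented). Flagged candidates are evaluated one level more stringently: a
would-be PASS keeps PASS only if π_alt also clears an extra-strict PASS
quantile (level 1 − (1 − 0.9999)/10), otherwise each tier shifts down one.
An annotate-only mode records the flag without demotion.

## Synthetic data generator

The simulator emulates the study design the pipeline targets: a random
reference (GC fraction 0.41), germline SNPs at one per kb (heterozygous
VAF 0.5 or homozygous VAF 1.0, ratio 2:1), somatic SNVs spiked at true VAFs
drawn from a configurable distribution (default uniform on [0.1, 0.6] — the
range a high-depth caller can see), and single-end 100 bp reads at matched
80× tumor / 80× normal with a uniform 0.5% substitution error at constant
Q30. A somatic variant with true VAF *v* in a sample of purity *p* appears
on tumor-cell reads with probability *v*, so its expected observed fraction
is *v·p*. Clonality labels are minted at generation time (true VAF ≥ 0.35 →
clonal). The mini-dbSNP holds every germline site plus 10% decoy records at
non-variant positions, exercising both outcomes of the membership lookup.

Purity dilution mixes reads in silico: each tumor read is kept with
probability *p* and each normal read with probability 1 − *p*. Matched
depths are the default precisely so this mixing preserves total coverage —
how the original cell-line dilutions matched coverage is not documented, so
this is an explicit modeling choice. Purity 1 reproduces the tumor reads
exactly and purity 0 the normal reads.

What the generator does **not** model: quality-score decay or any
quality–error correlation, strand bias, FFPE artifacts, paired-end
fragments, indels, clipping, mapping ambiguity, copy-number alterations.
Tests passing on these fixtures therefore demonstrate the pipeline's
statistical and determinism contracts, not robustness to real-data artifact
modes. The uniform-Q30 error model is in one respect *harsher* than real
data: every simulated error survives the base-quality prefilter, which is
what makes the VAF-ratio veto (above) the binding constraint on recall.

## Benchmarking conventions

Call sets are compared as sets of (CHROM, POS, REF, ALT) keys; indels are
dropped and multi-allelic records decomposed before any comparison.
Consensus truth sets exclude records carrying any of the eight low-quality
FILTER labels (LOWSUPPORT, OXOGFAIL, bSeq, bPcr, GERM1000G, GERMOVLP,
NORMALPANEL, REMAPFAIL), with any-match semantics over semicolon-separated
labels. Tier-selection policies: all tiers (WGS), all except Tier5 (WES),
PASS only (for callers without tiers). F1 = 2PR/(P+R), defined as 0 when
P + R = 0; recall against an empty truth set is NaN with a warning.

VAF bins (0–0.2, 0.2–0.3, 0.3–0.4, 0.4–0.5, >0.5) and depth bins (<20,
20–40, 40–60, 60–80, >80× for WGS; 40× steps to >160× for WES) are
left-closed right-open with an open-ended last bin. Depth and VAF are
recounted once per unique key from the BAMs, so every call set is binned by
the same numbers; uncovered keys get depth 0 and are excluded from VAF
bins. Clonality comparison restricts calls to the clonality-labeled truth
subset, so only recall is defined there and the API refuses other metrics.
Variant-effect terms are merged into four classes for WES (nonsynonymous,
synonymous, untranslated region, others) and six for WGS (plus intergenic
region and intron); unknown terms map to "others" with a warning.
Dilution curves score each diluted call set against the purity-1.0 call set.

## Problem sizes and numerical choices

The test suite and acceptance script run on 100 kb genomes (30 kb for unit
fixtures): large enough for ~100 germline and up to 200 somatic sites plus
a realistic noise-site population, small enough that the whole suite
simulates, calls and evaluates everything from scratch in a few minutes.
Worker-count determinism is exercised at 60×/30× over worker counts
{1, 2, 4, 8} and chunk sizes from 10 kb to whole-contig; mixture recovery
uses 5000 draws and Beta recovery 2000 draws, matching the scale at which
the respective estimators are used. All randomness flows from explicit
seeds through `numpy.random.SeedSequence`, so every artifact — FASTA, BAM,
VCF, fit — is bit-reproducible.

Numerical details worth knowing: the π EM iterates to an L∞ fixed-point
tolerance of 1e-12 (cheap at pileup depths); GMM responsibilities are
computed in log space with `logsumexp`; the Beta log-likelihood uses
`betaln`; candidate ties between equal-π alleles break by read count, then
allele order; and VCF emission goes through pysam's htslib writer, which
renders floats deterministically, making byte-level output comparison
meaningful.

## Known limitations

- The evolutionary-model likelihood of the original caller is not public in
  the source this package was built from; the error-perturbed multinomial
  MAP used here is a documented stand-in with the same interface and
  summary statistic, isolated behind `call_model`.
- The published tier thresholds and the exact role of dbSNP membership in
  the original cutoff computation are likewise not public; both are
  realized as configurable rules (noise-quantile cutoffs, one-level
  demotion).
- Tumor-only calling, indels and FFPE-aware error modeling are out of
  scope.
- `mean_depth` and allele recounting iterate per position/key through
  pysam; they are meant for fixture-scale evaluation, not whole-genome
  production runs.
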