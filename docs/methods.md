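# Methods

This note documents the models, numerical choices and limitations behind
`scmosaic`. It describes what the code computes; every number quoted
here is produced by the test suite or by `scripts/acceptance.py`.

## Data model and conventions

Calls are tidy tables (`chrom, pos, ref, alt, cell, individual,
variant_class, mode`) with 1-based positions and VCF-style anchored
indels; internally all interval arithmetic is BED-style 0-based
half-open, and the genome is addressed by a single global coordinate
(contigs concatenated in reference order). Substitutions are classified
into the standard 96 channels with pyrimidine-strand collapse (the
channel of an SNV equals the channel of its reverse complement — a
tested invariant); indels into the standard 83 channels by homopolymer
length, flanking repeat count and microhomology. Sex chromosomes are
not modelled; synthetic genomes are autosome-like by construction.

## Burden extrapolation and aging models

A cell's genome-wide burden is `S · V`: the VAF-based call count times
the genotyper's calls-to-burden scaling factor. Rescued calls are
excluded from burden and from spectra because they are selected partly
on their signature. MDA burdens are corrected by fitting the cell's
spectrum to the active catalog augmented with an MDA artifact signature
and summing the scaled exposures of everything except the artifact; the
correction can only lower a burden, with equality exactly when the
artifact exposure is zero.

Aging models are `burden ~ 0 + cell_type + age:cell_type` with a
per-individual random intercept, fit by REML (statsmodels `MixedLM`).
Inference is Wald with the normal approximation; a cross-check test
verifies the fixed effects against R's `lme4` to ~4 digits on the same
data. (A Satterthwaite small-sample correction is not available in
statsmodels; with cohorts of ≥30 cells the normal approximation is the
practical equivalent, and the simulation-calibration test shows ≥90%
CI coverage at the default cohort size.) If the random-intercept
variance collapses to zero, if every cell is its own individual, or if
the mixed fit fails to converge, the fit falls back to OLS with HC3
robust errors and records `method = "ols_hc3"`; on noiseless input this
fallback recovers generating coefficients exactly. Cells flagged HIGH
(burden residual > k·MAD from a robust per-type trend *and* elevated
SBS19-like exposure; k = 4 by default — the flagging thresholds are
configuration, not printed constants) or LOW (≤2 calls) are excluded
from every aging fit.

## Sensitivity estimation

Leave-one-out germline controls measure VAF-based detection
sensitivity: `S_R = called / eligible` per region and cell, with
minimum-depth eligibility (6 reads for SNVs, 10 for indels) and a
50-control minimum per region (below it the estimate is null and the
cell is dropped from that region with renormalized weights — the
behavior when cells lack estimates is a package decision). The
rescue-inclusive sensitivity is `min(1, S_R·(V+M)/V)`, undefined when
V = 0. Group sensitivity weights cells by their mutation contribution
(V+M, or V in VAF-only analyses) and is always a convex combination of
the per-cell values.

## Enrichment

Quantile regions are equal-count bins of per-1 kb-window covariate
values, ties broken by genomic order (deterministic; the tie rule is a
package choice). The alignability mask uses a rank-based upper depth
cut (exactly the top 2.5% of windows), minimum cross-cell depth 6, and
bulk accessibility at depth ≥5 in every bulk sample; 1 kb windows with
more than two unalignable 100 bp sub-windows are discarded, and 1 Mb
windows follow the same rule proportionally (>20% unalignable).

The permutation null re-places each call uniformly over eligible sites
matching its SBS96 trinucleotide context (ID83 channel for 1 bp indels;
longer indels fall back to uniform eligible placement with a log
message). Sensitivity adjustment divides observed counts by the group
sensitivity and renormalizes so the corrected counts sum to the
observed total — the null is uniform over the eligible genome and needs
no adjustment, and conservation of the total (exact, tested) keeps the
two comparable. The per-region p-value is the fraction of iterations
whose |log enrichment| exceeds the observed |log enrichment|, floored
at 1/n_iterations (10,000 by default). An analytic mean
(`expected_null_counts`) replaces sampling for exact oracle
comparisons; on toy genomes it matches exhaustive enumeration over all
context-matching placements to 1e-12.

Signature-exposure enrichment substitutes NNLS exposures for counts,
uses VAF-based calls only, 3 quantiles instead of 10, and no
sensitivity adjustment; regions with <30 calls are flagged low-count.
Bootstrapped CI bars are not implemented (the resampling unit is
ambiguous); permutation bands are reported instead.

## Lineage dating

Sharing rules: shared = called in ≥1 cell with ≥2 supporting reads in
the other; private = 0 supporting reads at depth ≥6; otherwise
indeterminate (including sites with no cross-support row). Germline
hSNPs classified by the same rules give the misclassification fraction
f, and `N = s/(1−f)`; the private→shared error rate is assumed 0. MRCA
time is `T = (N·S − I)/R`, clipped to [0, subject age] with the clip
logged; the reported interval takes all four combinations of the
trend-line CI bounds and is labelled as an uncertainty probe, not a
confidence interval. Related pairs are flagged when their shared count
exceeds cohort mean + 5·MAD (absolute fallback 20 when only one pair
exists); the threshold is a package choice since "unusually high" has
no printed definition.

## Tumor comparison

Hypermutators are removed by Tukey's standard upper fence (Q3 +
1.5·IQR; the fence constant is the conventional choice). Density
tracks sum per-sample mutation fractions over retained 1 Mb windows.
Correlations are Pearson by default (Spearman by flag); covariate
regressions use the −1/x transform with non-positive covariate windows
dropped. Gene odds ratios use plain interval overlap of calls with a
non-overlapping gene model, top-n tumor genes with ties broken by
genomic order, Fisher's exact two-sided p, and a 0.5 continuity
correction (flagged) on zero cells; gene length is deliberately not
controlled in the ranking.

## The synthetic cohort generator

The generator is first-class, tested code and the package's only data
source in the test suite. It emulates:

* linear aging of true per-cell burdens with per-individual Gaussian
  random intercepts and Poisson cell-level noise;
* signature mixtures per cell type, either as fixed fractions or as
  per-signature yearly rates (rate mode: the total slope is the sum of
  the rates; intercepts split proportionally unless configured);
* context-faithful placement: SNVs at sites admitting their drawn
  channel (rejection-free via per-context site indexes), 1 bp indels at
  homopolymer runs, longer indels by capped rejection sampling (error
  if a channel is unplaceable);
* region-dependent mutagenesis (per-covariate-quantile multipliers) and
  region-dependent detection: total detection probability
  `baseline × multiplier`, VAF/rescue split by a rescue fraction, and
  germline controls detected with the VAF-based probability — so the
  sensitivity module's estimates converge to the configured model (a
  tested calibration);
* lineage pairs sharing an injected pre-split mutation set, with
  cross-cell read support subject to configurable allelic dropout
  (dropout draws are made independently per cell and per site, so the
  hSNP misclassification fraction measures the same two-sided rate
  that affects somatic shared sites — consistency, not the raw
  per-site dropout, is what the f-correction needs);
* tumor cohorts with Poisson per-sample burdens, a configurable
  hypermutator fraction/fold, and density log-linearly coupled to a
  covariate track.

Default conditions: genome 2 × 1 Mb (large enough that every SBS96
context has thousands of placement sites while keeping runs desk-scale;
burden estimation is insensitive to genome size because the scaling
factor is defined by construction); 13 donors × 5 OL-like cells (ages
0.4–83) plus 19 donors × 3 neuron-like cells; OL sSNV aging 29/year
with intercept 165 and random-intercept s.d. 25, neurons 16/107/20;
indels 2.1 and 2.9 per year (intercept 10, s.d. 2 — intercepts and
random-effect s.d. are package choices; the sources report indel
intercepts only as "comparable"); detection baseline 0.48 (SNV) / 0.41
(indel) with rescue fraction 0.2; germline controls every 1.5 kb,
depth ~30×. Per-signature yearly rates used by the exposure studies:
OL SBS1 2.77, SBS5 22.7, SBS16 0.18, with SBS32 as the 3.35/year
remainder so the rates sum to the 29/year total (the SBS32 rate is not
reported separately); neuron SBS1 0.29, SBS5 14.5, SBS16 2.0 (these
sum to 16.79, slightly above the total-burden slope of 16 — the burden
and exposure studies are therefore run as separate simulations, each
faithful to its own fitted values). Indel rates: OL ID2 0.10, ID4
0.09, ID5 0.72, ID8 0.40, ID9 0.69, ID11 0.10 (sum 2.1); neuron ID2
0.02, ID4 1.20, ID5 0.60, ID8 0.73, ID9 0.25, ID11 0.10 (sum 2.9);
ID5/ID8/ID11 splits are package choices filling the unreported
remainder.

Signature catalogs are **synthetic**: deterministic stand-ins with the
qualitative character of the correspondingly named published signatures
(SBS1-like mass on C>T at NpCpG, SBS16-like on T>C, SBS5-like broad,
etc.; ID signatures supported on channels the simulator can place).
They make simulation, NNLS fitting and recovery tests self-contained;
real analyses should load a published catalog via `load_catalog`. The
ID83 per-channel sensitivity correction vector defaults to identity
and is a configuration asset.

What the generator does **not** emulate: read-level data (no
FASTQ/BAM), amplification chemistry beyond a rescue fraction and an
optional artifact admixture, mutational hotspots beyond the covariate
coupling, clonal structure beyond explicit lineage pairs, or real
human genome composition (GC structure, repeats, mappability). Passing
tests therefore demonstrate the correctness and calibration of the
analysis machinery under the stated generative model, not performance
on real scWGS data.

## Problem sizes and determinism

Recovery studies run 20 seeds of the default cohorts (≈120 cells,
≈60,000 calls per seed) and complete in about two minutes on one CPU;
the enrichment calibration suites use single-donor cohorts with 1,000–
2,000 permutation iterations. All randomness flows from explicit
integer seeds through `numpy.random.Generator`; identical
configurations produce byte-identical outputs, and derived sub-seeds
come from `SeedSequence` so a single master seed reproduces every
study.

## Known limitations

* Wald rather than Satterthwaite inference in mixed models (see above).
* The permutation eligible genome is shared across cells of a group
  (per-cell depth masks are supported through per-cell
  `EligibleSites`, but the generator emits a shared mask).
* Multi-bp indel permutation falls back to uniform placement rather
  than full repeat/microhomology matching.
* MRCA intervals are not confidence intervals; they propagate only
  trend-line parameter uncertainty, not counting noise in N.
* The gene model is a flat interval union (no transcript structure);
  expression mapping implements the max-over-genes / ≥20% coverage
  rule on that union.
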