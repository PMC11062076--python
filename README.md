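# scmosaic

Post-calling analysis of somatic mutation catalogs from single-cell
whole-genome sequencing (scWGS) of aging human brain cells.

Single-cell genotypers emit, per cell, a set of somatic SNV and small
(1–30 bp) indel calls, leave-one-out germline control outcomes, and a
calls-to-burden scaling factor. `scmosaic` takes those outputs and
answers the downstream questions: how fast do mutations accumulate with
age in each cell type, which mutational signatures drive the
accumulation, where in the genome do mutations land once detection
sensitivity is controlled for, how long ago did two related cells share
an ancestor, and how closely does a cell type's mutation density profile
resemble tumor genomes. It is aimed at somatic mosaicism researchers who
have per-cell call tables (or want to prototype against realistic
synthetic ones — the package generates complete synthetic cohorts with
known ground truth).

## The models

**Aging burden.** Per-cell genome-wide burden is extrapolated as
`burden = S · V`, where `V` counts VAF-based calls and `S` is the
genotyper's calls-to-burden scaling factor (signature-rescued calls are
never extrapolated). Burdens are fit with a mixed-effects linear model

```
burden ~ age × cell_type + (1 | individual)
```

giving per-cell-type rates R (mutations/year) and intercepts I, Wald CIs
and per-coefficient tests. Burdens from MDA-amplified cells are first
corrected by removing the NNLS exposure to an MDA artifact signature.

**Signatures.** Per-cell SBS96/ID83 spectra (VAF-based calls only,
scaled to burden units) are fit by non-negative least squares to an
active signature catalog; per-signature exposures re-enter the same
aging model to give per-signature yearly rates.

**Regional enrichment.** The genome is masked for alignability, tiled
at 1 kb, and binned into equal-count quantiles of a covariate (or into
categorical states). Observed counts per region are divided by a
location-specific detection sensitivity `W` estimated from leave-one-out
germline controls (`S_R = called/eligible`, rescue-adjusted by
`min(1, S·(V+M)/V)`, weighted across cells by mutation counts), then
renormalized to the original total. Enrichment is the corrected count
over the mean of a spectrum-preserving permutation null (each call
re-placed uniformly over eligible sites matching its trinucleotide or
indel context); two-sided permutation p-values are floored at
1/10,000.

**Lineage dating.** For a cell pair, a call is *shared* if ≥2 supporting
reads appear in the other cell; germline hSNPs classified by the same
rules measure the misclassification fraction `f`; the corrected shared
count `N = s/(1−f)` is mapped onto the aging trend line to date the most
recent common ancestor: `T = (N·S − I)/R`.

**Tumor comparison.** Tumor catalogs lose Tukey-fence hypermutators,
are normalized per sample and summed into 1 Mb density tracks, then
correlated with sensitivity-corrected single-cell densities, regressed
on covariates (scaled by −1/x), and compared through odds ratios of
mutations hitting each tumor type's most-mutated genes.

## Worked example

Simulate the default two-cell-type cohort (13 donors contributing five
oligodendrocytes each, ages 0.4–83; 19 donors contributing three neurons
each), run burden extrapolation and the mixed aging model:

```python
from scmosaic import studies

r = studies.run_burden_study(seed=1)
print(f"OL slope      : {r['slope_OL']:.1f} sSNVs/year")
print(f"neuron slope  : {r['slope_neuron']:.1f} sSNVs/year")
print(f"slope excess  : {r['pct_excess']:.0f}%")
```

prints

```
OL slope      : 28.7 sSNVs/year
neuron slope  : 15.8 sSNVs/year
slope excess  : 82%
```

(The fitted model also reports 95% CIs — here 28.2–29.2 and 15.3–16.2 —
via `r['model'].slope_ci`.)

i.e. the pipeline recovers the generating rates (29 and 16 sSNVs/year):
oligodendrocyte-like cells gain roughly 82% more sSNVs per year than
neuron-like cells in this cohort, and the difference is detected by the
mixed-model t-test on the age × cell-type interaction.

The same study can be driven from the shell:

```bash
scmosaic all --out run1 --seed 1 --n-permutations 1000
```

which writes call tables, burden and aging reports, sensitivity tables,
regional enrichment and signature exposures into `run1/`.

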