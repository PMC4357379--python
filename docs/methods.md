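# Methods

## Droplet partition model

A well partitions a 20 µL reaction into `n_droplets` (default 20,000)
droplets of nominal volume 0.85 nL. Each template species (mutant
allele, wild-type allele, target locus, reference locus) loads into
droplets as an independent Poisson process at rate
λ = total copies / n_droplets — the well-mixed dilute-template
assumption. DNA mass converts to copies at 3.3 pg per haploid genome
(~303 haploid genome equivalents per ng), so 10 ng of diploid DNA
carries ~3,030 copies of any autosomal locus, split between alleles.

Fluorescence amplitudes are drawn from Gaussian clusters per channel:
negative 1000 ± 100 and positive 5000 ± 300 arbitrary units by default
(configurable). Droplets holding more than one template of a species
take the same positive amplitude (saturating end-point chemistry). A
mutant amplicon not recognised by the mutant probe appears on the
wild-type channel at an intermediate amplitude
`neg + cross_reactivity × (pos − neg)` — but only in droplets without
true wild-type template, which would otherwise saturate the channel.
The cross-hybridization efficiency of real probes is not quantified
anywhere we could calibrate against, so `cross_reactivity` is a free
parameter (default 0.3) and no particular value is claimed faithful.

What the simulator deliberately omits: PCR efficiency and thermocycler
kinetics, droplet coalescence, inter-cluster "rain" beyond the single
aberrant cluster, channel crosstalk, and plate-layout effects. Passing
tests therefore demonstrate correctness of the partition-statistics
chain under clean cluster structure, not robustness to every instrument
artifact of real wells.

## Quantification

Thresholds are placed per channel at the midpoint of the two 1-D
cluster centers found by deterministic 2-means (centers initialised
evenly over the amplitude range; quantile initialisation collapses when
one cluster dominates). When the centers are closer than 3 pooled
within-cluster standard deviations the channel is treated as a single
population and a fixed cutoff (default 3000) is used, logged at warning
level. Amplitudes exactly at a cutoff count as negative (explicit
tie-break).

λ̂ = −ln(n_neg/n_total) is the maximum-likelihood estimator under the
binomial–Poisson model; tests verify it against a brute-force likelihood
grid to 4 decimals. The 95% interval is the Wilson score interval on
the negative fraction mapped through −ln (bounds swap); the score method
is used because it remains well-behaved at extreme fractions. A well
with zero negative droplets is returned flagged `saturated` with NaN
concentration instead of +∞. Copies/µL = λ / droplet volume; λ in
copies/droplet is the primary unit throughout.

Aberrant-cluster detection clusters the wild-type-channel amplitudes of
mutant-channel-negative droplets into three components and reports the
middle one when it is separated from both neighbours by ≥ 4 pooled
within-cluster standard deviations and holds ≥ 1% of the well and ≥ 20
droplets (all configurable). The minimums suppress noise-driven false
clusters; the occupancy is reported relative to the whole well so it can
be compared with the mutant-positive fraction of a variant-targeting
assay on the same sample.

## Mutation calling

f = mut/(mut+wt) on estimated template copies, with a Wilson score
interval treating copies as effective binomial counts. Heterogeneity is
interval-based — heterogeneous iff the upper 95% bound of f is below
1/2 — rather than a fixed cutoff on f, because the decision should
scale with counting depth; both printed worked examples (459/479
homogeneous, 179/302 heterogeneous) reproduce under this rule. Tumour
fraction p = min(2f, 1).

Panel logic: any assay with mutant-channel λ lower bound > 0 and ≥ 5
mutant-positive droplets is a direct call (ties → largest f); otherwise
a detected aberrant cluster yields an indirect call ("unknown rare
variant", sequencing recommended, f derived from the aberrant occupancy
through the Poisson model); otherwise wild-type. Direct positives in
both GNAQ and GNA11 are flagged anomalous, not silently resolved, since
the hotspot mutations are mutually exclusive. Absence of aberrance is
treated as wild-type — whether every possible rare variant would
produce an aberrant cluster is unknowable from within the assay.

## Copy-number classification

cn = 2 λ_target/λ_reference; the delta-method standard error is
reported but classes are assigned on the point value. Class boundaries
(configurable): loss < 1.9, normal [1.9, 2.1], gain (2.1, 3.1],
amplification > 3.1. The half-open boundary assignment at 2.1 and 3.1
was a genuinely open design point (published descriptions of the gain
upper bound disagree between "< 3.1" and "< 3.2"); the chosen rule is
the one that reproduces every verifiable published count on the
packaged cohort, including the 24 gain / 28 amplification split with
the three 3.1-valued tumours classed as gain. Monosomy 3 is called at
chr3 cn < 1.9.

Chromosome-8 mechanism: 8q normal/loss → no aberration; 8q gain with
8p > 2.1 → trisomy 8 (balanced arm increase); 8q gain with 8p ≤ 2.1 →
isochromosome 8q; 8q amplification with 8p > 2.1 → trisomy plus
isochromosome; amplification with normal 8p → isochromosome 8q. Missing
8p yields an explicit `undetermined`, never a guess.

Reference validity: with ≥ 2 candidate reference loci, any candidate
whose ratio to the median deviates by more than 15% (configurable) is
flagged and excluded; the consensus is the mean of survivors; fewer
than two survivors flags the whole sample. Samples with a flagged
reference fall back to SNP-array values for all loci; unflagged samples
never consult the SNP columns.

## Cohort simulator

Class mix defaults to the joint distribution observed in the packaged
66-tumour cohort (disomy-3: 11/8/4 and monosomy-3: 3/16/24 across 8q
normal/gain/amplification). True copy numbers: chr3 ∈ {1, 2}; 8q gain =
3 copies with the trisomy/isochromosome split 8:16; amplification draws
4–6 copies with 6/28 of cases carrying trisomy on top of the
isochromosome. Observed platform values are purity-weighted mixtures of
tumour and normal copy number plus Gaussian noise (default sd 0.1),
rounded to one decimal as platforms report. Survival is exponential per
8q class with hazard h = −ln(S₅)/60 per month calibrated to five-year
survivals of 93% / 67% / 29% (normal/gain/amplification), censored at a
157-month follow-up horizon or by light exponential loss to follow-up
(rate 0.004/month). These defaults are the study conditions of the
simulated analyses and were fixed when the generator was written.

## Cohort statistics

Pearson correlation (scipy) over complete pairs; karyotype codes are
ordinal, excluded from copy-number correlations by default and, when
explicitly requested, mapped with a sign convention flag (default −1 so
that code 1 = monosomy aligns with low copy number; the original coding
direction of such data is not standardised). Kaplan–Meier, log-rank and
Cox regression go through lifelines; ties use the Efron approximation,
appropriate for moderately tied monthly data. Five-year survival is
read from the KM curve as the last step at or before 60 months.
Two-sided p-values throughout; no multiple-testing correction.

## Problem sizes and tolerances in the test suite

Monte-Carlo checks use 20,000-droplet wells with 40–100 seeds
(estimator bias, CI coverage with 500 binomial replicates, copy-number
recovery), 2,000-patient cohorts for survival calibration (±0.03 on
S(60)) and hazard-ratio recovery (mean log-HR within 5% over 10–20
seeds), and 30 replicates for null-behaviour checks. These sizes give
standard errors several times smaller than the asserted tolerances
while keeping the default suite fast. All simulations are seeded;
repeated pipeline runs are byte-identical.

## Known limitations

* The amplitude model is Gaussian with a single aberrant cluster; real
  wells show rain and drift that the threshold fitter has not been
  exercised against.
* Indirect-call allele fractions inherit any bias in aberrant-cluster
  occupancy (mutant droplets that also carry wild-type template
  saturate the channel and are invisible to the aberrant cluster, a
  factor e^(−λ_wt) at the simulator's settings).
* Survival simulation ties hazard to the 8q class only; chromosome-3
  status enters the simulated cohorts' class mix but not their hazards,
  so per-chr3 survival contrasts are emergent, not calibrated.
* Karyotype-platform correlations depend on an inclusion/coding
  convention that real datasets do not standardise; they are offered as
  a documented best effort.
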