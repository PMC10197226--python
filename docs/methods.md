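# Methods

This note documents the models, estimators, default parameters and design
choices behind `poolscan`, and what the synthetic-data generator does and
does not emulate.

## Pool-seq sampling model

All SNP statistics assume two nested binomial samplings per pool and locus:
chromosomes into the pool (2N draws from the population frequency, N
diploids) and reads onto chromosomes (C draws at coverage C). The FST
estimator corrects for both stages: ĥ = 2p̂(1−p̂)·n/(n−1)·C/(C−1) is unbiased
for the population heterozygosity under this model (the C/(C−1) factor
undoes read sampling, the n/(n−1) factor — n the haploid pool size — undoes
chromosome sampling), so Q̂₁ = 1 − mean(ĥ) and Q̂₂ = p̂ₐp̂ᵦ + (1−p̂ₐ)(1−p̂ᵦ) are
unbiased within- and between-pool identity probabilities and the ratio
(Q̂₁−Q̂₂)/(1−Q̂₂) is calibrated: an island-model simulation with true FST
0.05 returns the truth within ±0.01 (acceptance output
`fst_island_global_estimate`). Loci fixed for the same allele in both pools
(Q̂₂ = 1) are excluded from per-locus output and from both global sums.

Nucleotide diversity per window is Σĥ/window-size; windows without table
SNPs report 0 (pool-seq tables carry no per-site coverage for monomorphic
sites, so "no SNPs" is treated as "no variation", the cited sliding-window
tools' behaviour).

## Contrast association

The resistance association is the analytic core of the hierarchical
population model: standardized deviations ãₗⱼ = (p̂ₗⱼ − π̂ₗ)/√(π̂ₗ(1−π̂ₗ)) with
π̂ₗ the unweighted pool mean; Ω̂ = L⁻¹Σãₗãₗᵀ plus a ridge of 10⁻⁶·trace/J;
C2 = (cᵀã)²/(cᵀΩ̂c) referred to χ²(1). Because the same data enter the
numerator and Ω̂, the statistic is self-calibrating: on a 50,000-locus null
simulation the p < 0.05 fraction is 0.0505 and the Kolmogorov–Smirnov test
against χ²(1) is non-significant. Binomial sampling noise inflates diag(Ω̂);
no noise subtraction is applied (it would threaten positive-definiteness),
which is harmless for C2 since the inflation enters the denominator
consistently. π̂ₗ as an unweighted mean is adequate at four pools with
similar coverages; a hierarchical estimate would matter only with very
unequal pools.

The local FDR uses π̂₀ = min(1, #{p > 0.5}/(0.5m)) and the Grenander
(monotone non-increasing, least-concave-majorant) density of the p-values —
deterministic, no bandwidth; lfdr(p) = min(1, π̂₀/f̂(p)), made monotone by a
running maximum. The Bayes factor is the Gaussian conjugate form
BF = (1+τ)^(−1/2)·exp(y²τ/(2(1+τ))) on the standardized contrast y, τ = 1
("unit-information"-like); it is reported in deciban and its 5 dB filter is
severable from the call set.

Outlier calls are the conjunction (AND) of the four filters, with strict
inequalities at the thresholds (lfdr < 0.2, dB > 5, strictly higher derived
frequency); the top-5% FST flag is computed on MAF-retained loci and keeps
ties at the quantile.

## SV detection

Per scaffold, proper pairs are FR pairs with insert at or below the
empirical 99% quantile; insert mean/sd come from those, and the clustering
distance (`insertSizeDiffCutoff`) is 4×sd. Everted pairs (left read −,
right read +) mark tandem-duplication junctions; same-strand pairs mark
inversion boundaries (both orientations) and inverted-duplication junctions
(one orientation). Single-linkage clustering joins two pairs when both left
and right coordinates agree within the cutoff; clusters need ≥ 3 supporting
pairs (mapping noise floor; the support threshold is configurable).

Event breakpoints use an insert-aware per-pair estimator: a
junction-adjacent read on the + strand sits on average half an insert
upstream of its breakpoint, a − read half an insert minus a read length
downstream, so each pair votes jl = left ± (μ/2 or μ/2 − read_len) by
strand and the event takes the median vote. The naive alternative
(medians of innermost read edges) carries a deterministic ~μ/2 ≈ 150 bp
bias for standard 2×100 bp / 300 bp libraries, larger than the insert sd
itself; the corrected estimator places breakpoints within ~40 bp on
planted events.

Cross-pool matching requires the same orientation class and start/end
agreement within the sum of the two pools' cutoffs (inclusive), greedily by
nearest start; unmatched focal events keep reference support 0 so
focal-specific SVs stay visible. Depth ratios are TE-masked means
(intervals > 90% masked give missing values); the empirical null allocates
the 10,000 windows equally over 8 log-spaced size classes between 500 bp
and 2.5 Mb with log-uniform sizes within class (the class count and total
are configurable; the total-n reading was chosen over per-class). Typing:
everted + ratio > q75 → tandem duplication; same-strand + ratio > q75 →
inverted duplication; same-strand + ratio in [q25, q75] → inversion;
everything else is discarded, as are events < 3.5 kb and events whose
breakpoint-side 150 bp windows overlap TEs by more than 100 bp.

A known sensitivity property follows from the typing rule: an inversion
does not change read depth, so its ratio is statistically exchangeable with
same-size null windows and the 25–75% retention keeps a true inversion only
~50–75% of the time (the upper end when the event sits at the large end of
its size class, whose interquartile range is set by smaller, noisier
windows). Duplications at moderate frequency are essentially always
retained (ratio 1+f ≫ q75).

Event frequencies invert the discordant-support geometry: the expected
number of junction-spanning read pairs is f·(C/2r)·E[(F−2r)⁺] per junction
(C base coverage, r read length, F the insert), so the raw ratio
2·support·r/(flank coverage·E[(F−2r)⁺]·junctions) estimates f for
copy-neutral events — and f/(1+f) for duplications, whose inward 150 bp
flanks are themselves amplified; the duplication estimate is therefore
inverted (r/(1−r)) and capped at 1. Inversions contribute two junctions,
duplications one. Median |f̂−f| on planted tandem duplications is ~0.13
across f ∈ {0.2, 0.5, 0.8}; the error is dominated by Poisson support
noise at low f and by the cap at high f.

SV FST is (f₁−f₂)²/(f₁(1−f₂)+f₂(1−f₁)) (0 when both frequencies are 0),
computed only for events strictly more frequent in the focal pool, with a
per-class top-10% selection. Gene overlap extends events by 1 kb both ways.

## Enrichment tests

Exact binomial upper tails (scipy's regularized incomplete beta agrees with
brute-force pmf summation to < 10⁻¹²) with Bonferroni for linkage-group and
SV–gene-overlap enrichment; two-sample proportion χ² with Yates continuity
correction (the R default) and Benjamini–Hochberg for category tests. The
per-scaffold SV test is the two-cell χ² (in/out of scaffold, 1 d.f.) with
Bonferroni and removal of scaffolds with < 5 expected events; the Yates
correction is applied by default because the plain form's familywise error
measures 0.060 at expected counts ~25 (uniform-placement simulation,
3,000 replicates) versus 0.031 with the correction — the uncorrected
arithmetic remains available via `continuity=False`.

## Bioassay

Probit fits are binomial GLMs (statsmodels IRLS, probit link) of mortality
on log₁₀ dose, with Abbott's correction applied to treated proportions when
control mortality is non-zero (standard toxicology practice; the original
tool chain's behaviour is not documented). LD_p inverts the linear
predictor at Φ⁻¹(p) with a delta-method standard error from the (a, b)
covariance; the strain comparison is a two-sided z-test on log₁₀ LD95
differences (the printed goodness-of-fit statistic of the motivating
design is not defined anywhere we could verify, so the comparison is
labelled as what it is), with significance stars at 0.05 and 0.001.
Resistance ratios are max/min of the two LD95 values, reported raw and
rounded. Across 100 simulated assays (3 replicates × 10 insects × 7
doses), the 95% Wald CI covers the true LD95 in ≥ 95 of 100 runs.

## Synthetic-data generator

The generator is first-class, tested code and defines the study conditions:
four pools (fieldA/fieldB resistant, labA/labB susceptible; 30, 30, 28, 30
diploids), depth 30× (Poisson per locus and pool, truncated at the coverage
floor), ancestral derived-allele frequencies Beta(0.7, 0.7) truncated to
[0.05, 0.95] (U-shaped like real folded spectra), truncated-normal pool
deviations with a block covariance Ω (diagonal 0.02, small shared
background, extra fieldA–labA covariance for the same-origin pair — which
is what makes those two pools nearest neighbours in PCA), and two-stage
binomial count sampling. Selected loci get a frequency shift δ (default
0.35) added to the derived allele in both resistant pools; their ancestral
frequencies are drawn Uniform(0.05, 0.25) because resistance alleles are
derived and ancestrally rare (the classic kdr pattern: absent from the
susceptible strain, tens of percent in the field strain). Clipping at
[0, 1] biases extreme-frequency loci slightly; the Ω-recovery test budgets
for it.

Genes are placed without overlap with log-normal lengths (median 7 kb),
carry stop-free random CDS sequences (so coding effects and πN/πS are
computable without a reference FASTA), ~3.3% are assigned to one of ten
resistance categories, and TE intervals cover a configurable fraction (5%
default). Read pairs are background FR fragments (insert Normal(300, 50),
read length 100 — note E[(F−2r)⁺] ≈ r for this standard geometry) plus
junction-spanning discordant pairs at rate f·λ·E[(F−2r)⁺] with
class-correct mapping geometry; depth tracks are per-base Poisson with a
(1+f) factor inside duplications. Bioassay tables are binomial probit
curves, optionally with control mortality.

Not emulated: sequencing error and base-quality structure, mappability and
GC biases (depth is homogeneous Poisson), linkage disequilibrium between
loci (every locus is independent), overlapping or nested SVs, and
inter-scaffold events. Passing tests therefore demonstrate estimator and
pipeline correctness under the declared sampling model, not robustness to
alignment artifacts on real genomes — the TE masking and extremity filters
exist for the latter but are exercised only synthetically.

## Statistical power at the design scale

At depth 30× and 60 haploids per pool, the contrast variance has a sampling
floor of Σc²(1/2N + 1/C) ≈ 0.167 on the standardized scale even with zero
drift, capping the median contrast z-score near 3 for a δ = 0.35 shift at
intermediate frequencies. The strict lfdr < 0.2 rule at 0.1% signal mass
(100 selected among 100,000 loci) requires p ≈ 10⁻⁴ (z ≈ 4), so the
combined filter is precise (measured precision 1.0) but recovers only the
strongest minority of selected loci (measured recall ~0.07 under these
conditions). This is a property of the decision rule at this design scale,
not an implementation artifact: power rises steeply with depth, pool size,
or effect size. The power-style check that is robust at this scale —
median C2 of selected loci above the null 95th percentile — passes with a
wide margin.

## Problem sizes used in tests

Unit tests run at 10²–10⁴ loci; calibration checks use 20,000–50,000 loci;
the outlier-recovery scenario uses 100,000 loci over three 10 Mb scaffolds;
SV scenarios plant 45 and 27 events on three ~3 Mb scaffolds at 30×
(≈ 1.3M read pairs per pool); πN/πS neutrality uses 500 genes × 120 SNPs;
probit recovery uses 100 assays. The full suite runs in well under five
minutes; the acceptance script in about half a minute.
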