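# Methods

This note documents the models, estimators and numerical choices behind
`crowscape`: what each component assumes, which parameters matter and why
their defaults are what they are, what the synthetic-data generator does
and does not emulate, and the known limitations.

## 1. Estimators

**Weir–Cockerham F_ST.** Per segregating site the 1984 two-level variance
components a (among populations), b (among individuals within populations)
and c (within individuals) are computed from diploid genotype counts,
using observed heterozygosity and the unequal-sample-size corrections. A
site enters a pair's analysis only if each population has genotype calls
for at least 50% of its individuals (inclusive at exactly 50%). Window
F_ST is the ratio of sums, sum(a)/sum(a+b+c), over the window's usable
sites. Negative window estimates are retained — they carry information
about the estimator's null distribution and the z-standardization is
honest only if they are kept — and are clamped to [0, 1−1e−9] solely
inside the PBS logarithms.

**PBS.** PBS₁ = [−ln(1−F₁₂) − ln(1−F₁₃) + ln(1−F₂₃)] / 2, i.e. the whole
sum halved. The three branch statistics satisfy the identity
PBS₁+PBS₂+PBS₃ = −½[ln(1−F₁₂)+ln(1−F₁₃)+ln(1−F₂₃)], which the test suite
asserts on random inputs.

**SFS statistics.** π and Watterson's θ are per callable base (window span
minus masked bases); Tajima's D uses the standard variance constants;
Fay & Wu's H is the per-window θ_π − θ_H on the unfolded spectrum
(θ_H = Σ 2 S_i i² / (n(n−1))); Fu & Li's D (outgroup version) uses the
segregating-site count and the derived-singleton count. The textbook
formulas assume a constant number of sampled alleles, but missing
genotypes make the called-allele count vary by site; each window therefore
uses its modal called-allele count and excludes deviating sites, with the
excluded count logged. Windows whose modal count is below 4 alleles are
flagged missing, as are D/H in windows without segregating sites (π and θ
are 0 there, not missing). Sites without a usable ancestral allele are
excluded from the unfolded statistics but retained for π, θ, F_ST and
D_xy.

**D_xy.** Σ_sites [p_A(1−p_B) + p_B(1−p_A)] divided by the window's
callable span; monomorphic callable sites contribute zero to the numerator
and sit in the denominator. Callability here is span minus mask — with
called genotypes there is no per-pair depth information, so the paper-style
depth-aware callability is out of reach; the simulator's mask emulates the
repeat-exclusion component.

**Linkage disequilibrium.** Mean haplotype r² over all SNP pairs within a
window, restricted to SNPs with minor allele frequency above 0.1; windows
with fewer than two qualifying SNPs, and all windows on scaffolds shorter
than the window size, are missing.

**Patterson's D.** Frequency-mode ABBA/BABA with the ancestral state as
outgroup allele: ABBA = (1−p₁)p₂p₃, BABA = p₁(1−p₂)p₃. Z comes from a
delete-one block jackknife over contiguous blocks (default 50 windows =
2.5 Mb at the default window size, comfortably above the background LD
scale); |Z| ≥ 3 is flagged significant.

**Haplotype scans.** EHH at distance x from a core is the probability that
two distinct carrier haplotypes are identical over every site between the
core and x; the implementation computes it from the cumulative OR of
pairwise mismatches, which makes the walk cost linear in sites × pairs.
iHH integrates EHH by trapezoid against physical distance until the curve
first drops below 0.05 (the cited scan tool's default; configurable); a
site whose curve never decays below the cutoff before the scaffold edge,
or whose walk crosses a physical gap larger than 200 kb while still above
the cutoff, is flagged NaN rather than extrapolated. Raw iHS is
ln(iHH_ancestral/iHH_derived), so sweeps on the derived background are
negative; nSL is identical with distance counted in segregating sites (and
no gap rule, since it uses no physical distance); XP-EHH is
ln(iHH_A/iHH_B) over all haplotypes regardless of allele, standardized
genome-wide. iHS and nSL are standardized to mean 0 / s.d. 1 within 100
equal-width derived-frequency bins; at desk-scale site counts many bins
would hold a handful of sites and their sample s.d. would be garbage, so
bins with fewer than 20 finite values are merged with their right
neighbour (the trailing remainder merges left). Single-SNP outliers are
the union of the tails below the 0.5th and above the 99.5th percentile (1%
combined); the printed-source ambiguity between a 0.05th and a 0.5th
percentile lower tail is resolved in favour of 1% combined, consistent
with the α³ form of the shared-outlier expectation, and both tails are
parameters.

**Shared-outlier expectation.** Under independence, a SNP in the set
shared across all zones is an outlier in zone z with probability
α·prop_z, so the expected number of SNPs flagged in every zone is
n_shared · Π_z (α · prop_z). α defaults to 0.01.

## 2. The decomposition

F_ST′ is the per-comparison z-score of window F_ST over all non-missing
windows (computed per comparison, not pooled). ΔF_ST′ subtracts the
per-window maximum F_ST′ over the available controls; a window is dropped
only when the focal value or every control is missing. Outlier calls use
the empirical percentile (linear interpolation) with a strict inequality;
percentiles are per track. Peaks are maximal runs of strictly adjacent
outlier windows within a scaffold (a `max_gap` parameter admits gaps if
wanted); classification is peak-level: one ΔF_ST′-outlier member makes the
peak contact_zone.

**Clustering test.** Statistic: mean run length of flagged windows. Null:
independent shuffle of the flag vector within each scaffold, which
preserves per-scaffold outlier counts and makes positions exchangeable. (A
circular rotation was considered and rejected: rotation preserves run
structure, so it cannot detect clustering of the runs themselves.) The
statistic is a ratio of small integers, so the permutation distribution is
heavily tied; `clustering_test` returns both the conservative p-value
(1 + #{null ≥ obs})/(n_perm + 1), which is valid but sub-uniform, and a
seeded tie-randomized p-value that is exactly Uniform(0,1) under the null
and is the right object for calibration checks.

**Moran's I.** Lag-1 binary adjacency between consecutive non-missing
windows of a scaffold, row-normalized (interior windows average their two
neighbours, ends take their single neighbour); genome-wide I is the
weight-sum-weighted average over scaffolds. Constant or <3-window
scaffolds are flagged NaN.

**Correlation panels.** Four families of Pearson correlations between
per-window tracks: (a) one intra-population statistic between populations;
(b) statistic pairs within a population; (c) a pair statistic against an
intra-population statistic of a *non-member* population; (d) pair
statistics between *disjoint* comparisons. The exclusions in (c) and (d)
remove pseudo-replication: a pair statistic and its own member's diversity
(or two overlapping pairs) share the very allele-frequency draws they are
built from and correlate mechanically even under a flat landscape. A
partial-correlation helper residualizes both tracks on a covariate (e.g. a
substitution-rate proxy for mutation rate) before correlating.

**Interaction model.** OLS of diversity on z-standardized recombination
proxy, gene density and their product; constant predictors or a design
condition number above 1e8 raise a collinearity flag.

**Isolation by distance.** Genetic distance F_ST/(1−F_ST) (F_ST = 1 is an
error, not an infinity swallowed silently), great-circle geographic
distance on a sphere of radius 6371 km, population coordinates as
sample-size-weighted means of sampling locations. Mantel r is the Pearson
correlation of off-diagonal entries; p permutes population labels with a
seeded generator (two-sided on |r|); residuals from the least-squares line
identify pairs more similar than geography predicts.

**Tension-zone scaling.** With equal dispersal σ, the selection
coefficient maintaining a zone of width w scales as s ∼ (σ/w)², so a
width ratio ρ implies a ρ²-fold change in s.

## 3. The synthetic-data generator

The generator is a hierarchical Balding–Nichols model, not a coalescent:
adequate to produce every statistical structure the pipeline tests, and
orders of magnitude faster, with exact planted truth.

**Linked-selection landscape.** Covariates ρ_w (recombination proxy,
lognormal-like) and g_w (gene density, logistic of a Gaussian field) are
generated as Gaussian random fields smoothed per scaffold at the
configured autocorrelation length (default 3 windows). B_w is a
deterministic monotone map of the min–max-normalized covariates —
hazard = 0.35·g + 0.35·(1−ρ) + 0.30·g·(1−ρ), B = B_max − (B_max−B_min)·hazard
— decreasing in gene density, increasing in recombination, with a positive
interaction, and bounded in (0, 1]. B acts twice, mirroring background
selection: it amplifies drift, F_{p,w} = 1 − exp(−t_p/B_w), and it thins
diversity, with the per-window site count proportional to B_w.

**Frequencies.** The ancestral derived-allele frequency follows the
discretized neutral spectrum P(i) ∝ 1/i over i = 1..2N−1 (N = 1000); a
sample of n alleles from this density has expected unfolded SFS ∝ 1/i
exactly, which is what makes the neutral Tajima's D calibration a
meaningful check. Within each window the spectrum is sampled by systematic
(stratified) quantiles assigned to sites in random order, and site counts
are deterministic round(λ_w): both choices remove between-window sampling
noise of the *shared* inputs, which would otherwise masquerade as shared
landscape structure (with i.i.d. draws, r(π_i, π_j) ≈ 0.5 between
populations even under a flat B — shared ancestral composition, not
biology — and no flat-landscape null would be clean). Each node's
frequency is a Beta draw around its parent with the window's F; planted
contact-zone windows add `divergence_boost` to F for exactly one member of
the focal pair; gene-flow edges then mix sink frequencies as
(1−m)·p_sink + m·p_source. Frequencies outside [0,1] raise, never clamp.

**Haplotypes.** A first-order latent-quantile copying chain: a uniform u
persists site-to-site with probability 1−r (r = `ld_refresh_prob`,
default 0.08) and the allele is 1[u < p_site]. Marginals are exactly
Bernoulli(p) — LD is added without distorting frequencies — and r² decays
geometrically with the number of intervening sites. Sweeps are planted by
construction: carriers (default half the haplotypes) copy a single
template over a tract of `strength × sweep_tract_bp` (default 100 kb)
around the core, whose derived allele is given exactly to the carriers.
Deterministic truth, no forward simulation.

**Default scenario.** Twelve populations in six pairs off a star root: one
focal pair (t = 0.05 per branch, the recent radiation) and five control
pairs with t ∈ {0.01, 0.025, 0.05, 0.1, 0.3}, spanning genome-wide F_ST
from ~0.02 to ~0.45 — the gradient of overall differentiation the control
design needs. 20 scaffolds × 100 windows of 50 kb; 60 expected SNPs per
window (the real study's density is an order of magnitude higher; 60 is
the desk-scale point at which window estimator noise stays subdominant to
the landscape signal); B ∈ [0.2, 1]; 6 diploids per population;
divergence_boost = 1.0, which drives the boosted member's drift to
near-fixation — planted windows emulate the near-fixed divergent
haplotype blocks observed at real contact-zone peaks rather than a mild
quantitative shift. These defaults are the study conditions of the
acceptance suite and are not tuned per test.

**What the generator does not emulate.** No coalescent correlation
structure between windows beyond the B field; no recombination-map
realism; no sequencing error, coverage variation or phasing error; no
sex-linked inheritance; gene flow is a one-shot frequency admixture, not
continuous migration; sweeps are hard by construction. Passing tests
therefore demonstrate that the pipeline recovers the targeted structures
when present at realistic magnitudes — not that the statistics are robust
to ascertainment, phasing or mapping artefacts of real data.

## 4. Numerical and interface conventions

Internal coordinates are 0-based half-open; VCF is read/written 1-based;
BED is 0-based half-open; a 1-based position P maps to window
floor((P−1)/window_size). Trailing short windows are kept and flagged;
length-normalized statistics use the actual span. Missing window values
are NaN, never silent zeros. All randomness flows from
`numpy.random.default_rng(seed)` in a fixed order, so identical seed and
config give byte-identical outputs. The pipeline runner hashes stage
inputs (content hashes, not timestamps) and skips stages whose inputs and
outputs are unchanged.

## 5. Problem sizes used by the test and acceptance suites

Decomposition recovery runs 25 replicates of the full default scenario
(2,000 windows, 6 pairs). The correlation sign structure pools three seeds
of a 10 × 80-window variant with no planted windows, against a
constant-B control arm. Sweep recovery runs 25 replicates of a
2-scaffold × 40-window scenario with 10 diploids and one planted sweep per
replicate. Null calibrations use 200 trials with 199 permutations each;
the neutral Tajima's D check uses 600 windows of a zero-drift, flat-B
configuration (zero drift because Balding–Nichols drift is not a
stationary SFS evolution — any t > 0 distorts the spectrum away from the
neutral 1/i expectation, as real drift would). The ABBA-BABA fixture uses
a deep donor branch (t = 0.6) against shallow sisters (t = 0.1) so that
m = 0.1 produces D well above jackknife noise at desk scale.
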