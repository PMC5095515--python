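# crowscape

Decomposition of heterogeneous genomic differentiation landscapes across
population pairs — the comparative genome-scan logic used to separate
*shared linked selection* from *contact-zone-specific divergent selection*
in recently radiated species complexes (the motivating system is a crow
species complex with multiple hybrid zones), implemented as a tested,
reusable Python pipeline with a synthetic-data generator carrying planted
truth.

## The problem and the method

Windowed relative differentiation (Weir–Cockerham F<sub>ST</sub>) is
heterogeneous along any genome. Two very different processes produce
peaks: linked/background selection acting on a genome architecture shared
by *all* populations, and divergent selection specific to a hybrid or
contact zone. The decomposition separates them empirically:

1. For each comparison, window F<sub>ST</sub> is z-standardized over the
   genome: **F<sub>ST</sub>′** = (F<sub>ST</sub> − mean)/s.d.
2. A set of allopatric, phenotype-matched **control pairs** provides a
   per-window empirical null: the maximum control F<sub>ST</sub>′ at each
   window is a conservative estimate of shared (linked-selection-driven)
   differentiation there.
3. Net differentiation of a focal contact-zone pair is
   **ΔF<sub>ST</sub>′(w) = F<sub>ST</sub>′(w) − max over controls**.
4. Windows above the 99th percentile of F<sub>ST</sub>′ are outliers;
   maximal runs of adjacent outlier windows are merged into peaks. A peak
   containing at least one ΔF<sub>ST</sub>′ outlier window is classified
   **contact_zone**, otherwise **shared**.

Supporting evidence implemented alongside: per-window π, Watterson's θ,
Tajima's D, Fay & Wu's H, Fu & Li's D, D<sub>xy</sub>, mean r², the
population branch statistic PBS, Patterson's D (ABBA-BABA with block
jackknife), haplotype scans (EHH, iHH, iHS, nSL, XP-EHH with 100-bin
frequency standardization and single-SNP outlier calls), the
shared-outlier expectation under independence, outlier clustering and
Moran's I autocorrelation, the between-track correlation panels, the
ρ × gene-density interaction model for diversity, isolation by distance
(Mantel test on F<sub>ST</sub>/(1−F<sub>ST</sub>) vs great-circle
distance), and the tension-zone scaling s ∼ (σ/w)².

Because real inputs at study scale are not reproducible on a desk, the
`simdata` module generates multi-population genotypes with the statistical
structure the analysis assumes — a shared linked-selection factor
B<sub>w</sub> built from recombination and gene-density covariates,
hierarchical Balding–Nichols allele frequencies on a population tree,
planted contact-zone windows, planted sweeps with extended core
haplotypes, and gene-flow edges — plus TSV truth tables, so every stage is
testable end to end. See `docs/methods.md` for the model and its limits.

## Worked example

```python
import numpy as np
from crowscape import simdata, sitestats, landscape, haplostats

cfg = simdata.default_scenario(seed=7)      # 2,000 windows, 12 populations,
sim = simdata.simulate(cfg)                 # 1 focal + 5 control pairs,
vm, windex, popmap = simdata.to_variant_matrix(sim)  # 20 planted windows

controls = [(f"ctrl{i}_a", f"ctrl{i}_b") for i in range(1, 6)]
z = landscape.zscore_fst(
    sitestats.pair_window_fst(vm, "focal_a", "focal_b", windex).values)
control_z = [landscape.zscore_fst(
    sitestats.pair_window_fst(vm, *c, windex).values) for c in controls]
delta = landscape.delta_fst(z, control_z)
z_flags = landscape.call_outlier_windows(z, 99)
d_flags = landscape.call_outlier_windows(delta, 99)
peaks = landscape.classify_peaks(z_flags, d_flags, windex.windows,
                                 fst_prime=z, delta=delta)
```

With seed 7 this prints (via the summaries in the example script below):

```
outlier windows (F_ST' > 99th pct): 20
peaks: 20 (18 contact_zone, 2 shared)
planted contact-zone windows recovered: 18/20
control ctrl5: mean run length 1.11, p = 0.009, Moran's I = 0.142
expected shared haplotype outliers across three zones: 1.8
fold-change in s for a 3x wider tension zone: 9
```

Reading this: the focal comparison's 20 outlier windows are dominated by
the planted contact-zone windows, 18 of which are recovered and correctly
classified against the control null. In the allopatric control comparison
— where only the shared linked-selection landscape operates — outlier
windows are significantly clustered (permutation p = 0.009) and the
F<sub>ST</sub>′ track is spatially autocorrelated (Moran's I = 0.14),
the signature expected when differentiation tracks a smooth underlying
B<sub>w</sub> landscape. The last two numbers are the analytic results:
with 1% outlier tails per zone, zone proportions 1.00/0.69/0.48 and
5,447,980 shared SNPs, ~1.8 SNPs are expected to be outliers in all three
zones by chance; and a three-fold wider tension zone at equal dispersal
implies a 9-fold weaker selection coefficient.

The same pipeline runs from the shell:

```bash
crowscape simulate --out sim/ --seed 7
crowscape run --config run.yaml          # simulate -> ingest -> stats ->
                                         # haploscan -> decompose
```

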