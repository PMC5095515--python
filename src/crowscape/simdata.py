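"""Synthetic multi-population genotype data with planted truth.

Generates diploid genotypes and phased haplotypes for a set of populations
related by a rooted tree, on a genome of tiling non-overlapping windows.
The generator reproduces the statistical structure that the landscape
decomposition assumes in real data:

* a shared per-window linked-selection factor ``B_w`` in (0, 1], built from
  recombination-rate and gene-density covariates, which (i) amplifies drift
  (``F = 1 - exp(-t / B_w)``) and (ii) thins the density of segregating
  sites, so that diversity is reduced, and differentiation elevated, in the
  same windows for every population;
* contact-zone windows where one member of a focal pair receives an extra
  divergence boost on top of the shared landscape;
* sweep regions where the derived allele at a core site rides on one
  extended haplotype, so extended-haplotype-homozygosity statistics decay
  slowly on the derived background;
* gene-flow edges that mix sink allele frequencies toward a source.

Allele frequencies follow a hierarchical Balding-Nichols model: an
ancestral frequency is drawn from the neutral 1/i spectrum (discretized as
derived-allele counts in a notional pool of ``2 * grid_n`` chromosomes) and
each node's frequency is a Beta draw around its parent with drift parameter
``F``. Haplotypes carry background LD through a first-order latent-quantile
copying chain whose per-site marginal is exactly Bernoulli(p), so allele
frequencies are undistorted by the LD mechanism.

Everything is driven by a single :class:`numpy.random.Generator`; identical
seed and config give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "PopulationSpec",
    "ContactZoneSpec",
    "SweepSpec",
    "GeneFlowSpec",
    "SimConfig",
    "SimTruth",
    "SimResult",
    "build_linked_selection_landscape",
    "simulate_frequencies",
    "emit_genotypes_and_haplotypes",
    "simulate",
    "write_sim_output",
    "default_scenario",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One sampled population (leaf of the population tree).

    ``t`` is the branch length to ``parent`` in drift units; the realized
    per-window drift parameter is ``F_w = 1 - exp(-t / B_w)``.
    """

    label: str
    n_diploid: int
    t: float
    parent: str = "root"
    lat: float = 0.0
    lon: float = 0.0


@dataclass(frozen=True)
class ContactZoneSpec:
    """A focal pair with planted divergent windows.

    ``divergence_boost`` is added to the drift parameter of ``pop_a`` (only)
    at ``n_divergent_windows`` windows chosen uniformly at random.
    """

    pop_a: str
    pop_b: str
    n_divergent_windows: int
    divergence_boost: float


@dataclass(frozen=True)
class SweepSpec:
    """A planted selective sweep.

    The derived allele at the core site (centre of ``window`` on
    ``scaffold``) is placed on a single extended core haplotype shared by
    all carriers over a tract of ``strength * tract_bp`` bases.
    """

    population: str
    scaffold: int
    window: int
    strength: float = 1.0
    carrier_fraction: float = 0.5


@dataclass(frozen=True)
class GeneFlowSpec:
    """Admixture edge: sink frequencies become (1-m)*sink + m*source."""

    source: str
    sink: str
    m: float


@dataclass
class SimConfig:
    seed: int = 0
    n_scaffolds: int = 20
    windows_per_scaffold: int = 100
    window_size: int = 50_000
    snps_per_window: float = 25.0
    populations: list[PopulationSpec] = field(default_factory=list)
    # linked-selection landscape
    b_autocorr_windows: float = 3.0
    b_min: float = 0.2
    b_max: float = 1.0
    # when True the landscape is flat at b_max (control scenario)
    b_constant: bool = False
    contact_zones: list[ContactZoneSpec] = field(default_factory=list)
    sweeps: list[SweepSpec] = field(default_factory=list)
    gene_flow: list[GeneFlowSpec] = field(default_factory=list)
    # haplotype background LD: per-site probability of refreshing the latent
    # copying state; smaller -> longer-range r^2
    ld_refresh_prob: float = 0.08
    # sweep tract length in bases at strength 1
    sweep_tract_bp: int = 100_000
    # fraction of windows that contain a masked sub-interval
    mask_fraction: float = 0.0
    # masked sub-interval length as a fraction of the window
    mask_span_fraction: float = 0.2
    # notional pool size for the discretized neutral ancestral spectrum
    grid_n: int = 1000

    def __post_init__(self) -> None:
        if self.n_scaffolds <= 0 or self.windows_per_scaffold <= 0:
            raise ValueError("need at least one scaffold and one window")
        for p in self.populations:
            if p.n_diploid != 0 and p.n_diploid < 2:
                # n_diploid == 0 marks an unsampled internal node
                raise ValueError(f"population {p.label}: need >=2 diploids")
        for cz in self.contact_zones:
            if cz.divergence_boost <= 0:
                raise ValueError("divergence_boost must be > 0")
        for gf in self.gene_flow:
            if not 0.0 <= gf.m <= 0.5:
                raise ValueError("admixture fraction m must be in [0, 0.5]")
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels")

    @property
    def n_windows(self) -> int:
        return self.n_scaffolds * self.windows_per_scaffold

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimTruth:
    """Ground truth emitted alongside the data."""

    windows: pd.DataFrame           # scaffold, start, end, wid, B, rho, gene_density, lam
    drift: pd.DataFrame             # wid x population -> F_{p,w}
    contact_windows: pd.DataFrame   # pair label, wid, boost
    sweep_sites: pd.DataFrame       # population, scaffold, pos, wid, strength
    gene_flow: pd.DataFrame         # source, sink, m


@dataclass
class SimResult:
    config: SimConfig
    windows: pd.DataFrame               # scaffold, start, end, wid
    sites: pd.DataFrame                 # scaffold, pos (1-based), wid
    freqs: dict[str, np.ndarray]        # population -> derived freq per site
    haplotypes: dict[str, np.ndarray]   # population -> (2*n_diploid, n_sites) uint8
    truth: SimTruth
    mask: pd.DataFrame                  # scaffold, start, end (0-based half-open)

    def genotypes(self, pop: str) -> np.ndarray:
        """(n_diploid, n_sites) derived-allele dosage."""
        h = self.haplotypes[pop]
        return h[0::2] + h[1::2]


# ---------------------------------------------------------------------------
# landscape


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-12:
        return np.full_like(x, 0.5, dtype=float)
    return (x - lo) / (hi - lo)


def build_linked_selection_landscape(
    config: SimConfig,
    rho: np.ndarray | None = None,
    gene_density: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window linked-selection factor ``B_w`` in (0, 1].

    ``B_w`` is a deterministic monotone function of the covariates: it
    decreases with gene density, increases with the recombination proxy, and
    contains a positive rho x gene-density interaction, mirroring the
    background-selection expectation that diversity is most reduced where
    recombination is low and coding density high. If covariates are not
    supplied they are generated as Gaussian random fields smoothed at
    ``b_autocorr_windows`` (per scaffold), which gives B its spatial
    autocorrelation.

    Returns ``(B, rho, gene_density)``, each of length ``config.n_windows``.
    """
    nw = config.n_windows
    if nw <= 0:
        raise ValueError("non-positive window count")
    if rho is None or gene_density is None:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        sigma = max(config.b_autocorr_windows, 1e-6)
        per_scaf = config.windows_per_scaffold
        raw_r = rng.standard_normal(nw)
        raw_g = rng.standard_normal(nw)
        sm_r = np.concatenate([
            gaussian_filter1d(raw_r[i * per_scaf:(i + 1) * per_scaf], sigma, mode="nearest")
            for i in range(config.n_scaffolds)
        ])
        sm_g = np.concatenate([
            gaussian_filter1d(raw_g[i * per_scaf:(i + 1) * per_scaf], sigma, mode="nearest")
            for i in range(config.n_scaffolds)
        ])
        if rho is None:
            rho = np.exp(sm_r)          # positive, lognormal-like
        if gene_density is None:
            gene_density = 1.0 / (1.0 + np.exp(-sm_g))   # in (0, 1)
    rho = np.asarray(rho, dtype=float)
    gene_density = np.asarray(gene_density, dtype=float)
    if rho.shape != (nw,) or gene_density.shape != (nw,):
        raise ValueError("covariate tracks must cover every window")

    if config.b_constant:
        b = np.full(nw, config.b_max)
        return b, rho, gene_density

    gn = _minmax(gene_density)
    rn = _minmax(rho)
    # hazard in [0, 1], monotone up in gene density and down in rho, with a
    # positive interaction term; max hazard at (g max, rho min)
    hazard = 0.35 * gn + 0.35 * (1.0 - rn) + 0.30 * gn * (1.0 - rn)
    b = config.b_max - (config.b_max - config.b_min) * hazard
    assert np.all(b > 0) and np.all(b <= 1.0)
    return b, rho, gene_density


# ---------------------------------------------------------------------------
# frequencies


def _ancestral_freqs(site_wid: np.ndarray, n_windows: int, grid_n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Ancestral derived-allele frequencies from the neutral spectrum.

    The spectrum is discretized as counts i = 1 .. 2N-1 in a pool of 2N
    chromosomes with P(i) proportional to 1/i; a sample of n alleles taken
    from this density has expected unfolded SFS proportional to 1/i, the
    neutral equilibrium. Within each window the density is sampled by
    systematic (stratified) quantiles, assigned to sites in random order:
    every window then carries essentially the same ancestral-frequency
    composition, so finite-window sampling of the spectrum does not
    masquerade as shared between-population landscape structure.
    """
    two_n = 2 * grid_n
    i = np.arange(1, two_n)
    w = 1.0 / i
    cdf = np.cumsum(w / w.sum())
    counts = np.bincount(site_wid, minlength=n_windows)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    within = np.arange(site_wid.size) - starts[site_wid]
    q = (within + 0.5) / counts[site_wid]
    vals = (np.searchsorted(cdf, q, side="left") + 1) / two_n
    # shuffle assignment within each window so frequency is independent of
    # position
    perm = np.lexsort((rng.random(site_wid.size), site_wid))
    anc = np.empty(site_wid.size)
    anc[perm] = vals
    return anc


def _resolve_tree(config: SimConfig) -> list[PopulationSpec]:
    """Topological order of nodes (parents before children)."""
    by_label = {p.label: p for p in config.populations}
    order: list[PopulationSpec] = []
    placed = {"root"}
    pending = list(config.populations)
    while pending:
        progressed = False
        for p in list(pending):
            if p.parent in placed:
                order.append(p)
                placed.add(p.label)
                pending.remove(p)
                progressed = True
        if not progressed:
            bad = ", ".join(p.label for p in pending)
            raise ValueError(f"unresolvable tree (cycle or missing parent): {bad}")
    return order


def simulate_frequencies(
    config: SimConfig,
    b_landscape: np.ndarray,
    site_wid: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, np.ndarray], pd.DataFrame, pd.DataFrame]:
    """Hierarchical Balding-Nichols allele frequencies for every node.

    Each node's frequency at a site in window w is Beta-distributed around
    its parent's frequency with drift F = 1 - exp(-t / B_w); planted
    contact-zone windows add ``divergence_boost`` to F for ``pop_a`` of the
    focal pair; gene-flow edges then mix sink frequencies toward the source.

    Returns (ancestral freqs, node->freq arrays, drift table, contact-window
    table).
    """
    anc = _ancestral_freqs(site_wid, config.n_windows, config.grid_n, rng)
    order = _resolve_tree(config)
    nw = config.n_windows

    # planted contact-zone windows, chosen before any drift draw
    contact_rows = []
    boost_by_pop: dict[str, np.ndarray] = {}
    for cz in config.contact_zones:
        wids = rng.choice(nw, size=cz.n_divergent_windows, replace=False)
        for wid in np.sort(wids):
            contact_rows.append(
                {"pair": f"{cz.pop_a}~{cz.pop_b}", "wid": int(wid), "boost": cz.divergence_boost}
            )
        extra = boost_by_pop.setdefault(cz.pop_a, np.zeros(nw))
        extra[np.sort(wids)] += cz.divergence_boost
    contact_df = pd.DataFrame(contact_rows, columns=["pair", "wid", "boost"])

    freqs: dict[str, np.ndarray] = {"root": anc}
    drift_cols: dict[str, np.ndarray] = {}
    for node in order:
        f_w = 1.0 - np.exp(-node.t / b_landscape)
        if node.label in boost_by_pop:
            f_w = np.minimum(f_w + boost_by_pop[node.label], 0.999)
        drift_cols[node.label] = f_w
        parent_p = freqs[node.parent]
        f_site = f_w[site_wid]
        p = parent_p.copy()
        drifting = f_site > 1e-12
        if np.any(drifting):
            pf = parent_p[drifting]
            lam = (1.0 - f_site[drifting]) / f_site[drifting]
            # Beta(p*lam, (1-p)*lam); degenerate parent frequencies stay fixed
            interior = (pf > 0) & (pf < 1)
            out = pf.copy()
            if np.any(interior):
                out[interior] = rng.beta(pf[interior] * lam[interior],
                                         (1.0 - pf[interior]) * lam[interior])
            p[drifting] = out
        freqs[node.label] = p

    for gf in config.gene_flow:
        if gf.source not in freqs or gf.sink not in freqs:
            raise ValueError(f"gene-flow edge references unknown population: {gf}")
        freqs[gf.sink] = (1.0 - gf.m) * freqs[gf.sink] + gf.m * freqs[gf.source]

    for label, p in freqs.items():
        if np.any(p < 0) or np.any(p > 1):
            raise AssertionError(f"frequency outside [0,1] for node {label}")

    drift_df = pd.DataFrame(drift_cols)
    drift_df.insert(0, "wid", np.arange(nw))
    return anc, freqs, drift_df, contact_df


# ---------------------------------------------------------------------------
# haplotypes / genotypes


def _copy_chain_haplotype(
    p: np.ndarray, refresh: np.ndarray, draws: np.ndarray
) -> np.ndarray:
    """One haplotype from the latent-quantile lag-1 copying chain.

    A latent uniform u persists from the previous site unless refreshed;
    the allele is 1 iff u < p_site. Marginals are exactly Bernoulli(p);
    persistence creates positive LD that decays geometrically with the
    number of intervening sites.
    """
    idx = np.where(refresh, np.arange(p.size), -1)
    np.maximum.accumulate(idx, out=idx)
    u = draws[idx]
    return (u < p).astype(np.uint8)


def emit_genotypes_and_haplotypes(
    config: SimConfig,
    sites: pd.DataFrame,
    freqs: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Sample phased haplotypes for every population.

    Genotypes are the sum of two independent haplotypes, i.e. Binomial(2, p)
    at the margin; sweeps are planted afterwards by
    :func:`_plant_sweeps` (called from :func:`simulate`).
    """
    n_sites = len(sites)
    scaf = sites["scaffold"].to_numpy()
    new_scaffold = np.empty(n_sites, dtype=bool)
    new_scaffold[0] = True
    new_scaffold[1:] = scaf[1:] != scaf[:-1]

    haplotypes: dict[str, np.ndarray] = {}
    for pop in config.populations:
        if pop.n_diploid == 0:
            continue
        p = freqs[pop.label]
        n_hap = 2 * pop.n_diploid
        hmat = np.empty((n_hap, n_sites), dtype=np.uint8)
        for h in range(n_hap):
            refresh = rng.random(n_sites) < config.ld_refresh_prob
            refresh |= new_scaffold
            draws = rng.random(n_sites)
            hmat[h] = _copy_chain_haplotype(p, refresh, draws)
        haplotypes[pop.label] = hmat
    return haplotypes


def _plant_sweeps(
    config: SimConfig,
    sites: pd.DataFrame,
    haplotypes: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    pos = sites["pos"].to_numpy()
    scaf = sites["scaffold"].to_numpy()
    for sw in config.sweeps:
        if sw.population not in haplotypes:
            raise ValueError(f"sweep in unknown population {sw.population}")
        centre = sw.window * config.window_size + config.window_size // 2
        on_scaf = np.flatnonzero(scaf == sw.scaffold)
        if on_scaf.size == 0:
            raise ValueError(f"sweep on empty scaffold {sw.scaffold}")
        core = on_scaf[np.argmin(np.abs(pos[on_scaf] - centre))]
        half = 0.5 * sw.strength * config.sweep_tract_bp
        tract = on_scaf[np.abs(pos[on_scaf] - pos[core]) <= half]
        hmat = haplotypes[sw.population]
        n_hap = hmat.shape[0]
        n_car = max(2, int(round(sw.carrier_fraction * n_hap)))
        carriers = rng.choice(n_hap, size=n_car, replace=False)
        template = hmat[carriers[0], tract].copy()
        for c in carriers:
            hmat[c, tract] = template
        hmat[:, core] = 0
        hmat[carriers, core] = 1
        rows.append({
            "population": sw.population, "scaffold": int(sw.scaffold),
            "pos": int(pos[core]), "wid": int(sites["wid"].iloc[core]),
            "strength": sw.strength, "n_carriers": n_car,
            "tract_start": int(pos[tract[0]]), "tract_end": int(pos[tract[-1]]),
        })
    return pd.DataFrame(rows, columns=[
        "population", "scaffold", "pos", "wid", "strength", "n_carriers",
        "tract_start", "tract_end",
    ])


# ---------------------------------------------------------------------------
# top level


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: landscape -> frequencies -> haplotypes.

    Sites monomorphic across the union of all sampled haplotypes are
    dropped (they would not appear in a variant catalogue).
    """
    rng = np.random.default_rng(config.seed)
    b, rho, gdens = build_linked_selection_landscape(config, rng=rng)

    nw = config.n_windows
    per_scaf = config.windows_per_scaffold
    wsize = config.window_size
    wid_all = np.arange(nw)
    windows = pd.DataFrame({
        "scaffold": wid_all // per_scaf,
        "start": (wid_all % per_scaf) * wsize,
        "end": (wid_all % per_scaf) * wsize + wsize,
        "wid": wid_all,
    })

    # diversity thinning: SNP count per window scales with B_w
    # (deterministic, so count noise does not add spurious shared structure)
    lam = config.snps_per_window * b / float(np.mean(b))
    n_per_window = np.maximum(np.round(lam).astype(int), 2)

    site_wid = np.repeat(wid_all, n_per_window)
    offsets = rng.integers(0, wsize, size=site_wid.size)
    pos = (site_wid % per_scaf) * wsize + offsets + 1      # 1-based in scaffold
    scaf = site_wid // per_scaf
    order = np.lexsort((pos, scaf))
    site_wid, pos, scaf = site_wid[order], pos[order], scaf[order]
    # drop duplicate positions within a scaffold
    keep = np.empty(pos.size, dtype=bool)
    keep[0] = True
    keep[1:] = (pos[1:] != pos[:-1]) | (scaf[1:] != scaf[:-1])
    site_wid, pos, scaf = site_wid[keep], pos[keep], scaf[keep]
    sites = pd.DataFrame({"scaffold": scaf, "pos": pos, "wid": site_wid})

    anc, freqs, drift_df, contact_df = simulate_frequencies(config, b, site_wid, rng)
    haplotypes = emit_genotypes_and_haplotypes(config, sites, freqs, rng)
    sweep_df = _plant_sweeps(config, sites, haplotypes, rng)

    # restrict to sites segregating in the pooled sample
    total = np.zeros(len(sites), dtype=np.int64)
    n_hap_total = 0
    for pop in config.populations:
        if pop.n_diploid == 0:
            continue
        total += haplotypes[pop.label].sum(axis=0, dtype=np.int64)
        n_hap_total += haplotypes[pop.label].shape[0]
    seg = (total > 0) & (total < n_hap_total)
    seg_idx = np.flatnonzero(seg)
    sites = sites.iloc[seg_idx].reset_index(drop=True)
    haplotypes = {k: v[:, seg_idx] for k, v in haplotypes.items()}
    pop_labels = {p.label for p in config.populations if p.n_diploid > 0}
    freqs = {k: v[seg_idx] for k, v in freqs.items() if k in pop_labels}
    if len(sweep_df):
        old_to_new = -np.ones(seg.size, dtype=np.int64)
        old_to_new[seg_idx] = np.arange(seg_idx.size)
        # core sites are always segregating (carriers derived, rest ancestral)

    # mask: a sub-interval in a random subset of windows
    mask_rows = []
    if config.mask_fraction > 0:
        n_masked = int(round(config.mask_fraction * nw))
        masked_wids = np.sort(rng.choice(nw, size=n_masked, replace=False))
        span = int(config.mask_span_fraction * wsize)
        for wid in masked_wids:
            w = windows.iloc[int(wid)]
            off = int(rng.integers(0, wsize - span)) if wsize > span else 0
            mask_rows.append({
                "scaffold": int(w["scaffold"]),
                "start": int(w["start"]) + off,
                "end": int(w["start"]) + off + span,
            })
    mask = pd.DataFrame(mask_rows, columns=["scaffold", "start", "end"])

    truth_windows = windows.copy()
    truth_windows["B"] = b
    truth_windows["rho"] = rho
    truth_windows["gene_density"] = gdens
    truth_windows["lam"] = lam
    truth = SimTruth(
        windows=truth_windows,
        drift=drift_df,
        contact_windows=contact_df,
        sweep_sites=sweep_df,
        gene_flow=pd.DataFrame(
            [dataclasses.asdict(g) for g in config.gene_flow],
            columns=["source", "sink", "m"],
        ),
    )
    return SimResult(
        config=config, windows=windows, sites=sites, freqs=freqs,
        haplotypes=haplotypes, truth=truth, mask=mask,
    )


# ---------------------------------------------------------------------------
# output


def _scaffold_name(i: int) -> str:
    return f"scaffold_{i}"


def write_sim_output(sim: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write VCF, mask BED, popmap TSV, covariate TSV, truth TSVs, config YAML.

    The VCF is 4.2, phased, with the ancestral allele in ``INFO/AA`` (the
    REF allele is always ancestral by construction). The BED mask is
    0-based half-open. Paths are returned keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = sim.config
    paths: dict[str, Path] = {}

    sample_names: list[str] = []
    sample_pop: list[tuple[str, str]] = []
    for pop in cfg.populations:
        for i in range(pop.n_diploid):
            name = f"{pop.label}_{i}"
            sample_names.append(name)
            sample_pop.append((name, pop.label))

    scaffold_len = cfg.windows_per_scaffold * cfg.window_size
    vcf_path = outdir / "sim.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=crowscape-simulate\n")
        for s in range(cfg.n_scaffolds):
            fh.write(f"##contig=<ID={_scaffold_name(s)},length={scaffold_len}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        scaf = sim.sites["scaffold"].to_numpy()
        pos = sim.sites["pos"].to_numpy()
        hap_cols = [sim.haplotypes[p.label] for p in cfg.populations
                    if p.n_diploid > 0]
        for j in range(len(sim.sites)):
            gts = []
            for hmat in hap_cols:
                col = hmat[:, j]
                gts.extend(f"{col[k]}|{col[k + 1]}" for k in range(0, col.size, 2))
            fh.write(f"{_scaffold_name(scaf[j])}\t{pos[j]}\t.\tA\tT\t.\tPASS\tAA=A\tGT\t"
                     + "\t".join(gts) + "\n")
    paths["vcf"] = vcf_path

    bed_path = outdir / "mask.bed"
    with open(bed_path, "w") as fh:
        for _, row in sim.mask.iterrows():
            fh.write(f"{_scaffold_name(int(row['scaffold']))}\t{int(row['start'])}\t{int(row['end'])}\n")
    paths["mask"] = bed_path

    pm_path = outdir / "popmap.tsv"
    by_label = {p.label: p for p in cfg.populations}
    with open(pm_path, "w") as fh:
        fh.write("individual\tpopulation\tlat\tlon\n")
        for name, label in sample_pop:
            p = by_label[label]
            fh.write(f"{name}\t{label}\t{p.lat}\t{p.lon}\n")
    paths["popmap"] = pm_path

    cov_path = outdir / "covariates.tsv"
    cov = sim.truth.windows[["scaffold", "start", "end", "rho", "gene_density"]].copy()
    cov["scaffold"] = cov["scaffold"].map(_scaffold_name)
    cov.to_csv(cov_path, sep="\t", index=False)
    paths["covariates"] = cov_path

    tw = sim.truth.windows.copy()
    tw["scaffold"] = tw["scaffold"].map(_scaffold_name)
    tw.to_csv(outdir / "truth_windows.tsv", sep="\t", index=False)
    sim.truth.drift.to_csv(outdir / "truth_drift.tsv", sep="\t", index=False)
    sim.truth.contact_windows.to_csv(outdir / "truth_contact_windows.tsv", sep="\t", index=False)
    sw = sim.truth.sweep_sites.copy()
    if len(sw):
        sw["scaffold"] = sw["scaffold"].map(_scaffold_name)
    sw.to_csv(outdir / "truth_sweeps.tsv", sep="\t", index=False)
    sim.truth.gene_flow.to_csv(outdir / "truth_gene_flow.tsv", sep="\t", index=False)
    paths["truth_windows"] = outdir / "truth_windows.tsv"

    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(sim.config.to_dict(), fh, sort_keys=False)
    paths["config"] = outdir / "sim_config.yaml"
    return paths


def to_variant_matrix(sim: SimResult):
    """Adapt a :class:`SimResult` to the analysis-side data model without a
    VCF round trip: returns ``(VariantMatrix, WindowIndex, PopulationMap)``
    identical to loading the written VCF/BED/popmap."""
    from .variantio import PopulationMap, VariantMatrix, WindowIndex

    cfg = sim.config
    samples, rows = [], []
    for p in cfg.populations:
        for i in range(p.n_diploid):
            samples.append(f"{p.label}_{i}")
            rows.append({"individual": f"{p.label}_{i}", "population": p.label,
                         "lat": p.lat, "lon": p.lon})
    popmap = PopulationMap(pd.DataFrame(rows))

    n_sites = len(sim.sites)
    geno = np.empty((n_sites, len(samples)), dtype=np.int8)
    col = 0
    for p in cfg.populations:
        if p.n_diploid == 0:
            continue
        h = sim.haplotypes[p.label]
        g = (h[0::2] + h[1::2]).T
        geno[:, col:col + p.n_diploid] = g
        col += p.n_diploid

    scaf_names = np.array([_scaffold_name(s) for s in sim.sites["scaffold"]],
                          dtype=object)
    n = n_sites
    vm = VariantMatrix(
        scaffold=scaf_names,
        pos=sim.sites["pos"].to_numpy(),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["T"] * n, dtype=object),
        ancestral=np.array(["A"] * n, dtype=object),
        genotypes=geno,
        samples=samples,
        popmap=popmap,
        scaffold_lengths={_scaffold_name(s): cfg.windows_per_scaffold * cfg.window_size
                          for s in range(cfg.n_scaffolds)},
    )

    wdf = sim.windows.copy()
    wdf["scaffold"] = wdf["scaffold"].map(_scaffold_name)
    callable_bp = np.full(len(wdf), float(cfg.window_size))
    for _, m in sim.mask.iterrows():
        wid0 = int(m["scaffold"]) * cfg.windows_per_scaffold
        w_lo = wid0 + int(m["start"]) // cfg.window_size
        # the generator masks a sub-interval within a single window
        callable_bp[w_lo] -= int(m["end"]) - int(m["start"])
    wdf["callable"] = callable_bp
    wdf["short"] = False
    windex = WindowIndex(windows=wdf, site_wid=sim.sites["wid"].to_numpy(),
                         window_size=cfg.window_size)
    return vm, windex, popmap


def hapset_for(sim: SimResult, population: str):
    """A :class:`~crowscape.haplostats.HaplotypeSet` for one population."""
    from .haplostats import HaplotypeSet

    scaf = np.array([_scaffold_name(s) for s in sim.sites["scaffold"]], dtype=object)
    return HaplotypeSet(sim.haplotypes[population], scaf,
                        sim.sites["pos"].to_numpy())


# ---------------------------------------------------------------------------
# canned scenarios


def default_scenario(
    seed: int = 0,
    *,
    b_constant: bool = False,
    n_contact_windows: int = 20,
    divergence_boost: float = 1.0,
    sweeps: list[SweepSpec] | None = None,
    n_diploid: int = 6,
    n_scaffolds: int = 20,
    windows_per_scaffold: int = 100,
    snps_per_window: float = 60.0,
) -> SimConfig:
    """The study-like scenario: one focal contact-zone pair plus five
    allopatric, phenotype-matched control pairs spanning a gradient of
    genome-wide differentiation, all sharing one linked-selection landscape.

    Branch lengths give pairwise drift spanning roughly the F_ST range
    0.02-0.45 across control pairs, with the focal pair at the shallow end
    (a recent radiation). Coordinates spread the populations across a
    continental scale so isolation-by-distance analyses have geography to
    work with.
    """
    t_controls = [0.01, 0.025, 0.05, 0.1, 0.3]
    pops = [
        PopulationSpec("focal_a", n_diploid, 0.05, lat=46.0, lon=9.0),
        PopulationSpec("focal_b", n_diploid, 0.05, lat=48.0, lon=14.0),
    ]
    for i, t in enumerate(t_controls, start=1):
        pops.append(PopulationSpec(f"ctrl{i}_a", n_diploid, t,
                                   lat=40.0 + 2.5 * i, lon=20.0 + 12.0 * i))
        pops.append(PopulationSpec(f"ctrl{i}_b", n_diploid, t,
                                   lat=42.0 + 2.5 * i, lon=26.0 + 12.0 * i))
    czs = []
    if n_contact_windows > 0:
        czs = [ContactZoneSpec("focal_a", "focal_b", n_contact_windows, divergence_boost)]
    return SimConfig(
        seed=seed,
        n_scaffolds=n_scaffolds,
        windows_per_scaffold=windows_per_scaffold,
        snps_per_window=snps_per_window,
        populations=pops,
        b_constant=b_constant,
        contact_zones=czs,
        sweeps=sweeps or [],
    )
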