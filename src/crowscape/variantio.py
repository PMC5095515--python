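"""Variant input/output: VCF + mask BED + popmap into the internal model.

Coordinate conventions follow each format's standard: VCF positions are
1-based, BED intervals and all internal window coordinates are 0-based
half-open. A site at 1-based position P falls in window
``floor((P - 1) / window_size)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationMap",
    "VariantMatrix",
    "WindowIndex",
    "read_popmap",
    "read_mask",
    "load_variants",
    "load_haplotypes",
    "site_coverage_filter",
    "assign_windows",
    "write_vcf",
    "read_covariates",
]

MISSING = -1


@dataclass
class PopulationMap:
    """individual -> population, with optional sampling coordinates."""

    table: pd.DataFrame  # individual, population, lat, lon

    def __post_init__(self) -> None:
        required = {"individual", "population"}
        if not required.issubset(self.table.columns):
            raise ValueError("popmap needs 'individual' and 'population' columns")
        if self.table["individual"].duplicated().any():
            raise ValueError("duplicate individuals in popmap")

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population"]))

    def individuals(self, population: str) -> list[str]:
        sel = self.table[self.table["population"] == population]
        if sel.empty:
            raise KeyError(f"unknown population {population!r}")
        return list(sel["individual"])

    def population_of(self, individual: str) -> str:
        sel = self.table[self.table["individual"] == individual]
        if sel.empty:
            raise KeyError(f"individual {individual!r} not in popmap")
        return sel["population"].iloc[0]

    def coordinates(self) -> pd.DataFrame:
        """One (lat, lon) per population: the sample-size-weighted mean of
        its individuals' sampling locations (pooled locations average)."""
        if not {"lat", "lon"}.issubset(self.table.columns):
            raise ValueError("popmap has no lat/lon columns")
        return self.table.groupby("population", sort=False)[["lat", "lon"]].mean()


def read_popmap(path: str | Path) -> PopulationMap:
    return PopulationMap(pd.read_csv(path, sep="\t"))


@dataclass
class VariantMatrix:
    """Biallelic SNP genotypes as alternate-allele dosage.

    ``genotypes`` is (n_sites, n_samples) int8 in {0, 1, 2, MISSING};
    ``ancestral`` holds the ancestral base or '' where unknown.
    """

    scaffold: np.ndarray          # str per site
    pos: np.ndarray               # 1-based int per site
    ref: np.ndarray
    alt: np.ndarray
    ancestral: np.ndarray
    genotypes: np.ndarray
    samples: list[str]
    popmap: PopulationMap
    scaffold_lengths: dict[str, int] = field(default_factory=dict)
    filter_log: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for s in np.unique(self.scaffold):
            p = self.pos[self.scaffold == s]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {s}")

    @property
    def n_sites(self) -> int:
        return self.pos.size

    def sample_columns(self, population: str) -> np.ndarray:
        inds = set(self.popmap.individuals(population))
        return np.array([i for i, s in enumerate(self.samples) if s in inds], dtype=int)

    def derived_polarized(self) -> tuple[np.ndarray, np.ndarray]:
        """(polarizable mask, derived-dosage matrix).

        Where the ancestral allele equals ALT the dosage is flipped so the
        matrix counts derived alleles; sites with no valid ancestral call
        are masked out.
        """
        anc_is_ref = self.ancestral == self.ref
        anc_is_alt = self.ancestral == self.alt
        ok = anc_is_ref | anc_is_alt
        g = self.genotypes.copy()
        flip = np.flatnonzero(anc_is_alt)
        sub = g[flip]
        miss = sub == MISSING
        sub = 2 - sub
        sub[miss] = MISSING
        g[flip] = sub
        return ok, g

    def allele_counts(self, population: str, genotypes: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
        """(alt/derived allele count, called allele count) per site."""
        cols = self.sample_columns(population)
        g = (self.genotypes if genotypes is None else genotypes)[:, cols]
        called = g != MISSING
        ac = np.where(called, g, 0).sum(axis=1)
        an = 2 * called.sum(axis=1)
        return ac, an


def read_mask(path: str | Path) -> dict[str, IntervalTree]:
    """BED mask (0-based half-open) as per-scaffold interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            start, end = int(f[1]), int(f[2])
            if end > start:
                trees.setdefault(f[0], IntervalTree()).addi(start, end)
    return trees


def load_variants(
    vcf_path: str | Path,
    mask_bed: str | Path | None = None,
    popmap: PopulationMap | str | Path | None = None,
    exclude_scaffolds: set[str] | None = None,
) -> VariantMatrix:
    """Read a VCF into a :class:`VariantMatrix`, applying the site filters:
    only biallelic SNPs, sites inside mask intervals removed, optional
    scaffold exclusion (e.g. sex-linked scaffolds).

    Every sample in the VCF must appear in the popmap, otherwise this is a
    hard error.
    """
    if popmap is None:
        raise ValueError("a population map is required")
    if not isinstance(popmap, PopulationMap):
        popmap = read_popmap(popmap)
    mask = read_mask(mask_bed) if mask_bed else {}
    exclude_scaffolds = exclude_scaffolds or set()

    vcf = VCF(str(vcf_path), gts012=False)
    known = set(popmap.table["individual"])
    orphans = [s for s in vcf.samples if s not in known]
    if orphans:
        raise ValueError(f"individuals in VCF absent from popmap: {orphans}")
    samples = list(vcf.samples)
    n = len(samples)

    scaffold_lengths: dict[str, int] = {}
    for s in vcf.seqnames:
        try:
            scaffold_lengths[s] = vcf.seqlens[vcf.seqnames.index(s)]
        except (AttributeError, IndexError):   # header without lengths
            pass

    scaf, pos, ref, alt, anc = [], [], [], [], []
    geno_rows = []
    removed = {"masked": {}, "not_biallelic_snp": {}, "excluded_scaffold": {}}

    def bump(reason: str, chrom: str) -> None:
        removed[reason][chrom] = removed[reason].get(chrom, 0) + 1

    for v in vcf:
        chrom = v.CHROM
        if chrom in exclude_scaffolds:
            bump("excluded_scaffold", chrom)
            continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            bump("not_biallelic_snp", chrom)
            continue
        tree = mask.get(chrom)
        if tree is not None and tree.overlaps(v.POS - 1):
            bump("masked", chrom)
            continue
        row = np.full(n, MISSING, dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a, b = g[0], g[1]
            if a >= 0 and b >= 0:
                row[i] = a + b
        geno_rows.append(row)
        scaf.append(chrom)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        aa = v.INFO.get("AA")
        anc.append(aa.upper() if isinstance(aa, str) else "")

    log_rows = [
        {"scaffold": c, "reason": r, "n_removed": k}
        for r, d in removed.items() for c, k in sorted(d.items())
    ]
    flog = pd.DataFrame(log_rows, columns=["scaffold", "reason", "n_removed"])
    for _, row in flog.iterrows():
        logger.info("removed %d sites on %s (%s)", row.n_removed, row.scaffold, row.reason)

    return VariantMatrix(
        scaffold=np.array(scaf, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        ancestral=np.array(anc, dtype=object),
        genotypes=(np.vstack(geno_rows) if geno_rows
                   else np.empty((0, n), dtype=np.int8)),
        samples=samples,
        popmap=popmap,
        scaffold_lengths=scaffold_lengths,
        filter_log=flog,
    )


def load_haplotypes(
    vcf_path: str | Path,
    popmap: PopulationMap,
    mask_bed: str | Path | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Phased haplotypes per population from a phased VCF.

    Returns ``(pop -> (2n, n_sites) uint8 derived-allele matrix, scaffold
    array, 1-based positions)``. Alleles are polarized to the ancestral
    state from INFO/AA; sites without a usable ancestral call, with any
    unphased or missing genotype, or failing the biallelic-SNP filter are
    dropped. Unphased genotypes in retained heterozygous sites are a hard
    error: haplotype statistics are meaningless on unphased data.
    """
    mask = read_mask(mask_bed) if mask_bed else {}
    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    known = set(popmap.table["individual"])
    orphans = [s for s in samples if s not in known]
    if orphans:
        raise ValueError(f"individuals in VCF absent from popmap: {orphans}")

    scaf, pos = [], []
    hap_rows = []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        tree = mask.get(v.CHROM)
        if tree is not None and tree.overlaps(v.POS - 1):
            continue
        aa = v.INFO.get("AA")
        aa = aa.upper() if isinstance(aa, str) else ""
        if aa == v.REF:
            flip = False
        elif aa == v.ALT[0]:
            flip = True
        else:
            continue
        row = np.empty(2 * len(samples), dtype=np.uint8)
        ok = True
        for i, g in enumerate(v.genotypes):
            a, b, phased = g[0], g[1], g[2]
            if a < 0 or b < 0:
                ok = False
                break
            if a != b and not phased:
                raise ValueError(
                    f"unphased heterozygote at {v.CHROM}:{v.POS} sample {samples[i]}"
                )
            row[2 * i], row[2 * i + 1] = a, b
        if not ok:
            continue
        if flip:
            row = 1 - row
        hap_rows.append(row)
        scaf.append(v.CHROM)
        pos.append(v.POS)

    full = np.vstack(hap_rows).T if hap_rows else np.empty((2 * len(samples), 0), np.uint8)
    out: dict[str, np.ndarray] = {}
    for popl in popmap.populations:
        inds = set(popmap.individuals(popl))
        cols = [i for i, s in enumerate(samples) if s in inds]
        hap_idx = np.array([[2 * i, 2 * i + 1] for i in cols]).ravel()
        out[popl] = full[hap_idx]
    return out, np.array(scaf, dtype=object), np.array(pos, dtype=np.int64)


def site_coverage_filter(vm: VariantMatrix, pop_a: str, pop_b: str) -> np.ndarray:
    """Pair-specific boolean mask of sites where each population has
    genotype calls for at least 50% of its individuals (inclusive)."""
    keep = np.ones(vm.n_sites, dtype=bool)
    for popl in (pop_a, pop_b):
        cols = vm.sample_columns(popl)
        if cols.size == 0:
            raise ValueError(f"population {popl!r} has no samples in the VCF")
        called = (vm.genotypes[:, cols] != MISSING).sum(axis=1)
        keep &= called * 2 >= cols.size
    return keep


@dataclass
class WindowIndex:
    """Non-overlapping windows tiling each scaffold.

    ``windows`` has one row per window (scaffold, start, end, wid,
    callable, short); ``callable`` is the unmasked span in bases, used to
    normalize D_xy. ``site_wid`` maps each site of the associated
    VariantMatrix to its window id (global, contiguous).
    """

    windows: pd.DataFrame
    site_wid: np.ndarray
    window_size: int

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def assign_windows(
    vm: VariantMatrix,
    window_size: int,
    mask_bed: str | Path | None = None,
) -> WindowIndex:
    """Tile every scaffold with non-overlapping windows and map sites.

    Scaffold lengths come from the VCF header where available, otherwise
    from the last observed site. Trailing short windows are kept and
    flagged ``short``. Callable span per window is the window length minus
    any masked overlap.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    mask = read_mask(mask_bed) if mask_bed else {}

    scaffolds = list(dict.fromkeys(vm.scaffold))
    rows = []
    wid0: dict[str, int] = {}
    wid = 0
    for s in scaffolds:
        length = vm.scaffold_lengths.get(s)
        if length is None:
            length = int(vm.pos[vm.scaffold == s].max())
        wid0[s] = wid
        start = 0
        while start < length:
            end = min(start + window_size, length)
            masked = 0
            tree = mask.get(s)
            if tree is not None:
                for iv in tree.overlap(start, end):
                    masked += min(iv.end, end) - max(iv.begin, start)
            rows.append({
                "scaffold": s, "start": start, "end": end, "wid": wid,
                "callable": (end - start) - masked,
                "short": end - start < window_size,
            })
            wid += 1
            start += window_size
    windows = pd.DataFrame(rows)
    offsets = np.array([wid0[s] for s in vm.scaffold])
    site_wid = offsets + (vm.pos - 1) // window_size
    return WindowIndex(windows=windows, site_wid=site_wid, window_size=window_size)


def write_vcf(vm: VariantMatrix, path: str | Path) -> None:
    """Write the matrix back out as an (unphased) VCF 4.2 text file."""
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for s, length in vm.scaffold_lengths.items():
            fh.write(f"##contig=<ID={s},length={length}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vm.samples) + "\n")
        for j in range(vm.n_sites):
            info = f"AA={vm.ancestral[j]}" if vm.ancestral[j] else "."
            gts = "\t".join(gt_of[int(g)] for g in vm.genotypes[j])
            fh.write(f"{vm.scaffold[j]}\t{vm.pos[j]}\t.\t{vm.ref[j]}\t{vm.alt[j]}"
                     f"\t.\tPASS\t{info}\tGT\t{gts}\n")


def read_covariates(path: str | Path, window_index: WindowIndex) -> pd.DataFrame:
    """Per-window covariate TSV keyed by (scaffold, start), aligned to the
    window index; windows without a covariate row get NaN."""
    cov = pd.read_csv(path, sep="\t")
    merged = window_index.windows.merge(cov, on=["scaffold", "start"],
                                        how="left", suffixes=("", "_cov"))
    return merged
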