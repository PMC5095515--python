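"""Per-window diversity and differentiation statistics.

All windowed statistics share one convention: a window with no usable site
carries NaN (explicitly missing), never a silent zero. Site-frequency-
spectrum statistics assume a constant number of sampled alleles within a
window; because missing genotypes make the called-allele count vary by
site, each window uses its modal called-allele count and excludes the
(counted, logged) sites that deviate from it.

The Weir-Cockerham F_ST follows the 1984 two-level variance-component
estimator (diploid, observed heterozygosity, unequal sample sizes);
windowed values are the ratio of summed components sum(a)/sum(a+b+c).
Negative window estimates are reported as computed and only clamped inside
the PBS logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variantio import MISSING, VariantMatrix, WindowIndex, site_coverage_filter

logger = logging.getLogger(__name__)

__all__ = [
    "WindowTrack",
    "unfolded_sfs",
    "diversity_stats",
    "window_r2",
    "wc_fst_per_site",
    "window_fst",
    "pair_window_fst",
    "dxy",
    "pbs",
    "abba_baba",
]


@dataclass
class WindowTrack:
    """One statistic, one population/pair/trio, one value per window."""

    statistic: str
    label: str
    values: np.ndarray          # NaN = missing
    n_sites: np.ndarray | None = None

    def to_frame(self, windows: pd.DataFrame) -> pd.DataFrame:
        out = windows[["scaffold", "start", "end", "wid"]].copy()
        out["statistic"] = self.statistic
        out["label"] = self.label
        out["value"] = self.values
        out["n_sites"] = self.n_sites if self.n_sites is not None else np.nan
        return out


# ---------------------------------------------------------------------------
# SFS statistics


def _harmonics(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i**2))


def unfolded_sfs(vm: VariantMatrix, population: str) -> np.ndarray:
    """Unfolded (derived-allele) site frequency spectrum.

    Bin i counts sites with i derived alleles among called alleles,
    i = 1 .. 2n-1 where n is the population's diploid sample size. Sites
    with missing or unusable ancestral state are excluded, as are sites
    where the derived count reaches 0 or the called total (not segregating
    in this population).
    """
    ok, derived = vm.derived_polarized()
    if not np.any(ok):
        logger.warning("no polarizable sites for population %s", population)
    cols = vm.sample_columns(population)
    n_bins = 2 * cols.size
    g = derived[:, cols]
    called = g != MISSING
    dac = np.where(called, g, 0).sum(axis=1)
    spectrum = np.zeros(n_bins - 1, dtype=np.int64)
    use = ok & (dac > 0) & (dac < 2 * called.sum(axis=1))
    for i in dac[use]:
        spectrum[i - 1] += 1
    return spectrum


def diversity_stats(
    vm: VariantMatrix,
    population: str,
    windex: WindowIndex,
    min_alleles: int = 4,
) -> pd.DataFrame:
    """Per-window pi, Watterson's theta, Tajima's D, Fay & Wu's H and
    Fu & Li's D for one population.

    pi and theta_W are per callable site (the window's unmasked span);
    H is the per-window sum theta_pi - theta_H on the polarized spectrum.
    Windows with no segregating site have pi = theta_W = 0 and missing
    D/H; windows whose modal called-allele count is below ``min_alleles``
    are entirely missing.
    """
    cols = vm.sample_columns(population)
    g = vm.genotypes[:, cols]
    called_alleles = 2 * (g != MISSING).sum(axis=1)
    ac = np.where(g != MISSING, g, 0).sum(axis=1)
    ok_anc, derived_all = vm.derived_polarized()
    dac = np.where(derived_all[:, cols] != MISSING, derived_all[:, cols], 0).sum(axis=1)

    nw = windex.n_windows
    out = {k: np.full(nw, np.nan) for k in
           ("pi", "theta_w", "tajimas_d", "fay_wu_h", "fu_li_d")}
    n_seg = np.zeros(nw, dtype=np.int64)
    n_used = np.zeros(nw, dtype=np.int64)
    n_skipped = np.zeros(nw, dtype=np.int64)

    callable_bp = windex.windows["callable"].to_numpy(dtype=float)
    site_wid = windex.site_wid
    for wid in range(nw):
        idx = np.flatnonzero(site_wid == wid)
        if idx.size == 0 or callable_bp[wid] <= 0:
            if callable_bp[wid] > 0:
                for k in ("pi", "theta_w"):
                    out[k][wid] = 0.0
            continue
        counts = called_alleles[idx]
        vals, freq = np.unique(counts[counts > 0], return_counts=True)
        if vals.size == 0:
            continue
        n = int(vals[np.argmax(freq)])          # modal called-allele count
        use = idx[counts == n]
        n_skipped[wid] = idx.size - use.size
        n_used[wid] = use.size
        if n < min_alleles:
            continue
        j = ac[use]
        seg = (j > 0) & (j < n)
        s = int(np.count_nonzero(seg))
        n_seg[wid] = s
        a1, a2 = _harmonics(n)
        pi_sum = float(np.sum(2.0 * j[seg] * (n - j[seg])) / (n * (n - 1)))
        out["pi"][wid] = pi_sum / callable_bp[wid]
        out["theta_w"][wid] = s / a1 / callable_bp[wid]
        if s > 0:
            b1 = (n + 1) / (3.0 * (n - 1))
            b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
            c1 = b1 - 1.0 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
            e1 = c1 / a1
            e2 = c2 / (a1**2 + a2)
            var = e1 * s + e2 * s * (s - 1)
            if var > 0:
                out["tajimas_d"][wid] = (pi_sum - s / a1) / np.sqrt(var)

        # unfolded statistics on the polarizable subset
        pol = use[ok_anc[use]]
        if pol.size and n > 2:
            i_d = dac[pol]
            segp = (i_d > 0) & (i_d < n)
            i_d = i_d[segp]
            eta = i_d.size
            if eta > 0:
                theta_pi = float(np.sum(2.0 * i_d * (n - i_d)) / (n * (n - 1)))
                theta_h = float(np.sum(2.0 * i_d.astype(float) ** 2) / (n * (n - 1)))
                out["fay_wu_h"][wid] = theta_pi - theta_h
                eta_s = int(np.count_nonzero(i_d == 1))
                c_n = 2.0 * (n * a1 - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
                v_d = 1.0 + (a1**2 / (a2 + a1**2)) * (c_n - (n + 1) / (n - 1.0))
                u_d = a1 - 1.0 - v_d
                var = u_d * eta + v_d * eta**2
                if var > 0:
                    out["fu_li_d"][wid] = (eta - a1 * eta_s) / np.sqrt(var)

    res = windex.windows[["scaffold", "start", "end", "wid"]].copy()
    for k, v in out.items():
        res[k] = v
    res["n_segregating"] = n_seg
    res["n_sites_used"] = n_used
    res["n_sites_skipped"] = n_skipped
    res["n_callable"] = callable_bp
    total_skipped = int(n_skipped.sum())
    if total_skipped:
        logger.info("%s: %d sites deviated from the modal allele count and "
                    "were excluded from SFS statistics", population, total_skipped)
    return res


# ---------------------------------------------------------------------------
# linkage disequilibrium


def window_r2(
    haplotypes: np.ndarray,
    site_wid: np.ndarray,
    windows: pd.DataFrame,
    window_size: int,
    maf_min: float = 0.1,
) -> np.ndarray:
    """Mean haplotype r^2 over all pairwise SNP combinations per window.

    Only SNPs with minor allele frequency strictly above ``maf_min`` enter;
    windows with fewer than two qualifying SNPs are missing, as are all
    windows on scaffolds shorter than the window size (their physical span
    is not comparable).
    """
    freq = haplotypes.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    qual = maf > maf_min

    scaffold_len = windows.groupby("scaffold")["end"].max()
    short_scaffold = set(scaffold_len[scaffold_len < window_size].index)

    nw = len(windows)
    out = np.full(nw, np.nan)
    for wid in range(nw):
        if windows["scaffold"].iloc[wid] in short_scaffold:
            continue
        idx = np.flatnonzero((site_wid == wid) & qual)
        if idx.size < 2:
            continue
        x = haplotypes[:, idx].astype(float)
        r = np.corrcoef(x, rowvar=False)
        iu = np.triu_indices(idx.size, k=1)
        out[wid] = float(np.nanmean(r[iu] ** 2))
    return out


# ---------------------------------------------------------------------------
# F statistics


def wc_fst_per_site(
    vm: VariantMatrix,
    pop_a: str,
    pop_b: str,
    site_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Weir-Cockerham (1984) per-site variance components for one pair.

    Returns a DataFrame with per-site components ``a`` (among populations),
    ``b`` (among individuals within populations), ``c`` (within
    individuals) and a ``used`` flag; sites monomorphic across both
    populations, or failing the pair coverage filter, are excluded.
    """
    if site_mask is None:
        site_mask = site_coverage_filter(vm, pop_a, pop_b)

    n_i, p_i, h_i = [], [], []
    for popl in (pop_a, pop_b):
        colsp = vm.sample_columns(popl)
        g = vm.genotypes[:, colsp]
        called = g != MISSING
        n = called.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, g, 0).sum(axis=1) / (2.0 * n)
            h = (g == 1).sum(axis=1) / n
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n1, n2 = n_i
    p1, p2 = p_i
    h1, h2 = h_i

    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
                           / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                     - hbar * (2 * nbar - 1) / (4.0 * nbar))
        c = hbar / 2.0

    poly = (pbar > 0) & (pbar < 1)
    used = site_mask & poly & (nbar > 1) & np.isfinite(a)
    return pd.DataFrame({"a": a, "b": b, "c": c, "used": used})


def window_fst(components: pd.DataFrame, site_wid: np.ndarray, n_windows: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Windowed F_ST as the ratio of summed variance components.

    Returns (per-window F_ST with NaN where no site was usable, per-window
    usable-site count).
    """
    used = components["used"].to_numpy()
    a = np.where(used, components["a"].to_numpy(), 0.0)
    tot = np.where(used, (components["a"] + components["b"] + components["c"]).to_numpy(), 0.0)
    sum_a = np.bincount(site_wid, weights=a, minlength=n_windows)
    sum_t = np.bincount(site_wid, weights=tot, minlength=n_windows)
    n_sites = np.bincount(site_wid, weights=used.astype(float), minlength=n_windows)
    out = np.full(n_windows, np.nan)
    ok = (n_sites > 0) & (sum_t != 0)
    out[ok] = sum_a[ok] / sum_t[ok]
    return out, n_sites.astype(np.int64)


def pair_window_fst(vm: VariantMatrix, pop_a: str, pop_b: str, windex: WindowIndex
                    ) -> WindowTrack:
    comp = wc_fst_per_site(vm, pop_a, pop_b)
    vals, n_sites = window_fst(comp, windex.site_wid, windex.n_windows)
    return WindowTrack("fst", f"{pop_a}~{pop_b}", vals, n_sites)


# ---------------------------------------------------------------------------
# divergence


def dxy(
    vm: VariantMatrix,
    pop_a: str,
    pop_b: str,
    windex: WindowIndex,
    site_mask: np.ndarray | None = None,
) -> WindowTrack:
    """Average pairwise nucleotide divergence per callable site.

    Per site the contribution is p_A(1-p_B) + p_B(1-p_A); the window sum is
    divided by the window's callable span, in which monomorphic callable
    sites implicitly contribute zero. Windows with zero callable span are
    missing.
    """
    if site_mask is None:
        site_mask = site_coverage_filter(vm, pop_a, pop_b)
    ac_a, an_a = vm.allele_counts(pop_a)
    ac_b, an_b = vm.allele_counts(pop_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = ac_a / an_a
        pb = ac_b / an_b
    contrib = pa * (1 - pb) + pb * (1 - pa)
    usable = site_mask & np.isfinite(contrib)
    nw = windex.n_windows
    num = np.bincount(windex.site_wid, weights=np.where(usable, contrib, 0.0),
                      minlength=nw)
    callable_bp = windex.windows["callable"].to_numpy(dtype=float)
    vals = np.full(nw, np.nan)
    ok = callable_bp > 0
    vals[ok] = num[ok] / callable_bp[ok]
    n_sites = np.bincount(windex.site_wid, weights=usable.astype(float), minlength=nw)
    return WindowTrack("dxy", f"{pop_a}~{pop_b}", vals, n_sites.astype(np.int64))


# ---------------------------------------------------------------------------
# population branch statistic


def pbs(fst_12: np.ndarray, fst_13: np.ndarray, fst_23: np.ndarray) -> np.ndarray:
    """Population branch statistic for population 1.

    PBS_1 = [-ln(1-F12) - ln(1-F13) + ln(1-F23)] / 2, with every F clamped
    to [0, 1-1e-9] before the log. Missing whenever any input is missing.
    """
    tracks = [np.asarray(t, dtype=float) for t in (fst_12, fst_13, fst_23)]
    if not (tracks[0].shape == tracks[1].shape == tracks[2].shape):
        raise ValueError("PBS inputs must share one window index")
    t12, t13, t23 = (-np.log(1.0 - np.clip(t, 0.0, 1.0 - 1e-9)) for t in tracks)
    return (t12 + t13 - t23) / 2.0


# ---------------------------------------------------------------------------
# ABBA-BABA


@dataclass
class DStatResult:
    d: float
    z: float
    n_abba: float
    n_baba: float
    n_blocks: int
    significant: bool

    def __repr__(self) -> str:  # pragma: no cover
        return (f"DStatResult(d={self.d:.4f}, z={self.z:.2f}, "
                f"significant={self.significant})")


def abba_baba(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    block_id: np.ndarray,
) -> DStatResult:
    """Patterson's D from derived-allele frequencies in P1, P2, P3.

    The outgroup is the ancestral state (derived frequency 0), so
    ABBA = (1-p1) p2 p3 and BABA = p1 (1-p2) p3 summed over sites;
    D = (ABBA - BABA) / (ABBA + BABA). The Z score comes from a delete-one
    block jackknife over ``block_id`` (contiguous genomic blocks);
    |Z| >= 3 is flagged significant. With haploid single-individual input
    (frequencies in {0, 1}) this reduces to the site-pattern count form.
    """
    p1, p2, p3 = (np.asarray(x, dtype=float) for x in (p1, p2, p3))
    abba = (1 - p1) * p2 * p3
    baba = p1 * (1 - p2) * p3
    tot_a, tot_b = float(abba.sum()), float(baba.sum())
    denom = tot_a + tot_b
    if denom == 0:
        return DStatResult(np.nan, np.nan, 0.0, 0.0, 0, False)
    d = (tot_a - tot_b) / denom

    blocks = np.unique(block_id)
    d_jack = []
    for blk in blocks:
        keep = block_id != blk
        a, b = abba[keep].sum(), baba[keep].sum()
        if a + b > 0:
            d_jack.append((a - b) / (a + b))
    d_jack = np.asarray(d_jack)
    nb = d_jack.size
    if nb < 2:
        return DStatResult(d, np.nan, tot_a, tot_b, nb, False)
    var = (nb - 1) / nb * np.sum((d_jack - d_jack.mean()) ** 2)
    z = d / np.sqrt(var) if var > 0 else np.nan
    return DStatResult(d, z, tot_a, tot_b, nb,
                       bool(np.isfinite(z) and abs(z) >= 3.0))
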