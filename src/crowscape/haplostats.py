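"""Haplotype-homozygosity selection scans: EHH, iHH, iHS, nSL, XP-EHH.

EHH at distance x from a core site is the probability that two distinct
haplotypes carrying the core allele are identical at every site between
the core and x. iHH integrates the EHH curve (trapezoid, physical
distance) outward in both directions until it decays below a cutoff;
unstandardized iHS is ln(iHH_ancestral / iHH_derived), so a sweep on the
derived background gives negative raw values. nSL is identical except
distance is counted in segregating sites, making it robust to
recombination-rate heterogeneity. XP-EHH contrasts total (allele-agnostic)
iHH between two populations.

Raw scores are standardized within derived-allele-frequency bins (100
equal-width bins by default; sparse bins are merged with neighbours so
every bin has enough sites for a stable mean and s.d.), yielding
approximately N(0,1) scores whose extreme tails flag candidate sweeps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeSet",
    "ehh",
    "site_ihh",
    "ihh_and_ihs",
    "nsl",
    "xpehh",
    "standardize",
    "snp_outliers",
    "shared_outlier_expectation",
]

EHH_CUTOFF = 0.05
MAX_GAP_BP = 200_000


@dataclass
class HaplotypeSet:
    """Phased haplotypes for one population, polarized 0=ancestral 1=derived.

    ``haps`` is (n_haplotypes, n_sites) with exactly two rows per diploid;
    ``pos`` is 1-based and strictly increasing within each scaffold.
    """

    haps: np.ndarray
    scaffold: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        if self.haps.shape[0] % 2:
            raise ValueError("odd number of haplotypes: expected 2 per diploid")
        if self.haps.shape[1] != self.pos.size or self.pos.size != self.scaffold.size:
            raise ValueError("haps, pos and scaffold are misaligned")

    @property
    def derived_freq(self) -> np.ndarray:
        return self.haps.mean(axis=0)

    def scaffold_slices(self) -> list[tuple[str, slice]]:
        out = []
        start = 0
        for i in range(1, self.scaffold.size + 1):
            if i == self.scaffold.size or self.scaffold[i] != self.scaffold[i - 1]:
                out.append((self.scaffold[start], slice(start, i)))
                start = i
        return out


# ---------------------------------------------------------------------------
# EHH


def _ehh_curve(haps: np.ndarray, core: int, step: int,
               stop_below: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """EHH values walking from ``core`` in direction ``step`` (+1/-1).

    ``haps`` holds only the carrier haplotypes. Returns (site indices
    including the core, EHH at each); EHH(core) = 1 and the curve is
    non-increasing. The walk stops at the scaffold edge, when EHH reaches
    0, or one site after EHH first drops below ``stop_below``.

    Vectorized over haplotype pairs: identity between the core and site j
    is the complement of the cumulative OR of per-site mismatches, so whole
    blocks of the curve are computed with one pairwise comparison.
    """
    k = haps.shape[0]
    if k < 2:
        raise ValueError("EHH undefined with fewer than 2 carrier haplotypes")
    pairs = k * (k - 1)
    n_sites = haps.shape[1]
    span = (n_sites - 1 - core) if step > 0 else core
    idx_out = [np.array([core])]
    ehh_out = [np.array([1.0])]
    done = 0
    block = 64
    mismatch = np.zeros((k, k), dtype=bool)
    while done < span:
        take = min(block, span - done)
        if step > 0:
            j = np.arange(core + done + 1, core + done + 1 + take)
        else:
            j = np.arange(core - done - 1, core - done - 1 - take, -1)
        x = haps[:, j]
        m = x[:, None, :] != x[None, :, :]
        m[:, :, 0] |= mismatch
        np.logical_or.accumulate(m, axis=2, out=m)
        ehh = 1.0 - m.sum(axis=(0, 1)) / pairs
        idx_out.append(j)
        ehh_out.append(ehh)
        cut = np.flatnonzero((ehh == 0.0) | (ehh < stop_below))
        if cut.size:
            stop = cut[0] + 1
            idx_out[-1] = j[:stop]
            ehh_out[-1] = ehh[:stop]
            break
        mismatch = m[:, :, -1]
        done += take
        block *= 2
    return np.concatenate(idx_out), np.concatenate(ehh_out)


def ehh(hapset: HaplotypeSet, core: int, allele: int, direction: int = 1
        ) -> tuple[np.ndarray, np.ndarray]:
    """EHH decay curve for carriers of ``allele`` at site index ``core``.

    ``direction`` +1 walks toward higher positions, -1 toward lower.
    Returns (site indices, EHH values) starting at the core (EHH = 1).
    The walk stays within the core's scaffold.
    """
    for scaf, sl in hapset.scaffold_slices():
        if sl.start <= core < sl.stop:
            local = hapset.haps[:, sl]
            carriers = local[local[:, core - sl.start] == allele]
            idx, vals = _ehh_curve(carriers, core - sl.start, 1 if direction >= 0 else -1)
            return idx + sl.start, vals
    raise IndexError(f"core site {core} out of range")


def _integrate_side(
    carriers: np.ndarray,
    pos: np.ndarray,
    core: int,
    step: int,
    cutoff: float,
    max_gap_bp: float,
) -> tuple[float, float]:
    """One-sided iHH in base pairs and in site units from a single walk.

    Returns (ihh_bp, ihh_sites); a component is NaN when the EHH curve
    never decays below ``cutoff`` before the scaffold edge, and ihh_bp is
    additionally NaN when a physical gap larger than ``max_gap_bp`` is
    crossed while still above the cutoff (no interpolation across mask
    gaps).
    """
    idx, vals = _ehh_curve(carriers, core, step, stop_below=cutoff)
    below = np.flatnonzero(vals < cutoff)
    if below.size == 0:
        return np.nan, np.nan      # ran off the scaffold while above cutoff
    stop = below[0]
    d_sites = np.arange(stop + 1, dtype=float)
    ihh_sites = float(np.trapezoid(vals[: stop + 1], d_sites))
    gaps = np.abs(np.diff(pos[idx[: stop + 1]]))
    if gaps.size and np.max(gaps) > max_gap_bp:
        return np.nan, ihh_sites
    d_bp = np.abs(pos[idx[: stop + 1]] - pos[core]).astype(float)
    ihh_bp = float(np.trapezoid(vals[: stop + 1], d_bp))
    return ihh_bp, ihh_sites


def site_ihh(
    haps: np.ndarray,
    pos: np.ndarray,
    core: int,
    allele: int | None,
    cutoff: float = EHH_CUTOFF,
    max_gap_bp: float = MAX_GAP_BP,
    site_distance: bool = False,
) -> float:
    """Integrated EHH at one core site for one allele's carriers (or all
    haplotypes when ``allele`` is None, as used by XP-EHH)."""
    carriers = haps if allele is None else haps[haps[:, core] == allele]
    if carriers.shape[0] < 2:
        return np.nan
    which = 1 if site_distance else 0
    left = _integrate_side(carriers, pos, core, -1, cutoff, max_gap_bp)[which]
    right = _integrate_side(carriers, pos, core, +1, cutoff, max_gap_bp)[which]
    return left + right


def _scan_both(
    hapset: HaplotypeSet,
    min_freq: float,
    cutoff: float,
    max_gap_bp: float,
) -> pd.DataFrame:
    """Raw iHS and nSL for every scoreable site, sharing one EHH walk per
    (site, allele, direction)."""
    freq = hapset.derived_freq
    raw_ihs = np.full(freq.size, np.nan)
    raw_nsl = np.full(freq.size, np.nan)
    for _, sl in hapset.scaffold_slices():
        haps = hapset.haps[:, sl]
        pos = hapset.pos[sl]
        f = freq[sl.start:sl.stop]
        for core in np.flatnonzero((f >= min_freq) & (f <= 1 - min_freq)):
            anc = haps[haps[:, core] == 0]
            der = haps[haps[:, core] == 1]
            if anc.shape[0] < 2 or der.shape[0] < 2:
                continue
            a_bp = a_nsl = d_bp = d_nsl = 0.0
            for step in (-1, +1):
                ab, an = _integrate_side(anc, pos, core, step, cutoff, max_gap_bp)
                db, dn = _integrate_side(der, pos, core, step, cutoff, max_gap_bp)
                a_bp += ab
                a_nsl += an
                d_bp += db
                d_nsl += dn
            if np.isfinite(a_bp) and np.isfinite(d_bp) and a_bp > 0 and d_bp > 0:
                raw_ihs[sl.start + core] = np.log(a_bp / d_bp)
            if np.isfinite(a_nsl) and np.isfinite(d_nsl) and a_nsl > 0 and d_nsl > 0:
                raw_nsl[sl.start + core] = np.log(a_nsl / d_nsl)
    return pd.DataFrame({
        "scaffold": hapset.scaffold, "pos": hapset.pos,
        "freq_derived": freq, "raw_ihs": raw_ihs, "raw_nsl": raw_nsl,
    })


def scan_ihs_nsl(
    hapset: HaplotypeSet,
    min_freq: float = 0.05,
    cutoff: float = EHH_CUTOFF,
    max_gap_bp: float = MAX_GAP_BP,
    n_bins: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Both within-population scans from one pass; returns (iHS, nSL)
    per-site tables with raw and standardized columns."""
    both = _scan_both(hapset, min_freq, cutoff, max_gap_bp)
    out = []
    for col in ("raw_ihs", "raw_nsl"):
        df = both[["scaffold", "pos", "freq_derived"]].copy()
        df["raw"] = both[col]
        std, bins = standardize(df["raw"].to_numpy(),
                                df["freq_derived"].to_numpy(), n_bins=n_bins)
        df["standardized"] = std
        df["freq_bin"] = bins
        out.append(df)
    return out[0], out[1]


def ihh_and_ihs(
    hapset: HaplotypeSet,
    min_freq: float = 0.05,
    cutoff: float = EHH_CUTOFF,
    max_gap_bp: float = MAX_GAP_BP,
    n_bins: int = 100,
) -> pd.DataFrame:
    """Per-site raw and frequency-standardized iHS.

    Sites with derived frequency outside [min_freq, 1-min_freq], fewer than
    two carriers of either allele, or an EHH curve that never decays below
    the cutoff before the scaffold edge (or a gap > ``max_gap_bp``) carry
    NaN and are excluded from standardization.
    """
    return scan_ihs_nsl(hapset, min_freq, cutoff, max_gap_bp, n_bins)[0]


def nsl(
    hapset: HaplotypeSet,
    min_freq: float = 0.05,
    cutoff: float = EHH_CUTOFF,
    n_bins: int = 100,
) -> pd.DataFrame:
    """Per-site raw and standardized nSL (iHS with distance in number of
    segregating sites instead of base pairs)."""
    return scan_ihs_nsl(hapset, min_freq, cutoff, np.inf, n_bins)[1]


def xpehh(
    hapset_a: HaplotypeSet,
    hapset_b: HaplotypeSet,
    cutoff: float = EHH_CUTOFF,
    max_gap_bp: float = MAX_GAP_BP,
) -> pd.DataFrame:
    """Per-site raw and genome-wide-standardized XP-EHH = ln(iHH_A/iHH_B).

    Both populations must be phased on the same sites (site lists are
    intersected by scaffold+position); iHH is integrated over all
    haplotypes regardless of allele. A sweep present only in A pushes
    XP-EHH to the positive extreme at the core.
    """
    key_a = pd.MultiIndex.from_arrays([hapset_a.scaffold, hapset_a.pos])
    key_b = pd.MultiIndex.from_arrays([hapset_b.scaffold, hapset_b.pos])
    common = key_a.intersection(key_b)
    ia = key_a.get_indexer(common)
    ib = key_b.get_indexer(common)
    order = np.argsort(ia)
    ia, ib = ia[order], ib[order]

    sub_a = HaplotypeSet(hapset_a.haps[:, ia], hapset_a.scaffold[ia], hapset_a.pos[ia])
    sub_b = HaplotypeSet(hapset_b.haps[:, ib], hapset_b.scaffold[ib], hapset_b.pos[ib])

    raw = np.full(ia.size, np.nan)
    for (scaf, sl_a), (_, sl_b) in zip(sub_a.scaffold_slices(), sub_b.scaffold_slices()):
        ha, pa = sub_a.haps[:, sl_a], sub_a.pos[sl_a]
        hb, pb = sub_b.haps[:, sl_b], sub_b.pos[sl_b]
        for core in range(pa.size):
            va = site_ihh(ha, pa, core, None, cutoff, max_gap_bp)
            vb = site_ihh(hb, pb, core, None, cutoff, max_gap_bp)
            if np.isfinite(va) and np.isfinite(vb) and va > 0 and vb > 0:
                raw[sl_a.start + core] = np.log(va / vb)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu, sd = np.nanmean(raw), np.nanstd(raw)
    std = (raw - mu) / sd if sd and np.isfinite(sd) and sd > 0 else np.full_like(raw, np.nan)
    return pd.DataFrame({
        "scaffold": sub_a.scaffold, "pos": sub_a.pos,
        "freq_derived_a": sub_a.derived_freq, "raw": raw, "standardized": std,
    })


# ---------------------------------------------------------------------------
# standardization and outliers


def standardize(
    values: np.ndarray,
    freq: np.ndarray,
    n_bins: int = 100,
    min_per_bin: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize raw scores to mean 0 / s.d. 1 within derived-frequency
    bins.

    Frequencies are cut into ``n_bins`` equal-width bins on [0, 1]; bins
    with fewer than ``min_per_bin`` finite values are merged with the next
    bin to the right (the last bin merges leftward) so every standardizing
    group has a stable mean and s.d. Returns (standardized values, final
    bin id per site); sites with NaN raw values stay NaN.
    """
    values = np.asarray(values, dtype=float)
    freq = np.asarray(freq, dtype=float)
    raw_bin = np.clip((freq * n_bins).astype(int), 0, n_bins - 1)
    finite = np.isfinite(values)

    # merge sparse bins left-to-right
    counts = np.bincount(raw_bin[finite], minlength=n_bins)
    acc = 0
    group = 0
    group_of = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        group_of[b] = group
        acc += counts[b]
        if acc >= min_per_bin:
            group += 1
            acc = 0
    if acc > 0 and group > 0:      # leftover tail joins the previous group
        group_of[group_of == group] = group - 1
    bins = group_of[raw_bin]

    out = np.full_like(values, np.nan)
    for g in np.unique(bins[finite]):
        sel = finite & (bins == g)
        mu = values[sel].mean()
        sd = values[sel].std()
        if sd > 0:
            out[sel] = (values[sel] - mu) / sd
        else:
            out[sel] = 0.0
    return out, bins


def snp_outliers(
    standardized: np.ndarray,
    alpha_low: float = 0.005,
    alpha_high: float = 0.995,
) -> np.ndarray:
    """Flag sites in the extreme tails of a standardized track.

    Sites strictly below the ``alpha_low`` empirical quantile or strictly
    above the ``alpha_high`` quantile are outliers (1% combined by
    default). NaN sites are never flagged.
    """
    x = np.asarray(standardized, dtype=float)
    finite = np.isfinite(x)
    n = int(finite.sum())
    min_tail = min(alpha_low, 1.0 - alpha_high)
    if min_tail > 0 and n < 1.0 / min_tail:
        warnings.warn(f"only {n} sites: tail quantiles at alpha={min_tail} are unstable",
                      stacklevel=2)
    if n == 0:
        return np.zeros_like(x, dtype=bool)
    lo = np.quantile(x[finite], alpha_low)
    hi = np.quantile(x[finite], alpha_high)
    out = np.zeros_like(x, dtype=bool)
    out[finite] = (x[finite] < lo) | (x[finite] > hi)
    if not out.any():
        warnings.warn("no outliers flagged (degenerate or constant track)",
                      stacklevel=2)
    return out


def shared_outlier_expectation(
    alpha: float,
    props: tuple[float, ...] | list[float],
    n_shared: int,
    observed: int | None = None,
) -> tuple[float, float | None]:
    """Expected count of SNPs flagged as outliers in every zone by chance.

    Under independence, a SNP in the cross-zone shared set is an outlier in
    zone z with probability alpha * prop_z, where prop_z is the proportion
    of zone z's outliers that lie in the shared-SNP set; the expected
    shared-outlier count is n_shared * prod_z(alpha * prop_z). Returns
    (expectation, observed/expected ratio or None).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_shared < 0:
        raise ValueError("n_shared must be >= 0")
    expectation = float(n_shared)
    for p in props:
        if not 0.0 <= p <= 1.0:
            raise ValueError("zone proportions must be in [0, 1]")
        expectation *= alpha * p
    ratio = observed / expectation if (observed is not None and expectation > 0) else None
    return expectation, ratio
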