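"""Differentiation-landscape decomposition.

The central contrast: z-standardize each comparison's windowed F_ST over
the genome (F_ST'), subtract at every window the maximum F_ST' across a
set of allopatric, phenotype-matched control comparisons to obtain the net
differentiation dF_ST' of a focal (contact-zone) comparison, and call
outlier windows at an empirical percentile of each track. Runs of adjacent
F_ST' outlier windows form peaks; a peak containing at least one dF_ST'
outlier window is attributed to contact-zone-specific divergent selection
("contact_zone"), otherwise to selection pressures shared across the whole
complex ("shared", e.g. linked/background selection on a common genomic
architecture).

Supporting evidence lives here too: outlier clustering (permutation test
on mean run length), Moran's I autocorrelation along scaffolds, the
between-track correlation panels, the recombination x gene-density
interaction model for diversity, isolation by distance (Mantel test on
F_ST/(1-F_ST) vs great-circle distance), and the tension-zone scaling of
selection with zone width, s ~ (sigma/w)^2.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "zscore_fst",
    "delta_fst",
    "call_outlier_windows",
    "PeakCall",
    "classify_peaks",
    "peaks_to_frame",
    "clustering_test",
    "morans_i",
    "correlation_panels",
    "partial_correlation",
    "interaction_model",
    "great_circle_km",
    "ibd_mantel",
    "selection_width_scaling",
]


def zscore_fst(values: np.ndarray) -> np.ndarray:
    """F_ST': z-standardize a windowed track over its non-missing windows,
    expressing each window in genome-wide standard deviations."""
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need at least 2 non-missing windows")
    mu = x[finite].mean()
    sd = x[finite].std()
    if sd <= 1e-12 * max(1.0, abs(mu)):
        raise ValueError("zero variance: track cannot be z-standardized")
    out = np.full_like(x, np.nan)
    out[finite] = (x[finite] - mu) / sd
    return out


def delta_fst(focal: np.ndarray, controls: list[np.ndarray]) -> np.ndarray:
    """dF_ST': focal F_ST' minus the per-window maximum control F_ST'.

    The maximum is over the controls non-missing at that window; a window
    is missing only if the focal value or every control is missing.
    """
    if not controls:
        raise ValueError("empty control set")
    focal = np.asarray(focal, dtype=float)
    ctrl = np.vstack([np.asarray(c, dtype=float) for c in controls])
    if ctrl.shape[1] != focal.size:
        raise ValueError("focal and control tracks must share one window index")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cmax = np.nanmax(ctrl, axis=0)
    out = focal - cmax
    out[~np.isfinite(focal) | ~np.isfinite(cmax)] = np.nan
    return out


def call_outlier_windows(values: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Flag windows strictly above the empirical ``percentile`` of the
    track (missing windows are never flagged)."""
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    n = int(finite.sum())
    if n == 0:
        return np.zeros_like(x, dtype=bool)
    if n < 100:
        warnings.warn(f"only {n} non-missing windows: the {percentile}th "
                      "percentile is unstable", stacklevel=2)
    cut = np.percentile(x[finite], percentile)
    out = np.zeros_like(x, dtype=bool)
    out[finite] = x[finite] > cut
    return out


@dataclass
class PeakCall:
    scaffold: object
    start: int
    end: int
    wids: list[int]
    peak_class: str            # "shared" or "contact_zone"
    max_fst_prime: float
    max_delta: float

    @property
    def n_windows(self) -> int:
        return len(self.wids)

    @property
    def span_kb(self) -> float:
        return (self.end - self.start) / 1000.0


def classify_peaks(
    fst_flags: np.ndarray,
    delta_flags: np.ndarray,
    windows: pd.DataFrame,
    fst_prime: np.ndarray | None = None,
    delta: np.ndarray | None = None,
    max_gap: int = 0,
) -> list[PeakCall]:
    """Merge F_ST'-outlier windows into peaks and classify each.

    Peaks are maximal runs of flagged windows on one scaffold separated by
    at most ``max_gap`` unflagged windows (default: strict adjacency). A
    peak is ``contact_zone`` if any member window is also a dF_ST' outlier,
    else ``shared``; the two classes are mutually exclusive and every
    flagged window belongs to exactly one peak.
    """
    fst_flags = np.asarray(fst_flags, dtype=bool)
    delta_flags = np.asarray(delta_flags, dtype=bool)
    wids = windows["wid"].to_numpy()
    scaf = windows["scaffold"].to_numpy()
    flagged = np.flatnonzero(fst_flags)
    peaks: list[PeakCall] = []
    run: list[int] = []

    def close_run(run: list[int]) -> None:
        members = [int(w) for w in run]
        is_cz = bool(delta_flags[members].any())
        fp = (np.nanmax(fst_prime[members]) if fst_prime is not None else np.nan)
        dl = np.nan
        if delta is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                dl = np.nanmax(delta[members])
        peaks.append(PeakCall(
            scaffold=scaf[members[0]],
            start=int(windows["start"].iloc[members[0]]),
            end=int(windows["end"].iloc[members[-1]]),
            wids=members,
            peak_class="contact_zone" if is_cz else "shared",
            max_fst_prime=float(fp),
            max_delta=float(dl),
        ))

    for w in flagged:
        if run and (scaf[w] == scaf[run[-1]]) and (wids[w] - run[-1] <= 1 + max_gap):
            run.append(int(w))
        else:
            if run:
                close_run(run)
            run = [int(w)]
    if run:
        close_run(run)
    return peaks


def peaks_to_frame(peaks: list[PeakCall]) -> pd.DataFrame:
    rows = [{
        "scaffold": p.scaffold, "start": p.start, "end": p.end,
        "n_windows": p.n_windows, "span_kb": p.span_kb, "class": p.peak_class,
        "max_fst_prime": p.max_fst_prime, "max_delta": p.max_delta,
        "wids": ",".join(map(str, p.wids)),
    } for p in peaks]
    return pd.DataFrame(rows, columns=[
        "scaffold", "start", "end", "n_windows", "span_kb", "class",
        "max_fst_prime", "max_delta", "wids"])


# ---------------------------------------------------------------------------
# clustering and autocorrelation


def _runs(flags: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True."""
    padded = np.concatenate([[0], flags.astype(np.int8), [0]])
    d = np.diff(padded)
    return np.flatnonzero(d == -1) - np.flatnonzero(d == 1)


def clustering_test(
    flags: np.ndarray,
    windows: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Permutation test for spatial clustering of outlier windows.

    Statistic: mean run length of consecutive flagged windows (runs cannot
    span scaffolds). Null: the flag vector is independently shuffled within
    each scaffold, preserving each scaffold's outlier count while making
    window positions exchangeable — under this null adjacency is pure
    chance, so the statistic directly measures clustering.

    Returns (observed statistic, p, p_randomized). ``p`` is the
    conservative permutation p-value (1 + #{null >= obs}) / (n_perm + 1);
    because the statistic is discrete (ratios of small integers) its null
    ties are massive and ``p`` is strongly sub-uniform. ``p_randomized``
    breaks ties with a seeded uniform draw, giving an exactly
    Uniform(0, 1) null — use it for calibration checks; use ``p`` for
    inference.
    """
    flags = np.asarray(flags, dtype=bool)
    if not flags.any():
        raise ValueError("no flagged windows")
    scaf = windows["scaffold"].to_numpy()
    scaffolds = list(dict.fromkeys(scaf))
    per_scaf = [np.flatnonzero(scaf == s) for s in scaffolds]
    obs = float(np.mean(np.concatenate([_runs(flags[idx]) for idx in per_scaf])))
    if flags.all():
        warnings.warn("all windows flagged: clustering test degenerate", stacklevel=2)
        return obs, 1.0, 1.0
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        lengths = [np.empty(0, dtype=np.int64)]
        for idx in per_scaf:
            f = flags[idx]
            if f.any():
                f = rng.permutation(f)
                lengths.append(_runs(f))
        null[b] = np.mean(np.concatenate(lengths))
    n_gt = int(np.count_nonzero(null > obs + 1e-12))
    n_eq = int(np.count_nonzero(np.abs(null - obs) <= 1e-12))
    p = (1.0 + n_gt + n_eq) / (n_perm + 1.0)
    p_rand = (n_gt + rng.uniform() * (1.0 + n_eq)) / (n_perm + 1.0)
    return obs, float(p), float(p_rand)


def morans_i(values: np.ndarray, windows: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Moran's I with lag-1 adjacency along each scaffold.

    Weights are binary adjacency between consecutive non-missing windows of
    a scaffold, row-normalized. Scaffold values are combined genome-wide as
    the weight-sum-weighted average. Returns (genome-wide I, per-scaffold
    table); scaffolds with a constant track or fewer than 3 usable windows
    are flagged NaN and excluded from the genome-wide average.
    """
    x = np.asarray(values, dtype=float)
    scaf = windows["scaffold"].to_numpy()
    rows = []
    for s in dict.fromkeys(scaf):
        v = x[scaf == s]
        v = v[np.isfinite(v)]
        n = v.size
        if n < 3 or np.ptp(v) == 0:
            rows.append({"scaffold": s, "I": np.nan, "n": n, "w_sum": 0.0})
            continue
        z = v - v.mean()
        # row-normalized neighbour mean: ends have one neighbour
        nb = np.empty(n)
        nb[0] = z[1]
        nb[-1] = z[-2]
        nb[1:-1] = 0.5 * (z[:-2] + z[2:])
        i_val = float(np.sum(z * nb) / np.sum(z * z))
        rows.append({"scaffold": s, "I": i_val, "n": n, "w_sum": float(n)})
    df = pd.DataFrame(rows)
    ok = df["I"].notna()
    if not ok.any():
        return np.nan, df
    w = df.loc[ok, "w_sum"].to_numpy()
    genome = float(np.average(df.loc[ok, "I"].to_numpy(), weights=w))
    return genome, df


# ---------------------------------------------------------------------------
# correlation structure


def _pearson(x: np.ndarray, y: np.ndarray, min_windows: int = 10
             ) -> tuple[float, bool]:
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 2 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        return np.nan, True
    r = float(stats.pearsonr(x[ok], y[ok]).statistic)
    return r, n < min_windows


def partial_correlation(x: np.ndarray, y: np.ndarray, covariate: np.ndarray) -> float:
    """Pearson correlation of x and y after regressing the covariate out of
    both (controls e.g. the mutation-rate proxy dS)."""
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(covariate)
    x, y, c = x[ok], y[ok], covariate[ok]
    design = np.column_stack([np.ones(c.size), c])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return float(stats.pearsonr(rx, ry).statistic)


def correlation_panels(
    intra: dict[tuple[str, str], np.ndarray],
    inter: dict[tuple[str, str], np.ndarray],
    min_windows: int = 10,
) -> pd.DataFrame:
    """Pairwise Pearson correlations of windowed tracks, by panel.

    ``intra`` maps (statistic, population) to a per-window track; ``inter``
    maps (statistic, "A~B") pair labels. Panels:

    a. the same intra-population statistic between pairs of populations;
    b. different statistics within one population;
    c. an inter-population statistic of a pair against an intra-population
       statistic of a population outside that pair (member populations are
       excluded as pseudo-replicated: they share the very allele-frequency
       draws the pair statistic is built from);
    d. inter-population statistics between disjoint comparisons — pairs of
       pairs sharing a population are excluded as pseudo-replicated.
       Covers both the same statistic across comparisons and different
       statistics (e.g. F_ST vs D_xy) across disjoint comparisons.
    """
    rows = []

    def add(panel, stat_x, label_x, stat_y, label_y, x, y):
        r, unstable = _pearson(x, y, min_windows)
        rows.append({"panel": panel, "stat_x": stat_x, "label_x": label_x,
                     "stat_y": stat_y, "label_y": label_y, "r": r,
                     "unstable": unstable})

    intra_stats = sorted({s for s, _ in intra})
    pops = sorted({p for _, p in intra})
    for s in intra_stats:
        for p1, p2 in itertools.combinations(pops, 2):
            if (s, p1) in intra and (s, p2) in intra:
                add("a", s, p1, s, p2, intra[(s, p1)], intra[(s, p2)])

    for p in pops:
        stats_here = [s for s in intra_stats if (s, p) in intra]
        for s1, s2 in itertools.combinations(stats_here, 2):
            add("b", s1, p, s2, p, intra[(s1, p)], intra[(s2, p)])

    for (s_inter, pair), track in sorted(inter.items()):
        members = set(pair.split("~"))
        for s_intra in intra_stats:
            for p in pops:
                if p not in members and (s_intra, p) in intra:
                    add("c", s_inter, pair, s_intra, p, track, intra[(s_intra, p)])

    inter_stats = sorted({s for s, _ in inter})
    for sa, sb in itertools.combinations_with_replacement(inter_stats, 2):
        pairs_a = sorted(p for st, p in inter if st == sa)
        pairs_b = sorted(p for st, p in inter if st == sb)
        seen = set()
        for pa in pairs_a:
            for pb in pairs_b:
                if sa == sb and pa == pb:
                    continue
                if set(pa.split("~")) & set(pb.split("~")):
                    continue   # pseudo-replicated: shares a population
                key = (min((sa, pa), (sb, pb)), max((sa, pa), (sb, pb)))
                if key in seen:
                    continue
                seen.add(key)
                add("d", sa, pa, sb, pb, inter[(sa, pa)], inter[(sb, pb)])

    return pd.DataFrame(rows, columns=["panel", "stat_x", "label_x", "stat_y",
                                       "label_y", "r", "unstable"])


def interaction_model(
    pi_track: np.ndarray,
    rho_track: np.ndarray,
    gene_density_track: np.ndarray,
) -> dict:
    """OLS of diversity on recombination, gene density and their product.

    Predictors are z-standardized before fitting, so the interaction
    coefficient is in s.d. units. Returns coefficients, p-values, R^2 and a
    collinearity flag (raised when a predictor is constant or the design is
    numerically singular).
    """
    ok = (np.isfinite(pi_track) & np.isfinite(rho_track)
          & np.isfinite(gene_density_track))
    if ok.sum() < 30:
        raise ValueError("need at least 30 aligned non-missing windows")
    y = np.asarray(pi_track, dtype=float)[ok]
    r = np.asarray(rho_track, dtype=float)[ok]
    g = np.asarray(gene_density_track, dtype=float)[ok]
    collinear = False
    for v in (r, g):
        if np.ptp(v) == 0:
            collinear = True
    if collinear:
        return {"collinear": True, "params": None, "pvalues": None, "r_squared": np.nan}
    rz = (r - r.mean()) / r.std()
    gz = (g - g.mean()) / g.std()
    design = sm.add_constant(np.column_stack([rz, gz, rz * gz]))
    fit = sm.OLS(y, design).fit()
    names = ["const", "rho", "gene_density", "rho_x_gene_density"]
    if fit.condition_number > 1e8:
        collinear = True
    return {
        "collinear": collinear,
        "params": dict(zip(names, fit.params)),
        "pvalues": dict(zip(names, fit.pvalues)),
        "r_squared": float(fit.rsquared),
        "nobs": int(fit.nobs),
    }


# ---------------------------------------------------------------------------
# isolation by distance


EARTH_RADIUS_KM = 6371.0


def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Haversine distance on a spherical Earth."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = (np.sin((la2 - la1) / 2) ** 2
         + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2)
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def ibd_mantel(
    fst_matrix: pd.DataFrame,
    coordinates: pd.DataFrame,
    n_perm: int = 9999,
    seed: int | None = None,
) -> dict:
    """Isolation by distance: Mantel test of linearized F_ST against
    great-circle distance.

    Genetic distance is F_ST/(1-F_ST) (F_ST = 1 is a hard error: infinite
    distance); geographic distance is the great-circle distance between
    population coordinates (pooled sampling locations should already be
    sample-size-weighted means). The Mantel r is the Pearson correlation of
    the off-diagonal entries; its p-value permutes population labels of one
    matrix. Residuals of genetic on geographic distance are returned per
    pair: strongly negative residuals mark pairs genetically more similar
    than geography predicts.
    """
    pops = list(fst_matrix.index)
    if len(pops) < 3:
        raise ValueError("Mantel test needs at least 3 populations")
    f = fst_matrix.to_numpy(dtype=float)
    if not np.allclose(f, f.T, equal_nan=True):
        raise ValueError("F_ST matrix must be symmetric")
    if np.any(f >= 1.0):
        raise ValueError("F_ST = 1 gives infinite linearized distance")
    gen = f / (1.0 - f)
    npop = len(pops)
    geo = np.zeros((npop, npop))
    for i, j in itertools.combinations(range(npop), 2):
        ci = coordinates.loc[pops[i]]
        cj = coordinates.loc[pops[j]]
        geo[i, j] = geo[j, i] = great_circle_km(ci["lat"], ci["lon"],
                                                cj["lat"], cj["lon"])

    iu = np.triu_indices(npop, k=1)
    x, y = geo[iu], gen[iu]
    r_obs = float(stats.pearsonr(x, y).statistic)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(npop)
        yp = gen[np.ix_(perm, perm)][iu]
        if abs(float(stats.pearsonr(x, yp).statistic)) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1.0) / (n_perm + 1.0)

    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    pairs = pd.DataFrame({
        "pop_a": [pops[i] for i in iu[0]],
        "pop_b": [pops[j] for j in iu[1]],
        "geo_km": x, "gen_linearized": y, "residual": resid,
    })
    return {"r": r_obs, "p": float(p), "n_perm": n_perm, "pairs": pairs,
            "slope": float(slope), "intercept": float(intercept)}


def selection_width_scaling(width_ratio: float) -> float:
    """Fold-reduction in the selection coefficient maintaining a tension
    zone that is ``width_ratio`` times wider, at equal dispersal:
    s ~ (sigma/w)^2, so the fold-change is width_ratio**2."""
    if width_ratio <= 0:
        raise ValueError("width ratio must be positive")
    return float(width_ratio) ** 2
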