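"""Windowed statistics against independent brute-force oracles.

The oracles iterate over haplotype pairs and SFS bins directly, or evaluate
the textbook formulas step by step, independently of the vectorized
implementations they check.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_variant_matrix
from crowscape import sitestats
from crowscape.sitestats import (
    abba_baba,
    diversity_stats,
    dxy,
    pbs,
    unfolded_sfs,
    wc_fst_per_site,
    window_fst,
    window_r2,
)
from crowscape.variantio import MISSING, assign_windows

RTOL = 1e-10


# ---------------------------------------------------------------------------
# oracles


def oracle_diversity(haps, callable_bp):
    """pi, theta_W, Tajima's D, Fay & Wu's H, Fu & Li's D by enumeration.

    ``haps`` is (n_haplotypes, n_sites) 0/1 with 0 = ancestral.
    """
    n, n_sites = haps.shape
    # pi: mean pairwise difference, all haplotype pairs
    diffs = [np.sum(haps[i] != haps[j])
             for i, j in itertools.combinations(range(n), 2)]
    pi_sum = np.mean(diffs)
    dac = haps.sum(axis=0)
    seg = (dac > 0) & (dac < n)
    s = int(seg.sum())
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    theta_w = s / a1

    # Tajima's D
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    taj_d = (pi_sum - theta_w) / np.sqrt(e1 * s + e2 * s * (s - 1))

    # Fay & Wu's H from the SFS
    sfs = np.bincount(dac[seg], minlength=n)
    theta_pi = sum(sfs[i] * 2 * i * (n - i) for i in range(1, n)) / (n * (n - 1))
    theta_h = sum(sfs[i] * 2 * i**2 for i in range(1, n)) / (n * (n - 1))
    h = theta_pi - theta_h

    # Fu & Li's D (with outgroup)
    eta = s
    eta_s = int(sfs[1])
    c_n = 2 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    v_d = 1 + (a1**2 / (a2 + a1**2)) * (c_n - (n + 1) / (n - 1))
    u_d = a1 - 1 - v_d
    fu_li = (eta - a1 * eta_s) / np.sqrt(u_d * eta + v_d * eta**2)
    return (pi_sum / callable_bp, theta_w / callable_bp, taj_d, h, fu_li)


def oracle_wc_components(gt1, gt2):
    """Weir & Cockerham (1984) a, b, c for one site, two populations,
    written directly from the published recipe on genotype lists."""
    n1, n2 = len(gt1), len(gt2)
    p1 = sum(gt1) / (2 * n1)
    p2 = sum(gt2) / (2 * n2)
    h1 = sum(1 for g in gt1 if g == 1) / n1
    h2 = sum(1 for g in gt2 if g == 1) / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def _vm_from_haps(haps_by_pop, pos=None, scaffold_length=None):
    pops, cols = [], []
    for label, h in haps_by_pop.items():
        g = h[0::2] + h[1::2]
        cols.append(g.T)
        pops += [label] * (h.shape[0] // 2)
    return make_variant_matrix(np.hstack(cols), pops, pos=pos,
                               scaffold_length=scaffold_length)


# ---------------------------------------------------------------------------
# tests


class TestUnfoldedSFS:
    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(1)
        haps = (rng.random((8, 50)) < rng.uniform(0.05, 0.9, 50)).astype(np.uint8)
        vm = _vm_from_haps({"X": haps})
        spec = unfolded_sfs(vm, "X")
        dac = haps.sum(axis=0)
        expected = np.bincount(dac[(dac > 0) & (dac < 8)], minlength=8)[1:]
        assert np.array_equal(spec, expected)

    def test_fixed_derived_not_counted(self):
        haps = np.ones((6, 5), dtype=np.uint8)
        vm = _vm_from_haps({"X": haps})
        assert unfolded_sfs(vm, "X").sum() == 0

    def test_single_site_increments_one_bin(self):
        haps = np.zeros((8, 1), dtype=np.uint8)
        haps[:3, 0] = 1          # 3 derived of 8 alleles
        vm = _vm_from_haps({"X": haps})
        spec = unfolded_sfs(vm, "X")
        assert spec[2] == 1 and spec.sum() == 1

    def test_missing_ancestral_excluded(self):
        haps = np.zeros((6, 2), dtype=np.uint8)
        haps[:2, :] = 1
        vm = _vm_from_haps({"X": haps})
        vm.ancestral[0] = ""
        assert unfolded_sfs(vm, "X").sum() == 1


class TestDiversityStats:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        haps = (rng.random((10, 20)) < rng.uniform(0.1, 0.9, 20)).astype(np.uint8)
        vm = _vm_from_haps({"X": haps}, scaffold_length=2000)
        windex = assign_windows(vm, 50_000)
        res = diversity_stats(vm, "X", windex)
        exp = oracle_diversity(haps, callable_bp=2000)
        got = (res["pi"][0], res["theta_w"][0], res["tajimas_d"][0],
               res["fay_wu_h"][0], res["fu_li_d"][0])
        for g, e in zip(got, exp):
            assert g == pytest.approx(e, rel=RTOL)

    def test_all_singletons_give_negative_tajima(self):
        haps = np.zeros((10, 5), dtype=np.uint8)
        for j in range(5):
            haps[j % 10, j] = 1
        vm = _vm_from_haps({"X": haps})
        windex = assign_windows(vm, 50_000)
        assert diversity_stats(vm, "X", windex)["tajimas_d"][0] < 0

    def test_no_segregation_flags_d_missing(self):
        haps = np.zeros((8, 3), dtype=np.uint8)
        vm = _vm_from_haps({"X": haps}, scaffold_length=1000)
        windex = assign_windows(vm, 50_000)
        res = diversity_stats(vm, "X", windex)
        assert res["pi"][0] == 0 and res["theta_w"][0] == 0
        assert np.isnan(res["tajimas_d"][0])

    def test_too_few_alleles_flagged_missing(self):
        g = np.array([[1, 1]], dtype=np.int8)        # 1 site, 2 diploids
        vm = make_variant_matrix(g, ["X", "X"])
        vm.genotypes[:, 1] = MISSING                 # modal n = 2 < 4
        windex = assign_windows(vm, 50_000)
        res = diversity_stats(vm, "X", windex)
        assert np.isnan(res["pi"][0])

    def test_matches_msprime_tskit(self):
        # independent simulator + implementation: neutral coalescent via
        # msprime, pi and Tajima's D via tskit
        msprime = pytest.importorskip("msprime")
        ts = msprime.sim_mutations(
            msprime.sim_ancestry(6, sequence_length=100_000,
                                 recombination_rate=1e-8, population_size=1e4,
                                 random_seed=5),
            rate=2e-8, random_seed=5, model=msprime.BinaryMutationModel())
        haps = ts.genotype_matrix().T.astype(np.uint8)
        pos = ts.sites_position.astype(np.int64) + 1
        vm = _vm_from_haps({"X": haps}, pos=pos, scaffold_length=100_000)
        windex = assign_windows(vm, 50_000)
        res = diversity_stats(vm, "X", windex)
        exp_pi = ts.diversity(windows=[0, 50_000, 100_000])
        exp_d = ts.Tajimas_D(windows=[0, 50_000, 100_000])
        assert np.allclose(res["pi"].to_numpy(), exp_pi, rtol=1e-8)
        assert np.allclose(res["tajimas_d"].to_numpy(), exp_d, rtol=1e-8)


class TestWindowR2:
    def test_perfect_coupling(self):
        haps = np.zeros((6, 2), dtype=np.uint8)
        haps[:3] = 1
        windows = pd.DataFrame({"scaffold": ["s1"], "start": [0],
                                "end": [50_000], "wid": [0]})
        out = window_r2(haps, np.zeros(2, dtype=int), windows, 50_000)
        assert out[0] == pytest.approx(1.0)

    def test_low_maf_snp_excluded(self):
        haps = np.zeros((12, 3), dtype=np.uint8)
        haps[:6, 0] = 1
        haps[:6, 1] = 1
        haps[0, 2] = 1            # MAF 1/12 < 0.1: excluded
        haps[1, 2] = 1            # keep window at 3 SNPs, one filtered
        haps[1, 2] = 0
        windows = pd.DataFrame({"scaffold": ["s1"], "start": [0],
                                "end": [50_000], "wid": [0]})
        out = window_r2(haps, np.zeros(3, dtype=int), windows, 50_000)
        assert out[0] == pytest.approx(1.0)   # only the coupled pair remains

    def test_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(3)
        haps = (rng.random((10, 5)) < 0.5).astype(np.uint8)
        windows = pd.DataFrame({"scaffold": ["s1"], "start": [0],
                                "end": [50_000], "wid": [0]})
        out = window_r2(haps, np.zeros(5, dtype=int), windows, 50_000)
        f = haps.mean(axis=0)
        keep = [j for j in range(5) if min(f[j], 1 - f[j]) > 0.1]
        r2s = []
        for i, j in itertools.combinations(keep, 2):
            pa, pb = f[i], f[j]
            pab = np.mean(haps[:, i] * haps[:, j])
            d = pab - pa * pb
            r2s.append(d**2 / (pa * (1 - pa) * pb * (1 - pb)))
        assert out[0] == pytest.approx(np.mean(r2s), rel=RTOL)

    def test_short_scaffold_excluded(self):
        haps = np.zeros((6, 2), dtype=np.uint8)
        haps[:3] = 1
        windows = pd.DataFrame({"scaffold": ["s1"], "start": [0],
                                "end": [20_000], "wid": [0]})
        out = window_r2(haps, np.zeros(2, dtype=int), windows, 50_000)
        assert np.isnan(out[0])


class TestWeirCockerham:
    def test_toy_table_matches_hand_oracle(self):
        # pop1: AA, AA, Aa ; pop2: aa, aa, Aa (alt = a)
        g = np.array([[0, 0, 1, 2, 2, 1]], dtype=np.int8)
        vm = make_variant_matrix(g, ["P1"] * 3 + ["P2"] * 3)
        comp = wc_fst_per_site(vm, "P1", "P2")
        a, b, c = oracle_wc_components([0, 0, 1], [2, 2, 1])
        assert comp["a"][0] == pytest.approx(a, rel=RTOL)
        assert comp["b"][0] == pytest.approx(b, rel=RTOL)
        assert comp["c"][0] == pytest.approx(c, rel=RTOL)

    def test_random_fixture_matches_oracle(self):
        rng = np.random.default_rng(11)
        g = rng.integers(0, 3, size=(50, 9)).astype(np.int8)
        vm = make_variant_matrix(g, ["P1"] * 5 + ["P2"] * 4)
        comp = wc_fst_per_site(vm, "P1", "P2")
        for s in range(50):
            if not comp["used"][s]:
                continue
            a, b, c = oracle_wc_components(list(g[s, :5]), list(g[s, 5:]))
            assert comp["a"][s] == pytest.approx(a, rel=RTOL, abs=1e-14)
            assert comp["b"][s] == pytest.approx(b, rel=RTOL, abs=1e-14)
            assert comp["c"][s] == pytest.approx(c, rel=RTOL, abs=1e-14)

    def test_identical_populations_give_nonpositive_estimate(self):
        g = np.array([[0, 1, 2, 0, 1, 2]], dtype=np.int8)
        vm = make_variant_matrix(g, ["P1"] * 3 + ["P2"] * 3)
        comp = wc_fst_per_site(vm, "P1", "P2")
        assert comp["a"][0] <= 1e-12

    def test_reciprocally_fixed_site_is_one(self):
        g = np.array([[0, 0, 0, 2, 2, 2]], dtype=np.int8)
        vm = make_variant_matrix(g, ["P1"] * 3 + ["P2"] * 3)
        comp = wc_fst_per_site(vm, "P1", "P2")
        tot = comp["a"][0] + comp["b"][0] + comp["c"][0]
        assert comp["a"][0] / tot == pytest.approx(1.0, rel=RTOL)

    def test_monomorphic_site_excluded(self):
        g = np.array([[0, 0, 0, 0, 0, 0]], dtype=np.int8)
        vm = make_variant_matrix(g, ["P1"] * 3 + ["P2"] * 3)
        assert not wc_fst_per_site(vm, "P1", "P2")["used"][0]


class TestWindowFst:
    def test_ratio_of_sums_matches_oracle(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, size=(20, 8)).astype(np.int8)
        vm = make_variant_matrix(g, ["P1"] * 4 + ["P2"] * 4)
        comp = wc_fst_per_site(vm, "P1", "P2")
        vals, n = window_fst(comp, np.zeros(20, dtype=int), 1)
        num = den = 0.0
        for s in range(20):
            if comp["used"][s]:
                a, b, c = oracle_wc_components(list(g[s, :4]), list(g[s, 4:]))
                num += a
                den += a + b + c
        assert vals[0] == pytest.approx(num / den, rel=RTOL)

    def test_single_site_window_equals_site_value(self):
        g = np.array([[0, 0, 1, 2, 2, 1]], dtype=np.int8)
        vm = make_variant_matrix(g, ["P1"] * 3 + ["P2"] * 3)
        comp = wc_fst_per_site(vm, "P1", "P2")
        vals, _ = window_fst(comp, np.zeros(1, dtype=int), 1)
        site = comp["a"][0] / (comp["a"][0] + comp["b"][0] + comp["c"][0])
        assert vals[0] == pytest.approx(site, rel=RTOL)

    def test_empty_window_is_missing_not_zero(self):
        g = np.array([[0, 1, 2, 0, 1, 2]], dtype=np.int8)
        vm = make_variant_matrix(g, ["P1"] * 3 + ["P2"] * 3)
        comp = wc_fst_per_site(vm, "P1", "P2")
        vals, _ = window_fst(comp, np.zeros(1, dtype=int), 3)
        assert np.isnan(vals[1]) and np.isnan(vals[2])


class TestDxy:
    def test_reciprocally_fixed_site(self):
        g = np.array([[0, 0, 0, 2, 2, 2]], dtype=np.int8)
        vm = make_variant_matrix(g, ["P1"] * 3 + ["P2"] * 3,
                                 scaffold_length=10_000)
        windex = assign_windows(vm, 10_000)
        tr = dxy(vm, "P1", "P2", windex)
        assert tr.values[0] == pytest.approx(1e-4, rel=RTOL)

    def test_hand_computed_window(self):
        # frequencies pA = (0.5, 1.0, 0.25), pB = (0.25, 0.0, 0.25)
        g = np.array([
            [1, 1, 0, 1],
            [2, 2, 0, 0],
            [1, 0, 1, 0],
        ], dtype=np.int8)
        vm = make_variant_matrix(g, ["P1", "P1", "P2", "P2"],
                                 scaffold_length=1000)
        windex = assign_windows(vm, 1000)
        tr = dxy(vm, "P1", "P2", windex)
        expected = ((0.5 * 0.75 + 0.25 * 0.5)
                    + (1.0 * 1.0 + 0.0)
                    + (0.25 * 0.75 + 0.25 * 0.75)) / 1000
        assert tr.values[0] == pytest.approx(expected, rel=RTOL)

    def test_symmetric_in_population_labels(self, small_sim_vm):
        vm, windex, _ = small_sim_vm
        a = dxy(vm, "focal_a", "ctrl1_a", windex).values
        b = dxy(vm, "ctrl1_a", "focal_a", windex).values
        assert np.allclose(a, b, equal_nan=True)

    def test_identical_populations_zero(self):
        g = np.zeros((2, 6), dtype=np.int8)
        vm = make_variant_matrix(g, ["P1"] * 3 + ["P2"] * 3,
                                 scaffold_length=1000)
        windex = assign_windows(vm, 1000)
        assert dxy(vm, "P1", "P2", windex).values[0] == 0.0


class TestPBS:
    def test_equal_fst_closed_form(self):
        f = np.array([0.3])
        assert pbs(f, f, f)[0] == pytest.approx(-np.log(1 - 0.3) / 2)

    def test_ln2_closed_form(self):
        assert pbs(np.array([0.5]), np.array([0.5]), np.array([0.0]))[0] \
            == pytest.approx(np.log(2))

    def test_missing_propagates(self):
        out = pbs(np.array([np.nan]), np.array([0.1]), np.array([0.1]))
        assert np.isnan(out[0])

    def test_mismatched_indices_error(self):
        with pytest.raises(ValueError):
            pbs(np.zeros(3), np.zeros(2), np.zeros(3))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 0.95), min_size=3, max_size=3))
    def test_branch_sum_identity(self, fsts):
        f12, f13, f23 = (np.array([v]) for v in fsts)
        total = pbs(f12, f13, f23) + pbs(f12, f23, f13) + pbs(f13, f23, f12)
        expected = 0.5 * (-np.log(1 - f12) - np.log(1 - f13) - np.log(1 - f23))
        assert total[0] == pytest.approx(expected[0], rel=1e-9, abs=1e-12)

    def test_doubled_drift_elevates_own_branch(self):
        from crowscape.simdata import PopulationSpec, SimConfig, simulate, to_variant_matrix
        cfg = SimConfig(seed=21, n_scaffolds=4, windows_per_scaffold=25,
                        snps_per_window=60,
                        populations=[PopulationSpec("P1", 6, 0.1),
                                     PopulationSpec("P2", 6, 0.05),
                                     PopulationSpec("P3", 6, 0.05)],
                        b_constant=True)
        sim = simulate(cfg)
        vm, windex, _ = to_variant_matrix(sim)
        f12 = sitestats.pair_window_fst(vm, "P1", "P2", windex).values
        f13 = sitestats.pair_window_fst(vm, "P1", "P3", windex).values
        f23 = sitestats.pair_window_fst(vm, "P2", "P3", windex).values
        pbs1 = pbs(f12, f13, f23)
        pbs2 = pbs(f12, f23, f13)
        assert np.nanmedian(pbs1) > 1.5 * np.nanmedian(pbs2)


class TestAbbaBaba:
    def test_count_arithmetic(self):
        # haploid-style frequencies giving 30 ABBA and 10 BABA patterns
        p1 = np.array([0] * 30 + [1] * 10, dtype=float)
        p2 = 1 - p1
        p3 = np.ones(40)
        res = abba_baba(p1, p2, p3, np.arange(40) // 10)
        assert res.d == pytest.approx(0.5)

    def test_symmetric_counts_give_zero(self):
        p1 = np.array([0.0, 1.0])
        p2 = np.array([1.0, 0.0])
        p3 = np.ones(2)
        res = abba_baba(p1, p2, p3, np.zeros(2, dtype=int))
        assert res.d == 0.0

    def test_no_informative_sites_flagged(self):
        z = np.zeros(5)
        res = abba_baba(z, z, z, np.zeros(5, dtype=int))
        assert np.isnan(res.d) and not res.significant

    def test_matches_per_site_oracle(self):
        rng = np.random.default_rng(2)
        p1, p2, p3 = rng.random((3, 30))
        res = abba_baba(p1, p2, p3, np.arange(30) // 5)
        abba = sum((1 - a) * b * c for a, b, c in zip(p1, p2, p3))
        baba = sum(a * (1 - b) * c for a, b, c in zip(p1, p2, p3))
        assert res.d == pytest.approx((abba - baba) / (abba + baba), rel=RTOL)
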