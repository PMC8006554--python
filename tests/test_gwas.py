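"""Kruskal-Wallis scan, peak calling and haplotype-effect analyses."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from canopyqtl import (
    EffectVector,
    HaplotypeScan,
    QTLSpec,
    SimConfig,
    effect_correlation,
    find_peaks,
    gen_founder_mosaic,
    gen_phenotypes,
    group_compare,
    haplotype_effects,
    kruskal_wallis,
    run_gwas,
    significance_tier,
)
from canopyqtl.simulate import draw_qtl_effects


# --- Kruskal-Wallis -------------------------------------------------------

def kw_bruteforce(groups):
    """Independent mean-rank statistic: ranks by explicit sorting, H
    from the defining sum, tie correction from first principles."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        rbar = sum(ranks[start : start + len(g)]) / len(g)
        h += len(g) * (rbar - (n + 1) / 2) ** 2
        start += len(g)
    h *= 12 / (n * (n + 1))
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    corr = 1 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / corr if corr > 0 else float("nan")


def test_worked_example():
    H, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert H == pytest.approx(7.2, abs=1e-12)
    assert df == 2
    assert p == pytest.approx(0.0273, abs=1e-4)


def test_exchangeability_of_group_order():
    a, b = [3.1, 0.2, 5.0], [1.1, 4.4]
    assert kruskal_wallis([a, b]) == kruskal_wallis([b, a])


def test_matches_scipy_with_ties():
    from scipy.stats import kruskal

    rng = np.random.default_rng(0)
    for _ in range(50):
        groups = [list(rng.integers(0, 6, rng.integers(2, 8))) for _ in range(rng.integers(2, 5))]
        if len({v for g in groups for v in g}) < 2:
            continue
        H, df, p = kruskal_wallis(groups)
        sH, sp = kruskal(*groups)
        assert H == pytest.approx(sH, abs=1e-10)
        assert p == pytest.approx(sp, abs=1e-10)


def test_matches_bruteforce_oracle_on_small_n():
    rng = np.random.default_rng(1)
    for _ in range(20):
        sizes = rng.integers(2, 4, rng.integers(2, 4))
        if sizes.sum() > 8:
            continue
        groups = [list(rng.integers(0, 5, s)) for s in sizes]
        if len({v for g in groups for v in g}) < 2:
            continue
        H, _, _ = kruskal_wallis(groups)
        assert H == pytest.approx(kw_bruteforce(groups), abs=1e-12)


def test_exact_permutation_null_calibration():
    """chi-square p is a fair approximation of the exact permutation p."""
    groups = [[1.0, 5.0, 2.5], [4.0, 3.0], [6.0, 0.5, 7.0]]
    pooled = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]
    H_obs, _, p_chi2 = kruskal_wallis(groups)
    count = total = 0
    for perm in itertools.permutations(pooled):
        regrouped, start = [], 0
        for s in sizes:
            regrouped.append(list(perm[start : start + s]))
            start += s
        h = kw_bruteforce(regrouped)
        total += 1
        if h >= H_obs - 1e-12:
            count += 1
    p_exact = count / total
    # at N = 8 the chi-square reference is a coarse approximation to the
    # exact permutation null; agreement to ~0.1 is what it can deliver
    assert abs(p_chi2 - p_exact) < 0.1


def test_degenerate_inputs():
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2, 3]])
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2], []])
    H, df, p = kruskal_wallis([[3, 3], [3, 3, 3]])
    assert math.isnan(H) and math.isnan(p) and df == 1


# --- scan -----------------------------------------------------------------

def test_monomorphic_snp_discarded(small_haplo, small_pheno):
    haplo = small_haplo
    values = haplo.values.copy()
    values[:, 0] = 3  # all lines carry one founder
    from canopyqtl.haplotypes import HaplotypeMatrix

    mono = HaplotypeMatrix(values=values, line_ids=haplo.line_ids, snp_map=haplo.snp_map)
    res = run_gwas(mono, small_pheno, "VF", 1)
    assert res.table.iloc[0]["status"] == "discarded"
    assert np.isnan(res.table.iloc[0]["p"])


def test_noiseless_qtl_attains_chromosome_maximum():
    cfg = SimConfig(n_lines=100, n_chroms=2, n_snps_per_chrom=60, seed=21)
    haplo = gen_founder_mosaic(cfg)
    causal = 30
    tab = gen_phenotypes(haplo, [QTLSpec(causal, tuple(range(8)))], noise_sd=0.0,
                         n_environments=1, seed=22)[0]
    res = run_gwas(haplo, tab, "VF", 1)
    chrom1 = res.table[res.table["chrom"] == 1]
    tested = chrom1[chrom1["status"] == "tested"]
    assert tested.loc[tested["neglog10p"].idxmax()].name == causal


def test_line_permutation_invariance(small_haplo, small_pheno):
    res = run_gwas(small_haplo, small_pheno, "VF", 1)
    rng = np.random.default_rng(3)
    perm = rng.permutation(small_haplo.n_lines)
    from canopyqtl.haplotypes import HaplotypeMatrix

    shuffled = HaplotypeMatrix(
        values=small_haplo.values[perm],
        line_ids=[small_haplo.line_ids[i] for i in perm],
        snp_map=small_haplo.snp_map,
    )
    res2 = run_gwas(shuffled, small_pheno, "VF", 1)
    pd.testing.assert_frame_equal(res.table, res2.table)


def test_scan_matches_scipy_per_snp(small_haplo, small_pheno):
    from scipy.stats import kruskal

    res = run_gwas(small_haplo, small_pheno, "VF", 1, min_groups=3, min_group_size=2)
    y = small_pheno.set_index("line_id")["value"].loc[small_haplo.line_ids].to_numpy()
    for s in range(0, small_haplo.n_snps, 7):
        lab = small_haplo.values[:, s]
        sizes = np.bincount(lab, minlength=9)[1:]
        groups = [y[lab == f] for f in range(1, 9) if sizes[f - 1] >= 2]
        if len(groups) < 3:
            assert res.table.iloc[s]["status"] == "discarded"
            continue
        sH, sp = kruskal(*groups)
        assert res.table.iloc[s]["H"] == pytest.approx(sH, abs=1e-10)
        assert res.table.iloc[s]["p"] == pytest.approx(sp, abs=1e-10)


def test_missing_phenotypes_are_dropped(small_haplo, small_pheno):
    pheno = small_pheno.copy()
    pheno.loc[pheno.index[:5], "value"] = np.nan
    res = run_gwas(small_haplo, pheno, "VF", 1)
    assert res.model.y.size == small_haplo.n_lines - 5


def test_absent_trait_rejected(small_haplo, small_pheno):
    with pytest.raises(ValueError):
        run_gwas(small_haplo, small_pheno, "SDW", 1)


def test_summary_mentions_trait_and_peaks(small_haplo, small_pheno):
    res = run_gwas(small_haplo, small_pheno, "VF", 1)
    text = res.summary(min_distance=10, n_top=3)
    assert "Kruskal-Wallis" in text and "VF" in text


# --- peak calling ---------------------------------------------------------

def test_peak_examples():
    assert find_peaks([1, 3, 1, 2, 1], min_distance=1) == [(1, 3.0), (3, 2.0)]
    assert find_peaks([1, 3, 1, 2, 1], min_distance=3) == [(1, 3.0)]
    assert find_peaks([1, 2, 3, 4, 5], min_distance=1) == []
    assert find_peaks([1, 2], min_distance=1) == []


def test_plateau_takes_leftmost_index():
    assert find_peaks([0, 2, 2, 2, 0], min_distance=1) == [(1, 2.0)]


def test_nans_never_peak():
    track = [1.0, np.nan, 1.0, 5.0, 1.0]
    assert find_peaks(track, min_distance=1) == [(3, 5.0)]


def test_matches_scipy_on_tie_free_tracks():
    from scipy.signal import find_peaks as scipy_find_peaks

    rng = np.random.default_rng(4)
    for _ in range(20):
        track = rng.normal(0, 1, 300)
        track += np.linspace(0, 1e-9, 300)  # breaks exact plateaus
        for dist in (1, 5, 50):
            ours = sorted(i for i, _ in find_peaks(track, min_distance=dist, n_top=None))
            theirs = sorted(scipy_find_peaks(track, distance=dist)[0].tolist())
            assert ours == theirs


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.integers(0, 30), min_size=3, max_size=200), st.integers(1, 40))
def test_peak_spacing_invariant(track, dist):
    peaks = find_peaks(np.asarray(track, dtype=float), min_distance=dist, n_top=None)
    idx = [i for i, _ in peaks]
    for a, b in itertools.combinations(idx, 2):
        assert abs(a - b) >= dist


# --- effects and correlations --------------------------------------------

def test_noiseless_effects_recover_planted_values():
    cfg = SimConfig(n_lines=120, n_chroms=1, n_snps_per_chrom=30, seed=31)
    haplo = gen_founder_mosaic(cfg)
    planted = (2.0, -1.0, 0.5, 3.0, -2.0, 1.5, 0.0, -0.5)
    tab = gen_phenotypes(haplo, [QTLSpec(10, planted)], noise_sd=0.0,
                         n_environments=1, seed=32)[0]
    snp = haplo.snp_map.iloc[10]["snp_id"]
    vec = haplotype_effects(haplo, tab, snp, "VF", 1)
    present = np.isfinite(vec.means)
    diffs = vec.means[present] - np.asarray(planted)[present]
    assert np.allclose(diffs, diffs[0])  # equal up to a common constant


def test_absent_founder_leaves_gap(small_pheno, small_haplo):
    values = small_haplo.values.copy()
    values[values[:, 3] == 1, 3] = 2  # remove founder AK at SNP 3
    from canopyqtl.haplotypes import HaplotypeMatrix

    haplo = HaplotypeMatrix(values=values, line_ids=small_haplo.line_ids,
                            snp_map=small_haplo.snp_map)
    snp = haplo.snp_map.iloc[3]["snp_id"]
    vec = haplotype_effects(haplo, small_pheno, snp, "VF", 1)
    assert np.isnan(vec.means[0])
    assert np.isfinite(vec.means).sum() == 7


def test_fewer_than_three_groups_discards_vector(small_pheno, small_haplo):
    values = small_haplo.values.copy()
    values[:, 0] = np.where(values[:, 0] % 2 == 0, 1, 2)
    from canopyqtl.haplotypes import HaplotypeMatrix

    haplo = HaplotypeMatrix(values=values, line_ids=small_haplo.line_ids,
                            snp_map=small_haplo.snp_map)
    snp = haplo.snp_map.iloc[0]["snp_id"]
    vec = haplotype_effects(haplo, small_pheno, snp, "VF", 1)
    assert vec.discarded
    assert np.isnan(vec.means).all()


def make_vec(means, snp="s"):
    m = np.asarray(means, dtype=float)
    return EffectVector(snp_id=snp, means=m, group_sizes=np.ones(8, dtype=np.int64))


def test_effect_correlation_extremes():
    x = make_vec([1, 2, 3, 4, 5, 6, 7, 8])
    assert effect_correlation(x, x)[0] == pytest.approx(1.0)
    y = make_vec([-v for v in [1, 2, 3, 4, 5, 6, 7, 8]])
    assert effect_correlation(x, y)[0] == pytest.approx(-1.0)


def test_effect_correlation_matches_direct_formula():
    xv = np.arange(1.0, 9.0)
    yv = np.array([2, 1, 4, 3, 6, 5, 8, 7], dtype=float)
    r, p, n = effect_correlation(make_vec(xv), make_vec(yv))
    rx = xv - xv.mean()
    ry = yv - yv.mean()
    r_direct = (rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum())
    assert n == 8
    assert r == pytest.approx(r_direct, abs=1e-12)


def test_effect_correlation_needs_three_pairs():
    x = make_vec([1, 2, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan])
    r, p, n = effect_correlation(x, x)
    assert math.isnan(r) and n == 2


def test_significance_tiers():
    assert significance_tier(0.005) == "**"
    assert significance_tier(0.03) == "*"
    assert significance_tier(0.07) == "+"
    assert significance_tier(0.5) == ""


# --- allele-class comparison ---------------------------------------------

def test_group_compare_worked_example():
    t, df, p = group_compare([1, 2, 3], [4, 5, 6])
    assert t == pytest.approx(-3.674, abs=1e-3)
    assert df == 4
    assert p == pytest.approx(0.0213, abs=1e-4)


def test_group_compare_symmetry_and_identity():
    t1, _, p1 = group_compare([1, 2, 3], [4, 5, 6])
    t2, _, p2 = group_compare([4, 5, 6], [1, 2, 3])
    assert t1 == pytest.approx(-t2)
    assert p1 == pytest.approx(p2)
    t, df, p = group_compare([2, 2, 2], [2, 2])
    assert (t, p) == (0.0, 1.0)


def test_group_compare_degenerate_unequal_means():
    t, df, p = group_compare([1, 1], [2, 2])
    assert math.isinf(t) and t < 0 and p == 0.0


def test_group_compare_uses_pooled_variance():
    # Student's t (pooled), not Welch: check against the pooled formula
    a = np.array([1.0, 2.0, 3.0, 8.0])
    b = np.array([4.0, 5.0])
    t, df, p = group_compare(a, b)
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    t_direct = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    assert t == pytest.approx(t_direct, abs=1e-12)
    assert df == 4
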