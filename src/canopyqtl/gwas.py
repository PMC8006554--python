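"""Haplotype-based GWAS: Kruskal-Wallis scan, peak calling, effects.

The scan tests, at every SNP, whether phenotype distributions differ
among founder-haplotype groups using the Kruskal-Wallis rank-sum test
(mid-ranks for ties, chi-square approximation with k-1 df).  QTLs are
called as local maxima of the -log10 P track subject to a minimum
index separation, following the common ``findpeaks``-style greedy rule.
At a QTL, the haplotype effect is summarized by the length-8 vector of
mean phenotype per founder group; effect vectors from different traits
or years are compared by Pearson correlation.

The scan is exposed statsmodels-style: build a :class:`HaplotypeScan`
from a haplotype matrix and a phenotype table, call :meth:`fit`, and
work with the returned :class:`HaplotypeScanResults` (per-SNP table,
``find_peaks``, ``haplotype_effects``, ``summary``, ``manhattan``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .haplotypes import FOUNDERS, HaplotypeMatrix

__all__ = [
    "KWResult",
    "EffectVector",
    "QTLPeak",
    "kruskal_wallis",
    "find_peaks",
    "HaplotypeScan",
    "HaplotypeScanResults",
    "run_gwas",
    "haplotype_effects",
    "effect_correlation",
    "group_compare",
    "significance_tier",
]


class KWResult(NamedTuple):
    H: float
    df: int
    p: float


def _tie_correction(values: np.ndarray) -> float:
    """1 - sum(t^3 - t) / (N^3 - N) over tie groups; 0 if all tied."""
    n = values.size
    _, counts = np.unique(values, return_counts=True)
    return 1.0 - float(((counts**3 - counts).sum()) / (n**3 - n))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Kruskal-Wallis rank-sum test over k groups.

    Mid-ranks are assigned to ties; the statistic

        H = [12 / (N (N+1))] * sum_i n_i (rbar_i - (N+1)/2)^2

    is divided by the tie-correction factor 1 - sum(t^3 - t)/(N^3 - N)
    and referred to the chi-square upper tail with df = k - 1.

    If every value is identical the tie correction is 0 and the test is
    undefined: ``H`` and ``p`` are returned as NaN (flagged), with df
    still k - 1.

    Raises
    ------
    ValueError
        Fewer than 2 groups, an empty group, or total N < 3.
    """
    arrs = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrs)
    n = pooled.size
    if n < 3:
        raise ValueError("need at least 3 values in total")
    df = len(arrs) - 1
    tc = _tie_correction(pooled)
    if tc == 0.0:
        return KWResult(H=math.nan, df=df, p=math.nan)
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrs:
        r = ranks[start : start + a.size]
        start += a.size
        h += a.size * (r.mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    h /= tc
    return KWResult(H=float(h), df=df, p=float(stats.chi2.sf(h, df)))


@dataclass(frozen=True)
class QTLPeak:
    snp_id: str
    chrom: int
    pos: int
    index: int
    neglog10p: float
    rank: int


def find_peaks(
    track: np.ndarray,
    min_distance: int = 100,
    n_top: Optional[int] = 8,
) -> List[Tuple[int, float]]:
    """Call peaks on a -log10 P track in map order.

    Candidates are strict local maxima (greater than both neighbours;
    a flat maximum contributes its leftmost index).  Candidates are
    selected greedily in decreasing height, discarding any candidate
    within ``min_distance`` indices of an already selected peak, until
    ``n_top`` peaks are kept (``None`` = no limit).  NaNs (untested
    SNPs) never form peaks.  Tracks shorter than 3 yield no peaks.

    Returns ``[(index, height), ...]`` sorted by decreasing height.
    """
    if min_distance < 1:
        raise ValueError("min_distance must be >= 1")
    t = np.asarray(track, dtype=np.float64)
    if t.size < 3:
        return []
    t = np.where(np.isnan(t), -np.inf, t)
    candidates: List[Tuple[int, float]] = []
    i = 1
    n = t.size
    while i < n - 1:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1  # run of equal values [i..j]
        if np.isfinite(t[i]) and t[i] > t[i - 1] and j + 1 < n and t[i] > t[j + 1]:
            candidates.append((i, float(t[i])))
        i = j + 1
    candidates.sort(key=lambda ih: (-ih[1], ih[0]))
    selected: List[Tuple[int, float]] = []
    for idx, h in candidates:
        if n_top is not None and len(selected) >= n_top:
            break
        if all(abs(idx - s) >= min_distance for s, _ in selected):
            selected.append((idx, h))
    return selected


@dataclass
class EffectVector:
    """Mean phenotype per founder haplotype at one SNP.

    ``means`` has one entry per founder (NaN where the founder is
    absent); the whole vector is discarded (all-NaN, ``discarded``
    True) when fewer than 3 haplotype groups are present.
    """

    snp_id: str
    means: np.ndarray
    group_sizes: np.ndarray
    discarded: bool = False

    def __post_init__(self) -> None:
        if self.means.shape != (8,) or self.group_sizes.shape != (8,):
            raise ValueError("means and group_sizes must have length 8")

    def as_series(self) -> pd.Series:
        return pd.Series(self.means, index=list(FOUNDERS), name=self.snp_id)


def significance_tier(p: float) -> str:
    """Annotation tiers: '**' P<0.01, '*' P<0.05, '+' P<0.1, '' else."""
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "+"
    return ""


class HaplotypeScan:
    """Per-SNP Kruskal-Wallis model of one trait in one environment.

    Parameters
    ----------
    haplo
        Founder-label matrix with its SNP map.
    pheno
        Long-format phenotype table (``line_id``, ``trait``,
        ``environment``, ``value``).
    trait, environment
        Which phenotype slice to scan.  Lines without a value are
        dropped (not imputed).
    """

    def __init__(
        self,
        haplo: HaplotypeMatrix,
        pheno: pd.DataFrame,
        trait: str,
        environment: Optional[int] = None,
    ):
        sub = pheno[pheno["trait"] == trait]
        if environment is not None:
            sub = sub[sub["environment"] == environment]
        sub = sub.dropna(subset=["value"])
        if len(sub) == 0:
            raise ValueError(f"no phenotype values for trait {trait!r}, environment {environment!r}")
        if sub["line_id"].duplicated().any():
            raise ValueError("more than one value per line for this trait/environment slice")
        order = {lid: i for i, lid in enumerate(haplo.line_ids)}
        known = sub["line_id"].map(order).dropna()
        rows = known.astype(int).to_numpy()
        self.haplo = haplo
        self.trait = trait
        self.environment = environment
        self.y = sub.loc[known.index, "value"].to_numpy(dtype=np.float64)
        self.labels = haplo.values[rows, :]
        self.line_ids = [haplo.line_ids[r] for r in rows]
        if self.y.size < 3:
            raise ValueError("need at least 3 phenotyped lines")

    def fit(self, min_groups: int = 3, min_group_size: int = 2) -> "HaplotypeScanResults":
        """Run the scan.

        At each SNP, lines are grouped by founder label (missing labels
        dropped); groups smaller than ``min_group_size`` are dropped;
        the SNP is tested iff at least ``min_groups`` groups remain
        (the 1-or-2-haplotype discard rule at the default), otherwise
        flagged ``discarded``.
        """
        if min_groups < 2:
            raise ValueError("min_groups must be >= 2")
        y = self.y
        n_all = y.size
        # fast path reusables: ranks of the full line set
        ranks_all = stats.rankdata(y)
        tc_all = _tie_correction(y)
        H = np.full(self.haplo.n_snps, np.nan)
        P = np.full(self.haplo.n_snps, np.nan)
        DF = np.zeros(self.haplo.n_snps, dtype=np.int64)
        NG = np.zeros(self.haplo.n_snps, dtype=np.int64)
        status = np.empty(self.haplo.n_snps, dtype=object)
        for s in range(self.haplo.n_snps):
            lab = self.labels[:, s]
            sizes = np.bincount(lab, minlength=9)
            keep = np.flatnonzero(sizes[1:] >= min_group_size) + 1
            n_groups = keep.size
            NG[s] = n_groups
            if n_groups < min_groups:
                status[s] = "discarded"
                continue
            DF[s] = n_groups - 1
            used = n_all - sizes[0] - sizes[1:][sizes[1:] < min_group_size].sum()
            if used == n_all:
                # all lines participate: reuse global ranks/tie correction
                if tc_all == 0.0:
                    status[s] = "degenerate"
                    continue
                rsum = np.bincount(lab, weights=ranks_all, minlength=9)[1:]
                nz = sizes[1:] > 0
                h = (
                    12.0
                    / (n_all * (n_all + 1))
                    * float(
                        (sizes[1:][nz] * (rsum[nz] / sizes[1:][nz] - (n_all + 1) / 2.0) ** 2).sum()
                    )
                    / tc_all
                )
            else:
                include = np.isin(lab, keep)
                yy = y[include]
                tc = _tie_correction(yy)
                if tc == 0.0:
                    status[s] = "degenerate"
                    continue
                r = stats.rankdata(yy)
                ll = lab[include]
                m = yy.size
                rsum = np.bincount(ll, weights=r, minlength=9)[1:]
                cnt = np.bincount(ll, minlength=9)[1:]
                nz = cnt > 0
                h = (
                    12.0
                    / (m * (m + 1))
                    * float((cnt[nz] * (rsum[nz] / cnt[nz] - (m + 1) / 2.0) ** 2).sum())
                    / tc
                )
            H[s] = h
            P[s] = stats.chi2.sf(h, n_groups - 1)
            status[s] = "tested"
        table = self.haplo.snp_map.copy()
        table["n_groups"] = NG
        table["H"] = H
        table["df"] = DF
        table["p"] = P
        table["neglog10p"] = -np.log10(P)
        table["status"] = status
        n_tested = int((table["status"] == "tested").sum())
        # informational only: the scan ranks peaks, it does not threshold
        table["p_bonferroni"] = np.clip(P * max(n_tested, 1), 0.0, 1.0)
        return HaplotypeScanResults(model=self, table=table, min_groups=min_groups, min_group_size=min_group_size)


class HaplotypeScanResults:
    """Results of a haplotype scan: per-SNP track plus QTL utilities."""

    def __init__(self, model: HaplotypeScan, table: pd.DataFrame, min_groups: int, min_group_size: int):
        self.model = model
        self.table = table
        self.min_groups = min_groups
        self.min_group_size = min_group_size

    @property
    def neglog10p(self) -> np.ndarray:
        return self.table["neglog10p"].to_numpy()

    def find_peaks(self, min_distance: int = 100, n_top: Optional[int] = 8) -> pd.DataFrame:
        """Call QTL peaks on the -log10 P track (map order).

        ``min_distance`` is in SNP-index units, as in the reference
        peak-finding routine; bp positions are reported alongside.
        """
        hits = find_peaks(self.neglog10p, min_distance=min_distance, n_top=n_top)
        rows = []
        for rank, (idx, h) in enumerate(hits, start=1):
            rec = self.table.iloc[idx]
            rows.append(
                QTLPeak(
                    snp_id=str(rec["snp_id"]),
                    chrom=int(rec["chrom"]),
                    pos=int(rec["pos"]),
                    index=idx,
                    neglog10p=float(h),
                    rank=rank,
                )
            )
        return pd.DataFrame([r.__dict__ for r in rows], columns=["snp_id", "chrom", "pos", "index", "neglog10p", "rank"])

    def haplotype_effects(self, snp_id: str) -> EffectVector:
        """Mean phenotype per founder group at one SNP (see
        :func:`haplotype_effects`)."""
        idx = self.model.haplo.snp_index(snp_id)
        return _effects_at(self.model.labels[:, idx], self.model.y, snp_id)

    def summary(self, min_distance: int = 100, n_top: Optional[int] = 8) -> str:
        """Plain-text summary: scan header plus the top QTL peaks."""
        t = self.table
        n_tested = int((t["status"] == "tested").sum())
        n_disc = int((t["status"] == "discarded").sum())
        lines = [
            "Haplotype-based GWAS (Kruskal-Wallis scan)",
            "=" * 58,
            f"trait: {self.model.trait}   environment: {self.model.environment}",
            f"lines: {self.model.y.size}   SNPs: {len(t)} "
            f"(tested {n_tested}, discarded {n_disc})",
            f"group rules: >= {self.min_groups} haplotype groups, "
            f"group size >= {self.min_group_size}",
            "",
            f"top peaks (min index distance {min_distance}):",
            f"{'rank':>4} {'snp_id':>12} {'chrom':>5} {'pos':>12} {'-log10P':>8}",
        ]
        for _, r in self.find_peaks(min_distance=min_distance, n_top=n_top).iterrows():
            lines.append(
                f"{int(r['rank']):>4} {r['snp_id']:>12} {int(r['chrom']):>5} "
                f"{int(r['pos']):>12} {r['neglog10p']:>8.3f}"
            )
        return "\n".join(lines)

    def manhattan(self, ax=None, min_distance: int = 100, n_top: Optional[int] = 8):
        """Manhattan plot of the -log10 P track with called peaks marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        t = self.table
        for ch, grp in t.groupby("chrom"):
            ax.scatter(grp.index, grp["neglog10p"], s=4, label=None,
                       color="tab:blue" if ch % 2 else "tab:cyan")
        peaks = self.find_peaks(min_distance=min_distance, n_top=n_top)
        if len(peaks):
            ax.scatter(peaks["index"], peaks["neglog10p"], s=30, color="tab:red", marker="v")
        ax.set_xlabel("SNP index (map order)")
        ax.set_ylabel(r"$-\log_{10} P$")
        ax.set_title(f"{self.model.trait} (env {self.model.environment})")
        return ax


def run_gwas(
    haplo: HaplotypeMatrix,
    pheno: pd.DataFrame,
    trait: str,
    environment: Optional[int] = None,
    min_groups: int = 3,
    min_group_size: int = 2,
) -> HaplotypeScanResults:
    """Convenience wrapper: build a :class:`HaplotypeScan` and fit it."""
    return HaplotypeScan(haplo, pheno, trait, environment).fit(
        min_groups=min_groups, min_group_size=min_group_size
    )


def _effects_at(labels: np.ndarray, y: np.ndarray, snp_id: str) -> EffectVector:
    means = np.full(8, np.nan)
    sizes = np.zeros(8, dtype=np.int64)
    for f in range(1, 9):
        sel = labels == f
        sizes[f - 1] = int(sel.sum())
        if sizes[f - 1] > 0:
            means[f - 1] = float(y[sel].mean())
    n_groups = int((sizes > 0).sum())
    if n_groups < 3:
        return EffectVector(snp_id=snp_id, means=np.full(8, np.nan), group_sizes=sizes, discarded=True)
    return EffectVector(snp_id=snp_id, means=means, group_sizes=sizes, discarded=False)


def haplotype_effects(
    haplo: HaplotypeMatrix,
    pheno: pd.DataFrame,
    snp_id: str,
    trait: str,
    environment: Optional[int] = None,
) -> EffectVector:
    """Length-8 vector of mean phenotype per founder haplotype at a SNP.

    Founders with no carriers are NaN; when fewer than 3 haplotype
    groups are present the whole vector is discarded (all-NaN).
    """
    model = HaplotypeScan(haplo, pheno, trait, environment)
    idx = haplo.snp_index(snp_id)
    return _effects_at(model.labels[:, idx], model.y, snp_id)


def effect_correlation(x: EffectVector, y: EffectVector) -> Tuple[float, float, int]:
    """Pearson correlation of two 8-founder effect vectors.

    Uses pairwise-complete founder entries; the two-sided p-value comes
    from the t transform with ``n_used - 2`` df.  With fewer than 3
    complete pairs the correlation is undefined and (NaN, NaN, n) is
    returned.
    """
    ok = np.isfinite(x.means) & np.isfinite(y.means)
    n_used = int(ok.sum())
    if n_used < 3:
        return (math.nan, math.nan, n_used)
    xv, yv = x.means[ok], y.means[ok]
    if np.std(xv) == 0 or np.std(yv) == 0:
        return (math.nan, math.nan, n_used)
    r, p = stats.pearsonr(xv, yv)
    return (float(r), float(p), n_used)


def group_compare(values_a: Sequence[float], values_b: Sequence[float]) -> Tuple[float, int, float]:
    """Two-sample pooled-variance (Student's) t-test, two-sided.

    Used to compare lines partitioned by a founder-allele class (for
    example the three founders sharing one allele of a candidate gene
    against the rest).  Returns ``(t, df, p)``.

    Degenerate case: zero pooled variance gives ``(0, df, 1.0)`` when
    the means are equal, and ``(+/-inf, df, 0.0)`` when they differ.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    df = a.size + b.size - 2
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if a.mean() == b.mean():
            return (0.0, df, 1.0)
        return (math.copysign(math.inf, a.mean() - b.mean()), df, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return (float(t), df, float(p))
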