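"""Shared statistical kernels.

Fisher/hypergeometric enrichment with odds ratios and confidence
intervals, Benjamini-Hochberg FDR, Spearman correlation (exact permutation
p for small n), Wilcoxon rank-sum with effect size, and nearest-TSS
gene-set enrichment.

Conventions: p-values two-sided unless stated; odds ratios use the
Haldane-Anscombe +0.5 correction only when a cell is zero, and only for
the ratio and its CI — the p-value always comes from the uncorrected
exact distribution.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .intervals import nearest_tss

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "CorrelationResult",
    "fisher_exact",
    "bh_fdr",
    "spearman",
    "spearman_matrix",
    "wilcoxon_rank_sum",
    "geneset_enrichment_nearest_tss",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows = condition, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    ci_low: float
    ci_high: float
    test_name: str = "fisher_exact"


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def fisher_exact(
    table: ContingencyTable, alternative: str = "two-sided", ci_level: float = 0.95
) -> EnrichmentResult:
    """Exact Fisher test with Haldane-corrected OR and log-normal CI.

    The two-sided p sums hypergeometric probabilities of tables (at fixed
    margins) no more probable than the observed one. The CI is a normal
    approximation on the log odds ratio of the (+0.5 if any zero cell)
    corrected table.
    """
    arr = table.as_array()
    _, p = sps.fisher_exact(arr, alternative=alternative)
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.5 + ci_level / 2)
    return EnrichmentResult(
        odds_ratio=orr,
        p_value=float(min(p, 1.0)),
        ci_low=math.exp(math.log(orr) - z * se),
        ci_high=math.exp(math.log(orr) + z * se),
    )


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values, order-matched to the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 8
) -> CorrelationResult:
    """Spearman rank correlation.

    rho is the Pearson correlation of mid-ranks. For n <= ``exact_max_n``
    the p-value enumerates all n! rank permutations (two-sided on |rho|);
    larger n uses the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    n = len(x)
    rx, ry = _rank(x), _rank(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return CorrelationResult(rho=float("nan"), p_value=1.0, n=n)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt((rxc**2).sum() * (ryc**2).sum())
        obs = abs(rho)
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = float(np.dot(rxc, ryc[list(perm)])) / denom
            if abs(r) >= obs - 1e-12:
                hits += 1
            total += 1
        p = hits / total
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, p_value=min(p, 1.0), n=n)


def spearman_matrix(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman between paired rows of X and Y (same shape).

    Vectorized t-approximation path used for the bulk pair-linking stages;
    returns (rho, p) arrays of length X.shape[0].
    """
    n = X.shape[1]
    RX = sps.rankdata(X, axis=1, method="average")
    RY = sps.rankdata(Y, axis=1, method="average")
    RX = RX - RX.mean(axis=1, keepdims=True)
    RY = RY - RY.mean(axis=1, keepdims=True)
    sx = np.sqrt((RX**2).sum(axis=1))
    sy = np.sqrt((RY**2).sum(axis=1))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (RX * RY).sum(axis=1) / denom
    rho = np.where(denom == 0, np.nan, rho)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1 - rho**2))
    p = 2 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(rho), 1.0, np.minimum(p, 1.0))
    return rho, p


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_max_total: int = 10
) -> tuple[float, float, float]:
    """Two-sided Wilcoxon/Mann-Whitney test with effect size r.

    Exact enumeration when n_x + n_y <= ``exact_max_total`` and no ties;
    otherwise the tie-corrected normal approximation. r = |z| / sqrt(n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(nx * ny / 2), 1.0, 0.0
    has_ties = len(np.unique(pooled)) < nx + ny
    method = "exact" if (nx + ny <= exact_max_total and not has_ties) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    p = float(res.pvalue)
    # z from the tie-corrected normal approximation (for r even on exact path)
    ranks = _rank(pooled)
    mu = nx * ny / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    n = nx + ny
    sigma2 = nx * ny / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    z = (u - mu) / math.sqrt(sigma2) if sigma2 > 0 else 0.0
    r = abs(z) / math.sqrt(n)
    return u, min(p, 1.0), r


def geneset_enrichment_nearest_tss(
    peaks: pd.DataFrame,
    tss_table: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Hypergeometric enrichment of peak-assigned genes in gene sets.

    Each peak is assigned the gene with the nearest expressed TSS; for each
    set the overlap between peak-assigned genes and the set is tested
    against the expressed-gene universe by the hypergeometric upper tail,
    with BH correction across sets.
    """
    universe = tss_table.loc[tss_table.get("expressed", True), "gene_id"]
    universe = set(universe)
    missing = [
        name for name, genes in gene_sets.items()
        if not set(genes) <= universe
    ]
    if missing:
        raise ValueError(f"gene sets with genes outside tss_table: {missing}")
    assigned = nearest_tss(peaks, tss_table)
    hit_genes = set(assigned["gene_id"].dropna())
    N = len(universe)
    K = len(hit_genes)
    rows = []
    for name, genes in gene_sets.items():
        genes = set(genes) & universe
        if not genes:
            warnings.warn(f"gene set {name!r} empty after universe filter")
            continue
        m = len(genes)
        k = len(genes & hit_genes)
        p = float(sps.hypergeom.sf(k - 1, N, m, K))
        rows.append({"set": name, "overlap": k, "set_size": m, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
    return df
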