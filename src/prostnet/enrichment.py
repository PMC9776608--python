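"""Gene-level statistics for transcriptomic meta-analysis.

Implements the scoring pipeline used to interpret two-group expression
experiments (e.g. castration vs. sham, antiandrogen vs. vehicle):

* ranking genes by the signed log10 p-value, the sign taken from the
  log2 fold-change;
* filtering differentially expressed genes (DEGs) at adjusted p < 0.05
  and |log2FC| > 1 (strict inequalities), with Benjamini–Hochberg FDR
  adjustment;
* pre-ranked gene-set enrichment: weighted Kolmogorov–Smirnov-style
  running sum, gene-permutation null, normalized enrichment score and
  leading edge;
* hypergeometric overrepresentation of a gene set in a DEG list;
* per-sample gene-set activity scores (mean of per-gene z-scores) with a
  two-group Wilcoxon rank-sum comparison.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "RankedList",
    "GseaScore",
    "EnrichmentResult",
    "OraResult",
    "RankSumResult",
    "rank_statistic",
    "build_ranked_list",
    "bh_adjust",
    "deg_filter",
    "gsea_es",
    "gsea_permutation",
    "ora_hypergeom",
    "set_activity_scores",
    "ranksum_test",
]

DE_COLUMNS = ("gene", "log2fc", "pvalue")


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (GMT-style)."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(map(str, self.members)))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class RankedList:
    """Genes in descending order of the ranking statistic.

    Ties in the statistic are broken lexicographically by gene identifier
    so the order is fully deterministic.
    """

    genes: tuple[str, ...]
    stats: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "stats", np.asarray(self.stats, dtype=float))
        if len(self.genes) != len(self.stats):
            raise ValueError("genes and stats must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GseaScore:
    """Enrichment score with its running sum, for one set on one list."""

    es: float
    running_sum: np.ndarray
    hit_indices: np.ndarray
    leading_edge: tuple[str, ...]
    overlap: int

    @property
    def empty_overlap(self) -> bool:
        return self.overlap == 0


@dataclass(frozen=True)
class EnrichmentResult:
    """Permutation-calibrated enrichment of one gene set."""

    set_name: str
    es: float
    nes: float
    p_perm: float
    n_perm: int
    leading_edge: tuple[str, ...]
    overlap: int


@dataclass(frozen=True)
class OraResult:
    """Hypergeometric overrepresentation of a set in a DEG list.

    ``k`` of the ``n`` DEGs fall in the set of size ``K`` within a
    universe of ``N`` genes; ``p_hyper`` is the exact upper tail
    P(X ≥ k).
    """

    set_name: str
    k: int
    n: int
    K: int
    N: int
    p_hyper: float
    adj_p: float = field(default=float("nan"))


@dataclass(frozen=True)
class RankSumResult:
    """Two-sided Wilcoxon rank-sum comparison of two groups."""

    statistic: float  # rank sum of the first group
    pvalue: float
    exact: bool


def _validate_p(p, name: str = "p") -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (not np.all(np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1)):
        raise ValueError(f"{name}-values must lie in (0, 1]")
    return p


def rank_statistic(log2fc, p):
    """Signed log10 p-value: ``sign(log2fc) · (−log10 p)``.

    Strongly significant upregulated genes score high, downregulated low;
    a fold-change of exactly zero contributes sign 0.  Accepts scalars or
    arrays; p must lie in (0, 1].
    """
    p = _validate_p(p)
    out = np.sign(log2fc) * (-np.log10(p))
    # normalize -0.0 from sign(0) * positive
    out = out + 0.0
    return float(out) if out.ndim == 0 else out


def build_ranked_list(table: pd.DataFrame) -> RankedList:
    """Rank a DE table by the signed log10 p statistic, descending.

    ``table`` needs columns ``gene``, ``log2fc`` and ``pvalue``; gene
    identifiers must be unique.  Ties are broken lexicographically by
    identifier.
    """
    _check_de_table(table)
    stat = rank_statistic(table["log2fc"].to_numpy(), table["pvalue"].to_numpy())
    order = sorted(
        range(len(table)),
        key=lambda i: (-stat[i], str(table["gene"].iloc[i])),
    )
    genes = tuple(str(table["gene"].iloc[i]) for i in order)
    return RankedList(genes=genes, stats=stat[order])


def _check_de_table(table: pd.DataFrame, need_adj: bool = False) -> None:
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    if table["gene"].duplicated().any():
        dups = table.loc[table["gene"].duplicated(), "gene"].unique()[:5]
        raise ValueError(f"duplicate gene identifiers: {list(dups)}")
    _validate_p(table["pvalue"].to_numpy())
    if need_adj:
        if "adj_p" not in table.columns or table["adj_p"].isna().any():
            raise ValueError(
                "adjusted p-values missing: run bh_adjust on the table first"
            )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = _validate_p(np.atleast_1d(p_values))
    if p.size == 0:
        return p
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def deg_filter(
    table: pd.DataFrame,
    alpha: float = 0.05,
    min_abs_lfc: float = 1.0,
    direction: str = "both",
) -> list[str]:
    """Differentially expressed genes at adj p < ``alpha``, |log2FC| > ``min_abs_lfc``.

    Both thresholds are strict.  ``direction`` selects "both" (|log2FC|),
    "up" (log2FC > threshold) or "down" (log2FC < −threshold).  The table
    must already carry adjusted p-values.
    """
    _check_de_table(table, need_adj=True)
    if direction not in ("both", "up", "down"):
        raise ValueError(f"direction must be both/up/down, got {direction!r}")
    lfc = table["log2fc"].to_numpy()
    sig = table["adj_p"].to_numpy() < alpha
    if direction == "both":
        sig &= np.abs(lfc) > min_abs_lfc
    elif direction == "up":
        sig &= lfc > min_abs_lfc
    else:
        sig &= lfc < -min_abs_lfc
    return [str(g) for g in table.loc[sig, "gene"]]


# ---------------------------------------------------------------------------
# Pre-ranked GSEA


def gsea_es(
    ranked: RankedList, gene_set: GeneSet, weight: float = 1.0
) -> GseaScore:
    """Weighted running-sum enrichment score of a set on a ranked list.

    Walking the list top to bottom, the running sum rises by
    ``|s_i|^weight / Σ_hits |s|^weight`` at member genes and falls by
    ``1/(N − K)`` at non-members; the ES is the signed extremum (an exact
    magnitude tie between the positive and negative extremum resolves to
    the positive one).  The
    leading edge contains the members at or before the maximum (ES > 0)
    or at or after the minimum (ES < 0).  A set covering the whole list
    is degenerate (no miss decrement) and raises; a set with no overlap
    returns an empty-overlap score with ES = NaN.
    """
    N = len(ranked)
    member = np.fromiter(
        (g in gene_set.members for g in ranked.genes), dtype=bool, count=N
    )
    hits = np.flatnonzero(member)
    K = hits.size
    if K == 0:
        return GseaScore(
            es=float("nan"),
            running_sum=np.zeros(N),
            hit_indices=hits,
            leading_edge=(),
            overlap=0,
        )
    if K == N:
        raise ValueError(
            "gene set covers the entire ranked list; miss decrement undefined"
        )
    w = np.abs(ranked.stats) ** weight
    nr = w[hits].sum()
    steps = np.full(N, -1.0 / (N - K))
    if nr > 0:
        steps[hits] = w[hits] / nr
    else:
        # all member statistics are zero: fall back to unweighted hits
        steps[hits] = 1.0 / K
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    if es >= 0:
        lead = hits[hits <= i_max]
    else:
        lead = hits[hits >= i_min]
    return GseaScore(
        es=float(es),
        running_sum=running,
        hit_indices=hits,
        leading_edge=tuple(ranked.genes[i] for i in lead),
        overlap=int(K),
    )


def _permutation_es(
    stats_abs_w: np.ndarray, K: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES of ``n_perm`` random size-K member sets on a fixed ranked list."""
    N = stats_abs_w.size
    # random K-subsets without replacement, vectorized over permutations
    keys = rng.random((n_perm, N))
    idx = np.argpartition(keys, K - 1, axis=1)[:, :K]
    member = np.zeros((n_perm, N), dtype=bool)
    np.put_along_axis(member, idx, True, axis=1)
    w_hit = np.where(member, stats_abs_w, 0.0)
    nr = w_hit.sum(axis=1, keepdims=True)
    miss = -1.0 / (N - K)
    ratio = np.zeros_like(w_hit)
    np.divide(w_hit, nr, out=ratio, where=nr > 0)
    inc = np.where(member, ratio, miss)
    zero_nr = (nr[:, 0] == 0)
    if zero_nr.any():
        inc[zero_nr] = np.where(member[zero_nr], 1.0 / K, miss)
    running = np.cumsum(inc, axis=1)
    hi = running.max(axis=1)
    lo = running.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


def gsea_permutation(
    ranked: RankedList,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
) -> EnrichmentResult:
    """Gene-permutation null for the enrichment score.

    Draws ``n_perm`` random member sets of the observed overlap size from
    the ranked universe and compares |ES| among permutations whose ES has
    the sign of the observed one:

    * ``p_perm = (1 + #{|ES_perm| ≥ |ES_obs|}) / (1 + #sign-matched)``
    * ``NES = ES_obs / mean(|ES_perm| among sign-matched)``

    Deterministic under ``seed``.  Requires ``n_perm ≥ 10``.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    score = gsea_es(ranked, gene_set, weight=weight)
    if score.empty_overlap:
        return EnrichmentResult(
            set_name=gene_set.name,
            es=float("nan"),
            nes=float("nan"),
            p_perm=float("nan"),
            n_perm=n_perm,
            leading_edge=(),
            overlap=0,
        )
    rng = np.random.default_rng(seed)
    w = np.abs(ranked.stats) ** weight
    es_perm = _permutation_es(w, score.overlap, n_perm, rng)
    same_sign = es_perm * score.es >= 0
    n_same = int(same_sign.sum())
    n_extreme = int((np.abs(es_perm[same_sign]) >= abs(score.es)).sum())
    p_perm = (1 + n_extreme) / (1 + n_same)
    mean_abs = float(np.abs(es_perm[same_sign]).mean()) if n_same else float("nan")
    nes = score.es / mean_abs if n_same and mean_abs > 0 else float("nan")
    return EnrichmentResult(
        set_name=gene_set.name,
        es=score.es,
        nes=float(nes),
        p_perm=float(p_perm),
        n_perm=n_perm,
        leading_edge=score.leading_edge,
        overlap=score.overlap,
    )


# ---------------------------------------------------------------------------
# Overrepresentation


def ora_hypergeom(
    deg: list[str], gene_set: GeneSet, universe: list[str]
) -> OraResult:
    """Upper-tail hypergeometric overrepresentation test.

    With ``N`` universe genes of which ``K`` belong to the set, and ``n``
    DEGs of which ``k`` overlap the set, returns the exact
    P(X ≥ k) for X ~ Hypergeometric(N, K, n).  The DEG list must be a
    subset of the universe; the set is intersected with the universe.
    """
    uni = set(map(str, universe))
    if len(uni) != len(universe):
        raise ValueError("universe contains duplicate genes")
    deg_set = set(map(str, deg))
    stray = sorted(deg_set - uni)
    if stray:
        raise ValueError(f"DEG genes not in universe: {stray[:10]}")
    members = gene_set.members & uni
    k = len(deg_set & members)
    n, K, N = len(deg_set), len(members), len(uni)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OraResult(set_name=gene_set.name, k=k, n=n, K=K, N=N, p_hyper=min(p, 1.0))


# ---------------------------------------------------------------------------
# Gene-set activity scores and two-group comparison


def set_activity_scores(expr: pd.DataFrame, gene_set: GeneSet) -> pd.Series:
    """Per-sample activity of a gene set in an expression matrix.

    ``expr`` holds samples in rows and genes in columns.  Each set gene is
    z-scored across samples (sample standard deviation; constant genes
    score zero) and the per-sample mean of those z-scores is returned.
    """
    present = [g for g in expr.columns if g in gene_set.members]
    if not present:
        raise ValueError(
            f"no genes of set {gene_set.name!r} present in the expression matrix"
        )
    sub = expr[present].to_numpy(dtype=float)
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    z = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.Series(z.mean(axis=1), index=expr.index, name=gene_set.name)


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1, n = len(a), len(pooled)
    w_obs = ranks[:n1].sum()
    e_w = n1 * (n + 1) / 2.0
    dev_obs = abs(w_obs - e_w)
    total = math.comb(n, n1)
    extreme = 0
    for combo in itertools.combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        if abs(w - e_w) >= dev_obs - 1e-12:
            extreme += 1
    return float(w_obs), extreme / total


def ranksum_test(scores_a, scores_b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Uses the exact permutation null, enumerated over all group
    assignments (ties handled through midranks), when both groups have at
    most 8 values; otherwise the normal approximation with tie
    correction.  The reported statistic is the rank sum of the first
    group.  Both groups need at least 2 values.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.size <= 8 and b.size <= 8:
        w, p = _exact_ranksum_p(a, b)
        return RankSumResult(statistic=w, pvalue=p, exact=True)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    w = float(res.statistic + a.size * (a.size + 1) / 2.0)  # U1 -> rank sum
    return RankSumResult(statistic=w, pvalue=float(res.pvalue), exact=False)
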