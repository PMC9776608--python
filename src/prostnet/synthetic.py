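"""Synthetic two-group expression experiments with planted gene sets.

Emulates the statistical structure of a castration-vs-sham or
treated-vs-control microarray comparison: a gene universe with Gaussian
log-scale expression, two sample groups, and one or more "planted" gene
sets whose members are shifted by a configurable effect size in group B.
Every stage of the enrichment pipeline (DE testing, ranking, filtering,
GSEA, ORA, activity scoring) can thus be exercised against a known ground
truth without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import GeneSet, bh_adjust, set_activity_scores

__all__ = [
    "PlantedSet",
    "SyntheticSpec",
    "default_spec",
    "generate_expression",
    "generate_de_table",
    "generate_activity_groups",
]


@dataclass(frozen=True)
class PlantedSet:
    """A gene set shifted by ``delta`` expression units in group B.

    ``direction`` "up" raises group B by ``delta``; "down" lowers it.
    """

    gene_set: GeneSet
    delta: float
    direction: str = "up"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")

    @property
    def signed_delta(self) -> float:
        return self.delta if self.direction == "up" else -self.delta


@dataclass(frozen=True)
class SyntheticSpec:
    """Design of a synthetic two-group experiment.

    ``n_genes`` background genes named ``G0000`` …; ``n_per_group``
    samples per condition; ``base_mean``/``base_sd`` parametrize the
    Gaussian background (log2-intensity-like units).  Planted sets may
    overlap only with consistent directions.
    """

    n_genes: int = 2000
    n_per_group: int = 10
    planted_sets: tuple[PlantedSet, ...] = ()
    base_mean: float = 8.0
    base_sd: float = 1.0
    seed: int | None = 1

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if self.base_sd <= 0:
            raise ValueError("base_sd must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        universe = set(self.gene_names())
        signed: dict[str, float] = {}
        for ps in self.planted_sets:
            outside = ps.gene_set.members - universe
            if outside:
                raise ValueError(
                    f"planted set {ps.gene_set.name!r} has members outside the "
                    f"universe, e.g. {sorted(outside)[:5]}"
                )
            for g in ps.gene_set.members:
                if g in signed and signed[g] * ps.signed_delta < 0:
                    raise ValueError(
                        f"gene {g!r} planted with conflicting directions"
                    )
                signed[g] = ps.signed_delta

    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes - 1)))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    def sample_names(self) -> list[str]:
        return [f"A{j:02d}" for j in range(self.n_per_group)] + [
            f"B{j:02d}" for j in range(self.n_per_group)
        ]

    def shift_vector(self) -> np.ndarray:
        """Per-gene signed shift applied to group B."""
        idx = {g: i for i, g in enumerate(self.gene_names())}
        delta = np.zeros(self.n_genes)
        for ps in self.planted_sets:
            for g in ps.gene_set.members:
                delta[idx[g]] = ps.signed_delta
        return delta


def default_spec(seed: int | None = 1, n_decoys: int = 0) -> SyntheticSpec:
    """The default planted design: one 50-gene up-set, δ = 2, n = 10/group.

    With ``n_decoys`` > 0, that many additional unshifted 50-gene decoy
    sets (disjoint from the planted set and from each other) are declared
    with δ = 0, so enrichment rankings can be benchmarked against
    same-size nulls.
    """
    names = SyntheticSpec(n_genes=2000, n_per_group=10, seed=seed).gene_names()
    planted = [
        PlantedSet(GeneSet("PLANTED_UP", frozenset(names[:50])), delta=2.0)
    ]
    for j in range(n_decoys):
        lo = 50 * (j + 1)
        planted.append(
            PlantedSet(
                GeneSet(f"DECOY_{j:02d}", frozenset(names[lo : lo + 50])), delta=0.0
            )
        )
    return SyntheticSpec(
        n_genes=2000,
        n_per_group=10,
        planted_sets=tuple(planted),
        base_mean=8.0,
        base_sd=1.0,
        seed=seed,
    )


def generate_expression(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Draw one expression matrix under the spec's design.

    Returns ``(expr, groups, truth)``: ``expr`` is samples × genes,
    values drawn independently as
    N(base_mean + signed δ_g · [sample in B], base_sd²); ``groups`` maps
    sample id to "A"/"B"; ``truth`` records each planted set's members
    and signed shift.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_names()
    samples = spec.sample_names()
    m = spec.n_per_group
    values = rng.normal(
        spec.base_mean, spec.base_sd, size=(2 * m, spec.n_genes)
    )
    values[m:] += spec.shift_vector()[None, :]
    expr = pd.DataFrame(values, index=samples, columns=genes)
    groups = pd.Series(["A"] * m + ["B"] * m, index=samples, name="group")
    truth = {
        ps.gene_set.name: {
            "members": sorted(ps.gene_set.members),
            "delta": ps.delta,
            "signed_delta": ps.signed_delta,
        }
        for ps in spec.planted_sets
    }
    return expr, groups, truth


def generate_de_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Per-gene Welch t-test table for a draw from the spec.

    ``log2fc`` is mean(B) − mean(A) (the values are already on a
    log-like scale), ``pvalue`` the two-sided Welch p, ``adj_p`` its
    Benjamini–Hochberg adjustment.  p-values are floored at the smallest
    positive float so the table never carries an exact zero.
    """
    expr, groups, _ = generate_expression(spec)
    a = expr.loc[groups == "A"].to_numpy()
    b = expr.loc[groups == "B"].to_numpy()
    t, p = stats.ttest_ind(b, a, axis=0, equal_var=False)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {
            "gene": expr.columns,
            "log2fc": b.mean(axis=0) - a.mean(axis=0),
            "pvalue": p,
        }
    )
    table["adj_p"] = bh_adjust(table["pvalue"].to_numpy())
    return table


def generate_activity_groups(
    spec: SyntheticSpec, gene_set: GeneSet
) -> tuple[pd.Series, pd.Series]:
    """Gene-set activity scores split by group, for a planted set.

    Draws an expression matrix, computes per-sample set-activity scores
    and returns them as ``(scores_A, scores_B)``.  The set must be one of
    the spec's planted sets (use δ = 0 to declare a null set).
    """
    if gene_set.name not in {ps.gene_set.name for ps in spec.planted_sets}:
        raise ValueError(
            f"set {gene_set.name!r} is not planted in this spec; declare it "
            "(with delta=0 for a null set) before scoring"
        )
    expr, groups, _ = generate_expression(spec)
    scores = set_activity_scores(expr, gene_set)
    return scores[groups == "A"], scores[groups == "B"]
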