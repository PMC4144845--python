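"""Suppression genetic interactions and epistasis classification.

Deletion of gene B suppresses deletion of gene A when A is the sicker single
mutant and the double mutant is fitter than A beyond A's measurement noise:
F_A < F_B and F_AB > F_A + sigma_A.  The per-gene suppressor fraction is
correlated with single-deletion fitness (Spearman, on raw data).

Epistasis between two mutations is measured against the multiplicative null,
eps = F_ab - F_a * F_b (fitness rescaled so F_wt = 1).  Sign epistasis:
one mutation's fitness effect changes sign between genetic backgrounds;
reciprocal sign epistasis: both do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "find_suppressors",
    "per_gene_suppressor_fraction",
    "suppression_fitness_correlation",
    "epistasis",
    "sign_epistasis_bootstrap",
    "suppression_wilcoxon",
    "cross_environment_consistency",
]


def find_suppressors(records: pd.DataFrame) -> pd.DataFrame:
    """Flag suppression pairs by the rule F_A < F_B and F_AB > F_A + sigma_A.

    ``records`` needs columns ``gene_a, gene_b, f_a, f_b, f_ab, sigma_a``.
    Records with a missing ``sigma_a`` (or other fitness field) are dropped.
    """
    required = ["gene_a", "gene_b", "f_a", "f_b", "f_ab", "sigma_a"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = records.dropna(subset=required[2:]).copy()
    df["suppressor"] = (df["f_a"] < df["f_b"]) & (df["f_ab"] > df["f_a"] + df["sigma_a"])
    return df


def per_gene_suppressor_fraction(
    flagged: pd.DataFrame,
    denominator: str = "tested",
) -> pd.DataFrame:
    """Per-gene-A fraction of suppressing partners.

    ``denominator='tested'`` divides by all partners tested for the gene;
    ``'interactions'`` divides by the gene's genetic interactions (requires a
    boolean ``is_interaction`` column).
    """
    if denominator == "tested":
        out = flagged.groupby("gene_a").agg(
            fitness=("f_a", "first"), fraction=("suppressor", "mean"),
            n=("suppressor", "size"),
        )
    elif denominator == "interactions":
        if "is_interaction" not in flagged.columns:
            raise ValueError("'interactions' denominator needs an is_interaction column")
        sub = flagged[flagged["is_interaction"].astype(bool)]
        out = sub.groupby("gene_a").agg(
            fitness=("f_a", "first"), fraction=("suppressor", "mean"),
            n=("suppressor", "size"),
        )
    else:
        raise ValueError("denominator must be 'tested' or 'interactions'")
    return out.reset_index()


@dataclass
class SuppressionCorrelation:
    rho: float
    pvalue: float
    n: int
    binned: pd.DataFrame


def suppression_fitness_correlation(per_gene: pd.DataFrame) -> SuppressionCorrelation:
    """Spearman correlation between single-deletion fitness and suppressor
    fraction, with quartile-binned medians for boxplot-style reporting."""
    if len(per_gene) < 10:
        raise ValueError("need >= 10 genes")
    if per_gene["fraction"].nunique() == 1:
        return SuppressionCorrelation(float("nan"), float("nan"), len(per_gene),
                                      pd.DataFrame())
    res = stats.spearmanr(per_gene["fitness"], per_gene["fraction"])
    bins = pd.qcut(per_gene["fitness"], 4, labels=["Q1", "Q2", "Q3", "Q4"])
    binned = per_gene.groupby(bins, observed=True).agg(
        median_fitness=("fitness", "median"),
        median_fraction=("fraction", "median"),
        n=("fraction", "size"),
    ).reset_index(names="quartile")
    return SuppressionCorrelation(float(res.statistic), float(res.pvalue),
                                  len(per_gene), binned)


@dataclass
class EpistasisResult:
    epsilon: float
    classification: str  # none | magnitude | sign | reciprocal_sign
    effects: dict[str, float]


def epistasis(f_wt: float, f_a: float, f_b: float, f_ab: float,
              tol: float = 1e-12) -> EpistasisResult:
    """Deviation from the multiplicative expectation and its sign structure.

    Fitness values are rescaled so F_wt = 1; eps = F_ab - F_a F_b.  A
    mutation shows a sign change when its fitness effect (beyond ``tol``)
    has opposite signs in the wild-type and in the other mutation's
    background.  Classification: ``reciprocal_sign`` if both mutations change
    sign, ``sign`` if exactly one, ``magnitude`` if |eps| > tol without a
    sign change, ``none`` otherwise.
    """
    if f_wt <= 0:
        raise ValueError("F_wt must be positive")
    fa, fb, fab = f_a / f_wt, f_b / f_wt, f_ab / f_wt
    eff = {
        "a_in_wt": fa - 1.0,
        "a_in_b": fab - fb,
        "b_in_wt": fb - 1.0,
        "b_in_a": fab - fa,
    }
    eps = fab - fa * fb

    def sign_change(in_wt: float, in_other: float) -> bool:
        return abs(in_wt) > tol and abs(in_other) > tol and (in_wt > 0) != (in_other > 0)

    flips = sign_change(eff["a_in_wt"], eff["a_in_b"]) + sign_change(
        eff["b_in_wt"], eff["b_in_a"]
    )
    if flips == 2:
        cls = "reciprocal_sign"
    elif flips == 1:
        cls = "sign"
    elif abs(eps) > tol:
        cls = "magnitude"
    else:
        cls = "none"
    return EpistasisResult(float(eps), cls, eff)


def sign_epistasis_bootstrap(
    sizes_wt,
    sizes_a,
    sizes_b,
    sizes_ab,
    n_boot: int = 2000,
    seed: int | None = None,
    ci: float = 0.95,
):
    """Bootstrap CI for the background-dependence of mutation b's effect.

    Statistic: (F_ab - F_a) - (F_b - F_wt) on mean colony sizes normalized to
    the wild-type mean in each resample.  Returns (statistic, lo, hi,
    significant) where significant means the percentile CI excludes 0.
    """
    rng = np.random.default_rng(seed)
    groups = [np.asarray(g, dtype=float) for g in (sizes_wt, sizes_a, sizes_b, sizes_ab)]

    def stat(samples) -> float:
        wt, a, b, ab = (s.mean() for s in samples)
        return (ab - a) / wt - (b - wt) / wt

    obs = stat(groups)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        boot[i] = stat([g[rng.integers(0, g.size, g.size)] for g in groups])
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return float(obs), float(lo), float(hi), bool(lo > 0 or hi < 0)


def suppression_wilcoxon(sizes_single, sizes_double) -> float:
    """One-sided Wilcoxon rank-sum p that the double mutant outgrows the
    sicker single mutant (colony-size replicates)."""
    return float(
        stats.mannwhitneyu(sizes_double, sizes_single, alternative="greater").pvalue
    )


def cross_environment_consistency(v1, v2) -> tuple[float, float]:
    """Spearman correlation of two genotypes' fitness across environments.

    Series inputs are aligned on their (environment) index; at least 5 shared
    environments are required.
    """
    if isinstance(v1, pd.Series) and isinstance(v2, pd.Series):
        shared = v1.index.intersection(v2.index)
        v1, v2 = v1[shared], v2[shared]
    x = np.asarray(v1, dtype=float)
    y = np.asarray(v2, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need >= 5 shared environments")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
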