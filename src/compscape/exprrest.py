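"""Transcriptome comparison of wild-type / ancestor / evolved triplets.

Differential expression of a gene between two strains requires both a
fold-change of at least 1.7 (|mean log2 difference| >= log2 1.7) and a
two-sample t-test p < 0.05 on the replicate log-ratios, with technical
replicates averaged within biological replicate first.  Distances between
strain profiles are Euclidean over the union of DE genes, normalized to the
ancestor-wild-type distance; the fraction of ancestor-DE genes that shift
significantly back toward the wild-type level in the evolved line measures
expression restoration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEConfig",
    "call_de",
    "de_union",
    "distance_triangle",
    "restoration_fractions",
    "robustness_filter",
]


@dataclass
class DEConfig:
    fold_change: float = 1.7
    p_threshold: float = 0.05
    excluded_genes: tuple = ()

    def __post_init__(self):
        if self.fold_change <= 1:
            raise ValueError("fold-change threshold must exceed 1")

    @property
    def log2_threshold(self) -> float:
        return math.log2(self.fold_change)


def _bio_means(df: pd.DataFrame, bio_groups: Sequence[int] | None) -> pd.DataFrame:
    """Average technical replicates within biological replicates.

    ``bio_groups[i]`` is the biological-replicate id of column i; by default
    consecutive column pairs form one biological replicate (2 bio x 2 tech).
    """
    if bio_groups is None:
        bio_groups = [i // 2 for i in range(df.shape[1])]
    groups = pd.Series(list(bio_groups), index=df.columns)
    return df.T.groupby(groups).mean().T


def call_de(
    a: pd.DataFrame,
    b: pd.DataFrame,
    config: DEConfig | None = None,
    bio_groups: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-gene DE call between two strains' replicate log2-ratio matrices.

    Returns a frame indexed by gene with ``log2_diff`` (mean a - mean b), the
    t-test ``p`` and the boolean ``de`` flag.
    """
    config = config or DEConfig()
    if a.shape[0] != b.shape[0]:
        raise ValueError("matrices must cover the same genes")
    am = _bio_means(a, bio_groups)
    bm = _bio_means(b, bio_groups)
    if am.shape[1] < 2 or bm.shape[1] < 2:
        raise ValueError("need >= 2 biological replicates per strain")
    diff = am.mean(axis=1) - bm.mean(axis=1)
    t = stats.ttest_ind(am, bm, axis=1)
    p = pd.Series(t.pvalue, index=a.index)
    # zero variance in both groups: p is NaN; equal means -> 1, different -> 0
    nan = p.isna()
    p[nan & (diff.abs() <= 1e-12)] = 1.0
    p[nan & (diff.abs() > 1e-12)] = 0.0
    de = (diff.abs() >= config.log2_threshold) & (p < config.p_threshold)
    out = pd.DataFrame({"log2_diff": diff, "p": p, "de": de})
    out.loc[out.index.isin(config.excluded_genes), "de"] = False
    return out


def de_union(
    wt: pd.DataFrame,
    anc: pd.DataFrame,
    evo: pd.DataFrame,
    config: DEConfig | None = None,
    bio_groups: Sequence[int] | None = None,
) -> pd.Index:
    """Genes DE in at least one of the three pairwise comparisons."""
    config = config or DEConfig()
    flags = (
        call_de(anc, wt, config, bio_groups)["de"]
        | call_de(evo, wt, config, bio_groups)["de"]
        | call_de(evo, anc, config, bio_groups)["de"]
    )
    return flags.index[flags]


@dataclass
class TriangleResult:
    d_anc_wt: float  # normalized: always 1
    d_evo_wt: float
    d_evo_anc: float
    raw_anc_wt: float
    radii: dict[str, float] = field(default_factory=dict)
    n_genes: int = 0
    defined: bool = True


def distance_triangle(
    wt: pd.DataFrame,
    anc: pd.DataFrame,
    evo: pd.DataFrame,
    gene_set: Iterable[str] | None = None,
    config: DEConfig | None = None,
    bio_groups: Sequence[int] | None = None,
) -> TriangleResult:
    """Normalized Euclidean distance triangle between mean strain profiles.

    Distances are computed over ``gene_set`` (default: the union of DE genes
    across the three pairwise comparisons) between per-strain mean profiles
    (average over all replicates), then divided by the ancestor-wild-type
    distance.  Replicate-noise radii are the distances between the two
    biological-replicate means of each strain, on the same scale.
    """
    if gene_set is None:
        gene_set = de_union(wt, anc, evo, config, bio_groups)
    genes = pd.Index(gene_set)
    w, a, e = (m.loc[genes] for m in (wt, anc, evo))

    def dist(x: pd.Series, y: pd.Series) -> float:
        return float(np.linalg.norm(x - y))

    d_aw = dist(a.mean(axis=1), w.mean(axis=1))
    d_ew = dist(e.mean(axis=1), w.mean(axis=1))
    d_ea = dist(e.mean(axis=1), a.mean(axis=1))
    if d_aw == 0:
        return TriangleResult(np.nan, np.nan, np.nan, 0.0, {}, len(genes), False)
    radii = {}
    for name, m in (("wt", w), ("ancestor", a), ("evolved", e)):
        bm = _bio_means(m, bio_groups)
        radii[name] = dist(bm.iloc[:, 0], bm.iloc[:, 1]) / d_aw
    return TriangleResult(1.0, d_ew / d_aw, d_ea / d_aw, d_aw, radii, len(genes))


@dataclass
class RestorationResult:
    fraction_restored: float
    fraction_unrestored: float
    n_ancestor_de: int
    labels: pd.Series = field(repr=False, default=None)


def restoration_fractions(
    wt: pd.DataFrame,
    anc: pd.DataFrame,
    evo: pd.DataFrame,
    config: DEConfig | None = None,
    bio_groups: Sequence[int] | None = None,
) -> RestorationResult:
    """Fraction of deletion-responsive genes whose expression evolves back.

    Among genes DE in ancestor vs wild type, a gene is ``restored`` when it is
    also DE in evolved vs ancestor with the opposite sign (a significant shift
    back toward the wild-type level at the full DE threshold), ``unrestored``
    otherwise; all remaining genes are ``other``.
    """
    config = config or DEConfig()
    anc_de = call_de(anc, wt, config, bio_groups)
    evo_de = call_de(evo, anc, config, bio_groups)
    labels = pd.Series("other", index=anc.index, name="restoration")
    de_mask = anc_de["de"]
    restored = de_mask & evo_de["de"] & (
        np.sign(evo_de["log2_diff"]) == -np.sign(anc_de["log2_diff"])
    )
    labels[de_mask] = "unrestored"
    labels[restored] = "restored"
    n_de = int(de_mask.sum())
    if n_de == 0:
        return RestorationResult(float("nan"), float("nan"), 0, labels)
    n_restored = int((labels == "restored").sum())
    return RestorationResult(n_restored / n_de, 1.0 - n_restored / n_de, n_de, labels)


def robustness_filter(
    matrices: Mapping[str, pd.DataFrame],
    exclude_lists: Iterable[Iterable[str]],
) -> dict[str, pd.DataFrame]:
    """Drop the union of the exclusion lists (CNV genes, aneuploidy-responsive
    genes, growth-rate-correlated genes, stochastic genes) from every matrix,
    so that downstream statistics can be recomputed on the filtered set."""
    excluded: set[str] = set()
    for lst in exclude_lists:
        excluded |= set(lst)
    out = {}
    for name, m in matrices.items():
        keep = ~m.index.isin(excluded)
        filtered = m.loc[keep]
        if filtered.empty:
            raise ValueError("exclusion removed all genes; distances undefined")
        out[name] = filtered
    return out
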