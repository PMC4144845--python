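"""Statistics on mutation tables from evolved clones.

Covers the de-novo / secondary-ancestor classification of variants, the
nonsynonymous-excess test of coding SNPs (a Poisson-binomial tail over
site-averaged per-substitution probabilities), gene-level parallelism between
lines, permutation tests of the functional relatedness between the deleted
gene and the genes hit by de-novo mutations, promoter enrichment, and the
paralog filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._codons import BASES, CODON_AA

__all__ = [
    "classify_mutation_status",
    "ns_site_probabilities",
    "ns_site_probability",
    "poisson_binomial_tail",
    "ns_excess_test",
    "parallelism",
    "RelatednessAnnotation",
    "functional_relatedness_test",
    "promoter_enrichment",
    "paralog_filter",
]

logger = logging.getLogger(__name__)

_KEY = ["chrom", "pos", "ref", "alt"]


def classify_mutation_status(
    evolved: pd.DataFrame,
    ancestors: pd.DataFrame,
    line_to_ancestor: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign de-novo / ancestral status to variants.

    ``evolved`` has one row per variant per line (columns ``line`` + the
    variant key chrom/pos/ref/alt); ``ancestors`` one row per variant per
    ancestor strain (column ``ancestor`` + key).  A variant in an evolved line
    is ``de_novo`` when absent from its own ancestor; present in its own
    ancestor it is ``ancestral``; absent from its own ancestor but present in
    other ancestors it is flagged ``ambiguous`` and excluded from the de-novo
    set.  An ancestor variant private to that ancestor is a
    ``secondary_ancestor`` mutation; shared by several ancestors it is library
    ``background``.
    """
    anc_sets: dict[str, set[tuple]] = {
        a: set(map(tuple, g[_KEY].itertuples(index=False)))
        for a, g in ancestors.groupby("ancestor")
    }
    variant_count: dict[tuple, int] = {}
    for s in anc_sets.values():
        for v in s:
            variant_count[v] = variant_count.get(v, 0) + 1

    evolved = evolved.copy()
    statuses = []
    for rec in evolved.itertuples(index=False):
        key = (rec.chrom, rec.pos, rec.ref, rec.alt)
        own = anc_sets.get(line_to_ancestor[rec.line], set())
        if key in own:
            statuses.append("ancestral")
        elif variant_count.get(key, 0) > 0:
            statuses.append("ambiguous")
        else:
            statuses.append("de_novo")
    evolved["status"] = statuses

    ancestors = ancestors.copy()
    ancestors["status"] = [
        "secondary_ancestor"
        if variant_count[(rec.chrom, rec.pos, rec.ref, rec.alt)] == 1
        else "background"
        for rec in ancestors.itertuples(index=False)
    ]
    return evolved, ancestors


# ---------------------------------------------------------------------------
# nonsynonymous excess
# ---------------------------------------------------------------------------


def _validate_orfs(orfs: Mapping[str, str]) -> None:
    if not orfs:
        raise ValueError("empty ORF set")
    for name, seq in orfs.items():
        if len(seq) % 3 != 0:
            raise ValueError(f"ORF {name!r} length not divisible by 3")


def ns_site_probabilities(orfs: Mapping[str, str]) -> dict[tuple[str, str], float]:
    """For every substitution type ref->alt, the probability that it is
    nonsynonymous when placed on a random coding position carrying ``ref``.

    Stop gains count as nonsynonymous.  Substitution types whose reference
    base is absent from the ORF set are omitted.
    """
    _validate_orfs(orfs)
    ns = {(r, a): 0 for r in BASES for a in BASES if a != r}
    tot = {r: 0 for r in BASES}
    for seq in orfs.values():
        for cs in range(0, len(seq), 3):
            codon = seq[cs : cs + 3]
            aa = CODON_AA[codon]
            for within in range(3):
                ref = codon[within]
                tot[ref] += 1
                for alt in BASES:
                    if alt == ref:
                        continue
                    mutated = codon[:within] + alt + codon[within + 1 :]
                    if CODON_AA[mutated] != aa:
                        ns[(ref, alt)] += 1
    return {
        (r, a): ns[(r, a)] / tot[r] for (r, a) in ns if tot[r] > 0
    }


def ns_site_probability(ref: str, alt: str, orfs: Mapping[str, str]) -> float:
    """Probability that substituting ``alt`` at a random coding site carrying
    ``ref`` changes the encoded amino acid."""
    if ref not in BASES or alt not in BASES or ref == alt:
        raise ValueError("ref and alt must be distinct bases in ACGT")
    probs = ns_site_probabilities(orfs)
    if (ref, alt) not in probs:
        raise ValueError(f"reference base {ref!r} absent from the ORF set")
    return probs[(ref, alt)]


def poisson_binomial_tail(ps: Sequence[float], k: int) -> float:
    """P(X >= k) for X a sum of independent Bernoulli(p_i), by exact DP."""
    ps = np.asarray(ps, dtype=float)
    n = ps.size
    if not 0 <= k <= n:
        raise ValueError("k out of range")
    dist = np.zeros(n + 1)
    dist[0] = 1.0
    for p in ps:
        dist[1:] = dist[1:] * (1.0 - p) + dist[:-1] * p
        dist[0] *= 1.0 - p
    return float(dist[k:].sum())


@dataclass
class NsExcessResult:
    n_coding_snps: int
    n_nonsynonymous: int
    ns_fraction: float
    tail_probability: float
    site_probabilities: dict[tuple[str, str], float]


def ns_excess_test(snps: pd.DataFrame, orfs: Mapping[str, str]) -> NsExcessResult:
    """Tail probability of at least the observed number of amino-acid-changing
    substitutions under random coding placement.

    ``snps`` needs columns ``ref, alt, coding_effect`` (effects counted as
    nonsynonymous: nonsynonymous and nonsense).  Each observed substitution
    type contributes its site-averaged probability p_i; the tail
    P(X >= observed NS count) of the Poisson-binomial sum is computed exactly.
    """
    coding = snps[snps["coding_effect"].isin(
        ["synonymous", "nonsynonymous", "nonsense"])]
    if coding.empty:
        raise ValueError("no observed coding SNPs")
    probs = ns_site_probabilities(orfs)
    try:
        ps = [probs[(r, a)] for r, a in zip(coding["ref"], coding["alt"])]
    except KeyError as exc:  # pragma: no cover - invalid input
        raise ValueError(f"substitution type {exc} not representable on ORF set")
    k = int(coding["coding_effect"].isin(["nonsynonymous", "nonsense"]).sum())
    tail = poisson_binomial_tail(ps, k)
    return NsExcessResult(len(coding), k, k / len(coding), tail, probs)


# ---------------------------------------------------------------------------
# parallelism
# ---------------------------------------------------------------------------


@dataclass
class ParallelismResult:
    within_mean: float
    between_mean: float
    n_within_pairs: int
    n_between_pairs: int


def _shared_fraction(a: set, b: set, method: str) -> float | None:
    if not a and not b:
        return None  # excluded
    inter = len(a & b)
    if method == "jaccard":
        return inter / len(a | b)
    if method == "min":
        denom = min(len(a), len(b))
        return inter / denom if denom else 0.0
    raise ValueError("method must be 'jaccard' or 'min'")


def parallelism(
    gene_sets: Mapping[str, set],
    genotypes: Mapping[str, str],
    method: str = "jaccard",
) -> ParallelismResult:
    """Mean shared fraction of mutated genes for same- vs different-genotype
    line pairs.

    The default sharing metric is the Jaccard index |A&B|/|A|B|; pairs where
    both sets are empty are excluded (logged).
    """
    lines = sorted(gene_sets)
    within, between = [], []
    n_excluded = 0
    for i, li in enumerate(lines):
        for lj in lines[i + 1 :]:
            frac = _shared_fraction(set(gene_sets[li]), set(gene_sets[lj]), method)
            if frac is None:
                n_excluded += 1
                continue
            (within if genotypes[li] == genotypes[lj] else between).append(frac)
    if n_excluded:
        logger.info("parallelism: %d both-empty pairs excluded", n_excluded)
    return ParallelismResult(
        float(np.mean(within)) if within else float("nan"),
        float(np.mean(between)) if between else float("nan"),
        len(within),
        len(between),
    )


# ---------------------------------------------------------------------------
# functional relatedness
# ---------------------------------------------------------------------------


@dataclass
class RelatednessAnnotation:
    """Functional-relatedness annotation layers.

    ``complexes`` and ``categories`` map gene -> set of ids; ``gi_similarity``
    and ``co_expression`` map unordered gene pairs (sorted tuples) to Pearson
    correlations.
    """

    complexes: Mapping[str, set] = field(default_factory=dict)
    categories: Mapping[str, set] = field(default_factory=dict)
    gi_similarity: Mapping[tuple[str, str], float] = field(default_factory=dict)
    co_expression: Mapping[tuple[str, str], float] = field(default_factory=dict)

    @staticmethod
    def from_tables(
        complexes: pd.DataFrame | None = None,
        categories: pd.DataFrame | None = None,
        gi_similarity: pd.DataFrame | None = None,
        co_expression: pd.DataFrame | None = None,
    ) -> "RelatednessAnnotation":
        """Build from two-column (gene, id) and three-column (a, b, r) tables."""

        def gene_map(df):
            out: dict[str, set] = {}
            if df is None:
                return out
            gcol, icol = df.columns[:2]
            for g, i in zip(df[gcol], df[icol]):
                out.setdefault(g, set()).add(i)
            return out

        def pair_map(df):
            out: dict[tuple[str, str], float] = {}
            if df is None:
                return out
            a, b, r = df.columns[:3]
            for x, y, v in zip(df[a], df[b], df[r]):
                out[tuple(sorted((x, y)))] = float(v)
            return out

        return RelatednessAnnotation(
            gene_map(complexes), gene_map(categories),
            pair_map(gi_similarity), pair_map(co_expression),
        )


_BINARY_MEASURES = {"co_complex": "complexes", "co_category": "categories"}
_CONT_MEASURES = {"gi_profile_similarity": "gi_similarity",
                  "co_expression": "co_expression"}


@dataclass
class RelatednessResult:
    measure: str
    observed: float
    null_mean: float
    enrichment: float
    pvalue: float
    n_pairs: int
    n_shuffles: int


def functional_relatedness_test(
    ko_by_line: Mapping[str, str],
    genes_by_line: Mapping[str, Sequence[str]],
    annotation: RelatednessAnnotation,
    measure: str,
    n_shuffles: int = 1000,
    seed: int | None = None,
) -> RelatednessResult:
    """Permutation test: are de-novo-mutated genes functionally related to the
    line's deleted gene?

    The observed statistic is, over all (knock-out gene, mutated gene) pairs
    with annotation coverage, the fraction co-annotated (binary measures
    ``co_complex`` / ``co_category``) or the mean pairwise similarity
    (``gi_profile_similarity`` / ``co_expression``).  The null reassigns the
    per-line mutated-gene lists to knock-out genotypes uniformly at random,
    preserving list sizes.  p uses the add-one permutation estimator.
    """
    lines = sorted(genes_by_line)
    kos = np.array([ko_by_line[l] for l in lines], dtype=object)
    lists = [list(genes_by_line[l]) for l in lines]

    if measure in _BINARY_MEASURES:
        gene_map = getattr(annotation, _BINARY_MEASURES[measure])

        def stat(ko_arr) -> tuple[float, int]:
            hits = n = 0
            for ko, genes in zip(ko_arr, lists):
                ko_ann = gene_map.get(ko)
                if ko_ann is None:
                    continue
                for g in genes:
                    g_ann = gene_map.get(g)
                    if g_ann is None:
                        continue
                    n += 1
                    hits += bool(ko_ann & g_ann)
            return (hits / n if n else np.nan), n

    elif measure in _CONT_MEASURES:
        pair_map = getattr(annotation, _CONT_MEASURES[measure])

        def stat(ko_arr) -> tuple[float, int]:
            vals = []
            for ko, genes in zip(ko_arr, lists):
                for g in genes:
                    v = pair_map.get(tuple(sorted((ko, g))))
                    if v is not None:
                        vals.append(v)
            return (float(np.mean(vals)) if vals else np.nan), len(vals)

    else:
        raise ValueError(f"unknown measure {measure!r}")

    observed, n_pairs = stat(kos)
    if n_pairs == 0:
        raise ValueError(f"measure {measure!r} has no annotation coverage")

    if pd.unique(kos).size < 2:
        warnings.warn("single genotype: shuffling is the identity, p = 1",
                      stacklevel=2)
        return RelatednessResult(measure, observed, observed, 1.0, 1.0,
                                 n_pairs, 0)

    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        null[s] = stat(rng.permutation(kos))[0]
    null_mean = float(np.nanmean(null))
    p = (1.0 + np.sum(null >= observed - 1e-12)) / (1.0 + n_shuffles)
    enrichment = observed / null_mean if null_mean else float("inf")
    return RelatednessResult(measure, float(observed), null_mean,
                             float(enrichment), float(p), n_pairs, n_shuffles)


# ---------------------------------------------------------------------------
# promoter enrichment, paralogs
# ---------------------------------------------------------------------------


@dataclass
class PromoterEnrichmentResult:
    n_promoter: int
    n_total: int
    expected_fraction: float
    pvalue: float


def promoter_enrichment(
    mutations: pd.DataFrame,
    promoters: pd.DataFrame,
    genome_size: int,
) -> PromoterEnrichmentResult:
    """Two-sided binomial test of promoter-mutation count vs the promoter
    fraction of the mutable genome.

    ``promoters`` holds 1-based inclusive windows (chrom, start, end);
    overlapping windows are merged before computing the expected fraction.
    """
    if mutations.empty:
        raise ValueError("no mutations supplied")
    total_bp = 0
    in_prom = np.zeros(len(mutations), dtype=bool)
    pos = mutations["pos"].to_numpy()
    chrom = mutations["chrom"].to_numpy()
    for chr_, grp in promoters.groupby("chrom"):
        iv = grp[["start", "end"]].sort_values("start").to_numpy()
        merged = []
        for s, e in iv:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            total_bp += e - s + 1
            in_prom |= (chrom == chr_) & (pos >= s) & (pos <= e)
    frac = total_bp / genome_size
    k, n = int(in_prom.sum()), len(mutations)
    p = float(stats.binomtest(k, n, frac, alternative="two-sided").pvalue)
    return PromoterEnrichmentResult(k, n, frac, p)


def paralog_filter(
    records: pd.DataFrame,
    evalue_max: float = 1e-8,
    min_aln_length: int = 100,
    min_similarity: float = 30.0,
) -> pd.DataFrame:
    """Paralog pairs: E < 1e-8, alignment > 100 residues, similarity > 30%,
    neither gene a transposon element.

    Required columns: ``gene_a, gene_b, evalue, aln_length, similarity,
    transposon_a, transposon_b``.  Records with missing fields are rejected
    and logged.
    """
    required = ["gene_a", "gene_b", "evalue", "aln_length", "similarity",
                "transposon_a", "transposon_b"]
    missing_cols = [c for c in required if c not in records.columns]
    if missing_cols:
        raise ValueError(f"missing columns: {missing_cols}")
    complete = records[required].notna().all(axis=1)
    n_rejected = int((~complete).sum())
    if n_rejected:
        logger.info("paralog_filter: %d records with missing fields rejected",
                    n_rejected)
    df = records[complete]
    keep = (
        (df["evalue"] < evalue_max)
        & (df["aln_length"] > min_aln_length)
        & (df["similarity"] > min_similarity)
        & ~df["transposon_a"].astype(bool)
        & ~df["transposon_b"].astype(bool)
    )
    return df[keep].reset_index(drop=True)
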