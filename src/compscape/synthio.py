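"""Synthetic-data generators for every input consumed by the pipeline.

Each generator is a pure function of its parameters and seed and returns, next
to the simulated tables, a :class:`GroundTruth` describing how the data were
built, so that every downstream estimator can be checked for recovery of known
truth.

The evolution generator emulates the structure of a large laboratory-evolution
experiment in budding yeast: 187 slow-growing single-gene deletion genotypes
evolved in four replicate populations each, alongside 22 evolving wild-type
control lineages, sampled on days 0/26/52/78/104 (~400 generations), with
relative fitness measured from >=4 technical replicates per line and
timepoint.  The defaults are calibrated so that control lineages gain ~5%
fitness on average, deletion lineages ~23%, and 68% of genotypes carry a
compensable defect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._codons import BASES, random_orf, snp_effect

__all__ = [
    "EvolutionSimParams",
    "GroundTruth",
    "simulate_evolution_experiment",
    "interleaved_layout",
    "simulate_growth_plate",
    "simulate_mutation_tables",
    "simulate_expression_triplets",
    "simulate_colony_plates",
    "simulate_gi_map",
]


@dataclass
class GroundTruth:
    """Container tying generated tables back to their construction."""

    trajectories: pd.DataFrame | None = None
    compensable: dict[str, bool] | None = None
    line_effects: pd.DataFrame | None = None
    restoration: pd.Series | None = None
    de_genes: list[str] | None = None
    suppression: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# evolution experiment
# ---------------------------------------------------------------------------


@dataclass
class EvolutionSimParams:
    """Parameters of the simulated evolution experiment.

    Attributes
    ----------
    n_genotypes, lines_per_genotype, n_controls
        Number of deletion genotypes, replicate evolving populations per
        genotype and evolving wild-type control lineages.
    timepoints_days
        Sampling days; must include day 0 and a final day.
    initial_fitness_distribution
        ``(low, high)`` of the uniform distribution of initial relative
        fitness of deletion genotypes (controls start at 1).
    control_drift, control_drift_sd
        Mean and between-line sd of the fractional fitness improvement every
        line gains from generic adaptation to the medium.  Drift is
        multiplicative (proportional to current fitness), so the relative
        improvement of a drifting line matches the evolving controls
        regardless of its initial fitness — the premise behind using the
        control RFI distribution as the null.
    compensable_fraction
        Probability that a genotype's defect is compensable.
    compensation_effect
        ``(mean, sd)`` of the extra total fitness recovery (absolute units,
        truncated at 0) gained by each line of a compensable genotype.
    replicate_noise_sd
        SD of technical-replicate measurement noise on relative fitness.
    replicates
        Technical replicates per line and timepoint (>= 4).
    trajectory_tau_days
        Timescale of the saturating (exponential-approach) trajectory.
    """

    n_genotypes: int = 187
    lines_per_genotype: int = 4
    n_controls: int = 22
    timepoints_days: Sequence[int] = (0, 26, 52, 78, 104)
    initial_fitness_distribution: tuple[float, float] = (0.5, 0.9)
    control_drift: float = 0.05
    control_drift_sd: float = 0.015
    compensable_fraction: float = 0.68
    compensation_effect: tuple[float, float] = (0.18, 0.09)
    replicate_noise_sd: float = 0.02
    replicates: int = 6
    trajectory_tau_days: float = 30.0
    seed: int | None = None

    def validate(self) -> None:
        lo, hi = self.initial_fitness_distribution
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("initial fitness range must satisfy 0 < low <= high < 1")
        if self.replicates < 4:
            raise ValueError("at least 4 technical replicates are required")
        days = list(self.timepoints_days)
        if 0 not in days or max(days) <= 0:
            raise ValueError("timepoints must include day 0 and a positive final day")
        if sorted(days) != days:
            raise ValueError("timepoints must be increasing")
        if not 0.0 <= self.compensable_fraction <= 1.0:
            raise ValueError("compensable_fraction must be in [0, 1]")
        if self.replicate_noise_sd < 0 or self.control_drift_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")


def _saturation(days: np.ndarray, tau: float) -> np.ndarray:
    """Fraction of the total gain realised by each day (0 at day 0, 1 at end)."""
    total = days.max()
    s = (1.0 - np.exp(-days / tau)) / (1.0 - math.exp(-total / tau))
    s[days == 0] = 0.0
    return s


def simulate_evolution_experiment(
    params: EvolutionSimParams,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate replicate-level relative-fitness observations.

    Returns a long table with columns ``genotype, line, role, day, replicate,
    fitness`` and the associated :class:`GroundTruth` (true trajectories,
    per-genotype compensable flags and per-line effect sizes).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    days = np.asarray(sorted(params.timepoints_days), dtype=float)
    sat = _saturation(days, params.trajectory_tau_days)
    eff_mean, eff_sd = params.compensation_effect

    rows: list[tuple] = []
    truth_rows: list[tuple] = []
    effect_rows: list[tuple] = []
    compensable: dict[str, bool] = {}

    def emit(genotype: str, line: str, role: str, f0: float, gain: float) -> None:
        traj = f0 + gain * sat
        for day, f_true in zip(days, traj):
            truth_rows.append((genotype, line, int(day), f_true))
            noise = rng.normal(0.0, params.replicate_noise_sd, size=params.replicates)
            for rep, eps in enumerate(noise, start=1):
                rows.append((genotype, line, role, int(day), rep, f_true + eps))

    for j in range(1, params.n_controls + 1):
        drift = rng.normal(params.control_drift, params.control_drift_sd)
        line = f"control_L{j:02d}"
        emit("control", line, "control", 1.0, drift)
        effect_rows.append(("control", line, 1.0, drift, 0.0))

    lo, hi = params.initial_fitness_distribution
    for g in range(1, params.n_genotypes + 1):
        genotype = f"g{g:03d}"
        f0 = rng.uniform(lo, hi)
        is_comp = bool(rng.random() < params.compensable_fraction)
        compensable[genotype] = is_comp
        for i in range(1, params.lines_per_genotype + 1):
            drift = rng.normal(params.control_drift, params.control_drift_sd)
            effect = max(0.0, rng.normal(eff_mean, eff_sd)) if is_comp else 0.0
            line = f"{genotype}_L{i}"
            emit(genotype, line, "deletion", f0, f0 * drift + effect)
            effect_rows.append((genotype, line, f0, drift, effect))

    fitness = pd.DataFrame(
        rows, columns=["genotype", "line", "role", "day", "replicate", "fitness"]
    )
    truth = GroundTruth(
        trajectories=pd.DataFrame(
            truth_rows, columns=["genotype", "line", "day", "true_fitness"]
        ),
        compensable=compensable,
        line_effects=pd.DataFrame(
            effect_rows,
            columns=["genotype", "line", "initial_fitness", "drift", "compensation_effect"],
        ),
    )
    return fitness, truth


# ---------------------------------------------------------------------------
# plate-reader growth curves
# ---------------------------------------------------------------------------


def interleaved_layout(
    strains: Sequence[str],
    n_rows: int = 16,
    n_cols: int = 24,
    plate: str = "plate1",
    empty_wells: Sequence[tuple[int, int]] = (),
    reference_strain: str = "reference",
) -> pd.DataFrame:
    """Layout with the reference strain interleaved at (even, even) positions.

    Mirrors a 384-well plate assembled from four 96-well plates, one of which
    carries the wild-type reference in all wells.  Row/column indices are
    0-based.  Sample strains cycle through the remaining positions.
    """
    empty = set(map(tuple, empty_wells))
    rows = []
    k = 0
    for r in range(n_rows):
        for c in range(n_cols):
            if (r, c) in empty:
                rows.append((plate, r, c, "", "empty"))
            elif r % 2 == 0 and c % 2 == 0:
                rows.append((plate, r, c, reference_strain, "reference"))
            else:
                rows.append((plate, r, c, strains[k % len(strains)], "sample"))
                k += 1
    return pd.DataFrame(rows, columns=["plate", "row", "col", "strain", "role"])


def simulate_growth_plate(
    layout: pd.DataFrame,
    true_rates: Mapping[str, float],
    noise_sd: float = 0.0,
    seed: int | None = None,
    od0: float = 0.027,
    carrying_capacity: float = 1.0,
    blank: float = 0.08,
    duration_hours: float = 24.0,
    interval_min: float = 20.0,
) -> pd.DataFrame:
    """OD time series for every well of ``layout``.

    Non-empty wells follow a logistic curve from inoculum ``od0`` to the
    carrying capacity at the well's true growth rate (per hour), on top of a
    constant optical blank, with multiplicative measurement noise.  Empty
    wells stay at blank level.
    """
    rng = np.random.default_rng(seed)
    t_min = np.arange(0.0, duration_hours * 60.0 + 0.5 * interval_min, interval_min)
    t_h = t_min / 60.0
    K = carrying_capacity

    out = []
    for rec in layout.itertuples(index=False):
        if rec.role == "empty":
            signal = np.zeros_like(t_h)
        else:
            r = float(true_rates[rec.strain])
            if r <= 0:
                raise ValueError(f"non-positive growth rate for strain {rec.strain!r}")
            e = np.exp(r * t_h)
            signal = K * od0 * e / (K + od0 * (e - 1.0))
        noise = rng.normal(0.0, noise_sd, size=t_h.size) if noise_sd > 0 else 0.0
        od = blank + signal + (blank + signal) * noise
        df = pd.DataFrame(
            {
                "plate": rec.plate,
                "row": rec.row,
                "col": rec.col,
                "strain": rec.strain,
                "role": rec.role,
                "time_min": t_min,
                "od": od,
            }
        )
        out.append(df)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# mutation tables
# ---------------------------------------------------------------------------


def simulate_mutation_tables(
    n_lines: int,
    orf_set_params: tuple[int, int] = (60, 200),
    mut_rate_params: tuple[float, float] = (6.0, 0.5),
    functional_bias: float = 0.3,
    seed: int | None = None,
    lines_per_genotype: int = 3,
    complex_size: int = 4,
    category_size: int = 10,
    intergenic_bp: int = 400,
    promoter_bp: int = 200,
    coding_fraction: float | None = None,
) -> tuple[pd.DataFrame, dict[str, str], dict]:
    """Simulate de-novo mutation tables over a synthetic genome.

    Per line, SNP and small-indel counts are Poisson with the given means
    (defaults: 6 SNPs and 0.5 indels per evolved clone).  A mutation is
    coding with probability ``coding_fraction`` — by default the coding
    fraction of the synthetic genome, i.e. placement is uniform along the
    genome, the null of the promoter-enrichment test (the rest land uniformly
    in intergenic space and are annotated ``promoter`` when inside an
    upstream window).  With probability ``functional_bias`` a coding SNP lands in a
    gene annotated as functionally related (same protein complex or
    functional category) to the line's deleted gene; otherwise the target
    gene is uniform.  Coding SNPs are annotated synonymous / nonsynonymous /
    nonsense by translating the synthetic ORF codon.

    Returns ``(mutations, orfs, annotations)`` where ``annotations`` holds the
    complex/category tables, the line -> knocked-out-gene map, promoter
    windows and the genome size.
    """
    if not 0.0 <= functional_bias <= 1.0:
        raise ValueError("functional_bias must be in [0, 1]")
    n_genes, n_codons = orf_set_params
    if n_genes <= 0:
        raise ValueError("empty ORF set")
    mean_snp, mean_indel = mut_rate_params
    rng = np.random.default_rng(seed)

    genes = [f"gene{i:03d}" for i in range(1, n_genes + 1)]
    orfs = {g: random_orf(n_codons, rng) for g in genes}
    gene_len = 3 * n_codons
    starts = {
        g: intergenic_bp + i * (gene_len + intergenic_bp) + 1  # 1-based
        for i, g in enumerate(genes)
    }
    genome_size = intergenic_bp + n_genes * (gene_len + intergenic_bp)

    complexes = pd.DataFrame(
        {"gene": genes, "complex": [f"cpx{i // complex_size:02d}" for i in range(n_genes)]}
    )
    categories = pd.DataFrame(
        {"gene": genes, "category": [f"cat{i // category_size:02d}" for i in range(n_genes)]}
    )
    related: dict[str, list[str]] = {}
    for g in genes:
        cpx = complexes.loc[complexes.gene == g, "complex"].iloc[0]
        cat = categories.loc[categories.gene == g, "category"].iloc[0]
        mates = set(complexes.loc[complexes["complex"] == cpx, "gene"])
        mates |= set(categories.loc[categories["category"] == cat, "gene"])
        mates.discard(g)
        related[g] = sorted(mates)

    if coding_fraction is None:
        coding_fraction = n_genes * gene_len / genome_size

    def intergenic_site():
        block = int(rng.integers(n_genes + 1))
        offset = int(rng.integers(intergenic_bp))
        pos = block * (gene_len + intergenic_bp) + offset + 1
        hit = (
            "promoter"
            if block < n_genes and offset >= intergenic_bp - promoter_bp
            else "intergenic"
        )
        ref = rng.choice(list(BASES))
        return pos, hit, ref

    n_genotypes = math.ceil(n_lines / lines_per_genotype)
    if n_genotypes > n_genes:
        raise ValueError("more genotypes than genes in the synthetic ORF set")
    ko_genes = list(rng.choice(genes, size=n_genotypes, replace=False))

    line_rows = []
    mut_rows = []
    for li in range(n_lines):
        line = f"line{li + 1:03d}"
        ko = ko_genes[li // lines_per_genotype]
        line_rows.append((line, ko))
        candidates = [g for g in genes if g != ko]
        rel = related[ko]
        for _ in range(rng.poisson(mean_snp)):
            if rng.random() < coding_fraction:
                if rel and rng.random() < functional_bias:
                    gene = rel[rng.integers(len(rel))]
                else:
                    gene = candidates[rng.integers(len(candidates))]
                pos0 = int(rng.integers(gene_len))
                ref = orfs[gene][pos0]
                alt = rng.choice([b for b in BASES if b != ref])
                mut_rows.append(
                    (line, ko, "chrI", starts[gene] + pos0, ref, alt, "snp",
                     gene, snp_effect(orfs[gene], pos0, alt), "de_novo")
                )
            else:
                pos, hit, ref = intergenic_site()
                alt = rng.choice([b for b in BASES if b != ref])
                mut_rows.append(
                    (line, ko, "chrI", pos, ref, alt, "snp", hit, "noncoding",
                     "de_novo")
                )
        for _ in range(rng.poisson(mean_indel)):
            if rng.random() < coding_fraction:
                gene = candidates[rng.integers(len(candidates))]
                pos0 = int(rng.integers(gene_len))
                ref = orfs[gene][pos0]
                alt = ref + rng.choice(list(BASES))
                mut_rows.append(
                    (line, ko, "chrI", starts[gene] + pos0, ref, alt, "indel",
                     gene, "frameshift", "de_novo")
                )
            else:
                pos, hit, ref = intergenic_site()
                alt = ref + rng.choice(list(BASES))
                mut_rows.append(
                    (line, ko, "chrI", pos, ref, alt, "indel", hit, "noncoding",
                     "de_novo")
                )

    mutations = pd.DataFrame(
        mut_rows,
        columns=["line", "genotype", "chrom", "pos", "ref", "alt", "class", "gene",
                 "coding_effect", "status"],
    )
    promoters = pd.DataFrame(
        {
            "chrom": "chrI",
            "start": [max(1, starts[g] - promoter_bp) for g in genes],
            "end": [starts[g] - 1 for g in genes],
            "gene": genes,
        }
    )
    annotations = {
        "complexes": complexes,
        "categories": categories,
        "lines": pd.DataFrame(line_rows, columns=["line", "ko_gene"]),
        "promoters": promoters,
        "genome_size": genome_size,
    }
    return mutations, orfs, annotations


# ---------------------------------------------------------------------------
# expression triplets
# ---------------------------------------------------------------------------


def simulate_expression_triplets(
    n_genes: int = 6000,
    n_de: int = 300,
    effect_log2: float = 2.0,
    restoration_fraction: float = 0.3,
    replicate_sd: float = 0.1,
    n_replicates: int = 4,
    seed: int | None = None,
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Simulate WT / ancestor / evolved log2-ratio matrices.

    The ancestor differs from wild type at ``n_de`` genes by +-``effect_log2``;
    in the evolved profile a ``restoration_fraction`` of those genes revert
    fully to the wild-type level, the rest stay at the ancestor level.
    Replicates (2 biological x 2 technical for the default of 4) carry iid
    Gaussian noise of sd ``replicate_sd``.
    """
    if not 0.0 <= restoration_fraction <= 1.0:
        raise ValueError("restoration_fraction must be in [0, 1]")
    if n_de > n_genes:
        raise ValueError("n_de must not exceed n_genes")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per strain")
    rng = np.random.default_rng(seed)

    genes = [f"y{i:04d}" for i in range(1, n_genes + 1)]
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    n_restored = int(round(restoration_fraction * n_de))
    restored_idx = de_idx[:n_restored]

    wt_true = np.zeros(n_genes)
    anc_true = wt_true.copy()
    anc_true[de_idx] = signs * effect_log2
    evo_true = anc_true.copy()
    evo_true[restored_idx] = 0.0

    cols = [f"rep{j + 1}" for j in range(n_replicates)]

    def noisy(true: np.ndarray) -> pd.DataFrame:
        data = true[:, None] + rng.normal(0.0, replicate_sd, size=(n_genes, n_replicates))
        return pd.DataFrame(data, index=genes, columns=cols)

    matrices = {"wt": noisy(wt_true), "ancestor": noisy(anc_true), "evolved": noisy(evo_true)}

    labels = pd.Series("other", index=genes, name="restoration")
    labels.iloc[de_idx] = "unrestored"
    labels.iloc[restored_idx] = "restored"
    truth = GroundTruth(
        restoration=labels,
        de_genes=[genes[i] for i in de_idx],
        extras={"anc_true": pd.Series(anc_true, index=genes)},
    )
    return matrices, truth


# ---------------------------------------------------------------------------
# colony plates
# ---------------------------------------------------------------------------


def simulate_colony_plates(
    effects: pd.DataFrame,
    environments: Sequence[str] | None = None,
    spatial_gradient: Mapping[str, float] | None = None,
    seed: int | None = None,
    n_replicates: int = 4,
    noise_sd: float = 0.1,
    n_rows: int = 24,
    n_cols: int = 32,
    reference_strain: str = "reference",
) -> pd.DataFrame:
    """Simulate colony-size tables on 768-position (24x32) arrays.

    ``effects`` has columns ``strain, line, day, environment, effect`` giving
    the true strain-by-environment size effect; ancestor (day 0) and evolved
    (day 104) units of a genotype are pinned on the same plate.  The reference
    strain (effect 1) occupies every (even, even) position.  Size = effect x
    smooth positional bias x lognormal noise.  One plate is produced per
    (environment, technical replicate).
    """
    required = {"strain", "line", "day", "environment", "effect"}
    if not required.issubset(effects.columns):
        raise ValueError(f"effects table needs columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    if environments is None:
        environments = list(pd.unique(effects["environment"]))
    grad = spatial_gradient or {}
    row_slope = float(grad.get("row_slope", 0.0))
    col_slope = float(grad.get("col_slope", 0.0))

    rows_out = []
    for env in environments:
        env_eff = effects[effects["environment"] == env]
        units = list(env_eff[["strain", "line", "day", "effect"]].itertuples(index=False))
        sample_positions = [
            (r, c)
            for r in range(n_rows)
            for c in range(n_cols)
            if not (r % 2 == 0 and c % 2 == 0)
        ]
        ref_positions = [
            (r, c) for r in range(n_rows) for c in range(n_cols) if r % 2 == 0 and c % 2 == 0
        ]
        if len(units) > len(sample_positions):
            raise ValueError("more strain/line/day units than plate positions")
        for rep in range(1, n_replicates + 1):
            plate = f"{env}_rep{rep}"

            def bias(r: int, c: int) -> float:
                return math.exp(
                    row_slope * (r - (n_rows - 1) / 2) + col_slope * (c - (n_cols - 1) / 2)
                )

            for (r, c) in ref_positions:
                size = bias(r, c) * (
                    math.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
                )
                rows_out.append((plate, r, c, reference_strain, "", -1, env, rep, size))
            for (r, c), u in zip(sample_positions, units):
                size = u.effect * bias(r, c) * (
                    math.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
                )
                rows_out.append((plate, r, c, u.strain, u.line, int(u.day), env, rep, size))
    return pd.DataFrame(
        rows_out,
        columns=["plate", "row", "col", "strain", "line", "day", "environment",
                 "replicate", "size"],
    )


# ---------------------------------------------------------------------------
# genetic-interaction map
# ---------------------------------------------------------------------------


def default_suppression_link(lo: float = 0.4) -> Callable[[np.ndarray], np.ndarray]:
    """Linear link: suppression probability rises as single-mutant fitness falls."""

    def link(f: np.ndarray) -> np.ndarray:
        return np.clip(0.02 + 0.28 * (1.0 - np.asarray(f)) / (1.0 - lo), 0.0, 1.0)

    return link


def simulate_gi_map(
    n_genes: int = 3880,
    fitness_dist: tuple[float, float] = (0.4, 1.0),
    suppression_link: Callable[[np.ndarray], np.ndarray] | None = None,
    seed: int | None = None,
    partners_per_gene: int = 50,
    sigma: float = 0.05,
    effect_mean: float = 0.1,
    effect_sd: float = 0.05,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate single- and double-deletion fitness pairs.

    Single-deletion fitness is uniform on ``fitness_dist``.  For each tested
    pair (A, B) with ``F_B > F_A``, the pair is made a true suppressor with
    probability ``suppression_link(F_A)``; suppressor pairs get
    ``F_AB > F_A + sigma_A`` and non-suppressors a near-multiplicative
    ``F_AB`` kept below the suppression threshold.
    """
    rng = np.random.default_rng(seed)
    lo, hi = fitness_dist
    link = suppression_link or default_suppression_link(lo)

    fitness = rng.uniform(lo, hi, size=n_genes)
    gene_ids = np.array([f"orf{i:04d}" for i in range(1, n_genes + 1)])

    a_idx = np.repeat(np.arange(n_genes), partners_per_gene)
    b_idx = rng.integers(0, n_genes, size=a_idx.size)
    # avoid self-pairs
    clash = b_idx == a_idx
    b_idx[clash] = (b_idx[clash] + 1) % n_genes

    f_a = fitness[a_idx]
    f_b = fitness[b_idx]
    sigma_a = np.full(a_idx.size, sigma)
    eligible = f_b > f_a
    p = link(f_a)
    true_supp = eligible & (rng.random(a_idx.size) < p)

    f_ab = np.minimum(f_a * f_b * (1.0 + rng.normal(0.0, 0.02, size=a_idx.size)),
                      f_a + 0.9 * sigma_a)
    f_ab = np.clip(f_ab, 0.0, None)
    boost = np.abs(rng.normal(effect_mean, effect_sd, size=a_idx.size)) + 1e-6
    f_ab = np.where(true_supp, f_a + sigma_a + boost, f_ab)

    table = pd.DataFrame(
        {
            "gene_a": gene_ids[a_idx],
            "gene_b": gene_ids[b_idx],
            "f_a": f_a,
            "f_b": f_b,
            "f_ab": f_ab,
            "sigma_a": sigma_a,
        }
    )
    truth_pairs = table[["gene_a", "gene_b", "f_a"]].copy()
    truth_pairs["true_suppressor"] = true_supp
    per_gene = (
        truth_pairs.groupby("gene_a")
        .agg(fitness=("f_a", "first"), true_fraction=("true_suppressor", "mean"))
        .reset_index()
    )
    truth = GroundTruth(
        suppression=truth_pairs,
        extras={"per_gene": per_gene, "link_probability": pd.Series(p, name="p")},
    )
    return table, truth
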