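"""Calling compensated lines and quantifying the structure of compensation.

A line counts as compensated when two criteria hold simultaneously: (i) its
fitness improvement over the experiment is significant (one-tailed Wilcoxon
rank-sum on replicate-level fitness, Benjamini-Hochberg corrected), and (ii)
its relative fitness improvement RFI = evolved/initial - 1 exceeds a cutoff
derived from the evolving wild-type controls, defined as the point a control
line exceeds with probability alpha under a maximum-likelihood normal fit to
the control RFIs.  A genotype shows evidence of compensatory evolution when at
least one of its replicate lines is compensated.

Relative compensation RC = (D_end - D_start) / (WT_end - D_start) measures the
fraction of the initial fitness deficit (relative to the evolving controls)
recovered by the end of the experiment: 0 = no improvement, 1 = the knock-out
reached control fitness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

__all__ = [
    "rfi",
    "relative_compensation",
    "control_improvement_cutoff",
    "control_rfis",
    "call_compensation",
    "aggregate_genotype_calls",
    "run_compensation_pipeline",
    "trend_test",
    "genotype_effect_anova",
    "genotype_specificity_randomization",
    "trajectory_saturation",
    "final_interval_depletion",
]


def rfi(initial, evolved):
    """Relative fitness improvement: evolved/initial - 1."""
    initial = np.asarray(initial, dtype=float)
    evolved = np.asarray(evolved, dtype=float)
    if np.any(initial <= 0):
        raise ValueError("initial fitness must be positive")
    out = evolved / initial - 1.0
    return float(out) if out.ndim == 0 else out


def relative_compensation(delta_start, delta_end, wt_end):
    """RC = (D_end - D_start) / (WT_end - D_start); NaN where undefined."""
    d0 = np.asarray(delta_start, dtype=float)
    d1 = np.asarray(delta_end, dtype=float)
    w1 = np.asarray(wt_end, dtype=float)
    denom = w1 - d0
    with np.errstate(divide="ignore", invalid="ignore"):
        rc = np.where(denom != 0, (d1 - d0) / denom, np.nan)
    if np.any(denom == 0):
        warnings.warn("WT_end equals D_start for some lines; RC undefined (NaN)",
                      stacklevel=2)
    return float(rc) if rc.ndim == 0 else rc


def control_improvement_cutoff(control_rfi_values, alpha: float = 0.05) -> float:
    """Improvement cutoff exceeded by a control line with probability ``alpha``.

    Maximum-likelihood normal fit (mean, sd) to the control RFIs; returns
    mu + z_{1-alpha} * sigma.  With zero variance the cutoff is the mean
    (with a warning).
    """
    x = np.asarray(control_rfi_values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 control RFI values")
    mu, sigma = stats.norm.fit(x)
    if sigma == 0:
        warnings.warn("control RFIs have zero variance; cutoff set to their mean",
                      stacklevel=2)
        return float(mu)
    return float(mu + stats.norm.ppf(1.0 - alpha) * sigma)


def _start_end(fitness: pd.DataFrame, start_day: int, end_day: int | None):
    days = np.sort(fitness["day"].unique())
    if end_day is None:
        end_day = int(days.max())
    if start_day not in days or end_day not in days:
        raise ValueError("start/end day not present in the fitness table")
    return start_day, end_day


def control_rfis(
    fitness: pd.DataFrame,
    start_day: int = 0,
    end_day: int | None = None,
    role: str = "control",
) -> pd.Series:
    """Per-control-line RFI; day-0 replicates are pooled across controls."""
    start_day, end_day = _start_end(fitness, start_day, end_day)
    ctrl = fitness[fitness["role"] == role]
    if ctrl.empty:
        raise ValueError("no control records in the fitness table")
    start_med = ctrl.loc[ctrl["day"] == start_day, "fitness"].median()
    end_med = ctrl[ctrl["day"] == end_day].groupby("line")["fitness"].median()
    return end_med / start_med - 1.0


def call_compensation(
    fitness: pd.DataFrame,
    cutoff: float,
    fdr: float = 0.05,
    start_day: int = 0,
    end_day: int | None = None,
) -> pd.DataFrame:
    """Per-line compensation calls for the deletion lines of a fitness table.

    ``fitness`` is replicate-level with columns ``genotype, line, role, day,
    fitness`` (relative to the unevolved wild type).  Start medians pool all
    replicates of a genotype's lines at the start day.  Returns one row per
    line with RFI, RC, improvement p and BH-adjusted q, and the compensated
    flag (q <= fdr AND RFI > cutoff).
    """
    start_day, end_day = _start_end(fitness, start_day, end_day)
    dele = fitness[fitness["role"] != "control"]
    ctrl_rfi = control_rfis(fitness, start_day, end_day)
    ctrl = fitness[fitness["role"] == "control"]
    wt_end = float(ctrl[ctrl["day"] == end_day].groupby("line")["fitness"].median().median())

    rows = []
    for genotype, grp in dele.groupby("genotype", sort=False):
        start_reps = grp.loc[grp["day"] == start_day, "fitness"].to_numpy()
        d_start = float(np.median(start_reps))
        for line, lg in grp.groupby("line", sort=False):
            end_reps = lg.loc[lg["day"] == end_day, "fitness"].to_numpy()
            if end_reps.size == 0 or start_reps.size == 0:
                continue  # skipped, logged by caller if needed
            d_end = float(np.median(end_reps))
            p = float(
                stats.mannwhitneyu(end_reps, start_reps, alternative="greater").pvalue
            )
            rows.append((genotype, line, d_start, d_end,
                         rfi(d_start, d_end),
                         relative_compensation(d_start, d_end, wt_end), p))
    calls = pd.DataFrame(
        rows, columns=["genotype", "line", "start_fitness", "end_fitness", "rfi",
                       "rc", "p"]
    )
    calls["q"] = bh_adjust(calls["p"])
    calls["cutoff"] = cutoff
    calls["compensated"] = (calls["q"] <= fdr) & (calls["rfi"] > cutoff)
    calls.attrs["control_rfis"] = ctrl_rfi
    calls.attrs["wt_end"] = wt_end
    return calls


def aggregate_genotype_calls(line_calls: pd.DataFrame) -> pd.DataFrame:
    """Genotype-level summary: compensated iff >=1 line is compensated."""
    agg = line_calls.groupby("genotype").agg(
        n_lines=("line", "size"),
        n_compensated=("compensated", "sum"),
        mean_rfi=("rfi", "mean"),
        mean_rc=("rc", "mean"),
    )
    agg["compensated"] = agg["n_compensated"] > 0
    return agg.reset_index()


def run_compensation_pipeline(
    fitness: pd.DataFrame,
    alpha: float = 0.05,
    fdr: float = 0.05,
    start_day: int = 0,
    end_day: int | None = None,
):
    """Controls -> cutoff -> per-line calls -> per-genotype aggregation."""
    ctrl_rfi = control_rfis(fitness, start_day, end_day)
    cutoff = control_improvement_cutoff(ctrl_rfi.to_numpy(), alpha=alpha)
    line_calls = call_compensation(fitness, cutoff, fdr=fdr, start_day=start_day,
                                   end_day=end_day)
    return line_calls, aggregate_genotype_calls(line_calls), cutoff


# ---------------------------------------------------------------------------
# trend, ANOVA, genotype specificity, saturation
# ---------------------------------------------------------------------------


@dataclass
class TrendTestResult:
    statistic: float
    pvalue: float
    table: pd.DataFrame


def trend_test(successes, totals, scores=None) -> TrendTestResult:
    """Cochran-Armitage chi-square test for trend in proportions.

    ``successes[i]`` of ``totals[i]`` in ordered bin i; ``scores`` default to
    equally spaced 0..k-1.  Bins with zero lines are merged into their left
    neighbour (right neighbour for the first bin), with a warning.
    """
    r = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if r.size != n.size or r.size < 2:
        raise ValueError("need >= 2 bins of (successes, totals)")
    if np.any(n == 0):
        warnings.warn("empty bins merged with neighbours", stacklevel=2)
        keep_r, keep_n = [], []
        for ri, ni in zip(r, n):
            if ni == 0:
                continue
            keep_r.append(ri)
            keep_n.append(ni)
        r, n = np.asarray(keep_r), np.asarray(keep_n)
        if r.size < 2:
            raise ValueError("fewer than 2 nonempty bins")
    x = np.arange(r.size, dtype=float) if scores is None else np.asarray(scores, float)
    N, R = n.sum(), r.sum()
    pbar = R / N
    num = float(np.sum(r * x) - pbar * np.sum(n * x))
    var = pbar * (1 - pbar) * (np.sum(n * x**2) - np.sum(n * x) ** 2 / N)
    if var == 0:
        stat, p = 0.0, 1.0
    else:
        stat = num**2 / var
        p = float(stats.chi2.sf(stat, df=1))
    table = pd.DataFrame({"score": x, "n": n, "successes": r, "proportion": r / n})
    return TrendTestResult(float(stat), p, table)


def genotype_effect_anova(gains: pd.DataFrame):
    """One-way ANOVA of per-line fitness gains with genotype as factor.

    ``gains`` has columns ``genotype, gain``.  Returns (F, df_between,
    df_within, p).  Requires >= 2 genotypes with >= 2 lines.
    """
    groups = [g["gain"].to_numpy() for _, g in gains.groupby("genotype")]
    if len(groups) < 2:
        raise ValueError("need >= 2 genotypes")
    if all(len(g) < 2 for g in groups):
        raise ValueError("all genotype groups are singletons")
    res = stats.f_oneway(*groups)
    df_between = len(groups) - 1
    df_within = sum(len(g) for g in groups) - len(groups)
    return float(res.statistic), df_between, df_within, float(res.pvalue)


def _categorize(flags_by_genotype: pd.core.groupby.SeriesGroupBy) -> pd.Series:
    def cat(v) -> str:
        s = int(np.sum(v))
        if s == 0:
            return "none"
        if s == len(v):
            return "all"
        return "mixed"

    return flags_by_genotype.apply(lambda v: cat(v.to_numpy()))


@dataclass
class SpecificityResult:
    observed: pd.Series  # counts per category
    null_mean: pd.Series
    statistic: float
    pvalue: float
    n_shuffles: int


def genotype_specificity_randomization(
    line_calls: pd.DataFrame,
    n_shuffles: int = 1000,
    seed: int | None = None,
    genotypes: list[str] | None = None,
) -> SpecificityResult:
    """Are compensation calls clustered by genotype?

    Genotypes are categorized as none / mixed / all by the fraction of their
    lines compensated; the null shuffles compensated flags across all lines
    (preserving the total count) and recategorizes.  The observed category
    counts are compared with the mean null counts by a chi-square test.
    ``genotypes`` restricts the analysis to a stratum (e.g. an initial-fitness
    range).
    """
    df = line_calls
    if genotypes is not None:
        df = df[df["genotype"].isin(genotypes)]
    geno = df["genotype"].to_numpy()
    flags = df["compensated"].to_numpy(dtype=bool)
    uniq = pd.unique(geno)
    if uniq.size < 2:
        raise ValueError("need >= 2 genotypes for the randomization test")
    sizes = pd.Series(geno).value_counts()
    if (sizes < 2).any():
        raise ValueError("every genotype needs >= 2 lines")
    if n_shuffles < 100:
        warnings.warn("n_shuffles < 100 gives a coarse null", stacklevel=2)
    rng = np.random.default_rng(seed)

    cats = ["none", "mixed", "all"]

    def counts(f: np.ndarray) -> pd.Series:
        ser = pd.Series(f).groupby(geno).agg(["sum", "size"])
        lab = np.where(ser["sum"] == 0, "none",
                       np.where(ser["sum"] == ser["size"], "all", "mixed"))
        return pd.Series(lab).value_counts().reindex(cats, fill_value=0)

    observed = counts(flags)
    null = np.zeros((n_shuffles, 3))
    f = flags.copy()
    for s in range(n_shuffles):
        rng.shuffle(f)
        null[s] = counts(f).to_numpy()
    null_mean = pd.Series(null.mean(axis=0), index=cats)

    keep = ~((observed == 0) & (null_mean == 0))
    obs_k, exp_k = observed[keep].to_numpy(float), null_mean[keep].to_numpy(float)
    if np.any(exp_k == 0):
        # a category never seen under the null but observed: maximal departure
        stat, p = float("inf"), 0.0
    else:
        exp_k = exp_k * obs_k.sum() / exp_k.sum()
        stat = float(np.sum((obs_k - exp_k) ** 2 / exp_k))
        dof = max(obs_k.size - 1, 1)
        p = 1.0 if stat == 0 else float(stats.chi2.sf(stat, df=dof))
    return SpecificityResult(observed, null_mean, stat, p, n_shuffles)


@dataclass
class SaturationResult:
    interval_tests: pd.DataFrame  # line, interval, days, p, q, significant
    one_improvement_lines: int
    final_interval_count: int
    expected_final: float
    statistic: float
    pvalue: float


def final_interval_depletion(final_count: int, n_lines: int, n_intervals: int = 4):
    """Chi-square of the final-interval improvement count vs uniform expectation.

    Among lines with exactly one significant improvement interval, a uniform
    assignment over the ``n_intervals`` consecutive intervals predicts
    ``n_lines / n_intervals`` in the final one.
    """
    expected = n_lines / n_intervals
    obs = np.array([final_count, n_lines - final_count], dtype=float)
    exp = np.array([expected, n_lines - expected], dtype=float)
    res = stats.chisquare(obs, exp)
    return float(res.statistic), float(res.pvalue), expected


def trajectory_saturation(fitness: pd.DataFrame, fdr: float = 0.05) -> SaturationResult:
    """Per-interval improvement calls and the final-interval depletion test.

    For each deletion line and each pair of consecutive timepoints, a
    one-sided Wilcoxon rank-sum test asks whether replicate fitness improved;
    p-values are BH-corrected across all line x interval tests.  Among lines
    with exactly one significant interval, a saturating process depletes the
    final interval relative to the uniform expectation n/4.
    """
    dele = fitness[fitness["role"] != "control"] if "role" in fitness else fitness
    days = np.sort(dele["day"].unique())
    if days.size < 2:
        raise ValueError("need >= 2 timepoints")
    intervals = list(zip(days[:-1], days[1:]))

    rows = []
    for line, grp in dele.groupby("line", sort=False):
        by_day = {d: g["fitness"].to_numpy() for d, g in grp.groupby("day")}
        for k, (d0, d1) in enumerate(intervals):
            if d0 not in by_day or d1 not in by_day:
                continue
            p = float(
                stats.mannwhitneyu(by_day[d1], by_day[d0], alternative="greater").pvalue
            )
            rows.append((line, k, f"{d0}-{d1}", p))
    tests = pd.DataFrame(rows, columns=["line", "interval", "days", "p"])
    tests["q"] = bh_adjust(tests["p"])
    tests["significant"] = tests["q"] <= fdr

    per_line = tests.groupby("line")["significant"].sum()
    one_imp = per_line[per_line == 1].index
    n_one = int(one_imp.size)
    final_idx = len(intervals) - 1
    final_count = int(
        tests[(tests["line"].isin(one_imp)) & tests["significant"]]["interval"]
        .eq(final_idx)
        .sum()
    )
    if n_one == 0:
        stat, p, expected = 0.0, 1.0, 0.0
    else:
        stat, p, expected = final_interval_depletion(final_count, n_one, len(intervals))
    return SaturationResult(tests, n_one, final_count, expected, stat, p)
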