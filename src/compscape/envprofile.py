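"""Multi-environment colony-size fitness profiling.

Colony sizes on high-density agar arrays carry smooth positional biases
(edge/gradient effects); these are estimated from interleaved reference
colonies by additive row/column median polish on log sizes and divided out.
Per line and environment, evolved (day 104) colonies are compared with the
ancestor (day 0) by a two-sided Wilcoxon rank-sum test, BH-corrected per
environment, and classified improved / equal / declined.  Coefficients of
variation of replicate-line fitness quantify the conditional (pleiotropic)
heterogeneity of evolved populations across environments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

__all__ = [
    "normalize_colony_sizes",
    "environment_fitness_calls",
    "cv_analysis",
    "cv_z_test",
]


def _median_polish(log_sizes: pd.DataFrame, n_iter: int = 10):
    """Row and column effects from reference colonies (additive, on logs).

    ``log_sizes`` has columns row, col, value.  Returns (grand, row_effects,
    col_effects) Series; positions without references get effect 0.
    """
    rows = log_sizes["row"]
    cols = log_sizes["col"]
    grand = 0.0
    row_eff = pd.Series(0.0, index=np.unique(rows))
    col_eff = pd.Series(0.0, index=np.unique(cols))
    resid = log_sizes["value"].copy()
    for _ in range(n_iter):
        rm = resid.groupby(rows).median()
        row_eff += rm
        resid = resid - rows.map(rm)
        cm = resid.groupby(cols).median()
        col_eff += cm
        resid = resid - cols.map(cm)
        for eff in (row_eff, col_eff):
            shift = float(eff.median())
            eff -= shift
            grand += shift
    return grand, row_eff, col_eff


def _interpolate_effects(eff: pd.Series, full_index) -> pd.Series:
    """Linearly interpolate row/column effects to indices lacking references."""
    out = eff.reindex(full_index)
    return out.interpolate(method="index", limit_direction="both")


def normalize_colony_sizes(
    records: pd.DataFrame,
    reference_strain: str = "reference",
    n_iter: int = 10,
) -> pd.DataFrame:
    """Remove smooth positional bias and scale so reference median = 1.

    ``records`` has columns ``plate, row, col, strain, size``.  Per plate, a
    bias surface grand + row + column effect is fitted to the log sizes of the
    reference colonies by median polish and divided out of every colony; the
    output is scaled so the median normalized reference size is 1.  Plates
    without references are only median-scaled (warning); plates whose
    references are all zero (failed pinning) are flagged and their sizes set
    to NaN.
    """
    out = records.copy()
    out["normalized_size"] = np.nan
    out["flagged"] = False
    for plate, sub in records.groupby("plate", sort=False):
        refs = sub[(sub["strain"] == reference_strain) & (sub["size"] > 0)]
        if refs.empty:
            if (sub[sub["strain"] == reference_strain]["size"] == 0).all() and (
                sub["strain"] == reference_strain
            ).any():
                out.loc[sub.index, "flagged"] = True
                continue
            warnings.warn(
                f"plate {plate!r}: no reference colonies; positional correction skipped",
                stacklevel=2,
            )
            med = float(sub.loc[sub["size"] > 0, "size"].median())
            out.loc[sub.index, "normalized_size"] = sub["size"] / med
            continue
        log_ref = pd.DataFrame(
            {"row": refs["row"], "col": refs["col"], "value": np.log(refs["size"])}
        )
        grand, row_eff, col_eff = _median_polish(log_ref, n_iter=n_iter)
        # references cover only part of the grid: interpolate the smooth
        # surface to rows/columns without reference colonies
        row_eff = _interpolate_effects(row_eff, np.unique(sub["row"]))
        col_eff = _interpolate_effects(col_eff, np.unique(sub["col"]))
        bias = grand + sub["row"].map(row_eff) + sub["col"].map(col_eff)
        with np.errstate(divide="ignore"):
            norm = sub["size"] / np.exp(bias)
        ref_med = float(norm[refs.index].median())
        out.loc[sub.index, "normalized_size"] = norm / ref_med
    return out


def environment_fitness_calls(
    records: pd.DataFrame,
    fdr: float = 0.05,
    min_replicates: int = 3,
    day_start: int = 0,
    day_end: int = 104,
) -> tuple[pd.DataFrame, pd.Series]:
    """Improved / equal / declined call per line and environment.

    ``records`` is replicate-level with columns ``line, environment, day,
    normalized_size`` (or ``size``).  A two-sided Wilcoxon rank-sum test
    compares day-104 with day-0 replicate sizes; p-values are BH-corrected
    within each environment; significant calls take the sign of the median
    difference.  Pairs with fewer than ``min_replicates`` replicates on
    either day get no call.  Returns the call table and the summary fractions
    over all called pairs.
    """
    col = "normalized_size" if "normalized_size" in records else "size"
    rows = []
    for (line, env), grp in records.groupby(["line", "environment"]):
        x0 = grp.loc[grp["day"] == day_start, col].dropna().to_numpy()
        x1 = grp.loc[grp["day"] == day_end, col].dropna().to_numpy()
        if min(x0.size, x1.size) < min_replicates:
            rows.append((line, env, np.nan, np.nan, np.nan, "no_call"))
            continue
        p = float(stats.mannwhitneyu(x1, x0, alternative="two-sided").pvalue)
        rows.append((line, env, float(np.median(x0)), float(np.median(x1)), p, ""))
    calls = pd.DataFrame(
        rows, columns=["line", "environment", "median_start", "median_end", "p", "call"]
    )
    calls["q"] = np.nan
    for env, grp in calls.groupby("environment"):
        calls.loc[grp.index, "q"] = bh_adjust(grp["p"])
    called = calls["call"] != "no_call"
    sig = called & (calls["q"] <= fdr)
    direction = np.sign(calls["median_end"] - calls["median_start"])
    calls.loc[called, "call"] = "equal"
    calls.loc[sig & (direction > 0), "call"] = "improved"
    calls.loc[sig & (direction < 0), "call"] = "declined"
    frac = calls.loc[called, "call"].value_counts(normalize=True).reindex(
        ["improved", "equal", "declined"], fill_value=0.0
    )
    return calls, frac


def cv_z_test(x, y) -> tuple[float, float]:
    """Large-sample Z-test comparing the CVs of two samples.

    Uses the delta-method variance of the sample CV under approximate
    normality, var(cv_hat) ~ cv^2 (0.5 + cv^2) / n.  Returns (z, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cvs, vs = [], []
    for v in (x, y):
        cv = v.std(ddof=1) / v.mean()
        cvs.append(cv)
        vs.append(cv**2 * (0.5 + cv**2) / v.size)
    z = (cvs[0] - cvs[1]) / np.sqrt(vs[0] + vs[1])
    return float(z), float(2 * stats.norm.sf(abs(z)))


@dataclass
class CvAnalysisResult:
    per_genotype: pd.DataFrame  # genotype, cv_selection, cv_other_mean
    wilcoxon_p: float
    spearman_rho: float | None = None
    spearman_p: float | None = None


def cv_analysis(
    fitness: pd.DataFrame,
    selection_env: str,
    gains: pd.Series | None = None,
    min_lines: int = 3,
) -> CvAnalysisResult:
    """Replicate-line fitness dispersion in vs outside the selection medium.

    ``fitness`` has columns ``genotype, line, environment, fitness``; the CV
    (sd/mean over a genotype's replicate lines) is computed per genotype and
    environment.  The CVs in the selection medium are compared with the mean
    CV over the other media by a Wilcoxon rank-sum test; when per-genotype
    mean fitness ``gains`` are supplied, their Spearman correlation with the
    mean other-media CV is reported.
    """
    rows = []
    for (genotype, env), grp in fitness.groupby(["genotype", "environment"]):
        vals = grp.groupby("line")["fitness"].mean()
        if vals.size < min_lines:
            continue
        mean = vals.mean()
        if mean == 0:
            continue  # CV undefined
        rows.append((genotype, env, float(vals.std(ddof=1) / mean)))
    cv = pd.DataFrame(rows, columns=["genotype", "environment", "cv"])
    sel = cv[cv["environment"] == selection_env].set_index("genotype")["cv"]
    other = (
        cv[cv["environment"] != selection_env].groupby("genotype")["cv"].mean()
    )
    genotypes = sel.index.intersection(other.index)
    per_genotype = pd.DataFrame(
        {"cv_selection": sel[genotypes], "cv_other_mean": other[genotypes]}
    ).reset_index()
    p = float(
        stats.mannwhitneyu(
            per_genotype["cv_selection"], per_genotype["cv_other_mean"],
            alternative="two-sided",
        ).pvalue
    )
    rho = rp = None
    if gains is not None:
        g = gains.reindex(genotypes)
        res = stats.spearmanr(g, other[genotypes])
        rho, rp = float(res.statistic), float(res.pvalue)
    return CvAnalysisResult(per_genotype, p, rho, rp)
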