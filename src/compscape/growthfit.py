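"""From plate-reader OD time series to plate-normalized relative fitness.

The estimator follows the standard microbial growth-curve workflow: the
maximum specific growth rate is the steepest slope of ln(OD - blank) over a
sliding window of readings; within-plate bias is removed by dividing each
sample well's rate by the median rate of neighbouring wild-type reference
wells; relative fitness of a strain at a timepoint is the median of its
normalized technical-replicate rates divided by the median of the wild-type
controls.  Records with fewer than four retained replicates are dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

__all__ = [
    "GrowthRateResult",
    "estimate_growth_rate",
    "estimate_plate_rates",
    "normalize_by_neighbors",
    "relative_fitness",
    "classify_slow_growers",
]

logger = logging.getLogger(__name__)


@dataclass
class GrowthRateResult:
    rate: float  # per hour
    ok: bool
    window: tuple[int, int] | None = None
    reason: str | None = None


def estimate_growth_rate(
    time_min,
    od,
    blank: float = 0.0,
    window_points: int = 5,
    min_signal_ratio: float = 2.0,
) -> GrowthRateResult:
    """Maximum log-linear slope of a growth curve, per hour.

    Fits a least-squares line to ln(od - blank) over every contiguous window
    of ``window_points`` readings with positive blank-corrected signal and
    returns the steepest slope.  The result is flagged not-ok (rate NaN) when
    the culture never rises above ``min_signal_ratio`` times the blank, or
    when no window of positive signal exists.
    """
    t = np.asarray(time_min, dtype=float) / 60.0
    y = np.asarray(od, dtype=float)
    if t.size != y.size:
        raise ValueError("time and od must have the same length")
    if t.size < 10:
        raise ValueError("need at least 10 readings")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if window_points < 3:
        raise ValueError("window_points must be >= 3")

    signal = y - blank
    if blank > 0 and y.max() <= min_signal_ratio * blank:
        return GrowthRateResult(np.nan, False, None, "no growth above blank")
    valid = signal > 0
    if valid.sum() < window_points:
        return GrowthRateResult(np.nan, False, None, "insufficient positive signal")

    logod = np.where(valid, np.log(signal, where=valid, out=np.zeros_like(signal)), np.nan)
    best = -np.inf
    best_win = None
    for i in range(t.size - window_points + 1):
        j = i + window_points
        if not valid[i:j].all():
            continue
        tw = t[i:j]
        yw = logod[i:j]
        slope = np.polyfit(tw, yw, 1)[0]
        if slope > best:
            best = slope
            best_win = (i, j)
    if best_win is None:
        return GrowthRateResult(np.nan, False, None, "no contiguous window of signal")
    return GrowthRateResult(float(best), True, best_win)


def estimate_plate_rates(
    od_table: pd.DataFrame,
    layout: pd.DataFrame,
    window_points: int = 5,
    blank: float | None = None,
) -> pd.DataFrame:
    """Per-well growth rates for a long-format OD table.

    ``od_table`` has columns ``plate, row, col, time_min, od``; ``layout``
    maps wells to ``strain`` and ``role`` (sample | reference | empty).  The
    optical blank is taken from ``blank`` if given, otherwise estimated per
    plate as the median OD of empty wells (0 if a plate has none).
    """
    merged = od_table.merge(layout, on=["plate", "row", "col"], how="left",
                            suffixes=("", "_layout"))
    if "role" not in merged:
        raise ValueError("layout must provide a 'role' column")
    out = []
    for plate, sub in merged.groupby("plate", sort=False):
        if blank is None:
            empties = sub[sub["role"] == "empty"]
            plate_blank = float(empties["od"].median()) if len(empties) else 0.0
        else:
            plate_blank = blank
        for (r, c), well in sub[sub["role"] != "empty"].groupby(["row", "col"]):
            well = well.sort_values("time_min")
            res = estimate_growth_rate(
                well["time_min"], well["od"], blank=plate_blank,
                window_points=window_points,
            )
            out.append(
                (plate, r, c, well["strain"].iloc[0], well["role"].iloc[0], res.rate, res.ok)
            )
    return pd.DataFrame(out, columns=["plate", "row", "col", "strain", "role", "rate", "ok"])


def normalize_by_neighbors(
    rates: pd.DataFrame,
    radius: int = 2,
    metric: str = "manhattan",
) -> pd.DataFrame:
    """Divide each well's rate by the median rate of nearby reference wells.

    ``rates`` has columns ``plate, row, col, role, rate`` (0-based indices).
    The neighbourhood is all reference wells within ``radius`` in Manhattan
    (default) or Chebyshev distance, excluding the well itself.  Wells with no
    reference in range fall back to the plate-wide reference median (with a
    warning).  The neighbourhood definition is recorded in ``.attrs``.
    """
    if metric not in {"manhattan", "chebyshev"}:
        raise ValueError("metric must be 'manhattan' or 'chebyshev'")
    out = rates.copy()
    out["normalized_rate"] = np.nan
    for plate, sub in rates.groupby("plate", sort=False):
        refs = sub[(sub["role"] == "reference") & np.isfinite(sub["rate"])]
        if refs.empty:
            raise ValueError(f"plate {plate!r} has no reference wells")
        ref_rc = refs[["row", "col"]].to_numpy()
        ref_rate = refs["rate"].to_numpy()
        plate_median = float(np.median(ref_rate))
        fell_back = 0
        for idx, rec in sub.iterrows():
            if not np.isfinite(rec["rate"]):
                continue
            dr = np.abs(ref_rc[:, 0] - rec["row"])
            dc = np.abs(ref_rc[:, 1] - rec["col"])
            dist = dr + dc if metric == "manhattan" else np.maximum(dr, dc)
            near = (dist > 0) & (dist <= radius)
            if near.any():
                denom = float(np.median(ref_rate[near]))
            else:
                denom = plate_median
                fell_back += 1
            out.loc[idx, "normalized_rate"] = rec["rate"] / denom
        if fell_back:
            warnings.warn(
                f"plate {plate!r}: {fell_back} wells had no reference within "
                f"radius {radius}; used the plate-wide reference median",
                stacklevel=2,
            )
    out.attrs["neighborhood"] = {"metric": metric, "radius": radius}
    return out


def relative_fitness(
    records: pd.DataFrame,
    wt_records: pd.DataFrame,
    min_replicates: int = 4,
    pool_day0: bool = True,
) -> pd.DataFrame:
    """Median-based relative fitness per strain/line/timepoint.

    ``records`` and ``wt_records`` are replicate-level tables with columns
    ``strain, line, day, rate`` (normalized rates).  Fitness is
    median(rates) / median(WT rates at the same day).  At day 0 the technical
    replicates of all isogenic lines of a strain are pooled, since those
    populations share no independent evolutionary history.  Records with
    fewer than ``min_replicates`` retained replicates are excluded (logged).
    """
    wt_median = wt_records.groupby("day")["rate"].median()

    rows = []
    for (strain, line, day), grp in records.groupby(["strain", "line", "day"]):
        vals = grp["rate"].to_numpy()
        if pool_day0 and day == 0:
            vals = records[(records["strain"] == strain) & (records["day"] == 0)][
                "rate"
            ].to_numpy()
        if vals.size < min_replicates:
            logger.info(
                "excluded %s/%s day %s: %d < %d replicates", strain, line, day,
                vals.size, min_replicates,
            )
            continue
        if day not in wt_median.index:
            raise ValueError(f"no wild-type records for day {day}")
        rows.append(
            (strain, line, int(day), float(np.median(vals)) / float(wt_median[day]),
             int(vals.size))
        )
    return pd.DataFrame(rows, columns=["strain", "line", "day", "fitness", "n_replicates"])


def classify_slow_growers(
    day0_records: pd.DataFrame,
    wt_rates,
    fdr: float = 0.05,
    max_fitness: float = 0.9,
) -> pd.DataFrame:
    """Genotypes with a significant >=10% day-0 fitness drop versus wild type.

    A genotype is retained iff its relative fitness is <= ``max_fitness`` and
    the one-tailed Wilcoxon rank-sum test of its replicate rates against the
    wild-type rates is significant after Benjamini-Hochberg correction at
    ``fdr``.
    """
    wt = np.asarray(wt_rates, dtype=float)
    if wt.size == 0:
        raise ValueError("empty wild-type rate set")
    wt_median = float(np.median(wt))

    genotypes, fits, pvals = [], [], []
    for strain, grp in day0_records.groupby("strain"):
        vals = grp["rate"].to_numpy()
        genotypes.append(strain)
        fits.append(float(np.median(vals)) / wt_median)
        pvals.append(
            float(stats.mannwhitneyu(vals, wt, alternative="less").pvalue)
        )
    q = bh_adjust(pvals)
    out = pd.DataFrame(
        {"strain": genotypes, "fitness": fits, "p": pvals, "q": q}
    )
    out["slow_grower"] = (out["fitness"] <= max_fitness) & (out["q"] <= fdr)
    return out
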