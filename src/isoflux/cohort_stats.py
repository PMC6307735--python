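"""Cohort statistics: normality gate, Student's t-tests, drift handling.

The statistical design mirrors the study protocol: Shapiro-Wilk normality is
checked (and reported, not auto-switched on) within each arm; comparisons
between different subjects use a two-tailed unpaired Student's t-test (pooled
variance; Welch optional); comparisons of the same subjects at two time
points use a one-tailed paired t-test with the accumulation direction
(final >= initial) fixed a priori.  Significance is declared at p < 0.05 and
no multiple-testing correction is applied, but the number of tests performed
is carried on the report so users can post-correct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass
class ComparisonResult:
    variable: str
    test: str                 # unpaired_two_tailed | paired_one_tailed
    n_aga: int
    n_fgr: int
    mean_aga: float
    sd_aga: float
    mean_fgr: float
    sd_fgr: float
    percent_difference: float   # 100 * (FGR - AGA) / AGA
    statistic: float
    p_value: float
    normality_p_aga: float | None = None
    normality_p_fgr: float | None = None
    tissue: str = ""
    group: str = ""

    @property
    def significant(self) -> bool:
        return bool(self.p_value < ALPHA)


@dataclass
class DriftFit:
    metabolite: str
    slope: float          # a.u. per hour
    intercept: float
    r_squared: float
    duration_h: float
    n_points: int


def normality_check(values) -> dict:
    """Shapiro-Wilk W and p for one arm (n >= 3; constant vectors rejected)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("normality check needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample: normality undefined")
    w, p = stats.shapiro(x)
    return {"W": float(w), "p": float(p)}


def compare_groups(aga, fgr, design: str = "unpaired_two_tailed", *,
                   variable: str = "", welch: bool = False,
                   tissue: str = "", group: str = "") -> ComparisonResult:
    """Compare two arms with the design-appropriate Student's t-test.

    ``design="unpaired_two_tailed"`` treats the arms as different subjects;
    ``design="paired_one_tailed"`` treats them as the same subjects at two
    time points, ordered (first, second), testing accumulation
    (second > first).  Percent difference is reported as
    100 * (second - first) / first, i.e. FGR relative to AGA.
    """
    a = np.asarray(aga, dtype=float)
    b = np.asarray(fgr, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each arm needs n >= 2")
    if design == "unpaired_two_tailed":
        res = stats.ttest_ind(b, a, equal_var=not welch)
    elif design == "paired_one_tailed":
        if a.size != b.size:
            raise ValueError("paired design requires equal-length arms with "
                             "shared subject keys")
        res = stats.ttest_rel(b, a, alternative="greater")
    else:
        raise ValueError(f"unknown design {design!r}")
    norm_a = normality_check(a)["p"] if a.size >= 3 and np.ptp(a) > 0 else None
    norm_b = normality_check(b)["p"] if b.size >= 3 and np.ptp(b) > 0 else None
    mean_a = float(np.mean(a))
    return ComparisonResult(
        variable=variable, test=design, n_aga=a.size, n_fgr=b.size,
        mean_aga=mean_a, sd_aga=float(np.std(a, ddof=1)),
        mean_fgr=float(np.mean(b)), sd_fgr=float(np.std(b, ddof=1)),
        percent_difference=100.0 * (float(np.mean(b)) - mean_a) / mean_a
        if mean_a != 0 else np.nan,
        statistic=float(res.statistic), p_value=float(res.pvalue),
        normality_p_aga=norm_a, normality_p_fgr=norm_b,
        tissue=tissue, group=group)


def compare_from_stats(mean1: float, sd1: float, n1: int,
                       mean2: float, sd2: float, n2: int) -> dict:
    """Two-tailed pooled-variance t-test from summary statistics."""
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=True)
    return {"t": float(t), "p": float(p)}


def fit_drift(timecourse, *, metabolite: str = "") -> DriftFit:
    """Ordinary least-squares line through an (hours, area) timecourse."""
    tc = np.asarray(timecourse, dtype=float)
    if tc.ndim != 2 or tc.shape[1] != 2:
        raise ValueError("timecourse must be a sequence of (t_h, area) pairs")
    t, y = tc[:, 0], tc[:, 1]
    if t.size < 3:
        raise ValueError("drift fit needs >= 3 timepoints")
    if np.ptp(t) == 0:
        raise ValueError("degenerate time axis")
    if np.ptp(t) <= 1.0:
        warnings.warn("timecourse spans <= 1 h; drift slope poorly determined")
    res = stats.linregress(t, y)
    return DriftFit(metabolite=metabolite, slope=float(res.slope),
                    intercept=float(res.intercept),
                    r_squared=float(res.rvalue ** 2),
                    duration_h=float(np.ptp(t)), n_points=t.size)


def initial_vs_final(initial: pd.DataFrame, final: pd.DataFrame, *,
                     value: str = "norm_volume",
                     by: str = "roi") -> tuple[list[ComparisonResult], pd.DataFrame]:
    """Paired one-tailed accumulation tests between two quantification tables.

    Samples present in only one table are excluded with a warning.  Returns
    one comparison per metabolite/ROI plus the per-sample difference table
    (final minus initial).
    """
    wi = initial.pivot_table(index="sample_id", columns=by, values=value)
    wf = final.pivot_table(index="sample_id", columns=by, values=value)
    shared = wi.index.intersection(wf.index)
    dropped = set(wi.index).symmetric_difference(wf.index)
    if dropped:
        warnings.warn(f"samples without a matched pair excluded: {sorted(dropped)}")
    wi, wf = wi.loc[shared], wf.loc[shared]
    results = []
    for col in wi.columns.intersection(wf.columns):
        x, y = wi[col].to_numpy(), wf[col].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 2:
            continue
        results.append(compare_groups(x[ok], y[ok], "paired_one_tailed",
                                      variable=str(col)))
    diff = (wf - wi)
    diff.columns.name = by
    return results, diff
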