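"""Disassembly-slope fits, group comparisons and cohort reporting.

Slopes are ordinary least squares over a stated time window (e.g. 0-4 min
for the inner scaffold, 2-4 min for the outer scaffold); two slopes are
compared with a Welch t-test on the slope estimates and their standard
errors.  Group comparisons use an unpaired (Welch) t-test for two groups and
one-way ANOVA followed by Tukey's HSD for more, annotated with the
significance convention * p<0.01, ** p<0.001, *** p<0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["SlopeFit", "ComparisonResult", "fit_slope", "compare_slopes",
           "compare_groups", "significance_stars", "aggregate_timecourses",
           "build_report"]


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of intensity vs. time over a window."""

    slope: float            # a.u./min
    intercept: float        # a.u.
    r_squared: float
    slope_stderr: float
    window_min: tuple[float, float]
    n_points: int

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_points < 2:
            raise ValueError("a slope fit needs at least 2 points")


@dataclass
class ComparisonResult:
    """Outcome of a statistical comparison."""

    test: str
    statistic: float
    p_value: float
    group_stats: pd.DataFrame = None          # mean, sem, n per group
    pairwise: pd.DataFrame = None             # adjusted p-values (Tukey)
    stars: str = ""


def significance_stars(p: float) -> str:
    """The significance annotation convention used throughout."""
    if p < 1e-4:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 1e-2:
        return "*"
    return ""


def fit_slope(times_min: Sequence[float], intensity: Sequence[float],
              t_start: float, t_end: float) -> SlopeFit:
    """OLS slope of intensity over the closed window [t_start, t_end]."""
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(intensity, dtype=float)
    sel = (t >= t_start) & (t <= t_end)
    t, y = t[sel], y[sel]
    if t.size < 2:
        raise ValueError(f"fewer than 2 points inside [{t_start}, {t_end}]")
    if np.ptp(t) == 0:
        raise ValueError("zero time variance inside the window")
    res = sps.linregress(t, y)
    return SlopeFit(float(res.slope), float(res.intercept),
                    float(res.rvalue ** 2), float(res.stderr),
                    (float(t_start), float(t_end)), int(t.size))


def compare_slopes(fit_a: SlopeFit, fit_b: SlopeFit) -> ComparisonResult:
    """Welch t-test on two slope estimates using their standard errors."""
    for f in (fit_a, fit_b):
        if not np.isfinite(f.slope_stderr) or f.slope_stderr <= 0:
            raise ValueError("both fits must carry a positive slope standard error")
        if f.n_points < 3:
            raise ValueError("slope comparison needs fits with >= 3 points")
    se2a, se2b = fit_a.slope_stderr ** 2, fit_b.slope_stderr ** 2
    tstat = (fit_a.slope - fit_b.slope) / np.sqrt(se2a + se2b)
    dfa, dfb = fit_a.n_points - 2, fit_b.n_points - 2
    df = (se2a + se2b) ** 2 / (se2a ** 2 / dfa + se2b ** 2 / dfb)
    p = 2.0 * sps.t.sf(abs(tstat), df)
    return ComparisonResult("welch_t_slopes", float(tstat), float(p),
                            stars=significance_stars(p))


def compare_groups(values_by_condition: Mapping[str, Sequence[float]]
                   ) -> ComparisonResult:
    """Unpaired t-test (2 groups) or one-way ANOVA + Tukey HSD (> 2 groups)."""
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_condition.items()}
    if len(groups) < 2:
        raise ValueError("at least 2 groups are required")
    for name, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {name!r} has n < 2")
    stats_rows = [dict(group=k, mean=v.mean(), sem=sps.sem(v), n=v.size)
                  for k, v in groups.items()]
    gtab = pd.DataFrame(stats_rows)
    vals = list(groups.values())
    if len(groups) == 2:
        t, p = sps.ttest_ind(vals[0], vals[1], equal_var=False)
        return ComparisonResult("welch_t", float(t), float(p), gtab,
                                stars=significance_stars(p))
    f, p = sps.f_oneway(*vals)
    data = np.concatenate(vals)
    labels = np.concatenate([[k] * v.size for k, v in groups.items()])
    tk = pairwise_tukeyhsd(data, labels)
    pair = pd.DataFrame(data=tk.summary().data[1:], columns=tk.summary().data[0])
    pair["stars"] = [significance_stars(pv) for pv in tk.pvalues]
    return ComparisonResult("anova_tukey", float(f), float(p), gtab, pair,
                            stars=significance_stars(p))


# ---------------------------------------------------------------------------
# Cohort reporting
# ---------------------------------------------------------------------------

def _mean_sem(values):
    v = np.asarray([x for x in values if x is not None], dtype=float)
    if v.size == 0:
        return np.nan, np.nan, 0
    sem = float(sps.sem(v)) if v.size > 1 else np.nan  # sem absent for n = 1
    return float(v.mean()), sem, int(v.size)


def aggregate_timecourses(tables: Sequence[pd.DataFrame], column: str
                          ) -> pd.DataFrame:
    """Mean +/- s.e.m. of one measurement column across movies per frame."""
    if not tables:
        raise ValueError("empty cohort")
    merged = pd.concat([t[["t_min", column]] for t in tables])
    g = merged.groupby("t_min")[column]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"count": "n"})


def build_report(cohort: Mapping[str, Sequence[dict]], out_dir=None,
                 make_plots: bool = True) -> dict[str, pd.DataFrame]:
    """Cohort tables (and optional plots) from per-movie analysis results.

    ``cohort`` maps condition name to a list of per-movie dicts with any of
    the keys ``boundaries`` (channel -> mean half-max radius, um), ``events``
    (:class:`~pcmkit.events.EventTimes` or dict), ``residual_au`` (float) and
    ``series`` (measurement DataFrame).  Emits a boundary table, an onset
    table (mean +/- sem per condition and event), a residual-intensity table
    and a slope-ready time-course table; deterministic given its inputs.
    """
    if not cohort or all(len(movies) == 0 for movies in cohort.values()):
        raise ValueError("empty cohort")
    tables: dict[str, pd.DataFrame] = {}

    rows = []
    for cond, movies in cohort.items():
        channels = sorted({ch for m in movies for ch in m.get("boundaries", {})})
        for ch in channels:
            mean, sem, n = _mean_sem([m.get("boundaries", {}).get(ch) for m in movies])
            rows.append(dict(condition=cond, channel=ch, hm_radius_um=mean,
                             sem=sem, n=n))
    if rows:
        tables["boundaries"] = pd.DataFrame(rows)

    rows = []
    event_fields = ["dissolution_onset_min", "volume_decrease_onset_min",
                    "rupture_onset_min", "packet_onset_min",
                    "stage1_onset_min", "stage2_onset_min"]
    for cond, movies in cohort.items():
        evs = [m["events"] if isinstance(m.get("events"), dict)
               else (m["events"].to_dict() if m.get("events") is not None else {})
               for m in movies]
        for fld in event_fields:
            vals = [e.get(fld) for e in evs if fld in e]
            if not vals:
                continue
            mean, sem, n = _mean_sem(vals)
            rows.append(dict(condition=cond, event=fld, mean_min=mean, sem=sem,
                             n_detected=n, n_movies=len(evs)))
    if rows:
        tables["onsets"] = pd.DataFrame(rows)

    rows = []
    for cond, movies in cohort.items():
        vals = [m.get("residual_au") for m in movies if m.get("residual_au") is not None]
        if vals:
            mean, sem, n = _mean_sem(vals)
            rows.append(dict(condition=cond, residual_au=mean, sem=sem, n=n))
    if rows:
        tables["residuals"] = pd.DataFrame(rows)

    for cond, movies in cohort.items():
        series = [m["series"] for m in movies if m.get("series") is not None]
        if series:
            tables[f"timecourse_{cond}"] = aggregate_timecourses(series, "centrosome_au")

    if out_dir is not None:
        from pathlib import Path
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, tab in tables.items():
            tab.to_csv(out_dir / f"{name}.csv", index=False)
        if make_plots:
            _plot_timecourses(tables, out_dir)
    return tables


def _plot_timecourses(tables, out_dir):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tc = {k.removeprefix("timecourse_"): v for k, v in tables.items()
          if k.startswith("timecourse_")}
    if not tc:
        return
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for cond, tab in tc.items():
        ax.errorbar(tab["t_min"], tab["mean"], yerr=tab["sem"].fillna(0.0),
                    label=cond, capsize=2)
    ax.set_xlabel("time post-NEBD (min)")
    ax.set_ylabel("centrosomal intensity (a.u.)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / "timecourses.png", dpi=150)
    plt.close(fig)
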