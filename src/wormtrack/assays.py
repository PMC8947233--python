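"""Statistics for pharmacological and egg-laying assays.

Covers the readouts used in worm neuropharmacology screens:

* paralysis time courses (aldicarb / levamisole) analyzed as the
  percentage of animals still moving at each time point, compared between
  groups with the log-rank test on right-censored paralysis times;
* convulsion proportions (PTZ) compared with Fisher's exact test under
  Bonferroni correction;
* egg-retention and reversal-rate group comparisons via two-sample
  t-test, one-way ANOVA with Bonferroni-corrected pairwise contrasts, or
  two-way ANOVA;
* the percent-rescue statistic quantifying how far a drug moves a mutant
  reversal rate back toward the solvent-matched wild-type rate:
  ``(1 - D1/D2) * 100`` with ``D1 = r_drug - r_wt`` and
  ``D2 = r_nodrug - r_wt`` — 0% when the drug changes nothing, 100% when
  the treated mutant matches wild type.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats


@dataclass(frozen=True)
class ParalysisRecord:
    """One animal in a paralysis assay: time of paralysis in minutes, or
    the censoring time (assay end) if it never paralyzed."""

    animal_id: str
    group: str
    event_time: float
    event_observed: bool = True

    def __post_init__(self) -> None:
        if self.event_time <= 0:
            raise ValueError("event_time must be > 0")


def records_from_frame(df: pd.DataFrame) -> list[ParalysisRecord]:
    """Build paralysis records from a tidy frame with columns
    ``animal_id, group, event_time, event_observed``."""
    return [
        ParalysisRecord(str(r.animal_id), str(r.group), float(r.event_time),
                        bool(r.event_observed))
        for r in df.itertuples(index=False)
    ]


def fraction_moving(records: list[ParalysisRecord],
                    timepoints: np.ndarray | list[float]) -> pd.DataFrame:
    """Percentage of animals per group still moving at each timepoint.

    An animal is moving at time t when its paralysis (or censoring) time
    exceeds t; the curve is monotone non-increasing and starts at 100%.
    Returns a frame with columns ``group, time_min, pct_moving``.
    """
    if not records:
        raise ValueError("no records")
    timepoints = np.asarray(timepoints, dtype=float)
    rows = []
    by_group: dict[str, list[ParalysisRecord]] = {}
    for r in records:
        by_group.setdefault(r.group, []).append(r)
    for group, recs in by_group.items():
        if not recs:
            raise ValueError(f"empty group {group!r}")
        times = np.array([r.event_time for r in recs])
        for t in timepoints:
            pct = 100.0 * float(np.mean(times > t))
            rows.append({"group": group, "time_min": float(t),
                         "pct_moving": pct})
    return pd.DataFrame(rows)


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    defined: bool  # False when neither group has any observed event


def logrank_test(group_a: list[ParalysisRecord],
                 group_b: list[ParalysisRecord]) -> LogrankResult:
    """Two-group log-rank chi-square (1 df) on paralysis times, with
    right censoring respected."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("log-rank needs >= 2 animals per group")
    ta = np.array([r.event_time for r in group_a])
    ea = np.array([r.event_observed for r in group_a], dtype=bool)
    tb = np.array([r.event_time for r in group_b])
    eb = np.array([r.event_observed for r in group_b], dtype=bool)
    if not ea.any() and not eb.any():
        return LogrankResult(statistic=np.nan, p_value=np.nan, defined=False)
    res = _lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogrankResult(statistic=float(res.test_statistic),
                         p_value=float(res.p_value), defined=True)


def proportion_test(tables: list[np.ndarray | list[list[int]]],
                    n_comparisons: int | None = None) -> pd.DataFrame:
    """Two-sided Fisher exact test per 2x2 table, Bonferroni-corrected.

    The Bonferroni multiplier defaults to the number of tables and is
    always explicit in the output; adjusted p values are capped at 1.
    Returns columns ``comparison, odds_ratio, p_raw, p_adjusted``.
    """
    if not tables:
        raise ValueError("no tables")
    if n_comparisons is None:
        n_comparisons = len(tables)
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    rows = []
    for i, table in enumerate(tables):
        t = np.asarray(table, dtype=int)
        if t.shape != (2, 2) or (t < 0).any():
            raise ValueError("each table must be 2x2 with counts >= 0")
        odds, p = stats.fisher_exact(t, alternative="two-sided")
        rows.append({"comparison": i, "odds_ratio": float(odds),
                     "p_raw": float(p),
                     "p_adjusted": min(1.0, float(p) * n_comparisons)})
    return pd.DataFrame(rows)


@dataclass
class GroupCompareResult:
    method: str
    omnibus_statistic: float | None
    omnibus_p: float | None
    pairwise: pd.DataFrame  # columns: group_a, group_b, statistic, p_raw, p_adjusted
    defined: bool = True


def _pairwise_t(values_by_group: dict, pairs: list[tuple],
                n_comparisons: int) -> pd.DataFrame:
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_ind(values_by_group[a], values_by_group[b],
                               equal_var=True)
        rows.append({"group_a": a, "group_b": b, "statistic": float(t),
                     "p_raw": float(p),
                     "p_adjusted": min(1.0, float(p) * n_comparisons)})
    return pd.DataFrame(rows)


def group_compare(values_by_group: dict[str, np.ndarray | list[float]],
                  method: str = "anova_bonferroni") -> GroupCompareResult:
    """Compare per-animal values across groups.

    ``t_test`` — two-sample pooled-variance t-test for every group pair
    (Bonferroni-adjusted when there are more than two groups);
    ``anova_bonferroni`` — one-way ANOVA omnibus F plus Bonferroni-adjusted
    pairwise t contrasts; ``two_way`` — two-way ANOVA with interaction,
    group keys being ``(factor_a, factor_b)`` tuples, plus Bonferroni
    pairwise cell contrasts.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for k, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs >= 2 values")
    if all(np.var(v) == 0 for v in groups.values()):
        means = {k: v.mean() for k, v in groups.items()}
        if len(set(means.values())) == 1:
            # no variance anywhere and identical means: test undefined
            return GroupCompareResult(method=method, omnibus_statistic=np.nan,
                                      omnibus_p=np.nan,
                                      pairwise=pd.DataFrame(), defined=False)
    pairs = list(itertools.combinations(sorted(groups, key=str), 2))

    if method == "t_test":
        pw = _pairwise_t(groups, pairs, n_comparisons=max(len(pairs), 1))
        if len(pairs) == 1:
            pw.loc[:, "p_adjusted"] = pw["p_raw"]
        return GroupCompareResult(method=method, omnibus_statistic=None,
                                  omnibus_p=None, pairwise=pw)
    if method == "anova_bonferroni":
        f, p = stats.f_oneway(*groups.values())
        pw = _pairwise_t(groups, pairs, n_comparisons=len(pairs))
        return GroupCompareResult(method=method, omnibus_statistic=float(f),
                                  omnibus_p=float(p), pairwise=pw)
    if method == "two_way":
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rows = []
        for key, vals in groups.items():
            if not (isinstance(key, tuple) and len(key) == 2):
                raise ValueError("two_way needs (factor_a, factor_b) keys")
            for v in vals:
                rows.append({"fa": str(key[0]), "fb": str(key[1]), "y": v})
        df = pd.DataFrame(rows)
        model = smf.ols("y ~ C(fa) * C(fb)", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        pw = _pairwise_t(groups, pairs, n_comparisons=len(pairs))
        return GroupCompareResult(
            method=method,
            omnibus_statistic=float(anova.loc["C(fa)", "F"]),
            omnibus_p=float(anova.loc["C(fa)", "PR(>F)"]),
            pairwise=pw)
    raise ValueError(f"unknown method: {method!r}")


@dataclass(frozen=True)
class RescueResult:
    """Percent rescue of an abnormal reversal rate by a drug.

    ``r_drug``/``r_nodrug`` are the mutant reversal rates with and without
    the drug; ``r_wt`` is the wild-type rate under the matched solvent.
    ``rescue_pct = (1 - delta1/delta2) * 100`` with
    ``delta1 = r_drug - r_wt`` and ``delta2 = r_nodrug - r_wt``.
    """

    r_drug: float
    r_nodrug: float
    r_wt: float
    delta1: float
    delta2: float
    rescue_pct: float


def percent_rescue(r_drug: float, r_nodrug: float, r_wt: float) -> RescueResult:
    """Percent rescue of the mutant reversal rate by a drug.

    0% when the drug leaves the mutant rate unchanged; 100% when the
    treated mutant matches the solvent-matched wild type.  Undefined when
    the untreated mutant already equals wild type (``delta2 = 0``).
    All three rates must come from solvent-matched cohorts: solvents
    themselves shift reversal rates, so the wild-type reference is always
    wild type plus the same solvent at the same concentration.
    """
    delta1 = r_drug - r_wt
    delta2 = r_nodrug - r_wt
    if delta2 == 0:
        raise ZeroDivisionError(
            "percent rescue undefined: untreated mutant rate equals the "
            "wild-type rate (delta2 = 0)")
    pct = (1.0 - delta1 / delta2) * 100.0
    return RescueResult(r_drug=r_drug, r_nodrug=r_nodrug, r_wt=r_wt,
                        delta1=delta1, delta2=delta2, rescue_pct=pct)
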