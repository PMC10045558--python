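"""Animal survival analysis: Kaplan-Meier curves, log-rank tests, %ILS.

Survival records are one row per animal (group, id, days since
implantation, event flag; event = death/euthanasia, censored = alive at
study end).  The module wraps lifelines for the product-limit estimator
and the asymptotic log-rank test, adds the exact permutation version of
the log-rank test for the very small group sizes typical of rodent
studies, and computes the percent increase in life span

    %ILS = (MST_group - MST_ref) * 100 / MST_ref

relative to an untreated reference group, where MST is the median
survival time.

The study-level interface is statsmodels-shaped: build a
:class:`SurvivalStudy` from a tidy dataframe, ``fit`` it, and read the
per-group summary table off the returned :class:`SurvivalStudyResults`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from ._util import round_half_up
from .errors import InputValidationError, UndefinedResultError

__all__ = [
    "km_curve",
    "median_survival",
    "percent_ils",
    "logrank_test",
    "logrank_permutation_test",
    "LogrankResult",
    "SurvivalStudy",
    "SurvivalStudyResults",
]

SURVIVAL_COLUMNS = ["group", "animal_id", "days", "event"]


def _as_arrays(times, events=None):
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise InputValidationError("at least one record is required")
    if np.any(t <= 0):
        raise InputValidationError("survival times must be > 0")
    if events is None:
        e = np.ones_like(t, dtype=bool)
    else:
        e = np.asarray(events).astype(bool)
        if e.shape != t.shape:
            raise InputValidationError("times and event flags must have the same length")
    return t, e


def km_curve(times, events=None) -> KaplanMeierFitter:
    """Product-limit (Kaplan-Meier) estimator of the survival function.

    Returns a fitted :class:`lifelines.KaplanMeierFitter`; the step
    function starts at 1, is right-continuous and non-increasing, and
    censored times leave the curve unchanged while shrinking the risk
    set.  ``events=None`` means no censoring.
    """
    t, e = _as_arrays(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    return kmf


def _km_steps(kmf: KaplanMeierFitter):
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def median_survival(curve_or_times, events=None, *, _half_tol: float = 1e-9) -> float:
    """Median survival time from a KM curve (or raw times).

    The median is the smallest time with S(t) <= 0.5.  When the curve
    sits exactly at 0.5 over an interval -- as happens for an even
    number of uncensored animals -- the midpoint of the two bracketing
    event times is reported, matching the classical sample median.
    If the curve never reaches 0.5 the median is undefined and
    :class:`~borondose.errors.UndefinedResultError` is raised.
    """
    kmf = curve_or_times if isinstance(curve_or_times, KaplanMeierFitter) else km_curve(curve_or_times, events)
    t, s = _km_steps(kmf)
    below = np.flatnonzero(s <= 0.5 + _half_tol)
    if below.size == 0:
        raise UndefinedResultError("survival curve never reaches 0.5; median undefined")
    i = below[0]
    if abs(s[i] - 0.5) <= _half_tol:
        # flat at exactly one half: midpoint convention
        later = np.flatnonzero(s < 0.5 - _half_tol)
        if later.size == 0:
            raise UndefinedResultError("curve settles at 0.5 without dropping below; median undefined")
        return 0.5 * (t[i] + t[later[0]])
    return float(t[i])


def percent_ils(mst_group: float, mst_ref: float, ndigits: int = 1) -> float:
    """Percent increase in life span relative to a reference median."""
    if not mst_ref > 0:
        raise InputValidationError("reference median survival must be > 0")
    if not np.isfinite(mst_group):
        raise UndefinedResultError("group median survival is undefined; %ILS undefined")
    return round_half_up((mst_group - mst_ref) * 100.0 / mst_ref, ndigits)


@dataclass(frozen=True)
class LogrankResult:
    statistic: float          # chi-square, 1 df
    pvalue: float
    significant: bool
    method: str = "asymptotic"


def logrank_test(times_a, events_a, times_b, events_b, alpha: float = 0.05) -> LogrankResult:
    """Two-group log-rank test (hypergeometric variance, chi^2_1 p-value)."""
    ta, ea = _as_arrays(times_a, events_a)
    tb, eb = _as_arrays(times_b, events_b)
    if int(ea.sum() + eb.sum()) == 0:
        raise UndefinedResultError("no events in either group; log-rank test undefined")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogrankResult(
        statistic=float(res.test_statistic),
        pvalue=float(res.p_value),
        significant=bool(res.p_value < alpha),
    )


def _logrank_chi2(times: np.ndarray, events: np.ndarray, in_a: np.ndarray) -> float:
    """Log-rank chi-square via the standard O-E / hypergeometric-variance sums."""
    order = np.argsort(times, kind="stable")
    t, e, a = times[order], events[order], in_a[order]
    o_minus_e = 0.0
    var = 0.0
    i = 0
    n = t.size
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        at_risk = n - i
        at_risk_a = int(a[i:].sum())
        d = int(e[i:j].sum())
        if d > 0:
            d_a = int((e[i:j] & a[i:j]).sum())
            frac = at_risk_a / at_risk
            o_minus_e += d_a - d * frac
            if at_risk > 1:
                var += d * frac * (1 - frac) * (at_risk - d) / (at_risk - 1)
        i = j
    if var == 0:
        return 0.0
    return o_minus_e**2 / var


def logrank_permutation_test(times_a, events_a, times_b, events_b,
                             max_exhaustive: int = 12, n_mc: int = 20000,
                             seed: Optional[int] = None) -> LogrankResult:
    """Permutation log-rank test, exact for small studies.

    All group-label assignments are enumerated when the total sample
    size is at most ``max_exhaustive`` (preserving group sizes);
    otherwise a Monte Carlo sample of assignments is used.  The p-value
    is the fraction of assignments whose chi-square statistic is at
    least the observed one (two-sided by construction).
    """
    ta, ea = _as_arrays(times_a, events_a)
    tb, eb = _as_arrays(times_b, events_b)
    if int(ea.sum() + eb.sum()) == 0:
        raise UndefinedResultError("no events in either group; log-rank test undefined")
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    n, n_a = times.size, ta.size
    base = np.zeros(n, dtype=bool)
    base[:n_a] = True
    observed = _logrank_chi2(times, events, base)
    tol = 1e-12
    if n <= max_exhaustive:
        hits = total = 0
        for combo in itertools.combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            total += 1
            if _logrank_chi2(times, events, mask) >= observed - tol:
                hits += 1
        p = hits / total
        method = "exact permutation"
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        idx = np.arange(n)
        for _ in range(n_mc):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(idx, size=n_a, replace=False)] = True
            if _logrank_chi2(times, events, mask) >= observed - tol:
                hits += 1
        p = (hits + 1) / (n_mc + 1)
        method = "monte-carlo permutation"
    return LogrankResult(statistic=float(observed), pvalue=float(p),
                         significant=bool(p < 0.05), method=method)


class SurvivalStudy:
    """A grouped preclinical survival study.

    Parameters
    ----------
    data : DataFrame
        Tidy table with columns ``group``, ``animal_id``, ``days``,
        ``event`` (1 = death/euthanasia, 0 = censored).
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in SURVIVAL_COLUMNS if c not in data.columns]
        if missing:
            raise InputValidationError(f"survival table is missing columns {missing}")
        if (data["days"] <= 0).any():
            raise InputValidationError("survival times must be > 0")
        self.data = data.copy()
        self.data["event"] = self.data["event"].astype(int)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SurvivalStudy":
        return cls(df)

    def groups(self):
        return list(dict.fromkeys(self.data["group"]))

    def fit(self, ref: Optional[str] = None, ils_reference: str = "median") -> "SurvivalStudyResults":
        """Fit per-group KM curves and assemble the study summary.

        ``ref`` names the reference (untreated) group for %ILS and
        pairwise log-rank tests; ``ils_reference`` selects whether the
        %ILS denominator is the reference group's median (the defining
        equation) or its mean (an occasionally used variant -- the two
        coincide when the reference distribution is symmetric).
        """
        if ils_reference not in ("median", "mean"):
            raise InputValidationError("ils_reference must be 'median' or 'mean'")
        curves: Dict[str, KaplanMeierFitter] = {}
        for g in self.groups():
            sub = self.data[self.data["group"] == g]
            curves[g] = km_curve(sub["days"], sub["event"])
        return SurvivalStudyResults(study=self, curves=curves, ref=ref,
                                    ils_reference=ils_reference)


@dataclass
class SurvivalStudyResults:
    """Per-group medians, means, %ILS and log-rank comparisons."""

    study: SurvivalStudy
    curves: Dict[str, KaplanMeierFitter]
    ref: Optional[str]
    ils_reference: str = "median"
    _summary: Optional[pd.DataFrame] = field(default=None, repr=False)

    def median(self, group: str) -> float:
        return median_survival(self.curves[group])

    def _ref_value(self) -> float:
        sub = self.study.data[self.study.data["group"] == self.ref]
        if self.ils_reference == "mean":
            return float(sub["days"].mean())
        return self.median(self.ref)

    def pct_ils(self, group: str) -> float:
        if self.ref is None:
            raise InputValidationError("no reference group set; %ILS undefined")
        return percent_ils(self.median(group), self._ref_value())

    def logrank_vs_ref(self, group: str, permutation: bool = False) -> LogrankResult:
        if self.ref is None:
            raise InputValidationError("no reference group set")
        a = self.study.data[self.study.data["group"] == group]
        b = self.study.data[self.study.data["group"] == self.ref]
        fn = logrank_permutation_test if permutation else logrank_test
        return fn(a["days"], a["event"], b["days"], b["event"])

    def summary(self) -> pd.DataFrame:
        """Report-style table: n, mean +/- SD, median, 95% CI, %ILS, p."""
        if self._summary is not None:
            return self._summary
        rows = []
        for g in self.study.groups():
            sub = self.study.data[self.study.data["group"] == g]
            kmf = self.curves[g]
            try:
                med = self.median(g)
                med_str = f"{med:.1f}"
            except UndefinedResultError:
                med, med_str = np.nan, "undefined"
            ci = self._median_ci(kmf)
            row = {
                "group": g,
                "n": len(sub),
                "mean": round_half_up(sub["days"].mean(), 1),
                "sd": round_half_up(sub["days"].std(ddof=1), 1) if len(sub) > 1 else np.nan,
                "median": med,
                "median_display": med_str,
                "ci95": ci,
            }
            if self.ref is not None and g != self.ref:
                row["pct_ils"] = self.pct_ils(g) if np.isfinite(med) else np.nan
                lr = self.logrank_vs_ref(g)
                row["logrank_p"] = lr.pvalue
            else:
                row["pct_ils"] = np.nan
                row["logrank_p"] = np.nan
            rows.append(row)
        self._summary = pd.DataFrame(rows)
        return self._summary

    @staticmethod
    def _median_ci(kmf: KaplanMeierFitter) -> str:
        """95% CI of the median as a display string; open upper bounds

        are rendered with a trailing dash (e.g. ``27-``)."""
        from lifelines.utils import median_survival_times

        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        lo_s = "?" if not np.isfinite(lo) else f"{lo:g}"
        if not np.isfinite(hi):
            return f"{lo_s}-"
        return f"{lo_s}-{hi:g}"

    def plot(self, ax=None):
        """Overlay the per-group KM curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for g, kmf in self.curves.items():
            kmf.plot_survival_function(ax=ax, label=str(g))
        ax.set_xlabel("days after implantation")
        ax.set_ylabel("surviving fraction")
        return ax


def mean_sd(times) -> tuple:
    """Naive mean and SD of observed times (censored times enter as-is)."""
    t = np.asarray(times, dtype=float)
    return float(t.mean()), float(t.std(ddof=1)) if t.size > 1 else float("nan")
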