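"""Tumor-response classification and survival analysis for xenograft studies.

A treated xenograft trajectory is classified from its caliper-volume time
series: complete response (volume reaches zero, confirmed over consecutive
measurements, and stays zero to study end), regrowth after a confirmed
complete response, progression (the tumor-bearing limit is reached, which
ends the animal's time on study), or stable.  Survival endpoints are the
limit-reaching days; animals removed for non-tumor reasons are censored.

Kaplan–Meier estimation and the Mantel–Cox log-rank test are delegated to
lifelines behind this module's interface; results are returned as small
typed objects (:class:`KMCurve`, :class:`LogrankResult`) so downstream code
does not depend on lifelines' API.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "TumorGrowthRecord",
    "ResponseCall",
    "classify_response",
    "CRRate",
    "cr_rate",
    "SurvivalDataset",
    "KMCurve",
    "kaplan_meier",
    "LogrankResult",
    "logrank_test",
    "survival_summary",
]

RESPONSE_STATES = ("complete_response", "regrowth_after_cr", "progression", "stable")


@dataclass(frozen=True)
class TumorGrowthRecord:
    """One animal's caliper-volume trajectory."""

    animal_id: str
    group: str
    times_d: tuple[float, ...]
    volumes_mm3: tuple[float, ...]
    end_of_study_d: Optional[float] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_d, dtype=float)
        v = np.asarray(self.volumes_mm3, dtype=float)
        if t.size == 0:
            raise ValueError(f"{self.animal_id}: empty growth record")
        if t.size != v.size:
            raise ValueError(f"{self.animal_id}: times/volumes length mismatch")
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"{self.animal_id}: measurement days must be strictly increasing")
        if np.any(v < 0):
            raise ValueError(f"{self.animal_id}: negative volume")

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.times_d, dtype=float)

    @property
    def volumes(self) -> np.ndarray:
        return np.asarray(self.volumes_mm3, dtype=float)


@dataclass(frozen=True)
class ResponseCall:
    """Classification of one growth trajectory.

    ``cr_day`` is the day of the first measurement opening a qualifying
    zero-volume streak (if any); ``limit_day`` the day the tumor-bearing
    limit was reached (if any).
    """

    animal_id: str
    group: str
    state: str
    cr_day: Optional[float] = None
    limit_day: Optional[float] = None

    def __post_init__(self) -> None:
        if self.state not in RESPONSE_STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == "regrowth_after_cr" and self.cr_day is None:
            raise ValueError("regrowth_after_cr requires a cr_day")
        if self.state == "progression" and self.limit_day is None:
            raise ValueError("progression requires a limit_day")


def classify_response(
    rec: TumorGrowthRecord,
    limit_mm3: float = 1000.0,
    confirm_n: int = 2,
    limit_rule: str = "interpolate",
) -> ResponseCall:
    """Classify one trajectory against the tumor-bearing limit.

    Progression takes precedence: the analysis stops at the first limit
    crossing (appending post-limit measurements never changes the call).
    The crossing day is linearly interpolated between the bracketing
    measurements (``limit_rule="interpolate"``, the default — caliper days
    are sparse and the survival endpoint is the limit-reaching day) or
    taken as the first measurement at or above the limit
    (``limit_rule="first_measurement"``).

    A complete response requires ``confirm_n`` consecutive zero-volume
    measurements sustained to the end of the record; a qualifying zero
    streak followed by any positive volume is regrowth after CR.  A single
    unconfirmed zero leaves the animal "stable".
    """
    if limit_mm3 <= 0:
        raise ValueError("limit_mm3 must be > 0")
    if confirm_n < 1:
        raise ValueError("confirm_n must be >= 1")
    if limit_rule not in ("interpolate", "first_measurement"):
        raise ValueError(f"unknown limit_rule {limit_rule!r}")
    t, v = rec.times, rec.volumes

    # truncate at first limit crossing
    over = np.nonzero(v >= limit_mm3)[0]
    limit_day: Optional[float] = None
    if over.size:
        i = int(over[0])
        if limit_rule == "first_measurement" or i == 0 or v[i] == limit_mm3:
            limit_day = float(t[i])
        else:
            frac = (limit_mm3 - v[i - 1]) / (v[i] - v[i - 1])
            limit_day = float(t[i - 1] + frac * (t[i] - t[i - 1]))
        t, v = t[: i + 1], v[: i + 1]

    cr_day = _first_qualifying_zero(t, v, confirm_n)

    if limit_day is not None:
        return ResponseCall(rec.animal_id, rec.group, "progression", cr_day=cr_day, limit_day=limit_day)
    if cr_day is not None:
        # does the record end inside a zero streak?
        last_pos = np.nonzero(v > 0)[0]
        last_pos_day = t[last_pos[-1]] if last_pos.size else -np.inf
        if last_pos_day > cr_day:
            return ResponseCall(rec.animal_id, rec.group, "regrowth_after_cr", cr_day=cr_day)
        return ResponseCall(rec.animal_id, rec.group, "complete_response", cr_day=cr_day)
    return ResponseCall(rec.animal_id, rec.group, "stable")


def _first_qualifying_zero(t: np.ndarray, v: np.ndarray, confirm_n: int) -> Optional[float]:
    """Day opening the first run of >= confirm_n consecutive zero volumes."""
    run = 0
    for i, x in enumerate(v):
        if x == 0:
            run += 1
            if run == confirm_n:
                return float(t[i - confirm_n + 1])
        else:
            run = 0
    return None


@dataclass(frozen=True)
class CRRate:
    """Complete-response rate with its numerator and denominator."""

    n_cr: int
    n: int

    @property
    def fraction(self) -> float:
        return self.n_cr / self.n

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction

    def __str__(self) -> str:
        return f"{self.percent:.0f}% complete response ({self.n_cr}/{self.n})"


def cr_rate(calls: Sequence[ResponseCall]) -> CRRate:
    """Fraction of animals with a sustained complete response."""
    if not calls:
        raise ValueError("cr_rate of an empty list is undefined")
    return CRRate(sum(c.state == "complete_response" for c in calls), len(calls))


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored event-time records: (animal_id, group, time_d, event)."""

    records: tuple[tuple[str, str, float, int], ...]

    def __post_init__(self) -> None:
        for aid, grp, time_d, event in self.records:
            if not time_d > 0:
                raise ValueError(f"{aid}: time_d must be > 0")
            if event not in (0, 1):
                raise ValueError(f"{aid}: event must be 0 or 1")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalDataset":
        return cls(
            tuple(
                (str(r.animal_id), str(r.group), float(r.time_d), int(r.event))
                for r in df.itertuples()
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["animal_id", "group", "time_d", "event"])

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, grp, _, _ in self.records:
            seen.setdefault(grp, None)
        return tuple(seen)

    def group_arrays(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        rows = [(t, e) for _, g, t, e in self.records if g == group]
        if not rows:
            raise ValueError(f"no records in group {group!r}")
        arr = np.asarray(rows, dtype=float)
        return arr[:, 0], arr[:, 1].astype(int)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate for one group.

    ``times`` starts at 0 with S(0)=1; ``at_risk`` is the risk-set size
    just before each time.  ``median_d`` is the smallest event time with
    S <= 0.5, or None when the curve never falls that far (an undefined
    median — reported as such, never as infinity).
    """

    group: str
    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    median_d: Optional[float]

    def __post_init__(self) -> None:
        s = np.asarray(self.survival)
        if s.size == 0 or s[0] != 1.0:
            raise ValueError("survival must start at S(0)=1")
        if np.any(s < 0) or np.any(s > 1) or np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing within [0, 1]")

    @property
    def median_defined(self) -> bool:
        return self.median_d is not None

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(np.asarray(self.times), t, side="right") - 1
        return self.survival[max(idx, 0)]


def kaplan_meier(data: SurvivalDataset, group: str) -> KMCurve:
    """Kaplan–Meier product-limit estimate S(t) = prod (1 - d_i/n_i)."""
    durations, events = data.group_arrays(group)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events, label=group)
    sf = kmf.survival_function_[group]
    times = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    if times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    at_risk = np.array([(durations >= t).sum() for t in times], dtype=int)
    med = kmf.median_survival_time_
    median_d = None if np.isinf(med) else float(med)
    return KMCurve(
        group=group,
        times=tuple(times),
        survival=tuple(surv),
        at_risk=tuple(at_risk),
        median_d=median_d,
    )


@dataclass(frozen=True)
class LogrankResult:
    """Mantel–Cox log-rank test: chi-square statistic with 1 df."""

    chi2: float
    p_value: float
    df: int = 1

    def summary(self) -> str:
        return f"log-rank chi2={self.chi2:.4g}, df={self.df}, p={self.p_value:.4g}"


def logrank_test(data: SurvivalDataset, group_a: str, group_b: str) -> LogrankResult:
    """Two-sample Mantel–Cox log-rank test (aggregated ties, no correction).

    With no events in either group the statistic is 0 and p = 1.
    """
    ta, ea = data.group_arrays(group_a)
    tb, eb = data.group_arrays(group_b)
    if ea.sum() + eb.sum() == 0:
        return LogrankResult(chi2=0.0, p_value=1.0)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(chi2):  # degenerate risk sets
        return LogrankResult(chi2=0.0, p_value=1.0)
    return LogrankResult(chi2=chi2, p_value=p)


def survival_summary(
    curves: Mapping[str, KMCurve], reference_group: str
) -> pd.DataFrame:
    """Median survival per group and fold-change versus a reference.

    Groups whose curve never reaches S <= 0.5 have an undefined median and
    an undefined fold (NaN, ``median_defined=False``) — never infinity.
    """
    if reference_group not in curves:
        raise ValueError(f"unknown reference group {reference_group!r}")
    ref = curves[reference_group]
    if not ref.median_defined:
        raise ValueError(f"reference group {reference_group!r} has an undefined median")
    rows = []
    for name, c in curves.items():
        fold = c.median_d / ref.median_d if c.median_defined else np.nan
        rows.append((name, c.median_d if c.median_defined else np.nan, c.median_defined, fold))
    return pd.DataFrame(
        rows, columns=["group", "median_d", "median_defined", "fold_vs_reference"]
    )
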