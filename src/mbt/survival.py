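"""Survival analysis from first principles.

Implements the estimators the study's efficacy claim rests on:
Kaplan-Meier product-limit curves, arithmetic means truncated at a fixed
decimal place (the table-reporting convention that turns 8.667 into
8.6), and the Mantel-Cox log-rank test — observed-minus-expected events
under the hypergeometric model at each distinct event time, with ties
aggregated, a chi-square statistic on 1 degree of freedom and its upper
tail probability via the complementary error function.

Records use time in days from treatment; ``event`` is true for a
death/euthanasia-for-cause and false for censoring at the observation
horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError


@dataclass(frozen=True)
class SurvivalRecord:
    animal_id: str
    group: str
    time: float  # days from treatment
    event: bool  # True = death/euthanasia for cause, False = censored

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ConfigurationError("survival time must be > 0")


@dataclass(frozen=True)
class LogRankResult:
    statistic: float  # chi-square, 1 df
    df: int
    p: float  # raw upper-tail probability
    observed: tuple[float, float]  # events per group (A, B)
    expected: tuple[float, float]

    @property
    def p_reported(self) -> str:
        """Two-decimal truncated report; values below 0.01 print as '<0.01'."""
        truncated = truncate(self.p, 2)
        return "<0.01" if self.p < 0.01 else f"{truncated:.2f}"


def truncate(x: float, decimals: int) -> float:
    """Truncate toward zero at ``decimals`` places (8.667 -> 8.6 at 1)."""
    f = 10.0**decimals
    eps = math.copysign(1e-9, x)
    return math.trunc(x * f + eps) / f


def truncated_mean(times, decimals: int = 1) -> float:
    """Arithmetic mean truncated toward zero at the given decimal place."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ConfigurationError("empty time list")
    return truncate(float(t.mean()), decimals)


def km_estimate(records: list[SurvivalRecord]) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimator.

    Returns a step table with columns time, n_at_risk, n_events,
    survival; censored times shrink the risk set without adding steps.
    S(t) applies to all t at or beyond the row's time.
    """
    if not records:
        raise ConfigurationError("empty record list")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    rows = [{"time": 0.0, "n_at_risk": len(records), "n_events": 0, "survival": 1.0}]
    s = 1.0
    for t in np.unique(times):
        at_risk = int((times >= t).sum())
        d = int(events[times == t].sum())
        if d > 0:
            s *= 1.0 - d / at_risk
            rows.append({"time": float(t), "n_at_risk": at_risk, "n_events": d, "survival": s})
    return pd.DataFrame(rows)


def km_survival_at(km: pd.DataFrame, t: float) -> float:
    """Survival probability at time t from a km_estimate table."""
    past = km[km["time"] <= t]
    return float(past["survival"].iloc[-1])


def chi2_upper_tail(x: float, df: int = 1) -> float:
    """Upper tail of the chi-square distribution with 1 df via erfc(√(x/2))."""
    if x < 0:
        raise ConfigurationError("chi-square statistic must be >= 0")
    if df != 1:
        raise ConfigurationError("only df=1 is supported")
    return math.erfc(math.sqrt(x / 2.0))


def logrank_test(group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]) -> LogRankResult:
    """Mantel-Cox log-rank test between two groups of survival records.

    At each distinct event time, the observed events in group A are
    compared with their hypergeometric expectation given the pooled risk
    set; the statistic is (Σ(O−E))² / ΣVar, chi-square with 1 df.  A
    pooled comparison of one group against several others is obtained by
    concatenating the others into ``group_b``.
    """
    if not group_a or not group_b:
        raise ConfigurationError("both groups must be non-empty")
    t_a = np.array([r.time for r in group_a], dtype=float)
    e_a = np.array([r.event for r in group_a], dtype=bool)
    t_b = np.array([r.time for r in group_b], dtype=float)
    e_b = np.array([r.event for r in group_b], dtype=bool)
    all_event_times = np.unique(np.concatenate([t_a[e_a], t_b[e_b]]))
    if all_event_times.size == 0:
        raise ConfigurationError("no events in either group")

    o_minus_e = 0.0
    var = 0.0
    obs_a = obs_b = exp_a = exp_b = 0.0
    for t in all_event_times:
        n_a = int((t_a >= t).sum())
        n_b = int((t_b >= t).sum())
        n = n_a + n_b
        d_a = int(e_a[t_a == t].sum())
        d_b = int(e_b[t_b == t].sum())
        d = d_a + d_b
        ea = d * n_a / n
        o_minus_e += d_a - ea
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
        obs_a += d_a
        obs_b += d_b
        exp_a += ea
        exp_b += d * n_b / n

    if var == 0.0:
        statistic = 0.0
    else:
        statistic = o_minus_e**2 / var
    return LogRankResult(
        statistic=float(statistic),
        df=1,
        p=chi2_upper_tail(float(statistic)),
        observed=(obs_a, obs_b),
        expected=(exp_a, exp_b),
    )


def records_from_frame(frame: pd.DataFrame, group_col: str = "arm") -> dict[str, list[SurvivalRecord]]:
    """Split a cohort table (animal_id, arm, time_days, event) into record lists."""
    out: dict[str, list[SurvivalRecord]] = {}
    for _, row in frame.iterrows():
        rec = SurvivalRecord(
            animal_id=str(row["animal_id"]),
            group=str(row[group_col]),
            time=float(row["time_days"]),
            event=bool(row["event"]),
        )
        out.setdefault(rec.group, []).append(rec)
    return out


def table2_records() -> dict[str, list[SurvivalRecord]]:
    """The study cohort's printed survival times, as record lists.

    Treated arm: five animals censored at the 66-day horizon; sham
    (non-radioactive) arm: events at 9, 8, 9 days; control arm: events
    at 8, 6, 8 days.
    """
    def recs(group: str, times, event: bool) -> list[SurvivalRecord]:
        return [
            SurvivalRecord(animal_id=f"{group}_{i + 1}", group=group, time=t, event=event)
            for i, t in enumerate(times)
        ]

    return {
        "treated": recs("treated", (66, 66, 66, 66, 66), False),
        "sham": recs("sham", (9, 8, 9), True),
        "control": recs("control", (8, 6, 8), True),
    }
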