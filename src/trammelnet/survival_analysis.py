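"""Discard-survival estimation: immediate, captive vitality, Kaplan-Meier.

Immediate survival is the fraction of discarded animals still alive
when the gear reaches the deck; its uncertainty is a Bayesian
credibility interval from the Beta(alive + 1, dead + 1) posterior of a
binomial proportion under a uniform prior.

Short-term (seven-day) survival of undersized lobsters combines the
on-deck outcome with a captive observation cohort: animals alive on
arrival and not followed in captivity are right-censored at day zero,
and the product-limit (Kaplan-Meier) estimator with Greenwood variance
gives the combined survival curve.  Captive animals are scored on a
four-point vitality scale (DEAD < POOR < GOOD < EXCELLENT) on days
0, 1, 2, 4 and 7; DEAD is absorbing.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "VITALITY_LEVELS",
    "OBSERVATION_DAYS",
    "SurvivalCount",
    "VitalityRecord",
    "KMInput",
    "KMCurve",
    "immediate_survival",
    "km_fit",
    "vitality_table",
    "read_survival_counts",
    "read_km_input",
    "read_vitality",
    "immediate_survival_table",
]

#: ordinal vitality scale, worst to best; encoded 0-3
VITALITY_LEVELS = ("DEAD", "POOR", "GOOD", "EXCELLENT")
#: captive observation schedule (days)
OBSERVATION_DAYS = (0, 1, 2, 4, 7)


@dataclass(frozen=True)
class SurvivalCount:
    """Alive-at-arrival count for one species."""

    species: str
    alive: int
    total: int

    def __post_init__(self) -> None:
        if self.alive < 0 or self.total < self.alive:
            raise ValueError(
                f"{self.species}: need 0 <= alive <= total, got {self.alive}/{self.total}")


@dataclass(frozen=True)
class VitalityRecord:
    individual_id: str
    day: int
    status: str

    def __post_init__(self) -> None:
        if self.status not in VITALITY_LEVELS:
            raise ValueError(f"unknown vitality status {self.status!r}")
        if self.day < 0:
            raise ValueError("day must be >= 0")


@dataclass(frozen=True)
class KMInput:
    """One individual's follow-up: time in days and death indicator."""

    time: float
    event: bool  # True = death observed, False = right-censored

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time < 0:
            raise ValueError("time must be finite and >= 0")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival step function with Greenwood uncertainty."""

    times: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): step-function value at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def immediate_survival(count: SurvivalCount, ci_level: float = 0.95
                       ) -> tuple[float, float, float]:
    """Point estimate alive/total and Beta-posterior credibility bounds.

    The interval is the central ``ci_level`` quantile interval of
    Beta(alive + 1, total - alive + 1), the binomial posterior under a
    uniform prior.
    """
    if count.total < 1:
        raise ValueError("total must be >= 1")
    point = count.alive / count.total
    alpha = (1.0 - ci_level) / 2.0
    post = stats.beta(count.alive + 1, count.total - count.alive + 1)
    return point, float(post.ppf(alpha)), float(post.ppf(1.0 - alpha))


def km_fit(inputs: Sequence[KMInput], ci_level: float = 0.95) -> KMCurve:
    """Kaplan-Meier product-limit estimator with Greenwood variance.

    Ties at one time are processed deaths first, censorings second.  The
    confidence interval is computed on the log-survival scale,
    S * exp(+-z * se(log S)), clipped to [0, 1]; where S = 0 the
    Greenwood SE and interval collapse to 0.
    """
    if not inputs:
        raise ValueError("need at least one individual")
    times = np.array([i.time for i in inputs], dtype=float)
    events = np.array([i.event for i in inputs], dtype=bool)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    uniq = np.unique(times)
    at_risk = len(times)
    surv = 1.0
    green_sum = 0.0  # running sum of d / (n (n - d))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    out_t, out_s, out_se, out_lo, out_hi = [], [], [], [], []
    for t in uniq:
        here = times == t
        d = int(np.count_nonzero(events & here))
        c = int(np.count_nonzero(~events & here))
        if d > 0:
            surv *= 1.0 - d / at_risk
            if at_risk > d:
                green_sum += d / (at_risk * (at_risk - d))
            if surv > 0:
                se = surv * math.sqrt(green_sum)
                se_log = math.sqrt(green_sum)
                lo = min(1.0, max(0.0, surv * math.exp(-z * se_log)))
                hi = min(1.0, max(0.0, surv * math.exp(z * se_log)))
            else:
                se, lo, hi = 0.0, 0.0, 0.0
            out_t.append(float(t))
            out_s.append(surv)
            out_se.append(se)
            out_lo.append(lo)
            out_hi.append(hi)
        at_risk -= d + c
    return KMCurve(
        times=np.asarray(out_t), survival=np.asarray(out_s),
        greenwood_se=np.asarray(out_se), ci_low=np.asarray(out_lo),
        ci_high=np.asarray(out_hi),
    )


def vitality_table(records: Iterable[VitalityRecord]):
    """Day x status contingency counts of captive vitality trajectories.

    Validates the monotone-death invariant: an individual observed DEAD
    stays DEAD at every later observation day.
    """
    import pandas as pd

    records = list(records)
    by_indiv: dict[str, list[VitalityRecord]] = {}
    for r in records:
        by_indiv.setdefault(r.individual_id, []).append(r)
    for iid, recs in by_indiv.items():
        recs.sort(key=lambda r: r.day)
        dead = False
        for r in recs:
            if dead and r.status != "DEAD":
                raise ValueError(f"individual {iid} regressed from DEAD on day {r.day}")
            dead = dead or r.status == "DEAD"
    if not records:
        return pd.DataFrame(columns=list(VITALITY_LEVELS), dtype=int)
    days = sorted({r.day for r in records})
    table = pd.DataFrame(0, index=days, columns=list(VITALITY_LEVELS), dtype=int)
    for r in records:
        table.loc[r.day, r.status] += 1
    table.index.name = "day"
    return table


# ---------------------------------------------------------------------------
# File I/O and report helpers
# ---------------------------------------------------------------------------

def read_survival_counts(path: str | Path) -> list[SurvivalCount]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [SurvivalCount(r["species"], int(r["alive"]), int(r["total"]))
                for r in csv.DictReader(fh)]


def read_km_input(path: str | Path) -> list[KMInput]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [KMInput(float(r["time_days"]), r["event"] in ("True", "true", "1"))
                for r in csv.DictReader(fh)]


def read_vitality(path: str | Path) -> list[VitalityRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [VitalityRecord(r["individual_id"], int(r["day"]), r["status"])
                for r in csv.DictReader(fh)]


def immediate_survival_table(counts: Sequence[SurvivalCount]):
    """Per-species summary table: species, alive, total, point, 2.5%, 97.5%."""
    import pandas as pd

    rows = []
    for c in counts:
        point, lo, hi = immediate_survival(c)
        rows.append({"species": c.species, "alive": c.alive, "total": c.total,
                     "survival": point, "cri_2.5": lo, "cri_97.5": hi})
    return pd.DataFrame(rows)
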