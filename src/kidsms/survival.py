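"""Kaplan-Meier estimation and log-rank comparison of event ages.

Used to compare age at Kid-SMS risk stratification against age at
Ghent-2 diagnosis.  Estimation is delegated to lifelines; this module
fixes the contract: product-limit estimator, censored subjects reduce
the risk set without creating steps, deaths processed before
censorings at tied times, and subjects never reaching the endpoint
censored at age at last visit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import KidsmsError


@dataclass(frozen=True)
class EventSeries:
    """Ages at event or censoring with parallel event indicators."""

    times: tuple[float, ...]
    events: tuple[bool, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "events", tuple(bool(e) for e in self.events))
        if len(self.times) != len(self.events):
            raise ValueError("times and events must have equal length")
        if not self.times:
            raise ValueError("series must be non-empty")
        if any(not math.isfinite(t) or t < 0 for t in self.times):
            raise ValueError("times must be finite and non-negative")

    @property
    def n_events(self) -> int:
        return sum(self.events)


@dataclass(frozen=True)
class KMCurve:
    """Step representation of a Kaplan-Meier curve at event times."""

    event_times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    label: str = ""

    def to_table(self) -> pd.DataFrame:
        """Plain (time, at-risk, survival) table suitable for plotting."""
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "survival": self.survival,
            }
        )


def km_estimate(series: EventSeries) -> KMCurve:
    """Product-limit survival estimate of an event-age series.

    Returns the curve at the distinct event times only; censoring times
    shrink the risk set without introducing steps.

    Raises
    ------
    KidsmsError
        If the series contains no events (the estimator would be the
        constant 1 with nothing to anchor it).
    """
    if series.n_events == 0:
        raise KidsmsError("cannot estimate a survival curve without any events")
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(series.times), np.asarray(series.events, dtype=bool))
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = tuple(float(t) for t in event_rows.index)
    at_risk = tuple(int(n) for n in event_rows["at_risk"])
    survival = tuple(
        float(kmf.survival_function_.loc[t].iloc[0]) for t in event_rows.index
    )
    return KMCurve(
        event_times=times, survival=survival, at_risk=at_risk, label=series.label
    )


def logrank_test(a: EventSeries, b: EventSeries) -> float:
    """Two-sided p-value of the standard (unweighted) log-rank test, 1 df."""
    if a.n_events == 0 or b.n_events == 0:
        raise KidsmsError("log-rank test requires events in both series")
    result = _ll_logrank(
        np.asarray(a.times),
        np.asarray(b.times),
        event_observed_A=np.asarray(a.events, dtype=bool),
        event_observed_B=np.asarray(b.events, dtype=bool),
    )
    return float(result.p_value)
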