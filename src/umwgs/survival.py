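"""Relapse-free survival: Kaplan-Meier estimation and log-rank comparison.

Thin, typed wrappers over lifelines.  The product-limit estimator
S(t) = prod_{t_j <= t} (1 - d_j / n_j) is reported at event times together
with the at-risk counts; the median is the first time at which S drops to
0.5 or below (infinity when never reached).  Group curves are compared with
the Mantel-Cox log-rank test (df = 1, no multiplicity adjustment).
Censorings tied with events are handled by the standard convention:
censored subjects remain at risk for the event at that time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


@dataclass
class KmEstimate:
    group: str
    times: np.ndarray  # event times (steps)
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # n_j at each event time
    n_events: np.ndarray  # d_j at each event time
    median: float  # math.inf when not reached

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(
    times: np.ndarray, events: np.ndarray, group: str = ""
) -> KmEstimate:
    """Kaplan-Meier product-limit estimate for one group."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("empty group")
    if (times < 0).any():
        raise ValueError("negative follow-up time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    t = ev.index.to_numpy(dtype=float)
    d = ev["observed"].to_numpy(dtype=int)
    n = ev["at_risk"].to_numpy(dtype=int)
    s = kmf.survival_function_at_times(t).to_numpy(dtype=float)
    med = float(kmf.median_survival_time_)
    if not np.isfinite(med):
        med = math.inf
    return KmEstimate(group, t, s, n, d, med)


def logrank(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> dict:
    """Mantel-Cox log-rank comparison of two groups (df = 1)."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, bool), np.asarray(events_b, bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in the pooled cohort")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return {"chi_square": float(res.test_statistic), "p": float(res.p_value)}


def compare_groups(clinical: pd.DataFrame, label_col: str, a: str, b: str) -> dict:
    """Log-rank comparison of two labelled groups in a clinical table.

    ``clinical`` columns: time_years, event, plus *label_col*.
    """
    ga = clinical[clinical[label_col].astype(str) == a]
    gb = clinical[clinical[label_col].astype(str) == b]
    out = logrank(
        ga["time_years"].to_numpy(),
        ga["event"].to_numpy(),
        gb["time_years"].to_numpy(),
        gb["event"].to_numpy(),
    )
    out["groups"] = (a, b)
    out["n"] = (len(ga), len(gb))
    out["median"] = {
        a: km_estimate(ga["time_years"].to_numpy(), ga["event"].to_numpy(), a).median,
        b: km_estimate(gb["time_years"].to_numpy(), gb["event"].to_numpy(), b).median,
    }
    return out
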