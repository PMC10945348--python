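"""Kaplan-Meier estimation, log-rank testing, and risk stratification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from immunosig.errors import ValidationError

RISK_MAP = {"PD": "High-risk", "NPD": "Low-risk"}


@dataclass
class SurvivalCurve:
    """Right-continuous product-limit step function."""

    event_times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray  # n_i at each event time
    n_events: np.ndarray  # d_i at each event time
    survival: np.ndarray  # S(t_i) after each event time
    greenwood_var: np.ndarray

    def at(self, t: float) -> float:
        """S(t); 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def stratify_by_prediction(predictions: pd.Series | dict) -> pd.Series:
    """PD -> High-risk, NPD -> Low-risk."""
    predictions = pd.Series(predictions)
    unknown = set(predictions.unique()) - set(RISK_MAP)
    if unknown:
        raise ValidationError(f"unknown prediction labels: {sorted(unknown)}")
    return predictions.map(RISK_MAP).rename("risk")


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit estimator with Greenwood variance.

    Ties at an event time are handled as simultaneous deaths;
    censoring at an event time is ordered after the event.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValidationError("negative survival times")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValidationError("events must be 0/1")

    event_times = np.unique(times[events == 1])
    at_risk = np.array([(times >= t).sum() for t in event_times], dtype=float)
    n_events = np.array(
        [((times == t) & (events == 1)).sum() for t in event_times], dtype=float
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - n_events / at_risk
        survival = np.cumprod(factors)
        gw_terms = np.where(
            at_risk > n_events, n_events / (at_risk * (at_risk - n_events)), np.inf
        )
        greenwood = survival**2 * np.cumsum(gw_terms)
    return SurvivalCurve(
        event_times=event_times,
        at_risk=at_risk.astype(int),
        n_events=n_events.astype(int),
        survival=survival,
        greenwood_var=greenwood,
    )


def logrank_test(
    times_a,
    events_a,
    times_b,
    events_b,
    weighted: bool = False,
) -> tuple[float, float]:
    """Two-group log-rank test; ``weighted=True`` gives the Gehan-Wilcoxon
    variant (weights = pooled number at risk).

    Returns (chi_square, p) with 1 degree of freedom.
    """
    times_a = np.asarray(times_a, dtype=float)
    events_a = np.asarray(events_a, dtype=int)
    times_b = np.asarray(times_b, dtype=float)
    events_b = np.asarray(events_b, dtype=int)
    if events_a.sum() + events_b.sum() == 0:
        raise ValidationError("no events in either group")

    all_times = np.concatenate([times_a, times_b])
    all_events = np.concatenate([events_a, events_b])
    group = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))])
    event_times = np.unique(all_times[all_events == 1])

    num = 0.0
    var = 0.0
    for t in event_times:
        at_risk = all_times >= t
        n = at_risk.sum()
        n_a = (at_risk & (group == 0)).sum()
        d = ((all_times == t) & (all_events == 1)).sum()
        d_a = ((all_times == t) & (all_events == 1) & (group == 0)).sum()
        w = n if weighted else 1.0
        num += w * (d_a - d * n_a / n)
        if n > 1:
            var += w**2 * d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = num**2 / var
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def km_by_risk(
    times, events, risk: pd.Series
) -> tuple[dict[str, SurvivalCurve], float, float]:
    """Per-risk-class KM curves plus the log-rank test between them."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    risk = np.asarray(risk)
    classes = sorted(set(risk))
    if len(classes) != 2:
        raise ValidationError("risk stratification needs exactly two classes")
    curves = {c: km_estimate(times[risk == c], events[risk == c]) for c in classes}
    a, b = classes
    chi2, p = logrank_test(
        times[risk == a], events[risk == a], times[risk == b], events[risk == b]
    )
    return curves, chi2, p


def curve_to_frame(curve: SurvivalCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": curve.event_times,
            "at_risk": curve.at_risk,
            "n_events": curve.n_events,
            "survival": curve.survival,
            "greenwood_var": curve.greenwood_var,
        }
    )
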