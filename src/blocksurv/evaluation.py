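"""Predictive-performance measures for censored survival markers.

Cumulative/dynamic time-dependent ROC at a horizon t: cases are subjects
with an observed event by t, controls are subjects still event-free at t.
Cumulative sensitivity Se^C(q,t) = P(Q > q | T <= t) and dynamic
specificity Sp^D(q,t) = P(Q <= q | T > t) are estimated with inverse
probability-of-censoring weights from the Kaplan-Meier estimate of the
censoring distribution; the AUC is the trapezoidal area under the
resulting curve.  Harrell's C is computed by exact pair enumeration:
among pairs (i, j) with T_i > T_j and subject j an observed event, the
fraction with eta_i < eta_j (marker ties count 1/2 by default; a strict
mode reproduces the literal indicator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .coxmodel import CoxFit
from .integrate import IntegratedDataset
from .io import SurvivalOutcome

__all__ = [
    "ROCResult",
    "risk_marker",
    "cd_roc",
    "harrell_c",
    "median_survival_time",
]


@dataclass
class ROCResult:
    """Cumulative/dynamic ROC curve at one evaluation time."""

    t: float
    thresholds: np.ndarray
    sensitivity: np.ndarray  # Se^C at each threshold
    specificity: np.ndarray  # Sp^D at each threshold
    auc: float

    def curve(self) -> np.ndarray:
        """(1-specificity, sensitivity) points including the (0,0)/(1,1) anchors."""
        x = np.concatenate(([0.0], 1.0 - self.specificity[::-1], [1.0]))
        y = np.concatenate(([0.0], self.sensitivity[::-1], [1.0]))
        return np.column_stack([x, y])


def risk_marker(fit: CoxFit, data: IntegratedDataset) -> np.ndarray:
    """Linear predictor eta = component scores . coefficients."""
    missing = set(fit.labels) - set(data.labels)
    if missing:
        raise KeyError(f"components missing from data: {sorted(missing)}")
    if not fit.labels:
        return np.zeros(len(data.sample_ids))
    return data.scores[fit.labels].to_numpy(dtype=float) @ fit.coef


def _censoring_survival(survival: SurvivalOutcome) -> KaplanMeierFitter:
    """KM estimate of the censoring distribution (censoring as the event)."""
    kmf = KaplanMeierFitter()
    kmf.fit(survival.time, event_observed=1 - survival.event)
    return kmf

def _km_left(kmf: KaplanMeierFitter, times: np.ndarray) -> np.ndarray:
    """Left-continuous KM survival G(t-) evaluated at each time."""
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    vals = sf.iloc[:, 0].to_numpy(dtype=float)
    # G(t-) = value at the last grid point strictly below t
    pos = np.searchsorted(grid, np.asarray(times, dtype=float), side="left") - 1
    out = np.where(pos >= 0, vals[np.clip(pos, 0, None)], 1.0)
    return out


def cd_roc(marker: np.ndarray, survival: SurvivalOutcome, t: float) -> ROCResult:
    """Cumulative/dynamic ROC and AUC of a risk marker at horizon t.

    With no censoring before t, the AUC reduces exactly to the
    Mann-Whitney statistic between the groups {T <= t} and {T > t}.
    """
    marker = np.asarray(marker, dtype=float)
    time, event = survival.time, survival.event
    if not (time.min() <= t <= time.max()):
        raise ValueError(f"evaluation time {t} outside observed range "
                         f"[{time.min()}, {time.max()}]")
    cases = (time <= t) & (event == 1)
    controls = time > t
    if not cases.any() or not controls.any():
        raise ValueError(f"no cases or no controls at t={t}")

    kmf = _censoring_survival(survival)
    g_case = _km_left(kmf, time[cases])
    g_ctrl = float(_km_left(kmf, np.array([t]))[0])
    floor = 1e-12
    w_case = 1.0 / np.maximum(g_case, floor)
    w_ctrl = np.full(controls.sum(), 1.0 / max(g_ctrl, floor))

    q_case, q_ctrl = marker[cases], marker[controls]
    thresholds = np.unique(marker)
    wc_tot, wk_tot = w_case.sum(), w_ctrl.sum()
    se = np.array([(w_case[q_case > q]).sum() / wc_tot for q in thresholds])
    sp = np.array([(w_ctrl[q_ctrl <= q]).sum() / wk_tot for q in thresholds])

    # thresholds ascending -> (1-sp, se) descending in x; integrate ascending
    x = np.concatenate(([0.0], (1.0 - sp)[::-1], [1.0]))
    y = np.concatenate(([0.0], se[::-1], [1.0]))
    auc = float(np.trapezoid(y, x))
    return ROCResult(float(t), thresholds, se, sp, auc)


def harrell_c(
    marker: np.ndarray, survival: SurvivalOutcome, ties: str = "half"
) -> float:
    """Harrell's concordance index by exact pair enumeration.

    A pair (i, j) is comparable when T_i > T_j and subject j had an
    observed event; it is concordant when the longer-lived subject carries
    the lower risk (eta_i < eta_j).  ``ties="half"`` credits marker ties
    1/2 (the standard convention); ``ties="strict"`` applies the literal
    indicator, crediting ties nothing.
    """
    if ties not in ("half", "strict"):
        raise ValueError("ties must be 'half' or 'strict'")
    eta = np.asarray(marker, dtype=float)
    time, event = survival.time, survival.event
    # comparable[i, j]: T_i > T_j and d_j = 1
    comparable = (time[:, None] > time[None, :]) & (event[None, :] == 1)
    denom = comparable.sum()
    if denom == 0:
        raise ValueError("no comparable pairs (all subjects censored or tied times)")
    conc = comparable & (eta[:, None] < eta[None, :])
    num = float(conc.sum())
    if ties == "half":
        num += 0.5 * float((comparable & (eta[:, None] == eta[None, :])).sum())
    return num / float(denom)


def median_survival_time(survival: SurvivalOutcome) -> float:
    """Kaplan-Meier median: smallest time with survival estimate <= 0.5.

    The KM median is used rather than the raw sample median so that
    censored observations do not bias the above/below-median split.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(survival.time, event_observed=survival.event)
    med = kmf.median_survival_time_
    if not np.isfinite(med):
        floor = float(kmf.survival_function_.iloc[-1, 0])
        raise ValueError(
            f"Kaplan-Meier curve never reaches 0.5 (floor {floor:.2f}); "
            "pass an explicit evaluation time instead"
        )
    return float(med)
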