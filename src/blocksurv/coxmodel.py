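"""Cox proportional-hazards regression on integrated components.

The hazard model is h(t) = h0(t) * exp(b1 c1 + ... + bK cK) over component
scores.  The partial likelihood is maximized by Newton-Raphson with
step-halving, using the Efron correction for tied event times (Breslow
available); standard errors come from the inverse observed information.
Model selection is bidirectional stepwise on AIC = -2 logPL + 2k starting
from the full model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import SurvivalOutcome
from .integrate import IntegratedDataset
from .spca import SparseComponent

__all__ = [
    "CoxFit",
    "fit_cox",
    "hazard_ratio",
    "stepwise_aic",
    "report_table",
    "null_log_partial_likelihood",
    "StepwiseCoxPH",
]


class ConvergenceError(RuntimeError):
    """Raised when the Newton iteration cannot maximize the partial likelihood."""


@dataclass
class CoxFit:
    """Fitted Cox model over a set of component covariates."""

    labels: list[str]
    coef: np.ndarray
    se: np.ndarray
    p_value: np.ndarray
    log_likelihood: float
    n_events: int
    ties: str = "efron"

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * len(self.labels)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coef,
                "se": self.se,
                "hazard_ratio": self.hazard_ratios,
                "p_value": self.p_value,
            },
            index=pd.Index(self.labels, name="component"),
        )


def hazard_ratio(coefficient: float) -> float:
    """Multiplicative hazard effect of a one-unit covariate increase."""
    if not np.isfinite(coefficient):
        raise ValueError("coefficient must be finite")
    return float(np.exp(coefficient))


def _partial_likelihood_parts(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray, ties: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient and Hessian at beta.

    Efron handles tied event times by averaging the tied subjects out of
    the risk-set denominator; Breslow leaves the denominator untouched.
    """
    n, p = X.shape
    order = np.argsort(-time, kind="stable")  # descending time
    Xs, ts, ds = X[order], time[order], event[order]
    eta = Xs @ beta
    w = np.exp(eta)
    wX = w[:, None] * Xs
    wXX = np.einsum("i,ij,ik->ijk", w, Xs, Xs)
    # suffix (risk-set) cumulative sums: risk set at t = all with time >= t
    S0 = np.cumsum(w)
    S1 = np.cumsum(wX, axis=0)
    S2 = np.cumsum(wXX, axis=0)

    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        # subjects i..j share this time; risk set = everything up to j
        dead = np.arange(i, j + 1)[ds[i : j + 1] == 1]
        d = dead.size
        if d:
            s0, s1, s2 = S0[j], S1[j], S2[j]
            wd = w[dead].sum()
            wd1 = wX[dead].sum(axis=0)
            wd2 = wXX[dead].sum(axis=0)
            loglik += eta[dead].sum()
            grad += Xs[dead].sum(axis=0)
            for l in range(d):
                frac = l / d if ties == "efron" else 0.0
                phi = s0 - frac * wd
                z = s1 - frac * wd1
                q = s2 - frac * wd2
                loglik -= np.log(phi)
                grad -= z / phi
                hess -= q / phi - np.outer(z, z) / phi**2
        i = j + 1
    return loglik, grad, hess


def null_log_partial_likelihood(survival: SurvivalOutcome, ties: str = "efron") -> float:
    """Log partial likelihood of the empty model (all coefficients zero)."""
    X = np.zeros((len(survival.time), 1))
    ll, _, _ = _partial_likelihood_parts(X, survival.time, survival.event, np.zeros(1), ties)
    return float(ll)


def fit_cox(
    data: IntegratedDataset,
    survival: SurvivalOutcome,
    covariates: list[str] | None = None,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 100,
) -> CoxFit:
    """Maximize the Cox partial likelihood over a covariate subset.

    Raises on fewer than 2 events, collinear covariates, or monotone
    likelihood (coefficients diverging, as under perfect separation).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    labels = list(covariates) if covariates is not None else data.labels
    if data.sample_ids != survival.sample_ids:
        raise ValueError("integrated data and survival table sample order differ")
    if survival.n_events < 2:
        raise ValueError("need at least 2 observed events to fit a Cox model")
    X = data.scores[labels].to_numpy(dtype=float) if labels else np.zeros((len(survival.time), 0))
    p = X.shape[1]
    if p == 0:
        ll = null_log_partial_likelihood(survival, ties)
        return CoxFit([], np.zeros(0), np.zeros(0), np.zeros(0), ll,
                      survival.n_events, ties)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < p:
        raise ValueError(f"collinear covariates among {labels}")

    beta = np.zeros(p)
    ll, grad, hess = _partial_likelihood_parts(X, survival.time, survival.event, beta, ties)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix for {labels}") from exc
        # step-halving keeps the partial likelihood non-decreasing
        factor = 1.0
        for _ in range(40):
            cand = beta + factor * step
            ll_new, grad_new, hess_new = _partial_likelihood_parts(
                X, survival.time, survival.event, cand, ties
            )
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        else:
            raise ConvergenceError(f"step-halving failed for {labels}")
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > 50:
            raise ConvergenceError(
                f"coefficients diverging for {labels}: monotone likelihood "
                "(perfect separation of event order by a covariate)"
            )
    else:
        raise ConvergenceError(f"Newton iteration did not converge for {labels}")

    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    # monotone likelihood: coefficient drifts out while its information vanishes
    runaway = (np.abs(beta) > 5) & (np.abs(beta) / se < 0.01)
    if runaway.any():
        bad = [labels[i] for i in np.flatnonzero(runaway)]
        raise ConvergenceError(
            f"monotone likelihood for {bad}: coefficient effectively infinite "
            "(marker perfectly separates the event order)"
        )
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(labels, beta, se, pvals, float(ll), survival.n_events, ties)


def stepwise_aic(
    data: IntegratedDataset,
    survival: SurvivalOutcome,
    direction: str = "both",
    ties: str = "efron",
    start: str = "full",
) -> tuple[list[str], CoxFit]:
    """Greedy stepwise covariate selection by AIC.

    Starts from the full model; at each step every single addition and/or
    removal is evaluated and the move with the lowest AIC is taken; the
    search stops when no move improves the current AIC.  Ties between
    moves are broken by label order (candidates are scanned sorted and
    only a strict improvement replaces the incumbent move).
    """
    if direction not in ("both", "backward", "forward"):
        raise ValueError("direction must be 'both', 'backward' or 'forward'")
    all_labels = data.labels
    if not all_labels:
        raise ValueError("no covariates available")
    if start == "full":
        current = list(all_labels)
    elif start == "null":
        current = []
    else:
        raise ValueError("start must be 'full' or 'null'")

    def try_fit(labels: list[str]) -> CoxFit | None:
        try:
            return fit_cox(data, survival, labels, ties=ties)
        except (ValueError, ConvergenceError):
            return None

    fit = try_fit(current)
    if fit is None:
        raise ValueError("the starting model could not be fitted (collinear covariates?)")
    while True:
        moves: list[tuple[list[str], CoxFit]] = []
        if direction in ("both", "backward"):
            for lab in sorted(current):
                cand = [l for l in current if l != lab]
                f = try_fit(cand)
                if f is not None:
                    moves.append((cand, f))
        if direction in ("both", "forward"):
            for lab in sorted(set(all_labels) - set(current)):
                cand = current + [lab]
                cand = [l for l in all_labels if l in cand]  # keep column order
                f = try_fit(cand)
                if f is not None:
                    moves.append((cand, f))
        best = None
        for cand, f in moves:
            if best is None or f.aic < best[1].aic - 1e-10:
                best = (cand, f)
        if best is None or best[1].aic >= fit.aic - 1e-10:
            break
        current, fit = best
    return current, fit


def report_table(fit: CoxFit, provenance: dict[str, SparseComponent]) -> pd.DataFrame:
    """Selected-component report: block size, nonzeros kept, coefficient (SE), HR, p.

    Mirrors the usual stepwise-Cox summary layout for blockwise components.
    """
    rows = []
    for lab, b, se, hr, pv in zip(fit.labels, fit.coef, fit.se, fit.hazard_ratios, fit.p_value):
        if lab not in provenance:
            raise KeyError(f"no provenance for component {lab!r}")
        c = provenance[lab]
        rows.append(
            {
                "component": lab,
                "omics": c.layer_id,
                "n_variables": c.n_block_variables,
                "n_variables_remained": len(c.support),
                "coefficient": round(float(b), 4),
                "se": round(float(se), 4),
                "coefficient_se": f"{b:.2f} ({se:.2f})",
                "hazard_ratio": round(float(hr), 4),
                "p_value": float(pv),
            }
        )
    return pd.DataFrame(rows)


class StepwiseCoxPH(BaseEstimator):
    """Cox proportional-hazards estimator with stepwise-AIC covariate selection.

    Accepts ``X`` as a DataFrame of component scores (or any numeric
    covariates) and ``y`` as a DataFrame with ``time``/``status`` columns,
    a :class:`~blocksurv.io.SurvivalOutcome`, or a structured array with
    ``time`` and ``event`` fields.

    Parameters
    ----------
    select : bool, default=True
        Apply stepwise AIC; otherwise fit the full model.
    direction : {"both", "backward", "forward"}, default="both"
    ties : {"efron", "breslow"}, default="efron"

    Attributes
    ----------
    fit_ : CoxFit
    selected_ : list of str
    coef_ : ndarray over the selected covariates
    aic_ : float
    """

    def __init__(self, select: bool = True, direction: str = "both", ties: str = "efron"):
        self.select = select
        self.direction = direction
        self.ties = ties

    def fit(self, X, y):
        X = pd.DataFrame(X)
        X.index = X.index.astype(str)
        surv = _as_survival(y, X.index)
        data = IntegratedDataset(X.astype(float), provenance={})
        if self.select:
            self.selected_, self.fit_ = stepwise_aic(
                data, surv, direction=self.direction, ties=self.ties
            )
        else:
            self.fit_ = fit_cox(data, surv, ties=self.ties)
            self.selected_ = list(self.fit_.labels)
        self.coef_ = self.fit_.coef
        self.aic_ = self.fit_.aic
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X):
        """Linear risk marker eta = scores . coefficients (no baseline term)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "fit_")
        X = pd.DataFrame(X)
        missing = set(self.selected_) - set(X.columns)
        if missing:
            raise KeyError(f"missing covariates in X: {sorted(missing)}")
        return X[self.selected_].to_numpy(dtype=float) @ self.fit_.coef

    def score(self, X, y):
        """Harrell's concordance index of the fitted risk marker."""
        from .evaluation import harrell_c

        surv = _as_survival(y, pd.DataFrame(X).index)
        return harrell_c(self.predict(X), surv)


def _as_survival(y, index) -> SurvivalOutcome:
    if isinstance(y, SurvivalOutcome):
        return y
    if isinstance(y, pd.DataFrame):
        ids = [str(s) for s in y.index]
        return SurvivalOutcome(ids, y["time"].to_numpy(float), y["status"].to_numpy())
    arr = np.asarray(y)
    if arr.dtype.names:  # structured array (scikit-survival style)
        names = arr.dtype.names
        tname = "time" if "time" in names else names[1]
        ename = "event" if "event" in names else names[0]
        ids = [str(s) for s in index]
        return SurvivalOutcome(ids, arr[tname].astype(float), arr[ename].astype(int))
    raise TypeError("y must be a SurvivalOutcome, time/status DataFrame or structured array")
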