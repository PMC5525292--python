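"""Cox proportional-hazards regression by Newton-Raphson on the partial likelihood.

Supports both the Breslow and the Efron correction for tied event times (the
two are identical when no ties exist). Standard errors come from the inverse
of the observed information at the optimum; hazard ratios and 95% CIs use the
Wald normal approximation, HR = exp(coef), CI = exp(coef ± 1.96·SE).

A dedicated in-package solver is used (rather than delegating the fit) because
the risk-model stage needs both tie corrections behind one interface and an
explicit score-convergence guarantee; an external fitter serves as the
independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

Z_95 = 1.959963984540054  # standard normal 97.5% quantile


class CoxConvergenceError(RuntimeError):
    """Non-convergence or a monotone partial likelihood (complete separation)."""


@dataclass
class CoxFit:
    """A fitted Cox model over named covariates."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    ties: str
    n: int
    n_events: int
    converged: bool
    score_norm: float

    @property
    def hazard_ratio(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.coef - Z_95 * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.coef + Z_95 * self.se)

    @property
    def p_values(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": self.hazard_ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_values,
            },
            index=pd.Index(self.names, name="covariate"),
        )


def _loglik_grad_hess(
    beta: np.ndarray,
    x: np.ndarray,
    groups: list[tuple[np.ndarray, np.ndarray]],
    ties: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Partial log-likelihood, score and negative Hessian (information).

    ``groups`` holds, per distinct event time (descending), the indices of the
    risk set *increment* and of the tied deaths; risk-set sums are accumulated
    across iterations to stay O(n) per pass.
    """
    p = x.shape[1]
    eta = x @ beta
    w = np.exp(eta)
    wx = w[:, None] * x
    wxx = wx[:, :, None] * x[:, None, :]

    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    for risk_inc, deaths in groups:
        s0 += w[risk_inc].sum()
        s1 += wx[risk_inc].sum(axis=0)
        s2 += wxx[risk_inc].sum(axis=0)
        d = deaths.size
        if d == 0:
            continue
        loglik += eta[deaths].sum()
        if ties == "breslow":
            loglik -= d * np.log(s0)
            score += x[deaths].sum(axis=0) - d * s1 / s0
            info += d * (s2 / s0 - np.outer(s1, s1) / s0**2)
        else:  # efron
            wd0 = w[deaths].sum()
            wd1 = wx[deaths].sum(axis=0)
            wd2 = wxx[deaths].sum(axis=0)
            score += x[deaths].sum(axis=0)
            for ell in range(d):
                frac = ell / d
                denom = s0 - frac * wd0
                num1 = s1 - frac * wd1
                num2 = s2 - frac * wd2
                loglik -= np.log(denom)
                score -= num1 / denom
                info += num2 / denom - np.outer(num1, num1) / denom**2
    return loglik, score, info


def _event_groups(
    time: np.ndarray, event: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    order = np.argsort(-time, kind="stable")
    time_sorted = time[order]
    boundaries = np.flatnonzero(np.diff(time_sorted)) + 1
    groups = []
    start = 0
    for stop in list(boundaries) + [time.size]:
        block = order[start:stop]
        deaths = block[event[block] == 1]
        groups.append((block, deaths))
        start = stop
    return groups


def fit_cox(
    x: pd.DataFrame | np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox model; ``x`` is samples × covariates.

    Requires at least one event, no constant covariate and n > p. Raises
    :class:`CoxConvergenceError` on non-convergence or monotone likelihood
    (coefficients diverging, the complete-separation signature).
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    if isinstance(x, pd.DataFrame):
        names = [str(c) for c in x.columns]
        xmat = x.to_numpy(dtype=float)
    else:
        xmat = np.asarray(x, dtype=float)
        if xmat.ndim == 1:
            xmat = xmat[:, None]
        names = [f"x{i}" for i in range(xmat.shape[1])]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = xmat.shape
    if event.sum() < 1:
        raise ValueError("need >= 1 event")
    if n <= p:
        raise ValueError(f"need n > number of covariates ({n} <= {p})")
    if np.any(np.ptp(xmat, axis=0) == 0):
        const = [names[j] for j in np.flatnonzero(np.ptp(xmat, axis=0) == 0)]
        raise ValueError(f"constant covariate(s): {const}")

    center = xmat.mean(axis=0)
    xc = xmat - center  # centring improves conditioning; coefs are unchanged
    groups = _event_groups(time, event)

    beta = np.zeros(p)
    loglik_null, _, _ = _loglik_grad_hess(beta, xc, groups, ties)
    loglik = loglik_null
    score_norm = np.inf
    for _ in range(max_iter):
        loglik, score, info = _loglik_grad_hess(beta, xc, groups, ties)
        score_norm = float(np.max(np.abs(score)))
        if score_norm < tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError(
                "singular information matrix (collinear covariates?)"
            ) from exc
        if np.max(np.abs(step)) < 1e-12:
            break
        # step-halving if the likelihood worsens (relative tolerance: near the
        # optimum the quadratic step is always accepted)
        scale = 1.0
        for _half in range(30):
            candidate = beta + scale * step
            new_ll, _, _ = _loglik_grad_hess(candidate, xc, groups, ties)
            if new_ll >= loglik - 1e-9 * (1.0 + abs(loglik)):
                break
            scale /= 2.0
        beta = beta + scale * step
        if np.max(np.abs(beta)) > 50:
            raise CoxConvergenceError(
                "coefficients diverging (monotone likelihood / complete separation)"
            )
    else:
        if score_norm >= 1e-6:
            raise CoxConvergenceError(
                f"no convergence in {max_iter} iterations (|score| = {score_norm:.2e})"
            )
    loglik, score, info = _loglik_grad_hess(beta, xc, groups, ties)
    score_norm = float(np.max(np.abs(score)))
    # monotone-likelihood signature: an estimate drifting to +-infinity looks
    # "converged" because the score decays exponentially; flag coefficients
    # that are implausibly large in standardised covariate units
    std_units = np.abs(beta) * xc.std(axis=0)
    if np.any(std_units > 10):
        worst = names[int(np.argmax(std_units))]
        raise CoxConvergenceError(
            f"monotone likelihood / complete separation suspected for {worst!r} "
            f"(|coef|*sd = {std_units.max():.1f})"
        )
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise CoxConvergenceError("singular information at the optimum") from exc
    se = np.sqrt(np.diag(cov))
    return CoxFit(
        names=names,
        coef=beta,
        se=se,
        loglik=float(loglik),
        loglik_null=float(loglik_null),
        ties=ties,
        n=n,
        n_events=int(event.sum()),
        converged=score_norm < 1e-6,
        score_norm=score_norm,
    )
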