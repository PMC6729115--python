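"""Random-intercept logistic model on cumulative dropout indicators.

The outcome for participant i at question q is whether they have dropped out
of the survey *by* q (so the per-participant trajectory is a block of 0s
followed by 1s, or all 0s for completers).  Question enters as a categorical
covariate in a cell-means parameterisation — one logit-scale coefficient per
question, no global intercept — so successive-difference contrasts compare
adjacent questions' cumulative dropout probabilities directly.  A normal
participant-level random intercept absorbs the strong within-participant
dependence created by monotone dropout.

Estimation maximises the marginal likelihood, integrating the random effect
by Gauss–Hermite quadrature.  The sample is collapsed onto its distinct
response patterns first; under monotone dropout there are at most K+1 of
them, which makes the quadrature likelihood cheap at any sample size.

Questions whose cumulative dropout count is 0 or N are separated (the MLE
diverges); their coefficients are flagged non-estimable and pinned, and any
contrast touching them is excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .data import DropoutDataset, to_cumulative
from .inference import contrast_results
from .phases import PhaseDetection, boundaries_from_significance, count_phases

__all__ = ["GlmmFit", "fit_glmm", "detect_glmm"]

_PIN = 30.0  # logit value at which separated coefficients are pinned

#: Upper bound on the random-intercept standard deviation.  Perfectly
#: monotone trajectories make the marginal likelihood increase in sigma
#: without bound (the model approaches a saturated threshold model on exit
#: patterns), so the fit caps sigma at a value far beyond any practically
#: distinguishable heterogeneity and reports boundary estimates as
#: converged.  See docs/methods.md.
_SIGMA_MAX = 10.0


@dataclass(frozen=True)
class GlmmFit:
    """Fitted random-intercept cumulative-dropout model."""

    question_effects: np.ndarray  # K logits of P(dropped out by q)
    covariance: np.ndarray  # K x K, NaN rows/cols where non-estimable
    re_sd: float  # random-intercept standard deviation (>= 0)
    estimable: np.ndarray  # per-question flag
    converged: bool
    status: str  # ok | failed | degenerate
    loglik: float = np.nan
    n_restarts: int = 0
    message: str = ""

    @property
    def re_variance(self) -> float:
        return self.re_sd**2


def _monotone_patterns(dataset: DropoutDataset) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a dropout dataset onto its K+1 exit patterns.

    Returns ``(counts, Y)``: ``counts[e-1]`` participants exit at question e
    (row K = completers); ``Y`` holds each pattern's cumulative indicators.
    """
    K = dataset.design.n_questions
    counts = np.bincount(dataset.exit_codes, minlength=K + 2)[1:]
    e = np.arange(1, K + 2)[:, None]
    q = np.arange(1, K + 1)[None, :]
    Y = (q >= e).astype(float)
    return counts.astype(float), Y


def _table_patterns(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a long (participant_id, question, dropped_by) table."""
    wide = table.pivot(index="participant_id", columns="question", values="dropped_by")
    if wide.isna().any().any():
        raise ValueError("cumulative table must have one row per participant and question")
    mat = wide.to_numpy(dtype=float)
    Y, counts = np.unique(mat, axis=0, return_counts=True)
    return counts.astype(float), Y


def _nll_and_grad(theta, counts, Y, free, beta_fixed, nodes, logw, fix_sigma):
    """Negative marginal log-likelihood and gradient over free parameters."""
    beta = beta_fixed.copy()
    if fix_sigma is None:
        beta[free] = theta[:-1]
        sigma = theta[-1]
    else:
        beta[free] = theta
        sigma = fix_sigma
    eta = beta[:, None] + sigma * nodes[None, :]  # (K, J)
    # log f_e(u_j) = sum_q [y_q eta - log(1 + e^eta)]
    A = Y @ eta - np.logaddexp(0.0, eta).sum(axis=0)  # (E, J)
    logL = logsumexp(A + logw[None, :], axis=1)  # (E,)
    nll = -float(counts @ logL)

    omega = np.exp(A + logw[None, :] - logL[:, None])  # (E, J), rows sum to 1
    nw = counts[:, None] * omega  # (E, J)
    W = nw.sum(axis=0)  # (J,)
    M = Y.T @ nw  # (K, J)
    P = expit(eta)  # (K, J)
    dbeta = (M - P * W[None, :]).sum(axis=1)
    if fix_sigma is None:
        dsigma = float(nodes @ (M.sum(axis=0) - P.sum(axis=0) * W))
        grad = np.concatenate([-dbeta[free], [-dsigma]])
    else:
        grad = -dbeta[free]
    return nll, grad


def fit_glmm(
    data: DropoutDataset | pd.DataFrame,
    n_quad: int = 25,
    fix_re_sd: float | None = None,
    max_restarts: int = 2,
) -> GlmmFit:
    """Fit the random-intercept cumulative-dropout model by marginal ML.

    ``data`` is a :class:`DropoutDataset` or a long cumulative table with
    columns ``participant_id, question, dropped_by``.  ``fix_re_sd`` pins the
    random-intercept standard deviation (0 reduces the model to independent
    per-cell logistic regression, whose cell-means MLE is the empirical logit
    of each question's dropout proportion).  The reported coefficient
    covariance is the inverse observed information of the question effects at
    the optimum, holding the variance component at its estimate.
    """
    if isinstance(data, DropoutDataset):
        counts, Y = _monotone_patterns(data)
    else:
        counts, Y = _table_patterns(data)
    K = Y.shape[1]
    N = counts.sum()
    succ = counts @ Y  # per-question count of dropped_by = 1
    estimable = (succ > 0) & (succ < N)
    nan_cov = np.full((K, K), np.nan)
    if N == 0 or not estimable.any():
        return GlmmFit(
            question_effects=np.full(K, np.nan),
            covariance=nan_cov,
            re_sd=np.nan,
            estimable=np.zeros(K, dtype=bool),
            converged=False,
            status="degenerate",
            message="outcome constant at every question; nothing to fit",
        )

    beta_fixed = np.where(succ == 0, -_PIN, _PIN).astype(float)
    free = np.flatnonzero(estimable)

    # physicists' Gauss-Hermite mapped to N(0,1): u_j = sqrt(2) x_j
    x, w = np.polynomial.hermite.hermgauss(n_quad)
    nodes = np.sqrt(2.0) * x
    logw = np.log(w) - 0.5 * np.log(np.pi)

    p_emp = np.clip(succ / N, 1e-8, 1 - 1e-8)
    beta0 = np.log(p_emp / (1 - p_emp))[free]
    sigma0 = 1.0 if fix_re_sd is None else fix_re_sd

    args = (counts, Y, free, beta_fixed, nodes, logw, fix_re_sd)
    bounds = [(-_PIN, _PIN)] * len(free)
    if fix_re_sd is None:
        bounds.append((0.0, _SIGMA_MAX))
    gtol = 1e-3 * max(1.0, N / 100.0)

    def proj_grad(res):
        """Gradient with components pointing out of an active bound zeroed."""
        g = res.jac.copy()
        for i, (lo, hi) in enumerate(bounds):
            if (res.x[i] <= lo + 1e-10 and g[i] > 0) or (res.x[i] >= hi - 1e-10 and g[i] < 0):
                g[i] = 0.0
        return np.max(np.abs(g))

    best = None
    n_restarts = 0
    for attempt in range(max_restarts + 1):
        shift = (0.0, 0.5, -0.5)[attempt % 3]
        t0 = beta0 + shift
        if fix_re_sd is None:
            t0 = np.concatenate([t0, [max(sigma0 + shift, 0.1)]])
        res = minimize(
            _nll_and_grad,
            t0,
            args=args,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-13, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
        n_restarts = attempt
        if res.success and proj_grad(res) < gtol:
            best = res
            break
    res = best
    converged = bool(res.success and proj_grad(res) < gtol)

    beta_hat = beta_fixed.copy()
    if fix_re_sd is None:
        beta_hat[free] = res.x[:-1]
        sigma_hat = float(res.x[-1])
    else:
        beta_hat[free] = res.x
        sigma_hat = float(fix_re_sd)

    # observed information of the free question effects at (beta_hat, sigma_hat)
    cov = nan_cov.copy()
    if converged and len(free):
        H = _beta_hessian(beta_hat, sigma_hat, counts, Y, free, nodes, logw)
        try:
            cov_free = np.linalg.inv(H)
            cov_free = 0.5 * (cov_free + cov_free.T)
            cov[np.ix_(free, free)] = cov_free
        except np.linalg.LinAlgError:
            converged = False
    beta_out = np.where(estimable, beta_hat, np.nan)
    return GlmmFit(
        question_effects=beta_out,
        covariance=cov,
        re_sd=sigma_hat,
        estimable=estimable,
        converged=converged,
        status="ok" if converged else "failed",
        loglik=-float(res.fun),
        n_restarts=n_restarts,
        message=str(res.message),
    )


def _beta_hessian(beta, sigma, counts, Y, free, nodes, logw, step=1e-5):
    """Central-difference Hessian of the negative log-likelihood in beta."""
    nfree = len(free)
    H = np.empty((nfree, nfree))
    for j in range(nfree):
        h = step * max(1.0, abs(beta[free[j]]))
        b = beta.copy()
        b[free[j]] += h
        _, gp = _nll_and_grad(b[free], counts, Y, free, b, nodes, logw, sigma)
        b = beta.copy()
        b[free[j]] -= h
        _, gm = _nll_and_grad(b[free], counts, Y, free, b, nodes, logw, sigma)
        H[:, j] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def detect_glmm(dataset: DropoutDataset, alpha: float = 0.05, **fit_kwargs) -> PhaseDetection:
    """Locate the dropout phase from adjacent-question GLMM contrasts.

    The start of the dropout phase is the later question of the first
    significant adjacent pair after BH adjustment at ``alpha``; the end is
    the later question of the last significant pair.  The earliest
    reportable start is therefore question 2 and the latest end question K.
    """
    K = dataset.design.n_questions
    fit = fit_glmm(dataset, **fit_kwargs)
    if fit.status != "ok":
        return PhaseDetection(
            method="glmm",
            n_questions=K,
            start_question=None,
            end_question=None,
            n_phases=1,
            earliest=2,
            latest=K,
            fit_status=fit.status,
            info={"message": fit.message, "re_sd": fit.re_sd},
        )
    beta = np.where(fit.estimable, fit.question_effects, np.nan)
    table = contrast_results(beta, fit.covariance, alpha=alpha, estimable=fit.estimable)
    sig = table["significant"].to_numpy()
    start, end = boundaries_from_significance(sig, first_index=2)
    return PhaseDetection(
        method="glmm",
        n_questions=K,
        start_question=start,
        end_question=end,
        n_phases=count_phases(start, end, earliest=2, latest=K),
        earliest=2,
        latest=K,
        fit_status="ok",
        flags=sig,
        contrasts=table,
        info={"re_sd": fit.re_sd, "loglik": fit.loglik, "alpha": alpha},
    )
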