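"""Discrete-time survival analysis of survey dropout.

Dropout is treated as a time-to-event outcome on the question grid: each
participant contributes one person-period row per question reached, with
event = 1 in the final row if they dropped out there.  The model is a
Bernoulli regression of the event indicator with a step-function baseline
hazard — one dummy per question, no global intercept — so coefficient q is
the logit of the discrete hazard of dropping out at question q given the
participant reached it.

Because the question dummies saturate the model, the maximum-likelihood fit
has a closed form: coefficient q is the empirical logit d_q / n_q of the
observed hazard, with variance 1 / (n_q h_q (1 - h_q)), and the covariance
is diagonal.  Questions where nobody (or everybody) at risk drops out are
separated and flagged non-estimable.  Boundary and phase-count conventions
mirror the GLMM detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DropoutDataset, SurveyDesign, dataset_from_person_period, summarize
from .inference import contrast_results
from .phases import PhaseDetection, boundaries_from_significance, count_phases

__all__ = ["DtsaFit", "fit_dtsa", "detect_dtsa"]


@dataclass(frozen=True)
class DtsaFit:
    """Saturated discrete-hazard fit on person-period data."""

    hazard_effects: np.ndarray  # K logits of the per-question discrete hazard
    covariance: np.ndarray  # diagonal K x K, NaN where non-estimable
    estimable: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    converged: bool = True
    status: str = "ok"


def _risk_and_events(data: DropoutDataset | pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int]:
    if isinstance(data, DropoutDataset):
        s = summarize(data, mode="conditional")
        return s.n_at_risk, s.n_dropped, data.design.n_questions
    if len(data) == 0:
        raise ValueError("empty person-period table")
    K = int(data["question"].max())
    grp = data.groupby("question")
    n_at_risk = np.zeros(K, dtype=np.int64)
    n_events = np.zeros(K, dtype=np.int64)
    n_at_risk[grp.size().index.to_numpy() - 1] = grp.size().to_numpy()
    n_events[grp["event"].sum().index.to_numpy() - 1] = grp["event"].sum().to_numpy()
    return n_at_risk, n_events, K


def fit_dtsa(data: DropoutDataset | pd.DataFrame) -> DtsaFit:
    """Closed-form ML fit of the step-baseline discrete-hazard model.

    ``data`` is a dropout dataset or a person-period table with columns
    ``participant_id, question, event``.
    """
    n_at_risk, n_events, K = _risk_and_events(data)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = n_events / np.maximum(n_at_risk, 1)
    estimable = (n_at_risk > 0) & (n_events > 0) & (n_events < n_at_risk)
    beta = np.full(K, np.nan)
    var = np.full(K, np.nan)
    hq = h[estimable]
    nq = n_at_risk[estimable]
    beta[estimable] = np.log(hq / (1 - hq))
    var[estimable] = 1.0 / (nq * hq * (1 - hq))
    return DtsaFit(
        hazard_effects=beta,
        covariance=np.diag(var),
        estimable=estimable,
        n_at_risk=n_at_risk,
        n_events=n_events,
    )


def detect_dtsa(
    data: DropoutDataset | pd.DataFrame, alpha: float = 0.05
) -> PhaseDetection:
    """Locate the dropout phase from adjacent discrete-hazard contrasts.

    Adjacent hazards are compared on the logit scale with Wald z tests and
    BH adjustment at ``alpha``; pairs touching a non-estimable hazard are
    excluded.  Boundaries use the later question of the first/last
    significant pair, as in the GLMM detector.
    """
    fit = fit_dtsa(data)
    K = len(fit.hazard_effects)
    n_pairs_ok = (fit.estimable[:-1] & fit.estimable[1:]).sum()
    if n_pairs_ok == 0:
        return PhaseDetection(
            method="dtsa",
            n_questions=K,
            start_question=None,
            end_question=None,
            n_phases=1,
            earliest=2,
            latest=K,
            fit_status="degenerate",
            info={"message": "no adjacent pair with both hazards estimable"},
        )
    table = contrast_results(
        fit.hazard_effects, fit.covariance, alpha=alpha, estimable=fit.estimable
    )
    sig = table["significant"].to_numpy()
    start, end = boundaries_from_significance(sig, first_index=2)
    return PhaseDetection(
        method="dtsa",
        n_questions=K,
        start_question=start,
        end_question=end,
        n_phases=count_phases(start, end, earliest=2, latest=K),
        earliest=2,
        latest=K,
        fit_status="ok",
        flags=sig,
        contrasts=table,
        info={"alpha": alpha},
    )
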