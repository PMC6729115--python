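"""User-specified attrition-threshold detector.

The researcher states how much per-question dropout they consider
practically meaningful — a start threshold and an end threshold, usually
equal.  The first question whose dropout proportion strictly exceeds the
start threshold marks the beginning of the dropout phase; the last question
strictly exceeding the end threshold marks its end.  No model is fitted, so
the method's sensitivity is entirely in the user's hands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DropoutDataset, DropoutSummary, summarize
from .phases import PhaseDetection, boundaries_from_significance, count_phases

__all__ = ["ThresholdConfig", "detect_threshold"]


@dataclass(frozen=True)
class ThresholdConfig:
    """Thresholds on the per-question dropout proportion.

    Defaults: 3% for both boundaries, on conditional (discrete-hazard)
    proportions.  Exceedance is strict — a proportion exactly at the
    threshold does not trigger.
    """

    start_threshold: float = 0.03
    end_threshold: float = 0.03
    proportion_mode: str = "conditional"

    def __post_init__(self) -> None:
        for name in ("start_threshold", "end_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.proportion_mode not in ("conditional", "marginal"):
            raise ValueError(f"unknown proportion_mode {self.proportion_mode!r}")


def detect_threshold(
    data: DropoutDataset | DropoutSummary, config: ThresholdConfig = ThresholdConfig()
) -> PhaseDetection:
    """Scan per-question dropout proportions against the thresholds.

    Accepts a dataset (summarised under ``config.proportion_mode``) or a
    ready-made summary.  Questions with an undefined proportion (no one left
    at risk) terminate the scan range and mark the detection degenerate.
    """
    if isinstance(data, DropoutDataset):
        summary = summarize(data, mode=config.proportion_mode)
    else:
        summary = data
        if summary.mode != config.proportion_mode:
            raise ValueError(
                f"summary mode {summary.mode!r} does not match config "
                f"{config.proportion_mode!r}"
            )
    K = summary.design.n_questions
    prop = summary.proportion
    defined = summary.defined
    # scan only the defined prefix; an undefined question ends the range
    n_scan = int(np.argmin(defined)) if not defined.all() else K
    scanned = prop[:n_scan]
    start_exceed = np.zeros(K, dtype=bool)
    end_exceed = np.zeros(K, dtype=bool)
    start_exceed[:n_scan] = scanned > config.start_threshold
    end_exceed[:n_scan] = scanned > config.end_threshold

    start, _ = boundaries_from_significance(start_exceed, first_index=1)
    _, end = boundaries_from_significance(end_exceed, first_index=1)
    status = "ok" if n_scan == K else "degenerate"
    if (start is None) != (end is None) or (start is not None and start > end):
        # possible only with unequal thresholds; no coherent phase exists
        start = end = None
        status = "degenerate"
    return PhaseDetection(
        method="threshold",
        n_questions=K,
        start_question=start,
        end_question=end,
        n_phases=count_phases(start, end, earliest=1, latest=K),
        earliest=1,
        latest=K,
        fit_status=status,
        flags=start_exceed if config.start_threshold == config.end_threshold else None,
        info={
            "start_threshold": config.start_threshold,
            "end_threshold": config.end_threshold,
            "proportion_mode": config.proportion_mode,
        },
    )
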