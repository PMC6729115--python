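"""Phase boundaries and the phase-count rule shared by all detectors.

Every detector reports the start and end of the dropout phase on the
question grid (or neither, when no meaningful/significant attrition is found
anywhere).  The number of attrition phases follows from where those
boundaries sit relative to the earliest and latest positions the method
could possibly report:

* no boundaries                        -> 1 phase (stable throughout);
* start at the earliest possible slot
  and end at the latest               -> 1 phase (dropout throughout);
* exactly one boundary interior       -> 2 phases;
* both boundaries interior            -> 3 phases.

For the threshold scan the earliest slot is question 1; for contrast-based
methods the first comparison is (1, 2), so the earliest reportable start is
question 2.  The latest slot is question K for every method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PhaseDetection", "count_phases", "boundaries_from_significance"]


@dataclass(frozen=True)
class PhaseDetection:
    """Detected dropout-phase boundaries for one dataset and one method.

    ``start_question`` / ``end_question`` are 1-based question indices or
    None; ``flags`` holds the per-question exceedance (threshold method) or
    per-pair significance (model methods) indicators; ``contrasts`` is the
    adjacent-comparison table for model methods.
    """

    method: str
    n_questions: int
    start_question: int | None
    end_question: int | None
    n_phases: int
    earliest: int
    latest: int
    fit_status: str = "ok"  # ok | failed | degenerate
    flags: np.ndarray | None = None
    contrasts: pd.DataFrame | None = None
    info: dict = field(default_factory=dict)

    @property
    def usable(self) -> bool:
        return self.fit_status == "ok"


def count_phases(
    start_question: int | None,
    end_question: int | None,
    earliest: int,
    latest: int,
) -> int:
    """Number of attrition phases implied by the detected boundaries."""
    if start_question is None and end_question is None:
        return 1
    if start_question is None or end_question is None:
        raise ValueError("start and end must both be present or both absent")
    return 1 + int(start_question > earliest) + int(end_question < latest)


def boundaries_from_significance(
    significant: np.ndarray, first_index: int
) -> tuple[int | None, int | None]:
    """First/last True positions mapped onto the question grid.

    ``significant[j]`` refers to grid position ``first_index + j`` (question
    for exceedance flags, later index of the pair for contrast flags).
    """
    sig = np.asarray(significant, dtype=bool)
    if not sig.any():
        return None, None
    hits = np.flatnonzero(sig)
    return int(hits[0]) + first_index, int(hits[-1]) + first_index
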