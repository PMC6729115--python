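"""Representations of monotone survey dropout.

A participant who starts a survey of K ordered questions either answers all
of them (``COMPLETED``) or stops for good at some question q, having answered
questions 1..q-1.  Everything downstream — threshold scans, the cumulative
dropout mixed model, and the discrete-time survival fit — consumes one of the
three views defined here:

* dropout records (participant id, exit question),
* the cumulative long format (K rows per participant, ``dropped_by``),
* the person-period format (one row per question reached, ``event``).

Re-entry after dropout is not representable; questions are indexed 1..K.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "COMPLETED",
    "SurveyDesign",
    "DropoutDataset",
    "DropoutSummary",
    "NonmonotoneError",
    "from_response_matrix",
    "to_cumulative",
    "to_person_period",
    "dataset_from_cumulative",
    "dataset_from_person_period",
    "summarize",
    "read_wide_csv",
    "read_records_csv",
    "write_records_csv",
    "read_person_period_csv",
    "write_person_period_csv",
]

#: Sentinel exit value for participants who answered every question.
COMPLETED = "completed"

# Internal encoding: completers carry exit code K + 1, so "still at risk at
# question q" is simply ``code >= q`` for every participant.


class NonmonotoneError(ValueError):
    """A response row answers a question after an earlier unanswered one."""


@dataclass(frozen=True)
class SurveyDesign:
    """An ordered battery of ``n_questions`` survey items (1-based)."""

    n_questions: int

    def __post_init__(self) -> None:
        if self.n_questions < 2:
            raise ValueError(
                "a survey needs at least 2 questions for adjacent comparisons; "
                f"got {self.n_questions}"
            )


@dataclass(frozen=True)
class DropoutDataset:
    """Per-participant dropout records over a fixed question grid.

    ``exit_codes[i]`` is the question at which participant i dropped out
    (1..K) or K+1 if they completed the survey.  Use :attr:`completed` /
    :meth:`exit_question` for the user-facing view.
    """

    design: SurveyDesign
    participant_ids: np.ndarray  # object/str array, unique
    exit_codes: np.ndarray  # int array in 1..K+1

    def __post_init__(self) -> None:
        ids = np.asarray(self.participant_ids)
        codes = np.asarray(self.exit_codes, dtype=np.int64)
        object.__setattr__(self, "participant_ids", ids)
        object.__setattr__(self, "exit_codes", codes)
        if ids.shape != codes.shape or ids.ndim != 1:
            raise ValueError("participant_ids and exit_codes must be 1-d and aligned")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("participant ids must be unique")
        K = self.design.n_questions
        if codes.size and (codes.min() < 1 or codes.max() > K + 1):
            raise ValueError(f"exit questions must lie in 1..{K} or be {COMPLETED!r}")

    @classmethod
    def from_records(
        cls, records, design: SurveyDesign
    ) -> "DropoutDataset":
        """Build from (participant_id, exit) pairs; exit is 1..K or COMPLETED."""
        K = design.n_questions
        ids, codes = [], []
        for pid, exit_q in records:
            ids.append(pid)
            codes.append(K + 1 if exit_q == COMPLETED else int(exit_q))
        return cls(design, np.asarray(ids, dtype=object), np.asarray(codes))

    @property
    def n_participants(self) -> int:
        return len(self.exit_codes)

    @property
    def completed(self) -> np.ndarray:
        """Boolean mask of participants who answered all questions."""
        return self.exit_codes == self.design.n_questions + 1

    def exit_question(self, i: int):
        """Exit question of participant i, or the COMPLETED sentinel."""
        code = int(self.exit_codes[i])
        return COMPLETED if code == self.design.n_questions + 1 else code

    def records(self):
        """Iterate (participant_id, exit_question-or-COMPLETED) pairs."""
        for i, pid in enumerate(self.participant_ids):
            yield pid, self.exit_question(i)


@dataclass(frozen=True)
class DropoutSummary:
    """Per-question at-risk counts, dropout counts and dropout proportions.

    ``proportion[q-1]`` is the conditional (discrete-hazard) or marginal
    dropout proportion at question q, NaN where undefined (no one at risk).
    """

    design: SurveyDesign
    n_total: int
    n_at_risk: np.ndarray
    n_dropped: np.ndarray
    proportion: np.ndarray
    mode: str  # "conditional" | "marginal"

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.proportion)


# ---------------------------------------------------------------------------
# conversions


def from_response_matrix(
    matrix: pd.DataFrame,
    design: SurveyDesign,
    nonmonotone_policy: str = "error",
) -> DropoutDataset:
    """Derive dropout records from a wide answer matrix.

    ``matrix`` is indexed by participant id with exactly K answer columns;
    NaN / empty cells mean unanswered.  The exit question is the first
    unanswered question.  A row that answers a later question after a gap is
    nonmonotone: under ``policy="error"`` it raises, under ``"coerce"`` it is
    truncated at the first gap and counted in a warning.
    """
    if nonmonotone_policy not in ("error", "coerce"):
        raise ValueError(f"unknown nonmonotone_policy {nonmonotone_policy!r}")
    K = design.n_questions
    if matrix.shape[1] != K:
        raise ValueError(f"expected {K} answer columns, got {matrix.shape[1]}")
    ids = matrix.index.to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValueError("duplicate participant ids in response matrix")

    answered = matrix.notna().to_numpy()
    if answered.dtype != bool:  # pragma: no cover - notna always bool
        answered = answered.astype(bool)
    any_gap = ~answered.all(axis=1)
    first_gap = np.where(any_gap, np.argmin(answered, axis=1) + 1, K + 1)
    # nonmonotone: an answered cell strictly after the first gap
    cols = np.arange(1, K + 1)
    nonmono = (answered & (cols[None, :] > first_gap[:, None])).any(axis=1)
    if nonmono.any():
        bad = list(ids[nonmono][:5])
        if nonmonotone_policy == "error":
            raise NonmonotoneError(
                f"{nonmono.sum()} row(s) answer a question after a gap "
                f"(first ids: {bad}); pass nonmonotone_policy='coerce' to "
                "truncate at the first unanswered question"
            )
        warnings.warn(
            f"coerced {int(nonmono.sum())} nonmonotone row(s) to dropout at "
            "the first unanswered question",
            stacklevel=2,
        )
    return DropoutDataset(design, ids.astype(object), first_gap)


def to_cumulative(dataset: DropoutDataset) -> pd.DataFrame:
    """Long table with K rows per participant and a cumulative dropout flag.

    ``dropped_by`` is 1 from the exit question onward (a participant who has
    left stays left), 0 everywhere for completers.
    """
    K = dataset.design.n_questions
    n = dataset.n_participants
    q = np.tile(np.arange(1, K + 1), n)
    pid = np.repeat(dataset.participant_ids, K)
    dropped_by = (q >= np.repeat(dataset.exit_codes, K)).astype(np.int8)
    return pd.DataFrame(
        {"participant_id": pid, "question": q, "dropped_by": dropped_by}
    )


def to_person_period(dataset: DropoutDataset) -> pd.DataFrame:
    """Person-period table: one row per question reached, event=1 at exit.

    Completers contribute K event-free rows (censored after the last
    question).
    """
    K = dataset.design.n_questions
    rows_per = np.minimum(dataset.exit_codes, K)
    pid = np.repeat(dataset.participant_ids, rows_per)
    q = np.concatenate([np.arange(1, r + 1) for r in rows_per]) if len(rows_per) else np.array([], dtype=int)
    event = np.zeros(len(q), dtype=np.int8)
    last = np.cumsum(rows_per) - 1
    is_dropout = dataset.exit_codes <= K
    event[last[is_dropout]] = 1
    return pd.DataFrame({"participant_id": pid, "question": q, "event": event})


def dataset_from_cumulative(table: pd.DataFrame, design: SurveyDesign) -> DropoutDataset:
    """Recover dropout records from a cumulative table (round-trip inverse)."""
    K = design.n_questions
    ids, codes = [], []
    for pid, grp in table.groupby("participant_id", sort=False):
        grp = grp.sort_values("question")
        if len(grp) != K or not np.array_equal(grp["question"].to_numpy(), np.arange(1, K + 1)):
            raise ValueError(f"participant {pid!r}: expected exactly questions 1..{K}")
        d = grp["dropped_by"].to_numpy()
        if np.any(np.diff(d) < 0):
            raise ValueError(f"participant {pid!r}: dropped_by decreases (re-entry)")
        ids.append(pid)
        codes.append(int(np.argmax(d) + 1) if d.any() else K + 1)
    return DropoutDataset(design, np.asarray(ids, dtype=object), np.asarray(codes))


def dataset_from_person_period(table: pd.DataFrame, design: SurveyDesign) -> DropoutDataset:
    """Recover dropout records from a person-period table."""
    K = design.n_questions
    ids, codes = [], []
    for pid, grp in table.groupby("participant_id", sort=False):
        grp = grp.sort_values("question")
        q = grp["question"].to_numpy()
        ev = grp["event"].to_numpy()
        if not np.array_equal(q, np.arange(1, len(q) + 1)):
            raise ValueError(f"participant {pid!r}: questions must run 1..{len(q)} without gaps")
        if ev[:-1].any() or ev.sum() > 1:
            raise ValueError(f"participant {pid!r}: event must appear once, in the last row")
        ids.append(pid)
        if ev[-1] == 1:
            codes.append(len(q))
        else:
            if len(q) != K:
                raise ValueError(f"participant {pid!r}: censored before question {K}")
            codes.append(K + 1)
    return DropoutDataset(design, np.asarray(ids, dtype=object), np.asarray(codes))


# ---------------------------------------------------------------------------
# summaries


def summarize(dataset: DropoutDataset, mode: str = "conditional") -> DropoutSummary:
    """Per-question dropout counts and proportions.

    ``mode="conditional"`` gives the empirical discrete hazard
    n_dropped(q) / n_at_risk(q) — the probability of dropping at q given the
    participant reached q; ``"marginal"`` divides by the original sample size.
    Conditional proportions are NaN (undefined, not 0) where no one is at
    risk.
    """
    if mode not in ("conditional", "marginal"):
        raise ValueError(f"unknown proportion mode {mode!r}")
    K = dataset.design.n_questions
    codes = dataset.exit_codes
    n_total = dataset.n_participants
    qs = np.arange(1, K + 1)
    n_dropped = np.bincount(codes, minlength=K + 2)[1 : K + 1]
    n_at_risk = n_total - np.concatenate(([0], np.cumsum(n_dropped[:-1])))
    with np.errstate(invalid="ignore", divide="ignore"):
        if mode == "conditional":
            proportion = np.where(n_at_risk > 0, n_dropped / np.maximum(n_at_risk, 1), np.nan)
        else:
            proportion = n_dropped / n_total if n_total else np.full(K, np.nan)
    return DropoutSummary(
        design=dataset.design,
        n_total=n_total,
        n_at_risk=n_at_risk.astype(np.int64),
        n_dropped=n_dropped.astype(np.int64),
        proportion=np.asarray(proportion, dtype=float),
        mode=mode,
    )


# ---------------------------------------------------------------------------
# CSV interfaces


def read_wide_csv(path_or_buf, design: SurveyDesign | None = None,
                  missing_token: str = "", nonmonotone_policy: str = "error") -> DropoutDataset:
    """Read a wide response CSV (``participant_id,Q1,...,QK``)."""
    df = pd.read_csv(path_or_buf, dtype=str, keep_default_na=False)
    if "participant_id" not in df.columns:
        raise ValueError("wide CSV must have a participant_id column")
    df = df.set_index("participant_id")
    df = df.mask(df == missing_token)
    if design is None:
        design = SurveyDesign(df.shape[1])
    return from_response_matrix(df, design, nonmonotone_policy=nonmonotone_policy)


def read_records_csv(path_or_buf, design: SurveyDesign) -> DropoutDataset:
    """Read a dropout-record CSV (``participant_id,exit_question``).

    A blank exit_question or the literal ``completed`` marks a completer.
    """
    df = pd.read_csv(path_or_buf, dtype={"participant_id": str, "exit_question": str},
                     keep_default_na=False)
    records = []
    for pid, raw in zip(df["participant_id"], df["exit_question"]):
        raw = raw.strip()
        exit_q = COMPLETED if raw in ("", COMPLETED) else int(raw)
        records.append((pid, exit_q))
    return DropoutDataset.from_records(records, design)


def write_records_csv(dataset: DropoutDataset, path_or_buf) -> None:
    df = pd.DataFrame(
        {
            "participant_id": dataset.participant_ids,
            "exit_question": [
                COMPLETED if c == dataset.design.n_questions + 1 else c
                for c in dataset.exit_codes
            ],
        }
    )
    df.to_csv(path_or_buf, index=False)


def read_person_period_csv(path_or_buf, design: SurveyDesign) -> DropoutDataset:
    df = pd.read_csv(path_or_buf, dtype={"participant_id": str})
    return dataset_from_person_period(df, design)


def write_person_period_csv(dataset: DropoutDataset, path_or_buf) -> None:
    to_person_period(dataset).to_csv(path_or_buf, index=False)


def sniff_format(path) -> str:
    """Guess which of the three CSV layouts a file uses, from its header."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
    cols = [c.strip() for c in header.split(",")]
    if cols[:2] == ["participant_id", "exit_question"]:
        return "records"
    if cols[:3] == ["participant_id", "question", "event"]:
        return "person-period"
    if cols and cols[0] == "participant_id" and len(cols) > 2:
        return "wide"
    raise ValueError(f"cannot recognise CSV header {header!r}")
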