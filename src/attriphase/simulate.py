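"""Simulation of phase-structured monotone survey dropout.

Each participant walks the questions in order and, at question q, drops out
with probability ``hazards[q]`` given they are still in the survey; survivors
of all K questions are completers.  A :class:`PhasePattern` is a hazard
vector with a known true phase structure: constant (one regime), two-phase
(stable-use regime then dropout regime, or the reverse), or the classic
three-phase shape — curiosity plateau, dropout phase, stable use phase.

Default regime rates: stable-use hazard 0.01 per question, mild dropout-phase
hazard 0.03, severe dropout-phase hazard 0.04.  These are the study
conditions under which the evaluation metrics are computed; see
docs/methods.md for how they were chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DropoutDataset, SurveyDesign

__all__ = [
    "DEFAULT_RATES",
    "PhasePattern",
    "SimulationConfig",
    "make_pattern",
    "canonical_transitions",
    "simulate_dataset",
    "simulate_batch",
]

#: Canonical per-question hazards for the three dropout regimes.
DEFAULT_RATES = {"stable": 0.01, "mild": 0.03, "severe": 0.04}

# Valid (shape, location) combinations.
_LOCATIONS = {
    "constant": ("none",),
    "two_phase": ("start", "middle", "end"),
    "two_phase_reverse": ("start", "middle", "end"),
    "three_phase": ("middle", "one_start", "one_end", "ends"),
}


@dataclass(frozen=True)
class PhasePattern:
    """A per-question hazard vector with its true phase structure."""

    name: str
    hazards: np.ndarray
    true_n_phases: int
    true_transitions: tuple[int, ...]

    def __post_init__(self) -> None:
        h = np.asarray(self.hazards, dtype=float)
        object.__setattr__(self, "hazards", h)
        if h.ndim != 1 or len(h) < 2:
            raise ValueError("hazards must be a vector of length >= 2")
        if np.any((h < 0) | (h > 1)):
            raise ValueError("hazards must lie in [0, 1]")
        # transitions are exactly the questions where the hazard changes
        changes = tuple(int(q) for q in np.flatnonzero(np.diff(h)) + 2)
        if changes != tuple(self.true_transitions):
            raise ValueError(
                f"true_transitions {self.true_transitions} inconsistent with "
                f"hazard changes at {changes}"
            )
        if self.true_n_phases != len(changes) + 1:
            raise ValueError("true_n_phases inconsistent with hazard vector")

    @property
    def n_questions(self) -> int:
        return len(self.hazards)


@dataclass(frozen=True)
class SimulationConfig:
    """Replication settings for a simulation batch."""

    n_participants: int = 200
    n_replicates: int = 10_000
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_replicates < 1:
            raise ValueError("n_participants and n_replicates must be >= 1")


def canonical_transitions(shape: str, location: str, K: int) -> tuple[int, ...]:
    """Regime-change questions for a preset, scaled from the K=20 anchors.

    A transition at question q means the hazard regime changes between q-1
    and q.  For K=20: two-phase start/middle/end transition at 5/10/15;
    three-phase presets use (8,14) middle, (4,10) one_start, (11,17) one_end,
    (4,17) ends.
    """
    if shape == "constant":
        return ()
    if shape in ("two_phase", "two_phase_reverse"):
        q = {"start": round(K / 4), "middle": round(K / 2), "end": round(3 * K / 4)}[location]
        return (int(q),)
    pairs = {
        "middle": (round(0.4 * K), round(0.7 * K)),
        "one_start": (round(K / 5), round(K / 2)),
        "one_end": (round(K / 2) + 1, round(0.85 * K)),
        "ends": (round(K / 5), round(0.85 * K)),
    }
    t1, t2 = pairs[location]
    return (int(t1), int(t2))


def make_pattern(
    shape: str,
    severity: str = "mild",
    location: str = "none",
    K: int = 20,
    rates: dict | None = None,
) -> PhasePattern:
    """Build a preset attrition pattern.

    ``shape`` is one of constant / two_phase / two_phase_reverse /
    three_phase; ``severity`` (mild, severe) sets the dropout-phase hazard —
    for constant shapes, mild means the stable rate throughout and severe the
    severe rate throughout; ``location`` places the transition(s) and must be
    compatible with the shape.  ``rates`` may override any of the canonical
    ``{"stable", "mild", "severe"}`` hazards.
    """
    if shape not in _LOCATIONS:
        raise ValueError(f"unknown shape {shape!r}")
    if severity not in ("mild", "severe"):
        raise ValueError(f"unknown severity {severity!r}")
    if location not in _LOCATIONS[shape]:
        raise ValueError(
            f"location {location!r} is not valid for shape {shape!r}; "
            f"choose from {_LOCATIONS[shape]}"
        )
    r = dict(DEFAULT_RATES)
    if rates:
        r.update(rates)
    for k, v in r.items():
        if not 0 <= v <= 1:
            raise ValueError(f"rate {k}={v} outside [0, 1]")
    stable = r["stable"]
    dropout = r[severity]

    h = np.full(K, stable)
    transitions = canonical_transitions(shape, location, K)
    if shape == "constant":
        h[:] = dropout if severity == "severe" else stable
    elif shape == "two_phase":
        h[transitions[0] - 1 :] = dropout
    elif shape == "two_phase_reverse":
        h[: transitions[0] - 1] = dropout
    else:  # three_phase
        t1, t2 = transitions
        h[t1 - 1 : t2 - 1] = dropout
    # a rate override can merge regimes; recompute the realised structure
    realised = tuple(int(q) for q in np.flatnonzero(np.diff(h)) + 2)
    name = f"{shape}_{severity}" + ("" if location == "none" else f"_{location}")
    return PhasePattern(
        name=name, hazards=h, true_n_phases=len(realised) + 1, true_transitions=realised
    )


def simulate_dataset(
    pattern: PhasePattern, n_participants: int, rng: np.random.Generator
) -> DropoutDataset:
    """Draw one dataset: independent hazard walks for each participant."""
    K = pattern.n_questions
    u = rng.random((n_participants, K))
    drop = u < pattern.hazards
    any_drop = drop.any(axis=1)
    exit_codes = np.where(any_drop, drop.argmax(axis=1) + 1, K + 1)
    ids = np.array([f"p{i + 1}" for i in range(n_participants)], dtype=object)
    return DropoutDataset(SurveyDesign(K), ids, exit_codes)


def simulate_batch(pattern: PhasePattern, config: SimulationConfig):
    """Yield ``config.n_replicates`` independent datasets.

    Replicate r uses a child stream spawned from
    ``SeedSequence(master_seed)``, so the batch is reproducible and each
    replicate's stream does not depend on how many others were consumed.
    """
    children = np.random.SeedSequence(config.master_seed).spawn(config.n_replicates)
    for child in children:
        yield simulate_dataset(pattern, config.n_participants, np.random.default_rng(child))
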