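"""Simulation-study orchestration: type I error, sensitivity, histograms.

Metric definitions follow the study design:

* **type I error** — the fraction of replicates in which at least 2
  attrition phases are detected although the simulated hazard is constant;
* **sensitivity** — the fraction of replicates in which exactly the true
  number of phases (2 or 3) is detected.

Replicates whose fit failed or was degenerate are excluded from the metric
denominator and reported separately (an optional mode counts them as
non-detections instead).  Boundary-choice histograms record how often each
question was picked as the start and end of the dropout phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dtsa import detect_dtsa
from .glmm import detect_glmm
from .phases import PhaseDetection, count_phases
from .simulate import PhasePattern, SimulationConfig, simulate_batch
from .threshold import ThresholdConfig, detect_threshold

__all__ = [
    "StudyResult",
    "type_i_error",
    "sensitivity",
    "boundary_histogram",
    "run_study",
    "default_patterns",
    "count_phases",
]

#: The full pattern grid of the simulation study, as (shape, severity, location).
STUDY_GRID = (
    [("constant", sev, "none") for sev in ("mild", "severe")]
    + [
        (shape, sev, loc)
        for sev in ("mild", "severe")
        for shape in ("two_phase", "two_phase_reverse")
        for loc in ("middle", "start", "end")
    ]
    + [
        ("three_phase", sev, loc)
        for sev in ("mild", "severe")
        for loc in ("middle", "one_start", "one_end", "ends")
    ]
)


@dataclass(frozen=True)
class StudyResult:
    """One cell of the study: a pattern × method metric with histograms."""

    pattern: str
    method: str
    metric_type: str  # type_i_error | sensitivity
    value: float
    n_effective: int
    n_failed: int
    start_histogram: dict
    end_histogram: dict
    config: dict = field(default_factory=dict)


def _usable(detections: list[PhaseDetection], include_degenerate: bool = False):
    keep = ("ok", "degenerate") if include_degenerate else ("ok",)
    return [d for d in detections if d.fit_status in keep]


def type_i_error(
    detections: list[PhaseDetection], failed_as_negative: bool = False
) -> float:
    """Fraction of usable replicates detecting >= 2 phases."""
    usable = _usable(detections)
    denom = len(detections) if failed_as_negative else len(usable)
    if denom == 0:
        raise ValueError("no usable replicates")
    return sum(d.n_phases >= 2 for d in usable) / denom


def sensitivity(
    detections: list[PhaseDetection],
    true_n_phases: int,
    failed_as_negative: bool = False,
) -> float:
    """Fraction of usable replicates detecting exactly the true phase count."""
    if true_n_phases not in (2, 3):
        raise ValueError("sensitivity is defined for true phase counts 2 and 3")
    usable = _usable(detections)
    denom = len(detections) if failed_as_negative else len(usable)
    if denom == 0:
        raise ValueError("no usable replicates")
    return sum(d.n_phases == true_n_phases for d in usable) / denom


def boundary_histogram(detections: list[PhaseDetection]) -> tuple[dict, dict]:
    """Counts of chosen start/end questions over usable replicates.

    Keys are question numbers plus ``"none"`` for replicates with no
    detected dropout phase.
    """
    start: dict = {}
    end: dict = {}
    for d in _usable(detections):
        ks = d.start_question if d.start_question is not None else "none"
        ke = d.end_question if d.end_question is not None else "none"
        start[ks] = start.get(ks, 0) + 1
        end[ke] = end.get(ke, 0) + 1
    return start, end


def default_patterns(K: int = 20, rates: dict | None = None) -> list[PhasePattern]:
    """The study's full pattern grid (2 constant + 12 two-phase + 8 three-phase)."""
    from .simulate import make_pattern

    return [make_pattern(s, sev, loc, K=K, rates=rates) for s, sev, loc in STUDY_GRID]


def _make_detector(method: str, alpha: float, threshold_config: ThresholdConfig):
    if method == "threshold":
        return lambda ds: detect_threshold(ds, threshold_config)
    if method == "glmm":
        return lambda ds: detect_glmm(ds, alpha=alpha)
    if method == "dtsa":
        return lambda ds: detect_dtsa(ds, alpha=alpha)
    raise ValueError(f"unknown method {method!r}")


def evaluate_cell(
    pattern: PhasePattern,
    method: str,
    config: SimulationConfig,
    alpha: float = 0.05,
    threshold_config: ThresholdConfig = ThresholdConfig(),
    failed_as_negative: bool = False,
) -> StudyResult:
    """Simulate one pattern, run one detector, compute its metric."""
    detector = _make_detector(method, alpha, threshold_config)
    detections = [detector(ds) for ds in simulate_batch(pattern, config)]
    usable = _usable(detections)
    n_failed = len(detections) - len(usable)
    if pattern.true_n_phases == 1:
        metric = "type_i_error"
        value = type_i_error(detections, failed_as_negative)
    else:
        metric = "sensitivity"
        value = sensitivity(detections, pattern.true_n_phases, failed_as_negative)
    start_hist, end_hist = boundary_histogram(detections)
    return StudyResult(
        pattern=pattern.name,
        method=method,
        metric_type=metric,
        value=value,
        n_effective=len(usable),
        n_failed=n_failed,
        start_histogram=start_hist,
        end_histogram=end_hist,
        config={
            "n_participants": config.n_participants,
            "n_replicates": config.n_replicates,
            "master_seed": config.master_seed,
            "alpha": alpha,
            "start_threshold": threshold_config.start_threshold,
            "end_threshold": threshold_config.end_threshold,
            "proportion_mode": threshold_config.proportion_mode,
            "hazards": pattern.hazards.tolist(),
            "true_n_phases": pattern.true_n_phases,
        },
    )


def run_study(
    patterns: list[PhasePattern],
    methods: list[str],
    config: SimulationConfig,
    alpha: float = 0.05,
    threshold_config: ThresholdConfig = ThresholdConfig(),
    failed_as_negative: bool = False,
    progress: bool = False,
) -> tuple[pd.DataFrame, list[StudyResult]]:
    """Run the full pattern × method grid.

    Returns the long results table (one row per cell, shaped like the
    study's summary table) and the per-cell :class:`StudyResult` objects
    with their histograms.  Every cell derives its replicate streams from
    ``config.master_seed``, so identical configs give identical results; the
    same replicate data are reused across methods within a pattern.
    """
    results: list[StudyResult] = []
    for pattern in patterns:
        for method in methods:
            if progress:  # pragma: no cover - cosmetic
                print(f"  {pattern.name} x {method} ...", flush=True)
            results.append(
                evaluate_cell(
                    pattern, method, config, alpha, threshold_config, failed_as_negative
                )
            )
    rows = []
    for r in results:
        shape, severity, location = _parse_name(r.pattern)
        rows.append(
            {
                "metric": r.metric_type,
                "shape": shape,
                "severity": severity,
                "location": location,
                "method": r.method,
                "value": r.value,
                "n_effective": r.n_effective,
                "n_failed": r.n_failed,
            }
        )
    return pd.DataFrame(rows), results


def _parse_name(name: str) -> tuple[str, str, str]:
    for shape in ("two_phase_reverse", "two_phase", "three_phase", "constant"):
        if name.startswith(shape + "_"):
            rest = name[len(shape) + 1 :].split("_", 1)
            severity = rest[0]
            location = rest[1] if len(rest) > 1 else "none"
            return shape, severity, location
    return name, "", ""
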