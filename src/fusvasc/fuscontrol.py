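"""Feedback-controlled sonication pressure simulator.

Models the closed-loop exposure protocol: a low-pressure baseline recording
calibrates an ultraharmonic detection threshold at 10x the baseline standard
deviation; during treatment the commanded pressure ramps up by a fixed
increment each pulse until the microbubble emissions reach the threshold,
whereupon the pressure is halved and held (halving again on any further
event) until the treatment ends.  Multiple grid targets are interleaved
within each pulse repetition period, and grids larger than 3x3 are covered
by two treatments separated by a fixed gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import EmissionTrace

__all__ = [
    "ControllerConfig",
    "PressureSeries",
    "calibrate_baseline",
    "run_controller",
    "simulate_treatment",
    "steady_state_summary",
]


@dataclass
class ControllerConfig:
    """Protocol constants of the feedback sonication controller."""

    baseline_pressure_kPa: float = 28.0
    baseline_duration_s: float = 10.0
    threshold_multiplier: float = 10.0
    ramp_increment_kPa: float = 8.0
    reduction_fraction: float = 0.5
    prf_Hz: float = 1.0
    burst_ms: float = 10.0
    treatment_s: float = 120.0
    grid: tuple[int, int] = (3, 3)
    grid_split_threshold: int = 9  # targets; a 3x3 grid fits one treatment
    inter_treatment_gap_s: float = 300.0
    resume_ramp_after_event: bool = False
    pressure_ceiling_kPa: float | None = None
    skull_transmission: float | None = None  # reporting-only derating

    def __post_init__(self) -> None:
        positive = (
            self.baseline_pressure_kPa,
            self.baseline_duration_s,
            self.threshold_multiplier,
            self.ramp_increment_kPa,
            self.prf_Hz,
            self.burst_ms,
            self.treatment_s,
            self.inter_treatment_gap_s,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("all controller parameters must be positive")
        if not 0 < self.reduction_fraction < 1:
            raise ValueError("reduction_fraction must lie in (0, 1)")
        if min(self.grid) < 1:
            raise ValueError("grid must be at least 1x1")

    @property
    def n_pulses(self) -> int:
        return int(round(self.prf_Hz * self.treatment_s))

    @property
    def n_targets(self) -> int:
        return int(self.grid[0] * self.grid[1])


@dataclass
class PressureSeries:
    """Per-pulse commanded pressures and threshold-event flags for one
    target, plus its schedule placement."""

    pressures_kPa: np.ndarray
    events: np.ndarray
    target: int = 0
    start_time_s: float = 0.0
    prf_Hz: float = 1.0
    burst_ms: float = 10.0
    threshold: float = float("nan")
    steady_state_fallback: bool = field(default=False)

    def __post_init__(self) -> None:
        self.pressures_kPa = np.asarray(self.pressures_kPa, dtype=float)
        self.events = np.asarray(self.events, dtype=bool)
        if np.any(self.pressures_kPa <= 0):
            raise ValueError("pressures must be positive")

    @property
    def n_pulses(self) -> int:
        return int(self.pressures_kPa.size)

    @property
    def event_count(self) -> int:
        return int(self.events.sum())

    def burst_times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_pulses) / self.prf_Hz

    def summary(self, cfg: "ControllerConfig | None" = None) -> dict:
        mean_ss, fallback = steady_state_summary(self)
        out = {
            "target": self.target,
            "n_pulses": self.n_pulses,
            "event_count": self.event_count,
            "mean_steady_state_kPa": mean_ss,
            "steady_state_fallback": fallback,
            "max_pressure_kPa": float(self.pressures_kPa.max()),
        }
        if cfg is not None and cfg.skull_transmission is not None:
            out["mean_steady_state_derated_kPa"] = (
                mean_ss * cfg.skull_transmission
            )
        return out


def calibrate_baseline(
    trace: EmissionTrace, cfg: ControllerConfig | None = None
) -> float:
    """Detection threshold: ``threshold_multiplier`` times the sample
    standard deviation of the mean-subtracted baseline recording."""
    cfg = cfg or ControllerConfig()
    baseline = np.asarray(trace.baseline_samples, dtype=float)
    if baseline.size < 2:
        raise ValueError("baseline needs at least two samples")
    sd = float((baseline - baseline.mean()).std(ddof=1))
    if sd == 0:
        raise ValueError("zero-variance baseline: threshold undefined")
    return cfg.threshold_multiplier * sd


def run_controller(
    trace: EmissionTrace,
    threshold: float,
    cfg: ControllerConfig | None = None,
    target: int = 0,
    start_time_s: float = 0.0,
) -> PressureSeries:
    """Simulate one target's pressure series against an emission trace.

    The pressure starts at the baseline calibration level and rises by the
    ramp increment after each event-free pulse; a pulse whose
    baseline-subtracted emission reaches the threshold halves the next
    pulse's pressure, after which the pressure is held (halving again on
    further events) until the treatment ends.  With
    ``resume_ramp_after_event`` the ramp restarts instead of holding.
    """
    cfg = cfg or ControllerConfig()
    n = cfg.n_pulses
    if trace.n_pulses < n:
        raise ValueError(
            f"trace covers {trace.n_pulses} pulses; treatment needs {n}"
        )
    baseline_mean = float(np.mean(trace.baseline_samples))
    pressures = np.empty(n)
    events = np.zeros(n, dtype=bool)
    p = cfg.baseline_pressure_kPa
    event_seen = False
    for i in range(n):
        if cfg.pressure_ceiling_kPa is not None:
            p = min(p, cfg.pressure_ceiling_kPa)
        pressures[i] = p
        amp = trace.emission(i, p)
        if amp - baseline_mean >= threshold:
            events[i] = True
            event_seen = True
            p = p * cfg.reduction_fraction
        elif not event_seen or cfg.resume_ramp_after_event:
            p = p + cfg.ramp_increment_kPa
        # else: hold
    return PressureSeries(
        pressures_kPa=pressures,
        events=events,
        target=target,
        start_time_s=start_time_s,
        prf_Hz=cfg.prf_Hz,
        burst_ms=cfg.burst_ms,
        threshold=threshold,
    )


def simulate_treatment(
    cfg: ControllerConfig,
    emission_models: Sequence | str | tuple,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> tuple[list[PressureSeries], pd.DataFrame]:
    """Simulate an interleaved grid treatment.

    ``emission_models`` is one event-model spec shared by all targets or a
    sequence with one spec per target (see
    :func:`fusvasc.synthgen.generate_emission_trace`).  Targets are cycled
    within each repetition period so each receives the full pulse count;
    grids above the split threshold are divided over two treatments whose
    sonications start ``inter_treatment_gap_s`` apart.

    Returns the per-target series and a tidy burst schedule.
    """
    from .synthgen import generate_emission_trace

    n_targets = cfg.n_targets
    if n_targets < 1:
        raise ValueError("grid with zero targets")
    if isinstance(emission_models, (str, tuple)):
        emission_models = [emission_models] * n_targets
    if len(emission_models) != n_targets:
        raise ValueError("need one emission model per target")

    if n_targets > cfg.grid_split_threshold:
        first = (n_targets + 1) // 2
        treatment_of = [0 if t < first else 1 for t in range(n_targets)]
    else:
        treatment_of = [0] * n_targets

    series: list[PressureSeries] = []
    baseline_n = max(2, int(round(cfg.baseline_duration_s * cfg.prf_Hz)))
    for t in range(n_targets):
        trace = generate_emission_trace(
            emission_models[t],
            n_pulses=cfg.n_pulses,
            noise_sd=noise_sd,
            seed=seed + t,
            baseline_samples=baseline_n,
        )
        threshold = calibrate_baseline(trace, cfg)
        start = treatment_of[t] * cfg.inter_treatment_gap_s
        series.append(
            run_controller(
                trace, threshold, cfg, target=t, start_time_s=start
            )
        )

    rows = []
    for s in series:
        within = [t for t in range(n_targets) if treatment_of[t] == treatment_of[s.target]]
        slot = within.index(s.target)
        for k, t0 in enumerate(s.burst_times_s()):
            rows.append(
                (
                    s.target,
                    treatment_of[s.target],
                    k,
                    t0 + slot * cfg.burst_ms / 1000.0,
                    s.pressures_kPa[k],
                    bool(s.events[k]),
                )
            )
    schedule = pd.DataFrame(
        rows,
        columns=[
            "target",
            "treatment",
            "pulse",
            "time_s",
            "pressure_kPa",
            "event",
        ],
    )
    return series, schedule


def steady_state_summary(
    series: PressureSeries,
    window: str = "post_first_event",
    trailing_fraction: float = 0.5,
) -> tuple[float, bool]:
    """Mean commanded pressure over the steady-state portion.

    The default window starts at the pulse after the first threshold event;
    if no event occurred the trailing ``trailing_fraction`` of the ramp is
    used instead and the fallback is flagged.  Returns ``(mean_kPa,
    fallback_used)``.
    """
    p = series.pressures_kPa
    if window == "trailing":
        k = max(1, int(round(trailing_fraction * p.size)))
        return float(p[-k:].mean()), False
    if window != "post_first_event":
        raise ValueError("window must be 'post_first_event' or 'trailing'")
    if series.events.any():
        first = int(np.argmax(series.events))
        if first + 1 < p.size:
            return float(p[first + 1 :].mean()), False
        return float(p[-1]), False
    k = max(1, int(round(trailing_fraction * p.size)))
    return float(p[-k:].mean()), True
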