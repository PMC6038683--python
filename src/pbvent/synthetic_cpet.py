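"""Synthetic cardiopulmonary-exercise ventilation generator.

Produces labeled periodic-breathing (PB) and non-PB breath-by-breath
ventilation series with the structure the downstream analysis assumes:
a resting breath rate that ramps up during exercise and back down during
recovery, a rising-then-falling ventilation trend, an optional slow
multiplicative oscillation for PB subjects, multiplicative lognormal noise,
and occasional gasping artifacts in which a single breath is recorded as two
spuriously low breaths.

Ground truth needed by tests (clean trend, modulation, gasp indices) is
stashed in ``BreathSeries.meta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .series import BreathSeries

__all__ = ["SubjectParams", "generate_subject", "generate_cohort"]


@dataclass(frozen=True)
class SubjectParams:
    """Parameters of one simulated subject.

    Rates are in breaths/min, ventilation in L/min, durations and the
    oscillation period in seconds. ``pb_amplitude`` is the multiplicative
    modulation depth m in [0, 1); ``noise_sigma`` the lognormal log-scale;
    ``gasp_prob`` the per-breath probability of a gasping artifact.
    """

    rest_rate: float = 15.0
    peak_rate: float = 40.0
    ve_rest: float = 10.0
    ve_peak: float = 60.0
    exercise_duration: float = 600.0
    recovery_duration: float = 240.0
    pb_amplitude: float = 0.0
    pb_period: float = 60.0
    noise_sigma: float = 0.08
    gasp_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rest_rate < self.peak_rate:
            raise ParameterError("rest_rate must be < peak_rate")
        if not self.ve_rest < self.ve_peak:
            raise ParameterError("ve_rest must be < ve_peak")
        if self.rest_rate <= 0:
            raise ParameterError("rest_rate must be positive")
        if self.ve_rest <= 0:
            raise ParameterError("ve_rest must be positive")
        if self.exercise_duration <= 0:
            raise ParameterError("exercise_duration must be positive")
        if self.recovery_duration < 0:
            raise ParameterError("recovery_duration must be non-negative")
        if not 0.0 <= self.pb_amplitude < 1.0:
            raise ParameterError("pb_amplitude must be in [0, 1)")
        if self.pb_period <= 0:
            raise ParameterError("pb_period must be positive")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be non-negative")
        if not 0.0 <= self.gasp_prob < 1.0:
            raise ParameterError("gasp_prob must be in [0, 1)")


def breath_rate(t: np.ndarray | float, params: SubjectParams) -> np.ndarray:
    """Instantaneous breath rate r(t) in breaths/min.

    Linear ramp rest_rate -> peak_rate over the exercise phase, then a linear
    return toward rest_rate over the recovery phase.
    """
    t = np.asarray(t, dtype=float)
    span = params.peak_rate - params.rest_rate
    up = params.rest_rate + span * np.clip(t / params.exercise_duration, 0.0, 1.0)
    if params.recovery_duration > 0:
        frac = np.clip((t - params.exercise_duration) / params.recovery_duration, 0.0, 1.0)
    else:
        frac = np.where(t > params.exercise_duration, 1.0, 0.0)
    return np.where(t <= params.exercise_duration, up, params.peak_rate - span * frac)


def clean_trend(t: np.ndarray | float, params: SubjectParams) -> np.ndarray:
    """Noise-free ventilation trend: linear rise to ve_peak at the end of the
    exercise phase, then exponential decay back toward ve_rest."""
    t = np.asarray(t, dtype=float)
    span = params.ve_peak - params.ve_rest
    rise = params.ve_rest + span * np.clip(t / params.exercise_duration, 0.0, 1.0)
    tau = max(params.recovery_duration, 1e-9) / 3.0
    fall = params.ve_rest + span * np.exp(-(t - params.exercise_duration) / tau)
    return np.where(t <= params.exercise_duration, rise, fall)


def _breath_times(params: SubjectParams) -> np.ndarray:
    """Breath times obtained by inverting the cumulative breath count
    N(t) = integral of r(s)/60 ds, so the total breath count matches the
    integrated rate to within one breath."""
    total = params.exercise_duration + params.recovery_duration
    grid = np.linspace(0.0, total, max(int(total * 20), 200))
    rate = breath_rate(grid, params) / 60.0
    cum = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2.0 * np.diff(grid))])
    n_breaths = int(math.floor(cum[-1]))
    return np.interp(np.arange(1, n_breaths + 1, dtype=float), cum, grid)


def generate_subject(params: SubjectParams, subject_id: str = "synthetic",
                     label: str | None = None) -> BreathSeries:
    """Simulate one breath-by-breath ventilation recording.

    Each breath's VE is ``clean_trend * (1 + m sin(2 pi t / pb_period + phi))
    * lognormal(0, noise_sigma)``. With probability ``gasp_prob`` a breath is
    replaced by two breaths whose VE is drawn uniformly in [0.2, 0.6] times
    the local clean trend, mimicking a gasping exhalation recorded as two
    spuriously low breaths. Deterministic for a fixed ``params.seed``.

    ``meta`` carries ``clean_trend`` (per emitted breath), ``gasp_indices``
    (final indices of artifact breaths) and ``phase`` (modulation phase).
    """
    rng = np.random.default_rng(params.seed)
    base_times = _breath_times(params)
    phi = rng.uniform(0.0, 2.0 * np.pi)

    times: list[float] = []
    ve: list[float] = []
    trend_out: list[float] = []
    gasp_indices: list[int] = []

    prev_t = 0.0
    for t in base_times:
        trend = float(clean_trend(t, params))
        is_gasp = params.gasp_prob > 0 and rng.random() < params.gasp_prob
        if is_gasp:
            # one exhalation recorded as two low breaths inside this interval
            t_mid = prev_t + 0.5 * (t - prev_t)
            for tg in (t_mid, t):
                tr = float(clean_trend(tg, params))
                gasp_indices.append(len(ve))
                times.append(tg)
                ve.append(rng.uniform(0.2, 0.6) * tr)
                trend_out.append(tr)
        else:
            mod = 1.0 + params.pb_amplitude * math.sin(2.0 * math.pi * t / params.pb_period + phi)
            noise = math.exp(rng.normal(0.0, params.noise_sigma)) if params.noise_sigma > 0 else 1.0
            times.append(float(t))
            ve.append(trend * mod * noise)
            trend_out.append(trend)
        prev_t = t

    return BreathSeries(
        subject_id=subject_id,
        times=np.array(times),
        ve=np.array(ve),
        label=label if label is not None else ("PB" if params.pb_amplitude > 0 else "unknown"),
        meta={
            "clean_trend": np.array(trend_out),
            "gasp_indices": np.array(gasp_indices, dtype=int),
            "phase": phi,
            "params": params,
        },
    )


def generate_cohort(n_pb: int, n_npb: int,
                    base_params: SubjectParams = SubjectParams(),
                    seed: int = 0,
                    pb_amplitude_range: tuple[float, float] = (0.2, 0.5),
                    npb_amplitude_range: tuple[float, float] = (0.0, 0.02),
                    pb_period_range: tuple[float, float] = (40.0, 90.0)) -> list[BreathSeries]:
    """Simulate a labeled cohort of ``n_pb`` PB and ``n_npb`` non-PB subjects.

    PB subjects draw their modulation depth from ``pb_amplitude_range`` and
    their oscillation period from ``pb_period_range``; non-PB subjects draw a
    near-zero depth from ``npb_amplitude_range``. Per-subject seeds derive
    deterministically from ``seed``.
    """
    if n_pb < 0 or n_npb < 0:
        raise ParameterError("n_pb and n_npb must be non-negative")
    rng = np.random.default_rng(seed)
    cohort: list[BreathSeries] = []
    for i in range(n_pb + n_npb):
        is_pb = i < n_pb
        lo, hi = pb_amplitude_range if is_pb else npb_amplitude_range
        amp = float(rng.uniform(lo, hi))
        period = float(rng.uniform(*pb_period_range))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        params = replace(base_params, pb_amplitude=amp, pb_period=period, seed=sub_seed)
        sid = f"pb{i + 1:04d}" if is_pb else f"npb{i - n_pb + 1:04d}"
        cohort.append(generate_subject(params, subject_id=sid,
                                       label="PB" if is_pb else "nPB"))
    return cohort
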