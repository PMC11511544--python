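"""Seedable generator of three-phase vital-sign sessions.

The generator emulates the statistical structure of the reference
recordings: a resting phase with stable vitals and a gyro-drift speed floor
of a few mm/s, a walking phase with moderate speeds and noisier heart rate,
and a running phase whose heart rate ramps toward the mid-150s BPM so the
alert path is exercised.  The speed channel is not drawn directly: a
synthetic gyroscope trace (deliberate swing about the vertical axis plus
white drift noise on all axes) is pushed through the kinematics module, so
resting "speed" is genuinely the cross-product image of gyro noise.

Artifact spikes — single-sample multiplicative excursions of the heart-rate
channel, the signature of a sensor shifting on skin during motion — are
injected at a Poisson rate during walking and running.  At rest the sensor
does not move, so the resting default injects none.  Width-1 spikes are the
false-alarm mechanism this system's filters exist to suppress: a width-5
mean reduces a lone spike fivefold, a σ=2 Gaussian kernel even further.

Everything is driven by one caller-supplied seed through a named generator;
there is no hidden global randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .alerts import AlertConfig, AlertLogic
from .kinematics import ArmModel, ImuReading, speed_series
from .session_io import Phase, PhaseSession, VitalSample

__all__ = ["PhaseParams", "default_params", "generate_session", "inject_spikes"]


def _dps_per_cm_s(arm: ArmModel) -> float:
    """Swing-axis (z) deg/s producing 1 cm/s of linear speed for this arm."""
    r = np.asarray(arm.r_m, dtype=float)
    r_eff = float(np.hypot(r[0], r[1]))  # |z-hat x r|
    if r_eff <= 0:
        raise ValueError("arm position vector must have a component off the z axis")
    return 180.0 / (np.pi * 100.0 * r_eff)


@dataclass(frozen=True)
class PhaseParams:
    """Level-and-noise description of one activity phase.

    Heart rate follows a saturating linear ramp
    ``min(hr_base_bpm + hr_ramp_bpm_per_s·t, hr_peak_bpm)`` plus Gaussian
    noise.  SpO2 is a near-integer plateau taking rare ±1 steps.  Both
    temperatures drift linearly with small jitter.  ``speed_base_cm_s`` is
    the target mean speed realised through the gyroscope model;
    ``gyro_noise_dps`` is white noise on all gyro axes and sets the resting
    drift floor.  Spikes are Poisson single-sample artifacts multiplying the
    heart rate by ``spike_gain``.
    """

    phase: Phase
    duration_s: float = 300.0
    hr_base_bpm: float = 77.0
    hr_sd_bpm: float = 2.2
    hr_ramp_bpm_per_s: float = 0.0
    hr_peak_bpm: float = 77.0
    spo2_base_pct: float = 97.0
    spo2_step_prob: float = 0.02
    ambient_c_base: float = 32.1
    ambient_drift_c_per_s: float = 0.015
    ambient_jitter_c: float = 0.02
    body_c_base: float = 35.7
    body_drift_c_per_s: float = -0.001
    body_jitter_c: float = 0.05
    speed_base_cm_s: float = 0.5
    speed_sd_cm_s: float = 0.3
    gyro_noise_dps: float = 0.9
    spike_rate_per_min: float = 0.0
    spike_gain: float = 1.5

    def __post_init__(self) -> None:
        for name in (
            "duration_s",
            "hr_base_bpm",
            "hr_peak_bpm",
            "spo2_base_pct",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "hr_sd_bpm",
            "hr_ramp_bpm_per_s",
            "spo2_step_prob",
            "ambient_jitter_c",
            "body_jitter_c",
            "speed_base_cm_s",
            "speed_sd_cm_s",
            "gyro_noise_dps",
            "spike_rate_per_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.spike_gain <= 0:
            raise ValueError("spike_gain must be positive")


_DEFAULTS: dict[Phase, PhaseParams] = {
    # stable vitals; speed floor is pure gyro drift, ~0.5 cm/s; no motion,
    # hence no motion-artifact spikes
    Phase.RESTING: PhaseParams(phase=Phase.RESTING),
    Phase.WALKING: PhaseParams(
        phase=Phase.WALKING,
        hr_base_bpm=80.0,
        hr_sd_bpm=12.0,
        hr_peak_bpm=80.0,
        spo2_base_pct=96.0,
        ambient_c_base=33.0,
        ambient_drift_c_per_s=-0.027,
        body_c_base=34.4,
        body_drift_c_per_s=0.0,
        body_jitter_c=0.15,
        speed_base_cm_s=28.0,
        speed_sd_cm_s=16.0,  # base + 2 sd ~ 60 cm/s walking ceiling
        gyro_noise_dps=2.0,
        spike_rate_per_min=1.0,
        spike_gain=1.5,
    ),
    Phase.RUNNING: PhaseParams(
        phase=Phase.RUNNING,
        hr_base_bpm=95.0,
        hr_sd_bpm=8.0,
        hr_ramp_bpm_per_s=0.5,
        hr_peak_bpm=155.0,  # > 150 so the default alert threshold is reachable
        spo2_base_pct=96.0,
        ambient_c_base=32.6,
        ambient_drift_c_per_s=-0.013,
        body_c_base=35.8,
        body_drift_c_per_s=-0.003,
        body_jitter_c=0.25,
        speed_base_cm_s=150.0,
        speed_sd_cm_s=70.0,
        gyro_noise_dps=3.0,
        spike_rate_per_min=1.0,
        spike_gain=1.4,
    ),
}


def default_params(phase: Phase | str) -> PhaseParams:
    """Default :class:`PhaseParams` emulating the reference recordings."""
    return _DEFAULTS[Phase(phase)]


def inject_spikes(
    series: Sequence[float],
    rate_per_min: float,
    gain: float,
    seed: "int | np.random.Generator",
    sample_period_s: float = 1.0,
) -> np.ndarray:
    """Multiply Poisson-placed single samples of ``series`` by ``gain``.

    The number of spikes is Poisson with mean rate·duration; positions are
    uniform without replacement.  Deterministic for a given seed; rate 0 or
    gain 1 return the series unchanged.
    """
    if rate_per_min < 0:
        raise ValueError("rate_per_min must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(series, dtype=float).copy()
    mean_events = rate_per_min * len(x) * sample_period_s / 60.0
    n_events = min(int(rng.poisson(mean_events)), len(x))
    if n_events and gain != 1.0:
        pos = rng.choice(len(x), size=n_events, replace=False)
        x[pos] *= gain
    return x


def _generate_phase(
    params: PhaseParams,
    period_s: float,
    rng: np.random.Generator,
    arm: ArmModel,
    alert_config: AlertConfig,
) -> PhaseSession:
    n = max(1, int(round(params.duration_s / period_s)))
    t = np.arange(n) * period_s

    hr_mean = np.minimum(
        params.hr_base_bpm + params.hr_ramp_bpm_per_s * t, params.hr_peak_bpm
    )
    hr = hr_mean + rng.normal(0.0, params.hr_sd_bpm, n)
    hr = inject_spikes(hr, params.spike_rate_per_min, params.spike_gain, rng, period_s)
    hr = np.clip(hr, 30.0, None)

    # integer plateau with rare +/-1 steps, wandering at most 2 from base
    steps = np.where(
        rng.random(n) < params.spo2_step_prob, rng.choice((-1.0, 1.0), size=n), 0.0
    )
    spo2 = np.clip(params.spo2_base_pct + np.cumsum(steps), 0.0, 100.0)
    spo2 = np.clip(spo2, params.spo2_base_pct - 2.0, params.spo2_base_pct + 2.0)

    ambient = (
        params.ambient_c_base
        + params.ambient_drift_c_per_s * t
        + rng.normal(0.0, params.ambient_jitter_c, n)
    )
    body = (
        params.body_c_base
        + params.body_drift_c_per_s * t
        + rng.normal(0.0, params.body_jitter_c, n)
    )

    # target speed realised through the gyroscope: swing about z plus drift
    # noise on every axis, then the cross-product kinematics
    target = np.clip(rng.normal(params.speed_base_cm_s, params.speed_sd_cm_s, n), 0.0, None)
    gyro = rng.normal(0.0, params.gyro_noise_dps, size=(n, 3))
    gyro[:, 2] += target * _dps_per_cm_s(arm)
    trace = [ImuReading(gyro_dps=(g[0], g[1], g[2])) for g in gyro]
    speed = speed_series(trace, arm)

    hr = np.round(hr, 2)
    spo2 = np.round(spo2, 1)
    ambient = np.round(ambient, 2)
    body = np.round(body, 2)
    speed = np.round(speed, 2)

    flags = hr > alert_config.hr_threshold_bpm
    if alert_config.logic is AlertLogic.HR_AND_SPEED:
        flags &= speed > alert_config.speed_threshold_cm_s

    samples = tuple(
        VitalSample(
            index=i + 1,
            time_s=float(t[i]),
            hr_bpm=float(hr[i]),
            spo2_pct=float(spo2[i]),
            ambient_c=float(ambient[i]),
            body_c=float(body[i]),
            speed_cm_s=float(speed[i]),
            alert=int(flags[i]),
        )
        for i in range(n)
    )
    return PhaseSession(phase=params.phase, samples=samples, sample_period_s=period_s)


def generate_session(
    params: PhaseParams | Sequence[PhaseParams],
    period_s: float = 1.0,
    seed: int = 0,
    arm: ArmModel | None = None,
    alert_config: AlertConfig | None = None,
) -> list[PhaseSession]:
    """Generate one session per :class:`PhaseParams`, in order.

    Deterministic for a given seed.  The per-sample alert flag is the
    device's instantaneous threshold test under ``alert_config`` (default
    thresholds when omitted).
    """
    if isinstance(params, PhaseParams):
        params = [params]
    params = list(params)
    if not params:
        raise ValueError("params must be non-empty")
    if period_s <= 0:
        raise ValueError("period_s must be positive")
    rng = np.random.default_rng(seed)
    arm = arm or ArmModel()
    alert_config = alert_config or AlertConfig()
    return [_generate_phase(p, period_s, rng, arm, alert_config) for p in params]
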