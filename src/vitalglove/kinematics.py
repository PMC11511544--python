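"""Gyroscope angular velocity to linear speed.

During running the hand sweeps an approximately circular arc about the elbow,
so the elbow is taken as the rotation origin.  With r the position vector
from the elbow to the sensor (metres) and ω the angular velocity (rad/s),
the linear velocity is the cross product

    v = ω × r,   vx = ωy·rz − ωz·ry,  vy = ωz·rx − ωx·rz,  vz = ωx·ry − ωy·rx

and the linear speed is ‖v‖, reported in cm/s.  The cm/s unit is deliberate:
gyroscope drift produces a small nonzero speed floor even at rest, which
m/s would round to an apparent perfect zero.

The sensor reports angular velocity in degrees/s; conversion to rad/s is an
explicit, mandatory step before the cross product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ImuReading",
    "ArmModel",
    "LinearVelocity",
    "deg_to_rad",
    "linear_velocity",
    "linear_speed",
    "speed_series",
]

Triplet = tuple[float, float, float]


@dataclass(frozen=True)
class ImuReading:
    """One instant of IMU data: gyroscope (deg/s) and optional accelerometer (g)."""

    gyro_dps: Triplet
    accel_g: Triplet | None = None

    def __post_init__(self) -> None:
        if len(self.gyro_dps) != 3 or not all(math.isfinite(v) for v in self.gyro_dps):
            raise ValueError("gyro_dps must be a finite 3-vector")
        if self.accel_g is not None and (
            len(self.accel_g) != 3 or not all(math.isfinite(v) for v in self.accel_g)
        ):
            raise ValueError("accel_g must be a finite 3-vector")


@dataclass(frozen=True)
class ArmModel:
    """Position vector from the elbow rotation origin to the sensor, metres.

    The default 0.25 m along x is a forearm-length scale; radius variation
    during the stride is neglected, so r is a per-session constant.
    """

    r_m: Triplet = (0.25, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.r_m) != 3 or not all(math.isfinite(v) for v in self.r_m):
            raise ValueError("r_m must be a finite 3-vector")
        if not np.linalg.norm(self.r_m) > 0:
            raise ValueError("|r| must be positive")


@dataclass(frozen=True)
class LinearVelocity:
    """Linear velocity triplet, m/s."""

    v_m_s: Triplet

    def __post_init__(self) -> None:
        if len(self.v_m_s) != 3 or not all(math.isfinite(v) for v in self.v_m_s):
            raise ValueError("v_m_s must be a finite 3-vector")


def deg_to_rad(omega_dps: Sequence[float]) -> np.ndarray:
    """Convert an angular-velocity triplet from degrees/s to rad/s."""
    omega = np.asarray(omega_dps, dtype=float)
    if not np.all(np.isfinite(omega)):
        raise ValueError("angular velocity must be finite")
    return omega * (math.pi / 180.0)


def linear_velocity(omega_rad_s: Sequence[float], arm: ArmModel) -> LinearVelocity:
    """Cross product v = ω × r for one angular-velocity sample (rad/s)."""
    omega = np.asarray(omega_rad_s, dtype=float)
    if omega.shape != (3,) or not np.all(np.isfinite(omega)):
        raise ValueError("omega_rad_s must be a finite 3-vector")
    v = np.cross(omega, np.asarray(arm.r_m, dtype=float))
    return LinearVelocity(v_m_s=(float(v[0]), float(v[1]), float(v[2])))


def linear_speed(v: LinearVelocity) -> float:
    """Euclidean norm of the linear velocity, converted to cm/s."""
    return float(np.linalg.norm(v.v_m_s)) * 100.0


def speed_series(imu_trace: Iterable[ImuReading], arm: ArmModel) -> np.ndarray:
    """Per-sample linear speed (cm/s) for an ordered IMU trace."""
    readings = list(imu_trace)
    if not readings:
        raise ValueError("imu_trace must be non-empty")
    gyro = np.asarray([r.gyro_dps for r in readings], dtype=float)
    omega = gyro * (math.pi / 180.0)
    v = np.cross(omega, np.asarray(arm.r_m, dtype=float))
    return np.linalg.norm(v, axis=1) * 100.0
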