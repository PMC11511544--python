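"""Session data model, CSV I/O, packaged reference tables and the node-path
interchange schema.

A *session* is one contiguous recording of a single activity phase (resting,
walking or running) sampled at a uniform period.  Each sample carries heart
rate (BPM), SpO2 (%), ambient and body temperature (°C), linear speed (cm/s)
and the device's instantaneous alert flag.

Eight 30-sample reference tables from the validation recordings of the glove
prototype ship with the package: the three raw phase tables, their width-5
moving-average counterparts and the two available Gaussian-filtered tables.
The Gaussian running table is excluded: the published version duplicates the
walking table cell-for-cell and is treated as an erratum.

The cloud transport of the original device stores each reading under
slash-delimited node paths (``sensor/gyro/x``, ``sensor/BPM``, ...); the
:class:`NodeRecord` helpers reproduce that layout as a JSON-friendly mapping
so sessions can round-trip through the same schema without any network code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "VitalSample",
    "PhaseSession",
    "CHANNELS",
    "CSV_COLUMNS",
    "NODE_PATHS",
    "FIXTURES",
    "load_session",
    "write_session",
    "load_fixture",
    "fixture_info",
    "to_node_record",
    "from_node_record",
]


class Phase(str, Enum):
    """Activity phase of a recording."""

    RESTING = "resting"
    WALKING = "walking"
    RUNNING = "running"


#: Continuous measurement channels of a sample, in canonical column order.
CHANNELS = ("hr_bpm", "spo2_pct", "ambient_c", "body_c", "speed_cm_s")

#: Mandatory CSV header (``time_s`` is optional and derived when absent).
CSV_COLUMNS = ("index", *CHANNELS, "alert")


@dataclass(frozen=True)
class VitalSample:
    """One timestamped multichannel reading.

    Parameters
    ----------
    index : int
        1-based sample ordinal within the session.
    time_s : float
        Seconds from session start; strictly increasing within a session.
    hr_bpm : float
        Heart rate, beats per minute (> 0).
    spo2_pct : float
        Peripheral oxygen saturation, percent (0–100).
    ambient_c, body_c : float
        Ambient and body temperature, °C.
    speed_cm_s : float
        Linear speed derived from the wrist gyroscope, cm/s (≥ 0).
    alert : int
        Instantaneous device alert flag, 0 or 1.
    """

    index: int
    time_s: float
    hr_bpm: float
    spo2_pct: float
    ambient_c: float
    body_c: float
    speed_cm_s: float
    alert: int

    def validate(self) -> None:
        """Raise :class:`ValueError` on the first violated field invariant."""
        if not self.hr_bpm > 0:
            raise ValueError(f"hr_bpm must be > 0, got {self.hr_bpm}")
        if not 0.0 <= self.spo2_pct <= 100.0:
            raise ValueError(f"spo2_pct must be in [0, 100], got {self.spo2_pct}")
        if self.speed_cm_s < 0:
            raise ValueError(f"speed_cm_s must be >= 0, got {self.speed_cm_s}")
        if self.alert not in (0, 1):
            raise ValueError(f"alert must be 0 or 1, got {self.alert}")
        if self.time_s < 0:
            raise ValueError(f"time_s must be >= 0, got {self.time_s}")
        for name in CHANNELS:
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class PhaseSession:
    """An ordered, uniformly sampled recording of one activity phase."""

    phase: Phase
    samples: tuple[VitalSample, ...]
    sample_period_s: float = 1.0

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("session must contain at least one sample")
        if self.sample_period_s <= 0:
            raise ValueError("sample_period_s must be positive")
        times = [s.time_s for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[VitalSample]:
        return iter(self.samples)

    def channel(self, name: str) -> np.ndarray:
        """Return one channel (or ``alert``/``time_s``) as a float array."""
        if name not in CHANNELS + ("alert", "time_s", "index"):
            raise KeyError(f"unknown channel {name!r}")
        return np.asarray([getattr(s, name) for s in self.samples], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Session as a DataFrame with the canonical column layout."""
        return pd.DataFrame(
            {
                "index": [s.index for s in self.samples],
                "time_s": [s.time_s for s in self.samples],
                **{c: self.channel(c) for c in CHANNELS},
                "alert": [s.alert for s in self.samples],
            }
        )

    def with_channels(self, **arrays: Iterable[float]) -> "PhaseSession":
        """Return a copy with the given channels replaced.

        All replacement arrays must share one length ``m <= len(self)``; when
        ``m < len(self)`` the trailing samples are dropped and samples are
        re-indexed 1..m (used by edge-truncating filters).  The alert column
        is carried over unchanged unless explicitly replaced.
        """
        lengths = {len(np.atleast_1d(np.asarray(v))) for v in arrays.values()}
        if len(lengths) != 1:
            raise ValueError("replacement channels must share one length")
        (m,) = lengths
        if m > len(self):
            raise ValueError("replacement channels longer than session")
        cols = {c: self.channel(c)[:m] for c in CHANNELS}
        alert = [s.alert for s in self.samples[:m]]
        for name, values in arrays.items():
            vals = np.asarray(values, dtype=float)
            if name == "alert":
                alert = [int(v) for v in vals]
            elif name in CHANNELS:
                cols[name] = vals
            else:
                raise KeyError(f"unknown channel {name!r}")
        samples = tuple(
            VitalSample(
                index=j + 1,
                time_s=j * self.sample_period_s,
                alert=alert[j],
                **{c: float(cols[c][j]) for c in CHANNELS},
            )
            for j in range(m)
        )
        return replace(self, samples=samples)


def _session_from_frame(
    frame: pd.DataFrame, phase: Phase, sample_period_s: float, origin: str
) -> PhaseSession:
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{origin}: missing column(s) {', '.join(missing)}")
    if len(frame) == 0:
        raise ValueError(f"{origin}: no samples")
    has_time = "time_s" in frame.columns
    samples = []
    for pos, row in enumerate(frame.itertuples(index=False), start=1):
        rec = row._asdict()
        try:
            values = {c: float(rec[c]) for c in CHANNELS}
            alert = float(rec["alert"])
            index = float(rec["index"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{origin}: row {pos}: non-numeric cell ({exc})") from None
        if any(not math.isfinite(v) for v in values.values()) or not math.isfinite(alert):
            raise ValueError(f"{origin}: row {pos}: non-numeric cell")
        if alert != int(alert):
            raise ValueError(f"{origin}: row {pos}: alert must be 0 or 1, got {alert}")
        time_s = float(rec["time_s"]) if has_time else (pos - 1) * sample_period_s
        sample = VitalSample(
            index=int(index), time_s=time_s, alert=int(alert), **values
        )
        try:
            sample.validate()
        except ValueError as exc:
            raise ValueError(f"{origin}: row {pos}: {exc}") from None
        samples.append(sample)
    if has_time:
        times = [s.time_s for s in samples]
        for pos in range(1, len(times)):
            if times[pos] <= times[pos - 1]:
                raise ValueError(f"{origin}: row {pos + 1}: non-monotonic time")
    return PhaseSession(phase=phase, samples=tuple(samples), sample_period_s=sample_period_s)


def load_session(
    path: str | Path, phase: Phase | str, sample_period_s: float = 1.0
) -> PhaseSession:
    """Read a session CSV.

    The file must carry a header naming at least the columns in
    :data:`CSV_COLUMNS`; a ``time_s`` column is honoured when present and
    otherwise derived from ``sample_period_s``.  Rows violating the
    :class:`VitalSample` invariants are rejected with a row-numbered error
    (row numbers count data rows, 1-based).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no samples") from None
    return _session_from_frame(frame, Phase(phase), sample_period_s, origin=str(path))


def write_session(session: PhaseSession, path: str | Path) -> None:
    """Write a session to CSV in the canonical column layout."""
    session.to_frame().to_csv(path, index=False)


# fixture id -> (packaged file, phase, filter provenance)
FIXTURES: dict[str, tuple[str, Phase, str]] = {
    "raw_resting": ("raw_resting.csv", Phase.RESTING, "raw"),
    "raw_walking": ("raw_walking.csv", Phase.WALKING, "raw"),
    "raw_running": ("raw_running.csv", Phase.RUNNING, "raw"),
    "ma_resting": ("ma_resting.csv", Phase.RESTING, "moving_average"),
    "ma_walking": ("ma_walking.csv", Phase.WALKING, "moving_average"),
    "ma_running": ("ma_running.csv", Phase.RUNNING, "moving_average"),
    "gauss_resting": ("gauss_resting.csv", Phase.RESTING, "gaussian"),
    "gauss_walking": ("gauss_walking.csv", Phase.WALKING, "gaussian"),
}


def fixture_info() -> list[dict[str, str]]:
    """Describe the packaged reference tables (id, phase, filter)."""
    return [
        {"name": name, "phase": phase.value, "filter": provenance}
        for name, (_, phase, provenance) in FIXTURES.items()
    ]


def load_fixture(name: str, sample_period_s: float = 1.0) -> PhaseSession:
    """Load one packaged 30-sample reference table verbatim.

    ``gauss_running`` is deliberately absent: the published running table of
    the Gaussian variant duplicates the walking table and is excluded as an
    erratum.
    """
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(FIXTURES))}"
        )
    filename, phase, _ = FIXTURES[name]
    ref = resources.files("vitalglove") / "fixtures" / filename
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path)
    return _session_from_frame(frame, phase, sample_period_s, origin=name)


#: Node paths of the cloud record layout, every one mandatory.
NODE_PATHS = (
    "sensor/acc/x",
    "sensor/acc/y",
    "sensor/acc/z",
    "sensor/gyro/x",
    "sensor/gyro/y",
    "sensor/gyro/z",
    "sensor/temp",
    "sensor/BPM",
    "sensor/alert",
    "timestamp",
)

# Extension paths carrying the remaining channels so that a sample
# round-trips losslessly through the record layout.
_EXTRA_PATHS = ("sensor/SpO2", "sensor/ambientTemp", "sensor/speed")


def to_node_record(sample: VitalSample, imu: "ImuReading | None" = None) -> dict[str, float]:
    """Serialize one sample (plus its IMU reading) to the node-path mapping.

    ``sensor/temp`` carries the body (skin-contact) temperature; the ambient
    reading, SpO2 and speed travel on extension paths so the mapping inverts
    exactly via :func:`from_node_record`.
    """
    gyro = tuple(imu.gyro_dps) if imu is not None else (0.0, 0.0, 0.0)
    acc = (
        tuple(imu.accel_g)
        if imu is not None and imu.accel_g is not None
        else (0.0, 0.0, 0.0)
    )
    record = {
        "sensor/acc/x": float(acc[0]),
        "sensor/acc/y": float(acc[1]),
        "sensor/acc/z": float(acc[2]),
        "sensor/gyro/x": float(gyro[0]),
        "sensor/gyro/y": float(gyro[1]),
        "sensor/gyro/z": float(gyro[2]),
        "sensor/temp": float(sample.body_c),
        "sensor/BPM": float(sample.hr_bpm),
        "sensor/alert": int(sample.alert),
        "timestamp": float(sample.time_s),
        "sensor/SpO2": float(sample.spo2_pct),
        "sensor/ambientTemp": float(sample.ambient_c),
        "sensor/speed": float(sample.speed_cm_s),
    }
    return record


def from_node_record(
    record: Mapping[str, float], index: int
) -> tuple[VitalSample, "ImuReading"]:
    """Invert :func:`to_node_record`; ``index`` restores the sample ordinal."""
    from .kinematics import ImuReading  # local import to avoid a cycle

    missing = [p for p in NODE_PATHS + _EXTRA_PATHS if p not in record]
    if missing:
        raise ValueError(f"node record missing path(s): {', '.join(missing)}")
    alert = record["sensor/alert"]
    if alert not in (0, 1):
        raise ValueError(f"sensor/alert must be 0 or 1, got {alert}")
    sample = VitalSample(
        index=index,
        time_s=float(record["timestamp"]),
        hr_bpm=float(record["sensor/BPM"]),
        spo2_pct=float(record["sensor/SpO2"]),
        ambient_c=float(record["sensor/ambientTemp"]),
        body_c=float(record["sensor/temp"]),
        speed_cm_s=float(record["sensor/speed"]),
        alert=int(alert),
    )
    sample.validate()
    imu = ImuReading(
        gyro_dps=(
            float(record["sensor/gyro/x"]),
            float(record["sensor/gyro/y"]),
            float(record["sensor/gyro/z"]),
        ),
        accel_g=(
            float(record["sensor/acc/x"]),
            float(record["sensor/acc/y"]),
            float(record["sensor/acc/z"]),
        ),
    )
    return sample, imu
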