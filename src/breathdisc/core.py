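"""Shared containers for eNose breath recordings and breathprint features.

A measurement consists of 7 metal-oxide sensor channels sampling exhaled
air and 7 identical sensors sampling ambient air in parallel.  From each
exhaled channel two quantities are read off after processing: the signal
peak during the slow expiration and the value at the end of the 5-s
breath hold.  The per-measurement feature vector ("breathprint") holds
the peaks normalised to the reference sensor (sensor 2) plus the
peak / breath-hold ratio of every sensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

N_SENSORS = 7
#: 1-based index of the most stable sensor, used as normalisation reference.
REFERENCE_SENSOR = 2

#: 13 informative features: 6 peak ratios (reference sensor's own ratio is
#: identically 1 and dropped) + 7 peak/breath-hold ratios.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"peak_ratio_s{s}" for s in range(1, N_SENSORS + 1) if s != REFERENCE_SENSOR
) + tuple(f"peak_bh_ratio_s{s}" for s in range(1, N_SENSORS + 1))


class Phase(IntEnum):
    """Phase of the breath maneuver a sample belongs to."""

    TIDAL = 0
    INSPIRATION = 1
    HOLD = 2
    EXPIRATION = 3


@dataclass
class SensorRecording:
    """Raw paired exhaled/ambient sensor traces for one breath maneuver.

    ``exhaled`` and ``ambient`` are ``(7, T)`` arrays on a common,
    strictly increasing time grid; ``phase`` (optional) labels each
    sample with the maneuver phase.
    """

    subject_id: str
    replicate: int
    time_s: np.ndarray
    exhaled: np.ndarray
    ambient: np.ndarray
    sample_rate_hz: float
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.exhaled = np.atleast_2d(np.asarray(self.exhaled, dtype=float))
        self.ambient = np.atleast_2d(np.asarray(self.ambient, dtype=float))
        t = self.time_s
        if t.ndim != 1 or t.size < 2:
            raise ValueError("time_s must be a 1-D grid with >= 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_s must be strictly increasing")
        for name, arr in (("exhaled", self.exhaled), ("ambient", self.ambient)):
            if arr.shape != (N_SENSORS, t.size):
                raise ValueError(
                    f"{name} must have shape ({N_SENSORS}, {t.size}), got {arr.shape}"
                )
        if self.phase is not None:
            self.phase = np.asarray(self.phase)
            if self.phase.shape != t.shape:
                raise ValueError("phase labels must align with the time grid")

    @property
    def n_samples(self) -> int:
        return self.time_s.size


@dataclass
class BreathFeatures:
    """Breathprint feature vector for one measurement (or merged pair).

    ``values`` follows :data:`FEATURE_NAMES`.  ``qc_ok`` is False when
    the recording failed landmark detection; ``qc_flags`` carries
    advisory flags (e.g. replicate discordance) that do not by
    themselves invalidate the measurement.
    """

    subject_id: str
    values: np.ndarray
    replicate: int | None = None
    qc_ok: bool = True
    qc_flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ValueError(
                f"expected {len(FEATURE_NAMES)} features, got {self.values.shape}"
            )
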