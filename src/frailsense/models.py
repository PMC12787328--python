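"""Core domain types.

The package models a home-monitoring frailty study: each participant has
anthropometrics that parameterize every cutoff, a ground-truth frailty
profile (the five binary Fried criteria), and a collection of sensor
streams (UWB position trajectories, grip trials, questionnaire answers)
from which the criteria are re-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, SchemaError

SEXES = ("male", "female")

#: Fried criterion names, in the order criteria are always reported.
CRITERIA = ("weight_loss", "exhaustion", "low_activity", "weakness", "slowness")

#: 15 feet in metres (1 ft = 0.3048 m): the walk distance used for slowness.
FIFTEEN_FEET_M = 4.572


@dataclass(frozen=True)
class FrailtyProfile:
    """Ground-truth state of the five Fried criteria (1 = criterion met)."""

    weight_loss: int = 0
    exhaustion: int = 0
    low_activity: int = 0
    weakness: int = 0
    slowness: int = 0

    def __post_init__(self) -> None:
        for name in CRITERIA:
            v = getattr(self, name)
            if v not in (0, 1):
                raise InvalidConfigError(f"profile field {name}={v!r} not in {{0,1}}")

    @property
    def total(self) -> int:
        return sum(getattr(self, name) for name in CRITERIA)

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in CRITERIA}


@dataclass(frozen=True)
class Participant:
    """Demographics and anthropometrics.

    BMI is derived (kg/m^2) and drives the sex-specific grip cutoff band;
    height drives the slowness threshold stratum; weight enters the
    CHAMPS energy-expenditure formula.
    """

    id: str
    sex: str
    age: float
    height_cm: float
    weight_kg: float
    inpatient: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise InvalidConfigError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise InvalidConfigError("height and weight must be positive")
        if self.age < 18:
            raise InvalidConfigError("participants are adults (age >= 18)")

    @property
    def bmi(self) -> float:
        return self.weight_kg / (self.height_cm / 100.0) ** 2


@dataclass
class Trajectory:
    """Ordered UWB position samples (metres) with Unix timestamps (s).

    Timestamps must be strictly increasing; coordinates finite. Arrays
    are stored column-wise for vectorized kinematics.
    """

    participant_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise SchemaError("t, x, y, z must have equal length")
        for arr, name in ((self.t, "t"), (self.x, "x"), (self.y, "y"), (self.z, "z")):
            if not np.all(np.isfinite(arr)):
                raise SchemaError(f"non-finite values in {name}")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            bad = int(np.argmin(np.diff(self.t) > 0)) + 1
            raise SchemaError(
                f"timestamps not strictly increasing at sample {bad} "
                f"(participant {self.participant_id})"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def xyz(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "t_unix_s": self.t,
                "x_m": self.x,
                "y_m": self.y,
                "z_m": self.z,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, participant_id: str, label: str = "") -> "Trajectory":
        sub = df[df["participant_id"] == participant_id]
        return cls(
            participant_id=participant_id,
            t=sub["t_unix_s"].to_numpy(),
            x=sub["x_m"].to_numpy(),
            y=sub["y_m"].to_numpy(),
            z=sub["z_m"].to_numpy(),
            label=label,
        )


@dataclass(frozen=True)
class Zone:
    """Axis-aligned rectangular floor zone, metres."""

    name: str
    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise InvalidConfigError(f"zone {self.name!r} has non-positive extent")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.x_min) & (x <= self.x_max) & (y >= self.y_min) & (y <= self.y_max)
        )

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))


@dataclass
class ZoneMap:
    """Named rectangular zones of the monitored floor plan."""

    zones: dict[str, Zone] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(name != z.name for name, z in self.zones.items()):
            raise InvalidConfigError("zone dict keys must match zone names")

    def __len__(self) -> int:
        return len(self.zones)

    def __iter__(self) -> Iterator[Zone]:
        return iter(self.zones.values())

    def __getitem__(self, name: str) -> Zone:
        return self.zones[name]

    @classmethod
    def from_dict(cls, spec: Mapping[str, Mapping[str, float]]) -> "ZoneMap":
        zones = {
            name: Zone(name=name, **{k: float(v) for k, v in rect.items()})
            for name, rect in spec.items()
        }
        return cls(zones=zones)

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {
            z.name: {"x_min": z.x_min, "x_max": z.x_max, "y_min": z.y_min, "y_max": z.y_max}
            for z in self
        }


@dataclass(frozen=True)
class GripTrial:
    """Peak force of one dynamometer squeeze."""

    participant_id: str
    hand: str  # "dominant" | "nondominant"
    trial: int
    peak_kg: float
    source: str = "standard"  # "standard" | "sensor"

    def __post_init__(self) -> None:
        if self.hand not in ("dominant", "nondominant"):
            raise InvalidConfigError(f"unknown hand {self.hand!r}")
        if self.peak_kg <= 0:
            raise InvalidConfigError("peak grip force must be positive")


@dataclass(frozen=True)
class CriterionFlags:
    """The five Fried criterion flags from one measurement route.

    Each flag is 0, 1 or None (missing, e.g. a failed grip measurement).
    ``source`` records whether the flags came from standard instruments
    or from the sensor pipeline; scoring treats both identically.
    """

    weight_loss: Optional[int] = None
    exhaustion: Optional[int] = None
    low_activity: Optional[int] = None
    weakness: Optional[int] = None
    slowness: Optional[int] = None
    source: str = "standard"

    def __post_init__(self) -> None:
        for name in CRITERIA:
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise InvalidConfigError(f"flag {name}={v!r} not in {{0,1,None}}")

    def as_dict(self) -> dict[str, Optional[int]]:
        return {name: getattr(self, name) for name in CRITERIA}

    @property
    def complete(self) -> bool:
        return all(getattr(self, name) is not None for name in CRITERIA)

    @property
    def partial_total(self) -> int:
        return sum(getattr(self, name) or 0 for name in CRITERIA)


@dataclass(frozen=True)
class FrailtyResult:
    """Total Fried score with its three-level category and dichotomy.

    ``category`` is None when any criterion is missing (incomplete
    result); ``total`` then holds the partial sum of observed flags.
    """

    total: int
    category: Optional[str]  # robust | pre_frail | frail | very_frail
    dichotomous: Optional[str]  # not_frail | frail
    complete: bool = True
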