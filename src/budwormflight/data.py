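"""Core data model and reduction of raw flight-mill measurements.

Each female spruce budworm moth is characterised by her morphology
(initial fresh mass ``Wb`` in mg, forewing length ``La`` in mm, single
forewing area ``Sf`` and total four-wing area ``Stot`` in mm^2, thorax
dry mass in mg) and the derived biomechanical ratios: wing load
``omega_tot = Wb / Stot`` (mg/mm^2), wing aspect ratio
``alpha_tot = (2 La)^2 / Stot``, and flight muscle ratio
``tau_t = thorax_dry / Wb``.

Flight outcomes come from a rotary flight mill recording rotations per
second over a 19-h test, and from high-speed video (960 frames/s) for
wingbeat frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STOT_FROM_SF_SLOPE",
    "STOT_FROM_SF_INTERCEPT",
    "FemaleTraits",
    "Environment",
    "FlightOutcome",
    "CostOutcome",
    "MillLog",
    "wingbeat_from_frames",
    "process_mill_log",
    "derive_traits",
    "read_females",
    "write_females",
    "read_mill_log",
]

# Linear relation between total four-wing area and single-forewing area,
# used to impute Stot when only Sf was measured: Stot = 3.763 Sf + 2.647.
STOT_FROM_SF_SLOPE = 3.763
STOT_FROM_SF_INTERCEPT = 2.647

VIDEO_FPS = 960
_BEATS_COUNTED = 10


@dataclass
class FemaleTraits:
    id: str
    Wb: float  # initial fresh mass, mg
    La: float  # forewing length, mm
    Sf: float | None  # single-forewing area, mm^2
    Stot: float  # total four-wing area, mm^2
    alpha_tot: float  # wing aspect ratio
    omega_tot: float  # wing load, mg/mm^2
    tau_t: float  # flight muscle ratio
    thorax_dry: float  # thorax dry mass, mg
    stot_imputed: bool = False


@dataclass
class Environment:
    T: float  # air temperature, degC
    Ap: float  # barometric pressure, kPa


@dataclass
class FlightOutcome:
    flew: bool
    onset_min: float | None = None
    wingbeat_hz: float | None = None
    speed_ms: float | None = None
    duration_h: float | None = None
    distance_km: float | None = None


@dataclass
class CostOutcome:
    Wa: float  # final fresh mass, mg
    Wd: float  # final dry mass, mg
    Pd: float | None = None  # final dry-mass proportion
    Pi: float | None = None  # initial dry-mass proportion
    Wloss: float | None = None
    Wwater: float | None = None
    Wfuel: float | None = None
    Wlipids: float | None = None


@dataclass
class MillLog:
    """Per-second rotation counts from one flight-mill channel."""

    samples: Sequence[tuple[float, int]]  # (elapsed second, rotation count)
    rotation_distance_m: float
    test_start: str = "15:00"

    def __post_init__(self):
        if self.rotation_distance_m is None or self.rotation_distance_m <= 0:
            raise ValueError(
                "rotation_distance_m must be configured (mill arm circumference, m); "
                "no default is applied"
            )
        t = np.array([s[0] for s in self.samples], dtype=float)
        c = np.array([s[1] for s in self.samples], dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("mill-log samples must be strictly increasing in time")
        if np.any(c < 0) or np.any(c != np.round(c)):
            raise ValueError("rotation counts must be non-negative integers")


def wingbeat_from_frames(frames_per_10_beats: float) -> float:
    """Wingbeat frequency (Hz) from the frame count spanning ten beats.

    With video at 960 FPS, frequency = 10 * 960 / frames.
    """
    if frames_per_10_beats is None or frames_per_10_beats < 1:
        raise ValueError("frame count must be a positive number >= 1")
    return _BEATS_COUNTED * VIDEO_FPS / frames_per_10_beats


def process_mill_log(log: MillLog, duration_rule: str = "active_seconds") -> FlightOutcome:
    """Reduce a rotation log to flight outcome variables.

    A female "flew" only if she made more than one complete rotation over
    the whole test.  Onset is the elapsed time (minutes) to the first
    second containing a rotation.  Distance is total rotations times the
    configured metres per rotation.  Duration is, by default, the
    cumulative number of seconds containing at least one rotation
    (``duration_rule="active_seconds"``); ``"span"`` instead uses the
    first-to-last-rotation interval.  Speed is distance / duration.
    """
    if duration_rule not in ("active_seconds", "span"):
        raise ValueError(f"unknown duration_rule {duration_rule!r}")
    t = np.array([s[0] for s in log.samples], dtype=float)
    c = np.array([s[1] for s in log.samples], dtype=float)
    total = float(c.sum()) if c.size else 0.0
    if total <= 1:
        return FlightOutcome(flew=False)
    active = c > 0
    onset_min = float(t[active][0]) / 60.0
    distance_m = total * log.rotation_distance_m
    if duration_rule == "active_seconds":
        duration_s = float(np.count_nonzero(active))
    else:
        duration_s = float(t[active][-1] - t[active][0] + 1.0)
    return FlightOutcome(
        flew=True,
        onset_min=onset_min,
        speed_ms=distance_m / duration_s,
        duration_h=duration_s / 3600.0,
        distance_km=distance_m / 1000.0,
    )


def derive_traits(
    id: str,
    Wb: float,
    La: float,
    thorax_dry: float,
    Sf: float | None = None,
    Stot: float | None = None,
) -> FemaleTraits:
    """Fill the derived biomechanical ratios from raw measurements.

    If ``Stot`` is missing it is imputed from the single-forewing area via
    the linear relation ``Stot = 3.763 Sf + 2.647`` and flagged.
    """
    for name, v in (("Wb", Wb), ("La", La), ("thorax_dry", thorax_dry)):
        if v is None or not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    imputed = False
    if Stot is None or (isinstance(Stot, float) and np.isnan(Stot)):
        if Sf is None or (isinstance(Sf, float) and np.isnan(Sf)):
            raise ValueError("need Stot or Sf to derive wing quantities")
        Stot = STOT_FROM_SF_SLOPE * Sf + STOT_FROM_SF_INTERCEPT
        imputed = True
    if Stot <= 0:
        raise ValueError("Stot must be positive")
    return FemaleTraits(
        id=id,
        Wb=Wb,
        La=La,
        Sf=Sf,
        Stot=Stot,
        alpha_tot=(2.0 * La) ** 2 / Stot,
        omega_tot=Wb / Stot,
        tau_t=thorax_dry / Wb,
        thorax_dry=thorax_dry,
        stot_imputed=imputed,
    )


# ---------------------------------------------------------------------------
# CSV I/O.  One row per female; columns named exactly as the dataclass
# fields; missing values are empty cells.

def read_females(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError("female table requires an 'id' column")
    return df


def write_females(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_mill_log(path, rotation_distance_m: float, test_start: str = "15:00") -> MillLog:
    """Read a two-column CSV (elapsed_s, rotations) into a MillLog."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[:2] != ["elapsed_s", "rotations"]:
        raise ValueError("mill log CSV must have columns elapsed_s, rotations")
    samples = list(zip(df["elapsed_s"].astype(float), df["rotations"].astype(int)))
    return MillLog(samples=samples, rotation_distance_m=rotation_distance_m, test_start=test_start)
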