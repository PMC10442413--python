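"""Experiment-design quantities for single-file crowd experiments.

Study 1 imposes walking speeds (1.41, 0.86, 0.31, 0.19 m/s, plus the freely
chosen speed and a standing baseline) by metronome-paced floor markers.
Study 2 sets density on a closed oval of circumference 14.97 m by the
number of occupants; the space available per person, gross and net of an
average human body depth of 28.8 cm, is what the proxemics of the situation
act on.  Net space maps onto Hall's interpersonal-distance zones (intimate,
personal, social, public; each with a near and far sub-zone).

Rounding convention: the published per-person space values are reproduced
only when the gross space is rounded to 2 decimals *before* the body depth
is subtracted and the result is rounded again (round–subtract–round).  For
example 24 occupants: 14.97/24 = 0.62375 -> 0.62; 0.62 − 0.288 = 0.332 ->
0.33, whereas subtracting first would give 0.34.  All arithmetic uses
decimal half-even rounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import pandas as pd

__all__ = [
    "HALL_ZONES",
    "OVAL_CIRCUMFERENCE_M",
    "BODY_DEPTH_M",
    "STUDY2_OCCUPANCIES",
    "OvalCondition",
    "SpeedCondition",
    "gross_space",
    "net_space",
    "hall_zone",
    "marker_spacing",
    "oval_condition",
    "design_table",
]

OVAL_CIRCUMFERENCE_M = 14.97
BODY_DEPTH_M = 0.288
STUDY2_OCCUPANCIES = (4, 8, 16, 20, 24, 32, 36, 40)

#: Hall interpersonal-distance zones: name -> half-open [lower, upper) in m.
HALL_ZONES: tuple[tuple[str, float, float], ...] = (
    ("intimate_near", 0.0, 0.15),
    ("intimate_far", 0.15, 0.45),
    ("personal_near", 0.45, 0.75),
    ("personal_far", 0.75, 1.2),
    ("social_near", 1.2, 2.1),
    ("social_far", 2.1, 3.6),
    ("public", 3.6, float("inf")),
)


def _round2(value: Decimal) -> float:
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def gross_space(circumference: float, n: int) -> float:
    """Space per person on the oval, m, rounded half-even to 2 decimals."""
    if n < 1:
        raise ValueError("occupant count must be >= 1")
    if circumference <= 0:
        raise ValueError("circumference must be positive")
    return _round2(Decimal(str(circumference)) / Decimal(n))


def net_space(gross: float, body_depth: float = BODY_DEPTH_M) -> float:
    """Gross space minus body depth, m (input is the already-rounded gross).

    Negative results are clipped to 0 with a warning.
    """
    if gross < 0:
        raise ValueError("gross space must be non-negative")
    value = _round2(Decimal(str(gross)) - Decimal(str(body_depth)))
    if value < 0:
        warnings.warn(
            f"net space {value:.2f} m clipped to 0 (body depth exceeds gross "
            "space)", stacklevel=2,
        )
        value = 0.0
    return value


def hall_zone(net: float) -> str:
    """Classify a net interpersonal distance into a Hall proxemic zone."""
    if net < 0:
        raise ValueError("net space must be non-negative")
    for name, lo, hi in HALL_ZONES:
        if lo <= net < hi:
            return name
    return HALL_ZONES[-1][0]


def marker_spacing(speed: float, metronome: float) -> float:
    """Distance between floor markers covered in two metronome beats, m."""
    if metronome <= 0:
        raise ValueError("metronome rate must be positive")
    return speed * 2.0 * 60.0 / metronome


@dataclass(frozen=True)
class OvalCondition:
    """One occupancy condition of the oval experiment."""

    n_persons: int
    circumference: float = OVAL_CIRCUMFERENCE_M
    body_depth: float = BODY_DEPTH_M

    @property
    def gross_space(self) -> float:
        return gross_space(self.circumference, self.n_persons)

    @property
    def net_space(self) -> float:
        return net_space(self.gross_space, self.body_depth)

    @property
    def hall_zone(self) -> str:
        return hall_zone(self.net_space)


@dataclass(frozen=True)
class SpeedCondition:
    """One imposed-speed condition of the walking-course experiment."""

    label: str
    speed: float          # m/s
    duration: float = 180.0
    headway: float = 1.5  # m between successive walkers

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be non-negative")


def oval_condition(n: int, circumference: float = OVAL_CIRCUMFERENCE_M,
                   body_depth: float = BODY_DEPTH_M) -> OvalCondition:
    return OvalCondition(n_persons=n, circumference=circumference,
                         body_depth=body_depth)


def design_table(occupancies: tuple[int, ...] = STUDY2_OCCUPANCIES,
                 circumference: float = OVAL_CIRCUMFERENCE_M,
                 body_depth: float = BODY_DEPTH_M) -> pd.DataFrame:
    """Per-person space and Hall zone for each occupancy condition."""
    rows = []
    for n in occupancies:
        c = oval_condition(n, circumference, body_depth)
        rows.append({
            "n_persons": n,
            "gross_space_m": c.gross_space,
            "net_space_m": c.net_space,
            "hall_zone": c.hall_zone,
        })
    return pd.DataFrame(rows)
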