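"""Stimulus set: the 2 (size) x 2 (mass) cylinder objects plus the washout reference.

All objects are cylinders of identical height lifted with a motion tracker
screwed to the base, so the *lifted* mass is the cylinder mass plus the
tracker mass.  Perceived-size cues are carried by the cylinder geometry only
(the tracker is visually matched across conditions), so object volume is the
cylinder volume without the tracker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

TRACKER_MASS_G = 75.0

#: canonical object labels, in (size, mass) factorial order
TEST_OBJECT_LABELS = ("small_light", "small_heavy", "large_light", "large_heavy")
WASHOUT_LABEL = "medium_washout"


@dataclass(frozen=True)
class ObjectSpec:
    """Geometry and mass of one stimulus cylinder.

    Attributes
    ----------
    label : str
        One of ``small_light``, ``small_heavy``, ``large_light``,
        ``large_heavy`` or ``medium_washout``.
    diameter_cm, height_cm : float
        Cylinder dimensions.
    base_mass_g : float
        Mass of the cylinder itself.
    tracker_mass_g : float
        Mass of the attached position tracker (75 g).
    """

    label: str
    diameter_cm: float
    height_cm: float
    base_mass_g: float
    tracker_mass_g: float = TRACKER_MASS_G

    def __post_init__(self) -> None:
        if self.diameter_cm <= 0 or self.height_cm <= 0:
            raise ValueError("cylinder dimensions must be positive")
        if self.base_mass_g <= 0 or self.tracker_mass_g < 0:
            raise ValueError("masses must be positive")

    @property
    def total_mass_g(self) -> float:
        """Lifted mass: cylinder plus tracker."""
        return self.base_mass_g + self.tracker_mass_g

    @property
    def volume_cm3(self) -> float:
        """Cylinder volume pi*r^2*h (tracker excluded; it is not a size cue)."""
        return math.pi * (self.diameter_cm / 2.0) ** 2 * self.height_cm

    @property
    def is_test(self) -> bool:
        return self.label != WASHOUT_LABEL


def make_object_set() -> list[ObjectSpec]:
    """Build the five stimulus objects.

    Four test cylinders form a full 2x2 cross of diameter {5, 10} cm and
    base mass {355, 490} g, all 7.5 cm tall; the washout reference is an
    intermediate 7.5 cm diameter, 490 g cylinder.
    """
    h = 7.5
    return [
        ObjectSpec("small_light", diameter_cm=5.0, height_cm=h, base_mass_g=355.0),
        ObjectSpec("small_heavy", diameter_cm=5.0, height_cm=h, base_mass_g=490.0),
        ObjectSpec("large_light", diameter_cm=10.0, height_cm=h, base_mass_g=355.0),
        ObjectSpec("large_heavy", diameter_cm=10.0, height_cm=h, base_mass_g=490.0),
        ObjectSpec(WASHOUT_LABEL, diameter_cm=7.5, height_cm=h, base_mass_g=490.0),
    ]


def object_map() -> dict[str, ObjectSpec]:
    """Label -> ObjectSpec for the standard stimulus set."""
    return {o.label: o for o in make_object_set()}


def size_of(label: str) -> str:
    """Size factor level (``small``/``large``/``medium``) of an object label."""
    return label.split("_")[0]


def weight_of(label: str) -> str:
    """Mass factor level (``light``/``heavy``/``washout``) of an object label."""
    return label.split("_")[1] if "_" in label else label
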