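"""Planar muscle-geometry relations.

In the planar right-triangle model of a pennate muscle belly,
``thickness = fascicle_length * sin(pennation)``.  These helpers convert
between the three quantities; curvature and aponeurosis angle are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MuscleGeometry:
    """One consistent (thickness, fascicle length, pennation) triple."""

    thickness_mm: float
    fascicle_length_mm: float
    pennation_deg: float

    def __post_init__(self) -> None:
        if not 0 < self.thickness_mm <= self.fascicle_length_mm:
            raise ValueError("need 0 < thickness <= fascicle length")
        if not 0 < self.pennation_deg <= 90:
            raise ValueError("pennation must be in (0, 90] degrees")


def pennation_from_thickness(thickness_mm: float, fascicle_length_mm: float) -> float:
    """Pennation angle (degrees) implied by belly thickness and fascicle length.

    ``arcsin(thickness / fascicle_length)``.

    Raises
    ------
    ValueError
        ``thickness <= 0`` or ``thickness > fascicle_length``.
    """
    if thickness_mm <= 0:
        raise ValueError(f"thickness must be positive, got {thickness_mm}")
    if thickness_mm > fascicle_length_mm:
        raise ValueError(
            f"thickness {thickness_mm} mm exceeds fascicle length {fascicle_length_mm} mm"
        )
    return float(np.degrees(np.arcsin(thickness_mm / fascicle_length_mm)))


def fascicle_from_thickness(thickness_mm: float, pennation_deg: float) -> float:
    """Fascicle length (mm) accommodating a belly thickness at fixed pennation.

    ``thickness / sin(pennation)``.

    Raises
    ------
    ValueError
        Pennation outside (0, 90] degrees or non-positive thickness.
    """
    if thickness_mm <= 0:
        raise ValueError(f"thickness must be positive, got {thickness_mm}")
    if not 0 < pennation_deg <= 90:
        raise ValueError(f"pennation must be in (0, 90] degrees, got {pennation_deg}")
    return float(thickness_mm / np.sin(np.radians(pennation_deg)))


def geometry_from_thickness(thickness_mm: float, fascicle_length_mm: float) -> MuscleGeometry:
    """Complete triple from thickness and fascicle length."""
    return MuscleGeometry(
        thickness_mm=thickness_mm,
        fascicle_length_mm=fascicle_length_mm,
        pennation_deg=pennation_from_thickness(thickness_mm, fascicle_length_mm),
    )


def thickness_change_example(
    thickness_mm: float = 15.0,
    fascicle_length_mm: float = 44.0,
    change_fraction: float = 0.15,
) -> dict[str, float]:
    """Effect of a fractional thickness change on pennation and fascicle length.

    Returns the initial pennation, the pennation after the thickness change
    at fixed fascicle length, and the fascicle length after the change at
    fixed pennation.
    """
    p0 = pennation_from_thickness(thickness_mm, fascicle_length_mm)
    t1 = thickness_mm * (1.0 + change_fraction)
    p1 = pennation_from_thickness(t1, fascicle_length_mm)
    l1 = fascicle_from_thickness(t1, p0)
    return {
        "thickness_mm": thickness_mm,
        "thickness_changed_mm": t1,
        "fascicle_length_mm": fascicle_length_mm,
        "pennation_deg": p0,
        "pennation_changed_deg": p1,
        "fascicle_length_changed_mm": l1,
    }
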