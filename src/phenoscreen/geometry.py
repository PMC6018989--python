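"""Spherocylinder geometry for rod-shaped cells.

A cell of length ``l`` and width ``w`` (both in µm, ``l >= w``) is modelled
as a cylinder of length ``l - w`` capped by two hemispheres of diameter
``w``.  The 2D quantities (projected area, perimeter) describe the outline
seen in a phase-contrast image; the 3D quantities (volume, surface area)
are derived from the same model.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "spherocylinder_volume",
    "spherocylinder_surface_area",
    "projected_area",
    "projected_perimeter",
    "circularity",
]


def spherocylinder_volume(length, width):
    """V = pi w^2 (l - w) / 4 + pi w^3 / 6; equals a sphere for l == w."""
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    return np.pi * width**2 * (length - width) / 4.0 + np.pi * width**3 / 6.0


def spherocylinder_surface_area(length, width):
    """SA = pi w (l - w) + pi w^2; equals a sphere's surface for l == w."""
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    return np.pi * width * (length - width) + np.pi * width**2


def projected_area(length, width):
    """Outline area: central rectangle plus two half-disk caps."""
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    return width * (length - width) + np.pi * width**2 / 4.0


def projected_perimeter(length, width):
    """Outline perimeter: two straight flanks plus the two cap arcs."""
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    return 2.0 * (length - width) + np.pi * width


def circularity(area, perimeter):
    """Shape factor 4*pi*A/P^2, equal to 1 for a circle and < 1 otherwise."""
    area = np.asarray(area, dtype=float)
    perimeter = np.asarray(perimeter, dtype=float)
    return 4.0 * np.pi * area / perimeter**2
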