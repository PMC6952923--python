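"""Torus geometry: charged-site coordinates of a sequence laid on a circle.

The sequence is treated as a closed loop (a torus, topologically): the ``n``
base anchors sit equally spaced on a circle whose circumference is
``n x 12.9`` angstrom, so adjacent anchors are 12.9 angstrom apart along the arc.  Each
base is a straight 8.6-angstrom segment carrying its three hydrogen-bonding
sites 2.385 angstrom apart, centred on the segment (offsets 1.915, 4.300, 6.685
angstrom from the anchor).  The segment direction distinguishes the three
structures:

* **Structure A** - bases lie in the torus plane, pointing radially outward
  (most exposed to hydrogen bonding; every z coordinate is exactly 0);
* **Structure B** - bases stand perpendicular to the plane (+z; the
  sterically most stable arrangement);
* **Structure C** - bases tilt 45 degrees between the two.

The rotational gauge is fixed by anchoring base 1 at angle 0 on the +x axis
with the origin at the circle centre; electric-field norms are gauge
invariant, individual x/y components are not.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .charges import ternary_vector

__all__ = [
    "BASE_SPACING",
    "BASE_LENGTH",
    "SITE_SPACING",
    "SITE_OFFSETS",
    "STRUCTURE_TILT_DEGREES",
    "TorusStructure",
    "Lattice",
    "build_structure",
    "build_lattice",
    "write_structure_table",
]

#: Arc length between adjacent base anchors (angstrom).
BASE_SPACING = 12.9
#: Length of the nucleobase segment (angstrom).
BASE_LENGTH = 8.6
#: Distance between adjacent hydrogen-bonding sites on one base (angstrom).
SITE_SPACING = 2.385
#: Site offsets along the base segment, centred on the 8.6 angstrom length:
#: midpoint 4.3 = 8.6/2, spacing 2.385.  First site innermost by default.
SITE_OFFSETS = (1.915, 4.300, 6.685)
#: Tilt of the base segment out of the torus plane, per structure label.
STRUCTURE_TILT_DEGREES = {"A": 0.0, "B": 90.0, "C": 45.0}


@dataclass(frozen=True)
class TorusStructure:
    """3n charged sites with 3-D coordinates for one sequence and structure.

    Arrays are site-major like :class:`~mirtorus.charges.TernaryVector`:
    entry ``(i-1)*n + (j-1)`` is site ``i`` of base ``j``.  Coordinates are
    in angstrom with the origin at the circle centre.
    """

    structure: str
    sequence: str
    radius: float
    site_index: np.ndarray  # (3n,) ints in 1..3
    base_index: np.ndarray  # (3n,) ints in 1..n
    charges: np.ndarray  # (3n,)
    coords: np.ndarray  # (3n, 3)

    @property
    def n(self) -> int:
        return len(self.sequence)

    def rotated_about_z(self, angle: float) -> "TorusStructure":
        """The same structure rotated rigidly about the z axis (radians)."""
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return replace(self, coords=self.coords @ rot.T)

    def bounding_box(self) -> np.ndarray:
        """Axis-aligned bounds of all sites, shape (3, 2) = per-axis (min, max)."""
        return np.stack([self.coords.min(axis=0), self.coords.max(axis=0)], axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.site_index,
                "base": self.base_index,
                "nucleobase": [self.sequence[j - 1] for j in self.base_index],
                "charge": self.charges,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
            }
        )


@dataclass(frozen=True)
class Lattice:
    """The 11 x 11 x 11 evaluation grid spanning a structure's bounding box.

    Per axis the 11 values run from the axis minimum to the axis maximum in
    equal steps (index a in -5..5 maps to ``min + (a+5)(max-min)/10``); a
    degenerate axis (max = min) repeats one value 11 times, so the grid
    always holds 1331 points, duplicates included.
    """

    points: np.ndarray  # (1331, 3)
    axes: np.ndarray  # (3, 11)
    bounds: np.ndarray  # (3, 2)


def build_structure(
    sequence: str,
    structure: str = "A",
    *,
    tilt_degrees: float | None = None,
    site_order: str = "inner_first",
) -> TorusStructure:
    """Lay a sequence on the torus circle under one structure convention.

    Parameters
    ----------
    sequence:
        RNA string, length >= 2 (a one-base "circle" is degenerate and
        rejected).
    structure:
        "A", "B" or "C" (tilt 0 / 90 / 45 degrees out of the torus plane).
    tilt_degrees:
        Override the structure's tilt angle; used to study the continuum
        between the in-plane and perpendicular arrangements.
    site_order:
        "inner_first" (default) places the First site closest to the
        backbone circle; "outer_first" reverses the three offsets.
    """
    label = structure.upper()
    if label not in STRUCTURE_TILT_DEGREES:
        raise ValueError(f"unknown structure label {structure!r}; expected A, B or C")
    if site_order not in ("inner_first", "outer_first"):
        raise ValueError(f"unknown site_order {site_order!r}")
    tv = ternary_vector(sequence)
    n = tv.n
    if n < 2:
        raise ValueError("need at least 2 bases to define the torus circle")

    tilt = STRUCTURE_TILT_DEGREES[label] if tilt_degrees is None else float(tilt_degrees)
    tilt_rad = np.deg2rad(tilt)

    radius = n * BASE_SPACING / (2.0 * np.pi)
    theta = 2.0 * np.pi * np.arange(n) / n
    radial = np.stack([np.cos(theta), np.sin(theta), np.zeros(n)], axis=1)  # (n, 3)
    anchors = radius * radial
    # Segment direction: radial component shrinks, +z component grows with tilt.
    z_hat = np.array([0.0, 0.0, 1.0])
    if tilt == 90.0:
        directions = np.tile(z_hat, (n, 1))  # exactly vertical, no trig residue
    else:
        directions = np.cos(tilt_rad) * radial + np.sin(tilt_rad) * z_hat  # (n, 3)

    offsets = np.array(SITE_OFFSETS)
    if site_order == "outer_first":
        offsets = offsets[::-1]

    # Site-major: site i block of n coordinates.
    coords = (
        anchors[None, :, :] + offsets[:, None, None] * directions[None, :, :]
    ).reshape(3 * n, 3)
    if tilt == 0.0:
        coords[:, 2] = 0.0  # exact in-plane layout, no trig residue

    site_index = np.repeat(np.arange(1, 4), n)
    base_index = np.tile(np.arange(1, n + 1), 3)
    return TorusStructure(
        structure=label,
        sequence=tv.sequence,
        radius=radius,
        site_index=site_index,
        base_index=base_index,
        charges=tv.elements.copy(),
        coords=coords,
    )


def build_lattice(structure: TorusStructure) -> Lattice:
    """Build the 11 x 11 x 11 grid over the structure's bounding box."""
    bounds = structure.bounding_box()
    axes = np.linspace(bounds[:, 0], bounds[:, 1], 11, axis=1)  # (3, 11)
    gx, gy, gz = np.meshgrid(axes[0], axes[1], axes[2], indexing="ij")
    points = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    return Lattice(points=points, axes=axes, bounds=bounds)


def write_structure_table(
    structure: TorusStructure, path: Union[str, Path, io.TextIOBase]
) -> None:
    """Export site coordinates as an XYZ-like TSV for visual inspection."""
    structure.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
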