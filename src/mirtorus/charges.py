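"""Hydrogen-bond-site charges of the four RNA nucleobases and the ternary encoding.

Each nucleobase interacts with other nucleic acids through (up to) three
hydrogen-bonding sites.  A sequence is therefore encoded not as a string of
four symbols but as a *ternary vector*: for each of the three sites the
partial charges of the atoms used for hydrogen bonding (AUHB) are listed in
sequence order, giving ``3n`` numbers for an ``n``-nt sequence, laid out
site-major::

    (e11, ..., e1n,  e21, ..., e2n,  e31, ..., e3n)

where ``e_ij`` is the charge at site ``i`` of base ``j``.  The charges are
Mulliken partial charges (elementary-charge units) computed once at the
B3LYP/6-31G(d) level; they are fixed constants here and are never
re-derived.  For adenine's amino group the two hydrogen charges are averaged
into a single First-site value, and the weakly bonding Third site of A is
kept so every base maps to the same three-element shape.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "AUHB_CHARGES",
    "ChargeVector",
    "TernaryVector",
    "InvalidBaseError",
    "charge_vector",
    "ternary_vector",
    "normalize_base",
    "charge_frame",
    "write_charge_table",
]

#: Partial charge at the First/Second/Third hydrogen-bonding site of each base.
AUHB_CHARGES: dict[str, tuple[float, float, float]] = {
    "A": (0.417, -0.514, 0.228),
    "U": (-0.506, 0.408, -0.471),
    "G": (-0.490, 0.414, 0.413),
    "C": (0.379, -0.558, -0.476),
}

SITE_NAMES = ("First", "Second", "Third")
BASE_NAMES = {"A": "Adenine", "U": "Uracil", "G": "Guanine", "C": "Cytosine"}


class InvalidBaseError(ValueError):
    """A symbol outside {A, C, G, U, T} (ambiguity codes included) was seen."""

    def __init__(self, symbol: str, position: int | None = None):
        self.symbol = symbol
        self.position = position
        where = "" if position is None else f" at position {position + 1}"
        super().__init__(
            f"invalid nucleobase symbol {symbol!r}{where}; expected one of A, C, G, U "
            "(T is accepted and read as U)"
        )


@dataclass(frozen=True)
class ChargeVector:
    """The three AUHB partial charges of one nucleobase.

    ``e1``/``e2``/``e3`` are the charges at the First/Second/Third
    hydrogen-bonding site, in elementary-charge units (dimensionless here).
    """

    base: str
    e1: float
    e2: float
    e3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.e1, self.e2, self.e3])


def normalize_base(symbol: str, position: int | None = None) -> str:
    """Uppercase a base symbol and map T to U; reject anything else."""
    b = symbol.upper()
    if b == "T":
        b = "U"
    if b not in AUHB_CHARGES:
        raise InvalidBaseError(symbol, position)
    return b


def charge_vector(base: str) -> ChargeVector:
    """Return the fixed charge triple for one nucleobase.

    Lowercase input and T (read as U) are accepted; ambiguity codes are not.
    """
    b = normalize_base(base)
    return ChargeVector(b, *AUHB_CHARGES[b])


@dataclass(frozen=True)
class TernaryVector:
    """Site-major charge encoding of an RNA sequence.

    ``elements`` holds ``3n`` values: the ``n`` First-site charges in
    sequence order, then the Second-site charges, then the Third-site
    charges.  ``site(i)`` (``i`` in 1..3) recovers one site's block.
    """

    sequence: str
    elements: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "elements", np.asarray(self.elements, dtype=float))
        if self.elements.shape != (3 * self.n,):
            raise ValueError(
                f"expected {3 * self.n} elements for a {self.n}-nt sequence, "
                f"got {self.elements.shape}"
            )

    @property
    def n(self) -> int:
        return len(self.sequence)

    def site(self, i: int) -> np.ndarray:
        if i not in (1, 2, 3):
            raise ValueError(f"site index must be 1, 2 or 3, got {i}")
        return self.elements[(i - 1) * self.n : i * self.n]


def ternary_vector(sequence: str) -> TernaryVector:
    """Encode a sequence as its 3n-element site-major ternary vector."""
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    bases = [normalize_base(ch, pos) for pos, ch in enumerate(sequence)]
    normalized = "".join(bases)
    per_base = np.array([AUHB_CHARGES[b] for b in bases])  # (n, 3)
    return TernaryVector(normalized, per_base.T.ravel())


def charge_frame() -> pd.DataFrame:
    """The charge constants as a tidy table (one row per nucleobase)."""
    rows = [
        {"nucleobase": BASE_NAMES[b], "code": b, "First": e1, "Second": e2, "Third": e3}
        for b, (e1, e2, e3) in AUHB_CHARGES.items()
    ]
    return pd.DataFrame(rows)


def write_charge_table(path: Union[str, Path, io.TextIOBase]) -> None:
    """Export the charge constants as TSV, exactly as stored (3 decimals)."""
    frame = charge_frame()
    frame.to_csv(path, sep="\t", index=False, float_format="%.3f")
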