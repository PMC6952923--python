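"""The four sequence score functions and the duplicate/uniqueness analysis.

Every method condenses the 3n-element ternary encoding of a sequence into a
three-element score vector:

* **VS** - per-site Euclidean norm, ``v_i = sqrt(sum_j e_ij^2)``;
* **Sum** - per-site charge sum, ``v_i = sum_j e_ij``;
* **EV_C** - the electric field of the 3n point charges evaluated at the
  torus centre (x/y/z components);
* **EV_S** - the field summed over the 11x11x11 lattice spanning the
  structure's bounding box.

Field values are proportional forms: the Coulomb prefactor and unit
conversions are dropped, so EV scores are in arbitrary units.  VS and Sum
depend only on base composition (permutation invariant); EV_C and EV_S see
base order through the geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .charges import TernaryVector, ternary_vector
from .geometry import Lattice, TorusStructure, build_lattice, build_structure

__all__ = [
    "METHODS",
    "STRUCTURES",
    "ScoreVector",
    "score_vs",
    "score_sum",
    "field_at_point",
    "fields_at_points",
    "score_ev_c",
    "score_ev_s",
    "score_sequence",
    "score_table",
    "duplicate_analysis",
]

logger = logging.getLogger(__name__)

METHODS = ("VS", "Sum", "EV_C", "EV_S")
STRUCTURES = ("A", "B", "C")

#: Sites closer than this to an evaluation point are skipped (angstrom).
SINGULARITY_CUTOFF = 1e-9


@dataclass(frozen=True)
class ScoreVector:
    """A three-element method score.

    For VS and Sum the values are per-site scores (First/Second/Third);
    for EV_C and EV_S they are the x/y/z field components, arbitrary units.
    ``structure`` is None for the geometry-free methods.
    """

    method: str
    structure: str | None
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (3,):
            raise ValueError("a score vector has exactly three values")


def _as_ternary(v: TernaryVector | str) -> TernaryVector:
    return v if isinstance(v, TernaryVector) else ternary_vector(v)


def score_vs(v: TernaryVector | str) -> ScoreVector:
    """Element-vector-size score: per-site root sum of squared charges."""
    tv = _as_ternary(v)
    vals = np.sqrt([np.sum(tv.site(i) ** 2) for i in (1, 2, 3)])
    return ScoreVector("VS", None, vals)


def score_sum(v: TernaryVector | str) -> ScoreVector:
    """Charge-sum score: per-site sum of charges."""
    tv = _as_ternary(v)
    vals = np.array([np.sum(tv.site(i)) for i in (1, 2, 3)])
    return ScoreVector("Sum", None, vals)


def fields_at_points(s: TorusStructure, points: np.ndarray) -> np.ndarray:
    """Proportional electric field of all 3n site charges at many points.

    Returns an (m, 3) array: sum over sites of charge x displacement /
    distance^3, with no physical prefactor.  Contributions from sites closer
    than ``SINGULARITY_CUTOFF`` to an evaluation point are skipped; the
    number skipped is logged as a warning.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    diff = pts[:, None, :] - s.coords[None, :, :]  # (m, 3n, 3)
    d2 = np.einsum("psk,psk->ps", diff, diff)
    near = d2 < SINGULARITY_CUTOFF**2
    n_skipped = int(near.sum())
    if n_skipped:
        logger.warning(
            "skipped %d site contribution(s) within %g angstrom of an evaluation point",
            n_skipped,
            SINGULARITY_CUTOFF,
        )
        d2 = np.where(near, np.inf, d2)
    inv_d3 = d2 ** (-1.5)
    return np.einsum("s,ps,psk->pk", s.charges, inv_d3, diff)


def field_at_point(s: TorusStructure, p: Sequence[float]) -> np.ndarray:
    """Proportional field at a single 3-D point (see :func:`fields_at_points`)."""
    return fields_at_points(s, np.asarray(p, dtype=float)[None, :])[0]


def score_ev_c(s: TorusStructure) -> ScoreVector:
    """Field evaluated at the circle centre (the coordinate origin)."""
    return ScoreVector("EV_C", s.structure, field_at_point(s, (0.0, 0.0, 0.0)))


def score_ev_s(s: TorusStructure, lattice: Lattice | None = None) -> ScoreVector:
    """Field summed over the 1331 lattice points inside the bounding box."""
    if lattice is None:
        lattice = build_lattice(s)
    total = fields_at_points(s, lattice.points).sum(axis=0)
    return ScoreVector("EV_S", s.structure, total)


def score_sequence(
    sequence: str, method: str, structure: str | None = None
) -> ScoreVector:
    """Score one sequence with one method (building geometry when needed)."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if method in ("VS", "Sum"):
        return score_vs(sequence) if method == "VS" else score_sum(sequence)
    if structure is None:
        raise ValueError(f"{method} requires a structure label (A, B or C)")
    s = build_structure(sequence, structure)
    return score_ev_c(s) if method == "EV_C" else score_ev_s(s)


def score_table(
    records: Iterable[tuple[str, str]],
    method: str,
    structure: str | None = None,
    *,
    unique_sequences: bool = False,
) -> pd.DataFrame:
    """Score many (id, sequence) records into a tidy table.

    With ``unique_sequences`` the first record of each distinct sequence is
    kept and later repeats are dropped before scoring.
    """
    records = list(records)
    if unique_sequences:
        seen: set[str] = set()
        deduped = []
        for rid, seq in records:
            if seq not in seen:
                seen.add(seq)
                deduped.append((rid, seq))
        records = deduped
    rows = []
    for rid, seq in records:
        sv = score_sequence(seq, method, structure)
        rows.append(
            {
                "id": rid,
                "sequence": seq,
                "method": method,
                "structure": structure if method in ("EV_C", "EV_S") else "NA",
                "v1": sv.values[0],
                "v2": sv.values[1],
                "v3": sv.values[2],
            }
        )
    return pd.DataFrame(rows)


def duplicate_analysis(
    scores: Iterable[tuple[str, "ScoreVector | np.ndarray"]],
    *,
    decimals: int = 10,
) -> tuple[int, int, int]:
    """Count duplicate and unique score vectors.

    Values are rounded to ``decimals`` places before comparison so that
    floating-point noise cannot split true duplicates.  A score shared by
    ``k > 1`` records contributes ``k`` to the duplicate count and nothing
    to the unique count, so ``duplicate + unique = total``.  Returns
    ``(n_duplicate, n_unique, pct_unique)`` with the percentage rounded to
    the nearest integer.
    """
    keys = []
    for _, sv in scores:
        vals = sv.values if isinstance(sv, ScoreVector) else np.asarray(sv, dtype=float)
        keys.append(tuple(np.round(vals, decimals)))
    if not keys:
        raise ValueError("duplicate analysis needs at least one score")
    counts = pd.Series(keys).value_counts()
    n_unique = int((counts == 1).sum())
    n_duplicate = int(counts[counts > 1].sum())
    pct_unique = round(100 * n_unique / len(keys))
    return n_duplicate, n_unique, pct_unique
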