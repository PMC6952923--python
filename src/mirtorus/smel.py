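"""SMEL and the regression statistics used to compare diseases.

SMEL (Score Multiplication Expression Level) attaches a disease context to
a sequence score: the three-element score vector is multiplied by the
miRNA's expression change ``x`` (fold change FC, or log2 FC) reported for
that disease.  Because SMEL is an exact scalar multiple of the score, the
regression of one SMEL component on another passes through the origin, and
diseases are compared by the *slopes* of those through-origin fits: for a
sigma multiplier ``k`` in {1, 2, 3}, two diseases differ significantly on
an axis pair when the intervals ``slope +/- k * SE`` do not overlap.  An
axis pair is marked "O" (distinguishing) only when every disease pair
differs; one overlapping pair gives "x".  Axis pairs whose values vanish
identically for a method/structure (the z axis of the in-plane Structure A
under the field methods) are reported "NA".

Fold changes can carry extreme literature-extraction outliers; an optional
filter sorts the FC values in descending order and, scanning from the
largest, removes values at least twice the next smaller one, stopping at
the first value that is not.  log2 FC values are never filtered.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .scoring import ScoreVector

__all__ = [
    "AXIS_PAIRS",
    "ExpressionRecord",
    "SmelVector",
    "RegressionResult",
    "SlopeComparison",
    "DiscriminationResult",
    "smel",
    "smel_table",
    "pairwise_regression",
    "regress_axes",
    "compare_slopes",
    "disease_discrimination",
    "filter_fc_outliers",
    "fc_outlier_mask",
]

#: Predictor-response component pairs, cyclic: x->y, y->z, z->x.
AXIS_PAIRS = ("x-y", "y-z", "z-x")
_AXIS_COLUMNS = {"x-y": (0, 1), "y-z": (1, 2), "z-x": (2, 0)}

#: Relative tolerance below which an axis is treated as identically zero.
_DEGENERATE_RTOL = 1e-12

MARK_ALL_SIGNIFICANT = "O"
MARK_NOT_SIGNIFICANT = "x"
MARK_NOT_APPLICABLE = "NA"


@dataclass
class ExpressionRecord:
    """One miRNA's expression change in one disease.

    At least one of ``fc`` (fold change, ratio > 0) and ``log2fc`` must be
    given; the missing one is derived (``fc = 2**log2fc``) on construction.
    """

    mirna_id: str
    disease: str
    fc: float | None = None
    log2fc: float | None = None

    def __post_init__(self):
        if self.fc is None and self.log2fc is None:
            raise ValueError(
                f"{self.mirna_id} ({self.disease}): need fc or log2fc, both missing"
            )
        if self.fc is not None and self.fc <= 0:
            raise ValueError(
                f"{self.mirna_id} ({self.disease}): fold change must be > 0, got {self.fc}"
            )
        if self.fc is None:
            self.fc = float(2.0**self.log2fc)
        if self.log2fc is None:
            self.log2fc = float(np.log2(self.fc))


@dataclass(frozen=True)
class SmelVector:
    """A score vector scaled by one expression value."""

    method: str
    structure: str | None
    expression_type: str  # "fc" | "log2fc"
    values: np.ndarray


@dataclass(frozen=True)
class RegressionResult:
    """Single (pairwise) regression of one score/SMEL component on another.

    ``stderr`` is the standard error of the slope; ``signed_fit`` is
    ``sign(slope) * r2``, the signed coefficient of determination.
    """

    axis_pair: str
    slope: float
    stderr: float
    pvalue: float
    r2: float
    signed_fit: float
    n: int
    through_origin: bool


@dataclass(frozen=True)
class SlopeComparison:
    """Whether two diseases' slopes differ at +/- k sigma on one axis pair."""

    disease_pair: tuple[str, str]
    axis_pair: str
    k: int
    significant: bool


@dataclass(frozen=True)
class DiscriminationResult:
    """Per-axis verdicts plus the underlying regressions and pair tests."""

    k: int
    marks: dict[str, str]  # axis pair -> "O" | "x" | "NA"
    comparisons: list[SlopeComparison]
    regressions: dict[tuple[str, str], RegressionResult]  # (disease, axis) ->


def smel(score: ScoreVector, x: float, expression_type: str = "log2fc") -> SmelVector:
    """Multiply a score vector by an expression value (elementwise)."""
    if not np.isfinite(x):
        raise ValueError(f"expression value must be finite, got {x}")
    return SmelVector(score.method, score.structure, expression_type, score.values * x)


def smel_table(
    scores: pd.DataFrame,
    records: Iterable[ExpressionRecord],
    expression_type: str = "log2fc",
) -> pd.DataFrame:
    """Join a score table with expression records into per-disease SMEL rows.

    ``scores`` is the output of :func:`mirtorus.scoring.score_table`;
    records whose id has no scored sequence are dropped.
    """
    if expression_type not in ("fc", "log2fc"):
        raise ValueError(f"expression_type must be 'fc' or 'log2fc', got {expression_type!r}")
    by_id = scores.set_index("id")
    rows = []
    for rec in records:
        if rec.mirna_id not in by_id.index:
            continue
        s = by_id.loc[rec.mirna_id]
        x = rec.fc if expression_type == "fc" else rec.log2fc
        rows.append(
            {
                "id": rec.mirna_id,
                "disease": rec.disease,
                "method": s["method"],
                "structure": s["structure"],
                "expression_type": expression_type,
                "x": x,
                "v1": s["v1"] * x,
                "v2": s["v2"] * x,
                "v3": s["v3"] * x,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "disease", "method", "structure", "expression_type", "x", "v1", "v2", "v3"],
    )


def pairwise_regression(
    points: "np.ndarray | Sequence[tuple[float, float]]",
    *,
    through_origin: bool = False,
    axis_pair: str = "x-y",
) -> RegressionResult:
    """Ordinary least squares of the second coordinate on the first.

    With ``through_origin`` the intercept is forced to zero (the SMEL
    convention); otherwise an intercept is fitted (the raw-score
    convention).  The p-value is the two-sided t test of the slope; the fit
    statistic is reported both as plain ``r2`` and as ``sign(slope) * r2``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (predictor, response)")
    a, b = pts[:, 0], pts[:, 1]
    if len(a) < 3:
        raise ValueError(f"need at least 3 points, got {len(a)}")
    if through_origin:
        if np.all(a == 0):
            raise ValueError("predictor is identically zero")
        design = a[:, None]
    else:
        if np.ptp(a) == 0:
            raise ValueError("predictor has zero variance")
        design = sm.add_constant(a)
    fit = sm.OLS(b, design).fit()
    slope = float(fit.params[-1])
    stderr = float(fit.bse[-1])
    if stderr == 0.0:
        pvalue = 0.0 if slope != 0 else 1.0  # exact fit: the t statistic diverges
    else:
        pvalue = float(fit.pvalues[-1])
    r2 = float(fit.rsquared)
    return RegressionResult(
        axis_pair=axis_pair,
        slope=slope,
        stderr=stderr,
        pvalue=pvalue,
        r2=r2,
        signed_fit=float(np.sign(slope) * r2),
        n=len(a),
        through_origin=through_origin,
    )


def _degenerate(column: np.ndarray, scale: float) -> bool:
    return bool(np.all(np.abs(column) <= _DEGENERATE_RTOL * scale))


def regress_axes(
    values: np.ndarray,
    *,
    through_origin: bool = False,
    axis_pairs: Sequence[str] = AXIS_PAIRS,
) -> dict[str, RegressionResult | None]:
    """Regress every axis pair of an (n, 3) component array.

    An axis pair whose predictor or response is identically zero (relative
    to the overall component scale) carries no information for the
    method/structure and maps to None (reported "NA" downstream).
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 2 or vals.shape[1] != 3:
        raise ValueError("values must be an (n, 3) component array")
    scale = max(float(np.abs(vals).max()), 1.0)
    out: dict[str, RegressionResult | None] = {}
    for pair in axis_pairs:
        ia, ib = _AXIS_COLUMNS[pair]
        if _degenerate(vals[:, ia], scale) or _degenerate(vals[:, ib], scale):
            out[pair] = None
            continue
        out[pair] = pairwise_regression(
            vals[:, [ia, ib]], through_origin=through_origin, axis_pair=pair
        )
    return out


def compare_slopes(r1: RegressionResult, r2: RegressionResult, k: int) -> bool:
    """True when the slope +/- k*SE intervals of the two fits do not overlap."""
    if r1.axis_pair != r2.axis_pair:
        raise ValueError(
            f"axis-pair mismatch: {r1.axis_pair!r} vs {r2.axis_pair!r}"
        )
    lo1, hi1 = r1.slope - k * r1.stderr, r1.slope + k * r1.stderr
    lo2, hi2 = r2.slope - k * r2.stderr, r2.slope + k * r2.stderr
    return bool(hi1 < lo2 or hi2 < lo1)


def disease_discrimination(
    smel_by_disease: Mapping[str, np.ndarray],
    k: int,
    *,
    axis_pairs: Sequence[str] = AXIS_PAIRS,
    through_origin: bool = True,
) -> DiscriminationResult:
    """Test whether slope intervals separate every pair of diseases.

    ``smel_by_disease`` maps each disease label to its (n, 3) SMEL
    component array (n >= 3 points each).  For every axis pair each
    disease is regressed and all disease pairs are interval-tested at
    +/- k sigma; the axis verdict is "O" only when every pair separates,
    "x" otherwise, and "NA" when the axis pair is undefined for any
    disease (identically-zero components).
    """
    diseases = list(smel_by_disease)
    if len(diseases) < 2:
        raise ValueError("need at least 2 diseases to compare")
    fits: dict[tuple[str, str], RegressionResult] = {}
    per_disease = {
        d: regress_axes(
            smel_by_disease[d], through_origin=through_origin, axis_pairs=axis_pairs
        )
        for d in diseases
    }
    marks: dict[str, str] = {}
    comparisons: list[SlopeComparison] = []
    for pair in axis_pairs:
        if any(per_disease[d][pair] is None for d in diseases):
            marks[pair] = MARK_NOT_APPLICABLE
            continue
        all_significant = True
        for d1, d2 in combinations(diseases, 2):
            sig = compare_slopes(per_disease[d1][pair], per_disease[d2][pair], k)
            comparisons.append(SlopeComparison((d1, d2), pair, k, sig))
            all_significant &= sig
        marks[pair] = MARK_ALL_SIGNIFICANT if all_significant else MARK_NOT_SIGNIFICANT
        for d in diseases:
            fits[(d, pair)] = per_disease[d][pair]
    return DiscriminationResult(k=k, marks=marks, comparisons=comparisons, regressions=fits)


def fc_outlier_mask(values: Sequence[float], *, mode: str = "cascade") -> np.ndarray:
    """Keep-mask for the descending-sort fold-change outlier rule.

    Sorted in descending order, values are scanned from the largest: while
    a value is at least twice the next smaller one it is an outlier, and
    the scan stops at the first value that is not.  ``mode="cascade"``
    (default) removes every value passed before the stop; ``mode="first"``
    removes at most the single largest value.  The mask is aligned to the
    input order; the rule applies to FC only (never filter log2 FC).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        return np.ones(0, dtype=bool)
    if np.any(vals <= 0):
        raise ValueError("fold changes must be positive")
    if mode not in ("cascade", "first"):
        raise ValueError(f"unknown mode {mode!r}; expected 'cascade' or 'first'")
    order = np.argsort(-vals, kind="stable")
    ranked = vals[order]
    n_removed = 0
    for i in range(len(ranked) - 1):
        if ranked[i] >= 2.0 * ranked[i + 1]:
            n_removed = i + 1
            if mode == "first":
                break
        else:
            break
    keep = np.ones(len(vals), dtype=bool)
    keep[order[:n_removed]] = False
    return keep


def filter_fc_outliers(
    values: Sequence[float], *, mode: str = "cascade"
) -> tuple[np.ndarray, np.ndarray]:
    """Split fold changes into (kept, removed), both in descending order."""
    vals = np.asarray(values, dtype=float)
    keep = fc_outlier_mask(vals, mode=mode)
    kept = np.sort(vals[keep])[::-1]
    removed = np.sort(vals[~keep])[::-1]
    return kept, removed
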