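"""Independent brute-force oracles used only for cross-checking.

These deliberately mirror the written definitions with plain Python loops
and textbook formulas, not the vectorized implementation paths.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def brute_force_field(structure, point):
    """Plain triple-loop field sum: charge x displacement / distance^3."""
    ex = ey = ez = 0.0
    px, py, pz = point
    for q, (x, y, z) in zip(structure.charges, structure.coords):
        dx, dy, dz = px - x, py - y, pz - z
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        if d < 1e-9:
            continue  # same skip rule as the implementation
        ex += q * dx / d**3
        ey += q * dy / d**3
        ez += q * dz / d**3
    return np.array([ex, ey, ez])


def brute_force_ev_s(structure, lattice):
    """Quadruple loop: field summed over every lattice point."""
    total = np.zeros(3)
    for p in lattice.points:
        total += brute_force_field(structure, p)
    return total


def closed_form_ols(a, b, through_origin=False):
    """Textbook least-squares slope, SE, p-value and r^2 for one predictor."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(a)
    if through_origin:
        slope = float(np.sum(a * b) / np.sum(a * a))
        resid = b - slope * a
        dof = n - 1
        se = math.sqrt(np.sum(resid**2) / dof / np.sum(a * a))
        r2 = 1.0 - np.sum(resid**2) / np.sum(b * b)  # uncentered
    else:
        am, bm = a.mean(), b.mean()
        sxx = np.sum((a - am) ** 2)
        sxy = np.sum((a - am) * (b - bm))
        syy = np.sum((b - bm) ** 2)
        slope = float(sxy / sxx)
        resid = b - bm - slope * (a - am)
        dof = n - 2
        se = math.sqrt(np.sum(resid**2) / dof / sxx)
        r2 = float(sxy**2 / (sxx * syy))
    if se == 0.0:
        p = 0.0 if slope != 0 else 1.0
    else:
        p = 2.0 * stats.t.sf(abs(slope) / se, dof)
    return slope, se, p, r2
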