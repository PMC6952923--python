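"""Seeded generator for miRNA-like sequences and disease expression panels.

Real inputs to the analysis are mature miRNA sequences plus, per disease, a
set of miRNAs whose expression differs from healthy controls, each with a
fold change (FC) and/or its base-2 log (log2 FC) extracted from the
literature.  The generator emulates that statistical shape without any
download:

* sequences are uniform-random over A/C/G/U at lengths 18-25 nt (the
  mature-miRNA range), with a configurable composition;
* each disease reports a subset of the pool; its log2 FC values are drawn
  Normal(mu_d, sigma_d), roughly symmetric about zero, and FC = 2**log2FC
  is therefore heavy-tailed and positive;
* occasional extreme FC outliers (rate x magnitude) mimic the very large
  literature fold changes that motivate the descending-sort outlier rule;
* a slope-separation factor biases *which* miRNAs each disease reports
  (sampling weighted by the sequences' per-site score ratio), so the
  through-origin SMEL slopes of different diseases separate by a
  controllable amount; at zero separation all diseases sample uniformly
  and their slopes coincide up to noise.

Everything is reproducible from the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .scoring import score_vs
from .smel import ExpressionRecord

__all__ = ["DiseasePanel", "SimSpec", "simulate_sequences", "simulate_expression", "write_fixtures"]

BASES = ("A", "C", "G", "U")


@dataclass(frozen=True)
class DiseasePanel:
    """Size and log2-fold-change distribution of one disease's miRNA panel."""

    name: str
    n_mirnas: int = 80
    log2fc_mean: float = 0.0
    log2fc_sd: float = 2.0

    def __post_init__(self):
        if self.n_mirnas < 1:
            raise ValueError("a disease panel needs at least one miRNA")
        if self.log2fc_sd <= 0:
            raise ValueError("log2fc_sd must be > 0")


def _default_panels() -> tuple[DiseasePanel, ...]:
    # Four diseases of different major classes, each reporting a
    # literature-scale panel of differentially expressed miRNAs.
    return tuple(DiseasePanel(name) for name in ("AD", "COPD", "ST", "TB"))


@dataclass(frozen=True)
class SimSpec:
    """Study-condition parameters for one simulated dataset.

    Defaults mirror the analysis conditions: a pool the size of the human
    mature-miRNA catalogue (2656 sequences), 18-25 nt lengths, uniform base
    composition, four disease panels, a 2% outlier rate at 100x magnitude,
    and a moderate slope separation between diseases.
    """

    seed: int
    n_mirnas: int = 2656
    length_range: tuple[int, int] = (18, 25)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    diseases: tuple[DiseasePanel, ...] = field(default_factory=_default_panels)
    slope_separation: float = 1.0
    outlier_rate: float = 0.02
    outlier_magnitude: float = 100.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.n_mirnas < 2:
            raise ValueError("need at least 2 sequences")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError(f"bad length range {self.length_range}")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or np.any(comp < 0) or not np.isclose(comp.sum(), 1.0):
            raise ValueError("base composition must be 4 non-negative weights summing to 1")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier rate must lie in [0, 1]")
        if self.outlier_magnitude <= 0:
            raise ValueError("outlier magnitude must be > 0")
        for panel in self.diseases:
            if panel.n_mirnas > self.n_mirnas:
                raise ValueError(
                    f"{panel.name}: panel size {panel.n_mirnas} exceeds pool {self.n_mirnas}"
                )


def simulate_sequences(spec: SimSpec) -> list[tuple[str, str]]:
    """Draw the miRNA pool: ids ``sim-mir-0001`` ... with random sequences."""
    rng = np.random.default_rng((int(spec.seed), 11))
    lo, hi = spec.length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_mirnas)
    comp = np.asarray(spec.base_composition, dtype=float)
    comp = comp / comp.sum()
    width = len(str(spec.n_mirnas))
    records = []
    for i, length in enumerate(lengths, start=1):
        seq = "".join(rng.choice(BASES, size=length, p=comp))
        records.append((f"sim-mir-{i:0{width}d}", seq))
    return records


def _rank_bias(sequences: Sequence[tuple[str, str]]) -> np.ndarray:
    """Rank-standardized per-sequence score ratio in [-1, 1].

    The second/first VS site ratio orders sequences by the quantity that
    drives the x-y SMEL slope, so weighting disease membership by it
    shifts that slope in a controlled direction.
    """
    scores = [score_vs(seq).values for _, seq in sequences]
    ratios = np.array([v[1] / v[0] for v in scores])
    ranks = np.argsort(np.argsort(ratios))
    if len(ranks) == 1:
        return np.zeros(1)
    return 2.0 * ranks / (len(ranks) - 1) - 1.0


def simulate_expression(
    spec: SimSpec, sequences: Sequence[tuple[str, str]]
) -> list[ExpressionRecord]:
    """Draw each disease's panel of expression records from the pool.

    Disease d samples its miRNAs without replacement with weight
    ``exp(c_d * u_j)`` where ``u_j`` is the rank-standardized score ratio
    of sequence j and the ``c_d`` spread symmetrically over
    ``slope_separation * [-1, 1]`` across diseases.  log2 FC is then drawn
    Normal(mu_d, sigma_d); with probability ``outlier_rate`` the FC is
    multiplied by ``outlier_magnitude`` (log2 FC rederived, keeping the
    record consistent).
    """
    if len(spec.diseases) < 2:
        raise ValueError("need at least 2 diseases")
    rng = np.random.default_rng((int(spec.seed), 23))
    ids = [rid for rid, _ in sequences]
    u = _rank_bias(sequences)
    n_dis = len(spec.diseases)
    biases = spec.slope_separation * np.linspace(-1.0, 1.0, n_dis)
    records: list[ExpressionRecord] = []
    for panel, c in zip(spec.diseases, biases):
        weights = np.exp(c * u)
        weights /= weights.sum()
        chosen = rng.choice(len(ids), size=panel.n_mirnas, replace=False, p=weights)
        log2fc = rng.normal(panel.log2fc_mean, panel.log2fc_sd, size=panel.n_mirnas)
        fc = 2.0**log2fc
        outlier = rng.random(panel.n_mirnas) < spec.outlier_rate
        fc = np.where(outlier, fc * spec.outlier_magnitude, fc)
        for idx, f in zip(chosen, fc):
            records.append(ExpressionRecord(ids[idx], panel.name, fc=float(f)))
    return records


def write_fixtures(
    spec: SimSpec,
    fasta_path: Union[str, Path],
    expression_path: Union[str, Path],
) -> tuple[list[tuple[str, str]], list[ExpressionRecord]]:
    """Write a paired FASTA + expression CSV fixture and return the data."""
    sequences = simulate_sequences(spec)
    records = simulate_expression(spec, sequences)
    with open(fasta_path, "w") as fh:
        for rid, seq in sequences:
            fh.write(f">{rid}\n{seq}\n")
    with open(expression_path, "w") as fh:
        fh.write("mirna_id,disease,fc,log2fc\n")
        for rec in records:
            fh.write(f"{rec.mirna_id},{rec.disease},{rec.fc!r},{rec.log2fc!r}\n")
    return sequences, records
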