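"""Readers, writers and run configuration.

Sequences come in as standard FASTA (miRBase-style mature sequences; DNA
alphabet is tolerated, T is read as U).  Expression tables come in as CSV
with columns ``mirna_id, disease, fc, log2fc`` where either value column
may be blank but not both.  All outputs are TSV with a fixed column order
and 6-significant-digit floats so runs diff cleanly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
import yaml
from Bio import SeqIO

from .smel import ExpressionRecord

__all__ = [
    "read_fasta",
    "read_expression",
    "write_table",
    "RunConfig",
]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"

EXPRESSION_COLUMNS = ("mirna_id", "disease", "fc", "log2fc")


def read_fasta(path: Union[str, Path]) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file.

    Sequences are uppercased and U-normalized (T mapped to U, warned once
    per file); duplicate ids are warned about and kept; an empty file is an
    error.  Character validation beyond T happens at scoring time.
    """
    path = Path(path)
    records = []
    saw_t = False
    seen_ids: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "T" in seq:
            saw_t = True
            seq = seq.replace("T", "U")
        if rec.id in seen_ids:
            logger.warning("%s: duplicate id %r kept", path.name, rec.id)
        seen_ids.add(rec.id)
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if saw_t:
        logger.warning("%s: DNA alphabet detected, T read as U", path.name)
    return records


def read_expression(path: Union[str, Path]) -> list[ExpressionRecord]:
    """Read expression records from CSV, completing the missing FC column.

    Rows with both ``fc`` and ``log2fc`` blank are rejected with their row
    number.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in EXPRESSION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing expression columns {missing}")
    records = []
    for idx, row in frame.iterrows():
        fc = None if pd.isna(row["fc"]) else float(row["fc"])
        log2fc = None if pd.isna(row["log2fc"]) else float(row["log2fc"])
        try:
            records.append(
                ExpressionRecord(str(row["mirna_id"]), str(row["disease"]), fc, log2fc)
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx + 2}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no expression rows found")
    return records


def write_table(
    frame: pd.DataFrame,
    path: Union[str, Path],
    columns: Sequence[str] | None = None,
) -> None:
    """Write a TSV with fixed column order and 6-significant-digit floats."""
    if columns is not None:
        frame = frame[list(columns)]
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


_METHOD_CHOICES = ("VS", "Sum", "EV_C", "EV_S")
_STRUCTURE_CHOICES = ("A", "B", "C")


@dataclass
class RunConfig:
    """Validated configuration for an analysis run."""

    methods: tuple[str, ...] = ("VS",)
    structures: tuple[str, ...] = ("A", "B", "C")
    expression_type: str = "log2fc"
    sigma_levels: tuple[int, ...] = (1, 2, 3)
    drop_outliers: bool = False
    outlier_mode: str = "cascade"
    through_origin: bool = True
    duplicate_decimals: int = 10
    seed: int = 0

    def __post_init__(self):
        self.methods = tuple(self.methods)
        self.structures = tuple(self.structures)
        self.sigma_levels = tuple(int(k) for k in self.sigma_levels)
        for m in self.methods:
            if m not in _METHOD_CHOICES:
                raise ValueError(f"unknown method {m!r}; expected one of {_METHOD_CHOICES}")
        for s in self.structures:
            if s not in _STRUCTURE_CHOICES:
                raise ValueError(f"unknown structure {s!r}; expected one of {_STRUCTURE_CHOICES}")
        if self.expression_type not in ("fc", "log2fc"):
            raise ValueError(f"expression_type must be 'fc' or 'log2fc'")
        for k in self.sigma_levels:
            if k not in (1, 2, 3):
                raise ValueError(f"sigma level must be 1, 2 or 3, got {k}")
        if self.outlier_mode not in ("cascade", "first"):
            raise ValueError(f"unknown outlier mode {self.outlier_mode!r}")
        if self.duplicate_decimals < 0:
            raise ValueError("duplicate_decimals must be >= 0")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def describe(self) -> str:
        return ", ".join(f"{k}={v!r}" for k, v in vars(self).items())
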