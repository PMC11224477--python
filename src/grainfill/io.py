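"""CSV readers/writers and run configuration.

All tables are plain CSV with a header row; column matching is
case-insensitive and order-free.  Numbers are serialized with 6
significant digits by default (``full_precision=True`` writes repr-level
precision).  Unknown tillage or variety labels pass through with a
warning unless ``strict=True`` — the readers validate structure, not the
treatment vocabulary, so the tooling extends to other designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataValidationError
from .simulate import TILLAGE_LEVELS, VARIETIES

__all__ = [
    "read_filling_csv",
    "read_traits_csv",
    "write_csv",
    "RunConfig",
]

FILLING_COLUMNS = ["year", "tillage", "variety", "replicate", "dap", "weight"]
TRAIT_COLUMNS = ["year", "tillage", "variety", "replicate", "trait", "value"]
UNIT_KEYS = ["year", "tillage", "variety", "replicate"]


def _read_table(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    rename = {c: c.strip().lower() for c in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing column(s) {missing}")
    return df[required]


def _check_numeric(df: pd.DataFrame, path, cols: list[str]) -> pd.DataFrame:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise DataValidationError(
                f"{path}: non-numeric {c!r} at row(s) {[int(i) + 2 for i in bad[:5]]}"
            )
        df[c] = coerced
    return df


def _check_labels(df: pd.DataFrame, path, strict: bool) -> None:
    odd_t = sorted(set(df["tillage"]) - set(TILLAGE_LEVELS))
    odd_v = sorted(set(df["variety"]) - set(VARIETIES))
    msg = []
    if odd_t:
        msg.append(f"unknown tillage label(s) {odd_t}")
    if odd_v:
        msg.append(f"unknown variety label(s) {odd_v}")
    if msg:
        text = f"{path}: " + "; ".join(msg)
        if strict:
            raise DataValidationError(text)
        warnings.warn(text, stacklevel=3)


def read_filling_csv(path, strict: bool = False) -> pd.DataFrame:
    """Read a long-format filling series table.

    Requires columns year, tillage, variety, replicate, dap, weight
    (case-insensitive, any order).  Duplicate (unit, dap) rows and
    non-numeric dap/weight raise DataValidationError naming the row.
    """
    df = _read_table(path, FILLING_COLUMNS)
    df = _check_numeric(df, path, ["year", "replicate", "dap", "weight"])
    if (df["weight"] <= 0).any():
        bad = df.index[df["weight"] <= 0][:5]
        raise DataValidationError(
            f"{path}: non-positive weight at row(s) {[int(i) + 2 for i in bad]}"
        )
    dup = df.duplicated(subset=UNIT_KEYS + ["dap"])
    if dup.any():
        bad = df.index[dup][:5]
        raise DataValidationError(
            f"{path}: duplicate (unit, dap) at row(s) {[int(i) + 2 for i in bad]}"
        )
    _check_labels(df, path, strict)
    return df


def read_traits_csv(path, strict: bool = False) -> pd.DataFrame:
    """Read a long-format maturity-trait table.

    Requires columns year, tillage, variety, replicate, trait, value.
    Duplicate (unit, trait) rows raise DataValidationError.
    """
    df = _read_table(path, TRAIT_COLUMNS)
    df = _check_numeric(df, path, ["year", "replicate", "value"])
    dup = df.duplicated(subset=UNIT_KEYS + ["trait"])
    if dup.any():
        bad = df.index[dup][:5]
        raise DataValidationError(
            f"{path}: duplicate (unit, trait) at row(s) {[int(i) + 2 for i in bad]}"
        )
    _check_labels(df, path, strict)
    return df


def write_csv(df: pd.DataFrame, path, full_precision: bool = False,
              index: bool = False) -> None:
    """Write a table as CSV, 6 significant digits unless full_precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fmt = None if full_precision else "%.6g"
    df.to_csv(path, float_format=fmt, index=index)


@dataclass(frozen=True)
class RunConfig:
    """Options controlling a full pipeline run.

    constants: 'truncated' reproduces the truncated phase offsets
    (1.317 / 4.59512) used in printed grain-filling tables; 'exact' uses
    ln(2+sqrt(3)) / ln(99).  per_replicate selects per-unit curve fits
    (vs fitting treatment-mean series).  sle/sls are the stepwise entry
    and stay p thresholds; alpha the LSD significance level.
    """

    constants: str = "truncated"
    per_replicate: bool = True
    fit_tol: float = 1e-10
    fit_max_iter: int = 200
    sle: float = 0.15
    sls: float = 0.15
    alpha: float = 0.05
    seed: int = 0
    full_precision: bool = False
    lsd_combined_error: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise DataValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.constants not in ("truncated", "exact"):
            raise DataValidationError(
                f"constants must be 'truncated' or 'exact', got {self.constants!r}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kw = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        return cls(**kw, extra=extra)

    def to_yaml(self, path) -> None:
        data = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k != "extra"
        }
        Path(path).write_text(yaml.safe_dump(data | self.extra, sort_keys=False))
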