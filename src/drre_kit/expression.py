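"""Fold-change differential expression, profile classes and coregulation.

Differential expression on FPKM tables is a pure fold-change rule: a gene is
up-regulated at a timepoint when the (pseudocounted) ratio of regeneration to
control replicate-mean FPKM is at least ``theta`` (1.7 by default) and
down-regulated when the ratio is at most 1/theta.  No dispersion model and
no p-values are involved; that is the method being implemented, not an
omission.

Expression profiles over the three timepoints are classified as variable
(max/min ratio > 2) or, by mean FPKM, as high (> 30), moderate (5, 30],
low (1, 5] or silenced (<= 1).  Coregulation of a gene pair is the Pearson
correlation of log(FPKM + 0.01) across timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Union

import numpy as np
import pandas as pd

CONDITIONS = ("control", "regeneration")
TIMEPOINTS = ("early", "mid", "late")

PROFILE_CLASSES = ("variable", "high", "moderate", "low", "silenced")

__all__ = [
    "ExpressionMatrix", "DECall", "call_de", "classify_profile",
    "classify_profiles", "coregulation", "CONDITIONS", "TIMEPOINTS",
]


@dataclass(frozen=True)
class DECall:
    gene_id: str
    timepoint: str
    fold_change: float
    direction: str  # "up" | "down" | "nde"


class ExpressionMatrix:
    """Gene x sample FPKM, samples keyed ``condition_timepoint_rep``."""

    def __init__(self, df: pd.DataFrame):
        if (df.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        for col in df.columns:
            cond, tp, _rep = self._parse_key(col)
            if cond not in CONDITIONS or tp not in TIMEPOINTS:
                raise ValueError(f"bad sample key {col!r}")
        self.df = df.astype(float)

    @staticmethod
    def _parse_key(key: str):
        parts = key.split("_")
        if len(parts) != 3:
            raise ValueError(f"sample key {key!r} is not condition_timepoint_rep")
        return parts[0], parts[1], parts[2]

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"))

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.df.rename_axis("gene_id").to_csv(path, sep="\t")

    @property
    def genes(self) -> List[str]:
        return list(self.df.index)

    def _cols(self, condition: str, timepoint: str) -> List[str]:
        return [
            c for c in self.df.columns
            if self._parse_key(c)[:2] == (condition, timepoint)
        ]

    def condition_mean(self, condition: str, timepoint: str) -> pd.Series:
        """Replicate-mean FPKM per gene for one condition at one timepoint."""
        cols = self._cols(condition, timepoint)
        if not cols:
            raise ValueError(f"no samples for {condition}/{timepoint}")
        return self.df[cols].mean(axis=1)

    def timepoint_means(self, condition: str) -> pd.DataFrame:
        """Genes x timepoints replicate-mean FPKM for one condition."""
        return pd.DataFrame(
            {tp: self.condition_mean(condition, tp) for tp in TIMEPOINTS
             if self._cols(condition, tp)}
        )


def call_de(
    expr: ExpressionMatrix,
    timepoint: str,
    theta: float = 1.7,
    eps: float = 0.01,
) -> pd.DataFrame:
    """Call every gene up / down / nde at one timepoint.

    fold_change = (mean regeneration FPKM + eps) / (mean control FPKM + eps);
    up iff fold_change >= theta, down iff fold_change <= 1/theta.
    Returns a DataFrame with columns gene_id, timepoint, fold_change,
    direction (one row per gene).
    """
    ctl = expr.condition_mean("control", timepoint)
    reg = expr.condition_mean("regeneration", timepoint)
    fc = (reg + eps) / (ctl + eps)
    direction = np.where(fc >= theta, "up", np.where(fc <= 1.0 / theta, "down", "nde"))
    return pd.DataFrame({
        "gene_id": fc.index,
        "timepoint": timepoint,
        "fold_change": fc.values,
        "direction": direction,
    })


def de_sets(calls: pd.DataFrame) -> dict:
    """Up/down gene-id sets from a call_de table."""
    return {
        "up": set(calls.loc[calls.direction == "up", "gene_id"]),
        "down": set(calls.loc[calls.direction == "down", "gene_id"]),
    }


def classify_profile(values: Sequence[float], eps: float = 0.01) -> str:
    """Profile class of one gene from its three per-timepoint FPKM values."""
    if len(values) != 3:
        raise ValueError(f"expected 3 timepoint values, got {len(values)}")
    v = np.asarray(values, dtype=float)
    if (max(v) + eps) / (min(v) + eps) > 2.0:
        return "variable"
    mean = float(np.mean(v))
    if mean > 30:
        return "high"
    if mean > 5:
        return "moderate"
    if mean > 1:
        return "low"
    return "silenced"


def classify_profiles(means: pd.DataFrame, eps: float = 0.01) -> pd.Series:
    """Per-gene profile class from a genes x 3-timepoint mean-FPKM table."""
    return means.apply(lambda row: classify_profile(row.values, eps), axis=1)


def coregulation(
    expr_a: Sequence[float], expr_b: Sequence[float], eps: float = 0.01
) -> float:
    """Pearson correlation of log(FPKM + eps) across timepoints.

    Returns NaN when either log-profile has zero variance (correlation
    undefined).  Requires >= 3 timepoints.
    """
    a = np.log(np.asarray(expr_a, dtype=float) + eps)
    b = np.log(np.asarray(expr_b, dtype=float) + eps)
    if len(a) != len(b):
        raise ValueError("profiles have different numbers of timepoints")
    if len(a) < 3:
        raise ValueError("coregulation needs >= 3 timepoints")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
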