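"""Significance filters and S1/S2/D cooperativity counting.

For each protein pair's 6×10 correlation table a per-row threshold is
computed on the absolute values — the row median by default, or the first
tertile, first quartile, or mean.  Entries strictly above their row's
threshold are "significant", giving the boolean matrix L; the companion
matrix Z records the sign of each entry (c ≥ 0 counts as positive).

Cooperativity between the two pairs is then counted over every triple
(p¹-row m1, p²-row m2, mode n) — 6×6×10 = 360 triples on the default grids:

* **S1**: only pair 1 significant (L1[m1,n] and not L2[m2,n]),
* **S2**: only pair 2 significant,
* **D**:  both significant,

each split into a positive/negative subtype from Z: for S_i the sign of the
significant pair's entry, for D whether the two signs agree.

The quantile threshold is the inf-form on the empirical CDF (the smallest
order statistic whose rank fraction reaches p), and the comparison is
strictly greater.  Together these give the exact per-row counts 5 (median),
6 (tertile) and 7 (quartile) whenever a row's absolute values are distinct,
and hence the identities s_i + d = 180 / 216 / 252.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .segment_correlation import CorrelationTable

__all__ = [
    "FilterSpec",
    "LogicPair",
    "CoopCounts",
    "FILTER_METHODS",
    "row_threshold",
    "logic_pair",
    "coop_counts",
    "significant_per_row",
]

FILTER_METHODS = ("median", "tertile", "quartile", "mean")


@dataclass(frozen=True)
class FilterSpec:
    """Choice of per-row significance threshold; comparison is strict >."""

    method: str = "median"

    def __post_init__(self):
        if self.method not in FILTER_METHODS:
            raise ValueError(
                f"filter must be one of {FILTER_METHODS}, got {self.method!r}"
            )


@dataclass
class LogicPair:
    """Boolean significance (L) and sign (Z) matrices of one table."""

    L: np.ndarray
    Z: np.ndarray
    thresholds: np.ndarray  # per-row threshold actually applied

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=bool)
        self.Z = np.asarray(self.Z, dtype=bool)
        if self.L.shape != self.Z.shape:
            raise ValueError("L and Z must have the same shape")


@dataclass(frozen=True)
class CoopCounts:
    """Triple counts of the three cooperative modes and their sign subtypes."""

    s1: int
    s2: int
    d: int
    s1_pos: int
    s1_neg: int
    s2_pos: int
    s2_neg: int
    d_pos: int
    d_neg: int
    n_triples: int

    def __post_init__(self):
        if self.s1_pos + self.s1_neg != self.s1:
            raise ValueError("s1 subtypes do not sum to s1")
        if self.s2_pos + self.s2_neg != self.s2:
            raise ValueError("s2 subtypes do not sum to s2")
        if self.d_pos + self.d_neg != self.d:
            raise ValueError("d subtypes do not sum to d")
        if self.s1 + self.d > self.n_triples or self.s2 + self.d > self.n_triples:
            raise ValueError("counts exceed the number of triples")

    def as_dict(self) -> dict:
        return {
            "s1": self.s1,
            "s2": self.s2,
            "d": self.d,
            "s1_pos": self.s1_pos,
            "s1_neg": self.s1_neg,
            "s2_pos": self.s2_pos,
            "s2_neg": self.s2_neg,
            "d_pos": self.d_pos,
            "d_neg": self.d_neg,
            "n_triples": self.n_triples,
        }


def row_threshold(row: np.ndarray, filter_spec: FilterSpec) -> float:
    """Per-row significance threshold computed on |values|.

    median — mean of the two central order statistics for an even count;
    mean — arithmetic mean; tertile/quartile — the smallest order statistic
    v with empirical CDF F(v) = rank/n ≥ 1/3 (resp. 1/4).
    """
    a = np.abs(np.asarray(row, dtype=float))
    if a.size == 0:
        raise ValueError("empty row")
    if filter_spec.method == "median":
        return float(np.median(a))
    if filter_spec.method == "mean":
        return float(a.mean())
    p = 1.0 / 3.0 if filter_spec.method == "tertile" else 0.25
    srt = np.sort(a)
    rank = math.ceil(p * a.size)  # smallest rank with rank/n ≥ p
    return float(srt[rank - 1])


def logic_pair(table: CorrelationTable, filter_spec: FilterSpec) -> LogicPair:
    """Significance matrix L = (|c_mn| > threshold_m) and sign matrix Z = (c ≥ 0)."""
    thresholds = np.array(
        [row_threshold(row, filter_spec) for row in table.values]
    )
    L = np.abs(table.values) > thresholds[:, None]
    Z = table.values >= 0
    return LogicPair(L, Z, thresholds)


def coop_counts(pair1: LogicPair, pair2: LogicPair) -> CoopCounts:
    """Count S1/S2/D triples and their sign subtypes.

    Every combination of a row of pair 1's matrices (a p¹ value), a row of
    pair 2's (p²), and a mode column is one triple; the direct triple loop
    below is the definition.
    """
    L1, Z1 = pair1.L, pair1.Z
    L2, Z2 = pair2.L, pair2.Z
    if L1.shape != L2.shape:
        raise ValueError("the two logic pairs must have identical dimensions")
    n_rows, n_modes = L1.shape
    s1 = s2 = d = s1_pos = s2_pos = d_pos = 0
    for m1 in range(n_rows):
        for m2 in range(n_rows):
            for n in range(n_modes):
                sig1, sig2 = L1[m1, n], L2[m2, n]
                if sig1 and not sig2:
                    s1 += 1
                    s1_pos += Z1[m1, n]
                elif sig2 and not sig1:
                    s2 += 1
                    s2_pos += Z2[m2, n]
                elif sig1 and sig2:
                    d += 1
                    d_pos += Z1[m1, n] == Z2[m2, n]
    n_triples = n_rows * n_rows * n_modes
    return CoopCounts(
        s1=s1,
        s2=s2,
        d=d,
        s1_pos=int(s1_pos),
        s1_neg=s1 - int(s1_pos),
        s2_pos=int(s2_pos),
        s2_neg=s2 - int(s2_pos),
        d_pos=int(d_pos),
        d_neg=d - int(d_pos),
        n_triples=n_triples,
    )


def significant_per_row(pair: LogicPair) -> list[int]:
    """Number of significant entries in each row (diagnostic for tied rows)."""
    return [int(r.sum()) for r in pair.L]
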