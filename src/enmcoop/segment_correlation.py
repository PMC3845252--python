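"""Maximal-correlation segment matching between two unequal-length curves.

Given the per-residue curves of two proteins of lengths x ≤ y in one mode,
the core statistic slides a window of λ residues over both curves and finds
the placement pair maximising the absolute Pearson correlation; the signed
correlation of that best pair is the table entry c_mn.  λ is parameterised
as a fraction p = λ/x of the shorter protein, over the grid
p = 1.0, 0.9, …, 0.5, and modes 7..16 give the columns — hence the 6×10
correlation table per protein pair.

Also here: the PCA condensation of a protein's 10 (noisy) rotation-angle
curves into a single first-principal-component curve, and the Fourier
magnitude transform used as an alternative angle-curve representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "SegmentMatch",
    "CorrelationTable",
    "CondensedCurve",
    "DEFAULT_P_GRID",
    "pearson",
    "best_segment_pair",
    "lambda_from_p",
    "correlation_table",
    "pc1_condense",
    "fourier_magnitude",
    "write_table_tsv",
]

DEFAULT_P_GRID = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)

#: |correlations| closer than this count as tied in the segment search, so
#: that floating-point noise cannot reorder mathematically equal windows
TIE_TOL = 1e-12


@dataclass(frozen=True)
class SegmentMatch:
    """Best λ-window placement on curves A and B with its signed correlation."""

    start_a: int
    start_b: int
    length: int
    correlation: float
    degenerate: bool = False

    def overlap(self, other_start: int, which: str = "a") -> int:
        """Overlap in positions with another window of the same length."""
        start = self.start_a if which == "a" else self.start_b
        return max(0, self.length - abs(start - other_start))


@dataclass
class CorrelationTable:
    """Signed best-segment correlations c_mn: rows p values, columns modes."""

    pair_id: int
    p_grid: tuple[float, ...]
    mode_numbers: tuple[int, ...]
    values: np.ndarray  # (len(p_grid), len(mode_numbers))
    matches: list[list[SegmentMatch]] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.p_grid), len(self.mode_numbers)):
            raise ValueError("values shape must match p grid × mode list")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("|c_mn| must not exceed 1")
        self.values = v


@dataclass(frozen=True)
class CondensedCurve:
    """A single curve standing in for a protein's 10 per-mode curves."""

    protein_id: str
    kind: str  # "pc1" | "fourier-magnitude"
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if self.kind == "fourier-magnitude" and np.any(v < 0):
            raise ValueError("Fourier magnitudes cannot be negative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation; 0 when either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D sequences of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        return 0.0
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def _window_matrix(curve: np.ndarray, lam: int):
    """Centered sliding windows and their norms: (n_win, λ), (n_win,)."""
    w = sliding_window_view(curve, lam).astype(float)
    wc = w - w.mean(axis=1, keepdims=True)
    return wc, np.linalg.norm(wc, axis=1)


def best_segment_pair(
    f1: Sequence[float], f2: Sequence[float], lam: int, search: str = "all"
) -> SegmentMatch:
    """Window pair of length λ with the largest |Pearson correlation|.

    ``search='all'`` (default) examines every start pair (i, j);
    ``search='shift'`` only slides one curve along the other, i.e. the
    window pairs (max(0, −ℓ), max(0, ℓ)) over all alignment lags ℓ.  Ties
    (|c| within ``TIE_TOL``) are broken by the smallest i, then the
    smallest j.  A window with zero variance contributes correlation 0 and
    marks the match degenerate.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    x = min(len(f1), len(f2))
    if not 2 <= lam <= x:
        raise ValueError(f"λ = {lam} outside valid range [2, {x}]")
    a, na = _window_matrix(f1, lam)
    b, nb = _window_matrix(f2, lam)
    denom = np.outer(na, nb)
    degenerate = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(degenerate, 0.0, (a @ b.T) / np.where(degenerate, 1.0, denom))
    corr = np.clip(corr, -1.0, 1.0)

    if search == "shift":
        n_a, n_b = corr.shape
        mask = np.ones_like(corr, dtype=bool)
        for lag in range(-(n_a - 1), n_b):
            mask[max(0, -lag), max(0, lag)] = False
        corr = np.where(mask, -np.inf, corr)  # excluded placements never win
        abs_corr = np.where(mask, -np.inf, np.abs(corr))
    elif search == "all":
        abs_corr = np.abs(corr)
    else:
        raise ValueError(f"unknown search mode {search!r}")

    # first (row-major) window within TIE_TOL of the maximum wins
    flat = int(np.argmax(abs_corr >= np.max(abs_corr) - TIE_TOL))
    i, j = divmod(flat, corr.shape[1])
    return SegmentMatch(
        start_a=int(i),
        start_b=int(j),
        length=lam,
        correlation=float(corr[i, j]),
        degenerate=bool(degenerate[i, j]),
    )


def lambda_from_p(p: float, x: int) -> int:
    """λ = round(p·x), half away from zero, clamped to [2, x]."""
    lam = int(np.floor(p * x + 0.5))
    return max(2, min(lam, x))


def correlation_table(
    curves_a: Sequence,
    curves_b: Sequence,
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    pair_id: int = 1,
    search: str = "all",
) -> CorrelationTable:
    """Assemble the p-by-mode table of best-segment correlations.

    ``curves_a``/``curves_b`` are the per-mode curves of the two proteins,
    aligned by position in the sequence; entries may be MagnitudeCurve /
    AngleCurve / CondensedCurve objects (their ``values`` are used, and mode
    numbers are taken from them when present) or plain arrays.
    """
    if len(curves_a) == 0 or len(curves_a) != len(curves_b):
        raise ValueError("need one curve per mode for both proteins")

    def _vals(c):
        return np.asarray(getattr(c, "values", c), dtype=float)

    def _mode(c, fallback):
        return int(getattr(c, "mode_number", fallback))

    arrs_a = [_vals(c) for c in curves_a]
    arrs_b = [_vals(c) for c in curves_b]
    len_a = {len(a) for a in arrs_a}
    len_b = {len(b) for b in arrs_b}
    if len(len_a) != 1 or len(len_b) != 1:
        raise ValueError("curves of one protein must share a length across modes")
    x = min(len_a.pop(), len_b.pop())
    mode_numbers = tuple(_mode(c, 7 + k) for k, c in enumerate(curves_a))

    values = np.empty((len(p_grid), len(curves_a)))
    matches: list[list[SegmentMatch]] = []
    for m, p in enumerate(p_grid):
        lam = lambda_from_p(p, x)
        row = []
        for n, (fa, fb) in enumerate(zip(arrs_a, arrs_b)):
            match = best_segment_pair(fa, fb, lam, search=search)
            values[m, n] = match.correlation
            row.append(match)
        matches.append(row)
    return CorrelationTable(pair_id, tuple(p_grid), mode_numbers, values, matches)


def pc1_condense(curves: Sequence, protein_id: str | None = None) -> CondensedCurve:
    """First-principal-component score curve of a stack of per-mode curves.

    Positions are observations (rows), modes variables (columns); columns
    are mean-centered and the length-L score series on the first principal
    axis is returned.  The sign is fixed so the condensed curve correlates
    non-negatively with the per-position mean of the input curves.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves to condense")
    cols = [np.asarray(getattr(c, "values", c), dtype=float) for c in curves]
    if len({len(c) for c in cols}) != 1:
        raise ValueError("curves must share one length")
    if len(cols[0]) < 2:
        raise ValueError("curves must have length ≥ 2")
    X = np.column_stack(cols)
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ValueError("zero total variance; nothing to condense")
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = u[:, 0] * s[0]
    mean_curve = X.mean(axis=1)
    if pearson(scores, mean_curve) < 0:
        scores = -scores
    if protein_id is None:
        protein_id = getattr(curves[0], "protein_id", "protein")
    return CondensedCurve(protein_id, "pc1", scores)


def fourier_magnitude(
    curve: Sequence[float], protein_id: str = "protein"
) -> CondensedCurve:
    """Unnormalised DFT magnitude of the full curve, DC bin included."""
    values = np.asarray(getattr(curve, "values", curve), dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 points")
    mags = np.abs(np.fft.fft(values))
    pid = getattr(curve, "protein_id", protein_id)
    return CondensedCurve(pid, "fourier-magnitude", mags)


def write_table_tsv(table: CorrelationTable, path: str | Path) -> None:
    """Serialise a table as TSV (rows p, columns modes, signed values).

    A companion ``<path>.matches.tsv`` lists (start_a, start_b, λ) per cell
    when matches were recorded.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("p\t" + "\t".join(f"mode_{n}" for n in table.mode_numbers) + "\n")
        for p, row in zip(table.p_grid, table.values):
            fh.write(f"{p:g}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    if table.matches is not None:
        with open(path.with_suffix(path.suffix + ".matches.tsv"), "w") as fh:
            fh.write("p\tmode\tstart_a\tstart_b\tlambda\tdegenerate\n")
            for p, row in zip(table.p_grid, table.matches):
                for n, m in zip(table.mode_numbers, row):
                    fh.write(
                        f"{p:g}\t{n}\t{m.start_a}\t{m.start_b}\t{m.length}"
                        f"\t{int(m.degenerate)}\n"
                    )
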