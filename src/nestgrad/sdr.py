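"""Similarity-difference-replacement (SDR) simplex decomposition.

For every pair of communities the comparison is split into three relativized
components that sum to one: similarity S, richness/abundance difference D,
and replacement R.  In the binary form, with a = shared species, b and c the
species unique to either community and n = a + b + c,

    S = a/n,    D = |b - c|/n,    R = 2 min(b, c)/n.

The abundance form replaces a, b, c by the Ruzicka components
A = sum_k min(x_k, y_k), B = sum_k max(x_k - y_k, 0), C = sum_k max(y_k - x_k, 0)
(so S is the Ruzicka index).  The complements 1-S (turnover), 1-D (agreement)
and 1-R (nestedness) are averaged over all pairs and reported as percentages;
because (1-S) + (1-D) + (1-R) = 2 per pair, the three percentages sum to 200.
This nestedness component is a different quantity from NODF/WNODF and the two
are not directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import logging

import numpy as np
import pandas as pd

from nestgrad.data import CommunityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SDRTriple:
    """One pair's similarity / difference / replacement; s + d + r = 1."""

    s: float
    d: float
    r: float


@dataclass
class SDRResult:
    """Pairwise SDR table plus mean percentage contributions.

    ``pct_turnover`` = mean(1-S) x 100, ``pct_agreement`` = mean(1-D) x 100,
    ``pct_nestedness`` = mean(1-R) x 100; the three sum to 200 (each pair's
    complements sum to 2).
    """

    pairs: pd.DataFrame  # columns: i, j, s, d, r
    pct_turnover: float
    pct_agreement: float
    pct_nestedness: float
    mode: str
    aggregate: str = "mean"


def sdr_binary_pair(x: Sequence[float], y: Sequence[float]) -> SDRTriple:
    """SDR components for one pair of presence/absence vectors."""
    xb = np.asarray(x, dtype=float) > 0
    yb = np.asarray(y, dtype=float) > 0
    if xb.shape != yb.shape:
        raise ValueError("vectors must have equal length")
    a = int((xb & yb).sum())
    b = int((xb & ~yb).sum())
    c = int((~xb & yb).sum())
    n = a + b + c
    if n == 0:
        raise ValueError("empty union: SDR undefined for two empty communities")
    return SDRTriple(s=a / n, d=abs(b - c) / n, r=2 * min(b, c) / n)


def sdr_abundance_pair(x: Sequence[float], y: Sequence[float]) -> SDRTriple:
    """SDR components for one pair of abundance vectors (Ruzicka family)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("vectors must have equal length")
    if (xa < 0).any() or (ya < 0).any():
        raise ValueError("abundances must be non-negative")
    a = float(np.minimum(xa, ya).sum())
    b = float(np.maximum(xa - ya, 0.0).sum())
    c = float(np.maximum(ya - xa, 0.0).sum())
    n = a + b + c
    if n == 0:
        raise ValueError("both vectors all-zero: SDR undefined")
    return SDRTriple(s=a / n, d=abs(b - c) / n, r=2 * min(b, c) / n)


def sdr_simplex(
    m: CommunityMatrix | np.ndarray,
    mode: Literal["binary", "abundance"] = "binary",
    aggregate: Literal["mean", "pooled"] = "mean",
) -> SDRResult:
    """SDR decomposition over all unordered column pairs of a community matrix.

    ``aggregate="mean"`` (default) averages the per-pair relativized indices;
    ``"pooled"`` instead relativizes the summed raw components over all pairs
    (ratio-of-sums).  Degenerate pairs (empty union) are excluded and logged.
    """
    cells = m.cells if isinstance(m, CommunityMatrix) else np.asarray(m, dtype=float)
    labels = m.col_labels if isinstance(m, CommunityMatrix) else [str(j) for j in range(cells.shape[1])]
    if cells.shape[1] < 2:
        raise ValueError("need at least 2 columns for pairwise SDR")
    pair_fn = sdr_binary_pair if mode == "binary" else sdr_abundance_pair
    rows = []
    raw_sums = np.zeros(3)  # pooled A, B, C
    for i in range(cells.shape[1]):
        for j in range(i + 1, cells.shape[1]):
            x, y = cells[:, i], cells[:, j]
            if mode == "binary":
                x, y = (x > 0).astype(float), (y > 0).astype(float)
            try:
                t = pair_fn(x, y)
            except ValueError:
                logger.warning("excluding degenerate pair (%s, %s)", labels[i], labels[j])
                continue
            rows.append({"i": labels[i], "j": labels[j], "s": t.s, "d": t.d, "r": t.r})
            raw_sums += (
                np.minimum(x, y).sum(),
                np.maximum(x - y, 0.0).sum(),
                np.maximum(y - x, 0.0).sum(),
            )
    if not rows:
        raise ValueError("no non-degenerate column pairs")
    pairs = pd.DataFrame(rows)
    if aggregate == "mean":
        s, d, r = pairs["s"].mean(), pairs["d"].mean(), pairs["r"].mean()
    elif aggregate == "pooled":
        a, b, c = raw_sums
        n = raw_sums.sum()
        s, d, r = a / n, abs(b - c) / n, 2 * min(b, c) / n
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return SDRResult(
        pairs=pairs,
        pct_turnover=100.0 * (1.0 - s),
        pct_agreement=100.0 * (1.0 - d),
        pct_nestedness=100.0 * (1.0 - r),
        mode=mode,
        aggregate=aggregate,
    )
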