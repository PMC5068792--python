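"""Community distances and permutation tests (PERMANOVA, Mantel).

These tests establish that the environmental gradient (soil pH) structures
the communities before any nestedness hypothesis is imposed: one-way and
two-way (crossed, balanced) PERMANOVA partition the squared inter-point
distances among factor levels and assess pseudo-F by permutation, and the
Mantel test correlates community dissimilarity with environmental distance
across sites.

Distances follow the conventions of the analyses they feed: Jaccard on
sample-level presence/absence (PERMANOVA), Morisita-Horn on pooled site
frequencies (Mantel), Ruzicka as the quantitative Jaccard analogue.  All
permutation p-values use the add-one correction (#extreme + 1)/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from nestgrad.data import CommunityMatrix


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with labels, zero diagonal enforced."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class PermanovaTerm:
    name: str
    df: int
    ss: float
    pseudo_f: float
    p: float


@dataclass
class PermanovaResult:
    terms: list[PermanovaTerm]
    df_residual: int
    ss_residual: float
    ss_total: float
    n_permutations: int
    seed: int | None

    def term(self, name: str) -> PermanovaTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t.name, "df": t.df, "ss": t.ss, "pseudo_f": t.pseudo_f, "p": t.p}
            for t in self.terms
        ]
        rows.append(
            {"term": "residual", "df": self.df_residual, "ss": self.ss_residual,
             "pseudo_f": np.nan, "p": np.nan}
        )
        return pd.DataFrame(rows)


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int | None
    tail: str = "two-sided"


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def jaccard_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """1 - a/(a+b+c) on presence/absence."""
    xb = np.asarray(x, dtype=float) > 0
    yb = np.asarray(y, dtype=float) > 0
    union = int((xb | yb).sum())
    if union == 0:
        raise ValueError("empty union: Jaccard distance undefined")
    return 1.0 - int((xb & yb).sum()) / union


def morisita_horn_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """1 - 2*sum(x_k y_k) / [(sum x_k^2/X^2 + sum y_k^2/Y^2) * X * Y]."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    X, Y = xa.sum(), ya.sum()
    if X <= 0 or Y <= 0:
        raise ValueError("zero total abundance: Morisita-Horn undefined")
    sim = 2.0 * float(xa @ ya) / (((xa**2).sum() / X**2 + (ya**2).sum() / Y**2) * X * Y)
    return float(np.clip(1.0 - sim, 0.0, 1.0))


def ruzicka_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """1 - sum(min)/sum(max) (quantitative Jaccard)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    denom = float(np.maximum(xa, ya).sum())
    if denom == 0:
        raise ValueError("both vectors all-zero: Ruzicka distance undefined")
    return 1.0 - float(np.minimum(xa, ya).sum()) / denom


_DISTANCES: dict[str, Callable] = {
    "jaccard": jaccard_distance,
    "morisita-horn": morisita_horn_distance,
    "ruzicka": ruzicka_distance,
}


def pairwise_distances(
    m: CommunityMatrix | np.ndarray,
    metric: Literal["jaccard", "morisita-horn", "ruzicka"] = "jaccard",
    axis: Literal["columns", "rows"] = "columns",
    labels: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Distance matrix over the columns (default) or rows of a community
    matrix; for ``axis="rows"`` each row is one observation vector (e.g. one
    sample's phylotype profile)."""
    cells = m.cells if isinstance(m, CommunityMatrix) else np.asarray(m, dtype=float)
    if axis == "columns":
        vectors = cells.T
        default_labels = m.col_labels if isinstance(m, CommunityMatrix) else None
    else:
        vectors = cells
        default_labels = m.row_labels if isinstance(m, CommunityMatrix) else None
    if labels is None:
        labels = default_labels or [str(i) for i in range(len(vectors))]
    fn = _DISTANCES[metric]
    n = len(vectors)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(vectors[i], vectors[j])
    return DistanceMatrix(labels=list(labels), values=d)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _ss_total(d2: np.ndarray) -> float:
    n = d2.shape[0]
    return float(np.triu(d2, k=1).sum()) / n


def _ss_within(d2: np.ndarray, codes: np.ndarray) -> float:
    """Sum over groups of (1/n_g) * sum of within-group squared distances."""
    ss = 0.0
    for g in np.unique(codes):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss += float(np.triu(sub, k=1).sum()) / len(idx)
    return ss


def _as_distance(d: DistanceMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(d, DistanceMatrix):
        return d.values, d.labels
    d = np.asarray(d, dtype=float)
    return d, [str(i) for i in range(d.shape[0])]


def permanova_oneway(
    d: DistanceMatrix | np.ndarray,
    groups: Sequence[str],
    n_perm: int | str = 9999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F = [(SS_total - SS_within)/(a-1)] /
    [SS_within/(N-a)], p by permutation of group labels.

    ``n_perm="exhaustive"`` enumerates every distinct relabeling instead of
    sampling (feasible for small designs); p is then the exact fraction of
    relabelings with F at least the observed.
    """
    values, _ = _as_distance(d)
    codes = pd.Categorical(list(groups)).codes
    N = values.shape[0]
    if len(codes) != N:
        raise ValueError("group labels must match distance matrix size")
    a = len(np.unique(codes))
    if a < 2:
        raise ValueError("need at least 2 groups")
    if N - a < 1:
        raise ValueError("no residual degrees of freedom")
    d2 = values**2
    sst = _ss_total(d2)

    def pseudo_f(c: np.ndarray) -> float:
        ssw = _ss_within(d2, c)
        if ssw == 0:
            return np.inf
        return ((sst - ssw) / (a - 1)) / (ssw / (N - a))

    f_obs = pseudo_f(codes)
    if n_perm == "exhaustive":
        import itertools

        perms = sorted(set(itertools.permutations(codes.tolist())))
        count = sum(pseudo_f(np.array(p)) >= f_obs for p in perms)
        p = count / len(perms)  # identity is one of the enumerated relabelings
        n_perm = len(perms)
        seed = None
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            if pseudo_f(rng.permutation(codes)) >= f_obs:
                count += 1
        p = (count + 1) / (n_perm + 1)
    ssw = _ss_within(d2, codes)
    return PermanovaResult(
        terms=[PermanovaTerm(name="groups", df=a - 1, ss=sst - ssw, pseudo_f=f_obs, p=p)],
        df_residual=N - a,
        ss_residual=ssw,
        ss_total=sst,
        n_permutations=n_perm,
        seed=seed,
    )


def permanova_twoway(
    d: DistanceMatrix | np.ndarray,
    factor_a: Sequence[str],
    factor_b: Sequence[str],
    n_perm: int = 9999,
    seed: int | None = None,
    names: tuple[str, str] = ("A", "B"),
) -> PermanovaResult:
    """Two-way crossed balanced PERMANOVA.

    The squared-distance partition gives SS for each main effect (among-level
    SS pooled by that factor), the interaction (among-cell SS minus the main
    effects), and the residual (within cells).  Each term's pseudo-F is its
    mean square against the residual mean square; p-values come from
    unrestricted permutation of the raw observations (rows of the distance
    matrix), recomputing every term per permutation.
    """
    values, _ = _as_distance(d)
    N = values.shape[0]
    ca = pd.Categorical(list(factor_a)).codes
    cb = pd.Categorical(list(factor_b)).codes
    if len(ca) != N or len(cb) != N:
        raise ValueError("factor labels must match distance matrix size")
    na, nb = len(np.unique(ca)), len(np.unique(cb))
    cells_code = ca * nb + cb
    counts = np.bincount(cells_code, minlength=na * nb)
    if len(np.unique(counts)) != 1 or (counts == 0).any():
        raise ValueError("two-way PERMANOVA requires a balanced crossed design")
    df_a, df_b = na - 1, nb - 1
    df_ab = df_a * df_b
    df_res = N - na * nb
    if df_res < 1:
        raise ValueError("no residual degrees of freedom (one observation per cell)")
    d2 = values**2
    sst = _ss_total(d2)

    def term_fs(perm: np.ndarray) -> tuple[float, float, float]:
        pa, pb, pc = ca[perm], cb[perm], cells_code[perm]
        ss_a = sst - _ss_within(d2, pa)
        ss_b = sst - _ss_within(d2, pb)
        ssw_cells = _ss_within(d2, pc)
        ss_cells = sst - ssw_cells
        ss_ab = ss_cells - ss_a - ss_b
        ms_res = ssw_cells / df_res
        if ms_res == 0:
            return np.inf, np.inf, np.inf
        return (ss_a / df_a) / ms_res, (ss_b / df_b) / ms_res, (ss_ab / df_ab) / ms_res

    identity = np.arange(N)
    f_a, f_b, f_ab = term_fs(identity)
    rng = np.random.default_rng(seed)
    counts_ge = np.zeros(3, dtype=int)
    for _ in range(n_perm):
        # permuting observation indices relabels rows/columns of d jointly,
        # i.e. permutes raw observations while factor layout stays fixed
        fs = term_fs(rng.permutation(N))
        counts_ge += np.asarray(fs) >= np.array([f_a, f_b, f_ab])
    p_a, p_b, p_ab = (counts_ge + 1) / (n_perm + 1)

    ss_a = sst - _ss_within(d2, ca)
    ss_b = sst - _ss_within(d2, cb)
    ssw_cells = _ss_within(d2, cells_code)
    ss_ab = (sst - ssw_cells) - ss_a - ss_b
    return PermanovaResult(
        terms=[
            PermanovaTerm(name=names[0], df=df_a, ss=ss_a, pseudo_f=f_a, p=float(p_a)),
            PermanovaTerm(name=names[1], df=df_b, ss=ss_b, pseudo_f=f_b, p=float(p_b)),
            PermanovaTerm(
                name=f"{names[0]} x {names[1]}", df=df_ab, ss=ss_ab,
                pseudo_f=f_ab, p=float(p_ab),
            ),
        ],
        df_residual=df_res,
        ss_residual=ssw_cells,
        ss_total=sst,
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


def mantel(
    d1: DistanceMatrix | np.ndarray,
    d2: DistanceMatrix | np.ndarray,
    n_perm: int | str = 9999,
    seed: int | None = None,
    tail: Literal["two-sided", "greater", "less"] = "two-sided",
) -> MantelResult:
    """Mantel test: Pearson r over the lower triangles of two distance
    matrices, p by permuting one matrix's labels (``n_perm="exhaustive"``
    enumerates all label permutations; feasible for few items)."""
    v1, l1 = _as_distance(d1)
    v2, l2 = _as_distance(d2)
    if isinstance(d1, DistanceMatrix) and isinstance(d2, DistanceMatrix):
        if l1 != l2:
            if set(l1) != set(l2):
                raise ValueError("distance matrices must share labels")
            order = [l2.index(l) for l in l1]
            v2 = v2[np.ix_(order, order)]
    n = v1.shape[0]
    if v2.shape[0] != n:
        raise ValueError("distance matrices must have the same size")
    if n < 4:
        raise ValueError("need at least 4 items for a Mantel test")
    iu = np.triu_indices(n, k=1)
    x = v1[iu]

    def corr(mat: np.ndarray) -> float:
        y = mat[iu]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("zero variance in a distance triangle")
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(v2)

    def extreme(r: float) -> bool:
        if tail == "greater":
            return r >= r_obs
        if tail == "less":
            return r <= r_obs
        return abs(r) >= abs(r_obs)

    if n_perm == "exhaustive":
        import itertools

        perms = list(itertools.permutations(range(n)))
        count = sum(extreme(corr(v2[np.ix_(p, p)])) for p in perms)
        return MantelResult(
            r=r_obs, p=count / len(perms), n_permutations=len(perms), seed=None, tail=tail
        )
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        count += extreme(corr(v2[np.ix_(perm, perm)]))
    return MantelResult(
        r=r_obs, p=(count + 1) / (n_perm + 1), n_permutations=n_perm, seed=seed, tail=tail
    )
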