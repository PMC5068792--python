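"""NODF/WNODF nestedness indices and fixed-fixed null-model tests.

NODF (nestedness metric based on overlap and decreasing fill) scores, for an
ordered pair of columns or rows, the percentage of the sparser vector's
presences that are shared with the denser one, zeroed when fill does not
strictly decrease along the imposed order.  WNODF is the quantitative
analogue: the percentage of the lighter vector's nonzero cells that are
*strictly* smaller than the corresponding cell of the heavier vector, zeroed
when the marginal total does not strictly decrease.

Unlike packing-based formulations that re-sort the matrix by marginal totals,
the orientation of every pair here follows the order the matrix is given in,
so that a hypothesis-imposed arrangement (columns by decreasing pH, rows by
phylotype occurrence) is what the index measures.  ``ordering="by_marginal_total"``
recovers the conventional maximally-packed form.

Significance is assessed against Monte-Carlo null ensembles: binary matrices
are randomized under the fixed-fixed constraint (row and column totals both
preserved) with the curveball trade algorithm (or checkerboard swaps);
quantitative matrices are randomized by shuffling the binary skeleton
fixed-fixed and then reallocating the observed positive values uniformly at
random over the occupied cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass
from typing import Iterator, Literal, Sequence

import numpy as np

from nestgrad.data import CommunityMatrix

logger = logging.getLogger(__name__)

Axis = Literal["columns", "rows", "both"]
Ordering = Literal["as_given", "by_marginal_total"]


@dataclass
class NestednessResult:
    """Observed index plus its Monte-Carlo null summary.

    ``z`` is ``(observed - null_mean) / null_sd`` (None when the null has zero
    spread); ``p_upper``/``p_lower`` use the add-one correction
    ``(#{null >= obs} + 1) / (n_null + 1)`` so finite sampling never reports
    p = 0.  A significantly positive Z indicates nestedness, a significantly
    negative Z anti-nestedness.
    """

    metric: str
    axis: str
    observed: float
    null_mean: float
    null_sd: float
    z: float | None
    p_upper: float
    p_lower: float
    n_null: int
    sampler: str
    seed: int | None

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Index computation
# ---------------------------------------------------------------------------


def paired_nodf(left: Sequence[float], right: Sequence[float]) -> float:
    """Paired NODF term for two binary vectors, ``left`` being the one placed
    earlier in the imposed order.

    Returns 0 unless fill strictly decreases (fill(right) < fill(left));
    otherwise 100 x (shared presences) / fill(right).
    """
    l = np.asarray(left, dtype=float)
    r = np.asarray(right, dtype=float)
    if l.shape != r.shape:
        raise ValueError("paired vectors must have equal length")
    fill_l = int((l > 0).sum())
    fill_r = int((r > 0).sum())
    if fill_r == 0:
        logger.debug("paired_nodf: empty right vector (degenerate pair)")
        return 0.0
    if fill_r >= fill_l:
        return 0.0
    shared = int(((l > 0) & (r > 0)).sum())
    return 100.0 * shared / fill_r


def paired_wnodf(left: Sequence[float], right: Sequence[float]) -> float:
    """Paired WNODF term for two non-negative vectors.

    Returns 0 unless the marginal total strictly decreases; otherwise
    100 x #{k : 0 < right_k < left_k} / #{k : right_k > 0}.  Cells where the
    two vectors tie at a positive value do not count as nested.
    """
    l = np.asarray(left, dtype=float)
    r = np.asarray(right, dtype=float)
    if l.shape != r.shape:
        raise ValueError("paired vectors must have equal length")
    nz = int((r > 0).sum())
    if nz == 0:
        logger.debug("paired_wnodf: empty right vector (degenerate pair)")
        return 0.0
    if r.sum() >= l.sum():
        return 0.0
    smaller = int(((r > 0) & (r < l)).sum())
    return 100.0 * smaller / nz


def _as_cells(m: CommunityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(m, CommunityMatrix):
        return m.cells
    return np.asarray(m, dtype=float)


def _pack(cells: np.ndarray) -> np.ndarray:
    """Sort rows and columns by marginal total, descending (stable)."""
    row_order = np.argsort(-cells.sum(axis=1), kind="stable")
    col_order = np.argsort(-cells.sum(axis=0), kind="stable")
    return cells[np.ix_(row_order, col_order)]


def _pairwise_mean(cells: np.ndarray, axis: Axis, paired) -> float:
    terms: list[float] = []
    if axis in ("columns", "both"):
        n = cells.shape[1]
        if n < 2 and axis == "columns":
            raise ValueError("need at least 2 columns")
        for i in range(n):
            for j in range(i + 1, n):
                terms.append(paired(cells[:, i], cells[:, j]))
    if axis in ("rows", "both"):
        n = cells.shape[0]
        if n < 2 and axis == "rows":
            raise ValueError("need at least 2 rows")
        for i in range(n):
            for j in range(i + 1, n):
                terms.append(paired(cells[i, :], cells[j, :]))
    if not terms:
        raise ValueError(f"no pairs along axis {axis!r}")
    return float(np.mean(terms))


def nodf(
    m: CommunityMatrix | np.ndarray,
    axis: Axis = "columns",
    ordering: Ordering = "as_given",
) -> float:
    """NODF over ordered pairs along the given axis, in [0, 100]."""
    cells = _as_cells(m)
    if isinstance(m, CommunityMatrix) and m.cell_kind != "presence":
        raise ValueError("nodf requires a presence/absence matrix")
    if not np.isin(cells, (0.0, 1.0)).all():
        raise ValueError("nodf requires a binary matrix")
    if ordering == "by_marginal_total":
        cells = _pack(cells)
    return _pairwise_mean(cells, axis, paired_nodf)


def wnodf(
    m: CommunityMatrix | np.ndarray,
    axis: Axis = "rows",
    ordering: Ordering = "as_given",
) -> float:
    """Weighted NODF over ordered pairs along the given axis, in [0, 100]."""
    cells = _as_cells(m)
    if isinstance(m, CommunityMatrix) and m.cell_kind == "presence":
        raise ValueError("wnodf requires a quantitative (count or abundance) matrix")
    if ordering == "by_marginal_total":
        cells = _pack(cells)
    return _pairwise_mean(cells, axis, paired_wnodf)


# ---------------------------------------------------------------------------
# Null models
# ---------------------------------------------------------------------------


def _has_checkerboard(rows: list[set[int]]) -> bool:
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            if rows[i] - rows[j] and rows[j] - rows[i]:
                return True
    return False


def sample_fixed_fixed(
    m: CommunityMatrix | np.ndarray,
    n: int,
    seed: int | np.random.Generator | None = None,
    algorithm: Literal["curveball", "swap"] = "curveball",
    burn_in: int | None = None,
    thin: int = 10,
) -> Iterator[np.ndarray]:
    """Yield ``n`` binary matrices with exactly the input's row and column
    sums, sampled from the fixed-fixed ensemble by a Markov chain.

    ``curveball`` trades random subsets of the symmetric difference between
    two rows' occupied-column sets; ``swap`` flips random 2x2 checkerboard
    submatrices (with rejection, hence also uniform).  Successive outputs are
    separated by ``thin`` attempted perturbations after a ``burn_in`` (default
    5 x max(n_rows, n_cols)) of attempted perturbations; counting attempts
    rather than acceptances keeps the chain's stationary distribution exactly
    uniform over the ensemble.
    """
    cells = _as_cells(m)
    if not np.isin(cells, (0.0, 1.0)).all():
        raise ValueError("fixed-fixed sampling requires a binary matrix")
    if (cells.sum(axis=1) == 0).any() or (cells.sum(axis=0) == 0).any():
        raise ValueError("matrix has an all-zero row or column")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R, C = cells.shape
    if burn_in is None:
        burn_in = 5 * max(R, C)

    rows = [set(np.flatnonzero(cells[i] > 0).tolist()) for i in range(R)]
    if not _has_checkerboard(rows):
        warnings.warn(
            "matrix admits no fixed-fixed perturbation; the ensemble is a "
            "singleton and every null sample equals the input",
            stacklevel=2,
        )
        for _ in range(n):
            yield cells.copy()
        return

    def rows_to_matrix() -> np.ndarray:
        out = np.zeros((R, C))
        for i, s in enumerate(rows):
            out[i, list(s)] = 1.0
        return out

    def curveball_step() -> bool:
        i, j = rng.choice(R, size=2, replace=False)
        a = list(rows[i] - rows[j])
        b = list(rows[j] - rows[i])
        if not a or not b:
            return False
        pool = a + b
        pick = rng.permutation(len(pool))[: len(a)]
        new_a = {pool[k] for k in pick}
        if new_a == set(a):
            return False
        common_i = rows[i] & rows[j]
        rows[i] = common_i | new_a
        rows[j] = (rows[j] - set(b)) | (set(pool) - new_a)
        return True

    def swap_step() -> bool:
        i, j = rng.choice(R, size=2, replace=False)
        k, l = rng.choice(C, size=2, replace=False)
        ik, il = k in rows[i], l in rows[i]
        jk, jl = k in rows[j], l in rows[j]
        if ik and jl and not il and not jk:
            rows[i].remove(k); rows[i].add(l)
            rows[j].remove(l); rows[j].add(k)
            return True
        if il and jk and not ik and not jl:
            rows[i].remove(l); rows[i].add(k)
            rows[j].remove(k); rows[j].add(l)
            return True
        return False

    # thin/burn_in count *attempted* perturbations: rejected attempts are the
    # self-loops that make the chain's transition matrix symmetric and its
    # stationary distribution exactly uniform over the fixed-fixed ensemble.
    step = curveball_step if algorithm == "curveball" else swap_step
    for _ in range(burn_in):
        step()
    for _ in range(n):
        for _ in range(thin):
            step()
        yield rows_to_matrix()


def sample_weighted_null(
    m: CommunityMatrix | np.ndarray,
    n: int,
    seed: int | np.random.Generator | None = None,
    scheme: Literal[
        "margins_fixed", "skeleton_shuffle", "cell_permute_within_rows"
    ] = "margins_fixed",
    burn_in: int | None = None,
    thin: int | None = None,
) -> Iterator[np.ndarray]:
    """Yield ``n`` randomized quantitative matrices.

    ``margins_fixed`` (default) samples uniformly from the non-negative
    integer matrices with exactly the input's row and column totals — the
    quantitative analogue of the binary fixed-fixed constraint — by a
    Markov chain of +/-1 transfers on random 2x2 submatrices (symmetric
    proposals with rejection, hence uniform).  Requires integer cells.

    ``skeleton_shuffle`` randomizes the binary skeleton fixed-fixed, then
    assigns the observed multiset of positive cell values uniformly at random
    to the occupied cells (value multiset and fill preserved; margins not).
    ``cell_permute_within_rows`` permutes each row's values across columns.
    """
    cells = _as_cells(m)
    if (cells < 0).any():
        raise ValueError("weighted null requires a non-negative matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if scheme == "cell_permute_within_rows":
        for _ in range(n):
            out = cells.copy()
            for i in range(out.shape[0]):
                out[i] = out[i][rng.permutation(out.shape[1])]
            yield out
        return
    if scheme == "skeleton_shuffle":
        values = cells[cells > 0]
        skeleton = (cells > 0).astype(float)
        ff_kwargs = {}
        if burn_in is not None:
            ff_kwargs["burn_in"] = burn_in
        if thin is not None:
            ff_kwargs["thin"] = thin
        for null_skel in sample_fixed_fixed(skeleton, n, seed=rng, **ff_kwargs):
            out = np.zeros(cells.shape, dtype=float)
            occ = np.flatnonzero(np.ascontiguousarray(null_skel).ravel() > 0)
            out.flat[occ] = rng.permutation(values)
            yield out
        return
    if scheme != "margins_fixed":
        raise ValueError(f"unknown scheme {scheme!r}")

    ints = np.rint(cells)
    if not np.allclose(cells, ints, atol=1e-9):
        raise ValueError(
            "margins_fixed requires an integer matrix (e.g. occurrence counts); "
            "for normalized matrices randomize the underlying counts and "
            "re-apply the normalization"
        )
    state = ints.astype(np.int64)
    R, C = state.shape
    if R < 2 or C < 2:
        raise ValueError("need at least a 2x2 matrix")
    if burn_in is None:
        burn_in = 20 * R * C
    if thin is None:
        thin = max(R * C, 10)

    def transfer() -> None:
        i, j = rng.choice(R, size=2, replace=False)
        k, l = rng.choice(C, size=2, replace=False)
        # +1 to (i,k),(j,l) and -1 to (i,l),(j,k); reject if any cell would go
        # negative; the reverse move has equal probability, so the stationary
        # law is uniform over the margin-constrained tables
        if state[i, l] > 0 and state[j, k] > 0:
            state[i, k] += 1
            state[j, l] += 1
            state[i, l] -= 1
            state[j, k] -= 1

    for _ in range(burn_in):
        transfer()
    for _ in range(n):
        for _ in range(thin):
            transfer()
        yield state.astype(float)


# ---------------------------------------------------------------------------
# Monte-Carlo significance
# ---------------------------------------------------------------------------


def nestedness_test(
    m: CommunityMatrix | np.ndarray,
    metric: Literal["nodf", "wnodf"] = "nodf",
    axis: Axis = "columns",
    n_null: int = 1000,
    seed: int | None = None,
    algorithm: Literal["curveball", "swap"] = "curveball",
    scheme: Literal[
        "margins_fixed", "skeleton_shuffle", "cell_permute_within_rows"
    ] = "margins_fixed",
    burn_in: int | None = None,
    thin: int | None = None,
    nulls: "Iterator[np.ndarray] | None" = None,
    sampler_label: str | None = None,
) -> NestednessResult:
    """Monte-Carlo test of a nestedness index against its null ensemble.

    The matrix must already be arranged per the gradient hypothesis (columns
    by pH, rows by occurrence); null matrices inherit the same arrangement
    because the samplers preserve row/column identity.  NODF uses the binary
    fixed-fixed null; WNODF uses by default the quantitative margins-fixed
    null (row and column totals of the count matrix preserved), matching the
    constraint family of the binary test.  ``nulls`` may supply a custom
    ensemble (e.g. margins-fixed counts pushed through the same normalization
    as the observed matrix).
    """
    cells = _as_cells(m)
    if metric == "nodf":
        index = lambda a: nodf(a, axis=axis, ordering="as_given")
        sampler = sampler_label or f"fixed_fixed/{algorithm}"
        if nulls is None:
            ff_kwargs = {} if burn_in is None else {"burn_in": burn_in}
            if thin is not None:
                ff_kwargs["thin"] = thin
            nulls = sample_fixed_fixed(
                cells, n_null, seed=seed, algorithm=algorithm, **ff_kwargs
            )
        observed = nodf(m, axis=axis, ordering="as_given")
    elif metric == "wnodf":
        index = lambda a: wnodf(a, axis=axis, ordering="as_given")
        sampler = sampler_label or f"weighted/{scheme}"
        if nulls is None:
            nulls = sample_weighted_null(
                cells, n_null, seed=seed, scheme=scheme, burn_in=burn_in, thin=thin
            )
        observed = wnodf(m, axis=axis, ordering="as_given")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    nulls_iter = nulls

    null_values = np.fromiter((index(a) for a in nulls_iter), dtype=float, count=n_null)
    null_mean = float(null_values.mean())
    null_sd = float(null_values.std(ddof=1)) if n_null > 1 else 0.0
    z = (observed - null_mean) / null_sd if null_sd > 0 else None
    p_upper = (int((null_values >= observed).sum()) + 1) / (n_null + 1)
    p_lower = (int((null_values <= observed).sum()) + 1) / (n_null + 1)
    return NestednessResult(
        metric=metric,
        axis=axis,
        observed=float(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p_upper=p_upper,
        p_lower=p_lower,
        n_null=n_null,
        sampler=sampler,
        seed=seed,
    )
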