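import numpy as np
import pytest

from nestgrad.data import CommunityMatrix, SampleRecord, SampleTable


@pytest.fixture
def toy_table() -> SampleTable:
    """Two sites, four samples, four phylotypes; acid site holds a subset."""
    rows = [
        # neutral site: all four phylotypes across two samples
        ("n1", "neutral", 7.0, "gen1", 3),
        ("n1", "neutral", 7.0, "gen2", 2),
        ("n1", "neutral", 7.0, "spec1", 4),
        ("n2", "neutral", 7.2, "gen1", 1),
        ("n2", "neutral", 7.2, "spec2", 5),
        # acidic site: generalists only
        ("a1", "acidic", 3.6, "gen1", 6),
        ("a1", "acidic", 3.6, "gen2", 1),
        ("a2", "acidic", 3.4, "gen1", 2),
    ]
    return SampleTable(
        records=[
            SampleRecord(sample_id=s, group_id=g, ph=ph, phylotype_id=p, clone_count=c)
            for s, g, ph, p, c in rows
        ]
    )


@pytest.fixture
def nested_matrix() -> CommunityMatrix:
    """Perfectly nested 3x3 presence matrix, columns rich -> poor."""
    return CommunityMatrix(
        row_labels=["p1", "p2", "p3"],
        col_labels=["g1", "g2", "g3"],
        cells=np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]], dtype=float),
        cell_kind="presence",
        col_gradient=np.array([7.0, 5.0, 3.0]),
        row_occurrence=np.array([3, 2, 1]),
    )


def brute_nodf(cells: np.ndarray, axis: str) -> float:
    """Independent NODF oracle: explicit loops over ordered pairs."""
    terms = []

    def pair(left, right):
        fl = sum(1 for v in left if v > 0)
        fr = sum(1 for v in right if v > 0)
        if fr == 0 or fr >= fl:
            return 0.0
        shared = sum(1 for a, b in zip(left, right) if a > 0 and b > 0)
        return 100.0 * shared / fr

    r, c = cells.shape
    if axis in ("columns", "both"):
        for i in range(c):
            for j in range(i + 1, c):
                terms.append(pair(cells[:, i], cells[:, j]))
    if axis in ("rows", "both"):
        for i in range(r):
            for j in range(i + 1, r):
                terms.append(pair(cells[i, :], cells[j, :]))
    return sum(terms) / len(terms)


def brute_wnodf(cells: np.ndarray, axis: str) -> float:
    """Independent WNODF oracle: explicit loops over ordered pairs."""
    terms = []

    def pair(left, right):
        nz = sum(1 for v in right if v > 0)
        if nz == 0 or sum(right) >= sum(left):
            return 0.0
        smaller = sum(1 for a, b in zip(left, right) if 0 < b < a)
        return 100.0 * smaller / nz

    r, c = cells.shape
    if axis in ("columns", "both"):
        for i in range(c):
            for j in range(i + 1, c):
                terms.append(pair(cells[:, i].tolist(), cells[:, j].tolist()))
    if axis in ("rows", "both"):
        for i in range(r):
            for j in range(i + 1, r):
                terms.append(pair(cells[i, :].tolist(), cells[j, :].tolist()))
    return sum(terms) / len(terms)
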