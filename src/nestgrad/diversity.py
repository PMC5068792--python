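"""Analytic rarefaction and phylotype pH-generality profiling.

Rarefaction is the classical hypergeometric formulation: for clone counts
N_1..N_S totalling N, the expected richness in a random subsample of n clones
(without replacement) is

    E[S_n] = sum_i (1 - q_i),   q_i = C(N - N_i, n) / C(N, n),

with variance

    Var[S_n] = sum_i q_i (1 - q_i)
             + 2 sum_{i<j} [ C(N - N_i - N_j, n) / C(N, n) - q_i q_j ].

Binomial coefficients are evaluated in log space so clone totals in the
thousands are safe.  The sampling-sufficiency criterion checks that the 95%
confidence half-width (1.96 sqrt(Var)) at a configurable point of the curve
(default: the penultimate subsample size, n = N - 1) is below a threshold
such as 0.4 phylotype.

Generality profiling summarizes, per phylotype, the soil-pH values of the
samples it occupied: the lowest pH measures acid tolerance and the standard
deviation of pH measures niche breadth; a negative correlation between the
two is the signature of acid-tolerant taxa being pH generalists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from nestgrad.data import SampleTable


@dataclass
class RarefactionCurve:
    """Expected richness, variance, and 95% CI half-width per subsample size."""

    n: np.ndarray
    expected_richness: np.ndarray
    variance: np.ndarray

    @property
    def ci95_halfwidth(self) -> np.ndarray:
        return 1.96 * np.sqrt(self.variance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.n,
                "expected_richness": self.expected_richness,
                "variance": self.variance,
                "ci95_halfwidth": self.ci95_halfwidth,
            }
        )


@dataclass(frozen=True)
class GeneralityProfile:
    """Per-phylotype occupancy summary along the pH gradient.

    ``sd_ph`` is defined only for phylotypes occupying at least two samples;
    inclusion in the generality correlation additionally requires
    ``n_samples_present`` at or above the configured minimum (default 3).
    """

    phylotype_id: str
    n_samples_present: int
    min_ph: float
    sd_ph: float | None
    in_correlation_set: bool


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _q(N: int, Ni: int, n: int) -> float:
    """P(species with Ni individuals absent from a subsample of n)."""
    if N - Ni < n:
        return 0.0
    return float(np.exp(_log_comb(N - Ni, n) - _log_comb(N, n)))


def rarefy(counts: Sequence[int], n: int) -> tuple[float, float]:
    """Expected richness and variance for a subsample of ``n`` clones."""
    counts = np.asarray(counts, dtype=int)
    if (counts <= 0).any():
        raise ValueError("counts must be positive integers")
    N = int(counts.sum())
    if not 1 <= n <= N:
        raise ValueError(f"subsample size {n} outside [1, {N}]")
    q = np.array([_q(N, Ni, n) for Ni in counts])
    expected = float((1.0 - q).sum())
    var = float((q * (1.0 - q)).sum())
    S = len(counts)
    for i in range(S):
        for j in range(i + 1, S):
            qij = _q(N, int(counts[i] + counts[j]), n)
            var += 2.0 * (qij - q[i] * q[j])
    return expected, max(var, 0.0)


def rarefaction_curve(counts: Sequence[int], step: int = 1) -> RarefactionCurve:
    """Rarefaction over the grid n = 1, 1+step, ... with the endpoint N always
    included."""
    counts = np.asarray(counts, dtype=int)
    N = int(counts.sum())
    if step < 1:
        raise ValueError("step must be >= 1")
    grid = list(range(1, N + 1, step))
    if grid[-1] != N:
        grid.append(N)
    ns = np.array(grid)
    exp = np.empty(len(ns))
    var = np.empty(len(ns))
    for k, n in enumerate(ns):
        exp[k], var[k] = rarefy(counts, int(n))
    return RarefactionCurve(n=ns, expected_richness=exp, variance=var)


def sufficiency_check(
    counts: Sequence[int],
    threshold: float = 0.4,
    at: Literal["penultimate"] | float = "penultimate",
) -> tuple[bool, float]:
    """Has sequencing depth made the rarefaction CI narrow enough?

    Evaluates the 95% CI half-width at the penultimate point (n = N - 1,
    default) or at a fraction ``at`` of N, and compares it to ``threshold``
    (phylotype units).  Returns (passed, half-width).
    """
    counts = np.asarray(counts, dtype=int)
    N = int(counts.sum())
    if N < 2:
        raise ValueError("need at least 2 clones")
    if at == "penultimate":
        n_eval = N - 1
    else:
        n_eval = max(1, min(N, int(round(float(at) * N))))
    _, var = rarefy(counts, n_eval)
    halfwidth = 1.96 * float(np.sqrt(var))
    return halfwidth <= threshold, halfwidth


# ---------------------------------------------------------------------------
# pH-generality profiling
# ---------------------------------------------------------------------------


def generality_profiles(
    table: SampleTable,
    min_occurrences: int = 3,
) -> list[GeneralityProfile]:
    """Per-phylotype lowest occupied pH and SD of occupied-sample pH.

    Every occupied phylotype gets a profile; ``in_correlation_set`` marks
    those meeting ``min_occurrences``.  SD uses the sample (n-1) denominator.
    """
    ph_by: dict[str, list[float]] = {}
    for rec in table.records:
        if rec.ph is None:
            raise ValueError(f"sample {rec.sample_id!r} has no pH value")
        ph_by.setdefault(rec.phylotype_id, []).append(rec.ph)
    profiles = []
    for pid, phs in ph_by.items():
        n = len(phs)
        profiles.append(
            GeneralityProfile(
                phylotype_id=pid,
                n_samples_present=n,
                min_ph=float(min(phs)),
                sd_ph=float(np.std(phs, ddof=1)) if n >= 2 else None,
                in_correlation_set=n >= min_occurrences,
            )
        )
    return profiles


def generality_correlation(
    profiles: Sequence[GeneralityProfile],
) -> tuple[float, float, int]:
    """Pearson correlation of pH niche breadth (sd_ph) against acid tolerance
    (min_ph) over the profiles in the correlation set.

    Returns (r, two-sided p from the t distribution with n-2 df, n).  A
    significantly negative r means more acid-tolerant phylotypes span wider
    pH ranges, i.e. are generalists.
    """
    eligible = [p for p in profiles if p.in_correlation_set and p.sd_ph is not None]
    if len(eligible) < 3:
        raise ValueError("need at least 3 eligible profiles for a correlation")
    x = np.array([p.min_ph for p in eligible])
    y = np.array([p.sd_ph for p in eligible])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in min_ph or sd_ph")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(eligible)
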