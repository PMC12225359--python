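"""Group summaries and Mann-Whitney U comparison of pooled transition
probabilities.

Window-level transition probabilities from all records of a group are
pooled into one sample per transition type, summarised by mean and
sample SD, and two groups are compared per transition with a two-sided
Mann-Whitney U rank-sum test.  Pooled samples contain many exact 0s and
1s, so tie handling is explicit throughout: midranks, the tie-corrected
variance, and a continuity correction in the normal approximation.
Small samples are compared by exact enumeration of all label
assignments, which remains valid under ties.

The A-row samples of a group are pointwise complements (P_AA = 1 - P_AN
window by window, both defined in exactly the same windows), so the
report necessarily shows mean(A->A) + mean(A->N) = 1, equal SDs, and
identical p-values for the two rows of a row pair; likewise for the N
row.  Overlapping windows also make the pooled samples autocorrelated;
the test treats them as independent by construction (see the package
methods note for the resulting caveat on p-value calibration).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import EmptySeriesWarning, ValidationError
from .markov import TABLE_ORDER, Transition, WindowEstimates

__all__ = [
    "TransitionSummary",
    "MannWhitneyResult",
    "GroupComparison",
    "summarize",
    "mann_whitney_u",
    "compare_groups",
    "comparison_frame",
]

#: `auto` mode uses exact enumeration when the smaller sample has at most
#: this many observations ...
EXACT_MAX_MIN_N = 8
#: ... and the number of label assignments C(n_x + n_y, min) is at most this.
EXACT_MAX_ASSIGNMENTS = 200_000


@dataclass(frozen=True)
class TransitionSummary:
    """Mean / sample-SD / n of one group's pooled probability sample."""

    transition: Transition | None
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class MannWhitneyResult:
    """U statistic of the first sample and the two-sided p-value."""

    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal_approximation"


@dataclass(frozen=True)
class GroupComparison:
    """One report row: a transition compared between two groups."""

    transition: Transition
    u_statistic: float
    p_value: float
    summary_a: TransitionSummary
    summary_b: TransitionSummary
    method: str

    @property
    def computable(self) -> bool:
        return self.method != "not_computable"


def summarize(
    samples: Sequence[float] | np.ndarray,
    transition: Transition | None = None,
) -> TransitionSummary:
    """Arithmetic mean and sample SD (denominator n-1) of a pooled sample.

    An empty sample yields NaN markers with a warning; a single
    observation has a defined mean but NaN SD.
    """
    arr = np.asarray(samples, dtype=float)
    n = int(arr.size)
    if n == 0:
        warnings.warn(
            "empty probability sample; summary is undefined",
            EmptySeriesWarning,
            stacklevel=2,
        )
        return TransitionSummary(transition, float("nan"), float("nan"), 0)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n > 1 else float("nan")
    return TransitionSummary(transition, mean, sd, n)


def _u_from_ranks(ranks_x: np.ndarray, n_x: int) -> float:
    return float(ranks_x.sum() - n_x * (n_x + 1) / 2.0)


def _exact_two_sided(pooled_ranks: np.ndarray, n_x: int, u_obs: float) -> float:
    """Exact two-sided p by enumerating every assignment of group labels.

    All C(n, n_x) subsets of the pooled midranks are equally likely under
    the null; the p-value is the fraction whose U lies at least as far
    from the null mean n_x*n_y/2 as the observed U.  Valid under ties.
    """
    n = pooled_ranks.size
    n_y = n - n_x
    mu = n_x * n_y / 2.0
    dev_obs = abs(u_obs - mu)
    count = 0
    total = 0
    offset = n_x * (n_x + 1) / 2.0
    for idx in itertools.combinations(range(n), n_x):
        u = pooled_ranks[list(idx)].sum() - offset
        # small tolerance: midranks are multiples of 0.5, exact in float
        if abs(u - mu) >= dev_obs - 1e-9:
            count += 1
        total += 1
    return count / total


def _approx_two_sided(
    pooled: np.ndarray, pooled_ranks: np.ndarray, n_x: int, u_obs: float
) -> float:
    """Normal approximation with tie-corrected variance and continuity
    correction."""
    n = pooled.size
    n_y = n - n_x
    mu = n_x * n_y / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    sigma2 = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # every pooled value identical
        return 1.0
    numer = max(abs(u_obs - mu) - 0.5, 0.0)
    z = numer / math.sqrt(sigma2)
    return float(min(1.0, 2.0 * norm.sf(z)))


def mann_whitney_u(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    mode: str = "auto",
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    ``u_statistic`` is the U of ``x`` (so U_x + U_y = n_x * n_y).  In
    ``auto`` mode the exact null distribution is enumerated when the
    smaller sample has at most ``EXACT_MAX_MIN_N`` observations and the
    enumeration stays below ``EXACT_MAX_ASSIGNMENTS`` subsets; otherwise
    the tie-corrected, continuity-corrected normal approximation is
    used.  ``mode`` may force ``"exact"`` or ``"approx"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ValidationError(f"unknown mode {mode!r}")

    n_x, n_y = int(x.size), int(y.size)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks for ties
    u_obs = _u_from_ranks(ranks[:n_x], n_x)

    if mode == "exact":
        use_exact = True
    elif mode == "approx":
        use_exact = False
    else:
        use_exact = (
            min(n_x, n_y) <= EXACT_MAX_MIN_N
            and math.comb(n_x + n_y, min(n_x, n_y)) <= EXACT_MAX_ASSIGNMENTS
        )

    if use_exact:
        p = _exact_two_sided(ranks, n_x, u_obs)
        return MannWhitneyResult(u_obs, p, "exact")
    p = _approx_two_sided(pooled, ranks, n_x, u_obs)
    return MannWhitneyResult(u_obs, p, "normal_approximation")


def _pool(group: Iterable[WindowEstimates], transition: Transition) -> np.ndarray:
    vectors = [np.asarray(we.samples.get(transition, ()), dtype=float) for we in group]
    if not vectors:
        return np.empty(0)
    return np.concatenate(vectors) if vectors else np.empty(0)


def compare_groups(
    group_a: Sequence[WindowEstimates],
    group_b: Sequence[WindowEstimates],
    mode: str = "auto",
) -> list[GroupComparison]:
    """Compare two groups per transition type (rows in table order
    A to N, A to A, N to A, N to N).

    Window-level probabilities are pooled across all records of each
    group; each transition gets its own summary pair and two-sided
    Mann-Whitney p-value.  A transition with an empty pooled sample in
    either group is reported as not computable (NaN statistics) without
    affecting the other rows.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValidationError("each group needs at least one record")
    rows: list[GroupComparison] = []
    for t in TABLE_ORDER:
        xa = _pool(group_a, t)
        xb = _pool(group_b, t)
        if xa.size == 0 or xb.size == 0:
            warnings.warn(
                f"transition {t.label}: empty pooled sample in one group; "
                "row not computable",
                EmptySeriesWarning,
                stacklevel=2,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", EmptySeriesWarning)
                sa, sb = summarize(xa, t), summarize(xb, t)
            rows.append(
                GroupComparison(t, float("nan"), float("nan"), sa, sb, "not_computable")
            )
            continue
        res = mann_whitney_u(xa, xb, mode=mode)
        rows.append(
            GroupComparison(
                t,
                res.u_statistic,
                res.p_value,
                summarize(xa, t),
                summarize(xb, t),
                res.method,
            )
        )
    return rows


def comparison_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Tabulate comparison rows (one per transition) as a DataFrame."""
    return pd.DataFrame(
        {
            "transition": [c.transition.label for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
            "mean_a": [c.summary_a.mean for c in comparisons],
            "mean_b": [c.summary_b.mean for c in comparisons],
            "sd_a": [c.summary_a.sd for c in comparisons],
            "sd_b": [c.summary_b.sd for c in comparisons],
            "n_a": [c.summary_a.n for c in comparisons],
            "n_b": [c.summary_b.n for c in comparisons],
            "u_statistic": [c.u_statistic for c in comparisons],
            "method": [c.method for c in comparisons],
        }
    )
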