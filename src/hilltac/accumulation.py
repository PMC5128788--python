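"""Smoothed taxa-accumulation curves, read subsampling and stability scoring.

A taxa-accumulation curve (TAC) tracks the diversity of the pooled community
as samples are added; smoothing averages the curve over random sample
orderings so it does not depend on the arbitrary order samples were taken.
Accumulation pools raw read counts before computing the Hill number — the
curve approaches the gamma diversity of the whole study, not the mean of
per-sample values.

Read-depth analysis asks the complementary question: at a fixed community,
how many reads are enough for a stable diversity estimate?  Reads are
subsampled without replacement (multivariate hypergeometric), a grid of
depths is scanned, and a stability criterion declares the first depth at
which the curve has flattened.  Rare-insensitive orders (a >= 1) stabilize at
depths where raw richness is still climbing, which is the practical payoff of
the Hill framework for undersampled communities.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.special import gammaln

from .diversity_core import hill_number
from .io_tables import CommunityTable

logger = logging.getLogger(__name__)

__all__ = [
    "AccumulationCurve",
    "DepthAnalysisResult",
    "StabilityResult",
    "smoothed_tac",
    "expected_richness_tac",
    "subsample_reads",
    "expected_rarefied_richness",
    "depth_analysis",
    "default_depth_grid",
    "stability_score",
]

DEFAULT_N_PERM = 100
DEFAULT_REPS = 10
DEFAULT_WINDOW_FRAC = 0.1
DEFAULT_TOL = 0.02
#: Depth grids span a 16-fold range ending at the full read total by default.
DEFAULT_DEPTH_SPAN = 16
DEFAULT_N_DEPTHS = 8


@dataclass(frozen=True)
class AccumulationCurve:
    """Mean +/- spread of a diversity measure as accumulation proceeds.

    ``steps`` counts accumulated samples (sample-based TACs) or reads
    (depth curves); ``sd`` is the across-permutation standard deviation.
    """

    order_a: float
    steps: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_perm: int

    def __post_init__(self) -> None:
        steps = np.asarray(self.steps)
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if not (steps.shape == mean.shape == sd.shape) or steps.ndim != 1:
            raise ValueError("steps, mean and sd must be 1-D of equal length")
        if np.any(np.diff(steps) <= 0):
            raise ValueError("steps must be strictly increasing")
        if (sd < 0).any():
            raise ValueError("sd must be non-negative")
        object.__setattr__(self, "steps", steps)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)


class StabilityResult(NamedTuple):
    reached: bool
    at_step: int | None


def _check_positive_samples(table: CommunityTable) -> None:
    sums = table.sample_sums()
    if (sums == 0).any():
        empty = [s for s, n in zip(table.sample_ids, sums) if n == 0]
        raise ValueError(
            f"samples with zero reads are not analyzable: {empty}; "
            "drop them or pool before building curves"
        )


def smoothed_tac(
    table: CommunityTable,
    a: float,
    n_perm: int = DEFAULT_N_PERM,
    seed=0,
    exhaustive: bool = False,
) -> AccumulationCurve:
    """Smoothed taxa-accumulation curve for Hill order ``a``.

    For each k = 1..n_samples, the curve value is the average over sample
    orderings of ``hill_number`` applied to the pooled counts of the first k
    samples.  ``exhaustive=True`` enumerates all orderings (feasible only for
    small tables) instead of drawing ``n_perm`` random ones.
    """
    if table.n_samples < 2:
        raise ValueError(
            "smoothed_tac needs >= 2 samples; for a single sample use "
            "depth_analysis to accumulate reads instead"
        )
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _check_positive_samples(table)

    n = table.n_samples
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    values = np.empty((len(perms), n))
    for r, perm in enumerate(perms):
        cum = np.cumsum(table.counts[:, perm], axis=1)
        for k in range(n):
            values[r, k] = hill_number(cum[:, k], a)
    return AccumulationCurve(
        order_a=float(a),
        steps=np.arange(1, n + 1),
        mean=values.mean(axis=0),
        sd=values.std(axis=0, ddof=0),
        n_perm=len(perms),
    )


def _log_comb(n, k):
    """log C(n, k) elementwise, -inf where k > n."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(k > n, -np.inf, out)


def expected_richness_tac(table: CommunityTable) -> np.ndarray:
    """Analytic expectation of the a = 0 TAC (sample-based rarefaction).

    With T samples and taxon i present in t_i of them, the expected richness
    after pooling k uniformly chosen samples is
    ``sum_i [1 - C(T - t_i, k) / C(T, k)]``.  This closed form exists only
    for richness; it is the exact mean of the Monte-Carlo smoothed curve.
    """
    t_i = (table.counts > 0).sum(axis=1)
    t_i = t_i[t_i > 0]
    T = table.n_samples
    ks = np.arange(1, T + 1)
    # absent-in-all-k probability per taxon and k
    log_p = _log_comb((T - t_i)[:, None], ks[None, :]) - _log_comb(T, ks)[None, :]
    return (1.0 - np.exp(log_p)).sum(axis=0)


def subsample_reads(
    counts, depth: int, seed=0, method: str = "hypergeometric"
) -> np.ndarray:
    """Randomly subsample a fixed number of reads from an abundance vector.

    The default draws without replacement (multivariate hypergeometric on the
    counts), matching what subsampling a sequencing library means; the result
    sums to ``depth`` exactly.  ``method="multinomial"`` resamples reads with
    replacement from the observed proportions and is the only way to request
    ``depth > N``.
    """
    arr = np.asarray(counts)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("abundance vector must be non-empty and 1-D")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.array_equal(arr, np.round(arr)):
            raise ValueError("subsampling requires integer read counts")
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise ValueError("abundance vector contains negative counts")
    total = int(arr.sum())
    if total == 0:
        raise ValueError("abundance vector sums to zero")
    depth = int(depth)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    if method == "hypergeometric":
        if depth > total:
            raise ValueError(
                f"cannot draw {depth} reads without replacement from {total}; "
                "use method='multinomial' to resample beyond the observed depth"
            )
        return rng.multivariate_hypergeometric(arr, depth).astype(np.int64)
    if method == "multinomial":
        return rng.multinomial(depth, arr / total).astype(np.int64)
    raise ValueError(f"unknown method {method!r}")


def expected_rarefied_richness(counts, depth: int) -> float:
    """Closed-form expected richness of a ``depth``-read subsample.

    Hypergeometric rarefaction: ``E[S_d] = sum_i [1 - C(N - n_i, d) / C(N, d)]``
    over taxa with ``n_i > 0``.  Serves as the independent check on
    :func:`subsample_reads`.
    """
    arr = np.asarray(counts, dtype=np.int64)
    n_i = arr[arr > 0]
    total = int(n_i.sum())
    depth = int(depth)
    if not 0 < depth <= total:
        raise ValueError(f"depth must be in 1..{total}, got {depth}")
    log_p = _log_comb(total - n_i, depth) - _log_comb(total, depth)
    return float((1.0 - np.exp(log_p)).sum())


def default_depth_grid(
    n_reads: int,
    n_depths: int = DEFAULT_N_DEPTHS,
    span: float = DEFAULT_DEPTH_SPAN,
) -> np.ndarray:
    """Log-spaced subsampling depths ending at the full read total.

    ``n_depths`` depths from ``n_reads / span`` to ``n_reads`` — a 16-fold,
    8-point grid by default (25,000..400,000 for a 400k-read study).
    """
    if n_reads < n_depths:
        raise ValueError(f"need at least {n_depths} reads for the default grid")
    depths = np.unique(
        np.round(
            np.exp(np.linspace(math.log(n_reads / span), math.log(n_reads), n_depths))
        ).astype(np.int64)
    )
    return depths[depths >= 1]


@dataclass(frozen=True)
class DepthAnalysisResult:
    """Replicate diversity values over a depth grid, per Hill order.

    ``values[a]`` is a (reps x len(depths)) matrix; every entry at depth d is
    computed from exactly d subsampled reads.  ``stability_depth[a]`` is the
    smallest depth satisfying the stability criterion, or ``None`` when the
    curve never flattens on the grid.
    """

    depths: np.ndarray
    orders: tuple[float, ...]
    values: dict[float, np.ndarray]
    stability_depth: dict[float, int | None]
    reps: int
    window_frac: float
    tol: float

    def mean_curve(self, a: float) -> np.ndarray:
        return self.values[float(a)].mean(axis=0)


def depth_analysis(
    counts,
    depths=None,
    orders=(0.0, 1.0, 2.0),
    reps: int = DEFAULT_REPS,
    seed=0,
    window_frac: float = DEFAULT_WINDOW_FRAC,
    tol: float = DEFAULT_TOL,
) -> DepthAnalysisResult:
    """Subsample a community over a depth grid and score curve stability.

    For each depth, ``reps`` independent subsamples are drawn and every
    requested Hill order is evaluated on each; the stability criterion
    (:func:`stability_score`) is then applied to each order's mean curve.
    """
    arr = np.asarray(counts, dtype=np.int64)
    total = int(arr.sum())
    if depths is None:
        depths = default_depth_grid(total)
    depths = np.asarray(depths, dtype=np.int64)
    if depths.ndim != 1 or depths.size == 0:
        raise ValueError("depths must be a non-empty 1-D sequence")
    if np.any(np.diff(depths) <= 0):
        raise ValueError("depths must be strictly ascending")
    if reps < 2:
        raise ValueError("reps must be >= 2")
    orders = tuple(float(a) for a in orders)

    rng = np.random.default_rng(seed)
    values = {a: np.empty((reps, depths.size)) for a in orders}
    for j, depth in enumerate(depths):
        for r in range(reps):
            sub = subsample_reads(arr, int(depth), seed=rng)
            for a in orders:
                values[a][r, j] = hill_number(sub, a)

    stability: dict[float, int | None] = {}
    for a in orders:
        reached, at_step = stability_score(
            depths, values[a].mean(axis=0), window_frac=window_frac, tol=tol
        )
        stability[a] = int(at_step) if reached else None
    return DepthAnalysisResult(
        depths=depths,
        orders=orders,
        values=values,
        stability_depth=stability,
        reps=reps,
        window_frac=window_frac,
        tol=tol,
    )


def stability_score(
    steps,
    mean,
    window_frac: float = DEFAULT_WINDOW_FRAC,
    tol: float = DEFAULT_TOL,
) -> StabilityResult:
    """First step at which an accumulation curve has flattened.

    Step ``s`` is declared stable when, over the trailing window from ``s`` up
    to the first grid point at least ``window_frac`` of the full step range
    beyond ``s``, the maximum relative change from the value at ``s`` is
    ``<= tol``.  Snapping the window end to the next available grid point
    keeps every non-final step eligible on sparse (e.g. log-spaced) grids.
    The final step has nothing ahead of it and can never be declared stable.
    """
    steps = np.asarray(steps, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if steps.shape != mean.shape or steps.ndim != 1:
        raise ValueError("steps and mean must be 1-D of equal length")
    if steps.size < 3:
        raise ValueError("need at least 3 curve points to assess stability")
    if not 0 < window_frac < 1:
        raise ValueError("window_frac must be in (0, 1)")
    if tol <= 0:
        raise ValueError("tol must be positive")
    window = window_frac * (steps[-1] - steps[0])
    for i in range(steps.size - 1):
        target = steps[i] + window
        ahead = np.nonzero(steps >= target)[0]
        ahead = ahead[ahead > i]
        if ahead.size == 0:
            break  # later anchors only have shorter look-aheads
        j = int(ahead[0])
        if mean[i] == 0:
            continue
        rel = np.max(np.abs(mean[i + 1 : j + 1] - mean[i])) / abs(mean[i])
        if rel <= tol:
            return StabilityResult(True, int(round(steps[i])))
    return StabilityResult(False, None)
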