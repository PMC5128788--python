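"""Hill numbers and classical richness/coverage estimators.

The Hill number of order ``a`` is the effective number of taxa

    N_a = (sum_i p_i^a) ** (1 / (1 - a)),        a != 1,

the reciprocal generalized mean of the proportional abundances ``p_i``.  Its
special cases anchor the profile: ``N_0`` is observed richness, ``N_1`` the
exponential of Shannon entropy (continuity limit at a = 1), ``N_2`` the
reciprocal Simpson concentration.  Raising ``a`` progressively discounts rare
taxa, which is what makes the profile useful for hyperdiverse, undersampled
communities: low orders chase the rare tail that sequencing never exhausts,
high orders converge with modest read depth.

Orders a < 1 are supported but amplify rare-taxon uncertainty; estimates there
should be read with the same caution as raw richness.

An "abundance vector" throughout this package is a 1-D array of per-taxon
read counts for one community (one sample, or a pool of samples).  Zero
entries are legal and ignored by every statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "hill_number",
    "hill_profile",
    "HillProfile",
    "chao1",
    "goods_coverage",
    "frequency_counts",
    "diversity_summary",
]

#: Orders within this distance of 1 are routed to the entropy limit to avoid
#: the floating-point blow-up of the 1/(1-a) exponent.
ORDER_ONE_GUARD = 1e-6

DEFAULT_ORDERS = (0.0, 1.0, 2.0)


def _as_counts(counts, *, require_integer: bool = False) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"abundance vector must be 1-D, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("abundance vector is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("abundance vector contains non-finite values")
    if (arr < 0).any():
        raise ValueError("abundance vector contains negative counts")
    if require_integer and not np.array_equal(arr, np.round(arr)):
        raise ValueError("this estimator requires integer read counts")
    if arr.sum() == 0:
        raise ValueError("abundance vector sums to zero")
    return arr


def hill_number(counts, a: float) -> float:
    """Hill number ``N_a`` of one abundance vector.

    ``a = 0`` returns observed richness exactly (as a float); orders within
    ``ORDER_ONE_GUARD`` of 1 use the exponential-Shannon limit.
    """
    arr = _as_counts(counts)
    if not np.isfinite(a):
        raise ValueError("order a must be finite")
    if a < 0:
        raise ValueError(f"order a must be >= 0, got {a}")
    p = arr[arr > 0]
    if a == 0:
        return float(p.size)
    p = p / p.sum()
    if abs(a - 1.0) < ORDER_ONE_GUARD:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**a) ** (1.0 / (1.0 - a)))


@dataclass(frozen=True)
class HillProfile:
    """Diversity values ``N_a`` over a grid of orders ``a``."""

    orders: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        orders = np.asarray(self.orders, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if orders.shape != values.shape or orders.ndim != 1:
            raise ValueError("orders and values must be 1-D of equal length")
        object.__setattr__(self, "orders", orders)
        object.__setattr__(self, "values", values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"order_a": self.orders, "hill_number": self.values})


def hill_profile(counts, orders=DEFAULT_ORDERS) -> HillProfile:
    """Evaluate the Hill profile over ascending orders ``a >= 0``."""
    orders = np.asarray(orders, dtype=float)
    if orders.ndim != 1 or orders.size == 0:
        raise ValueError("orders must be a non-empty 1-D sequence")
    if np.any(np.diff(orders) < 0):
        raise ValueError("orders must be sorted ascending")
    values = np.array([hill_number(counts, a) for a in orders])
    return HillProfile(orders=orders, values=values)


def frequency_counts(counts) -> dict[int, int]:
    """Tally ``F_k``: the number of taxa observed exactly ``k`` times (k >= 1)."""
    arr = _as_counts(counts, require_integer=True).astype(np.int64)
    ks, fs = np.unique(arr[arr > 0], return_counts=True)
    return {int(k): int(f) for k, f in zip(ks, fs)}


def chao1(counts) -> float:
    """Chao1 estimated richness.

    Classic form ``S_obs + F1^2 / (2 F2)`` when doubletons exist; when
    ``F2 = 0`` the bias-corrected form ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))``
    is used instead (the classic ratio is undefined there).
    """
    arr = _as_counts(counts, require_integer=True).astype(np.int64)
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    logger.info(
        "chao1: F2 = 0 (F1 = %d), using bias-corrected form S_obs + F1(F1-1)/2",
        f1,
    )
    return s_obs + f1 * (f1 - 1) / 2.0


def goods_coverage(counts) -> float:
    """Good's coverage ``1 - F1 / N``.

    The estimated probability that one more read belongs to an
    already-observed taxon; the standard "sampling completeness" of a
    sequencing library.
    """
    arr = _as_counts(counts, require_integer=True).astype(np.int64)
    f1 = int((arr == 1).sum())
    return 1.0 - f1 / arr.sum()


def diversity_summary(table, orders=DEFAULT_ORDERS, include_pooled: bool = True):
    """Per-sample (and pooled) diversity table.

    One row per sample with ``N`` (reads), ``S_obs``, the Hill numbers for
    each requested order, Chao1, Good's coverage and the singleton/doubleton
    tallies.  Samples with zero reads are rejected: pool or drop them first.
    """
    from .io_tables import CommunityTable, pool_samples  # cycle-free import

    if not isinstance(table, CommunityTable):
        raise TypeError("diversity_summary expects a CommunityTable")
    rows = []
    vectors = [(sid, table.counts[:, j]) for j, sid in enumerate(table.sample_ids)]
    if include_pooled:
        vectors.append(("pooled", pool_samples(table)))
    for name, vec in vectors:
        if vec.sum() == 0:
            raise ValueError(
                f"sample {name!r} has zero reads; drop it before analysis"
            )
        fk = frequency_counts(vec)
        row = {
            "sample_id": name,
            "N": int(vec.sum()),
            "S_obs": int((vec > 0).sum()),
        }
        for a in orders:
            row[f"N_{a:g}"] = hill_number(vec, a)
        row["chao1"] = chao1(vec)
        row["goods_coverage"] = goods_coverage(vec)
        row["F1"] = fk.get(1, 0)
        row["F2"] = fk.get(2, 0)
        rows.append(row)
    return pd.DataFrame(rows)
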