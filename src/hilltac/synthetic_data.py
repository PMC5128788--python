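"""Synthetic hyperdiverse communities and multi-sample sequencing studies.

Real soil 16S surveys combine three statistical features this generator
emulates: a heavy-tailed taxon-abundance distribution (log-normal or Zipf)
with thousands of taxa, sampling-by-sequencing (a multinomial draw of reads
from the true proportions, so rare taxa are seen once, twice or never), and
multi-sample designs with tens of samples at fixed per-sample depth.

Two presets bracket the regimes of interest:

* ``amazon_like`` — deeply sequenced: log-normal TAD (sigma = 2), 5,000
  taxa, 66 samples x 6,000 reads (~400k reads total);
* ``texas_like`` — shallowly sequenced: Zipf TAD (gamma = 1.1), 5,000 taxa,
  36 samples x 860 reads (~31k reads total).

The generator does not simulate sequencing error (chimeras, homopolymer
artifacts inflating singletons), so synthetic rare tails are "real" taxa by
construction — see docs/methods.md for what that implies about tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_tables import CommunityTable

logger = logging.getLogger(__name__)

__all__ = [
    "CommunitySpec",
    "make_community",
    "sample_reads",
    "make_study",
    "amazon_like",
    "texas_like",
]

_TADS = ("lognormal", "zipf", "uniform")


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of one true community.

    ``S`` true taxa with relative abundances drawn from the named TAD:
    ``lognormal`` uses (mu, sigma) on the log scale, ``zipf`` decays as
    rank**(-gamma), ``uniform`` gives equal shares.  ``seed`` fixes the
    log-normal draw; Zipf and uniform TADs are deterministic in rank.
    """

    S: int
    tad: str = "lognormal"
    mu: float = 0.0
    sigma: float = 2.0
    gamma: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError(f"S must be >= 1, got {self.S}")
        if self.tad not in _TADS:
            raise ValueError(f"tad must be one of {_TADS}, got {self.tad!r}")
        if self.tad == "lognormal" and self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.tad == "zipf" and self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")


def make_community(spec: CommunitySpec) -> np.ndarray:
    """True relative abundances (descending, summing to 1) for a spec."""
    if spec.tad == "uniform":
        probs = np.full(spec.S, 1.0 / spec.S)
    elif spec.tad == "zipf":
        weights = np.arange(1, spec.S + 1, dtype=float) ** (-spec.gamma)
        probs = weights / weights.sum()
    else:  # lognormal
        rng = np.random.default_rng(spec.seed)
        abund = rng.lognormal(mean=spec.mu, sigma=spec.sigma, size=spec.S)
        abund = np.sort(abund)[::-1]
        probs = abund / abund.sum()
    return probs


def sample_reads(probs, depth: int, seed=0) -> np.ndarray:
    """Multinomial draw of ``depth`` reads from true proportions.

    Models sampling-by-sequencing: each read lands on taxon i with
    probability ``p_i``, independently; the result sums to ``depth``.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or probs.size == 0:
        raise ValueError("probs must be a non-empty 1-D vector")
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(
            f"probs must be non-negative and sum to 1 (got sum {probs.sum()!r})"
        )
    depth = int(depth)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.multinomial(depth, probs).astype(np.int64)


def make_study(
    spec: CommunitySpec,
    n_samples: int,
    depth_per_sample: int,
    overdispersion: float = 0.0,
    seed=0,
) -> CommunityTable:
    """Simulate a multi-sample study as a :class:`CommunityTable`.

    Every sample is a multinomial draw of ``depth_per_sample`` reads.  With
    ``overdispersion > 0`` each sample's proportions are first jittered by a
    Dirichlet draw with concentration ``probs / overdispersion`` — a
    Dirichlet-multinomial-style between-sample variance whose strength grows
    with the parameter (0 means identical expected proportions everywhere).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if overdispersion < 0:
        raise ValueError("overdispersion must be >= 0")
    probs = make_community(spec)
    rng = np.random.default_rng(seed)
    counts = np.empty((spec.S, n_samples), dtype=np.int64)
    for j in range(n_samples):
        p_j = probs
        if overdispersion > 0:
            p_j = rng.dirichlet(probs / overdispersion)
        counts[:, j] = rng.multinomial(int(depth_per_sample), p_j)
    width = max(5, len(str(spec.S)))
    taxon_ids = tuple(f"OTU{i + 1:0{width}d}" for i in range(spec.S))
    sample_ids = tuple(f"S{j + 1:03d}" for j in range(n_samples))
    return CommunityTable(taxon_ids=taxon_ids, sample_ids=sample_ids, counts=counts)


def amazon_like(seed: int = 0, overdispersion: float = 0.0) -> CommunityTable:
    """Deeply sequenced log-normal preset: 5,000 taxa, 66 x 6,000 reads."""
    spec = CommunitySpec(S=5000, tad="lognormal", mu=0.0, sigma=2.0, seed=seed)
    return make_study(spec, n_samples=66, depth_per_sample=6000,
                      overdispersion=overdispersion, seed=seed + 1)


def texas_like(seed: int = 0, overdispersion: float = 0.0) -> CommunityTable:
    """Shallowly sequenced Zipf preset: 5,000 taxa, 36 x 860 reads."""
    spec = CommunitySpec(S=5000, tad="zipf", gamma=1.1, seed=seed)
    return make_study(spec, n_samples=36, depth_per_sample=860,
                      overdispersion=overdispersion, seed=seed + 1)
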