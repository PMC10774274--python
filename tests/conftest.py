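"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (per-base boolean masks, exhaustive
enumeration) and independent of the implementation paths they check.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from clipfoot.idr import MatchedPeakPairs
from clipfoot.intervals import GenomicInterval, IntervalSet

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

CHROM_LEN = 10_000


# ---------------------------------------------------------------------------
# per-base boolean-mask oracles
# ---------------------------------------------------------------------------

def mask_of(intervals, length: int = CHROM_LEN, chrom: str = "chr1"):
    m = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            m[iv.start:iv.end] = True
    return m


def mask_to_intervals(mask, chrom: str = "chr1") -> list[GenomicInterval]:
    """Maximal runs of True, as intervals."""
    out = []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def random_interval_set(rng, n: int, chrom: str = "chr1",
                        length: int = CHROM_LEN, max_width: int = 200,
                        scored: bool = False) -> IntervalSet:
    ivs = []
    for _ in range(n):
        w = int(rng.integers(1, max_width))
        s = int(rng.integers(0, length - w))
        score = float(rng.random() * 100) if scored else None
        ivs.append(GenomicInterval(chrom, s, s + w, score=score))
    return IntervalSet(ivs)


# ---------------------------------------------------------------------------
# copula-mixture pair simulator (independent of clipfoot.simulate)
# ---------------------------------------------------------------------------

def simulate_score_pairs(n: int, pi1: float, rho: float, mu: float,
                         sd: float, seed: int) -> MatchedPeakPairs:
    """Matched score pairs drawn directly from the two-component model:
    with probability pi1 a correlated bivariate signal draw, otherwise
    independent standard normals; scores reported as exp(latent)."""
    rng = np.random.default_rng(seed)
    sig = rng.random(n) < pi1
    shared = rng.standard_normal(n)
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    z1 = np.where(sig, mu + sd * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * e1),
                  rng.standard_normal(n))
    z2 = np.where(sig, mu + sd * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * e2),
                  rng.standard_normal(n))
    regions = [GenomicInterval("chr1", 10 * i, 10 * i + 5) for i in range(n)]
    return MatchedPeakPairs(regions, np.exp(z1), np.exp(z2),
                            list(range(n)), list(range(n)))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
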