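"""Shared fixtures, strategies and independent oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def proportion_vectors(min_n: int = 3, max_n: int = 12):
    """Hypothesis strategy for valid proportion vectors (not all-zero)."""
    return (
        st.integers(min_value=min_n, max_value=max_n)
        .flatmap(
            lambda n: st.lists(
                st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                min_size=n,
                max_size=n,
            )
        )
        .map(np.asarray)
        .filter(lambda v: v.sum() > 1e-6)
        .map(lambda v: v / v.sum())
    )


def compositions(units: int, bins: int):
    """All probability vectors with `units` equal atoms over `bins` categories."""
    for c in itertools.combinations_with_replacement(range(bins), units):
        yield np.bincount(np.array(c), minlength=bins) / units


def gini_pairwise(p: np.ndarray) -> float:
    """Brute-force oracle: normalised pairwise mean absolute difference,
    scaled so the singleton attains 1."""
    n = len(p)
    return float(np.abs(p[:, None] - p[None, :]).sum() / (2 * (n - 1)))


def li_bruteforce(p: np.ndarray, median_cat: int) -> int:
    """Independent Location Index oracle enumerating every (bin, radius) pair."""
    n = len(p)
    scores = []
    for b in range(1, n + 1):
        total = 0.0
        for r in range(n):
            lo, hi = max(1, b - r), min(n, b + r)
            total += p[lo - 1 : hi].sum()
        scores.append(total)
    best = max(scores)
    cands = [b for b in range(1, n + 1) if np.isclose(scores[b - 1], best, atol=1e-12)]
    return min(cands, key=lambda b: (abs(b - median_cat), b))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
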