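"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from hrvtrial import CohortSpec, gen_cohort


def oracle_percussion_rate(a, b, m, s):
    """Exhaustive triple-loop percussion rate, written independently here.

    Enumerates every window start, compares the two windows element by
    element, and counts exact matches; used as the ground truth for the
    vectorized implementation.
    """
    a = list(a)
    b = list(b)
    n = len(a)
    n_windows = n - m - s + 1
    assert n_windows >= 1
    count = 0
    for i in range(n_windows):
        ok = True
        for j in range(m):
            if a[i + j] != b[i + s + j]:
                ok = False
        if ok:
            count += 1
    return count / n_windows


def oracle_match_count(a, b, m, s, n_windows):
    """Raw match count over a fixed window-index range."""
    count = 0
    for i in range(n_windows):
        if all(a[i + j] == b[i + s + j] for j in range(m)):
            count += 1
    return count


@pytest.fixture(scope="session")
def default_cohort():
    """One fixed synthetic cohort at the study's design values."""
    return gen_cohort(CohortSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
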