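"""Shared fixtures and the independent naive SAW oracle used against the
optimized lattice enumerator."""

from __future__ import annotations

import numpy as np
import pytest

# Independent brute-force oracle for diamond-lattice self-avoiding walks.
# Written as plain recursion over dict-based sites, deliberately sharing no
# code with kisfold.lattice; the only admissible shortcut is the exact
# parity/distance bound (it never changes a count).

_VECS = ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1))


def naive_neighbors(site):
    sign = -1 if site[0] % 2 else 1
    return [tuple(c + sign * v for c, v in zip(site, vec)) for vec in _VECS]


def naive_count_walks(start, end, n_steps, obstacles=frozenset()):
    """Count SAWs of exactly n_steps bonds from start to end, recursively."""

    def rec(site, steps_left, visited):
        dist = max(abs(a - b) for a, b in zip(site, end))
        if dist > steps_left or (dist - steps_left) % 2 != 0:
            return 0
        if steps_left == 0:
            return 1 if site == end else 0
        total = 0
        for nb in naive_neighbors(site):
            if nb in visited or nb in obstacles:
                continue
            total += rec(nb, steps_left - 1, visited | {nb})
        return total

    return rec(start, n_steps, frozenset([start]))


def naive_count_free(n_steps):
    """Count all SAWs of n_steps bonds from the origin (no symmetry use)."""

    def rec(site, steps_left, visited):
        if steps_left == 0:
            return 1
        total = 0
        for nb in naive_neighbors(site):
            if nb not in visited:
                total += rec(nb, steps_left - 1, visited | {nb})
        return total

    return rec((0, 0, 0), n_steps, frozenset([(0, 0, 0)]))


def random_lattice_site(rng: np.random.Generator, span: int = 6):
    """A uniform random diamond-lattice site near the origin."""
    while True:
        base = rng.integers(-span, span + 1, size=3)
        for cand in ((base // 2) * 2, (base // 2) * 2 + 1):
            site = tuple(int(c) for c in cand)
            x, y, z = site
            if x % 2 == 0 and (x + y + z) % 4 == 0:
                return site
            if x % 2 != 0 and (x + y + z) % 4 == 3:
                return site


@pytest.fixture(scope="session")
def published_table():
    from kisfold.entropy import load_published_table

    return load_published_table()


@pytest.fixture(scope="session")
def nn_table():
    from kisfold.energetics import load_nn_table

    return load_nn_table()


@pytest.fixture(scope="session")
def two_minimum_fixture():
    from kisfold.fixtures import generate_fixture

    return generate_fixture("two_minimum_dimer", seed=0)
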