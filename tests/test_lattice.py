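"""Diamond-lattice self-avoiding-walk engine: oracle equivalence and
structural invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kisfold import lattice as lat
from tests.conftest import (
    naive_count_free,
    naive_count_walks,
    random_lattice_site,
)


class TestLatticeStructure:
    def test_every_site_has_four_equidistant_neighbors(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            site = random_lattice_site(rng)
            nbrs = lat.DiamondLattice.neighbors(site)
            assert len(nbrs) == 4
            dists = {
                sum((a - b) ** 2 for a, b in zip(site, nb)) for nb in nbrs
            }
            assert dists == {3}
            for nb in nbrs:
                assert lat.DiamondLattice.is_site(nb)
                assert lat.DiamondLattice.sublattice(nb) != lat.DiamondLattice.sublattice(site)

    def test_neighbor_relation_is_symmetric(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            site = random_lattice_site(rng)
            for nb in lat.DiamondLattice.neighbors(site):
                assert site in lat.DiamondLattice.neighbors(nb)


class TestFreeCoil:
    def test_one_step_walk_equals_coordination_number(self):
        assert lat.count_free_walks(1) == 4

    def test_two_steps_no_immediate_reversal(self):
        # 4 first bonds x 3 continuations: self-avoidance forbids reversal
        assert lat.count_free_walks(2) == 12

    @pytest.mark.parametrize("n_steps", [2, 3, 4, 5, 6, 7, 8])
    def test_counts_match_naive_enumeration(self, n_steps):
        assert lat.count_free_walks(n_steps) == naive_count_free(n_steps)

    def test_enumerate_free_coil_uses_two_bonds_per_nt(self):
        cc = lat.enumerate_free_coil(1)
        assert cc.n_conformations == lat.count_free_walks(2) == 12
        assert cc.ln_omega == pytest.approx(math.log(12))
        assert cc.symmetry_factor == lat.FREE_COIL_SYMMETRY_FACTOR == 12

    def test_cap_is_an_explicit_error(self):
        with pytest.raises(lat.EnumerationCapError):
            lat.enumerate_free_coil(13)
        with pytest.raises(lat.EnumerationCapError):
            lat.free_coil_series(40)

    def test_growth_is_asymptotically_linear_and_window_stable(self):
        series = lat.free_coil_series(8)
        n = np.array(sorted(series))
        ln = np.log([series[k] for k in n])
        slope_lo = np.polyfit(n[1:6], ln[1:6], 1)[0]
        slope_hi = np.polyfit(n[3:8], ln[3:8], 1)[0]
        assert slope_lo == pytest.approx(slope_hi, abs=0.05)


class TestAnchoredLoops:
    def test_adjacent_anchors_one_step(self):
        start = (0, 0, 0)
        end = (1, 1, 1)
        assert lat.count_anchored_walks(start, end, 1).n_conformations == 1

    def test_cannot_return_to_origin_in_two_steps(self):
        cc = lat.count_anchored_walks((0, 0, 0), (0, 0, 0), 2)
        assert cc.n_conformations == 0
        assert cc.ln_omega == float("-inf")

    def test_parity_incompatible_anchors_return_zero_with_note(self):
        # odd step count between same-sublattice anchors is impossible
        cc = lat.count_anchored_walks((0, 0, 0), (0, 2, 2), 3)
        assert cc.n_conformations == 0
        assert cc.note is not None

    def test_oracle_equivalence_on_random_cases(self):
        rng = np.random.default_rng(202)
        for _ in range(40):
            n_nt = int(rng.integers(1, 5))
            start = random_lattice_site(rng, span=3)
            end = random_lattice_site(rng, span=3)
            obstacles = frozenset(
                random_lattice_site(rng, span=4) for _ in range(rng.integers(0, 8))
            ) - {start, end}
            got = lat.enumerate_anchored_loop(start, end, n_nt, obstacles)
            want = naive_count_walks(start, end, 2 * n_nt, obstacles)
            assert got.n_conformations == want

    def test_adding_obstacles_never_increases_the_count(self):
        rng = np.random.default_rng(303)
        start = (0, 0, 0)
        end = (0, 2, 2)
        obstacles: set = set()
        prev = lat.count_anchored_walks(start, end, 8).n_conformations
        for _ in range(10):
            obstacles.add(random_lattice_site(rng, span=3))
            obstacles -= {start, end}
            cur = lat.count_anchored_walks(start, end, 8, obstacles).n_conformations
            assert cur <= prev
            prev = cur

    def test_counts_invariant_under_point_group(self):
        # joint coordinate permutation+sign flips that preserve the lattice:
        # even permutations with an even number of sign flips
        rng = np.random.default_rng(404)
        perms = [(0, 1, 2), (1, 2, 0), (2, 0, 1)]
        flips = [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]

        def transform(site, perm, flip):
            return tuple(flip[k] * site[perm[k]] for k in range(3))

        for _ in range(10):
            start = random_lattice_site(rng, span=3)
            end = random_lattice_site(rng, span=3)
            obstacles = frozenset(
                random_lattice_site(rng, span=3) for _ in range(4)
            ) - {start, end}
            base = lat.count_anchored_walks(start, end, 6, obstacles).n_conformations
            perm = perms[rng.integers(len(perms))]
            flip = flips[rng.integers(len(flips))]
            got = lat.count_anchored_walks(
                transform(start, perm, flip),
                transform(end, perm, flip),
                6,
                frozenset(transform(o, perm, flip) for o in obstacles),
            ).n_conformations
            assert got == base

    def test_first_anchored_walk_is_valid_and_deterministic(self):
        start, end = (0, 0, 0), (0, 2, 2)
        w1 = lat.first_anchored_walk(start, end, 4)
        w2 = lat.first_anchored_walk(start, end, 4)
        assert w1 is not None
        assert w1.sites == w2.sites
        w1.validate()
        assert len(w1) == 4


class TestSnap:
    def test_point_on_a_site_snaps_to_it(self):
        lattice = lat.DiamondLattice()
        for site in [(0, 0, 0), (1, 1, 1), (0, 2, 2), (-1, -1, 1)]:
            assert lat.snap_to_lattice(lattice.to_cartesian(site)) == site

    def test_midpoint_tie_breaks_lexicographically(self):
        lattice = lat.DiamondLattice()
        a, b = (0, 0, 0), (1, 1, 1)
        mid = 0.5 * (lattice.to_cartesian(a) + lattice.to_cartesian(b))
        assert lat.snap_to_lattice(mid) == min(a, b)

    def test_snap_minimizes_distance_over_local_brute_force(self):
        rng = np.random.default_rng(55)
        lattice = lat.DiamondLattice()
        for _ in range(300):
            p = rng.uniform(-12, 12, size=3)
            site = lat.snap_to_lattice(p)
            best = np.linalg.norm(lattice.to_cartesian(site) - p)
            # exhaustive search over a generous local neighbourhood
            u = p / lattice.unit
            base = np.floor(u).astype(int)
            for dx in range(-3, 5):
                for dy in range(-3, 5):
                    for dz in range(-3, 5):
                        cand = (base[0] + dx, base[1] + dy, base[2] + dz)
                        if not lat.DiamondLattice.is_site(tuple(int(c) for c in cand)):
                            continue
                        d = np.linalg.norm(np.asarray(cand) * lattice.unit - p)
                        assert best <= d + 1e-9

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.tuples(
            st.floats(-20, 20, allow_nan=False),
            st.floats(-20, 20, allow_nan=False),
            st.floats(-20, 20, allow_nan=False),
        ),
        st.sampled_from([0, 1]),
    )
    def test_parity_restricted_snap_returns_requested_sublattice(self, p, parity):
        site = lat.snap_to_lattice(np.array(p), parity=parity)
        assert lat.DiamondLattice.sublattice(site) == parity
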