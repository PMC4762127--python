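"""Two-strand partition functions, landscapes, and melting: closed-form
two-state checks and oracle equivalence of the exhaustive enumerator."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import brentq

from kisfold import ensemble as ENS
from kisfold.constants import KB_KCAL_PER_MOL_K, kbt
from kisfold.energetics import stem_enthalpy_entropy
from kisfold.structure import pairs_cross

CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


# ---------------------------------------------------------------------------
# Independent brute-force pair-set oracle
# ---------------------------------------------------------------------------


def oracle_pair_sets(seqs, min_helix=2, min_hairpin=3):
    """All valid pair sets by direct matching enumeration + validation."""
    flat = "".join(seqs)
    n = len(flat)
    boundary = len(seqs[0]) if len(seqs) == 2 else n

    def strand(i):
        return 0 if i < boundary else 1

    def ok_pair(i, j):
        if (flat[i], flat[j]) not in CANONICAL:
            return False
        if strand(i) == strand(j) and j - i - 1 < min_hairpin:
            return False
        return True

    results = set()

    def valid(pairs):
        ps = set(pairs)
        # helix decomposition: maximal stacked runs
        runs = []
        for (i, j) in pairs:
            if (i - 1, j + 1) in ps:
                continue
            run = []
            a, b = i, j
            while (a, b) in ps:
                run.append((a, b))
                a, b = a + 1, b - 1
            runs.append(run)
        if any(len(r) < min_helix for r in runs):
            return False
        for r in runs:  # a run must keep one strand signature
            sig = {(strand(i), strand(j)) for i, j in r}
            if len(sig) != 1:
                return False
        crossings = [
            (x, y)
            for x, y in itertools.combinations(range(len(runs)), 2)
            if pairs_cross(runs[x][0], runs[y][0])
        ]
        if crossings:
            common = set(crossings[0])
            for c in crossings[1:]:
                common &= set(c)
            if not common:
                return False
        return True

    def rec(pos, pairs, used):
        if pos == n:
            if valid(pairs):
                results.add(frozenset(pairs))
            return
        if pos in used:
            rec(pos + 1, pairs, used)
            return
        rec(pos + 1, pairs, used)  # leave unpaired
        for j in range(pos + 1, n):
            if j in used or not ok_pair(pos, j):
                continue
            rec(pos + 1, pairs + [(pos, j)], used | {pos, j})

    rec(0, [], frozenset())
    return results


class TestEnumerationOracle:
    @pytest.mark.parametrize(
        "seqs",
        [
            ("GGGAAAACCC",),
            ("GGCAAAAGCC",),
            ("GGAAGG", "CCAACC"),
            ("GCGAAA", "AAACGC"),
            ("GGAAACC", "GGAACC"),
        ],
    )
    def test_enumerator_matches_brute_force_pair_sets(self, seqs):
        got = {
            frozenset(s.structure.pairs)
            for s in ENS.enumerate_structures(*seqs)
        }
        want = oracle_pair_sets(seqs)
        assert got == want

    def test_no_complementary_stretch_gives_only_the_open_state(self):
        states = ENS.enumerate_structures("AAA", "AAA")
        assert len(states) == 1
        assert states[0].structure.pairs == ()
        assert states[0].energy(310.15) == 0.0

    def test_single_duplex_toy_is_two_state_with_hand_checked_energy(self, nn_table):
        states = ENS.enumerate_structures("GG", "CC")
        dbns = sorted(s.structure.to_dotbracket() for s in states)
        assert dbns == ["((&))", "..&.."]
        duplex = next(s for s in states if s.structure.pairs)
        dh, ds = stem_enthalpy_entropy("GG", "CC", nn_table)
        # the bimolecular initiation is priced by dG_init, not the stack sum
        assert duplex.dh == pytest.approx(dh - nn_table.init[0])
        assert duplex.energy(310.15) == pytest.approx(nn_table.stack("GG/CC")[1])

    def test_length_cap_is_an_explicit_error(self):
        with pytest.raises(ValueError, match="cap"):
            ENS.enumerate_structures("A" * 16, "A" * 16)


class TestAssociation:
    def test_reference_concentration_recovers_dg_init(self):
        p = ENS.EnsembleParams(c_total=4.0)
        assert ENS.associate_free_energy(p) == pytest.approx(4.1, abs=1e-12)

    def test_dilute_worked_example(self):
        p = ENS.EnsembleParams(c_total=4e-6, temperature=310.15)
        expected = 4.1 - kbt(310.15) * math.log(1e-6)
        assert ENS.associate_free_energy(p) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(12.62, abs=0.01)

    def test_monotone_decreasing_in_concentration(self):
        vals = [
            ENS.associate_free_energy(ENS.EnsembleParams(c_total=c))
            for c in np.logspace(-9, 0, 25)
        ]
        assert all(b < a for a, b in zip(vals, vals[1:]))


class TestPartitionFunctions:
    def test_empty_bound_ensemble_reduces_to_the_two_state_closed_form(self):
        ens = ENS.DimerEnsemble.build("AAA", "AAA")
        p = ENS.EnsembleParams(c_total=1e-3)
        ps = ENS.partition_functions(ens, p)
        x = math.exp(-ps.dg_associate / kbt(p.temperature))
        assert ps.q1 == ps.q2 == ps.q12 == 1.0
        assert ps.bound_fraction == pytest.approx(x / (1 + x), rel=1e-9)

    @pytest.mark.parametrize("include_unpaired", [True, False])
    def test_single_duplex_matches_the_analytic_formula(self, include_unpaired):
        ens = ENS.DimerEnsemble.build("GG", "CC")
        p = ENS.EnsembleParams(c_total=1e-4, include_unpaired_associated=include_unpaired)
        ps = ENS.partition_functions(ens, p)
        duplex = next(s for s in ens.dimer if s.structure.pairs)
        bt = kbt(p.temperature)
        q12 = math.exp(-duplex.energy(p.temperature) / bt) + (1.0 if include_unpaired else 0.0)
        x = math.exp(-ps.dg_associate / bt) * q12
        assert ps.q12 == pytest.approx(q12, rel=1e-9)
        assert ps.bound_fraction == pytest.approx(x / (1 + x), rel=1e-9)

    def test_heating_melts_a_stable_duplex(self):
        ens = ENS.DimerEnsemble.build("GG", "CC")
        fracs = [
            ENS.partition_functions(
                ens, ENS.EnsembleParams(temperature=t, c_total=4.0)
            ).bound_fraction
            for t in (250.0, 300.0, 350.0)
        ]
        assert fracs[0] > fracs[1] > fracs[2]

    def test_q_is_at_least_one_with_the_open_chain_at_zero(self):
        ens = ENS.DimerEnsemble.build("GGAAGG", "CCAACC")
        ps = ENS.partition_functions(ens, ENS.EnsembleParams())
        assert ps.q1 >= 1.0 and ps.q2 >= 1.0 and ps.q12 >= 1.0


class TestLandscape:
    def test_one_structure_ensemble_puts_all_mass_at_nref_zero(self):
        ens = ENS.DimerEnsemble.build("GG", "CC")
        p = ENS.EnsembleParams(include_unpaired_associated=False)
        ref = next(s for s in ens.dimer if s.structure.pairs).structure
        grid = ENS.landscape(ens, ref, p)
        assert set(grid.mass) == {(2, 0)}
        assert grid.probability[(2, 0)] == pytest.approx(1.0, abs=1e-12)

    def test_mass_conservation_against_q12(self):
        ens = ENS.DimerEnsemble.build("GGAAGG", "CCAACC")
        p = ENS.EnsembleParams()
        ps = ENS.partition_functions(ens, p)
        ref = max(ens.dimer, key=lambda s: len(s.structure.pairs)).structure
        grid = ENS.landscape(ens, ref, p)
        expected = math.exp(-ps.dg_associate / kbt(p.temperature)) * ps.q12
        assert grid.total_mass == pytest.approx(expected, rel=1e-9)
        assert sum(grid.probability.values()) == pytest.approx(1.0, abs=1e-9)

    def test_minima_invariant_under_a_global_energy_shift(self, two_minimum_fixture):
        from kisfold.ensemble import DimerEnsemble, EnsembleParams, landscape

        fx = two_minimum_fixture
        ens = DimerEnsemble.build(*fx.sequences)
        p = EnsembleParams(temperature=293.15)
        base = landscape(ens, fx.reference, p).local_minima()
        shifted = ENS.DimerEnsemble(
            seq1=ens.seq1,
            seq2=ens.seq2,
            strand1=ens.strand1,
            strand2=ens.strand2,
            dimer=[
                ENS.ScoredStructure(
                    structure=s.structure,
                    dh=s.dh + 2.5,
                    ds=s.ds,
                    dg_const=s.dg_const,
                    kissing=s.kissing,
                )
                for s in ens.dimer
            ],
        )
        assert landscape(shifted, fx.reference, p).local_minima() == base

    def test_two_minimum_fixture_has_exactly_two_minima(self, two_minimum_fixture):
        fx = two_minimum_fixture
        ens = ENS.DimerEnsemble.build(*fx.sequences)
        grid = ENS.landscape(ens, fx.reference, ENS.EnsembleParams(temperature=293.15))
        minima = grid.local_minima()
        assert len(minima) == 2
        # one basin is duplex-like (non-native pairs dominate), the other
        # kissing-like (native pairs dominate)
        (a, b) = sorted(minima)
        assert a[0] < a[1] and b[0] > b[1]


class TestMelting:
    def test_populations_sum_to_one_everywhere(self):
        ens = ENS.DimerEnsemble.build("GGAAGG", "CCAACC")
        df = ENS.melting_profile(
            ens, ENS.EnsembleParams(c_total=1e-4), np.linspace(270, 370, 7)
        )
        total = df[["p_unbound", "p_kissing", "p_extended_duplex", "p_other_bound"]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_classification_is_a_partition(self):
        ens = ENS.DimerEnsemble.build("GGCAAAUCGC", "GCGAAAUGCC")
        classes = [ENS.classify_structure(s) for s in ens.dimer]
        assert set(classes) <= {"kissing", "extended_duplex", "other_bound"}
        assert len(classes) == len(ens.dimer)

    def test_two_state_midpoint_matches_the_analytic_melting_temperature(self, nn_table):
        # one duplex, unpaired-associated state excluded: bound fraction is
        # 1/2 exactly where dG_duplex(T) + dG_associate(T) = 0, i.e.
        # T_m = (dH_d + dG_init) / (dS_d + k_B ln(C_T/4))
        ens = ENS.DimerEnsemble.build("GG", "CC")
        c_total = 4.0  # the concentration term vanishes at C_T = 4
        duplex = next(s for s in ens.dimer if s.structure.pairs)
        t_m = (duplex.dh + 4.1) / (duplex.ds + KB_KCAL_PER_MOL_K * math.log(c_total / 4.0))

        def excess(t):
            p = ENS.EnsembleParams(
                temperature=t, c_total=c_total, include_unpaired_associated=False
            )
            return ENS.partition_functions(ens, p).bound_fraction - 0.5

        t_mid = brentq(excess, 150.0, 500.0, xtol=1e-10)
        assert t_mid == pytest.approx(t_m, abs=1e-6)

    def test_grid_must_increase(self):
        ens = ENS.DimerEnsemble.build("GG", "CC")
        with pytest.raises(ValueError):
            ENS.melting_profile(ens, ENS.EnsembleParams(), [300.0, 290.0])
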