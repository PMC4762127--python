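"""A-form geometry: closed-form end-to-end identity, helix construction,
scaffold assembly, and PDB round-trips."""

import math

import numpy as np
import pytest

from kisfold import geometry as G
from kisfold.io import read_pdb, write_pdb
from kisfold.structure import SecondaryStructure, parse_dotbracket


def kissing_structure(stem=3, l1=3, kiss=4, l2=0):
    from kisfold.fixtures import revcomp

    s, k = "G" * stem, ("GCGC" * 3)[:kiss]
    seq1 = s + "A" * l1 + k + "U" * l2 + revcomp(s)
    seq2 = s + "A" * l1 + revcomp(k) + "U" * l2 + revcomp(s)
    n1 = len(seq1)
    pairs = []
    for i in range(stem):
        pairs.append((i, n1 - 1 - i))
        pairs.append((n1 + i, n1 + len(seq2) - 1 - i))
    a0, b0 = stem + l1, n1 + stem + l1
    pairs += [(a0 + t, b0 + kiss - 1 - t) for t in range(kiss)]
    return SecondaryStructure((seq1, seq2), tuple(pairs))


class TestEndToEnd:
    def test_zero_steps_is_zero(self):
        assert G.helix_end_to_end(0) == 0.0

    def test_full_turn_reduces_to_pure_rise(self):
        # over one full period the chord term vanishes: z = h * s
        assert G.helix_end_to_end(11) == pytest.approx(2.7 * 11, abs=1e-12)

    def test_single_step_is_a_physical_p_p_distance(self):
        # adjacent-step P-P distance in an ideal A-form helix is ~6 A
        z1 = G.helix_end_to_end(1)
        assert z1 == pytest.approx(6.1973770656973795, abs=1e-9)

    def test_three_term_and_two_term_forms_agree(self):
        rng = np.random.default_rng(1)
        for s in rng.uniform(0.0, 50.0, size=1000):
            assert G.helix_end_to_end_three_term(s) == pytest.approx(
                G.helix_end_to_end_two_term(s), abs=1e-9
            )

    def test_negative_s_is_a_domain_error(self):
        with pytest.raises(ValueError):
            G.helix_end_to_end(-1.0)


class TestHelixBuilder:
    def test_single_pair_has_zero_strand_extent(self):
        h = G.build_aform_helix(1)
        assert h.n_residues == 2
        assert G.helix_end_to_end(0) == 0.0

    @pytest.mark.parametrize("n_bp", [2, 4, 7, 12, 21])
    def test_strand_end_separation_equals_closed_form(self, n_bp):
        h = G.build_aform_helix(n_bp)
        for chain in ("A", "B"):
            res = h.chain(chain)
            d = np.linalg.norm(res[-1].p - res[0].p)
            assert d == pytest.approx(G.helix_end_to_end(n_bp - 1), abs=1e-6)

    def test_strand_end_separation_for_s_up_to_20(self):
        h = G.build_aform_helix(21)
        res = h.chain("A")
        for s in range(21):
            d = np.linalg.norm(res[s].p - res[0].p)
            assert d == pytest.approx(G.helix_end_to_end(s), abs=1e-6)

    def test_all_virtual_bonds_have_exact_length(self):
        h = G.build_aform_helix(9)
        for chain in ("A", "B"):
            assert np.allclose(h.backbone_bond_lengths(chain), 3.9, atol=1e-9)

    def test_rise_and_twist_recovered_from_coordinates(self):
        # 12 bp spans a full turn, so the net strand displacement is the
        # exact helical axis; project onto it to recover rise and twist
        h = G.build_aform_helix(12)
        p = np.array([r.p for r in h.chain("A")])
        axis = p[11] - p[0]
        axis /= np.linalg.norm(axis)
        rises = np.diff(p @ axis)
        assert np.allclose(rises, 2.7, atol=1e-9)
        perp = p - np.outer(p @ axis, axis)
        x, y = perp[:, 0], perp[:, 1]
        # exact least-squares (Kasa) circle fit for the wheel centre
        A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
        cx, cy, _ = np.linalg.lstsq(A, x**2 + y**2, rcond=None)[0]
        angles = np.unwrap(np.arctan2(y - cy, x - cx))
        twists = np.diff(angles)
        assert np.allclose(twists, 2 * math.pi / 11, atol=1e-9)

    def test_strands_are_antiparallel_and_paired_at_same_height(self):
        h = G.build_aform_helix(6)
        pa = np.array([r.p for r in h.chain("A")])
        pb = np.array([r.p for r in h.chain("B")])
        assert np.allclose(pa[:, 2], pb[::-1, 2], atol=1e-9)

    def test_origin_frame_is_applied_rigidly(self):
        frame = G.helical_step_transform()
        h0 = G.build_aform_helix(4)
        h1 = G.build_aform_helix(4, origin_frame=frame)
        moved = G.apply_transform(frame, h0.coordinates())
        assert np.allclose(moved, h1.coordinates(), atol=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            G.build_aform_helix(0)
        with pytest.raises(ValueError):
            G.HelixGeometry(rise_per_bp=-1)


class TestScaffoldAssembly:
    def test_empty_structure_gives_empty_scaffold(self):
        st = parse_dotbracket("", "")
        assert G.assemble_scaffold(st).n_residues == 0

    def test_hairpin_scaffold_one_coordinate_pair_per_nt(self):
        st = parse_dotbracket("GGGAAAACCC", "(((....)))")
        sc = G.assemble_scaffold(st)
        assert sc.n_residues == 10
        sc.validate()
        # stem geometry matches the A-form builder
        stem_p = np.array([r.p for r in sc.residues if r.label == "helix"])
        ref = G.build_aform_helix(3)
        assert np.allclose(
            np.sort(stem_p.ravel()), np.sort(ref.coordinates()[::2].ravel()), atol=1e-9
        )

    def test_kissing_dimer_with_short_connectors_is_coaxial(self):
        sc = G.assemble_scaffold(kissing_structure(l2=0))
        sc.validate()
        # all helix P atoms lie on one helical wheel about the z axis
        hp = np.array([r.p for r in sc.residues if r.label == "helix"])
        assert np.allclose(np.linalg.norm(hp[:, :2], axis=1), 9.9, atol=1e-9)
        # stacked levels are evenly spaced in z: one shared (collinear) axis
        z = np.unique(np.round(hp[:, 2], 6))
        assert np.allclose(np.diff(z), 2.7, atol=1e-6)

    def test_unsatisfiable_anchor_gap_is_reported_infeasible(self):
        with pytest.raises(G.ScaffoldInfeasibleError):
            G.assemble_scaffold(kissing_structure(stem=3, l1=2, kiss=4))

    def test_loop_residues_are_labelled_and_clash_free(self):
        sc = G.assemble_scaffold(kissing_structure(stem=3, l1=3, kiss=4, l2=1))
        sc.validate()
        labels = {r.label for r in sc.residues}
        assert labels == {"helix", "loop"}

    def test_pdb_round_trip_to_millialngstrom(self, tmp_path):
        sc = G.assemble_scaffold(kissing_structure())
        path = tmp_path / "scaffold.pdb"
        write_pdb(path, sc)
        sc2 = read_pdb(path)
        assert np.abs(sc.coordinates() - sc2.coordinates()).max() < 1e-3
        assert [r.label for r in sc2.residues] == [r.label for r in sc.residues]
        # a second write is byte-identical (the format is lossy but stable)
        path2 = tmp_path / "scaffold2.pdb"
        write_pdb(path2, sc2)
        assert path.read_text() == path2.read_text()

    def test_pdb_has_ter_between_chains_and_cg_atom_names(self, tmp_path):
        sc = G.assemble_scaffold(kissing_structure())
        path = tmp_path / "scaffold.pdb"
        write_pdb(path, sc)
        text = path.read_text()
        atom_lines = [ln for ln in text.splitlines() if ln.startswith("ATOM")]
        names = {ln[12:16].strip() for ln in atom_lines}
        assert names == {"P", "C4'"}
        chains = [ln[21] for ln in atom_lines]
        assert set(chains) == {"A", "B"}
        ter_idx = [i for i, ln in enumerate(text.splitlines()) if ln.startswith("TER")]
        assert ter_idx, "expected TER records between chains"
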