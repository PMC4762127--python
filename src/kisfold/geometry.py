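"""A-form helix geometry at virtual-bond resolution and coarse-grained
scaffold assembly.

Each nucleotide is represented by two backbone pseudo-atoms, P and C4',
linked by virtual bonds of equal length.  Helices are ideal A-form: P atoms
sit on a helical wheel of radius ``r`` with rise ``h`` per base pair and a
twist of 2*pi/11 per step (11 bp per turn); C4' atoms are placed on the
perpendicular bisector of consecutive P atoms so that every intra-helix
virtual bond has exactly the configured length.  The closed-form strand
end-to-end distance over s steps is

    z(s) = sqrt{ (h s)^2 + r^2 [1 - cos(2 pi s / 11)]^2
                          + r^2 sin^2(2 pi s / 11) }
         = sqrt{ (h s)^2 + 4 r^2 sin^2(pi s / 11) }

(the chord identity (1-cos t)^2 + sin^2 t = 4 sin^2(t/2) halves the angle
in the simplified form).  Loop nucleotides are placed on diamond-lattice
self-avoiding walks bridging the helix anchor points.

Coordinate conventions: right-handed frames, Angstrom units, local helix
axis along +z, residues 1-based within each chain, chains lettered A, B in
input order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import lattice as lat
from .constants import (
    CLASH_DISTANCE,
    HELIX_BP_PER_TURN,
    HELIX_RADIUS,
    HELIX_RISE,
    VIRTUAL_BOND_LENGTH,
)
from .structure import SecondaryStructure


class ScaffoldInfeasibleError(ValueError):
    """A loop cannot bridge its anchors, or the topology is unsupported."""


@dataclass(frozen=True)
class HelixGeometry:
    """Ideal A-form helix parameters.

    ``bp_per_turn`` is fixed at 11 by the twist phase 2*pi*s/11 of the
    closed-form z(s); it is validated rather than tuned.
    """

    rise_per_bp: float = HELIX_RISE
    radius: float = HELIX_RADIUS
    bp_per_turn: int = HELIX_BP_PER_TURN
    n_bp: int = 1

    def __post_init__(self):
        if self.rise_per_bp <= 0:
            raise ValueError("rise_per_bp must be > 0")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.bp_per_turn < 1:
            raise ValueError("bp_per_turn must be >= 1")
        if self.n_bp < 1:
            raise ValueError("n_bp must be >= 1")

    @property
    def twist_per_bp(self) -> float:
        return 2.0 * math.pi / self.bp_per_turn


DEFAULT_GEOMETRY = HelixGeometry()


# ---------------------------------------------------------------------------
# Closed-form end-to-end distance
# ---------------------------------------------------------------------------


def helix_end_to_end(s: float, geom: HelixGeometry = DEFAULT_GEOMETRY) -> float:
    """Strand end-to-end distance z(s) over s helical steps ((s+1) base pairs).

    Accepts real s >= 0 (integer base-pair steps in normal use).
    """
    return helix_end_to_end_two_term(s, geom)


def helix_end_to_end_three_term(s: float, geom: HelixGeometry = DEFAULT_GEOMETRY) -> float:
    """The three-term Cartesian form of z(s)."""
    if s < 0:
        raise ValueError("helix parameter s must be >= 0")
    h, r = geom.rise_per_bp, geom.radius
    t = geom.twist_per_bp * s
    return math.sqrt((h * s) ** 2 + (r * (1.0 - math.cos(t))) ** 2 + (r * math.sin(t)) ** 2)


def helix_end_to_end_two_term(s: float, geom: HelixGeometry = DEFAULT_GEOMETRY) -> float:
    """The simplified two-term form of z(s) (chord identity, half angle)."""
    if s < 0:
        raise ValueError("helix parameter s must be >= 0")
    h, r = geom.rise_per_bp, geom.radius
    return math.sqrt((h * s) ** 2 + 4.0 * r * r * math.sin(geom.twist_per_bp * s / 2.0) ** 2)


def helical_step_transform(geom: HelixGeometry = DEFAULT_GEOMETRY) -> np.ndarray:
    """4x4 rigid transform advancing one helical step (+h rise, +2*pi/11 twist)."""
    t = geom.twist_per_bp
    m = np.eye(4)
    m[0, 0] = m[1, 1] = math.cos(t)
    m[0, 1] = -math.sin(t)
    m[1, 0] = math.sin(t)
    m[2, 3] = geom.rise_per_bp
    return m


def apply_transform(frame: np.ndarray, points: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(points)
    out = pts @ frame[:3, :3].T + frame[:3, 3]
    return out[0] if np.ndim(points) == 1 else out


# ---------------------------------------------------------------------------
# Scaffold container
# ---------------------------------------------------------------------------


@dataclass
class ScaffoldResidue:
    chain_id: str
    resi: int  # 1-based within the chain
    name: str  # base letter, or 'N' when unknown
    label: str  # 'helix' | 'loop'
    p: np.ndarray
    c4: np.ndarray


@dataclass
class ScaffoldStructure:
    """Per-nucleotide P/C4' pseudo-atom coordinates for one or two chains."""

    residues: list[ScaffoldResidue] = field(default_factory=list)
    bond_length: float = VIRTUAL_BOND_LENGTH

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def chain(self, chain_id: str) -> list[ScaffoldResidue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def coordinates(self) -> np.ndarray:
        """(2*n_residues, 3) array of pseudo-atom positions, backbone order."""
        if not self.residues:
            return np.zeros((0, 3))
        return np.array([xyz for r in self.residues for xyz in (r.p, r.c4)])

    def backbone_bond_lengths(self, chain_id: str) -> np.ndarray:
        atoms = np.array([xyz for r in self.chain(chain_id) for xyz in (r.p, r.c4)])
        if len(atoms) < 2:
            return np.zeros(0)
        return np.linalg.norm(np.diff(atoms, axis=0), axis=1)

    def validate(
        self,
        bond_tol: float = 1e-6,
        junction_tol: float = 5.0,
        clash_distance: float = CLASH_DISTANCE,
    ) -> None:
        """Check virtual-bond lengths and the non-bonded clash criterion.

        Bonds internal to a helix or to a lattice loop are exact to
        ``bond_tol``; bonds joining an off-lattice helix atom to a snapped
        loop atom may deviate by up to the snapping error and are allowed
        ``junction_tol``.  The clash criterion applies to non-bonded pairs,
        i.e. atoms more than three backbone bonds apart (1-2/1-3/1-4
        neighbours are governed by the bond geometry instead).
        """
        for cid in self.chain_ids:
            res = self.chain(cid)
            labels = [lb for r in res for lb in (r.label, r.label)]
            lengths = self.backbone_bond_lengths(cid)
            for k, d in enumerate(lengths):
                mixed = labels[k] != labels[k + 1]
                tol = junction_tol if mixed else bond_tol
                if abs(d - self.bond_length) > tol:
                    raise ValueError(
                        f"backbone bond {k} of chain {cid} has length {d:.3f} A "
                        f"(expected {self.bond_length} +/- {tol})"
                    )
        coords = self.coordinates()
        n = len(coords)
        if n > 1:
            d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
            bonded = np.zeros((n, n), dtype=bool)
            idx = 0
            for cid in self.chain_ids:
                m = 2 * len(self.chain(cid))
                for k in range(idx, idx + m - 1):
                    for off in range(1, 4):  # exclude 1-2, 1-3, 1-4 pairs
                        if k + off < idx + m:
                            bonded[k, k + off] = bonded[k + off, k] = True
                idx += m
            np.fill_diagonal(d, np.inf)
            d[bonded] = np.inf
            if np.min(d) < clash_distance:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise ValueError(
                    f"pseudo-atom clash: atoms {i} and {j} at {d[i, j]:.3f} A "
                    f"(< {clash_distance} A)"
                )


# ---------------------------------------------------------------------------
# A-form helix builder
# ---------------------------------------------------------------------------


def _strand_a_positions(n_bp: int, geom: HelixGeometry, bond_length: float):
    """P and C4' positions for the ascending strand, levels 0..n_bp-1.

    C4'(k) sits on the perpendicular bisector of P(k) and P(k+1) (a virtual
    P(n_bp) extends the last step), displaced toward the helix axis so that
    |P(k)-C4'(k)| = |C4'(k)-P(k+1)| = bond_length exactly.
    """
    h, r, t = geom.rise_per_bp, geom.radius, geom.twist_per_bp
    p = np.array(
        [(r * math.cos(t * k), r * math.sin(t * k), h * k) for k in range(n_bp + 1)]
    )
    chords = np.diff(p, axis=0)
    clen = np.linalg.norm(chords, axis=1)
    if np.any(clen > 2 * bond_length):
        raise ValueError(
            "helix step exceeds the reach of two virtual bonds; "
            "bond_length too short for this geometry"
        )
    mids = 0.5 * (p[:-1] + p[1:])
    c4 = np.empty_like(mids)
    for k in range(n_bp):
        chat = chords[k] / clen[k]
        radial = np.array([mids[k, 0], mids[k, 1], 0.0])
        radial -= np.dot(radial, chat) * chat
        radial /= np.linalg.norm(radial)
        offset = math.sqrt(bond_length**2 - (clen[k] / 2.0) ** 2)
        c4[k] = mids[k] - offset * radial  # inward, like C4' in A-RNA
    return p[:n_bp], c4


def _duplex_positions(n_bp: int, geom: HelixGeometry, bond_length: float):
    """P/C4' positions for both strands of an ideal A-form duplex.

    Strand alpha ascends levels 0..n_bp-1; strand beta is the dyad-related
    antiparallel strand: beta residue m sits at level n_bp-1-m, antipodal
    (angular offset pi) to its paired alpha residue.  The dyad is a proper
    rotation, so both strands are right-handed.
    """
    pa, c4a = _strand_a_positions(n_bp, geom, bond_length)
    t = geom.twist_per_bp
    two_alpha = t * (n_bp - 1) + math.pi
    axis = np.array([math.cos(two_alpha / 2.0), math.sin(two_alpha / 2.0), 0.0])
    rot = 2.0 * np.outer(axis, axis) - np.eye(3)
    z_mid = geom.rise_per_bp * (n_bp - 1) / 2.0
    center = np.array([0.0, 0.0, z_mid])
    pb = (pa - center) @ rot.T + center
    c4b = (c4a - center) @ rot.T + center
    return pa, c4a, pb, c4b


def build_aform_helix(
    n_bp: int,
    geom: HelixGeometry = DEFAULT_GEOMETRY,
    origin_frame: np.ndarray | None = None,
    bond_length: float = VIRTUAL_BOND_LENGTH,
    sequences: tuple[str, str] | None = None,
) -> ScaffoldStructure:
    """Build an ideal A-form duplex of ``n_bp`` base pairs.

    Returns two antiparallel chains (A ascending, B descending in space,
    both 5'->3' in residue order).  The distance between the P atoms of a
    strand s steps apart equals helix_end_to_end(s) exactly.
    """
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    pa, c4a, pb, c4b = _duplex_positions(n_bp, geom, bond_length)
    if origin_frame is not None:
        pa = apply_transform(origin_frame, pa)
        c4a = apply_transform(origin_frame, c4a)
        pb = apply_transform(origin_frame, pb)
        c4b = apply_transform(origin_frame, c4b)
    seq_a = sequences[0] if sequences else "N" * n_bp
    seq_b = sequences[1] if sequences else "N" * n_bp
    residues = [
        ScaffoldResidue("A", k + 1, seq_a[k], "helix", pa[k], c4a[k]) for k in range(n_bp)
    ] + [ScaffoldResidue("B", k + 1, seq_b[k], "helix", pb[k], c4b[k]) for k in range(n_bp)]
    return ScaffoldStructure(residues=residues, bond_length=bond_length)


# ---------------------------------------------------------------------------
# Scaffold assembly from a secondary structure
# ---------------------------------------------------------------------------


def _bridge_loop(
    start_pt: np.ndarray,
    end_pt: np.ndarray,
    n_nt: int,
    obstacles: set,
    lattice: lat.DiamondLattice,
    context_atoms=(),
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Place ``n_nt`` loop residues between two off-lattice anchor points.

    The bridge is a 2*n_nt+1-step walk from the snapped start (C4' of the
    preceding residue) to the snapped end (P of the following residue);
    vertices 2i-1 and 2i become the P and C4' of loop residue i.  The walk
    sites are added to ``obstacles`` so later loops avoid them.
    """
    if n_nt == 1:
        return [_single_nt_connector(start_pt, end_pt, lattice.bond_length, context_atoms)]
    n_steps = 2 * n_nt + 1
    s0 = lat.snap_to_lattice(start_pt, lattice)
    want = (lat.DiamondLattice.sublattice(s0) + n_steps) % 2
    s1 = lat.snap_to_lattice(end_pt, lattice, parity=want)
    obs = frozenset(obstacles) - {s0, s1}
    walk = lat.first_anchored_walk(s0, s1, n_steps, obs)
    if walk is None:
        raise ScaffoldInfeasibleError(
            f"loop of {n_nt} nt cannot bridge anchors {np.round(start_pt, 2)} -> "
            f"{np.round(end_pt, 2)} ({n_steps} virtual bonds)"
        )
    obstacles.update(walk.sites)
    verts = [lattice.to_cartesian(s) for s in walk.sites]
    return [(verts[2 * i + 1], verts[2 * i + 2]) for i in range(n_nt)]


def _single_nt_connector(
    start_pt: np.ndarray,
    end_pt: np.ndarray,
    bond: float,
    context_atoms=(),
) -> tuple[np.ndarray, np.ndarray]:
    """Exact off-lattice placement of a single connecting nucleotide.

    A 1-nt connector keeps its flanking helices coaxially stacked, so its
    two pseudo-atoms are placed as a symmetric three-bond zig-zag between
    the anchors (all bonds exactly ``bond``).  The bulge direction is
    chosen deterministically among eight candidates in the plane normal to
    the anchor axis, maximising the clearance from already-placed atoms.
    """
    gap = float(np.linalg.norm(end_pt - start_pt))
    if gap > 3 * bond:
        raise ScaffoldInfeasibleError(
            f"1-nt connector cannot bridge a {gap:.2f} A anchor gap "
            f"(max {3 * bond:.2f} A)"
        )
    d = (end_pt - start_pt) / gap
    mid = 0.5 * (start_pt + end_pt)
    radial = np.array([mid[0], mid[1], 0.0])
    radial -= np.dot(radial, d) * d
    if np.linalg.norm(radial) < 1e-6:
        radial = np.cross(np.array([0.0, 0.0, 1.0]), d)
    u0 = radial / np.linalg.norm(radial)
    u1 = np.cross(d, u0)
    delta = max((gap - bond) / 2.0, 0.0)
    w = math.sqrt(bond**2 - delta**2)
    ctx = np.array([np.asarray(a) for a in context_atoms]) if len(context_atoms) else None
    best = None
    best_clearance = -math.inf
    for k in range(8):
        ang = 2.0 * math.pi * k / 8.0
        u = math.cos(ang) * u0 + math.sin(ang) * u1
        p = start_pt + delta * d + w * u
        c4 = end_pt - delta * d + w * u
        if ctx is None:
            clearance = math.inf
        else:
            clearance = min(
                np.min(np.linalg.norm(ctx - p, axis=1)),
                np.min(np.linalg.norm(ctx - c4, axis=1)),
            )
        if clearance > best_clearance + 1e-9:
            best, best_clearance = (p, c4), clearance
    return best


def _tail_positions(anchor: np.ndarray, direction: np.ndarray, n_nt: int, bond: float):
    """Straight single-stranded tail: pseudo-atoms spaced one bond apart
    along ``direction`` away from the anchor, nearest residue last."""
    d = direction / np.linalg.norm(direction)
    out = []
    for i in range(n_nt):
        k = n_nt - i  # residue i of the tail, 5' end farthest out
        p = anchor + d * bond * (2 * k)
        c4 = anchor + d * bond * (2 * k - 1)
        out.append((p, c4))
    return out


def _occupied_sites(atom_list, lattice: lat.DiamondLattice) -> frozenset:
    """Hard-core excluded volume for off-lattice atoms: each atom blocks
    its nearest site on both sublattices (used by the entropy pipeline)."""
    occ = set()
    for a in atom_list:
        occ.add(lat.snap_to_lattice(a, lattice, parity=0))
        occ.add(lat.snap_to_lattice(a, lattice, parity=1))
    return frozenset(occ)


def _occupied_sites_single(atom_list, lattice: lat.DiamondLattice) -> frozenset:
    """Milder obstacle marking for scaffold bridging: nearest site only,
    leaving corridors between helices passable; clash-freedom is enforced
    by the final scaffold validation instead."""
    return frozenset(lat.snap_to_lattice(a, lattice) for a in atom_list)


def assemble_scaffold(
    structure: SecondaryStructure,
    geom: HelixGeometry = DEFAULT_GEOMETRY,
    bond_length: float = VIRTUAL_BOND_LENGTH,
    loop_confs: dict[int, lat.LatticeWalk] | None = None,
) -> ScaffoldStructure:
    """Assemble a coarse-grained 3D scaffold for a secondary structure.

    Helices joined by connecting loops of <= 1 nt are coaxially stacked on
    a common axis; longer loops are bridged by diamond-lattice walks.
    Supported topologies: the empty structure, single-chain nested stacks
    (hairpins with optional bulges/internal loops and tails), and the
    two-hairpin kissing dimer with short l2/l4.  An unsatisfiable anchor
    gap raises ScaffoldInfeasibleError.
    """
    if structure.total_length == 0:
        return ScaffoldStructure(residues=[], bond_length=bond_length)
    if structure.n_strands == 1:
        return _assemble_single_chain(structure, geom, bond_length, loop_confs)
    if structure.n_strands == 2 and structure.intermolecular_pairs:
        return _assemble_kissing_dimer(structure, geom, bond_length, loop_confs)
    raise ScaffoldInfeasibleError(
        "unsupported topology: expected a single chain or a kissing dimer"
    )


def _nested_chain_helices(structure: SecondaryStructure):
    """Helices of a single chain ordered outermost-first; raises if they are
    not a single nested stack."""
    helices = structure.helices()
    if any(structure.crossing_pairs):
        raise ScaffoldInfeasibleError("single-chain pseudoknots are not supported")
    helices.sort(key=lambda h: h[0][0])
    for outer, inner in zip(helices, helices[1:]):
        oi, oj = outer[-1]
        ii, ij = inner[0]
        if not (oi < ii and ij < oj):
            raise ScaffoldInfeasibleError(
                "multibranch junctions are not supported by the scaffold builder"
            )
    return helices


def _assemble_single_chain(structure, geom, bond_length, loop_confs):
    seq = structure.sequences[0]
    lattice = lat.DiamondLattice(bond_length)
    helices = _nested_chain_helices(structure)
    if not helices:
        raise ScaffoldInfeasibleError("structure has no helix to anchor the scaffold")
    total_bp = sum(len(h) for h in helices)
    pa, c4a, pb, c4b = _duplex_positions(total_bp, geom, bond_length)

    level = 0
    pos: dict[int, tuple[np.ndarray, np.ndarray, str]] = {}
    for h in helices:
        for i, j in h:
            m = total_bp - 1 - level
            pos[i] = (pa[level], c4a[level], "helix")
            pos[j] = (pb[m], c4b[m], "helix")
            level += 1

    helix_atoms = [a for lv in range(total_bp) for a in (pa[lv], c4a[lv], pb[total_bp - 1 - lv], c4b[total_bp - 1 - lv])]
    obstacles = set(_occupied_sites_single(helix_atoms, lattice))

    paired = sorted(pos)
    first, last = paired[0], paired[-1]
    # unpaired stretches between paired residues, bridged on the lattice
    runs: list[tuple[int, int]] = []
    prev = first
    for i in paired[1:]:
        if i > prev + 1:
            runs.append((prev, i))
        prev = i
    for a, b in runs:
        n_nt = b - a - 1
        ctx = [xyz for (pp, cc, _) in pos.values() for xyz in (pp, cc)]
        placed = _bridge_loop(pos[a][1], pos[b][0], n_nt, obstacles, lattice, ctx)
        for t, (pp, cc) in enumerate(placed):
            pos[a + 1 + t] = (pp, cc, "loop")
    # 5' and 3' tails extend straight away from the stack ends
    if first > 0:
        p0 = pos[first][0]
        away = np.array([p0[0], p0[1], 0.0])
        away = away / np.linalg.norm(away) + np.array([0.0, 0.0, -1.0])
        for t, (pp, cc) in enumerate(_tail_positions(p0, away, first, bond_length)):
            pos[t] = (pp, cc, "loop")
    if last < len(seq) - 1:
        n = len(seq) - 1 - last
        pl = pos[last][1]
        away = np.array([pl[0], pl[1], 0.0])
        away = away / np.linalg.norm(away) + np.array([0.0, 0.0, -1.0])
        tail = _tail_positions(pl, away, n, bond_length)[::-1]
        for t, (cc, pp) in enumerate(tail):  # outgoing tail: P leads, C4' trails
            pos[last + 1 + t] = (pp, cc, "loop")

    residues = [
        ScaffoldResidue("A", i + 1, seq[i], pos[i][2], pos[i][0], pos[i][1])
        for i in range(len(seq))
    ]
    return ScaffoldStructure(residues=residues, bond_length=bond_length)


def _kissing_layout(structure: SecondaryStructure):
    """Identify (stem1, stem2, kissing helix) of a two-hairpin kissing dimer."""
    helices = structure.helices()
    inter = [h for h in helices if not structure.is_intra(h[0])]
    intra1 = [h for h in helices if structure.is_intra(h[0]) and structure.strand_of(h[0][0]) == 0]
    intra2 = [h for h in helices if structure.is_intra(h[0]) and structure.strand_of(h[0][0]) == 1]
    if len(inter) != 1 or len(intra1) != 1 or len(intra2) != 1:
        raise ScaffoldInfeasibleError(
            "kissing assembly expects exactly one hairpin stem per chain "
            "plus one intermolecular kissing helix"
        )
    return intra1[0], intra2[0], inter[0]


def _assemble_kissing_dimer(structure, geom, bond_length, loop_confs):
    seq1, seq2 = structure.sequences
    off2 = structure.strand_offsets[1]
    lattice = lat.DiamondLattice(bond_length)
    stem1, stem2, kiss = _kissing_layout(structure)
    p1, p3, S = len(stem1), len(stem2), len(kiss)
    L = p1 + S + p3
    pa, c4a, pb, c4b = _duplex_positions(L, geom, bond_length)

    def alpha(level):
        return pa[level], c4a[level]

    def beta(level):
        return pb[L - 1 - level], c4b[L - 1 - level]

    # Stacked-duplex levels: stem1 occupies 0..p1-1, the kissing stem
    # p1..p1+S-1, stem2 p1+S..L-1.  Chain A ascends stem1 on the alpha
    # strand, crosses to the kissing strand on beta (3' end near stem1,
    # favouring H1-H2 coaxial stacking), and returns down the beta strand;
    # chain B is the mirror image through the kissing stem.
    pos: dict[int, tuple[np.ndarray, np.ndarray, str]] = {}
    for t, (i, j) in enumerate(stem1):  # i on alpha level t; j on beta level t
        pos[i] = (*alpha(t), "helix")
        pos[j] = (*beta(t), "helix")
    for t, (i, j) in enumerate(stem2):  # chain B stem tops the stack
        lv = L - 1 - t
        pos[i] = (*beta(lv), "helix")
        pos[j] = (*alpha(lv), "helix")
    for t, (i, j) in enumerate(sorted(kiss)):  # i in chain A, j in chain B
        # chain A kissing nucleotides descend the beta strand from the top
        # of the kissing stem; chain B ascends alpha.
        lv = p1 + S - 1 - t
        pos[i] = (*beta(lv), "helix")
        pos[j] = (*alpha(lv), "helix")

    helix_atoms = [xyz for (pp, cc, _) in pos.values() for xyz in (pp, cc)]
    obstacles = set(_occupied_sites_single(helix_atoms, lattice))

    paired = sorted(pos)
    prev = paired[0]
    chain_break = off2
    for i in paired[1:]:
        same_chain = (prev < chain_break) == (i < chain_break)
        if same_chain and i > prev + 1:
            n_nt = i - prev - 1
            ctx = [xyz for (pp, cc, _) in pos.values() for xyz in (pp, cc)]
            placed = _bridge_loop(pos[prev][1], pos[i][0], n_nt, obstacles, lattice, ctx)
            for t, (pp, cc) in enumerate(placed):
                pos[prev + 1 + t] = (pp, cc, "loop")
        prev = i

    for g, seq, off in ((0, seq1, 0), (1, seq2, off2)):
        for k in range(len(seq)):
            if off + k not in pos:
                raise ScaffoldInfeasibleError(
                    f"unpaired terminal tails are not supported in kissing "
                    f"dimers (residue {k + 1} of chain {'AB'[g]})"
                )

    residues = [
        ScaffoldResidue("A", k + 1, seq1[k], pos[k][2], pos[k][0], pos[k][1])
        for k in range(len(seq1))
    ] + [
        ScaffoldResidue("B", k + 1, seq2[k], pos[off2 + k][2], pos[off2 + k][0], pos[off2 + k][1])
        for k in range(len(seq2))
    ]
    return ScaffoldStructure(residues=residues, bond_length=bond_length)
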