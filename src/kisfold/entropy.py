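"""Conformational entropies for hairpin-hairpin kissing motifs.

The kissing complex (stems H1, H2/kissing, H3; loops l1..l4) is treated in
three steps:

1. With l2 and l4 short (<= 1 nt), H1-H2 and H2-H3 stack coaxially, so the
   relative orientation of H1 and H3 is fixed by the kissing-stem length;
   the eight anchor nucleotides flanking loops l1 and l3 are regenerated
   from ideal coaxial A-form geometry.
2. Loop conformations are exhaustively enumerated as self-avoiding
   virtual-bond walks on the diamond lattice between the snapped anchors.
3. Helix-occupied lattice sites are excluded-volume obstacles; the loop
   entropy is the log of the surviving conformation count.

The entropy change on kissing is measured against the free coil,
ln(omega_coil) = 2.05*l + 0.1 per loop of l nucleotides:

    dS / k_B  =  ln(omega_loop) - sum_loops ln(omega_coil)

Anchors here come from ideal geometry rather than an experimental NMR
template, so computed tables are Vfold-like but not identical to published
ones; the shipped table (data/kissing_entropy_table.tsv) carries the
published values for lookup.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd

from . import lattice as lat
from .constants import COIL_INTERCEPT, COIL_SLOPE, LOOP_ENUMERATION_CAP_NT
from .geometry import DEFAULT_GEOMETRY, HelixGeometry, _duplex_positions, _occupied_sites

#: Largest kissing-stem length covered by the published table.
H2_MAX = 8


class TableRangeError(KeyError):
    """An entropy-table lookup outside the table bounds."""


@dataclass(frozen=True)
class KissingTopology:
    """Stem/loop decomposition of a hairpin-hairpin kissing complex.

    Lengths: ``h2_len`` base pairs in the kissing stem (S), ``l1_len`` and
    ``l3_len`` nucleotides in the bridging loops, ``l2_len``/``l4_len``
    (<= 1 nt, enforcing coaxial stacking), and flanking stems H1/H3.
    """

    h2_len: int
    l1_len: int
    l3_len: int
    l2_len: int = 0
    l4_len: int = 0
    h1_len: int = 1
    h3_len: int = 1

    def __post_init__(self):
        for name in ("h2_len", "l1_len", "l3_len", "l2_len", "l4_len", "h1_len", "h3_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.l2_len > 1 or self.l4_len > 1:
            raise ValueError(
                "the coaxial-stacking entropy pipeline requires l2_len <= 1 and l4_len <= 1"
            )
        if self.h2_len < 1:
            raise ValueError("the kissing stem needs at least one base pair")


@dataclass(frozen=True)
class AnchorFrame:
    """Coordinates (Angstrom) of the eight anchor nucleotides: the start/end
    residues of loops l1 and l3 (a_i, a_j, b_i, b_j) and their pairing
    partners (primed)."""

    a_i: np.ndarray
    a_i_prime: np.ndarray
    a_j: np.ndarray
    a_j_prime: np.ndarray
    b_i: np.ndarray
    b_i_prime: np.ndarray
    b_j: np.ndarray
    b_j_prime: np.ndarray


@dataclass(frozen=True)
class LoopEntropy:
    """Entropy change on kissing-loop formation, in units of k_B.

    ``delta_S`` = ln_omega_loop - ln_omega_coil (negative = penalty);
    -inf with ``infeasible`` set when no conformation survives.
    """

    delta_S: float
    ln_omega_loop: float
    ln_omega_coil: float
    infeasible: bool = False
    counts: tuple[int, int] = (0, 0)


def coil_ln_omega(l_nt: int) -> float:
    """Free-coil reference ln(omega) = 2.05*l + 0.1 for an l-nt chain."""
    if l_nt < 0:
        raise ValueError("chain length must be >= 0")
    return COIL_SLOPE * l_nt + COIL_INTERCEPT if l_nt > 0 else 0.0


# ---------------------------------------------------------------------------
# Step 1: anchor frames from ideal coaxial geometry
# ---------------------------------------------------------------------------


def generate_anchor_frame(
    h2_len: int, geom: HelixGeometry = DEFAULT_GEOMETRY, h2_max: int = H2_MAX
) -> AnchorFrame:
    """Anchor coordinates for a kissing stem of ``h2_len`` base pairs.

    The frame is a coaxial stack of one flanking base pair (representing the
    loop-side pair of H1), the kissing stem, and one flanking pair (H3),
    built from ideal A-form geometry.  Deterministic by construction.
    """
    if h2_len < 1:
        raise ValueError("h2_len must be >= 1")
    if h2_len > h2_max:
        raise ValueError(f"h2_len {h2_len} exceeds the table range (max {h2_max})")
    n = h2_len + 2  # one flanking bp each side
    pa, _, pb, _ = _duplex_positions(n, geom, bond_length=lat.VIRTUAL_BOND_LENGTH)

    def alpha(level):
        return pa[level]

    def beta(level):
        return pb[n - 1 - level]

    # Level 0 is the H1 flanking pair, levels 1..h2_len the kissing stem,
    # level h2_len+1 the H3 flanking pair.  Loop l1 runs from the H1 pair
    # (alpha strand) to the 5' end of the chain-A kissing strand at the top
    # of H2 (beta strand); loop l3 is the mirror image.
    top = h2_len + 1
    return AnchorFrame(
        a_i=alpha(0),
        a_i_prime=beta(0),
        a_j=beta(h2_len),
        a_j_prime=alpha(h2_len),
        b_i=beta(top),
        b_i_prime=alpha(top),
        b_j=alpha(1),
        b_j_prime=beta(1),
    )


# ---------------------------------------------------------------------------
# Steps 2-3: lattice enumeration with excluded volume
# ---------------------------------------------------------------------------


def _helix_obstacles(
    h2_len: int, h1_len: int, h3_len: int, geom: HelixGeometry
) -> frozenset:
    """Lattice sites occupied by the coaxial H1 + H2 + H3 stack, aligned to
    the anchor frame (H1's loop-side pair at frame level 0).

    The alignment rotates/translates the stack by exact helical steps, so
    the atoms at any frame level are independent of the flank lengths:
    growing H1 or H3 strictly extends the obstacle set.
    """
    n = h1_len + h2_len + h3_len
    pa, c4a, pb, c4b = _duplex_positions(n, geom, bond_length=lat.VIRTUAL_BOND_LENGTH)
    k = h1_len - 1  # stack level k corresponds to frame level 0
    t = -k * geom.twist_per_bp
    rot = np.array(
        [
            [math.cos(t), -math.sin(t), 0.0],
            [math.sin(t), math.cos(t), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    shift = np.array([0.0, 0.0, -k * geom.rise_per_bp])
    lattice = lat.DiamondLattice()
    atoms = [rot @ a + shift for group in (pa, c4a, pb, c4b) for a in group]
    return _occupied_sites(atoms, lattice)


def _bridging_loop_count(
    h2_len: int,
    l_nt: int,
    flank_below: int,
    flank_above: int,
    geom: HelixGeometry,
    cap: int,
):
    """Conformation count of one bridging loop (the l1 problem).

    Loop l3 is the dyad image of l1 with the flanking stems exchanged, so
    it reuses this with (flank_below, flank_above) swapped -- the complex's
    own 2-fold symmetry, kept exact on the lattice.
    """
    frame = generate_anchor_frame(h2_len, geom)
    lattice = lat.DiamondLattice()
    obstacles = _helix_obstacles(h2_len, flank_below, flank_above, geom)
    s0 = lat.snap_to_lattice(frame.a_i, lattice)
    s1 = lat.snap_to_lattice(
        frame.a_j, lattice, parity=lat.DiamondLattice.sublattice(s0)
    )
    obs = obstacles - {s0, s1}
    return lat.enumerate_anchored_loop(s0, s1, l_nt, obs, cap=cap)


def kissing_entropy(
    topology: KissingTopology,
    geom: HelixGeometry = DEFAULT_GEOMETRY,
    cap: int = LOOP_ENUMERATION_CAP_NT,
) -> LoopEntropy:
    """Entropy change (k_B) on forming a loop-loop kissing interaction.

    Enumerates l1 walks anchored at (a_i, a_j) and l3 walks anchored at
    (b_i, b_j), both avoiding the helix-occupied sites; the loop entropy is
    ln(count_l1 * count_l3) and dS is taken relative to two free coils.
    """
    if topology.l1_len < 1 or topology.l3_len < 1:
        raise ValueError("kissing loops l1 and l3 must have at least 1 nt")
    if topology.l1_len > cap or topology.l3_len > cap:
        raise lat.EnumerationCapError(
            f"loop lengths ({topology.l1_len}, {topology.l3_len}) exceed the "
            f"enumeration cap of {cap} nt"
        )
    c1 = _bridging_loop_count(
        topology.h2_len, topology.l1_len, topology.h1_len, topology.h3_len, geom, cap
    )
    c3 = _bridging_loop_count(
        topology.h2_len, topology.l3_len, topology.h3_len, topology.h1_len, geom, cap
    )
    ln_coil = coil_ln_omega(topology.l1_len) + coil_ln_omega(topology.l3_len)
    n1, n3 = c1.n_conformations, c3.n_conformations
    if n1 == 0 or n3 == 0:
        return LoopEntropy(
            delta_S=float("-inf"),
            ln_omega_loop=float("-inf"),
            ln_omega_coil=ln_coil,
            infeasible=True,
            counts=(n1, n3),
        )
    ln_loop = math.log(n1) + math.log(n3)
    return LoopEntropy(
        delta_S=ln_loop - ln_coil,
        ln_omega_loop=ln_loop,
        ln_omega_coil=ln_coil,
        counts=(n1, n3),
    )


# ---------------------------------------------------------------------------
# Entropy tables
# ---------------------------------------------------------------------------


class EntropyTable:
    """ln(omega) values indexed by (h2_len, l1_len, l3_len).

    Missing cells (the published table's dashes) are explicit: lookups
    return None, never an extrapolation.  The coil reference is the linear
    model 2.05*l + 0.1.
    """

    def __init__(self, cells: dict[tuple[int, int, int], float | None], provenance: str = ""):
        self._cells = dict(cells)
        self.provenance = provenance
        self._bounds = {
            axis: (min(k[d] for k in cells), max(k[d] for k in cells))
            for d, axis in enumerate(("h2_len", "l1_len", "l3_len"))
        } if cells else {}

    def lookup(self, h2_len: int, l1_len: int, l3_len: int) -> float | None:
        key = (h2_len, l1_len, l3_len)
        for axis, value in zip(("h2_len", "l1_len", "l3_len"), key):
            lo, hi = self._bounds[axis]
            if not (lo <= value <= hi):
                raise TableRangeError(
                    f"{axis}={value} outside the table range [{lo}, {hi}]"
                )
        if key not in self._cells:
            raise TableRangeError(f"no table entry for (h2_len, l1_len, l3_len)={key}")
        return self._cells[key]

    def kissing_penalty_kbt(self, h2_len: int, l1_len: int, l3_len: int) -> float | None:
        """-T*dS in units of k_B*T from the table cell and the coil model,
        i.e. ln(omega_coil(l1)) + ln(omega_coil(l3)) - ln(omega)."""
        cell = self.lookup(h2_len, l1_len, l3_len)
        if cell is None:
            return None
        return coil_ln_omega(l1_len) + coil_ln_omega(l3_len) - cell

    def items(self):
        return self._cells.items()

    # -- serialization ---------------------------------------------------
    def to_tsv(self) -> str:
        buf = StringIO()
        for line in self.provenance.splitlines():
            buf.write(f"# {line}\n")
        df = pd.DataFrame(
            [
                {"h2_len": k[0], "l1_len": k[1], "l3_len": k[2],
                 "ln_omega": "" if v is None else f"{v:g}"}
                for k, v in sorted(self._cells.items())
            ]
        )
        df.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "EntropyTable":
        lines = text.splitlines()
        provenance = "\n".join(
            ln[2:] if ln.startswith("# ") else ln[1:]
            for ln in lines if ln.startswith("#")
        )
        body = "\n".join(ln for ln in lines if not ln.startswith("#"))
        df = pd.read_csv(StringIO(body), sep="\t", dtype={"ln_omega": str})
        cells: dict[tuple[int, int, int], float | None] = {}
        for row in df.itertuples(index=False):
            v = row.ln_omega
            missing = v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == ""
            cells[(int(row.h2_len), int(row.l1_len), int(row.l3_len))] = (
                None if missing else float(v)
            )
        return cls(cells, provenance)


def table_lookup(table: EntropyTable, h2_len: int, l1_len: int, l3_len: int) -> float | None:
    """Exact table cell, or None for a missing ('-') entry."""
    return table.lookup(h2_len, l1_len, l3_len)


def load_published_table() -> EntropyTable:
    """The shipped transcription of the published kissing-entropy table."""
    text = (
        importlib.resources.files("kisfold.data")
        .joinpath("kissing_entropy_table.tsv")
        .read_text()
    )
    return EntropyTable.from_tsv(text)


def compute_entropy_table(
    h2_range: range, l1_range: range, l3_range: range, geom: HelixGeometry = DEFAULT_GEOMETRY
) -> EntropyTable:
    """Recompute a Vfold-like ln(omega) table by lattice enumeration."""
    cells: dict[tuple[int, int, int], float | None] = {}
    for h2 in h2_range:
        for l1 in l1_range:
            for l3 in l3_range:
                le = kissing_entropy(KissingTopology(h2_len=h2, l1_len=l1, l3_len=l3), geom)
                cells[(h2, l1, l3)] = None if le.infeasible else le.ln_omega_loop
    return EntropyTable(cells, provenance="computed: ideal-geometry anchors, diamond-lattice enumeration")


# ---------------------------------------------------------------------------
# Effective loop lengths for general kissing motifs
# ---------------------------------------------------------------------------


def effective_loop_lengths(
    unpaired_counts: tuple[int, int, int, int],
    substructure_counts: tuple[int, int, int, int],
    h2_len: int,
    h1_len: int = 1,
    h3_len: int = 1,
) -> KissingTopology:
    """Reduce a general kissing motif to an effective four-loop topology.

    Each stem-loop substructure inside a loop is replaced by a single
    nucleotide, so the effective loop length is the number of unpaired
    nucleotides plus the number of stem-loop substructures.
    """
    if len(unpaired_counts) != 4 or len(substructure_counts) != 4:
        raise ValueError("expected per-loop counts for l1..l4")
    eff = [u + s for u, s in zip(unpaired_counts, substructure_counts)]
    return KissingTopology(
        h2_len=h2_len,
        l1_len=eff[0],
        l2_len=eff[1],
        l3_len=eff[2],
        l4_len=eff[3],
        h1_len=h1_len,
        h3_len=h3_len,
    )
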