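"""Exhaustive self-avoiding-walk enumeration on the diamond lattice.

The backbone of an RNA chain is represented by two virtual bonds per
nucleotide (P-C4' and C4'-P).  Loop conformations are modelled as
self-avoiding walks of these virtual bonds on the diamond lattice, which
reproduces the tetrahedral virtual-bond geometry of nucleic acids; the
conformational entropy of a loop is the logarithm of the number of viable
walks.  All enumerations here are exhaustive and deterministic -- no
sampling, no seeds.

Lattice encoding
----------------
Sites are integer triples.  Sublattice A sites have all-even coordinates
with x+y+z = 0 (mod 4); sublattice B sites have all-odd coordinates with
x+y+z = 3 (mod 4).  An A site's four neighbours are obtained by adding the
vectors (1,1,1), (1,-1,-1), (-1,1,-1), (-1,-1,1); a B site's by subtracting
them.  One lattice bond (length sqrt(3) in lattice units) maps to one
virtual bond of ``bond_length`` Angstrom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .constants import LOOP_ENUMERATION_CAP_NT, VIRTUAL_BOND_LENGTH

Site = tuple[int, int, int]

#: Neighbour displacement vectors for sublattice A (negate for B).
NEIGHBOR_VECTORS: tuple[Site, ...] = (
    (1, 1, 1),
    (1, -1, -1),
    (-1, 1, -1),
    (-1, -1, 1),
)

_VX = np.array([v[0] for v in NEIGHBOR_VECTORS], dtype=np.int64)
_VY = np.array([v[1] for v in NEIGHBOR_VECTORS], dtype=np.int64)
_VZ = np.array([v[2] for v in NEIGHBOR_VECTORS], dtype=np.int64)

#: Symmetry factor used by the free-coil enumeration: the lattice point
#: group (order 24) acts transitively on the 4 first-bond directions, and
#: the stabiliser of the first bond acts transitively on the 3 second-bond
#: directions, so walks of >= 2 steps are counted with the first two bonds
#: fixed and multiplied by 12.
FREE_COIL_SYMMETRY_FACTOR: int = 12


class EnumerationCapError(ValueError):
    """Raised when a requested enumeration exceeds the configured cap."""


@dataclass(frozen=True)
class DiamondLattice:
    """The diamond lattice with a physical bond-length scale.

    Parameters
    ----------
    bond_length:
        Physical length of one lattice bond (one virtual bond), Angstrom.
    """

    bond_length: float = VIRTUAL_BOND_LENGTH

    @property
    def unit(self) -> float:
        """Angstrom per integer lattice coordinate unit."""
        return self.bond_length / math.sqrt(3.0)

    @staticmethod
    def is_site(site: Site) -> bool:
        x, y, z = site
        if x % 2 == 0 and y % 2 == 0 and z % 2 == 0:
            return (x + y + z) % 4 == 0
        if x % 2 != 0 and y % 2 != 0 and z % 2 != 0:
            return (x + y + z) % 4 == 3
        return False

    @staticmethod
    def sublattice(site: Site) -> int:
        """0 for sublattice A (all-even), 1 for sublattice B (all-odd)."""
        if not DiamondLattice.is_site(site):
            raise ValueError(f"{site} is not a diamond-lattice site")
        return site[0] & 1

    @staticmethod
    def neighbors(site: Site) -> list[Site]:
        sign = -1 if (site[0] & 1) else 1
        if not DiamondLattice.is_site(site):
            raise ValueError(f"{site} is not a diamond-lattice site")
        return sorted(
            (site[0] + sign * v[0], site[1] + sign * v[1], site[2] + sign * v[2])
            for v in NEIGHBOR_VECTORS
        )

    def to_cartesian(self, site: Site) -> np.ndarray:
        return np.asarray(site, dtype=float) * self.unit

    def snap(self, point, parity: int | None = None) -> Site:
        """Nearest lattice site to a Cartesian point (see snap_to_lattice)."""
        return snap_to_lattice(point, self, parity=parity)


@dataclass(frozen=True)
class ConformationCount:
    """An exhaustive conformation count and its log.

    ``ln_omega`` is ln(n_conformations), or -inf for a count of zero (an
    infeasible loop, which is a legal result, not an error).  ``note``
    carries diagnostics such as anchor-parity incompatibility.
    """

    n_conformations: int
    ln_omega: float
    symmetry_factor: int = 1
    note: str | None = None

    @classmethod
    def from_count(
        cls, n: int, symmetry_factor: int = 1, note: str | None = None
    ) -> "ConformationCount":
        ln = math.log(n) if n > 0 else float("-inf")
        return cls(n_conformations=n, ln_omega=ln, symmetry_factor=symmetry_factor, note=note)


@dataclass
class LatticeWalk:
    """An anchored self-avoiding walk of virtual bonds.

    ``sites`` lists the walk vertices in order (anchor_start first).  A free
    end is represented by ``anchor_end is None``.
    """

    sites: list[Site]
    anchor_start: Site
    anchor_end: Site | None = None
    obstacles: frozenset[Site] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return max(len(self.sites) - 1, 0)

    def validate(self) -> None:
        if not self.sites:
            raise ValueError("empty walk")
        if self.sites[0] != self.anchor_start:
            raise ValueError("walk does not start at anchor_start")
        if self.anchor_end is not None and self.sites[-1] != self.anchor_end:
            raise ValueError("walk does not end at anchor_end")
        seen = set()
        for a, b in zip(self.sites, self.sites[1:]):
            if b not in DiamondLattice.neighbors(a):
                raise ValueError(f"{a} -> {b} is not a lattice bond")
        for s in self.sites:
            if not DiamondLattice.is_site(s):
                raise ValueError(f"{s} is not a lattice site")
            if s in seen:
                raise ValueError(f"site {s} revisited (walk not self-avoiding)")
            if s in self.obstacles:
                raise ValueError(f"site {s} is an obstacle")
            seen.add(s)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=False)  # caching corrupts recursive kernels on reload
def _free_dfs(x, y, z, depth, max_depth, occ, counts):
    counts[depth] += 1
    if depth == max_depth:
        return
    sign = 1 if (depth & 1) == 0 else -1
    if depth == max_depth - 1:
        c = 0
        for k in range(4):
            if occ[x + sign * _VX[k], y + sign * _VY[k], z + sign * _VZ[k]] == 0:
                c += 1
        counts[max_depth] += c
        return
    for k in range(4):
        nx = x + sign * _VX[k]
        ny = y + sign * _VY[k]
        nz = z + sign * _VZ[k]
        if occ[nx, ny, nz] == 0:
            occ[nx, ny, nz] = 1
            _free_dfs(nx, ny, nz, depth + 1, max_depth, occ, counts)
            occ[nx, ny, nz] = 0


@njit(cache=False)  # caching corrupts recursive kernels on reload
def _free_counts_kernel(max_depth):
    n = max_depth + 3
    occ = np.zeros((2 * n + 1, 2 * n + 1, 2 * n + 1), dtype=np.uint8)
    counts = np.zeros(max_depth + 1, dtype=np.int64)
    o = n
    occ[o, o, o] = 1
    # first bond fixed to +(1,1,1), second to -(1,-1,-1)
    occ[o + 1, o + 1, o + 1] = 1
    x2, y2, z2 = o, o + 2, o + 2
    occ[x2, y2, z2] = 1
    _free_dfs(x2, y2, z2, 2, max_depth, occ, counts)
    return counts


@njit(cache=False)  # caching corrupts recursive kernels on reload
def _anchored_dfs(x, y, z, depth, n_steps, start_sub, tx, ty, tz, occ):
    rem = n_steps - depth
    dx = tx - x if tx >= x else x - tx
    dy = ty - y if ty >= y else y - ty
    dz = tz - z if tz >= z else z - tz
    m = dx
    if dy > m:
        m = dy
    if dz > m:
        m = dz
    if m > rem:
        return 0
    if rem == 0:
        return 1  # pruning guarantees (x, y, z) == target here
    parity = (start_sub + depth) & 1
    sign = 1 if parity == 0 else -1
    total = 0
    for k in range(4):
        nx = x + sign * _VX[k]
        ny = y + sign * _VY[k]
        nz = z + sign * _VZ[k]
        if occ[nx, ny, nz] == 0:
            if rem == 1:
                if nx == tx and ny == ty and nz == tz:
                    total += 1
            else:
                occ[nx, ny, nz] = 1
                total += _anchored_dfs(
                    nx, ny, nz, depth + 1, n_steps, start_sub, tx, ty, tz, occ
                )
                occ[nx, ny, nz] = 0
    return total


# ---------------------------------------------------------------------------
# Free-coil enumeration
# ---------------------------------------------------------------------------

# One DFS to depth d yields counts for every depth <= d; cache the deepest run.
_FREE_COUNTS_CACHE: dict[str, np.ndarray] = {}


def count_free_walks(n_steps: int) -> int:
    """Exact number of self-avoiding walks of ``n_steps`` bonds from a site.

    Absolute count over all first-bond directions (no symmetry reduction in
    the returned value; internally walks of >= 2 steps are enumerated with
    the first two bonds fixed and scaled by ``FREE_COIL_SYMMETRY_FACTOR``).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if n_steps == 1:
        return 4  # the coordination number of the diamond lattice
    cached = _FREE_COUNTS_CACHE.get("counts")
    if cached is None or len(cached) <= n_steps:
        counts = _free_counts_kernel(n_steps)
        _FREE_COUNTS_CACHE["counts"] = counts
        cached = counts
    return int(cached[n_steps]) * FREE_COIL_SYMMETRY_FACTOR


def enumerate_free_coil(n_nt: int, cap: int = LOOP_ENUMERATION_CAP_NT) -> ConformationCount:
    """Count free-coil conformations of an ``n_nt``-nucleotide chain.

    Each nucleotide contributes two virtual bonds, so the chain is a
    2*n_nt-step self-avoiding walk anchored at a fixed origin.
    """
    if n_nt < 1:
        raise ValueError("n_nt must be >= 1")
    if n_nt > cap:
        raise EnumerationCapError(
            f"free-coil enumeration for {n_nt} nt exceeds the cap of {cap} nt; "
            "use the entropy-table interface for longer loops"
        )
    n = count_free_walks(2 * n_nt)
    return ConformationCount.from_count(n, symmetry_factor=FREE_COIL_SYMMETRY_FACTOR)


def free_coil_series(n_nt_max: int, cap: int = LOOP_ENUMERATION_CAP_NT) -> dict[int, int]:
    """Free-coil counts for every chain length 1..n_nt_max (single DFS pass)."""
    if n_nt_max > cap:
        raise EnumerationCapError(
            f"free-coil enumeration for {n_nt_max} nt exceeds the cap of {cap} nt"
        )
    count_free_walks(2 * n_nt_max)  # fills the cache to the deepest level
    return {n: count_free_walks(2 * n) for n in range(1, n_nt_max + 1)}


# ---------------------------------------------------------------------------
# Anchored enumeration
# ---------------------------------------------------------------------------


def count_anchored_walks(
    anchor_start: Site,
    anchor_end: Site,
    n_steps: int,
    obstacles: frozenset[Site] | set[Site] = frozenset(),
) -> ConformationCount:
    """Exact count of self-avoiding walks between two anchors.

    Walks have exactly ``n_steps`` bonds, start at ``anchor_start``, end at
    ``anchor_end`` and avoid every obstacle site.  A count of zero is a
    legal result.  Parity-incompatible anchors return 0 with a diagnostic
    note rather than raising.
    """
    for a in (anchor_start, anchor_end):
        if not DiamondLattice.is_site(a):
            raise ValueError(f"anchor {a} is not a diamond-lattice site")
    if anchor_start in obstacles or anchor_end in obstacles:
        raise ValueError("obstacles must not contain the anchors")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")

    start_sub = DiamondLattice.sublattice(anchor_start)
    end_sub = DiamondLattice.sublattice(anchor_end)
    if (start_sub + n_steps) % 2 != end_sub:
        return ConformationCount.from_count(
            0, note="anchor sublattices incompatible with the step parity"
        )
    delta = tuple(e - s for s, e in zip(anchor_start, anchor_end))
    if any((d - n_steps) % 2 != 0 for d in delta):
        return ConformationCount.from_count(
            0, note="anchor displacement parity incompatible with the step count"
        )
    if anchor_start == anchor_end and n_steps >= 1:
        # a self-avoiding walk can never return to its origin
        return ConformationCount.from_count(0, note="closed walks are excluded by self-avoidance")
    if max(abs(d) for d in delta) > n_steps:
        return ConformationCount.from_count(0, note="anchors out of reach for the step count")

    # Build a translated occupancy grid covering anchors, obstacles and reach.
    margin = n_steps + 1
    pts = [anchor_start, anchor_end]
    lo = [min(p[i] for p in pts) - margin for i in range(3)]
    hi = [max(p[i] for p in pts) + margin for i in range(3)]
    dims = tuple(h - l + 1 for l, h in zip(lo, hi))
    occ = np.zeros(dims, dtype=np.uint8)
    for s in obstacles:
        idx = tuple(c - l for c, l in zip(s, lo))
        if all(0 <= i < d for i, d in zip(idx, dims)):
            occ[idx] = 1
    sx, sy, sz = (c - l for c, l in zip(anchor_start, lo))
    tx, ty, tz = (c - l for c, l in zip(anchor_end, lo))
    occ[sx, sy, sz] = 1
    n = _anchored_dfs(sx, sy, sz, 0, n_steps, start_sub, tx, ty, tz, occ)
    return ConformationCount.from_count(int(n))


def enumerate_anchored_loop(
    anchor_start: Site,
    anchor_end: Site,
    n_nt: int,
    obstacles: frozenset[Site] | set[Site] = frozenset(),
    cap: int = LOOP_ENUMERATION_CAP_NT,
) -> ConformationCount:
    """Count loop conformations of ``n_nt`` nucleotides between two anchors.

    The loop contributes 2*n_nt virtual bonds; counts are absolute (no
    symmetry reduction -- the anchors break the lattice symmetry).
    """
    if n_nt < 1:
        raise ValueError("n_nt must be >= 1")
    if n_nt > cap:
        raise EnumerationCapError(
            f"anchored-loop enumeration for {n_nt} nt exceeds the cap of {cap} nt"
        )
    return count_anchored_walks(anchor_start, anchor_end, 2 * n_nt, obstacles)


def first_anchored_walk(
    anchor_start: Site,
    anchor_end: Site,
    n_steps: int,
    obstacles: frozenset[Site] | set[Site] = frozenset(),
) -> LatticeWalk | None:
    """The first anchored walk in deterministic (sorted-neighbour) order.

    Returns None when no walk exists.  Used by the scaffold assembler to
    pick a reproducible loop conformation without enumerating all of them.
    """
    check = count_anchored_walks(anchor_start, anchor_end, n_steps, obstacles)
    if check.n_conformations == 0 and check.note is not None:
        return None
    obstacles = frozenset(obstacles)
    path = [anchor_start]
    visited = {anchor_start}

    def dfs() -> bool:
        cur = path[-1]
        rem = n_steps - (len(path) - 1)
        if rem == 0:
            return cur == anchor_end
        if max(abs(e - c) for c, e in zip(cur, anchor_end)) > rem:
            return False
        for nb in DiamondLattice.neighbors(cur):
            if nb in visited or nb in obstacles:
                continue
            path.append(nb)
            visited.add(nb)
            if dfs():
                return True
            path.pop()
            visited.remove(nb)
        return False

    if not dfs():
        return None
    return LatticeWalk(
        sites=list(path),
        anchor_start=anchor_start,
        anchor_end=anchor_end,
        obstacles=obstacles,
    )


# ---------------------------------------------------------------------------
# Snapping
# ---------------------------------------------------------------------------


def snap_to_lattice(
    point, lattice: DiamondLattice | None = None, parity: int | None = None
) -> Site:
    """Nearest diamond-lattice site to a Cartesian point.

    Ties are broken deterministically toward the lexicographically smallest
    site.  ``parity`` (0 = sublattice A, 1 = B) restricts the search to one
    sublattice, which callers use to keep anchor pairs walk-compatible.
    """
    lattice = lattice or DiamondLattice()
    p = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("point coordinates must be finite")
    u = p / lattice.unit
    base = np.floor(u).astype(int)
    best: Site | None = None
    best_d2 = math.inf
    for dx in range(-2, 4):
        for dy in range(-2, 4):
            for dz in range(-2, 4):
                site = (int(base[0] + dx), int(base[1] + dy), int(base[2] + dz))
                if not DiamondLattice.is_site(site):
                    continue
                if parity is not None and (site[0] & 1) != parity:
                    continue
                d2 = float(np.sum((np.asarray(site) - u) ** 2))
                if d2 < best_d2 - 1e-9 or (
                    abs(d2 - best_d2) <= 1e-9 and (best is None or site < best)
                ):
                    best = site
                    best_d2 = d2
    assert best is not None
    return best
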