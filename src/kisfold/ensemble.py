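"""Two-strand partition functions, association thermodynamics, and
(native, non-native) free-energy landscapes at toy scale.

The two-strand system is split into unbound and bound ensembles:

    Q(T) = Q1 * Q2 + exp(-dG_associate / k_B T) * Q12

with Q1/Q2 the single-strand partition functions, Q12 the bound-complex
partition function, and the concentration-dependent association penalty

    dG_associate = dG_init - k_B T ln(C_T / 4).

Structures are enumerated exhaustively (complete sets of base pairs under
helix/loop constraints, kissing allowed), so all sums are exact; this
restricts inputs to a combined-length cap.  Both strands are taken at
C_T/2 with the printed C_T/4 convention used verbatim; homodimer symmetry
corrections are not applied.

Each structure is scored as dG(T) = dH - T*dS + dG_x, with dH/dS from the
nearest-neighbor table (stacks + terminal penalties; the bimolecular
initiation lives in dG_init), the kissing entropy (from the published
table against the 2.05*l + 0.1 coil) entering dS, and the affine
pseudoknot penalty dG_x used only when no table cell applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import DG_INIT, DIMER_LENGTH_CAP_NT, T_DEFAULT, KB_KCAL_PER_MOL_K, kbt
from .energetics import (
    NNTable,
    PseudoknotFeatures,
    PseudoknotPenaltyParams,
    load_nn_table,
    pseudoknot_energy,
    stem_enthalpy_entropy,
)
from .entropy import EntropyTable, TableRangeError, coil_ln_omega, load_published_table
from .structure import CANONICAL_PAIRS, SecondaryStructure, pairs_cross


@dataclass(frozen=True)
class EnsembleParams:
    """Thermodynamic conditions for the two-strand system."""

    temperature: float = T_DEFAULT
    c_total: float = 1e-6  # total strand concentration, mol/L
    dg_init: float = DG_INIT  # association initiation, kcal/mol
    include_unpaired_associated: bool = True

    def __post_init__(self):
        if self.c_total <= 0:
            raise ValueError("c_total must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class StructureConstraints:
    """Enumeration constraints keeping the toy ensemble exact."""

    min_helix: int = 2
    min_hairpin: int = 3
    length_cap: int = DIMER_LENGTH_CAP_NT


def associate_free_energy(params: EnsembleParams, temperature: float | None = None) -> float:
    """dG_associate = dG_init - k_B T ln(C_T / 4), kcal/mol."""
    t = params.temperature if temperature is None else temperature
    return params.dg_init - kbt(t) * math.log(params.c_total / 4.0)


# ---------------------------------------------------------------------------
# Structure enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoredStructure:
    """A structure with its enthalpy/entropy decomposition.

    dG(T) = dh - T * ds + dg_const (dg_const holds the affine pseudoknot
    fallback penalty, which has no tabulated dH/dS split).
    """

    structure: SecondaryStructure
    dh: float = 0.0
    ds: float = 0.0  # kcal/mol/K
    dg_const: float = 0.0
    kissing: tuple[int, int, int] | None = None  # (S, l1, l3) when detected

    def energy(self, temperature: float) -> float:
        return self.dh - temperature * self.ds + self.dg_const


def _candidate_runs(seqs: tuple[str, ...], constraints: StructureConstraints):
    """All maximal-extendable stacked runs of canonical pairs, as
    (pairs tuple, base bitmask)."""
    offsets = []
    acc = 0
    for s in seqs:
        offsets.append(acc)
        acc += len(s)
    n = acc
    flat = "".join(seqs)

    def strand_of(i):
        return 0 if len(offsets) == 1 or i < offsets[-1] else 1

    def ok_pair(i, j):
        if not (0 <= i < j < n):
            return False
        if (flat[i], flat[j]) not in CANONICAL_PAIRS:
            return False
        if strand_of(i) == strand_of(j) and j - i - 1 < constraints.min_hairpin:
            return False
        return True

    runs = []
    for i in range(n):
        for j in range(i + 1, n):
            if not ok_pair(i, j):
                continue
            sig = (strand_of(i), strand_of(j))
            # runs starting at the outermost pair (i, j)
            length = 0
            a, b = i, j
            while a < b and ok_pair(a, b) and (strand_of(a), strand_of(b)) == sig:
                length += 1
                a, b = a + 1, b - 1
            for m in range(constraints.min_helix, length + 1):
                pairs = tuple((i + t, j - t) for t in range(m))
                mask = 0
                for x, y in pairs:
                    mask |= (1 << x) | (1 << y)
                runs.append((pairs, mask))
    return runs


def _runs_cross(r1, r2) -> bool:
    return pairs_cross(r1[0], r2[0])


def _crossing_ok(chosen) -> bool:
    """No crossings, or all crossings share one common helix (a single
    kissing/pseudoknot interaction)."""
    crossings = [
        (a, b)
        for a in range(len(chosen))
        for b in range(a + 1, len(chosen))
        if _runs_cross(chosen[a][0], chosen[b][0])
    ]
    if not crossings:
        return True
    common = set(crossings[0])
    for c in crossings[1:]:
        common &= set(c)
    return bool(common)


def _enumerate_pair_sets(seqs: tuple[str, ...], constraints: StructureConstraints):
    """Every valid pair set, as a tuple of chosen runs.

    Two contiguously stacking runs are never chosen together (the merged
    run is its own candidate), so each pair set appears exactly once, with
    the chosen runs being exactly its maximal helices.
    """
    runs = sorted(_candidate_runs(seqs, constraints))
    out = []

    def extends(r_outer, r_inner) -> bool:
        a, b = r_outer[0][-1]
        return r_inner[0][0] == (a + 1, b - 1)

    def dfs(start: int, chosen: list, mask: int):
        if _crossing_ok(chosen):
            out.append(tuple(chosen))
        for k in range(start, len(runs)):
            pairs, rmask = runs[k]
            if rmask & mask:
                continue
            if any(extends(c, runs[k]) or extends(runs[k], c) for c in chosen):
                continue
            chosen.append(runs[k])
            dfs(k + 1, chosen, mask | rmask)
            chosen.pop()

    dfs(0, [], 0)
    return out


def _detect_kissing(structure: SecondaryStructure):
    """(S, l1, l3, l2, l4) of a two-hairpin kissing complex, or None."""
    if structure.n_strands != 2 or not structure.crossing_pairs:
        return None
    helices = structure.helices()
    inter = [h for h in helices if not structure.is_intra(h[0])]
    intra = [h for h in helices if structure.is_intra(h[0])]
    if len(inter) != 1 or len(intra) != 2:
        return None
    intra.sort(key=lambda h: structure.strand_of(h[0][0]))
    if {structure.strand_of(h[0][0]) for h in intra} != {0, 1}:
        return None
    kiss = inter[0]
    s1_in, s1_jn = intra[0][-1]
    s2_in, s2_jn = intra[1][-1]
    ka0, kb_hi = kiss[0]  # outermost kissing pair: smallest i, largest j
    ka_end, kb_lo = kiss[-1]
    l1 = ka0 - s1_in - 1
    l2 = s1_jn - ka_end - 1
    l3 = kb_lo - s2_in - 1
    l4 = s2_jn - kb_hi - 1
    if min(l1, l2, l3, l4) < 0:
        return None
    return len(kiss), l1, l3, l2, l4


@lru_cache(maxsize=8)
def _shared_tables() -> tuple[NNTable, EntropyTable]:
    return load_nn_table(), load_published_table()


def _score(
    structure: SecondaryStructure,
    nn: NNTable,
    table: EntropyTable,
    pk_params: PseudoknotPenaltyParams,
) -> ScoredStructure:
    dh = 0.0
    ds = 0.0
    dg_const = 0.0
    for helix in structure.helices():
        top = "".join(structure.base(i) for i, _ in helix)
        bottom = "".join(structure.base(j) for _, j in helix)
        hdh, hds = stem_enthalpy_entropy(top, bottom, nn)
        # remove the bimolecular initiation: association is priced by dG_init
        hdh -= nn.init[0]
        hds -= (nn.init[0] - nn.init[1]) / 310.15
        dh += hdh
        ds += hds
    kissing = None
    if structure.crossing_pairs:
        kiss = _detect_kissing(structure)
        cell = None
        if kiss is not None:
            s_len, l1, l3, l2, l4 = kiss
            kissing = (s_len, l1, l3)
            if l2 <= 1 and l4 <= 1 and min(l1, l3) >= 1:
                try:
                    cell = table.lookup(s_len, l1, l3)
                except TableRangeError:
                    cell = None
        if cell is not None:
            delta_s_kb = cell - coil_ln_omega(l1) - coil_ln_omega(l3)  # negative
            ds += KB_KCAL_PER_MOL_K * delta_s_kb
        else:
            # affine pseudoknot fallback: border pairs ~ one per involved
            # helix end facing the interior; unpaired bases inside the span
            span_pairs = sorted(structure.crossing_pairs)
            lo = min(p[0] for p in span_pairs)
            hi = max(p[1] for p in span_pairs)
            paired = {k for p in structure.pairs for k in p}
            u_p = sum(1 for k in range(lo, hi + 1) if k not in paired)
            involved = {
                h
                for h in structure.helices()
                if any(p in structure.crossing_pairs for p in h)
            }
            features = PseudoknotFeatures(n_border_pairs=2 * len(involved), n_unpaired=u_p)
            dg_const += pseudoknot_energy(features, pk_params)
    return ScoredStructure(structure=structure, dh=dh, ds=ds, dg_const=dg_const, kissing=kissing)


def enumerate_structures(
    seq1: str,
    seq2: str | None = None,
    constraints: StructureConstraints = StructureConstraints(),
    nn_table: NNTable | None = None,
    entropy_table: EntropyTable | None = None,
    pk_params: PseudoknotPenaltyParams = PseudoknotPenaltyParams(),
) -> list[ScoredStructure]:
    """Exhaustively enumerate and score secondary structures.

    With one sequence: all intramolecular structures.  With two: all
    structures of the bound two-strand system (intra + intermolecular,
    kissing allowed).  The open/unpaired state is always included at
    energy 0.
    """
    seqs = (seq1,) if seq2 is None else (seq1, seq2)
    seqs = tuple(s.strip().upper().replace("T", "U") for s in seqs)
    total = sum(len(s) for s in seqs)
    if total > constraints.length_cap:
        raise ValueError(
            f"combined length {total} nt exceeds the exhaustive-enumeration "
            f"cap of {constraints.length_cap} nt; reduce the input"
        )
    nn_default, table_default = _shared_tables()
    nn = nn_table or nn_default
    table = entropy_table or table_default
    out = []
    for chosen in _enumerate_pair_sets(seqs, constraints):
        pairs = tuple(p for run, _ in chosen for p in run)
        structure = SecondaryStructure(sequences=seqs, pairs=pairs)
        out.append(_score(structure, nn, table, pk_params))
    return out


@dataclass
class DimerEnsemble:
    """The three exhaustive ensembles of a two-strand system."""

    seq1: str
    seq2: str
    strand1: list[ScoredStructure]
    strand2: list[ScoredStructure]
    dimer: list[ScoredStructure]

    @classmethod
    def build(
        cls,
        seq1: str,
        seq2: str,
        constraints: StructureConstraints = StructureConstraints(),
        **kwargs,
    ) -> "DimerEnsemble":
        return cls(
            seq1=seq1,
            seq2=seq2,
            strand1=enumerate_structures(seq1, constraints=constraints, **kwargs),
            strand2=enumerate_structures(seq2, constraints=constraints, **kwargs),
            dimer=enumerate_structures(seq1, seq2, constraints=constraints, **kwargs),
        )


# ---------------------------------------------------------------------------
# Partition functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PartitionSet:
    """Boltzmann sums for the unbound strands and the bound complex."""

    q1: float
    q2: float
    q12: float
    q_total: float
    log_q1: float
    log_q2: float
    log_q12: float
    log_q_total: float
    bound_fraction: float
    dg_associate: float
    temperature: float


def _bound_states(ensemble: DimerEnsemble, params: EnsembleParams) -> list[ScoredStructure]:
    if params.include_unpaired_associated:
        return ensemble.dimer
    return [s for s in ensemble.dimer if s.structure.intermolecular_pairs]


def partition_functions(ensemble: DimerEnsemble, params: EnsembleParams) -> PartitionSet:
    """Q1, Q2, Q12 and the bound fraction at params.temperature.

    Sums run in log space (log-sum-exp), so results stay finite for
    energies up to a few hundred kcal/mol.
    """
    t = params.temperature
    beta = 1.0 / kbt(t)

    def log_q(states: list[ScoredStructure]) -> float:
        energies = [s.energy(t) for s in states]
        if not energies:
            return -math.inf
        return float(logsumexp([-beta * e for e in energies]))

    lq1 = log_q(ensemble.strand1)
    lq2 = log_q(ensemble.strand2)
    bound = _bound_states(ensemble, params)
    lq12 = log_q(bound)
    dga = associate_free_energy(params, t)
    lbound = -beta * dga + lq12
    lqtot = float(np.logaddexp(lq1 + lq2, lbound))
    return PartitionSet(
        q1=math.exp(lq1),
        q2=math.exp(lq2),
        q12=math.exp(lq12),
        q_total=math.exp(lqtot),
        log_q1=lq1,
        log_q2=lq2,
        log_q12=lq12,
        log_q_total=lqtot,
        bound_fraction=math.exp(lbound - lqtot),
        dg_associate=dga,
        temperature=t,
    )


# ---------------------------------------------------------------------------
# Landscapes
# ---------------------------------------------------------------------------


@dataclass
class LandscapeGrid:
    """Partition-function mass and free energy binned by (native,
    non-native) base-pair counts relative to a reference structure."""

    mass: dict[tuple[int, int], float]
    free_energy: dict[tuple[int, int], float]
    probability: dict[tuple[int, int], float]
    reference: SecondaryStructure
    temperature: float

    @property
    def total_mass(self) -> float:
        return sum(self.mass.values())

    def local_minima(self) -> list[tuple[int, int]]:
        """Bins strictly lower in free energy than all 8 neighbours
        (absent neighbours count as infinitely high)."""
        minima = []
        for (n, nn), f in self.free_energy.items():
            nbrs = [
                self.free_energy.get((n + dn, nn + dm), math.inf)
                for dn in (-1, 0, 1)
                for dm in (-1, 0, 1)
                if (dn, dm) != (0, 0)
            ]
            if all(f < g for g in nbrs):
                minima.append((n, nn))
        return sorted(minima)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "native": k[0],
                "non_native": k[1],
                "free_energy_kcal_mol": self.free_energy[k],
                "probability": self.probability[k],
            }
            for k in sorted(self.mass)
        ]
        return pd.DataFrame(rows)


def landscape(
    ensemble: DimerEnsemble,
    reference: SecondaryStructure,
    params: EnsembleParams,
) -> LandscapeGrid:
    """Bin the bound ensemble by (native, non-native) base-pair counts.

    A native pair is any pair of the reference structure; a non-native pair
    is any pair absent from it, intramolecular ones included.  Bin mass is
    summed Boltzmann weight (association factor included), so the total
    over bins equals exp(-dG_assoc/k_B T) * Q12.
    """
    if reference.sequences != (
        ensemble.strand1[0].structure.sequences[0],
        ensemble.strand2[0].structure.sequences[0],
    ):
        raise ValueError("reference structure must be over the same sequence pair")
    t = params.temperature
    beta = 1.0 / kbt(t)
    dga = associate_free_energy(params, t)
    ref = set(reference.pairs)
    mass: dict[tuple[int, int], float] = {}
    for s in _bound_states(ensemble, params):
        pairs = set(s.structure.pairs)
        key = (len(pairs & ref), len(pairs - ref))
        mass[key] = mass.get(key, 0.0) + math.exp(-beta * (s.energy(t) + dga))
    total = sum(mass.values())
    free_energy = {k: -kbt(t) * math.log(m) for k, m in mass.items()}
    probability = {k: m / total for k, m in mass.items()}
    return LandscapeGrid(
        mass=mass,
        free_energy=free_energy,
        probability=probability,
        reference=reference,
        temperature=t,
    )


# ---------------------------------------------------------------------------
# Melting
# ---------------------------------------------------------------------------


def classify_structure(s: ScoredStructure) -> str:
    """Partition of bound-ensemble structures into species classes."""
    st = s.structure
    if st.intermolecular_pairs and st.crossing_pairs:
        return "kissing"
    if st.intermolecular_pairs:
        return "extended_duplex"
    return "other_bound"


def melting_profile(
    ensemble: DimerEnsemble,
    params: EnsembleParams,
    t_grid,
) -> pd.DataFrame:
    """Bound fraction and species populations over a temperature grid.

    Populations are fractions of the full system (unbound + bound) and sum
    to 1 at every temperature.
    """
    t_grid = list(t_grid)
    if any(b <= a for a, b in zip(t_grid, t_grid[1:])):
        raise ValueError("temperature grid must be strictly increasing")
    rows = []
    for t in t_grid:
        p = EnsembleParams(
            temperature=t,
            c_total=params.c_total,
            dg_init=params.dg_init,
            include_unpaired_associated=params.include_unpaired_associated,
        )
        ps = partition_functions(ensemble, p)
        beta = 1.0 / kbt(t)
        row = {
            "temperature": t,
            "bound_fraction": ps.bound_fraction,
            "p_unbound": 1.0 - ps.bound_fraction,
            "p_kissing": 0.0,
            "p_extended_duplex": 0.0,
            "p_other_bound": 0.0,
        }
        for s in _bound_states(ensemble, p):
            w = math.exp(-beta * (s.energy(t) + ps.dg_associate) - ps.log_q_total)
            row[f"p_{classify_structure(s)}"] += w
        rows.append(row)
    return pd.DataFrame(rows)
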