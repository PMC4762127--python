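"""Closed-form free-energy models.

Four ingredients of kissing-complex/pseudoknot thermodynamics:

* nearest-neighbor stem free energies from a shipped stack table
  (parameters are data, not code);
* the affine H-type pseudoknot penalty
  G_pseudo = beta1 + beta2 * B_p + beta3 * U_p, with B_p the base pairs
  bordering the pseudoknot interior and U_p the unpaired bases inside it;
* the freely-jointed-chain (FJC) loop-stretching free energy beta*G(N,M,z)
  for a loop of N single-stranded segments (length a = 6.2 A) and M helix
  crossing segments (length b = 15 A) stretched to end-to-end distance z,
  with the Flory radius R_F = (N^(6/5) a^2 + M^(6/5) b^2)^(1/2);
* the total kissing-complex free energy
  dG = dG_stem1 + dG_stem2 + dG_kissing-stem - T*dS(S, l1, l2, l3, l4),
  with the entropy term supplied in k_B*T units.

beta is 1/(k_B*T) throughout: the FJC expression is dimensionless only
under that reading.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from io import StringIO

import pandas as pd

from .constants import T_DEFAULT, kbt

#: Fixed shortest-extension constant (Angstrom) in the FJC log term.
FJC_MIN_EXTENSION = 2.4


@dataclass(frozen=True)
class PseudoknotPenaltyParams:
    """Affine pseudoknot penalty coefficients, kcal/mol.

    Defaults are the commonly used H-type pseudoknot constants; all three
    are configurable data.
    """

    beta1: float = 9.6
    beta2: float = 0.1
    beta3: float = 0.6

    def __post_init__(self):
        for v in (self.beta1, self.beta2, self.beta3):
            if not math.isfinite(v):
                raise ValueError("pseudoknot penalty coefficients must be finite")


@dataclass(frozen=True)
class PseudoknotFeatures:
    """Counts entering the affine penalty: border pairs B_p, unpaired U_p."""

    n_border_pairs: int
    n_unpaired: int

    def __post_init__(self):
        if self.n_border_pairs < 0 or self.n_unpaired < 0:
            raise ValueError("pseudoknot feature counts must be non-negative")


@dataclass(frozen=True)
class FJCParams:
    """Freely-jointed-chain constants: segment lengths a (single-stranded)
    and b (helix crossing), Angstrom, and the reference constant C0
    (kcal/mol, set from experiment; defaults to 0)."""

    a: float = 6.2
    b: float = 15.0
    c0: float = 0.0

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("FJC segment lengths must be positive")


@dataclass(frozen=True)
class FreeEnergyBreakdown:
    """Total kissing-complex free energy and its reported parts."""

    stem_terms: tuple[float, ...]
    entropy_term_kbt: float
    temperature: float
    total: float
    note: str | None = None


def pseudoknot_energy(
    features: PseudoknotFeatures, params: PseudoknotPenaltyParams = PseudoknotPenaltyParams()
) -> float:
    """G_pseudo = beta1 + beta2 * B_p + beta3 * U_p, kcal/mol."""
    return params.beta1 + params.beta2 * features.n_border_pairs + params.beta3 * features.n_unpaired


def flory_radius(N: int, M: int, params: FJCParams = FJCParams()) -> float:
    """Flory radius R_F = (N^(6/5) a^2 + M^(6/5) b^2)^(1/2), Angstrom."""
    if N < 0 or M < 0:
        raise ValueError("segment counts must be non-negative")
    if N + M == 0:
        raise ValueError("at least one segment is required (N + M >= 1)")
    return math.sqrt(N ** 1.2 * params.a**2 + M ** 1.2 * params.b**2)


def fjc_stretch_free_energy(
    N: int,
    M: int,
    z: float,
    params: FJCParams = FJCParams(),
    temperature: float = T_DEFAULT,
) -> float:
    """Dimensionless beta*G(N, M, z) of stretching a loop to extension z.

    All five terms of the closed form are evaluated; at z = R_F the three
    z-dependent terms vanish identically and
    beta*G - beta*C0 = (3/2) ln(N^(6/5) a^2 + M^(6/5) b^2) = 3 ln R_F.
    """
    rf = flory_radius(N, M, params)
    contour = N * params.a + M * params.b
    zmin = FJC_MIN_EXTENSION
    if z <= zmin:
        raise ValueError(f"z = {z} violates the lower log bound z > {zmin} A")
    if z >= contour:
        raise ValueError(
            f"z = {z} violates the upper log bound z < N*a + M*b = {contour} A"
        )
    beta_c0 = params.c0 / kbt(temperature)
    term1 = 1.5 * math.log(N ** 1.2 * params.a**2 + M ** 1.2 * params.b**2)
    term3 = -(5.0 / 18.0) * math.log((z - zmin) / (rf - zmin))
    term4 = -(N + M - 2) * math.log((contour - z) / (contour - rf))
    slope = (
        5.0 / (2.0 * rf)
        + 5.0 / (18.0 * (rf - zmin))
        - (N + M - 2) / (contour - rf)
    )
    term5 = slope * (z - rf)
    return term1 + beta_c0 + term3 + term4 + term5


def kissing_complex_free_energy(
    stem_energies: tuple[float, ...] | list[float],
    entropy_term_kbt: float,
    temperature: float = T_DEFAULT,
    topology=None,
) -> FreeEnergyBreakdown:
    """Total kissing-complex free energy in kcal/mol.

    ``stem_energies`` are the nearest-neighbor free energies of stem1,
    stem2 and the kissing stem (kcal/mol); ``entropy_term_kbt`` is the
    kissing entropy penalty -T*dS in units of k_B*T (positive = penalty).
    A non-finite entropy term (infeasible loop) yields total = +inf with a
    diagnostic rather than an exception.
    """
    stems = tuple(float(e) for e in stem_energies)
    if not math.isfinite(entropy_term_kbt):
        return FreeEnergyBreakdown(
            stem_terms=stems,
            entropy_term_kbt=entropy_term_kbt,
            temperature=temperature,
            total=float("inf"),
            note="infeasible kissing loop: no viable conformation",
        )
    total = sum(stems) + entropy_term_kbt * kbt(temperature)
    return FreeEnergyBreakdown(
        stem_terms=stems,
        entropy_term_kbt=entropy_term_kbt,
        temperature=temperature,
        total=total,
    )


# ---------------------------------------------------------------------------
# Nearest-neighbor stem energies
# ---------------------------------------------------------------------------

_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
_WEAK_TERMINAL = {("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class NNTable:
    """Nearest-neighbor stack parameters (dH, dG37) plus special terms."""

    stacks: dict[str, tuple[float, float]] = field(default_factory=dict)
    init: tuple[float, float] = (0.0, 0.0)
    terminal_au: tuple[float, float] = (0.0, 0.0)

    @staticmethod
    def _normalize(key: str) -> str:
        top, bottom = key.split("/")
        flipped = bottom[::-1] + "/" + top[::-1]
        return min(key, flipped)

    def stack(self, key: str) -> tuple[float, float]:
        k = self._normalize(key)
        if k not in self.stacks and key not in self.stacks:
            raise KeyError(f"stack {key} not in the parameter table")
        return self.stacks.get(k, self.stacks.get(key))

    @classmethod
    def from_tsv(cls, text: str) -> "NNTable":
        body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("#"))
        df = pd.read_csv(StringIO(body), sep="\t")
        stacks: dict[str, tuple[float, float]] = {}
        init = terminal_au = (0.0, 0.0)
        for row in df.itertuples(index=False):
            if row.stack == "init":
                init = (float(row.dH), float(row.dG37))
            elif row.stack == "terminal_au":
                terminal_au = (float(row.dH), float(row.dG37))
            else:
                stacks[cls._normalize(row.stack)] = (float(row.dH), float(row.dG37))
        return cls(stacks=stacks, init=init, terminal_au=terminal_au)


def load_nn_table() -> NNTable:
    text = importlib.resources.files("kisfold.data").joinpath("nn_stacks.tsv").read_text()
    return NNTable.from_tsv(text)


def stem_enthalpy_entropy(
    top: str, bottom: str, table: NNTable | None = None
) -> tuple[float, float]:
    """(dH, dS) of a duplex: stack terms + initiation + terminal penalties.

    ``top`` is the 5'->3' strand, ``bottom`` the 3'->5' strand aligned under
    it; every opposing pair must be canonical.  dS is in kcal/mol/K,
    derived from dH and dG37 via dS = (dH - dG37) / 310.15.
    """
    table = table or load_nn_table()
    top, bottom = top.upper(), bottom.upper()
    if len(top) != len(bottom) or len(top) < 1:
        raise ValueError("duplex strands must be non-empty and equal length")
    for k, (x, w) in enumerate(zip(top, bottom)):
        if (x, w) not in _CANONICAL:
            raise ValueError(f"non-canonical pair {x}-{w} at duplex position {k + 1}")
    dh, dg37 = table.init
    for k in range(len(top) - 1):
        key = f"{top[k]}{top[k + 1]}/{bottom[k]}{bottom[k + 1]}"
        sdh, sdg = table.stack(key)
        dh += sdh
        dg37 += sdg
    for end in (0, len(top) - 1):
        if (top[end], bottom[end]) in _WEAK_TERMINAL:
            dh += table.terminal_au[0]
            dg37 += table.terminal_au[1]
    ds = (dh - dg37) / 310.15
    return dh, ds


def stem_free_energy(
    top: str, bottom: str, table: NNTable | None = None, temperature: float = T_DEFAULT
) -> float:
    """Nearest-neighbor duplex free energy dG(T) = dH - T*dS, kcal/mol."""
    dh, ds = stem_enthalpy_entropy(top, bottom, table)
    return dh - temperature * ds
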