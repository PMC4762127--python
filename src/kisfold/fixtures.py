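"""Deterministic synthetic fixtures: hairpins, kissing dimers, and a
two-minimum dimer.

The dimer fixtures emulate the architecture of dimerization-initiation
kissing systems: two hairpins with reverse-complementary loops that can
either kiss loop-to-loop or melt open and zip into an extended duplex.
Real dimerization sequences are not part of the package, so the
two-minimum fixture is an engineered palindrome-loop dimer whose exhaustive
landscape is verified at generation time to show the two coexisting basins
(kissing vs extended duplex).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import SecondaryStructure

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


class FixtureError(RuntimeError):
    """Fixture generation failed after bounded retries."""


@dataclass(frozen=True)
class Fixture:
    kind: str
    seed: int
    sequences: tuple[str, ...]
    reference: SecondaryStructure


def _random_stem(rng: np.random.Generator, n: int, gc_bias: float = 0.7) -> str:
    bases = rng.choice(
        ["G", "C", "A", "U"],
        size=n,
        p=[gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2, (1 - gc_bias) / 2],
    )
    return "".join(bases)


def _hairpin(rng: np.random.Generator, stem_len: int = 4, loop_len: int = 4) -> Fixture:
    stem = _random_stem(rng, stem_len)
    loop = "".join(rng.choice(["A", "U"], size=loop_len))
    seq = stem + loop + revcomp(stem)
    n = len(seq)
    pairs = tuple((i, n - 1 - i) for i in range(stem_len))
    return Fixture("hairpin", 0, (seq,), SecondaryStructure((seq,), pairs))


def _kissing_reference(seq1: str, seq2: str, stem_len: int, l1: int, kiss_len: int):
    """Reference pairs for two hairpins (stem + l1 + kiss + stem') whose
    loops kiss: chain layout stem-up, l1, kiss, stem-down with l2 = 0."""
    n1 = len(seq1)
    pairs = []
    for i in range(stem_len):  # hairpin stems
        pairs.append((i, n1 - 1 - i))
        pairs.append((n1 + i, n1 + len(seq2) - 1 - i))
    a0 = stem_len + l1
    b0 = n1 + stem_len + l1
    for t in range(kiss_len):  # antiparallel kissing pairs
        pairs.append((a0 + t, b0 + kiss_len - 1 - t))
    return SecondaryStructure((seq1, seq2), tuple(pairs))


def _kissing_dimer(
    rng: np.random.Generator, stem_len: int = 3, l1: int = 3, kiss_len: int = 4
) -> Fixture:
    for _ in range(64):
        stem1 = _random_stem(rng, stem_len)
        stem2 = _random_stem(rng, stem_len)
        kiss = _random_stem(rng, kiss_len, gc_bias=0.8)
        loop1 = "".join(rng.choice(["A", "U"], size=l1))
        loop2 = "".join(rng.choice(["A", "U"], size=l1))
        seq1 = stem1 + loop1 + kiss + revcomp(stem1)
        seq2 = stem2 + loop2 + revcomp(kiss) + revcomp(stem2)
        try:
            ref = _kissing_reference(seq1, seq2, stem_len, l1, kiss_len)
        except ValueError:
            continue
        return Fixture("kissing_dimer", 0, (seq1, seq2), ref)
    raise FixtureError("could not generate a valid kissing dimer")


def _revcomp_dimer_reference(stem: str, l1s: str, kiss: str, l2s: str):
    """Sequences and kissing reference for a dimer in which strand 2 is the
    exact reverse complement of strand 1 (so the fully zipped extended
    duplex competes with the loop-loop kissing fold)."""
    seq1 = stem + l1s + kiss + l2s + revcomp(stem)
    seq2 = revcomp(seq1)
    n1, n2 = len(seq1), len(seq2)
    pairs = []
    for i in range(len(stem)):
        pairs.append((i, n1 - 1 - i))
        pairs.append((n1 + i, n1 + n2 - 1 - i))
    a0 = len(stem) + len(l1s)
    b0 = n1 + len(stem) + len(l2s)
    for t in range(len(kiss)):
        pairs.append((a0 + t, b0 + len(kiss) - 1 - t))
    return seq1, seq2, SecondaryStructure((seq1, seq2), tuple(pairs))


#: Engineered (stem, l1, kiss, l2) candidates whose exhaustive landscapes
#: show the two-basin (kissing vs extended duplex) phenomenology.
_TWO_MINIMUM_CANDIDATES = [
    ("UC", "AU", "UUGC", "AU"),
    ("AG", "UU", "GCAA", "UA"),
    ("AA", "UU", "GAGUA", "UU"),
    ("AC", "UU", "UUAUGC", "AA"),
    ("CC", "AA", "UAUUCC", "UU"),
]


def _two_minimum_dimer(rng: np.random.Generator, max_random_trials: int = 64) -> Fixture:
    """A kissing dimer whose exhaustive (N, NN) landscape has exactly two
    local minima: a kissing basin and the extended-duplex basin.

    Candidates are verified at generation time with the ensemble module
    (seed permutes the candidate order); if none verifies, a bounded
    seeded random search runs before giving up."""
    from .ensemble import DimerEnsemble, EnsembleParams, landscape

    def verify(stem, l1s, kiss, l2s):
        seq1, seq2, ref = _revcomp_dimer_reference(stem, l1s, kiss, l2s)
        ens = DimerEnsemble.build(seq1, seq2)
        grid = landscape(ens, ref, EnsembleParams(temperature=293.15))
        if len(grid.local_minima()) == 2:
            return Fixture("two_minimum_dimer", 0, (seq1, seq2), ref)
        return None

    errors = []
    for idx in rng.permutation(len(_TWO_MINIMUM_CANDIDATES)):
        stem, l1s, kiss, l2s = _TWO_MINIMUM_CANDIDATES[idx]
        try:
            fx = verify(stem, l1s, kiss, l2s)
        except ValueError as exc:
            errors.append(str(exc))
            continue
        if fx is not None:
            return fx
        errors.append(f"candidate {idx}: wrong minima count")
    bases = np.array(list("AUGC"))
    for _ in range(max_random_trials):
        stem = "".join(rng.choice(bases, rng.integers(2, 4)))
        kiss = "".join(rng.choice(bases, rng.integers(4, 7)))
        l1s = "".join(rng.choice(["A", "U"], 2))
        l2s = "".join(rng.choice(["A", "U"], 2))
        try:
            fx = verify(stem, l1s, kiss, l2s)
        except ValueError:
            continue
        if fx is not None:
            return fx
    raise FixtureError(
        "no candidate produced a two-minimum landscape: " + "; ".join(errors[:5])
    )


def generate_fixture(kind: str, seed: int = 0, **options) -> Fixture:
    """Deterministic fixture for a given kind and seed.

    Kinds: ``hairpin``, ``kissing_dimer`` (two hairpins with
    reverse-complementary loops), ``two_minimum_dimer`` (landscape verified
    to show exactly two local minima at generation time).
    """
    rng = np.random.default_rng(seed)
    if kind == "hairpin":
        fx = _hairpin(rng, **options)
    elif kind == "kissing_dimer":
        fx = _kissing_dimer(rng, **options)
    elif kind == "two_minimum_dimer":
        fx = _two_minimum_dimer(rng, **options)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return Fixture(kind, seed, fx.sequences, fx.reference)
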