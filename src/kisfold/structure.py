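"""Secondary structures with pseudoknot/kissing pairs, and the extended
dot-bracket codec.

A structure is a set of base pairs over one or two strands.  Pairs are held
in a single global 5'->3' coordinate system (strand 1 followed by strand 2);
the strand separator ``&`` appears only in textual dot-bracket form.  Pairs
whose arcs cross in this global order are pseudoknot/kissing pairs and are
written with deeper bracket tiers ``[]``, ``{}``, ``<>``.

Indexing is 0-based and half-open internally; every user-facing surface
(CLI, file formats, error messages) is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

CANONICAL_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

_OPEN = "([{<"
_CLOSE = ")]}>"
_SEPARATOR = "&"


class StructureError(ValueError):
    """Malformed secondary structure or dot-bracket text."""


def pairs_cross(p: tuple[int, int], q: tuple[int, int]) -> bool:
    """True when the arcs of two pairs cross in the global linear order."""
    (i, j), (k, l) = sorted((tuple(sorted(p)), tuple(sorted(q))))
    return i < k < j < l


@dataclass(frozen=True)
class SecondaryStructure:
    """An ordered base-pair set over one or two strands."""

    sequences: tuple[str, ...]
    pairs: tuple[tuple[int, int], ...]  # global 0-based, i < j, sorted

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple(sorted(tuple(sorted(p)) for p in self.pairs)))
        self.validate()

    # -- geometry of the index space -------------------------------------
    @property
    def n_strands(self) -> int:
        return len(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)

    @cached_property
    def strand_offsets(self) -> tuple[int, ...]:
        offs, acc = [], 0
        for s in self.sequences:
            offs.append(acc)
            acc += len(s)
        return tuple(offs)

    def strand_of(self, i: int) -> int:
        for k in reversed(range(self.n_strands)):
            if i >= self.strand_offsets[k]:
                return k
        raise IndexError(i)

    def to_local(self, i: int) -> tuple[int, int]:
        s = self.strand_of(i)
        return s, i - self.strand_offsets[s]

    def base(self, i: int) -> str:
        s, k = self.to_local(i)
        return self.sequences[s][k]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        seen: set[int] = set()
        n = self.total_length
        if self.n_strands not in (0, 1, 2):
            raise StructureError("only single strands and dimers are supported")
        for seq in self.sequences:
            bad = set(seq) - set("AUGC")
            if bad:
                raise StructureError(f"non-RNA characters in sequence: {sorted(bad)}")
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise StructureError(f"pair ({i + 1}, {j + 1}) out of range")
            if i in seen or j in seen:
                raise StructureError(f"base in pair ({i + 1}, {j + 1}) is already paired")
            seen.update((i, j))
            if (self.base(i), self.base(j)) not in CANONICAL_PAIRS:
                raise StructureError(
                    f"non-canonical pair {self.base(i)}{i + 1}-{self.base(j)}{j + 1}"
                )

    # -- classification --------------------------------------------------
    def is_intra(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        return self.strand_of(i) == self.strand_of(j)

    @cached_property
    def intermolecular_pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple(p for p in self.pairs if not self.is_intra(p))

    @cached_property
    def intramolecular_pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple(p for p in self.pairs if self.is_intra(p))

    @cached_property
    def crossing_pairs(self) -> frozenset[tuple[int, int]]:
        """Pairs engaged in at least one crossing (pseudoknot/kissing pairs)."""
        out = set()
        for a in range(len(self.pairs)):
            for b in range(a + 1, len(self.pairs)):
                if pairs_cross(self.pairs[a], self.pairs[b]):
                    out.add(self.pairs[a])
                    out.add(self.pairs[b])
        return frozenset(out)

    def helices(self) -> list[tuple[tuple[int, int], ...]]:
        """Maximal stacked runs: (i, j) and (i+1, j-1) belong to one helix."""
        pairs = set(self.pairs)
        runs: list[tuple[tuple[int, int], ...]] = []
        seen: set[tuple[int, int]] = set()
        for i, j in self.pairs:
            if (i, j) in seen or (i - 1, j + 1) in pairs:
                continue  # not the outermost pair of its run
            run = []
            a, b = i, j
            while (a, b) in pairs:
                run.append((a, b))
                seen.add((a, b))
                a, b = a + 1, b - 1
            runs.append(tuple(run))
        return runs

    # -- text ------------------------------------------------------------
    def to_dotbracket(self) -> str:
        return write_dotbracket(self)


def _assign_levels(pairs: tuple[tuple[int, int], ...]) -> dict[tuple[int, int], int]:
    """Greedy nesting-level assignment: each pair takes the smallest tier on
    which it crosses no previously assigned pair."""
    levels: dict[tuple[int, int], int] = {}
    per_level: list[list[tuple[int, int]]] = []
    for p in sorted(pairs, key=lambda q: (q[0], -q[1])):
        for lv, assigned in enumerate(per_level):
            if not any(pairs_cross(p, q) for q in assigned):
                levels[p] = lv
                assigned.append(p)
                break
        else:
            levels[p] = len(per_level)
            per_level.append([p])
    if per_level and len(per_level) > len(_OPEN):
        raise StructureError("structure needs more bracket tiers than supported")
    return levels


def write_dotbracket(structure: SecondaryStructure) -> str:
    chars = ["."] * structure.total_length
    for (i, j), lv in _assign_levels(structure.pairs).items():
        chars[i] = _OPEN[lv]
        chars[j] = _CLOSE[lv]
    parts = []
    for s, off in zip(structure.sequences, structure.strand_offsets):
        parts.append("".join(chars[off : off + len(s)]))
    return _SEPARATOR.join(parts)


def parse_dotbracket(sequence: str, brackets: str) -> SecondaryStructure:
    """Parse extended dot-bracket text into a SecondaryStructure.

    ``sequence`` and ``brackets`` use the same ``&`` strand separator; the
    bracket string must match the sequence length position by position.
    Unbalanced brackets raise StructureError with a 1-based position.
    """
    seqs = tuple(s.strip().upper().replace("T", "U") for s in sequence.split(_SEPARATOR))
    dbn_parts = tuple(p.strip() for p in brackets.split(_SEPARATOR))
    if len(dbn_parts) != len(seqs):
        raise StructureError(
            f"strand separator count mismatch: {len(seqs)} sequences vs "
            f"{len(dbn_parts)} bracket segments"
        )
    if tuple(len(p) for p in dbn_parts) != tuple(len(s) for s in seqs):
        raise StructureError("bracket string length does not match sequence length")
    flat = "".join(dbn_parts)
    stacks: dict[int, list[int]] = {lv: [] for lv in range(len(_OPEN))}
    pairs = []
    for pos, ch in enumerate(flat):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks[_OPEN.index(ch)].append(pos)
        elif ch in _CLOSE:
            lv = _CLOSE.index(ch)
            if not stacks[lv]:
                raise StructureError(f"unbalanced '{ch}' at position {pos + 1}")
            pairs.append((stacks[lv].pop(), pos))
        else:
            raise StructureError(f"illegal structure character {ch!r} at position {pos + 1}")
    for lv, stack in stacks.items():
        if stack:
            raise StructureError(
                f"unbalanced '{_OPEN[lv]}' opened at position {stack[-1] + 1}"
            )
    return SecondaryStructure(sequences=seqs, pairs=tuple(pairs))
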