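# Methods

This note records the model, its parameters, the numerical choices, and
the limits of what the synthetic test systems demonstrate.

## Backbone model and lattice

The backbone is reduced to two pseudo-atoms per nucleotide, P and C4′,
joined by virtual bonds of one fixed length (default 3.9 Å, a typical RNA
virtual-bond length; configurable). Loop conformations are self-avoiding
walks of these bonds on the diamond lattice: every site has four
neighbours at tetrahedral angles, matching nucleic-acid virtual-bond
geometry, and one lattice bond maps to one virtual bond. Sites are
encoded as integer triples (sublattice A all-even with x+y+z ≡ 0 mod 4,
sublattice B all-odd with x+y+z ≡ 3 mod 4), so parity arguments give
exact feasibility pre-checks (a 2n-step walk joins same-sublattice sites;
displacement components are congruent to the step count mod 2).

Enumeration is exhaustive and deterministic — no sampling, no seeds.
Free-coil counts are accelerated by fixing the first two bonds and
multiplying by the symmetry factor 12 (the point group of order 24 acts
transitively on the 4 first-bond directions and its C3v stabiliser on the
3 second-bond directions); anchored counts are absolute, since anchors
break the symmetry. A depth-first kernel (numba-compiled) records counts
at every depth in one pass, so the full 4–12 nt coil series costs one
24-step traversal (~10^10 nodes, about two minutes on one CPU). Anchored
enumeration prunes on the Chebyshev-distance bound |Δ|∞ ≤ remaining
steps, which is exact on this lattice. The enumeration cap is 12 nt per
loop; beyond it the caller must use the table interface — never a silent
approximation. The cap is a deliberate desk-scale choice: counts grow as
μ² ≈ 8.3 per nucleotide.

Measured on this mapping, the fitted coil-entropy slope over n = 4..12 nt
is ~2.13 k_B/nt (2 ln μ with μ_diamond ≈ 2.88), consistent with the
2.05 k_B/nt linear coil model used as the entropy reference. The
intercepts of the enumerated series and the linear model differ by more
than the slope tolerance, so the reference ln ω_coil = 2.05 l + 0.1 is
used as given for penalties rather than re-derived; the suite checks the
slope and its stability between fit windows, not pointwise agreement of
the two coil models.

## A-form geometry

Ideal A-form parameters: rise h = 2.7 Å, P-radius r = 9.9 Å, 11 bp per
turn (the period is fixed, not tunable — it defines the twist phase
2πs/11 of the closed-form end-to-end distance). The strand end-to-end
distance over s steps is the Cartesian chord

    z(s) = sqrt[(hs)² + r²(1−cos 2πs/11)² + r² sin²(2πs/11)]
         = sqrt[(hs)² + 4r² sin²(πs/11)],

the half-angle in the simplified form following from
(1−cos t)² + sin²t = 4 sin²(t/2). The strand reference point for z(s) is
the P pseudo-atom. Built helices realise this exactly: P atoms lie on the
helical wheel; each C4′ sits on the perpendicular bisector of consecutive
P atoms, displaced toward the axis so both of its bonds have exactly the
virtual-bond length. The second strand is generated by a proper dyad
rotation (chirality preserved) with the dyad azimuth chosen so paired P
atoms are antipodal (19.8 Å across the duplex, close to A-RNA). Frames
are right-handed, Å units, helix axis +z, residues 1-based, chains
lettered in input order.

## Kissing entropy (three steps)

For a kissing complex with stems H1/H2/H3 and loops l1..l4, l2 and l4 are
restricted to ≤ 1 nt, which enforces coaxial stacking of H1–H2 and H2–H3
and makes the H1↔H3 orientation a function of the kissing-stem length
alone. The pipeline:

1. **Anchors.** The eight anchor nucleotides (ends of loops l1/l3 and
   their partners) are regenerated from ideal coaxial A-form geometry —
   one flanking pair, the kissing stem, one flanking pair on one common
   axis. No experimental template coordinates enter, so computed tables
   are *Vfold-like*, not identical to published ones (which used an NMR
   template); the published table ships separately for lookup.
2. **Loop walks.** Loop l1 (n nt) is a 2n-step anchored walk between the
   snapped anchors, the end anchor snapped to the sublattice the step
   parity requires. Loop l3 is handled as the dyad image of the l1
   problem with the flanking stems exchanged, which keeps the complex's
   2-fold symmetry exact on the lattice (swapping l1/l3 labels provably
   changes nothing).
3. **Excluded volume.** Every helix pseudo-atom blocks its nearest site
   on both sublattices. The obstacle stack is aligned to the anchor frame
   by exact helical-step transforms, so growing H1 or H3 strictly extends
   the obstacle set — the entropy penalty is monotone in the flank sizes
   by construction.

ΔS/k_B = ln(c_l1 · c_l3) − Σ(2.05 l + 0.1). A zero count is reported as
an infeasible topology (−∞), distinct from any numeric value. With the
ideal-geometry anchors the feasible region is stricter than the published
table (e.g. (S=6, l1=2, l3=2) is infeasible here but tabulated there);
the shipped table covers the published regime, and computed entropies are
exercised at small S with l ≥ 3.

The published-table transcription stores missing cells explicitly; two
cells with ambiguous digit grouping in the source — (3,3,3) and
(4,4,4) — are flagged unverified in the file header and excluded from
tests. General kissing motifs reduce to this four-loop topology by
replacing each stem-loop substructure with a single nucleotide (effective
loop length = unpaired nt + substructure count).

## Free-energy models

* **Nearest-neighbour stems.** Stack parameters (ΔH, ΔG37) ship as data
  (`data/nn_stacks.tsv`): the standard Watson–Crick RNA set plus a
  minimal wobble complement. ΔS is derived from (ΔH, ΔG37) at 310.15 K,
  giving ΔG(T) = ΔH − TΔS at any temperature. Duplex initiation and the
  per-terminal AU/GU penalty are separate terms. Only canonical pairs
  (A–U, G–C, G–U) are accepted; violations name the offending position.
* **Pseudoknot penalty.** G_pseudo = β1 + β2·B^p + β3·U^p with defaults
  (9.6, 0.1, 0.6) kcal/mol, configurable.
* **FJC loop stretching.** All five printed terms of βG(N, M, z) with
  a = 6.2 Å, b = 15 Å; β = 1/(k_BT) (the expression is dimensionless only
  under that reading). The 2.4 Å constant in the log term is a fixed
  model constant. C0 defaults to 0 (an experimental offset). Domain:
  2.4 < z < Na + Mb, violations name the bound. At z = R_F the three
  z-dependent terms vanish identically and βG − βC0 = 3 ln R_F; the full
  derivative there is 5/(2R_F), because the log-term derivatives cancel
  the matching pieces of the bracket coefficient.
* **Kissing total.** ΔG = ΣΔG_stem − TΔS with the entropy term supplied
  in k_BT units; k_B = 0.0019872 kcal/mol/K in exactly one place
  (`constants.py`); default temperature 310.15 K. An infeasible entropy
  yields +∞ with a diagnostic.

## Two-strand ensembles

Structures are complete pair sets under: canonical pairs only, minimum
helix 2 bp, minimum hairpin loop 3 nt, and at most one kissing/pseudoknot
interaction (all arc crossings must share one common helix). The
enumerator composes structures from maximal stacked runs (two contiguous
runs are never chosen together, so each pair set appears exactly once)
and is verified against a direct matching-enumeration oracle. The
combined-length cap is 30 nt — exhaustive sums stay exact and fast.

Scoring: stems by the NN table (stacks + terminal penalties; the
bimolecular initiation is priced once, by ΔG_init); a detected
two-hairpin kissing interaction by the entropy table against the coil
reference (a pure entropy, so it scales with T); other crossing
topologies, or kissing geometries outside the table, by the affine
pseudoknot penalty as a temperature-independent offset. Simple-loop
(hairpin/bulge/internal) entropies are not separately priced — a
deliberate toy-scale simplification that leaves the kissing/duplex
competition governed by stems, kissing entropy and association.

Q1·Q2 + e^(−βΔG_assoc)Q12 with ΔG_assoc = ΔG_init − k_BT ln(C_T/4)
(ΔG_init = 4.1 kcal/mol, treated as temperature-independent). Both
strands at C_T/2 with the printed C_T/4 convention verbatim; homodimer
symmetry corrections are omitted. Q12 includes the associated-but-
unpaired state by default (flag `include_unpaired_associated`). Sums run
in log space, so bound fractions stay finite for |E| up to hundreds of
kcal/mol. Landscapes bin the bound ensemble by (native, non-native) pair
counts relative to a reference — non-native means any pair absent from
the reference, intramolecular included — with bin free energy
−k_BT ln(mass) and minima defined as bins strictly below all eight
neighbours (absent neighbours count as +∞). Melting profiles report the
bound fraction and a partition of bound structures into kissing (has
crossings and intermolecular pairs), extended duplex (intermolecular, no
crossings) and other.

## Scaffold assembly

Helices joined by ≤ 1-nt connectors share one axis (coaxial stacking);
the single connecting nucleotide is placed as an exact three-bond zig-zag
whose bulge direction is chosen deterministically for maximal clearance.
Longer loops are bridged by the first (deterministically ordered)
anchored lattice walk of 2n+1 steps between the C4′ before the loop and
the P after it; helix atoms block their nearest lattice site, and each
placed walk blocks its own sites for later loops. Unbridgeable anchors
raise an infeasibility error — never a silent drop. Terminal tails extend
as straight virtual-bond runs away from the stack. Supported topologies:
single-chain nested stacks (hairpins, bulges, internal loops, tails) and
the two-hairpin kissing dimer with short l2/l4; multibranch junctions and
single-chain pseudoknots are rejected explicitly.

Validation distinguishes exact bonds (helix-internal and walk-internal,
10⁻⁶ Å) from junction bonds joining off-lattice helix atoms to snapped
walk ends, which may deviate by the parity-restricted snapping error
(FCC covering radius ≈ 4.5 Å; tolerance 5.0 Å). Clash checking (default
3.5 Å) applies to pairs more than three backbone bonds apart; 1-2/1-3/1-4
neighbours are governed by bond geometry. PDB output uses standard ATOM
lines with atom names P and C4′, one chain per strand, TER between
chains; coordinates round-trip to the format's 10⁻³ Å.

## Synthetic fixtures

The fixture generator emulates the architecture of dimerization-initiation
kissing systems: hairpins with reverse-complementary loops
(`kissing_dimer`) and, for the two-basin phenomenology, dimers in which
strand 2 is the exact reverse complement of strand 1 (`two_minimum_dimer`)
so the fully zipped extended duplex competes with the loop-loop kissing
fold. The two-minimum generator verifies, at generation time and with the
ensemble module itself, that the landscape has exactly two local minima
(a kissing-like basin at high native count and the extended-duplex basin),
drawing from a small engineered candidate family in seed-permuted order
with a bounded seeded random search as fallback. What these fixtures do
not emulate: natural sequence composition, non-canonical pairs, loop-loop
kinetics, salt dependence, and the sequence lengths of real dimerization
sites — passing tests demonstrate the statistical mechanics is computed
exactly at toy scale, not that real dimer populations are predicted.

## Numerical and interface conventions

Indices are 0-based half-open internally, 1-based in every user-facing
surface. One TSV dialect (tab, '.', no thousands separators). Snapping
ties break toward the lexicographically smallest site. Enumeration order
is sorted-neighbour, so sampled walks are reproducible without seeds.
CLI exit codes: 0 success, 2 usage error, 3 infeasible model input; every
run logs its fully resolved configuration, and unknown config keys are
rejected.

## Known limitations

* Kissing-entropy anchors from ideal geometry are stricter than
  template-derived ones; computed tables disagree with published values
  near the feasibility boundary.
* One orientation placement of the flanking stems (the canonical coaxial
  one); orientation averaging is out of scope.
* No dynamic-programming partition functions: inputs beyond 30 nt
  combined are refused rather than approximated.
* No all-atom reconstruction or refinement; scaffolds are virtual-bond
  resolution only.
* N-way junction entropies and riboswitch-scale folds are out of scope.
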