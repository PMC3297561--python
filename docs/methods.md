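# Methods

`mtencode` is a desk-scale feasibility analysis of one proposal for
molecular memory: that calcium-activated CaMKII holoenzymes write synaptic
information onto microtubule (MT) lattices by collectively phosphorylating
hexagonal neighborhoods of tubulin dimers. The package implements the five
quantitative legs of that argument — lattice geometry, hexagon docking,
state counting, binding energetics, ATP budgeting — plus the downstream
lattice behaviors (MAP attachment, motor guidance, C-terminal tails, logic
gates) that phosphorylation patterns could drive.

## Lattice geometry

A microtubule is a cylinder of `N` protofilaments (default 13) of 8 nm
tubulin dimers (two 4 nm monomers, α then β toward the plus end). Wall
diameters of 25/15 nm put all monomer centers on a 10 nm centerline
cylinder — the mean of the two wall radii, since only wall diameters are
commonly quoted. Lateral packing is skewed by a per-protofilament rise:

* **B lattice** — rise 0.92 nm, same-monomer (α–α/β–β) lateral contacts,
  the canonical 13_3 configuration with one seam;
* **A lattice** — rise 4.92 nm (one monomer plus 0.92 nm), α–β lateral
  contacts, no seam.

Dimer sites are indexed `(protofilament, axial)`, 0-based, with six
neighbor direction classes: protofilament ±, helical ± (helical+
increments the protofilament index), anti-helical ± (anti-helical+
decrements it while advancing one ring). The index offsets are
`(0,±1), (±1,0), (+1,−1), (−1,+1)` for both lattice families; only the
rise and the wrap differ.

**Cylinder wrap.** Completing one lateral turn accumulates
`N·rise / 8 nm` dimer rings of axial shift: 7.995 ≈ 8 for the A lattice
(hence no seam) and 1.495 for the B lattice. The B value is not a lattice
point — that *is* the seam — and the wrap offset used for the index graph
is `ceil(N·rise/8) = 2`. Rounding up, not to nearest, is forced by the
geometry: with offset 2 all four wrapped direction edges land on sites
whose minimum monomer-center distance equals the lateral lattice constant
(≈ 4.87 nm), whereas offset 1 sends the anti-helical wrap to a site 7 nm
away. The whole neighbor map is validated in the test suite against an
independent oracle: the graph obtained by thresholding pairwise minimum
monomer-center distances at 1.2× the lateral lattice constant reproduces
the labeled neighbor map edge-for-edge on 13×20 lattices of both types.

Finite lattices are open axially; operations that need a complete
neighborhood (patches, gate junctions) reject edge sites explicitly.

**Patches.** The A-lattice neighborhood of a dimer is the 7-dimer hexagon
(center + six graph neighbors); the B-lattice neighborhood is the 9-dimer
3×3 skewed block. Peripheral members are stored in a fixed clockwise order
starting from the upper-left (anti-helical+) neighbor; this single
numbering is reused by the encoding digits and the hexagon target masks.
The A7 patch extent (maximum pairwise monomer-center distance) is 20 nm,
set by its three-dimer axial span — the same scale as the CaMKII hexagon
breadth.

## CaMKII hexagon and alignment

The activated holoenzyme face is modeled as a rigid planar hexagon of six
kinase anchor points, breadth 20 nm (twice the circumradius), with a
per-kinase radial strain allowance (default 2 nm) standing in for linker
flexibility; no elastic linker model is attempted because none is
quantified. Targets are six dimers per patch: all six A7 peripherals, or
one of two fixed 6-of-8 masks on the B9 block — **B1** drops the two
long-diagonal corners (compact selection, 6-target extent 20.4 nm,
matching A7 within 1 nm) and **B2** drops the two short-diagonal corners
(wider selection, 23.7 nm, consistent with the B lattice needing more
linker flexibility). The masks are fixed constants, documented here and never varied.

Alignment is a rigid-body least-squares problem: Kabsch superposition
(proper rotations only) of the hexagon onto the six target contact points
(β-monomer centers by default), combined with a minimum-cost bijective
kinase→target assignment. The implementation seeds the search with the 12
dihedral orderings of the targets' angular sequence around the patch
normal and iterates (Kabsch fit, Hungarian reassignment) to a fixed point;
tests verify the result equals an exhaustive fit over all 720
permutations, each with its own Kabsch fit. Displacements are per-kinase
residual norms; infeasibility under the strain bound is a reported flag,
not an exception. Under the default regular hexagon the best-fit RMS is
3.63 nm on the A lattice and 3.83 nm (B1) on the B lattice — the A lattice
always fits at least as well, and the anisotropy of the dimer
neighborhood (16 nm tall, 9.6 nm wide) is what keeps a regular hexagon
from an exact fit.

## State counting

Dimer states are ternary: 0 none, 1 β-phosphorylated, 2 α-phosphorylated.
Three schemes are counted in closed form (`Σ_k C(n,k)(s−1)^k`, k up to the
six-kinase limit) and by exhaustive enumeration, which must agree exactly:

| scheme | sites | states/site | constraint | count | bits |
|---|---|---|---|---|---|
| binary_A | 6 | 2 | — | 64 | 6.00 |
| ternary_A | 6 | 3 | — | 729 | 9.51 |
| ternary_B | 8 | 3 | ≤ 6 non-zero | 5281 | 12.37 |

The ternary_B count is `3^8 − 2^8 − 8·2^7 = 5281`: all length-8 ternary
strings minus those with 8 or exactly 7 non-zero digits, i.e. at most six
of the eight peripheral dimers written by the six kinases of one face. The
central "address" dimer of a patch is never writable; attempts raise a
constraint error.

## Electrostatics and bioenergetics

The binding model is deliberately bare arithmetic: kinase positive
potential +1 kT/e × monomer surface charge −10 e → 10 kT attraction per
kinase–monomer contact, exactly linear up to 60 kT for six kinases. No
distance dependence, screening, or dielectric is modeled; continuum
Poisson–Boltzmann electrostatics is out of scope. Conversions use
k_B·T·N_A at 310 K = 0.6161 kcal/mol per kT, so 10 kT → 6.16 (prints as
6) and 20 kT → 12.32 (prints as 12) kcal/mol. The six-kinase maximum is
reported both ways: the direct 36.96 kcal/mol and the rounded chain
6 × round(6.16) = 36; both are computed, neither silently replaces the
other. "Significant vs thermal" flags ratios ≥ 10 kT, an order of
magnitude above thermal energy.

The ATP budget is a multiplicative chain with every factor a parameter:
2×10²⁶ ATP/day whole-body → ×(1/5)/86400 → 4.63×10²⁰ ATP/s brain
(one-significant-figure: 5×10²⁰); 100 Hz × 100 CaMKII subunits ×
10⁴ synapses × 1 ATP = 10⁸ ATP/s per neuron; ×10¹¹ neurons = 10¹⁹ ATP/s
brain-wide; fraction 2.0% against the rounded denominator (2.16%
unrounded). `rounded` selects the rounded denominator; both values are
always present in reports. Comparison constants (10⁴ ATP per synaptic
bit, 10⁶–10⁷ per spike-coded bit) are fixed reference values.

## Lattice automata

**MAP attachment** offers two selectable rules, defaulting to their
union because the source material does not say whether they are
alternatives: (a) a phosphorylated dimer with ≥ 2 phosphorylated neighbors
(all six hexagonal neighbors count); (b) intersections of phosphorylated
runs (≥ 3 consecutive dimers, a run being a maximal path in one direction
class) of two different direction classes. Spacing validation flags
consecutive same-protofilament MAPs outside 15–25 nm (two to three dimer
lengths), the optimal band for motor transport.

**Motor guidance** is a deterministic walk: at each step the motor takes
the phosphorylated neighbor maximizing plus-end progress, with the fixed
tie-break protofilament+ > helical+ > anti-helical+. It delivers at
structural/output MAP sites, stalls without a phosphorylated continuation,
and exits at the plus edge. It never steps onto an unphosphorylated dimer.

**Tail states** map phosphorylation to C-terminal tail extension: state 1
raises the β tail, state 2 the α tail, everything else stays down. This is
the designated hook for reaction–diffusion coupling, which is itself out
of scope.

**Logic gates.** Tokens carry a direction class and a binary phase fixed
at injection, advancing one neighbor per timestep. The two inputs travel
toward an interior junction along the helical+ and anti-helical+ classes
from equal arm lengths (default 4), so simultaneous injection means
simultaneous arrival. Junction rules (a minimal mechanism chosen as the package's design;
only the input/output behavior of such gates is constrained externally):

* two co-arriving tokens, equal phase → lateral components cancel, one
  token emitted along the output line (protofilament+ or the output MAP);
* two co-arriving tokens, opposite phase → annihilation;
* a lone token passes straight through an AND junction but is redirected
  onto the output line by an XOR junction.

AND gates inject both inputs in phase; XOR gates inject them in opposite
phase. The output bit is 1 iff a token crosses the output attachment
(3 dimers up the protofilament, or the MAP edge). All 16 outcomes
(AND/XOR × MAPs-as-input/MAPs-as-output × 4 input pairs) emerge from the
simulation and are invariant under translating the gate along the lattice;
every cancellation/merge is logged with site and timestep. The step cap is
10×(protofilaments + rings); pass-through tokens simply run off the open
lattice end and are discarded. Circuits chain gates through acyclic wiring
and evaluate each gate by simulation — NOT is XOR(x, 1) and OR is
XOR(XOR(a,b), AND(a,b)), checked exhaustively.

## Synthetic activity generator

The generator emulates the assumed input regime, not measured data:
periodic Ca²⁺-influx trains at a nominal frequency (LTP-range, 50–100 Hz)
with Gaussian timing jitter, clipped to the duration and sorted; an
activation efficacy that is Gaussian in log2(f / 50 Hz) with a 2-octave
bandwidth, scaled by `1 − w + w·synchrony` with w = 0.5 — the empirical
basis is only a qualitative optimum near 50 Hz for synchronized inputs, so
the curve's form and width are modeling choices fixed here; and ~100
activated subunits per influx as the default subunit count. Pattern
sampling phosphorylates each site independently with probability
`p = efficacy × occupancy`, where occupancy is the train's delivered event
rate over its nominal frequency (≤ 1) times the kinase-to-site coverage
(6 kinases over the scheme's sites — 0.75 for ternary_B), so one face can
never saturate an eight-site neighborhood. Constrained schemes are
rejection-sampled with a 1000-attempt cap. All randomness flows through a
single seeded NumPy generator; identical seeds give identical patterns
bit-for-bit.

What passing these tests does *not* show about real dendrites: no
Ca²⁺/CaM kinetics, no phosphatase turnover or pattern decay, no dendritic
geometry, and no quantitative frequency–density law — only the qualitative
structure (periodicity, jitter, tuning peak, monotone synchrony gain) is
emulated, so downstream results are conditional on that structure.

## Problem sizes and numerics

Test lattices are 13×20–24 (260–312 dimers); the geometry oracle is run at
13×20, the full permutation oracle over all 720 assignments per alignment,
and enumeration over all 3⁸ = 6561 ternary strings — each well under a
second. The acceptance script simulates both MAPs-as-input gates at (1,1)
on a fresh 13×24 B lattice with a seed-randomized junction placement
(the result is translation-invariant and deterministic). Coordinates are
exact to floating point; the only tolerance in the geometry is the 1e-6 nm
cylinder-radius check and the 0.001 Å PDB round-trip, set by the PDB
fixed-width format.

## Known limitations

Atomic structure, GTP/GDP state, dynamic instability, protofilament
supertwist beyond the single rise parameter, autophosphorylation kinetics,
the second hexamer ring of the holoenzyme, Poisson–Boltzmann fields,
phosphatase dynamics, and any clinical interpretation are all explicitly
out of scope. The gate mechanics are a minimal consistent realization of the target
input/output behavior, not a molecular dynamics claim.
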