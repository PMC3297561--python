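# mtencode

Feasibility analysis of synaptic memory encoding by CaMKII phosphorylation
of microtubule lattices.

Long-term potentiation activates the CaMKII holoenzyme, whose six extended
kinase domains form a hexagon ≈ 20 nm in breadth — the same size and
symmetry as the hexagonal dimer neighborhoods of the microtubule A and B
lattices. If each kinase can phosphorylate (or not) one tubulin dimer, a
single CaMKII–microtubule encounter could write an ordered array of six
bits or trits onto the lattice. `mtencode` implements that argument as
tested, reproducible code for computational neuroscientists and
biophysicists: lattice geometry and CaMKII-hexagon docking, exact
phosphorylation-state counting, coarse electrostatic binding bounds, an
ATP bioenergetics budget, and lattice signal-propagation automata whose
AND/XOR truth tables emerge from local junction rules.

## The model in brief

* **Geometry** — cylindrical 13-protofilament lattices of 8 nm dimers on a
  10 nm centerline radius; B lattice with 0.92 nm lateral rise and one
  seam, A lattice with 4.92 nm rise and none. Neighbor topology is
  validated against a distance-threshold oracle on monomer centers.
* **Capacity** — with the central "address" dimer excluded and at most six
  dimers written per face, the admissible state counts are
  2⁶ = 64 (binary, A lattice), 3⁶ = 729 (ternary, A), and
  3⁸ − 2⁸ − 8·2⁷ = 5281 (ternary, B; ≤ 6 of 8 sites), i.e. 6.0, 9.5 and
  12.4 bits per patch.
* **Energetics** — 1 kT/e kinase potential × −10 e monomer charge
  → 10 kT per contact, 60 kT for six kinases (6.2/37.0 kcal/mol at 310 K).
* **Budget** — 100 Hz × 100 subunits × 10⁴ synapses = 10⁸ ATP/s per
  neuron, 10¹⁹ ATP/s for 10¹¹ neurons ≈ 2% of the brain's 5×10²⁰ ATP/s.
* **Computation** — phosphorylation patterns select MAP attachment sites
  and guide motors; signal tokens on the lattice realize AND and XOR gates
  (and by composition NOT, OR, …) through phase-dependent cancellation at
  a junction.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Count the B-lattice ternary states and run the ATP budget:

```
$ mtencode capacity --scheme ternary_B
5281 states, 12.37 bits

$ mtencode budget --rounded
{
  "brain_atp_rate_per_s": 5e+20,
  "brain_atp_rate_per_s_unrounded": 4.62962962962963e+20,
  "neuron_encoding_rate_per_s": 100000000.0,
  "brain_encoding_rate_per_s": 1e+19,
  "encoding_fraction_percent": 2.0,
  "encoding_fraction_percent_unrounded": 2.16,
  ...
}
```

5281 is the number of distinct phosphorylation states one CaMKII face can
leave on a 9-dimer B-lattice patch (12.37 bits); the budget chain says
maximal encoding in every neuron would cost 10⁸ ATP/s per neuron and about
2% of brain ATP turnover — orders of magnitude below the 10⁴–10⁷ ATP per
bit of synaptic or spike signaling.

Run an AND gate with MAPs as inputs, both inputs active:

```
$ mtencode gate --type AND --io maps-as-input --inputs 1,1
{
  "gate": "AND",
  "io_mode": "maps-as-input",
  "inputs": [1, 1],
  "output": 1,
  "steps": 16,
  "cancellations": [
    {"site": [6, 12], "timestep": 4, "event": "merge"}
  ]
}
```

The two tokens travel the helical and anti-helical paths, meet in phase at
the junction at timestep 4, cancel their lateral components, and the
merged token exits along the protofilament output: the AND row (1,1) → 1
emerges from propagation, not from a lookup table.

The same library surface is available in Python:

```python
from mtencode.lattice import LatticeSpec, build_lattice, neighborhood_patch
from mtencode.hexagon import KinaseHexagon, align

lattice = build_lattice(LatticeSpec(lattice_type="A", n_dimer_rings=21))
patch = neighborhood_patch(lattice, lattice.site(6, 10))
result = align(KinaseHexagon.regular(breadth=20.0), patch, "A")
print(round(result.rms_mismatch, 2))   # 3.63 (nm)
```

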