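# Methods

## The two-state free-energy model

Every residue is treated as either fully ordered or fully disordered. An
ordered residue contributes its pairwise interaction energies with all
other ordered residues and no entropy. A disordered residue contributes
no interaction energy; instead it is paid an entropy credit whose form
depends on the topology of the disordered run it belongs to:

* a **tail** — a maximal disordered run containing the first or last
  residue — earns `E_d` per residue (a freed terminal residue explores
  conformations independently);
* an internal **loop** of length `L`, flanked by ordered residues on both
  sides, earns `β·ln(L/L₀)` per loop (the entropy of a tethered excursion
  grows only logarithmically with its length, because both ends remain
  pinned).

With temperature absorbed into the two coefficients, the score of an
assignment is

```
F = E − Σ_tails E_d·n_tail − Σ_loops β·ln(L/L₀),
```

and the breakdown `(E, tail_term, loop_term, F)` is carried with every
assignment; the identity `F = E − tail_term − loop_term` is exact and
property-tested to 1e−12.

Parameter defaults are `E_d = 2.0`, `β = 1.5`, `L₀ = 0.3` (energy units
matching the pair potential; these are the fitted values for this model
family) with internal loops required to be at least 4 residues long.
`min_loop_len/L₀ > 1` is enforced so loop credits are always positive.

### Searches

* `enumerate_terminal` — exhaustively scores every N-tail/C-tail length
  pair `(a, b)` with `a + b < n` (at most two disordered stretches, one
  per terminus; the fully disordered chain is excluded because the energy
  of an empty ordered set is degenerate). Block sums of the pair matrix
  are read from a 2-D prefix sum, so the whole scan is O(n²).
* `greedy_internal` — starts all-ordered and repeatedly flips the best
  block of `block = 4` consecutive currently-ordered residues to
  disordered, at any offset, committing the single flip that lowers F the
  most (best-improvement; ties go to the leftmost window) until no flip
  helps. Windows merging with existing disordered runs are re-classified
  as tails or loops by position before scoring. Disorder→order back-flips
  are not allowed; consequently internal runs grow in multiples of the
  block size, and the greedy result is an upper bound on the optimum.
* `exhaustive_search` — the exact reference for small chains: every
  admissible mask (tails of any length, internal runs ≥ `min_loop_len`,
  at least one ordered residue) is enumerated by composition; the
  admissible set depends only on `(n, min_loop_len)` and is cached, with
  energies evaluated in one vectorised pass. Refused above `max_n = 24`
  (the admissible set grows exponentially).

Tie-breaking everywhere is: lowest F, then fewest disordered residues,
then smallest N tail, then (exhaustive only) lexicographically first
mask. All searches are deterministic.

`profile_ensemble` runs the selected search on each model of an ensemble
and records the per-residue frequency of the disordered label — the
package's estimate of the extent of disorder at each position.
`compensation_curve` re-scores a sequence of assignments and tabulates
`(n_disordered, E, entropy_term, F)`: as more residues are freed the
retained energy rises while the entropy credit grows, leaving F much
flatter than E (entropy–enthalpy compensation), which is why free-energy
and energy rankings of decoys usually agree.

## The pair-energy backend

The free-energy model needs only a pairwise-decomposable interaction
energy with an attractive/repulsive split. The built-in backend is a 12-6
potential on per-residue interaction centers (side-chain heavy-atom
centroid; Cα for glycine), `E_ij = ε[(σ/r)¹² − 2(σ/r)⁶]` with
`σ = r_i + r_j` from a per-residue radius set scaled so GLY = 2.0 Å and
TRP = 3.4 Å, `ε = 1.0`, a 12 Å cutoff, and the positive part of each pair
term capped at `rep_cap = 10` to bound the r→0 singularity. Sequence
neighbours (|i−j| ≤ 1) are excluded as covalently constrained.
Externally computed pair energies (e.g. from a full atomistic force
field) can be injected from a plain-text table via
`load_interaction_matrix`, which is the recommended route when fidelity
to a particular energy function matters; hydrogen-bonding and solvation
are deliberately not modelled — a single attractive channel keeps the
masking decomposition exact.

### Repulsive-only masking

`masked_energy` scores a model with a set of designated disordered
residues contributing only their repulsive channel — including pairs
between two masked residues, so disordered segments cannot stabilise each
other either. `masked_energy_reduced` additionally reduces masked
residues to glycine-like centers: interaction center moved to Cα and
radius set to the smallest radius in the set, mimicking a minimal
backbone probe. The operational consequence, verified by test: for
clash-free masked conformations the score depends only on the unmasked
coordinates, so re-sampling a disordered tail does not move the score
(≤ 1e−9 drift), while a masked segment intercalated into the core is
penalised by its steric overlap alone.

## Reference disorder and evaluation

Reference disorder is derived from an ensemble (NMR-style) by superposing
all models on the medoid model — the one with minimum summed all-Cα RMSD
to the others — and computing each residue's root-mean-square Cα distance
from its ensemble-mean position; residues above 2.0 Å are disordered.
The stated quantity is dimensionally an RMS deviation in Å; a deliberate
protocol choice here is the medoid frame with an all-Cα fit and no
iterative core re-weighting, which is deterministic and does not
presuppose the disorder call being evaluated. A side effect worth knowing:
very mobile segments drag the global fit slightly, so residues at the
edges of a disordered run often fall below the threshold — reference
calls are conservative near boundaries.

Predictions are scored by `score = (1/N) Σ P_i`, where `P_i` is the
predicted frequency of residue i's reference state; the all-ordered null
model scores the ordered fraction of the reference. Tail predictions are
summarised by signed length differences (predicted − true) per terminus.

Structure similarity over a designated core uses least-squares rigid
superposition (Kabsch, via `scipy.spatial.transform.Rotation`): core Cα
RMSD, and core GDT-TS as the mean over 1/2/4/8 Å cutoffs of the largest
core fraction simultaneously superposable within the cutoff. GDT is
defined as a maximum over superpositions; here it is found by a seeded
fit-and-extend heuristic (seeds from every contiguous core fragment of
lengths 3/5/7, then include-within-cutoff / re-fit until the included set
converges, capped at 32 iterations). An exhaustive subset oracle
(`gdt_fraction_exhaustive`, ≤ 14 residues) backs the heuristic in tests;
they agree on well-separated displaced-block instances, though the
heuristic can in principle miss mixed subsets that only a global subset
search would find when displacements are comparable to the cutoff.

`scan_parameters` grids `E_d`, `β`, `L₀` over a benchmark and reports the
mean agreement score (internal mode) or the exact-tail-recovery fraction
(terminal mode), with the arg-max point taken first-in-grid-order on
ties.

## The synthetic-data generator

The generator emulates the study conditions with planted ground truth:

* **Core** — a compact self-avoiding virtual-bond chain (3.8 Å steps,
  ≥ 4.2 Å non-bonded separation) grown from the middle outward with a
  contact-seeking score (most neighbours in the 4.2–5.6 Å shell, ≥ 3
  contacts once the globule exists), so packing is protein-like; each
  residue's summed attraction comfortably exceeds `E_d`, which is what
  makes a folded core a *core* under the free-energy model. Growing the
  chain ends last leaves both termini surface-exposed. When internal
  loops are planted, the globule is grown in the half-space z ≤ −2.8 with
  the loop-flanking residues seeking the z = 0 plane, guaranteeing the
  anchors are never buried and the loop has free volume to explore.
* **Per-model variation** — the shared core scaffold gets chain-correlated
  Gaussian jitter (default 0.2 Å) followed by a constraint-projection
  repair (non-bonded pairs pushed back above 4.15 Å, bonds restored),
  so jitter never manufactures spurious steric repulsion.
* **Tails** — grown per model as self-avoiding walks bonded to the
  terminal core residue, leaving the core firmly (first step outward)
  then meandering with a weak outward bias and ≥ 5.5 Å core clearance;
  the resulting per-residue deviations far exceed the 2 Å threshold
  except immediately at the boundary. The anchor's own bonded chain
  neighbour is held only at normal non-bonded separation, since it is
  two positions away in sequence.
* **Loops** — sampled on circular major arcs between their two anchors
  with uniform arc spacing (so virtual bonds stay in the (2, 5) Å band by
  construction), per-model random bulge direction, arc-length fraction,
  apex skew and smoothed mid-loop-weighted jitter, with graded core
  clearance (loop ends hug their anchors, the middle swings free).
* **Collapsed decoys** — the stress case for the repulsive-only score: a
  chosen fraction of models have their disordered segments steered onto
  the core surface, with every third site pressed into mild steric
  overlap (nearest-core target 3.6 Å) and the rest in the attractive
  shell; acceptance requires ≥ 3 overlapping sites and ≥ 2 contacts per
  residue in the 3.9–5.6 Å band. Such models score *better* than
  clash-free ones under the full energy (the pathology) and *worse* under
  repulsive-only masking (its removal).
* Geometry construction is by bounded rejection sampling; a model that
  fails is retried up to 8 times with fresh sub-seeds drawn from the same
  parent generator, so ensembles are bit-reproducible given `seed`
  (mandatory). A placement that remains infeasible raises a
  `GenerationError` naming the segment.

Sequences are poly-A (core) and poly-G (disordered) unless supplied; the
backend keys only on radii. `generate_pair_matrix` provides
coordinate-free planted instances (sticky ordered complement, isolated
planted set, small deterministic jitter) for search unit tests.

### What passing tests do and do not show

The generator reproduces the *contact and deviation statistics* the
method depends on — cohesive cores, energetically isolated flexible
segments, deviation profiles straddling the 2 Å threshold, collapsed
segments with spurious contacts — but not real protein energetics:
no secondary structure, hydrogen bonding, solvation, side-chain packing
or realistic Ramachandran geometry. Green tests therefore demonstrate
that the assignment machinery, searches, scores and masking behave
exactly as specified on inputs with known answers; they do not certify
accuracy on real decoy sets, where the energy function's fidelity
dominates. The `load_interaction_matrix` escape hatch exists precisely so
real pair energies can be substituted.

## Numerical and design notes

* Problem sizes in tests and the acceptance script (cores of 12–40
  residues, ensembles of 5–10 models, 20-seed benchmarks, 12–20-residue
  oracle instances) were chosen as the smallest at which every planted
  effect is unambiguous; all quantities are recomputed from the seed at
  run time.
* Float ties in searches are broken by exact tuple comparison
  `(F, n_disordered, n_tail, …)`; no tolerance is applied, which is safe
  because competing assignments on random instances differ by far more
  than double-precision error, and exact ties (zero matrices) compare as
  exact equals.
* `Rotation.align_vectors` residuals put rigid-identity RMSD at ~1e−7,
  not 0; tolerances in tests reflect that.
* Whether the greedy search should allow disorder→order back-flips is
  genuinely open; this implementation forbids them, accepting block-size
  granularity in exchange for monotone F and a clean upper-bound
  guarantee. Loop entropy is per loop, not per residue — the length
  dependence enters only through `ln(L/L₀)`.
* Masked residues pay no intra-residue or torsional terms here; the
  backend has no such terms for unmasked residues either, so the
  comparison is consistent.

## Known limitations

* The greedy search cannot produce internal runs whose length is not a
  multiple of the block size unless they touch a terminus; predictions
  for loops of length 5–7 carry a one-to-three-residue granularity error.
* The GDT-TS heuristic is a documented stand-in for a full superposition
  search; equality with the exhaustive oracle is guaranteed only when
  displaced regions are well separated relative to the cutoffs.
* The deviation-based reference is conservative at run boundaries (see
  above); agreement scores on synthetic benchmarks penalise the predictor
  for correctly calling planted residues whose realised deviation fell
  just under the threshold.
* Single chains only; no Boltzmann weighting over sub-optimal
  assignments; no temperature scans.
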