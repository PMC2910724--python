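# Methods

## Model

The prediction unit is the surface patch. A residue belongs to the surface
when the solvent-accessible surface area (SASA) of its side chain, divided
by that residue type's side-chain SASA in an extended Gly-X-Gly tripeptide,
exceeds 6 % — computed at probe radius 1.2 Å (a deliberately small probe
that keeps crevice residues out of the surface set; the conventional 1.4 Å
is available as a parameter). A patch is a central surface residue plus its
19 nearest surface neighbours, so the number of patches equals the number
of surface residues and every surface residue centres exactly one patch.

The regression target of a patch is its number of epitopic residues
divided by the patch size (20), an approximately continuous quantity in
[0, 1] — the reason an ε-SVR is used rather than a classifier. At
prediction time the clamped SVR output is the patch score, a residue's
score is the arithmetic mean over all patches containing it, and the
top-ranked residues form the epitope call: a residue that keeps appearing
in high-scoring patches is likely epitopic even when its own patch is
mediocre.

## The six attributes

Residue-level terms (averaged over the patch members):

- **Epitope propensity.** From annotated training antigens, side-chain
  surface area is pooled by residue type over epitopic and non-epitopic
  surface residues; the table value is ln of the ratio of the two area
  fractions, with a pseudocount (default 1 Å² per type and class) keeping
  every entry finite. A residue scores its relative accessibility times its
  type's table value, so buried-ish residues contribute little regardless
  of type.
- **Conservation.** The residue's self-substitution score in a PSI-BLAST
  ASCII PSSM minus the BLOSUM62 diagonal for its type. Raw integer PSSM
  scores are used. Values below zero flag positions less conserved than
  the BLOSUM background — epitopes tend that way. Profiles are mapped to
  chains by exact substring match between the PSSM sequence and the
  ATOM-record sequence; unmapped residues score 0 with a warning.
- **Side-chain environment energy.** A statistical stand-in with a stable
  interface: residues are binned by relative accessibility
  (< 0.05, 0.05–0.25, 0.25–0.5, ≥ 0.5) and the score is
  −ln(P(bin | type) / P(bin)) with one pseudocount per cell, estimated from
  the training corpus. Flat statistics give 0 everywhere; a type that is
  rarely seen at a given burial is penalised there. A physics-based
  rotamer-energy term could replace it behind the same interface.

Patch-level terms:

- **Contact number** of the central residue: other residues whose
  side-chain geometric centre (Cα for glycine) lies within 10 Å of the
  centre's. The 10 Å cutoff and the side-chain-centre representative point
  are package choices, exposed as parameters.
- **Planarity**: RMS deviation of the members' representative points from
  their least-squares plane, computed from the smallest eigenvalue of the
  centred covariance (equivalently the smallest singular value). Flat
  patches score near 0; protrusions and pockets score higher. Fewer than
  three points, or collinear points, degenerate to 0 with a warning.
- **Secondary-structure composition**: the coil fraction of the patch
  (epitopes are loop-enriched). One scalar is required per attribute;
  helix/strand fractions are derivable from the assignment but never enter
  the model.

All six attributes and the label are min-max scaled to [0, 1]; the scaler
is fitted on the pooled training patches, persisted with the model, and
test-time values are clamped into the unit interval. An attribute constant
across training maps to 0.5.

## Training protocol

Hyperparameters follow the LIBSVM convention — cost *c*, RBF width *g*,
tube width *p* — searched over integer powers of two: c ∈ 2⁻¹⁰…2⁻¹,
g ∈ 2⁻¹²…2⁻³, p ∈ 2⁻⁵…2⁻² (400 points). Each point is evaluated by
per-antigen leave-one-out: the held-out antigen's patches are scored by a
model whose SVR, scaler, propensity table and burial-energy table are all
re-derived from the remaining antigens; the per-antigen AUCs are averaged.
Ties are broken toward the smallest (c, g, p). The final model pools every
training antigen. Hygiene is enforced, not advisory: scoring an antigen
with a table whose provenance includes it raises an error unless the
caller explicitly opts into a training-set evaluation.

Targets with no epitopic (or no non-epitopic) surface residues have no AUC
and are excluded from fold means with a warning; the summary helper can
alternatively count undefined targets as 0, the convention used when a
predictor returns nothing at all for a target.

## Consensus combiner

Given ranked residue lists from up to six predictors (generic slots S1–S6,
ordered by expected reliability), a request for E of N surface residues is
served by the tier E falls into: E ≤ ⌊0.25 N⌋ uses S1–S3; ⌊0.25 N⌋ < E ≤
⌊0.50 N⌋ adds S4, then S5, then S6 at 75 % and 100 %. Each tier is seeded
with the previous tier's result at its boundary (R25 ⊆ R50 ⊆ R75). Within
a tier, every active predictor's top list grows in steps of ⌈0.01 N⌉
residues; after each step, residues on ≥ 2 lists are collected; the loop
stops once seed ∪ collected reaches E, keeping the whole final step
(overshoot is not trimmed). Residues outside a predictor's coverage can
never receive its vote but stay eligible through the others; if full-length
lists cannot reach E the shortfall is flagged rather than padded. Sweeping
E over 1–100 % of N produces nested sets and hence a valid ROC for the
consensus itself.

## Evaluation

Prediction accuracy is precision: correctly predicted epitopic residues
over all predicted residues, undefined (an explicit error, not 0) for an
empty prediction. ROC curves grow the predicted set down the ranking in
steps of 1 % of the surface (at least one residue per step), prepend (0,0)
and append (1,1), and integrate by the trapezoid rule; ties in the ranking
are broken lexicographically by (chain, residue number, insertion code) so
results are deterministic. At one-residue steps the trapezoidal AUC equals
the Mann–Whitney statistic; at 1 % steps it stays within the
discretisation tolerance (≈ 0.02) verified in the tests. A paired t-test
helper compares per-target AUC vectors between predictors.

## Synthetic data: what it emulates, and what not

The generator emits four geometries with backbone + Cβ atoms at fixed PDB
precision (3 decimals; all ground truth is computed from the re-parsed
rounded coordinates so oracles and pipeline read identical input):

- *helix* / *two_chain*: ideal α-helical backbones (φ = −57°, ψ = −47°)
  built by NeRF chaining — canonical input for the secondary-structure
  heuristic, nearly all-surface;
- *sheet*: an antiparallel pair of extended strands;
- *globule*: residues snaked through a jittered cubic lattice (spacing
  4.3 Å) so an interior core genuinely fails the 6 % rule — the workhorse
  for surface/burial and training corpora.

Epitopes are spatial clusters: all surface residues within 11 Å (default)
of a random surface seed, re-labelled toward charged/polar types
(K/R/N/D/E) with probability 0.8 while the background leans hydrophobic —
the propensity signal. Synthetic PSSMs plant per-position offsets on the
BLOSUM62 diagonal, negative in the epitope — the conservation signal.
Defaults (96-residue globules, ~45–50 surface residues, epitopes covering
~15–35 % of the surface) were chosen to resemble the size and base rate of
real antigen benchmarks. Simulated ranked servers score
λ·label + (1−λ)·uniform noise; λ tunes each server's AUC monotonically and
saturates at perfect ranking for λ ≥ 0.5 (binary labels dominate bounded
noise from there).

Glycine is excluded from the generator's type pools: with backbone + Cβ
atoms every non-glycine type has identical side-chain geometry, so
re-labelling types after the surface has been computed cannot move the
surface set — the planted epitope is guaranteed to stay a surface subset.
The same atom complement means the Gly-X-Gly reference areas collapse to
one value for all non-glycine types; on full-atom experimental structures
the per-type references would differ and relative accessibilities computed
here would be inflated. Passing tests therefore demonstrate correctness of
the machinery (geometry, bookkeeping, learning protocol, voting,
evaluation) and recoverability of planted signals; they do not certify
predictive accuracy on real antigens, which depends on full side-chain
chemistry, real conservation profiles and real epitope annotation noise,
none of which the generator models.

## Numerical choices and edge cases

- SASA: Shrake–Rupley sphere sampling at 960 points per atom (isolated-atom
  area matches the analytic sphere to well under 1 %); hydrogens ignored;
  highest-occupancy altloc kept; first NMR model only; waters and (by
  default) HETATM ligands dropped; residue numbering kept verbatim.
- Reference side-chain areas are computed at runtime from the extended
  Gly-X-Gly models by the same SASA routine and cached per (probe radius,
  sample count), keeping the 6 % rule self-consistent for any probe.
- Surface threshold is strictly "greater than" 6 %; a residue at exactly
  0.06 is buried.
- Structures with fewer than 3 surface residues are rejected (the patch
  machinery is undefined there).
- Neighbour distances and ties: side-chain geometric centres by default
  (Cα–Cα available); equal distances broken by residue identifier.
- Secondary structure: mkdssp is used when on PATH; otherwise a
  deterministic heuristic assigns helix for φ ∈ (−100, −30) and
  ψ ∈ (−80, −5), strand for φ ∈ (−180, −90) and ψ ∈ (90, 180), with
  minimum run lengths 4 (helix) and 3 (strand), chain breaks detected by
  the C–N peptide-bond distance (> 2.5 Å), and coil elsewhere. Missing
  backbone atoms give coil with a warning.
- SVR predictions are clamped to [0, 1] (the regression target's range);
  constant training labels short-circuit to a constant predictor with a
  warning.
- Top-fraction selection takes ⌈fraction × N⌉ residues.
- Model files are JSON: support vectors, dual coefficients, bias, config,
  scaler and both training-derived tables, so a deserialized model predicts
  bit-identically without the training data.

## Problem sizes used in the shipped experiments

The acceptance script and the recovery tests use 12-antigen training
corpora (96-residue globules), the full 400-point grid, 5 label-permuted
replicates, and 6-antigen test corpora; the consensus oracle checks run
200 randomized instances spanning all four tiers. These sizes give stable
statistics (held-out AUC ≈ 0.95–0.99 for the planted signal, null ≈ 0.5)
while a full run stays within a few minutes on one CPU.

## Known limitations

- The burial-energy term is a statistical surrogate, not an optimized
  physical energy function.
- The secondary-structure heuristic is torsion-only (no hydrogen-bond
  pattern analysis) and deliberately conservative near element ends.
- PSSM-to-structure mapping requires an exact substring match; structures
  with internal gaps relative to the profile leave residues at
  conservation 0 rather than attempting an alignment.
- mmCIF input, multi-model ensembles, and bound/unbound superposition are
  out of scope.
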