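# Methods

## Model

The predictor is an edge-conditioned message-passing network over the
H-explicit molecular graph of one 3-D conformer.  Node features are an
element one-hot over {H, B, C, N, O, F, P, S, Cl, Br, I} plus
hybridisation, aromaticity, ring membership, scaled degree and
attached-H count, and formal charge.  Edges connect every atom pair
within a distance cutoff; the interatomic distance is expanded in
Gaussian radial basis functions.  Geometry enters only through
distances, so predictions are exactly invariant under rigid motions
and equivariant under atom reindexing (both verified numerically in
the test suite).  Each of the `n_steps` rounds gates the neighbour's
hidden state by a learned function of the edge features, aggregates by
sum, and applies a residual tanh update.  A per-atom MLP readout with
`n_quantiles` outputs produces, for every carbon, the predicted shift
at each quantile level; non-carbon atoms contribute messages but no
output.

The network and its training loop run on a small tape-based
reverse-mode autodiff core (`dp5q.autodiff`) written on numpy; it
implements exactly the primitives the model needs (dense algebra,
tanh/relu, gather/segment-sum for message passing, and the fused
asymmetric-Huber term with its analytic derivative).

## Objective

For observed shift `y` and per-quantile predictions `ŷ_τ`, each
quantile contributes `w_τ(r)·Huber_δ(r)` with `r = y − ŷ_τ` and
`w_τ = τ` for under-prediction, `1 − τ` for over-prediction; the Huber
scale is δ = 1e-4 ppm, so the term is everywhere within δ/2 of the
pinball loss whose minimiser is the τ-quantile, while the gradient is
continuous at r = 0.  The algebraic form used is the standard
`r²/(2δ)` inside |r| ≤ δ and `|r| − δ/2` outside; any C¹ smoothing
with the same δ→0 limit would satisfy the same tests.  Summed over the
99-level grid and added to the crossing penalty
`Σ_k max(0, ŷ_τk − ŷ_τk+1 + ε)` (ε = 1e-6, weight 1), the total loss
is averaged over atoms so its scale is batch-size independent.
Whether the quantile term is summed or averaged over grid levels only
rescales the learning rate; the sum is used.

## Training

Adam with stepwise learning-rate decay (`lr × (1−decay)^(steps //
interval)`), molecule-level train/validation split (default 10%
validation), early stopping on the first `patience` consecutive
epochs without strict validation improvement, returning the
best-validation checkpoint.  Library defaults follow the established
recipe for corpus-scale shift models: lr 5e-4, 4% decay per 100 000
steps, up to 1200 epochs, patience 10.  Every carbon atom inherits
the experimental shift assigned to its symmetry-equivalence class;
classes without an assigned peak are excluded from the objective.
Targets are internally standardised (mean/std of the training shifts)
and the output head maps back to ppm; the head weight matrix starts
at zero and its bias starts on a monotone unit-Gaussian quantile shape
with a 2 ppm prior width, so the spread is learned as a correction
rather than from a degenerate flat start.

## Scoring

Predicted per-atom quantile vectors are averaged within each carbon
equivalence class, repaired to non-decreasing order by sorting (the
training penalty discourages but cannot forbid residual crossings, and
the error score needs a valid CDF), and interpolated piecewise
linearly through the (value, τ) knots.  Outside the outermost knots
the CDF ramps linearly to exactly 0 and 1 over a width equal to the
adjacent inter-quantile gap — a local-scale extrapolation standing in
for the unmodelled 0th/100th percentiles.  A degenerate all-equal
vector acts as a step function: P = 0 at the predicted value, 1
elsewhere.  The atomic error score is the CDF mass inside
`[ŷ−|ŷ−y|, ŷ+|ŷ−y|]` around the median ŷ (the τ = 0.5 entry, or the
interpolated level when 0.5 is absent from the grid); DP5q = 1 − P;
the molecular score is the geometric mean of atomic scores computed in
log space, exactly 0 when any atomic score is 0.  Scoring is per
equivalence class (one experimental peak ↔ one score); MAE compares
class median predictions with assigned shifts.

When no assignment is supplied, peaks are matched to class medians by
exact minimum-cost bipartite matching on |Δδ| (Hungarian algorithm),
with surplus classes left unmatched and excluded from scoring — the
documented stand-in for the published assignment procedure, chosen
because it is optimal, deterministic and exhaustively testable.  Peak
intensities are not used.

## Synthetic data

The fixture generator emulates a curated shift corpus with fully known
statistics.  Each carbon's environment key — hybridisation,
aromaticity, ring membership, counts of attached C/O/N/halogen and of
β-heteroatoms — maps to a mean shift through an additive increment
rule spanning roughly 0–220 ppm, in the spirit of empirical ¹³C
substituent-increment schemes; attached-carbon and β-heteroatom terms
are included so that positional isomers produce distinct spectra,
which is what makes the same-formula benchmark discriminating.  The
noise is Gaussian, independent across carbons, with an
environment-dependent σ between 1 and 3 ppm, so the true quantile
function is `mean + σ·Φ⁻¹(τ)` in closed form — the ground truth for
all calibration tests.  One shift is drawn per equivalence class.
What the generator does *not* emulate: real database error structure,
solvent/temperature/referencing effects, assignment noise, exchange
broadening, or any correlation between atoms.  Passing the
calibration tests therefore demonstrates that the estimator recovers
a known heteroscedastic conditional distribution, not that it matches
experimental accuracy.

Same-formula candidate pools are generated as random labelled trees
(Prüfer sequences) over a fixed heavy-atom multiset (default nine
carbons + one oxygen), valence-filtered and de-duplicated by canonical
SMILES: every saturated acyclic tree over that multiset shares one
molecular formula.

## Desk-scale study conditions

The test suite and the acceptance script train at desk scale, chosen
to fit a single CPU: 240 training molecules with three independent
replicate spectra each (duplicates are legitimate corpus entries), 40
held-out molecules, hidden width 64, three message-passing steps,
cutoff 2.0 Å (the environment signal is two bonds local; the bonded
graph plus message passing carries it), batch 64, lr 3e-3 decayed by
30% every 300 steps (annealing to ~1e-5 so the crossing penalty can
settle adjacent quantiles), at most 700 epochs with patience 120.  The
benchmark pool is 50 constitutional isomers of C₉H₂₀O.  The
learning-rate/scheduling constants differ from the corpus-scale
library defaults because the desk corpus is ~100× smaller; they were
fixed once as part of the study conditions.

## Numerical choices and degenerate inputs

* Quantile grid: strictly increasing, open interval (0, 1); the
  default 99-level percentile grid contains τ = 0.5 exactly.
* Monotonic repair by sorting preserves the value multiset.
* Ties in peak assignment are broken towards the lexicographically
  smallest (peak, class) pairing via an infinitesimal index bias.
* Ensemble prediction averages per-conformer quantile vectors
  (uniformly by default, or Boltzmann-weighted from supplied energies)
  — the Wasserstein barycentre of the conformer distributions; it is
  order-preserving and conformer-order invariant.  Whether an
  energy-ranked workflow should Boltzmann-weight or pick the minimum
  is left to the caller through the weights argument.
* Curation order is fixed (spectrum presence → single fragment →
  element set → 50 ppm outlier); the outlier rule is per-atom maximum
  deviation with a strict boundary (exactly 50 ppm is kept), and the
  reference predictions it compares against are an injected input.
* Empty ratio-surface bins are reported as undefined (NaN), never 0.

## Known limitations

* The backbone is a generic small message-passing network, not a
  reproduction of any published architecture; corpus-scale accuracy
  claims are out of scope.
* ¹³C only; no ¹H, J-couplings or 2-D data.
* No force-field or DFT stage of its own: conformers come from RDKit
  ETKDG + MMFF or are supplied externally with energies.
* The crossing penalty suppresses but does not eliminate quantile
  crossing; inference always applies the sorting repair.
* Peak lists are assumed already extracted; no raw spectrum parsing.
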