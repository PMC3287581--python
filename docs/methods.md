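# Methods

## The cutoff-scanning signature

A protein chain is reduced to one point per residue. With residues
i = 1..n and centroid coordinates x_i (Å), the contact graph at cutoff d
joins every pair with ‖x_i − x_j‖ ≤ d. The signature of the chain is the
cumulative pair count at each threshold of an inclusive grid d_min + k·step,
k = 0..⌊(d_max − d_min)/step⌋; the default grid (0.0, 30.0, 0.2) has 151
thresholds. The threshold comparison is closed (≤) with an absolute
tolerance of 1e-9 Å: an inclusive comparison is the standard contact-map
convention, a strict one would be degenerate at the 0.0 Å end of the grid,
and the tolerance stabilizes exactly-representable boundary distances
(e.g. points placed exactly 3.8 Å apart). The threshold count is computed
with a guarded floor so float drift in (d_max − d_min)/step can never
produce 150 or 152 columns.

Counting is implemented as a sort of the n(n−1)/2 pairwise distances
followed by one binary search per threshold (O(n² log n + T log n) rather
than O(n²·T)); the naive double-loop count is the contract, and the test
suite checks equality against an explicit pair-enumeration oracle at all
151 thresholds on seeded random point sets.

Properties that follow from the definition, and are enforced as tests:
vectors are monotone non-decreasing; invariant under rigid motion and
residue reordering (they depend only on the distance multiset); the final
entry equals n(n−1)/2 whenever the chain diameter fits inside the grid;
scaling coordinates by c shifts counts along the cutoff axis. Consecutive
residue pairs are *not* masked — the 3.8–4.0 Å backbone peak is part of
the signature. Classification uses the raw integer cumulative counts;
first-difference (density) and pair-normalized forms are explicit opt-in
transforms used for inspection and plotting, not for the feature matrix.

## Preprocessing of coordinates

PDB input is parsed with gemmi. Only the first model of multi-model (NMR)
entries is used; each chain yields a separate signature vector (domain
files, e.g. from ASTRAL, are single-chain inputs). HETATM-only entities
(waters, ligands) are excluded, while ATOM records are accepted regardless
of residue name so modified residues deposited as ATOM (MSE, ...) count.
Alternate locations are resolved per atom name by highest occupancy, ties
to the first in file order. Centroid schemes: CA (default); CB with a CA
fallback for glycine only; LHA = last heavy side-chain atom in file order
(atoms outside N/CA/C/O/OXT, hydrogens excluded) with a CA fallback when
there is no side chain. Residues lacking the centroid atom are skipped
with a logged warning rather than zero-filled, so pair counts always refer
to observed residues. Insertion codes are part of residue identity;
residue order is file order. A minimum-length filter (default
recommendation: 10 residues) drops fragments whose signatures are
dominated by the backbone peak.

## SVD reduction

The feature matrix A (m structures × n cutoffs) is decomposed by thin SVD,
A = T·S·Dᵀ, without centering by default — the decomposition acts on the
raw count matrix; column-mean centering (PCA-style) is an option flag, and
when set the mean is stored and restored on reconstruction. Structures are
represented by row projections Tₖ·Sₖ: rows are proteins, and at k = p the
projection is an isometry on rows, so nearest-neighbour classification at
full rank is provably identical to classification on the raw features
(verified end-to-end in the tests). Rank-k reconstruction satisfies
Eckart–Young: its Frobenius error equals √(Σ_{i>k} σ_i²), which the tests
assert at 1e-8 relative tolerance.

Rank selection: the elbow of the spectrum, operationalized as
argmax_i log(σ_i/σ_{i+1}) — the largest consecutive drop on a log scale,
matching how singular-value spectra are read visually. Singular values
below 1e-12·σ₁ are treated as zero and cannot start a drop; a flat
spectrum raises an explicit error asking for a fixed k rather than
guessing. A fixed-k override is available throughout (k = 9 is a
documented operating point for curated enzyme-superfamily data). On
planted-rank matrices (orthogonal low-rank signal with smallest signal
singular value ≥ 100× the largest noise singular value), the auto rule
recovers the planted rank in ≥ 95/100 seeded trials for ranks 3 and 9; the
acceptance script re-measures this rate.

On the synthetic four-class data the elbow typically lands at k = 1,
because the leading component (overall contact volume, dominated by chain
length and compactness) carries almost all variance and already separates
the four geometry families; real, more heterogeneous data push the elbow
higher. This is a property of the elbow rule, not a tuned choice.

## Classification and evaluation

KNN (Euclidean distance on the representation in use; default k_nn = 5,
tuning grid {1, 3, 5, 7, 9}), Gaussian naive Bayes (variance floored via
sklearn's var_smoothing = 1e-9, since integer count features can have
zero within-class variance), and random forests (default 100 trees, √p
features per split) run behind one `ClassifierSpec` surface; scikit-learn
provides the estimators.

Evaluation is seeded stratified 10-fold cross-validation; predictions
from all folds are pooled into a single confusion matrix (so each row is
predicted exactly once), from which per-class precision = TP/(TP+FP),
recall = TP/(TP+FN), and F1 are computed. Undefined precision (a class
never predicted) is reported as 0 and flagged, keeping weighted averages
defined. AUC is one-vs-rest from classifier scores (KNN uses neighbour
vote fractions) and support-weighted across classes. Deltas between two
runs (e.g. raw vs SVD-reduced features) are percentage-point differences
formatted as "+9.0%" — 0.901 → 0.991 prints as +9.0%, not as a relative
change.

Hyperparameter tuning evaluates every spec on the same folds and seed and
returns the best by weighted precision (ties: weighted F1, then grid
order). Tuned-on-CV numbers are reported as-is; selecting and reporting on
the same folds is optimistically biased, and callers who need unbiased
estimates should hold out data before tuning.

## Synthetic structures

The generator emulates the geometric regimes whose contact signatures the
method exploits, without requiring any structure download:

| family            | construction                                   | key distances |
|-------------------|------------------------------------------------|---------------|
| ideal_helix       | rise 1.5 Å/res, 100° turn, radius 2.3 Å        | i,i+1 ≈ 3.83 Å; i,i+4 ≈ 6.2 Å |
| extended_strand   | zig-zag, 3.8 Å bonds, x-step 3.35 Å            | i,i+2 = 6.7 Å |
| polyproline_like  | left-handed helix, rise 3.1 Å, −120°/res       | i,i+1 = 3.8 Å, maximally extended |
| random_coil       | freely-jointed 3.8 Å walk, ≥3.8 Å self-clearance | compact, dense long-range contacts |

Helix parameters are textbook α-helix Cα geometry. The strand x-step is
set so the (i, i+2) distance is 6.7 Å (virtual Cα angle ≈ 124.6°), the
value observed in real β-strands. Gaussian coordinate noise of standard
deviation `noise_sd` (Å) is added to every point; it is the difficulty
dial, and cross-validated precision is non-increasing in it (tested at
three levels with 0.02 sampling tolerance). All randomness derives from
`numpy.random.SeedSequence`: the dataset builder spawns one child sequence
per chain from the master seed, so datasets are byte-reproducible across
platforms, including the emitted PDB fixture files (written through the
package's own PDB writer so parsing is exercised, not bypassed).

What the synthetic data does *not* model: side chains (the LHA scheme is
tested on hand-written mini-PDB records instead), realistic tertiary
packing, surface pockets, or the size and class imbalance of real
benchmark sets. Passing the pipeline tests therefore demonstrates that the
machinery is correct and that contact signatures separate geometrically
distinct families — not that any particular precision level will transfer
to PDB/SCOP-scale data, which must be ingested through the PDB reader and
label tables and evaluated the same way.

## Problem sizes and defaults

The shipped experiments use a four-class dataset of 30 chains per class,
50 residues per chain, noise 0.3 Å — small enough for the full pipeline
(151-column CSM, SVD, 10-fold CV) to run in seconds, large enough that
every class supports stratified 10-fold cross-validation with the
10-representative minimum. Elbow-recovery studies use 40×151 matrices and
100 trials per planted rank. Class-size filters default to the number of
folds so stratification is always feasible; 9 (EC) and 10 (SCOP) are the
conventional minimums for real data.

## Known limitations

- Inter-chain contacts are out of scope: each chain is featurized alone.
- All-atom or Delaunay-based contact definitions are not implemented; the
  signature is centroid- and cutoff-based by design.
- mmCIF input, automatic PDB download, and sequence-redundancy filtering
  are left to upstream tooling.
- The elbow rule keeps the top block of components; it cannot select a
  non-contiguous subset (feature selection is a different method).
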