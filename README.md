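# csmkit

Structure-based protein classification from inter-residue distance
patterns: the **Cutoff Scanning Matrix (CSM)** signature, SVD noise
reduction, and cross-validated classifiers for enzyme function prediction
(EC numbers, enzyme superfamilies) and structural classification (SCOP
class / fold / superfamily / family).

## Who it is for

Structural bioinformaticians who want an alignment-free, sequence-free
structural signature: given only the 3D coordinates of a protein chain or
domain, predict which functional or structural class it belongs to.

## The method

Reduce each chain to one centroid per residue (the Cα by default; Cβ or
the last heavy side-chain atom optionally). For a chain with *n* residues,
compute all *n(n−1)/2* pairwise Euclidean distances, then sweep a distance
cutoff *d* from 0.0 Å to 30.0 Å in 0.2 Å steps (151 thresholds, endpoints
inclusive). At each threshold, record

> CSM[i, t] = #{ (j, k) : j < k, ‖x_j − x_k‖ ≤ d_t }

— the edge count of the contact graph at cutoff *d_t*. One protein per row,
one cutoff per column: the CSM. Its profile encodes secondary-structure
content (the ~3.8 Å consecutive-Cα peak; 5–7 Å helix-turn contacts; ~6.7 Å
strand i,i+2 contacts) and, at larger cutoffs, overall packing and shape.

The matrix A is then factored A = T·S·Dᵀ by SVD, a rank k is chosen at the
elbow of the singular-value spectrum (largest consecutive log-scale drop,
or a fixed k), and each structure is represented by its rank-k row
projection Tₖ·Sₖ. KNN, Gaussian naive Bayes, or random-forest classifiers
are evaluated with seeded stratified 10-fold cross-validation; precision,
recall, F1 and one-vs-rest AUC are reported per class and support-weighted.

Real datasets (PDB entries, ASTRAL/SCOP domain files, EC tables) enter
through the PDB reader and plain-TSV label tables; a synthetic-structure
module generates idealized helix / strand / polyproline / coil chains so
the entire pipeline is testable offline.

## Worked example

```bash
python examples/03_classify_geometries.py
```

```
120 chains, 4 classes, 10-fold CV, KNN (k=5)

SVD-reduced features (rank 1):
class                      prec    rec     F1    AUC     n
coil                      1.000  0.867  0.929  0.963    30
helix                     0.882  1.000  0.938  0.986    30
pp2                       1.000  1.000  1.000  1.000    30
strand                    1.000  1.000  1.000  1.000    30
weighted avg              0.971  0.967  0.967  0.987   120

raw -> SVD deltas (percentage points):
  coil           dPrec   +0.0%   dRec   -3.3%
  helix          dPrec   -2.7%   dRec   +0.0%
  pp2            dPrec   +0.0%   dRec   +0.0%
  strand         dPrec   +0.0%   dRec   +0.0%
  weighted avg   dPrec   -0.7%   dRec   -0.8%
```

Four synthetic geometry families (30 chains each, 0.3 Å coordinate noise)
are classified from their cutoff-scanning signatures at 96.7% weighted
recall using a single SVD component per structure instead of 151 raw
counts; the delta table shows the percentage-point cost/gain of the SVD
step per class. `examples/01_contact_profile.py` prints the density
signatures behind the separation, and `examples/02_svd_elbow.py` the
spectrum and elbow.

A thin CLI wraps the same calls:

```bash
csm synth --preset four-class --n 30 --noise 0.3 --seed 0 --out scratch/demo
csm featurize scratch/demo/*.pdb --out scratch/demo.csm.tsv
csm classify scratch/demo.csm.tsv scratch/demo/labels.tsv --svd-k auto --compare-raw
```

## Applying to real data

Point `read_pdb_coordinates` at PDB files (first NMR model used, chains
split, ≥10-residue filter via `filter_chain_length`), and supply labels as
TSV (`structure_id` plus any of `ec`, `scop_class`, `scop_fold`,
`scop_superfamily`, `scop_family`, `superfamily`, `family`) or an
ASTRAL/SCOP `dir.cla` file via `read_scop_cla`. Filter classes to at least
9 (EC) or 10 (SCOP) representatives with `filter_min_representatives`,
then proceed exactly as in the examples.
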