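# music-deconv

Cell-type deconvolution of bulk RNA-seq samples using a **multi-subject
single-cell RNA-seq reference**, in the MuSiC style: cross-subject
variance-weighted non-negative least squares (W-NNLS), with a
tree-guided recursive mode for closely related (collinear) cell types
and a pseudo-bulk benchmarking harness with known ground truth.

It is written for computational biologists who have (a) a bulk RNA-seq
count matrix for a solid tissue and (b) labeled single-cell count data
from several subjects of the same tissue, and who want per-sample
cell-type proportions without hand-picking marker genes.

## Model

For gene *g*, cell type *k* and subject *j*, define the cell-type
relative abundance and cell-size factor

- θ<sub>jg</sub><sup>k</sup> = (pooled counts of *g* over type-*k* cells) / (total counts over those cells),
- S<sub>j</sub><sup>k</sup> = average library size of a type-*k* cell.

A bulk sample's relative abundance Y<sub>g</sub> then satisfies

```
Y_g  ∝  Σ_k  p_k · S^k · θ_g^k ,       p ≥ 0,  Σ_k p_k = 1
```

where *p* is the vector of cell-type proportions. The reference pools
θ across subjects into a cross-subject mean θ<sub>g</sub><sup>k</sup>
and variance σ²<sub>gk</sub>. Marginalizing the subject-level θ gives a
per-gene variance

```
Var[Y_g | p]  =  δ_g²  +  Σ_k (p_k S^k)² σ²_gk   =  1 / w_g ,
```

so the regression is solved by iteratively re-weighted NNLS: weights
start uniform (plain NNLS), then each iteration sets
w<sub>g</sub> = 1/(ν + r<sub>g</sub>² + Σ<sub>k</sub> q<sub>k</sub>² σ²<sub>gk</sub>)
from the current residuals *r* and raw coefficients *q* ∝ p·S. Genes
that are consistent across reference subjects are automatically
up-weighted; no marker pre-selection is needed. Because the model is a
"proportional to" relation, only read/UMI **counts** are valid input —
TPM is rejected (the per-type library-size factors are lost in TPM).

For tissues with closely related cell types whose signatures are nearly
collinear (e.g. proximal vs distal tubule), the **tree-guided recursive
mode** first estimates the proportions of cell-type *clusters* using
cluster-consistent genes (low within-cluster signature variance), then
resolves each cluster's members with genes re-selected for that stage,
rescaling so within-cluster proportions sum exactly to the cluster
estimate.

## Worked example

```python
import numpy as np
import pandas as pd
import music_deconv as md

# synthetic multi-subject single-cell data: 1000 genes, 3 cell types,
# 6 subjects, 50 cells per type, with cross-subject signature variation
params = md.SimParams(n_genes=1000, n_types=3, n_subjects=6, cells_per_type=50, seed=42)
sc, truth = md.simulate_sc(params)
ref = md.build_reference(md.compute_subject_abundance(sc))

# one bulk sample mixed at known proportions (0.5, 0.3, 0.2)
p_true = np.array([[0.5, 0.3, 0.2]])
bulk = md.simulate_bulk(truth, p_true, depth=100_000, noise_sd=0.1, seed=43)

table = md.deconvolve_all(bulk, ref)
print(table.proportions.round(3))
truth_df = pd.DataFrame(p_true, index=table.proportions.index, columns=table.proportions.columns)
rep = md.evaluate(truth_df, table.proportions)
print(f"R={rep.R:.3f}  RMSD={rep.RMSD:.4f}  mAD={rep.mAD:.4f}")
```

prints

```
cell_type  type_0  type_1  type_2
sample
bulk_00     0.498   0.303   0.199
R=1.000  RMSD=0.0020  mAD=0.0018
```

i.e. the mixing proportions (0.5, 0.3, 0.2) are recovered to within a
few parts per thousand; the fit converged in 8 weighted iterations with
a weighted R² of 0.97 (see `table.diagnostics()`).

## Command line

The same functionality is exposed as a `music` command:

```bash
music simulate   --scenario collinear_pair --seed 3 --out scn/
music build-ref  --sc-matrix scn/sc/counts.tsv --sc-metadata scn/sc/cell_metadata.tsv --out ref/
music cluster-types --ref ref/ --out tree/            # dendrogram + Newick
music deconvolve --bulk scn/bulk_counts.tsv --ref ref/ --tree scn/grouping.yaml --out est/
music evaluate   --truth scn/true_p.tsv --estimate est/proportions.tsv
music benchmark  --sc-matrix sc/counts.tsv --sc-metadata sc/cell_metadata.tsv \
                 --methods music,nnls --holdout loo --out bench/
```

Inputs are plain TSV/CSV (genes × columns, header row of IDs) or
MatrixMarket `.mtx` with `genes.tsv`/`barcodes.tsv` sidecars; cell
metadata is a TSV with `barcode`, `subject`, `cell_type` columns.
Outputs are tab-delimited tables plus JSON diagnostics; every run writes
its resolved configuration next to its outputs.

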