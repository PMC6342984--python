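import numpy as np
import pandas as pd
import pytest

from music_deconv import (
    BulkSample,
    ReferenceBasis,
    ScDataset,
    relative_abundance_bulk,
    scenario,
)


@pytest.fixture
def tiny_sc() -> ScDataset:
    """3 genes, 2 subjects, 2 cell types, hand-enterable integer counts."""
    # cells: s1/A, s1/A, s1/B, s2/A, s2/B, s2/B
    counts = np.array(
        [
            [2, 4, 1, 3, 0, 2],
            [1, 1, 5, 0, 3, 3],
            [3, 0, 2, 3, 1, 0],
        ]
    )
    return ScDataset(
        counts=counts,
        gene_ids=["g1", "g2", "g3"],
        cell_subject=["s1", "s1", "s1", "s2", "s2", "s2"],
        cell_type=["A", "A", "B", "A", "B", "B"],
    )


def subject_abundance_oracle(sc: ScDataset):
    """Naive per-cell loop computation of theta, cell counts and library
    sizes — written independently of the vectorized implementation."""
    subjects = sorted(set(sc.cell_subject))
    types = sorted(set(sc.cell_type))
    theta = {}
    m = {}
    lib = {}
    for subj in subjects:
        for ct in types:
            pooled = np.zeros(sc.n_genes)
            n_cells = 0
            for c in range(sc.n_cells):
                if sc.cell_subject[c] == subj and sc.cell_type[c] == ct:
                    n_cells += 1
                    for g in range(sc.n_genes):
                        pooled[g] += sc.counts[g, c]
            if n_cells == 0:
                continue
            total = pooled.sum()
            theta[(subj, ct)] = pooled / total
            m[(subj, ct)] = n_cells
            lib[(subj, ct)] = total / n_cells
    return theta, m, lib


def make_reference(theta_mean, theta_var=None, lib_size=None, gene_ids=None, type_ids=None):
    """Build a ReferenceBasis directly from matrices (test helper)."""
    theta_mean = np.asarray(theta_mean, dtype=float)
    G, K = theta_mean.shape
    return ReferenceBasis(
        theta_mean=theta_mean,
        theta_var=np.zeros((G, K)) if theta_var is None else np.asarray(theta_var, dtype=float),
        lib_size=np.ones(K) if lib_size is None else np.asarray(lib_size, dtype=float),
        n_subjects_per_type=np.full(K, 2),
        gene_ids=gene_ids or [f"g{i}" for i in range(G)],
        cell_type_ids=type_ids or [f"t{k}" for k in range(K)],
    )


def bulk_from_counts(counts, gene_ids, sample_id="s"):
    return BulkSample(
        y=relative_abundance_bulk(np.asarray(counts, dtype=float)),
        gene_ids=gene_ids,
        sample_id=sample_id,
    )


@pytest.fixture(scope="session")
def baseline_bundle():
    """One shared baseline synthetic scenario (seed fixed)."""
    return scenario("baseline", seed=1)


def scenario_rmsd_table(bundle, estimator):
    """Run an estimator over a scenario's bulk samples; returns (truth, estimates)."""
    ref, bulkdf = bundle["reference"], bundle["bulk_counts"]
    rows = {}
    for sid in bulkdf.columns:
        bs = bulk_from_counts(bulkdf[sid].to_numpy(float), bulkdf.index.to_numpy(object), sid)
        rows[sid] = estimator(bs, ref)
    return bundle["true_p"], pd.DataFrame(rows).T
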