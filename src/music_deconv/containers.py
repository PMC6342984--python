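"""Core in-memory containers shared across the package.

The central quantities follow the standard multi-subject deconvolution
model: for subject ``j``, gene ``g`` and cell type ``k``, the cell-type
relative abundance is

    theta_jg^k = (sum of counts of g over cells of type k in j)
                 / (total counts over those cells),

the average library size of type ``k`` in subject ``j`` is ``S_j^k``, and a
bulk profile satisfies ``Y_g ∝ Σ_k p_k S_k theta_g^k`` where ``p`` are the
cell-type proportions to be estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScDataset",
    "SubjectAbundance",
    "ReferenceBasis",
    "BulkSample",
    "WnnlsConfig",
    "DeconvolutionResult",
]


def _as_str_array(values: Sequence, what: str) -> np.ndarray:
    arr = np.asarray([str(v).strip() for v in values], dtype=object)
    if arr.ndim != 1:
        raise ValueError(f"{what} must be one-dimensional")
    return arr


@dataclass
class ScDataset:
    """Labeled multi-subject single-cell count matrix (genes x cells).

    Counts are read or UMI counts; both are treated as molecule-count
    proxies. Every cell carries exactly one subject label and one
    cell-type label. Labels are matched exactly after trimming
    surrounding whitespace.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_subject: np.ndarray
    cell_type: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a genes x cells matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids")
        self.cell_subject = _as_str_array(self.cell_subject, "cell_subject")
        self.cell_type = _as_str_array(self.cell_type, "cell_type")
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids has {len(self.gene_ids)} entries for {n_genes} gene rows"
            )
        if len(self.cell_subject) != n_cells or len(self.cell_type) != n_cells:
            raise ValueError("per-cell metadata length must equal the number of cells")
        if len(set(self.gene_ids)) != n_genes:
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def subjects(self) -> list[str]:
        return sorted(set(self.cell_subject))

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(self.cell_type))

    def subset_cells(self, mask: np.ndarray) -> "ScDataset":
        return ScDataset(
            counts=self.counts[:, mask],
            gene_ids=self.gene_ids,
            cell_subject=self.cell_subject[mask],
            cell_type=self.cell_type[mask],
        )


@dataclass
class SubjectAbundance:
    """Per-subject cell-type relative abundances and size factors.

    ``theta`` is subjects x genes x cell types with ``theta[j, :, k]``
    summing to one for every present (subject, type) pair and NaN slices
    for absent pairs — absence is recorded, never imputed as zero.
    """

    theta: np.ndarray
    cell_counts: np.ndarray  # subjects x types, m_j^k
    subject_lib_size: np.ndarray  # subjects x types, S_j^k (NaN when absent)
    subject_ids: np.ndarray
    gene_ids: np.ndarray
    cell_type_ids: np.ndarray

    @property
    def present(self) -> np.ndarray:
        """Boolean subjects x types mask of observed pairs."""
        return self.cell_counts > 0


@dataclass
class ReferenceBasis:
    """Cross-subject reference: mean and variance of theta plus cell-size
    factors.

    ``theta_mean[g, k]`` and ``theta_var[g, k]`` are the cross-subject
    mean and variance of ``theta_jg^k``; ``lib_size[k]`` is the common
    per-cell-type average library size used as the cell-size proxy.
    """

    theta_mean: np.ndarray
    theta_var: np.ndarray
    lib_size: np.ndarray
    n_subjects_per_type: np.ndarray
    gene_ids: np.ndarray
    cell_type_ids: np.ndarray
    var_estimator: str = "sample"
    subjects_per_type: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids")
        self.cell_type_ids = _as_str_array(self.cell_type_ids, "cell_type_ids")

    @property
    def n_genes(self) -> int:
        return self.theta_mean.shape[0]

    @property
    def n_types(self) -> int:
        return self.theta_mean.shape[1]

    def subset_types(self, types: Sequence[str]) -> "ReferenceBasis":
        """Restrict the reference to a subset of cell types.

        theta columns are kept as-is (they are compositions over genes,
        independent across types), so no renormalization is needed.
        """
        idx = [list(self.cell_type_ids).index(str(t).strip()) for t in types]
        return ReferenceBasis(
            theta_mean=self.theta_mean[:, idx],
            theta_var=self.theta_var[:, idx],
            lib_size=self.lib_size[idx],
            n_subjects_per_type=self.n_subjects_per_type[idx],
            gene_ids=self.gene_ids,
            cell_type_ids=self.cell_type_ids[idx],
            var_estimator=self.var_estimator,
            subjects_per_type={
                t: self.subjects_per_type.get(t, []) for t in self.cell_type_ids[idx]
            },
        )

    def subset_genes(self, genes: Sequence[str]) -> "ReferenceBasis":
        """Restrict to a gene subset (theta columns are NOT renormalized;
        the regression is scale-free in each column)."""
        pos = pd.Index(self.gene_ids).get_indexer([str(g).strip() for g in genes])
        if np.any(pos < 0):
            missing = [g for g, p in zip(genes, pos) if p < 0]
            raise KeyError(f"genes not in reference: {missing[:5]}")
        return ReferenceBasis(
            theta_mean=self.theta_mean[pos],
            theta_var=self.theta_var[pos],
            lib_size=self.lib_size,
            n_subjects_per_type=self.n_subjects_per_type,
            gene_ids=self.gene_ids[pos],
            cell_type_ids=self.cell_type_ids,
            var_estimator=self.var_estimator,
            subjects_per_type=self.subjects_per_type,
        )


@dataclass
class BulkSample:
    """One bulk expression vector as relative abundance over genes."""

    y: np.ndarray
    gene_ids: np.ndarray
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids")
        if self.y.ndim != 1 or len(self.y) != len(self.gene_ids):
            raise ValueError("y and gene_ids must be aligned vectors")
        if np.any(self.y < 0):
            raise ValueError("bulk relative abundance must be non-negative")
        total = self.y.sum()
        if not np.isfinite(total) or abs(total - 1.0) > 1e-8:
            raise ValueError(
                "bulk vector must be a relative abundance summing to 1; "
                "use relative_abundance_bulk() on raw counts first"
            )


@dataclass
class WnnlsConfig:
    """Tuning knobs for the iteratively re-weighted NNLS fit.

    nu damps the per-gene weight denominator (guards against zero
    residual + zero variance genes); tol is the L1 change in the
    proportion vector at which iteration stops.
    """

    max_iter: int = 1000
    tol: float = 1e-4
    nu: float = 1e-4
    center: bool = False
    fixed_weights: np.ndarray | None = None
    init: str = "nnls"  # or "uniform"

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.nu < 0:
            raise ValueError("nu must be non-negative")
        if self.init not in ("nnls", "uniform"):
            raise ValueError("init must be 'nnls' or 'uniform'")


@dataclass
class DeconvolutionResult:
    """Estimated proportions plus fit diagnostics for one bulk sample.

    ``p`` sums to one and is non-negative (constraints C1/C2); ``q`` is
    the RNA-fraction vector proportional to p_k * S_k, useful when only
    the fraction of RNA molecules per cell type is identified.
    """

    p: pd.Series
    q: pd.Series
    weights: pd.Series
    residuals: pd.Series
    n_iter: int
    converged: bool
    var_explained: float
    sample_id: str = "sample"
    flags: list = field(default_factory=list)
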