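"""Build the statistical reference from labeled multi-subject single-cell data.

For each subject j and cell type k the per-subject relative abundance is

    theta_jg^k = sum_{c in C_j^k} X_gc / sum_{c in C_j^k} sum_g' X_g'c

with C_j^k the cells of type k in subject j. Pooling across subjects gives
the cross-subject mean theta_g^k, the cross-subject variance sigma_gk^2
(the key ingredient of the gene weighting), and the per-type average
library size S^k used as the cell-size proxy.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .containers import ReferenceBasis, ScDataset, SubjectAbundance

logger = logging.getLogger(__name__)

__all__ = [
    "compute_subject_abundance",
    "build_reference",
    "relative_abundance_bulk",
]


def compute_subject_abundance(sc: ScDataset) -> SubjectAbundance:
    """Compute per-subject, per-cell-type relative abundances.

    Returns a tensor ``theta`` (subjects x genes x types) whose slices
    sum to one over genes for every observed (subject, type) pair, the
    cell counts ``m_j^k``, and the average library sizes ``S_j^k``.
    Pairs with no cells are recorded as absent (NaN theta, zero count).

    Raises
    ------
    ValueError
        If an observed (subject, type) pair has zero total counts — the
        relative abundance is then undefined (division by zero).
    """
    subjects = sc.subjects
    types = sc.cell_types
    n_s, n_g, n_k = len(subjects), sc.n_genes, len(types)

    theta = np.full((n_s, n_g, n_k), np.nan)
    cell_counts = np.zeros((n_s, n_k), dtype=int)
    lib_size = np.full((n_s, n_k), np.nan)

    counts = np.asarray(sc.counts, dtype=float)
    for j, subj in enumerate(subjects):
        for k, ct in enumerate(types):
            mask = (sc.cell_subject == subj) & (sc.cell_type == ct)
            m = int(mask.sum())
            if m == 0:
                continue
            pooled = counts[:, mask].sum(axis=1)
            total = pooled.sum()
            if total <= 0:
                raise ValueError(
                    f"subject {subj!r}, cell type {ct!r}: all cells have zero "
                    "total counts; relative abundance is undefined"
                )
            cell_counts[j, k] = m
            theta[j, :, k] = pooled / total
            lib_size[j, k] = total / m

    return SubjectAbundance(
        theta=theta,
        cell_counts=cell_counts,
        subject_lib_size=lib_size,
        subject_ids=np.asarray(subjects, dtype=object),
        gene_ids=sc.gene_ids,
        cell_type_ids=np.asarray(types, dtype=object),
    )


def build_reference(
    sub: SubjectAbundance,
    var_estimator: str = "sample",
    weight_by_cells: bool = False,
) -> ReferenceBasis:
    """Pool per-subject abundances into a cross-subject reference.

    Parameters
    ----------
    sub
        Output of :func:`compute_subject_abundance`.
    var_estimator
        ``"sample"`` (n-1 denominator, default) or ``"population"``
        (n denominator). A cell type observed in a single subject gets
        variance zero and is flagged with a warning either way.
    weight_by_cells
        If True, subject averages of theta are weighted by the number of
        cells m_j^k instead of treating subjects as exchangeable.
    """
    if var_estimator not in ("sample", "population"):
        raise ValueError("var_estimator must be 'sample' or 'population'")

    present = sub.present
    n_g = sub.theta.shape[1]
    n_k = sub.theta.shape[2]
    theta_mean = np.zeros((n_g, n_k))
    theta_var = np.zeros((n_g, n_k))
    lib_size = np.zeros(n_k)
    n_per_type = present.sum(axis=0).astype(int)
    subjects_per_type: dict[str, list[str]] = {}

    for k, ct in enumerate(sub.cell_type_ids):
        js = np.flatnonzero(present[:, k])
        if len(js) == 0:
            raise ValueError(f"cell type {ct!r} has no contributing subjects")
        subjects_per_type[str(ct)] = [str(sub.subject_ids[j]) for j in js]
        block = sub.theta[js, :, k]  # n_j x genes
        if weight_by_cells:
            w = sub.cell_counts[js, k].astype(float)
            w = w / w.sum()
            theta_mean[:, k] = w @ block
        else:
            theta_mean[:, k] = block.mean(axis=0)
        if len(js) == 1:
            warnings.warn(
                f"cell type {ct!r} has a single subject; its cross-subject "
                "variance is set to 0",
                stacklevel=2,
            )
            theta_var[:, k] = 0.0
        else:
            ddof = 1 if var_estimator == "sample" else 0
            theta_var[:, k] = block.var(axis=0, ddof=ddof)
        lib_size[k] = np.nanmean(sub.subject_lib_size[js, k])

    logger.info(
        "reference built: %d genes, %d cell types, variance estimator=%s",
        n_g, n_k, var_estimator,
    )
    return ReferenceBasis(
        theta_mean=theta_mean,
        theta_var=theta_var,
        lib_size=lib_size,
        n_subjects_per_type=n_per_type,
        gene_ids=sub.gene_ids,
        cell_type_ids=np.asarray(sub.cell_type_ids, dtype=object),
        var_estimator=var_estimator,
        subjects_per_type=subjects_per_type,
    )


def relative_abundance_bulk(bulk_counts: np.ndarray) -> np.ndarray:
    """Normalize a non-negative bulk count vector to relative abundance.

    Zeros are preserved; an all-zero (or negative-containing) vector is
    rejected.
    """
    x = np.asarray(bulk_counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("bulk counts must be a 1-D vector over genes")
    if np.any(x < 0):
        raise ValueError("bulk counts must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("bulk count vector has no positive entries")
    return x / total
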