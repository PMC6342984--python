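"""Iteratively re-weighted non-negative least squares deconvolution.

One bulk sample's relative abundance y over G genes is modeled as

    y_g = C * ( sum_k p_k S_k theta_g^k + eps_g ),     eps_g ~ N(0, delta_g^2)

with p the cell-type proportions (p >= 0, sum p = 1), S_k the cell-size
factor and C an unidentified normalizing constant. The regression is run
on the theta columns, so the raw non-negative coefficients are
q_k ∝ C p_k S_k (the RNA fraction of each cell type up to scale);
proportions follow as p = normalize(q / S).

Marginalizing over the cross-subject variability of theta gives the
per-gene variance

    Var[y_g | p] = C^2 delta_g^2 + sum_k (C p_k S_k)^2 sigma_gk^2
                 = 1 / w_g,

which is estimated iteratively: the residual r_g proxies C*delta_g and the
current coefficients q enter the variance term on the regression's own
scale, so C cancels. Genes with low cross-subject variance are up-weighted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .containers import BulkSample, DeconvolutionResult, ReferenceBasis, WnnlsConfig
from .reference import relative_abundance_bulk

logger = logging.getLogger(__name__)

__all__ = ["nnls", "deconvolve_sample", "deconvolve_all", "DeconvolutionTable"]

# weight denominators are floored here; when residuals, variances and nu are
# all zero every gene hits the floor, so weighting degenerates to unweighted
_DENOM_FLOOR = 1e-12


def nnls(design: np.ndarray, y: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Solve argmin_{b >= 0} sum_g w_g (y_g - (design @ b)_g)^2.

    Thin wrapper over the Lawson–Hanson solver; weights are applied by
    row-scaling with sqrt(w). Deterministic for fixed input.
    """
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    if design.ndim != 2 or y.ndim != 1 or design.shape[0] != len(y):
        raise ValueError("design (G x K) and y (G) must be conformable")
    if not np.any(design):
        raise ValueError("design matrix is all zero")
    if w is not None:
        w = np.asarray(w, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        sw = np.sqrt(w)
        design = design * sw[:, None]
        y = y * sw
    b, _ = scipy.optimize.nnls(design, y)
    return b


def _align(bulk: BulkSample, ref: ReferenceBasis):
    """Intersect gene identifiers, keeping the reference's ordering."""
    bulk_index = pd.Index(bulk.gene_ids)
    in_bulk = bulk_index.get_indexer(ref.gene_ids)
    keep = in_bulk >= 0
    if not keep.any():
        raise ValueError(
            f"sample {bulk.sample_id!r}: no shared genes between bulk and reference"
        )
    genes = ref.gene_ids[keep]
    y = bulk.y[in_bulk[keep]]
    theta = ref.theta_mean[keep]
    var = ref.theta_var[keep]
    return genes, y, theta, var


def _weighted_r2(y: np.ndarray, resid: np.ndarray, w: np.ndarray) -> float:
    denom = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    if denom <= 0:
        return float("nan")
    return 1.0 - float(np.sum(w * resid**2)) / denom


def deconvolve_sample(
    bulk: BulkSample,
    ref: ReferenceBasis,
    cfg: WnnlsConfig | None = None,
) -> DeconvolutionResult:
    """Estimate cell-type proportions for one bulk sample.

    Genes are matched by identifier intersection (reference order); the
    relative abundances are internally rescaled to mean one over the
    shared genes so the damping term nu and the variance term live on a
    common scale. Iteration stops when the L1 change of p drops below
    cfg.tol; non-convergence yields a warning and ``converged=False``,
    never an exception.
    """
    cfg = cfg or WnnlsConfig()
    genes, y_raw, theta, var = _align(bulk, ref)
    G, K = theta.shape
    S = np.asarray(ref.lib_size, dtype=float)
    flags: list[str] = []

    total = y_raw.sum()
    if total <= 0:
        return _degenerate_result(genes, ref, cfg, flags + ["all-zero bulk over shared genes"], bulk.sample_id)
    # mean-1 scale for the regression; p is invariant to this scaling
    y = y_raw / total * G
    X = theta * G
    var_s = var * G * G

    if cfg.center:
        # experimental: remove a multiplicative gene-specific offset shared
        # across cell types (log-scale additive protocol bias)
        offset = np.exp(np.mean(np.log1p(X), axis=1)) - 1.0
        offset = np.maximum(offset, 1e-12)
        y = y / offset
        X = X / offset[:, None]
        var_s = var_s / offset[:, None] ** 2
        flags.append("gene-wise centering applied")

    if cfg.fixed_weights is not None:
        w = _resolve_fixed_weights(cfg.fixed_weights, genes)
        q = nnls(X, y, w)
        return _finalize(q, X, y, w, S, genes, ref, 1, True, flags, bulk.sample_id)

    if cfg.init == "uniform":
        # start from uniform proportions: q ∝ p*S with best-fitting scale
        u = S / S.sum()
        d = X @ u
        c = max(float(d @ y) / float(d @ d), 0.0)
        q = c * u
    else:
        q = nnls(X, y)

    if q.sum() <= 0:
        return _degenerate_result(genes, ref, cfg, flags + ["all-zero NNLS solution"], bulk.sample_id)

    p = _q_to_p(q, S)
    w = np.ones(G)
    n_iter = 0
    converged = False
    for n_iter in range(1, cfg.max_iter + 1):
        resid = y - X @ q
        denom = cfg.nu + resid**2 + var_s @ (q**2)
        w = 1.0 / np.maximum(denom, _DENOM_FLOOR)
        q_new = nnls(X, y, w)
        if q_new.sum() <= 0:
            flags.append(f"all-zero weighted solution at iteration {n_iter}")
            break
        p_new = _q_to_p(q_new, S)
        delta = float(np.abs(p_new - p).sum())
        q, p = q_new, p_new
        if delta <= cfg.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"sample {bulk.sample_id!r}: W-NNLS did not converge in "
            f"{cfg.max_iter} iterations",
            stacklevel=2,
        )
    return _finalize(q, X, y, w, S, genes, ref, n_iter, converged, flags, bulk.sample_id)


def _q_to_p(q: np.ndarray, S: np.ndarray) -> np.ndarray:
    p = q / S
    return p / p.sum()


def _resolve_fixed_weights(fw, genes: np.ndarray) -> np.ndarray:
    if isinstance(fw, pd.Series):
        missing = [g for g in genes if g not in fw.index]
        if missing:
            raise ValueError(f"fixed_weights missing genes: {missing[:5]}")
        return fw.reindex(genes).to_numpy(dtype=float)
    fw = np.asarray(fw, dtype=float)
    if len(fw) != len(genes):
        raise ValueError(
            f"fixed_weights length {len(fw)} != {len(genes)} shared genes"
        )
    return fw


def _finalize(
    q: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    S: np.ndarray,
    genes: np.ndarray,
    ref: ReferenceBasis,
    n_iter: int,
    converged: bool,
    flags: list[str],
    sample_id: str,
) -> DeconvolutionResult:
    resid = y - X @ q
    p = _q_to_p(q, S)
    q_frac = q / q.sum()
    types = pd.Index(ref.cell_type_ids, name="cell_type")
    return DeconvolutionResult(
        p=pd.Series(p, index=types, name=sample_id),
        q=pd.Series(q_frac, index=types, name=sample_id),
        weights=pd.Series(w, index=pd.Index(genes, name="gene"), name="weight"),
        residuals=pd.Series(
            np.sqrt(w) * resid, index=pd.Index(genes, name="gene"), name="weighted_residual"
        ),
        n_iter=n_iter,
        converged=converged,
        var_explained=_weighted_r2(y, resid, w),
        sample_id=sample_id,
        flags=flags,
    )


def _degenerate_result(
    genes: np.ndarray,
    ref: ReferenceBasis,
    cfg: WnnlsConfig,
    flags: list[str],
    sample_id: str,
) -> DeconvolutionResult:
    K = ref.n_types
    warnings.warn(
        f"sample {sample_id!r}: degenerate fit ({flags[-1]}); returning uniform proportions",
        stacklevel=3,
    )
    types = pd.Index(ref.cell_type_ids, name="cell_type")
    gidx = pd.Index(genes, name="gene")
    return DeconvolutionResult(
        p=pd.Series(np.full(K, 1.0 / K), index=types, name=sample_id),
        q=pd.Series(ref.lib_size / ref.lib_size.sum(), index=types, name=sample_id),
        weights=pd.Series(np.ones(len(genes)), index=gidx, name="weight"),
        residuals=pd.Series(np.zeros(len(genes)), index=gidx, name="weighted_residual"),
        n_iter=0,
        converged=False,
        var_explained=float("nan"),
        sample_id=sample_id,
        flags=flags,
    )


@dataclass
class DeconvolutionTable:
    """Per-sample results keyed by sample id, with failures kept separate."""

    results: dict[str, DeconvolutionResult] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def proportions(self) -> pd.DataFrame:
        """Samples x cell types matrix of estimated proportions."""
        return pd.DataFrame({sid: r.p for sid, r in self.results.items()}).T.rename_axis("sample")

    @property
    def rna_fractions(self) -> pd.DataFrame:
        return pd.DataFrame({sid: r.q for sid, r in self.results.items()}).T.rename_axis("sample")

    def diagnostics(self) -> pd.DataFrame:
        rows = {
            sid: {
                "n_iter": r.n_iter,
                "converged": r.converged,
                "var_explained": r.var_explained,
                "flags": ";".join(r.flags),
            }
            for sid, r in self.results.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample")


def deconvolve_all(
    bulk_counts: pd.DataFrame,
    ref: ReferenceBasis,
    cfg: WnnlsConfig | None = None,
    units: str = "counts",
) -> DeconvolutionTable:
    """Deconvolve every column of a genes x samples count matrix.

    Samples are independent; per-sample errors are recorded as failure
    entries and processing continues. TPM input is rejected outright:
    without per-cell-type library sizes the cell-size factors cannot be
    recovered from TPM, so proportions are unidentifiable.
    """
    if units.lower() == "tpm":
        raise ValueError(
            "cell type proportions cannot be estimated from TPM input; "
            "provide read or UMI counts"
        )
    if units.lower() not in ("counts", "count", "reads", "umi"):
        raise ValueError(f"unknown units {units!r}; expected counts")
    table = DeconvolutionTable()
    for sid in bulk_counts.columns:
        try:
            y = relative_abundance_bulk(bulk_counts[sid].to_numpy(dtype=float))
            sample = BulkSample(
                y=y, gene_ids=bulk_counts.index.to_numpy(dtype=object), sample_id=str(sid)
            )
            table.results[str(sid)] = deconvolve_sample(sample, ref, cfg)
        except Exception as exc:  # per-sample isolation is the contract
            logger.warning("sample %r failed: %s", sid, exc)
            table.failures[str(sid)] = str(exc)
    return table
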