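"""Synthetic multi-subject single-cell and bulk data generators.

The generator mirrors the assumptions the estimator rests on: subjects
are exchangeable draws around a population signature (cross-subject
variability of theta, assumption A1), cell types differ in cell size
(A2), capture efficiency can vary by type (breaking A3' when non-uniform),
and single-cell counts suffer dropout. Per-subject signatures are built
by perturbing a base composition on the log scale with standard
deviation ``cross_subject_sd`` and renormalizing; for small per-gene
mass (many genes) this gives, to excellent approximation,

    E[theta_jg^k] = theta0_gk,
    Var[theta_jg^k] = theta0_gk^2 (exp(sd^2) - 1).

A Dirichlet alternative with exactly matched mean is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ReferenceBasis, ScDataset
from .reference import build_reference, compute_subject_abundance

__all__ = ["SimParams", "SimTruth", "simulate_sc", "simulate_bulk", "scenario", "SCENARIOS"]


@dataclass
class SimParams:
    """Knobs of the generative model.

    cross_subject_sd is the log-scale sd of per-subject signature
    perturbations (scalar or genes x types array); cell_size is the
    per-type relative cell size S^k; efficiency is the per-type capture
    efficiency gamma^k (uniform means proportions are identifiable);
    depth is the mean total count per cell at cell size and efficiency 1.
    """

    n_genes: int = 1000
    n_types: int = 6
    n_subjects: int = 6
    cells_per_type: int | Sequence[int] = 50
    base_theta: np.ndarray | None = None
    theta_conc: float = 0.3
    cross_subject_sd: float | np.ndarray = 0.25
    cell_size: Sequence[float] | None = None
    efficiency: Sequence[float] | None = None
    depth: float = 2000.0
    dropout_rate: float = 0.0
    dropout_model: str = "uniform"  # or "logistic" (expression-dependent)
    subject_law: str = "lognormal"  # or "dirichlet"
    gamma_disp: float | None = None  # per-cell NB-style overdispersion
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_types", "n_subjects"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if np.any(np.asarray(self.cells_per_type) < 1):
            raise ValueError("cells_per_type must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if np.any(np.asarray(self.cross_subject_sd) < 0):
            raise ValueError("cross_subject_sd must be non-negative")
        if self.subject_law not in ("lognormal", "dirichlet"):
            raise ValueError("subject_law must be 'lognormal' or 'dirichlet'")
        if self.dropout_model not in ("uniform", "logistic"):
            raise ValueError("dropout_model must be 'uniform' or 'logistic'")

    def resolved_cell_sizes(self) -> np.ndarray:
        if self.cell_size is not None:
            s = np.asarray(self.cell_size, dtype=float)
            if len(s) != self.n_types or np.any(s <= 0):
                raise ValueError("cell_size must be positive, one per type")
            return s
        # default: ~4x geometric spread across types, a realistic range for
        # solid-tissue cell types
        return np.geomspace(0.5, 2.0, self.n_types)

    def resolved_efficiency(self) -> np.ndarray:
        if self.efficiency is None:
            return np.ones(self.n_types)
        g = np.asarray(self.efficiency, dtype=float)
        if len(g) != self.n_types or np.any(g <= 0):
            raise ValueError("efficiency must be positive, one per type")
        return g

    def resolved_cells_per_type(self) -> np.ndarray:
        c = np.asarray(self.cells_per_type)
        if c.ndim == 0:
            c = np.full(self.n_types, int(c))
        if len(c) != self.n_types:
            raise ValueError("cells_per_type must be scalar or one per type")
        return c.astype(int)


@dataclass
class SimTruth:
    """Ground truth backing a simulated dataset."""

    theta_true: np.ndarray  # subjects x genes x types
    p_true: np.ndarray  # subjects x types (cell-count fractions)
    params: SimParams
    gene_ids: np.ndarray = field(default=None)
    cell_type_ids: np.ndarray = field(default=None)
    subject_ids: np.ndarray = field(default=None)


def _draw_base_theta(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    if params.base_theta is not None:
        bt = np.asarray(params.base_theta, dtype=float)
        if bt.shape != (params.n_genes, params.n_types):
            raise ValueError("base_theta must be genes x types")
        if np.any(bt < 0):
            raise ValueError("base_theta must be non-negative")
        return bt / bt.sum(axis=0, keepdims=True)
    return rng.dirichlet(
        np.full(params.n_genes, params.theta_conc), size=params.n_types
    ).T


def _draw_subject_theta(
    base: np.ndarray, params: SimParams, rng: np.random.Generator, n_subjects: int
) -> np.ndarray:
    G, K = base.shape
    sd = np.broadcast_to(np.asarray(params.cross_subject_sd, dtype=float), (G, K))
    theta = np.empty((n_subjects, G, K))
    for j in range(n_subjects):
        if params.subject_law == "lognormal":
            pert = base * np.exp(rng.normal(0.0, sd, size=(G, K)) - sd**2 / 2.0)
        else:
            # Dirichlet with mean exactly base; concentration tuned per column
            # so the typical relative spread tracks cross_subject_sd
            pert = np.empty_like(base)
            for k in range(K):
                s = float(np.mean(sd[:, k]))
                if s == 0:
                    pert[:, k] = base[:, k]
                    continue
                conc = max((np.exp(s**2) - 1) ** -1, 1e-3)
                alpha = np.maximum(base[:, k] * conc, 1e-12)
                pert[:, k] = rng.dirichlet(alpha)
        total = pert.sum(axis=0, keepdims=True)
        total[total == 0] = 1.0
        theta[j] = pert / total
    return theta


def simulate_sc(params: SimParams) -> tuple[ScDataset, SimTruth]:
    """Generate a labeled multi-subject single-cell dataset plus truth.

    Per subject and type the signature is a perturbed copy of the base
    composition; each cell's total count is Poisson around
    depth * cell_size * efficiency and its gene counts are multinomial in
    the subject's signature. Dropout zeroes entries independently.
    Bit-reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    base = _draw_base_theta(params, rng)
    theta = _draw_subject_theta(base, params, rng, params.n_subjects)
    S = params.resolved_cell_sizes()
    gamma = params.resolved_efficiency()
    cells_per_type = params.resolved_cells_per_type()

    gene_ids = np.array([f"g{i:05d}" for i in range(params.n_genes)], dtype=object)
    type_ids = np.array([f"type_{k}" for k in range(params.n_types)], dtype=object)
    subject_ids = np.array([f"subj_{j:02d}" for j in range(params.n_subjects)], dtype=object)

    blocks, subj_col, type_col = [], [], []
    for j in range(params.n_subjects):
        for k in range(params.n_types):
            m = cells_per_type[k]
            mean_total = params.depth * S[k] * gamma[k]
            totals = rng.poisson(mean_total, size=m)
            totals = np.maximum(totals, 1)
            probs = theta[j, :, k]
            if params.gamma_disp:
                block = np.empty((params.n_genes, m), dtype=np.int64)
                for c in range(m):
                    pc = probs * rng.gamma(params.gamma_disp, 1.0 / params.gamma_disp, params.n_genes)
                    block[:, c] = rng.multinomial(totals[c], pc / pc.sum())
            else:
                block = rng.multinomial(totals, probs).T
            blocks.append(block)
            subj_col.extend([subject_ids[j]] * m)
            type_col.extend([type_ids[k]] * m)
    counts = np.concatenate(blocks, axis=1)

    if params.dropout_rate > 0:
        if params.dropout_model == "uniform":
            keep = rng.random(counts.shape) >= params.dropout_rate
        else:
            # expression-dependent: low-count entries drop more often;
            # calibrated so the marginal rate is near dropout_rate
            x = np.log1p(counts)
            med = np.median(x[counts > 0]) if np.any(counts > 0) else 1.0
            pdrop = 1.0 / (1.0 + np.exp((x - med)))
            pdrop *= params.dropout_rate / max(pdrop.mean(), 1e-12)
            keep = rng.random(counts.shape) >= np.clip(pdrop, 0, 1)
        counts = counts * keep

    m_jk = np.tile(cells_per_type, (params.n_subjects, 1)).astype(float)
    p_true = m_jk / m_jk.sum(axis=1, keepdims=True)

    sc = ScDataset(
        counts=counts,
        gene_ids=gene_ids,
        cell_subject=np.asarray(subj_col, dtype=object),
        cell_type=np.asarray(type_col, dtype=object),
    )
    truth = SimTruth(
        theta_true=theta,
        p_true=p_true,
        params=params,
        gene_ids=gene_ids,
        cell_type_ids=type_ids,
        subject_ids=subject_ids,
    )
    return sc, truth


def simulate_bulk(
    truth: SimTruth,
    p: np.ndarray,
    depth: int = 100_000,
    noise_sd: float = 0.0,
    seed: int | None = None,
    subject_indices: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Generate bulk count columns from true signatures and proportions.

    Sample i mixes subject ``subject_indices[i]``'s signatures:
    expected relative abundance ∝ sum_k p_ik S_k theta_jg^k, multiplied
    by per-gene log-normal noise of sd ``noise_sd``, then sampled
    multinomially to ``depth`` total counts.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    K = truth.theta_true.shape[2]
    if p.shape[1] != K:
        raise ValueError(f"p must have {K} columns")
    if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("each row of p must lie on the simplex")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n_samples = p.shape[0]
    n_subjects = truth.theta_true.shape[0]
    if subject_indices is None:
        subject_indices = [i % n_subjects for i in range(n_samples)]
    rng = np.random.default_rng(truth.params.seed + 1 if seed is None else seed)
    S = truth.params.resolved_cell_sizes()

    cols = {}
    for i in range(n_samples):
        theta_j = truth.theta_true[subject_indices[i]]  # genes x types
        x = theta_j @ (p[i] * S)
        if noise_sd > 0:
            x = x * np.exp(rng.normal(0.0, noise_sd, size=len(x)))
        x = x / x.sum()
        cols[f"bulk_{i:02d}"] = rng.multinomial(depth, x)
    return pd.DataFrame(cols, index=pd.Index(truth.gene_ids, name="gene"))


# --- named stress scenarios ----------------------------------------------

SCENARIOS = (
    "baseline",
    "heteroscedastic",
    "collinear_pair",
    "missing_celltype",
    "mismatched_composition",
    "biased_theta",
    "dropout",
)

_N_BULK = 10
_BULK_DEPTH = 100_000
_BULK_NOISE_SD = 0.10


def _draw_mixtures(rng: np.random.Generator, n: int, K: int, alpha: float = 2.0) -> np.ndarray:
    return rng.dirichlet(np.full(K, alpha), size=n)


def scenario(name: str, seed: int = 0) -> dict:
    """Build one named stress fixture: single-cell data, reference, bulk
    counts and truth, configured to exhibit the named stressor.

    All scenarios share the baseline geometry (1000 genes, 6 types,
    6 reference subjects, 10 bulk samples from fresh subjects of the same
    population, bulk depth 1e5, multiplicative noise sd 0.1).
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; options: {', '.join(SCENARIOS)}")
    rng = np.random.default_rng(seed)
    params = SimParams(seed=seed)
    extras: dict = {}

    if name == "heteroscedastic":
        sd = np.full((params.n_genes, params.n_types), 0.05)
        noisy = rng.random(params.n_genes) < 0.25
        sd[noisy, :] = 1.2
        params = replace(params, cross_subject_sd=sd)
        extras["noisy_genes"] = noisy
    elif name == "collinear_pair":
        # two pairs of closely related cell types; in the reference they are
        # additionally observed through a per-type gene-wise capture bias
        # (consistent across subjects, so the cross-subject variance does not
        # flag it) — the condition the tree-guided recursion is built for
        base = _draw_base_theta(params, rng)
        m1 = rng.dirichlet(np.full(params.n_genes, params.theta_conc))
        m2 = rng.dirichlet(np.full(params.n_genes, params.theta_conc))
        base[:, 1] = 0.9 * base[:, 0] + 0.1 * m1
        base[:, 3] = 0.9 * base[:, 2] + 0.1 * m2
        base = base / base.sum(axis=0, keepdims=True)
        corr = min(
            float(np.corrcoef(base[:, 0], base[:, 1])[0, 1]),
            float(np.corrcoef(base[:, 2], base[:, 3])[0, 1]),
        )
        assert corr >= 0.95, f"planted pair correlation {corr:.3f} < 0.95"
        params = replace(params, base_theta=base)
        extras["planted_pairs"] = (("type_0", "type_1"), ("type_2", "type_3"))
        extras["pair_correlation"] = corr
        extras["capture_bias_sd"] = 0.3
        extras["grouping"] = {
            "pair_a": ["type_0", "type_1"],
            "pair_b": ["type_2", "type_3"],
            **{f"s{k}": [f"type_{k}"] for k in range(4, params.n_types)},
        }
    elif name == "mismatched_composition":
        params = replace(params, cells_per_type=[150, 90, 50, 25, 12, 6])
    elif name == "dropout":
        params = replace(params, dropout_rate=0.30)

    sc, truth = simulate_sc(params)

    # fresh subjects from the same population provide the bulk signatures
    bulk_params = replace(params, n_subjects=_N_BULK, cells_per_type=1, dropout_rate=0.0,
                          seed=seed + 10_000)
    if params.base_theta is None:
        # re-anchor on the same population base signature
        bulk_params = replace(bulk_params, base_theta=_draw_base_theta(params, np.random.default_rng(seed)))
    _, bulk_truth = simulate_sc(bulk_params)

    p = _draw_mixtures(rng, _N_BULK, params.n_types)
    if name == "missing_celltype":
        # the dropped type stays non-dominant in the bulk truth
        p = _draw_mixtures(rng, _N_BULK, params.n_types - 1) * 0.95
        p = np.column_stack([p, np.full(_N_BULK, 0.05)])

    bulk = simulate_bulk(truth=bulk_truth, p=p, depth=_BULK_DEPTH,
                         noise_sd=_BULK_NOISE_SD, seed=seed + 20_000)

    ref_sc = sc
    if name == "biased_theta":
        # reference subjects observed through a gene-wise multiplicative bias
        bias = np.exp(np.random.default_rng(seed + 30_000).normal(0.0, 0.3, params.n_genes))
        biased_counts = np.rint(sc.counts * bias[:, None]).astype(np.int64)
        ref_sc = ScDataset(biased_counts, sc.gene_ids, sc.cell_subject, sc.cell_type)
        extras["theta_bias_sd"] = 0.3
    elif name == "collinear_pair":
        # per-cell-type capture bias: same distortion for every subject, so
        # it evades the cross-subject-variance weighting
        brng = np.random.default_rng(seed + 30_000)
        bias = np.exp(brng.normal(0.0, extras["capture_bias_sd"], size=(params.n_genes, params.n_types)))
        biased = sc.counts.astype(float).copy()
        for k in range(params.n_types):
            mask = sc.cell_type == f"type_{k}"
            biased[:, mask] = biased[:, mask] * bias[:, [k]]
        ref_sc = ScDataset(np.rint(biased).astype(np.int64), sc.gene_ids, sc.cell_subject, sc.cell_type)

    ref = build_reference(compute_subject_abundance(ref_sc))
    if name == "missing_celltype":
        kept = [f"type_{k}" for k in range(params.n_types - 1)]
        ref = ref.subset_types(kept)
        extras["missing_type"] = f"type_{params.n_types - 1}"

    true_p = pd.DataFrame(
        p,
        index=pd.Index([f"bulk_{i:02d}" for i in range(_N_BULK)], name="sample"),
        columns=pd.Index([f"type_{k}" for k in range(params.n_types)], name="cell_type"),
    )
    return {
        "name": name,
        "params": params,
        "sc": sc,
        "truth": truth,
        "reference": ref,
        "bulk_counts": bulk,
        "true_p": true_p,
        **extras,
    }
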