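"""Tree-guided recursive deconvolution for closely related cell types.

Closely related cell types have correlated expression signatures, and the
resulting collinearity destabilizes a flat fit. The remedy implemented
here proceeds in stages: cluster the cell types by signature similarity,
estimate cluster-level proportions with genes that are consistent within
each cluster, then resolve each cluster's member types with genes
re-selected for that cluster, rescaling so the within-cluster proportions
sum exactly to the cluster's estimate. Nested groupings recurse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .containers import BulkSample, DeconvolutionResult, ReferenceBasis, WnnlsConfig
from .wnnls import deconvolve_sample

logger = logging.getLogger(__name__)

__all__ = [
    "CellTypeGrouping",
    "TreeResult",
    "cluster_cell_types",
    "select_cluster_consistent_genes",
    "recursive_deconvolve",
]

_EPS = 1e-12


@dataclass
class CellTypeGrouping:
    """A partition of cell types into named disjoint clusters.

    ``clusters`` maps cluster name -> list of member cell-type IDs.
    ``nesting`` optionally maps a cluster name to a sub-grouping applied
    recursively inside that cluster. ``per_cluster_genes`` optionally
    pins an explicit gene list per cluster (overriding automatic
    selection at that cluster's stage-2 fit).
    """

    clusters: dict[str, list[str]]
    nesting: dict[str, "CellTypeGrouping"] = field(default_factory=dict)
    per_cluster_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, members in self.clusters.items():
            members = [str(m).strip() for m in members]
            if not members:
                raise ValueError(f"cluster {name!r} is empty")
            clean[str(name)] = members
        self.clusters = clean
        all_members = [m for ms in self.clusters.values() for m in ms]
        if len(all_members) != len(set(all_members)):
            dup = sorted({m for m in all_members if all_members.count(m) > 1})
            raise ValueError(f"cell types assigned to multiple clusters: {dup}")
        for name in self.nesting:
            if name not in self.clusters:
                raise ValueError(f"nested grouping for unknown cluster {name!r}")

    @property
    def cell_types(self) -> list[str]:
        return [m for ms in self.clusters.values() for m in ms]

    def validate_against(self, ref: ReferenceBasis) -> None:
        known = set(ref.cell_type_ids)
        mine = set(self.cell_types)
        unknown = sorted(mine - known)
        if unknown:
            raise ValueError(
                f"grouping names unknown cell types {unknown}; known types: "
                f"{sorted(known)}"
            )
        missing = sorted(known - mine)
        if missing:
            raise ValueError(
                f"grouping does not cover cell types {missing}; clusters must "
                "partition all reference cell types"
            )
        for name, nested in self.nesting.items():
            if set(nested.cell_types) != set(self.clusters[name]):
                raise ValueError(
                    f"nested grouping of cluster {name!r} must partition exactly "
                    "that cluster's cell types"
                )


@dataclass
class TreeResult:
    """Agglomerative merge structure over cell types."""

    linkage: np.ndarray  # scipy linkage matrix, (K-1) x 4
    labels: list[str]
    distance_metric: str
    linkage_method: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["node_a", "node_b", "height", "n_leaves"]
        )

    def cut(self, n_clusters: int) -> CellTypeGrouping:
        """Helper: cut the dendrogram into a flat grouping (never applied
        automatically — groupings are a user decision)."""
        assignments = sch.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        clusters: dict[str, list[str]] = {}
        for lbl, a in zip(self.labels, assignments):
            clusters.setdefault(f"cluster_{a}", []).append(lbl)
        return CellTypeGrouping(clusters=dict(sorted(clusters.items())))

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = rec(node.get_left()), rec(node.get_right())
            return f"({left}:{node.dist:.6g},{right}:{node.dist:.6g})"

        return rec(tree) + ";"


def cluster_cell_types(
    ref: ReferenceBasis,
    metric: str = "correlation",
    linkage: str = "complete",
) -> TreeResult:
    """Hierarchically cluster cell types by their mean signature columns.

    ``correlation`` uses 1 - Pearson correlation between theta_mean
    columns; ``euclidean_log`` uses Euclidean distance between
    log1p-transformed columns. Deterministic for fixed inputs.
    """
    if ref.n_types < 2:
        raise ValueError("need at least 2 cell types to build a tree")
    if metric not in ("correlation", "euclidean_log"):
        raise ValueError("metric must be 'correlation' or 'euclidean_log'")
    if linkage not in ("complete", "average"):
        raise ValueError("linkage must be 'complete' or 'average'")
    cols = ref.theta_mean.T  # types x genes
    if metric == "correlation":
        dist = ssd.pdist(cols, metric="correlation")
    else:
        dist = ssd.pdist(np.log1p(cols), metric="euclidean")
    dist = np.clip(dist, 0.0, None)
    Z = sch.linkage(dist, method=linkage)
    return TreeResult(
        linkage=Z,
        labels=[str(t) for t in ref.cell_type_ids],
        distance_metric=metric,
        linkage_method=linkage,
    )


def _gene_scores(ref: ReferenceBasis, grouping: CellTypeGrouping) -> pd.Series:
    """Per-gene cluster-inconsistency score: the worst (largest) cluster's
    within-cluster variance of theta on the relative scale (variance
    divided by squared mean abundance, i.e. a squared coefficient of
    variation). The relative scale keeps the score comparable across the
    orders-of-magnitude spread of gene expression; normalizing by the
    mean itself would systematically favor weakly expressed genes.
    Singleton clusters contribute their cross-subject variance
    sigma_gk^2 instead — the only within-type variability available.
    """
    type_pos = {str(t): i for i, t in enumerate(ref.cell_type_ids)}
    mean_ab = ref.theta_mean.mean(axis=1)
    score = np.zeros(ref.n_genes)
    for members in grouping.clusters.values():
        idx = [type_pos[m] for m in members]
        if len(idx) > 1:
            v = ref.theta_mean[:, idx].var(axis=1, ddof=0)
        else:
            v = ref.theta_var[:, idx[0]]
        score = np.maximum(score, v / (mean_ab**2 + _EPS))
    return pd.Series(score, index=pd.Index(ref.gene_ids, name="gene"))


def select_cluster_consistent_genes(
    ref: ReferenceBasis,
    grouping: CellTypeGrouping,
    keep_fraction: float = 0.5,
) -> list[str]:
    """Pick the genes most consistent within every cluster.

    Genes are ranked by the worst-cluster within-cluster variance of
    theta_mean (normalized by mean abundance); the ``keep_fraction`` with
    the smallest scores survive. Genes expressed in no cell type are
    dropped before ranking. Ties resolve by reference gene order, so the
    selection is deterministic.
    """
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must be in (0, 1]")
    grouping.validate_against(ref)
    scores = _gene_scores(ref, grouping)
    expressed = ref.theta_mean.sum(axis=1) > 0
    scores = scores[expressed]
    if scores.empty:
        raise ValueError("no expressed genes available for selection")
    n_keep = max(1, int(np.ceil(keep_fraction * len(scores))))
    order = np.argsort(scores.to_numpy(), kind="stable")
    return list(scores.index[order[:n_keep]])


def _singleton_grouping(types: Sequence[str]) -> CellTypeGrouping:
    return CellTypeGrouping(clusters={str(t): [str(t)] for t in types})


def _collapse_reference(ref: ReferenceBasis, grouping: CellTypeGrouping) -> ReferenceBasis:
    """One representative column per cluster: unweighted mean of the member
    theta columns and of the member size factors. Cross-subject variances
    average as well (a conservative pooled uncertainty for the cluster)."""
    type_pos = {str(t): i for i, t in enumerate(ref.cell_type_ids)}
    names = list(grouping.clusters)
    tm = np.column_stack(
        [ref.theta_mean[:, [type_pos[m] for m in grouping.clusters[c]]].mean(axis=1) for c in names]
    )
    tv = np.column_stack(
        [ref.theta_var[:, [type_pos[m] for m in grouping.clusters[c]]].mean(axis=1) for c in names]
    )
    S = np.array([ref.lib_size[[type_pos[m] for m in grouping.clusters[c]]].mean() for c in names])
    nsub = np.array(
        [ref.n_subjects_per_type[[type_pos[m] for m in grouping.clusters[c]]].min() for c in names]
    )
    return ReferenceBasis(
        theta_mean=tm,
        theta_var=tv,
        lib_size=S,
        n_subjects_per_type=nsub,
        gene_ids=ref.gene_ids,
        cell_type_ids=np.asarray(names, dtype=object),
        var_estimator=ref.var_estimator,
    )


def recursive_deconvolve(
    bulk: BulkSample,
    ref: ReferenceBasis,
    grouping: CellTypeGrouping,
    cfg: WnnlsConfig | None = None,
    keep_fraction: float = 0.5,
    stage2_genes: str = "complement",
) -> DeconvolutionResult:
    """Two-stage (recursively nested) constrained deconvolution.

    Stage 1 collapses each cluster to its mean signature and estimates
    cluster proportions pi_c on cluster-consistent genes. Stage 2
    resolves each non-singleton cluster with a joint fit over all cell
    types restricted to genes re-selected for low within-type
    (cross-subject) variance across that cluster's members; the member
    types' relative proportions are then rescaled to sum exactly to
    pi_c. The final vector satisfies p >= 0 and sum p = 1 by
    construction. A cluster whose within fit fails splits its mass
    uniformly and is flagged in the diagnostics.

    ``stage2_genes`` picks the stage-2 gene sets: ``"complement"``
    (default) runs each cluster's resolving fit on the expressed genes
    NOT selected at stage 1 — the genes that discriminate within
    clusters; ``"reselect"`` instead re-selects, per cluster, genes with
    low within-type (cross-subject) variance across that cluster's
    members.
    """
    cfg = cfg or WnnlsConfig()
    grouping.validate_against(ref)
    if stage2_genes not in ("complement", "reselect"):
        raise ValueError("stage2_genes must be 'complement' or 'reselect'")

    # stage 1: cluster-level fit on cluster-consistent genes
    stage1_genes = select_cluster_consistent_genes(ref, grouping, keep_fraction)
    collapsed = _collapse_reference(ref, grouping).subset_genes(stage1_genes)
    stage1 = deconvolve_sample(bulk, collapsed, cfg)
    pi = stage1.p  # sums to 1 over clusters
    flags = [f"stage1: {len(grouping.clusters)} clusters, {len(stage1_genes)} genes"]
    flags += [f"stage1:{f}" for f in stage1.flags]

    complement: list[str] | None = None
    if stage2_genes == "complement":
        expressed = set(ref.gene_ids[ref.theta_mean.sum(axis=1) > 0])
        chosen = set(stage1_genes)
        complement = [g for g in ref.gene_ids if g in expressed and g not in chosen]
        if not complement:  # keep_fraction = 1: no genes left over, reuse all
            complement = [g for g in ref.gene_ids if g in expressed]

    p_parts: list[pd.Series] = []
    n_iter = stage1.n_iter
    converged = stage1.converged
    for cname, members in grouping.clusters.items():
        if len(members) == 1:
            p_parts.append(pd.Series([pi[cname]], index=pd.Index(members, name="cell_type")))
            continue
        sub_ref = ref.subset_types(members)
        if cname in grouping.nesting:
            within = _recurse_within(
                bulk, ref, grouping.nesting[cname], cfg, keep_fraction, flags, cname, stage2_genes
            )
        else:
            within = _fit_within(
                bulk, sub_ref, ref, grouping, cname, cfg, keep_fraction, flags, complement
            )
        if within is None:
            flags.append(f"cluster {cname!r}: within-cluster fit failed; uniform split")
            within = pd.Series(
                np.full(len(members), 1.0 / len(members)),
                index=pd.Index(members, name="cell_type"),
            )
            converged = False
        p_parts.append(within * pi[cname])

    p = pd.concat(p_parts)
    p = p.reindex(ref.cell_type_ids)
    p.index.name = "cell_type"
    total = float(p.sum())
    if total > 0:
        p = p / total  # exact C2 despite float rounding of the rescale
    S = pd.Series(ref.lib_size, index=p.index)
    q = p * S
    q = q / q.sum()
    return DeconvolutionResult(
        p=p.rename(bulk.sample_id),
        q=q.rename(bulk.sample_id),
        weights=stage1.weights,
        residuals=stage1.residuals,
        n_iter=n_iter,
        converged=converged,
        var_explained=stage1.var_explained,
        sample_id=bulk.sample_id,
        flags=flags,
    )


def _fit_within(
    bulk: BulkSample,
    sub_ref: ReferenceBasis,
    full_ref: ReferenceBasis,
    grouping: CellTypeGrouping,
    cname: str,
    cfg: WnnlsConfig,
    keep_fraction: float,
    flags: list[str],
    complement_genes: list[str] | None,
) -> pd.Series | None:
    """Resolve one cluster's member types; returns within-cluster
    proportions summing to one, or None on failure.

    The stage-2 regression keeps ALL cell types in the design (the other
    types' contributions to the bulk must be absorbed somewhere) but runs
    on the stage-2 gene set; only the member types' relative proportions
    are read off and rescaled to the cluster's stage-1 mass.
    """
    members = list(sub_ref.cell_type_ids)
    try:
        if cname in grouping.per_cluster_genes:
            genes = [g for g in grouping.per_cluster_genes[cname] if g in set(full_ref.gene_ids)]
        elif complement_genes is not None:
            genes = complement_genes
        else:
            genes = select_cluster_consistent_genes(
                sub_ref, _singleton_grouping(members), keep_fraction
            )
        fit = deconvolve_sample(bulk, full_ref.subset_genes(genes), cfg)
        flags.append(f"cluster {cname!r}: {len(genes)} genes, {fit.n_iter} iterations")
        within = fit.p.loc[members]
        if not np.isfinite(within.to_numpy()).all() or within.sum() <= 0:
            return None
        return within / within.sum()
    except Exception as exc:
        logger.warning("cluster %r within-fit failed: %s", cname, exc)
        return None


def _recurse_within(
    bulk: BulkSample,
    full_ref: ReferenceBasis,
    nested: CellTypeGrouping,
    cfg: WnnlsConfig,
    keep_fraction: float,
    flags: list[str],
    cname: str,
    stage2_genes: str,
) -> pd.Series | None:
    """Apply a nested grouping inside one cluster.

    The nested clusters are expanded to a full-reference grouping (all
    other cell types ride along as singletons, so no contribution is
    orphaned) and only the member types' relative proportions are kept.
    """
    members = set(nested.cell_types)
    try:
        expanded = CellTypeGrouping(
            clusters={
                **{f"__nested_{n}": ms for n, ms in nested.clusters.items()},
                **{f"__rest_{t}": [str(t)] for t in full_ref.cell_type_ids if str(t) not in members},
            },
            nesting={f"__nested_{n}": sub for n, sub in nested.nesting.items()},
            per_cluster_genes={f"__nested_{n}": g for n, g in nested.per_cluster_genes.items()},
        )
        res = recursive_deconvolve(bulk, full_ref, expanded, cfg, keep_fraction, stage2_genes)
        flags.append(f"cluster {cname!r}: nested recursion over {len(members)} types")
        within = res.p.loc[sorted(members)]
        if within.sum() <= 0:
            return None
        return within / within.sum()
    except Exception as exc:
        logger.warning("nested recursion in cluster %r failed: %s", cname, exc)
        return None
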