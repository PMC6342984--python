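"""On-disk formats: expression matrices, reference directories, groupings,
and result writing.

All tabular outputs are tab-delimited with a header row; floats are
written at 6 significant digits unless full precision is requested.
Gene and cell-type identifiers are matched exactly after trimming
surrounding whitespace (no case folding — gene symbols are
case-meaningful across species).
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import yaml

from .containers import ReferenceBasis, ScDataset
from .tree import CellTypeGrouping
from .wnnls import DeconvolutionTable

logger = logging.getLogger("music_deconv")

__all__ = [
    "read_expression",
    "read_sc_dataset",
    "write_sc_dataset",
    "read_reference",
    "write_reference",
    "read_grouping",
    "write_results",
    "setup_logging",
]


def setup_logging(verbosity: int = 0) -> None:
    level = logging.WARNING if verbosity <= 0 else logging.INFO if verbosity == 1 else logging.DEBUG
    logging.basicConfig(
        level=level,
        format="%(levelname)s %(name)s: %(message)s",
        stream=sys.stderr,
        force=True,
    )


def _check_ids(ids: pd.Index, what: str) -> pd.Index:
    ids = pd.Index([str(x).strip() for x in ids])
    if ids.duplicated().any():
        dupes = sorted(set(ids[ids.duplicated()]))
        raise ValueError(f"duplicate {what} identifiers: {dupes[:5]}")
    return ids


def read_expression(path: str | Path, layout: str = "dense") -> pd.DataFrame:
    """Read a genes x columns expression matrix.

    ``dense``: TSV/CSV with gene IDs in the first column and a header
    row of column (cell/sample) IDs. ``mtx``: MatrixMarket file with
    sidecar ``genes.tsv`` and ``barcodes.tsv`` (one ID per line) next to
    it. Duplicate gene IDs, non-numeric cells and sidecar/matrix
    dimension mismatches each raise a distinct error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "dense":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        if df.columns.empty or df.index.name is None and df.empty:
            raise ValueError(f"{path}: malformed header — expected gene ID column plus sample columns")
        try:
            df = df.astype(float)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric expression values ({exc})") from exc
        df.index = _check_ids(df.index, "gene")
        df.index.name = "gene"
        return df
    if layout == "mtx":
        mat = scipy.io.mmread(path).toarray() if path.suffix == ".mtx" else None
        if mat is None:
            raise ValueError(f"{path}: expected a .mtx file for layout='mtx'")
        gene_file = path.parent / "genes.tsv"
        col_file = path.parent / "barcodes.tsv"
        for f in (gene_file, col_file):
            if not f.exists():
                raise FileNotFoundError(f"{f}: sidecar file required for mtx layout")
        genes = [l.strip().split("\t")[0] for l in gene_file.read_text().splitlines() if l.strip()]
        cols = [l.strip().split("\t")[0] for l in col_file.read_text().splitlines() if l.strip()]
        if mat.shape != (len(genes), len(cols)):
            raise ValueError(
                f"{path}: matrix is {mat.shape} but sidecars give "
                f"{len(genes)} genes x {len(cols)} columns"
            )
        return pd.DataFrame(mat, index=_check_ids(pd.Index(genes), "gene"), columns=cols).rename_axis("gene")
    raise ValueError(f"unknown layout {layout!r}; expected 'dense' or 'mtx'")


def read_sc_dataset(matrix_path: str | Path, metadata_path: str | Path, layout: str = "dense") -> ScDataset:
    """Load a single-cell dataset: expression matrix + cell metadata TSV
    with required columns ``barcode``, ``subject``, ``cell_type``."""
    expr = read_expression(matrix_path, layout=layout)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"barcode", "subject", "cell_type"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{metadata_path}: metadata missing columns {sorted(missing)}")
    meta = meta.set_index(meta["barcode"].str.strip())
    unknown = [c for c in expr.columns if c not in meta.index]
    if unknown:
        raise ValueError(f"cells without metadata: {unknown[:5]}")
    meta = meta.loc[list(expr.columns)]
    return ScDataset(
        counts=expr.to_numpy(),
        gene_ids=expr.index.to_numpy(dtype=object),
        cell_subject=meta["subject"].str.strip().to_numpy(dtype=object),
        cell_type=meta["cell_type"].str.strip().to_numpy(dtype=object),
    )


def write_sc_dataset(sc: ScDataset, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    barcodes = [f"cell_{i:05d}" for i in range(sc.n_cells)]
    expr = pd.DataFrame(sc.counts, index=pd.Index(sc.gene_ids, name="gene"), columns=barcodes)
    mpath = outdir / "counts.tsv"
    expr.to_csv(mpath, sep="\t")
    meta = pd.DataFrame(
        {"barcode": barcodes, "subject": sc.cell_subject, "cell_type": sc.cell_type}
    )
    mdpath = outdir / "cell_metadata.tsv"
    meta.to_csv(mdpath, sep="\t", index=False)
    return {"matrix": mpath, "metadata": mdpath}


def write_reference(ref: ReferenceBasis, outdir: str | Path, full_precision: bool = False) -> None:
    """Write a reference directory: theta_mean.tsv, theta_var.tsv,
    lib_size.tsv and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.17g" if full_precision else "%.6g"
    gidx = pd.Index(ref.gene_ids, name="gene")
    cols = pd.Index(ref.cell_type_ids, name="cell_type")
    pd.DataFrame(ref.theta_mean, index=gidx, columns=cols).to_csv(
        outdir / "theta_mean.tsv", sep="\t", float_format=fmt
    )
    pd.DataFrame(ref.theta_var, index=gidx, columns=cols).to_csv(
        outdir / "theta_var.tsv", sep="\t", float_format=fmt
    )
    pd.DataFrame(
        {"cell_type": cols, "lib_size": ref.lib_size, "n_subjects": ref.n_subjects_per_type}
    ).to_csv(outdir / "lib_size.tsv", sep="\t", index=False, float_format=fmt)
    manifest = {
        "var_estimator": ref.var_estimator,
        "n_genes": int(ref.n_genes),
        "cell_types": [str(t) for t in ref.cell_type_ids],
        "subjects_per_type": {k: list(v) for k, v in ref.subjects_per_type.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_reference(refdir: str | Path) -> ReferenceBasis:
    refdir = Path(refdir)
    tm = pd.read_csv(refdir / "theta_mean.tsv", sep="\t", index_col=0, float_precision="round_trip")
    tv = pd.read_csv(refdir / "theta_var.tsv", sep="\t", index_col=0, float_precision="round_trip")
    ls = pd.read_csv(refdir / "lib_size.tsv", sep="\t", float_precision="round_trip")
    manifest = json.loads((refdir / "manifest.json").read_text())
    if list(tm.columns) != list(tv.columns) or list(tm.index) != list(tv.index):
        raise ValueError(f"{refdir}: theta_mean and theta_var are not aligned")
    ls = ls.set_index("cell_type").loc[list(tm.columns)]
    return ReferenceBasis(
        theta_mean=tm.to_numpy(),
        theta_var=tv.to_numpy(),
        lib_size=ls["lib_size"].to_numpy(dtype=float),
        n_subjects_per_type=ls["n_subjects"].to_numpy(dtype=int),
        gene_ids=tm.index.to_numpy(dtype=object),
        cell_type_ids=np.asarray(tm.columns, dtype=object),
        var_estimator=manifest.get("var_estimator", "sample"),
        subjects_per_type=manifest.get("subjects_per_type", {}),
    )


def _grouping_from_mapping(doc: dict) -> CellTypeGrouping:
    if "clusters" in doc:
        clusters = doc["clusters"]
        nesting = {
            name: _grouping_from_mapping(sub) for name, sub in (doc.get("nesting") or {}).items()
        }
        genes = doc.get("per_cluster_genes") or {}
    else:  # shorthand: mapping of cluster name -> member list
        clusters, nesting, genes = doc, {}, {}
    if not isinstance(clusters, dict) or not clusters:
        raise ValueError("grouping must map cluster names to non-empty cell-type lists")
    return CellTypeGrouping(
        clusters={str(k): list(v) for k, v in clusters.items()},
        nesting=nesting,
        per_cluster_genes={str(k): list(v) for k, v in genes.items()},
    )


def read_grouping(path: str | Path) -> CellTypeGrouping:
    """Read a YAML/JSON cell-type grouping.

    Either a shorthand mapping ``{cluster_name: [cell types...]}`` or the
    full form ``{clusters: {...}, nesting: {cluster_name: {...}},
    per_cluster_genes: {...}}``.
    """
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict) or not doc:
        raise ValueError(f"{path}: empty or non-mapping grouping file")
    return _grouping_from_mapping(doc)


def write_results(
    table: DeconvolutionTable,
    outdir: str | Path,
    write_weights: bool = False,
    full_precision: bool = False,
) -> None:
    """Write proportions.tsv (+ rna_fractions.tsv), optional weights.tsv,
    and diagnostics.json for a deconvolution run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.17g" if full_precision else "%.6g"
    table.proportions.to_csv(outdir / "proportions.tsv", sep="\t", float_format=fmt)
    table.rna_fractions.to_csv(outdir / "rna_fractions.tsv", sep="\t", float_format=fmt)
    if write_weights and table.results:
        weights = pd.DataFrame({sid: r.weights for sid, r in table.results.items()})
        weights.rename_axis("gene").to_csv(outdir / "weights.tsv", sep="\t", float_format=fmt)
    diagnostics = {
        "samples": {
            sid: {
                "n_iter": int(r.n_iter),
                "converged": bool(r.converged),
                "var_explained": None if np.isnan(r.var_explained) else float(r.var_explained),
                "flags": list(r.flags),
            }
            for sid, r in table.results.items()
        },
        "failures": dict(table.failures),
    }
    (outdir / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
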