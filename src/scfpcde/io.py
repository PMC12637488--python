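"""Readers and writers for expression matrices, pseudotime tables and results.

Supported on-disk formats are deliberately plain: Matrix Market (.mtx with
genes.tsv / barcodes.tsv sidecars), dense CSV/TSV with genes as rows, and
TSV/JSON outputs.  Orientation defaults to genes-as-rows; an explicit flag
flips it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .fpca import ExpressionMatrix, PseudotimeAxis

__all__ = [
    "read_expression",
    "read_pseudotime",
    "match_cells",
    "filter_genes",
    "write_results",
    "read_results",
    "write_dataset",
]

log = logging.getLogger("scfpcde")


def _package_version():
    try:
        return version("scfpcde")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def read_expression(path, fmt=None, cells_as_rows=False, scale="counts"):
    """Load a genes × cells matrix from MTX (with sidecars) or dense CSV/TSV.

    For ``fmt="mtx"`` the files ``genes.tsv`` and ``barcodes.tsv`` must sit
    next to the matrix file (one id per line).  Dense files need an index
    column of gene ids and a header row of cell ids.  ``cells_as_rows``
    transposes after reading.  Duplicate gene ids are rejected.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv", ".txt": "tsv"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name!r}")
    if fmt == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = pd.read_csv(path.parent / "genes.tsv", sep="\t", header=None)
        cells = pd.read_csv(path.parent / "barcodes.tsv", sep="\t", header=None)
        gene_ids = genes.iloc[:, 0].to_numpy(dtype=str)
        cell_ids = cells.iloc[:, 0].to_numpy(dtype=str)
        values = np.asarray(mat, dtype=float)
        if cells_as_rows:
            values = values.T
        if values.shape != (gene_ids.size, cell_ids.size):
            raise ValueError(
                f"matrix shape {values.shape} does not match sidecars "
                f"({gene_ids.size} genes, {cell_ids.size} cells)"
            )
    elif fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t", index_col=0)
        if cells_as_rows:
            df = df.T
        gene_ids = df.index.to_numpy(dtype=str)
        cell_ids = df.columns.to_numpy(dtype=str)
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as err:
            raise ValueError(f"non-numeric entries in {path}: {err}") from err
    else:
        raise ValueError(f"unknown expression format {fmt!r}")
    if pd.Index(gene_ids).has_duplicates:
        raise ValueError("duplicate gene ids in expression input")
    return ExpressionMatrix(values, gene_ids, cell_ids, scale=scale)


def read_pseudotime(path):
    """Read a cell_id / pseudotime (/ cluster) table; rescaling to [0, 1]
    happens when the axis is constructed."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    for col in ("cell_id", "pseudotime"):
        if col not in df.columns:
            raise ValueError(f"pseudotime table must contain a {col!r} column")
    if not np.all(np.isfinite(df["pseudotime"].to_numpy(dtype=float))):
        raise ValueError("non-finite pseudotime values")
    cluster = df["cluster"].to_numpy() if "cluster" in df.columns else None
    return PseudotimeAxis(
        df["cell_id"].to_numpy(dtype=str),
        df["pseudotime"].to_numpy(dtype=float),
        cluster=cluster,
    )


def match_cells(expr, axis):
    """Align expression columns with the pseudotime axis by cell id.

    Cells missing from either side are dropped (count logged); zero
    overlap is an error.  Returns (expression, axis) restricted to the
    shared cells, in axis order.
    """
    shared = [c for c in axis.cell_ids if c in set(expr.cell_ids)]
    dropped = (len(axis) - len(shared)) + (expr.n_cells - len(shared))
    if not shared:
        raise ValueError("no overlap between expression and pseudotime cell ids")
    if dropped:
        log.warning("dropped %d unmatched cells", dropped)
    col = {c: j for j, c in enumerate(expr.cell_ids)}
    keep_axis = np.array([c in col for c in axis.cell_ids])
    order = np.array([col[c] for c in shared])
    new_expr = ExpressionMatrix(
        expr.values[:, order], expr.gene_ids, np.asarray(shared), scale=expr.scale
    )
    new_axis = PseudotimeAxis(
        np.asarray(shared),
        axis.t[keep_axis],
        cluster=None if axis.cluster is None else axis.cluster[keep_axis],
    )
    return new_expr, new_axis


def filter_genes(expr, min_cells_expressed=0, max_sparsity=1.0):
    """Drop genes expressed in too few cells or with too many zeros.

    Generic quality filters (defaults keep everything); thresholds are a
    user choice, typically a handful of cells / 95-99% sparsity.
    """
    nonzero = (expr.values != 0).sum(axis=1)
    sparsity = 1.0 - nonzero / expr.n_cells
    keep = (nonzero >= min_cells_expressed) & (sparsity <= max_sparsity)
    if not keep.all():
        log.info("filtered out %d of %d genes", int((~keep).sum()), expr.n_genes)
    return ExpressionMatrix(
        expr.values[keep], expr.gene_ids[keep], expr.cell_ids, scale=expr.scale
    )


# ---------------------------------------------------------------------------
def _config_dict(results):
    model = results.model
    return {
        "n_basis": model.basis.n_basis,
        "order": model.basis.order,
        "penalty_order": model.basis.penalty_order,
        "lambda": results.smoothed.lam,
        "smoothing": model.smoothing if isinstance(model.smoothing, str) else float(model.smoothing),
        "n_components_rule": model.n_components,
        "var_threshold": model.var_threshold,
        "max_components": model.max_components,
        "tig_fraction": model.tig_fraction,
        "n_stages": model.n_stages,
        "pseudo_count": model.pseudo_count,
        "n_permutations": results.null.B,
        "null_method": results.null_method,
        "alpha": results.alpha,
        "seed": results.seed,
    }


def write_results(results, outdir, report=None):
    """Write results.tsv + metadata.json (+ benchmark.{tsv,json}).

    Everything is assembled in memory first so a validation failure never
    leaves partial files; column order and float formatting are fixed so
    identical runs produce byte-identical output.
    """
    outdir = Path(outdir)
    frame = results.to_frame()
    config = _config_dict(results)
    meta = {
        "package": "scfpcde",
        "version": _package_version(),
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest()[:16],
        "n_genes": int(results.centered.n_genes),
        "n_cells": int(results.centered.n_cells),
        "L": int(results.eigensystem.L),
        "eigenvalues": [float(v) for v in results.eigensystem.eigenvalues],
        "var_explained": [float(v) for v in results.eigensystem.var_explained],
        "n_tigs": int(results.is_tig.sum()),
        "n_tdegs": int(results.is_tdeg.sum()),
        "n_constant_genes": int(results.is_constant.sum()),
    }
    outdir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(outdir / "results.tsv", sep="\t", index=False,
                 float_format="%.10g")
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if report is not None:
        report.to_frame().to_csv(outdir / "benchmark.tsv", sep="\t",
                                 index=False, float_format="%.10g")
        with open(outdir / "benchmark.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return outdir / "results.tsv"


def read_results(outdir):
    """Round-trip reader for ``write_results`` output."""
    outdir = Path(outdir)
    frame = pd.read_csv(outdir / "results.tsv", sep="\t")
    with open(outdir / "metadata.json") as fh:
        meta = json.load(fh)
    return frame, meta


def write_eigensystem(eig, outdir):
    """Export eigenfunction coefficients (TSV) + spectral metadata (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coef = pd.DataFrame(
        eig.coef, columns=[f"FPC{k + 1}" for k in range(eig.L)]
    )
    coef.insert(0, "basis_fn", np.arange(eig.coef.shape[0]) + 1)
    coef.to_csv(outdir / "eigenfunctions.tsv", sep="\t", index=False,
                float_format="%.10g")
    meta = {
        "n_basis": eig.basis.n_basis,
        "order": eig.basis.order,
        "interior_knots": [float(k) for k in eig.basis.interior_knots],
        "eigenvalues": [float(v) for v in eig.eigenvalues],
        "var_explained": [float(v) for v in eig.var_explained],
        "total_variance": float(eig.total_variance),
    }
    with open(outdir / "eigensystem.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_dataset(data, outdir, fmt="mtx"):
    """Write a simulated dataset: counts, sidecars, truth labels, config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        scipy.io.mmwrite(
            outdir / "matrix.mtx", scipy.sparse.coo_matrix(data.counts),
            field="integer",
        )
    elif fmt == "csv":
        pd.DataFrame(
            data.counts, index=data.gene_ids, columns=data.cell_ids
        ).to_csv(outdir / "matrix.csv")
    else:
        raise ValueError(f"unknown dataset format {fmt!r}")
    pd.Series(data.gene_ids).to_csv(outdir / "genes.tsv", sep="\t",
                                    index=False, header=False)
    pd.Series(data.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t",
                                    index=False, header=False)
    pd.DataFrame({"cell_id": data.cell_ids, "pseudotime": data.t}).to_csv(
        outdir / "pseudotime.tsv", sep="\t", index=False, float_format="%.10g"
    )
    pd.DataFrame({"gene_id": data.gene_ids, "is_tdeg": data.is_tdeg}).to_csv(
        outdir / "truth.tsv", sep="\t", index=False
    )
    cfg = {
        "n_genes": data.config.n_genes,
        "n_tdeg": data.config.n_tdeg,
        "n_cells": data.config.n_cells,
        "eigenvalue_weights": list(data.config.eigenvalue_weights),
        "nb_dispersion": data.config.nb_dispersion,
        "dropout_keep_prob": data.config.dropout_keep_prob,
        "seed": data.config.seed,
        "sparsity": data.sparsity,
    }
    with open(outdir / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
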