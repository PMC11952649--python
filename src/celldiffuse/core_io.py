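"""Data model, file readers/writers and run configuration.

All coordinates live in a single full-resolution image frame: origin at the
top-left corner, x increasing rightward, y increasing downward.  Physical
units (microns) enter only through the spot diameter / pixel-size scalars the
caller provides; every distance in the package is computed in this one frame.

Matrix files are either Matrix Market triplets (1-based COO, ``.mtx``) with
sidecar id files ``<stem>.rows.txt`` / ``<stem>.cols.txt``, or dense CSV with
a mandatory header row (first column = row ids, remaining columns = genes).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger("celldiffuse")


class ValidationError(ValueError):
    """Raised when an input file or configuration violates a contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SpotExpression:
    """Spot-level expression matrix with spot geometry.

    ``matrix`` is spots x genes, non-negative.  ``diameter`` is the physical
    capture diameter in the same units as ``coords``.  ``cells_per_spot`` and
    ``enclosed_cells`` are populated by the simulator (how many / which cells
    each spot aggregated) and are optional for real data.
    """

    spot_ids: np.ndarray
    coords: np.ndarray
    diameter: float
    matrix: np.ndarray
    gene_ids: np.ndarray
    cells_per_spot: Optional[np.ndarray] = None
    enclosed_cells: Optional[list] = None

    def __post_init__(self) -> None:
        self.spot_ids = np.asarray(self.spot_ids)
        self.coords = np.asarray(self.coords, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids)
        if len(set(self.spot_ids.tolist())) != len(self.spot_ids):
            raise ValidationError("duplicate spot ids")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("spot coordinates must be finite")
        m = self.matrix
        n = m.shape[0]
        if n != len(self.spot_ids):
            raise ValidationError(
                f"matrix has {n} rows but {len(self.spot_ids)} spot ids"
            )
        if m.shape[1] != len(self.gene_ids):
            raise ValidationError("matrix column count != number of gene ids")
        mn = m.data.min(initial=0.0) if sp.issparse(m) else np.min(m, initial=0.0)
        if mn < 0:
            raise ValidationError("expression values must be non-negative")
        if self.diameter <= 0:
            raise ValidationError("spot diameter must be positive")

    @property
    def n_spots(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def dense(self) -> np.ndarray:
        m = self.matrix
        return m.toarray() if sp.issparse(m) else np.asarray(m)


@dataclass
class CellTable:
    """In-silico cells: centroids, morphological features, spot assignment.

    ``spot_assignment`` holds the index (into a SpotExpression) of each cell's
    nearest spot, or -1 for unassigned cells.  ``type_labels`` is optional and
    only used by entropy-based heterogeneity and by the simulator.
    """

    cell_ids: np.ndarray
    centroids: np.ndarray
    morph_features: Optional[np.ndarray] = None
    spot_assignment: Optional[np.ndarray] = None
    type_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if not np.all(np.isfinite(self.centroids)):
            raise ValidationError("cell centroids must be finite")
        if self.centroids.ndim != 2 or self.centroids.shape[1] != 2:
            raise ValidationError("centroids must be an (n, 2) array")
        if self.morph_features is not None:
            self.morph_features = np.asarray(self.morph_features, dtype=float)
            if self.morph_features.shape[0] != self.n_cells:
                raise ValidationError("morph_features row count != n_cells")
        if self.spot_assignment is not None:
            self.spot_assignment = np.asarray(self.spot_assignment, dtype=int)
            if self.spot_assignment.shape[0] != self.n_cells:
                raise ValidationError("spot_assignment length != n_cells")
        if self.type_labels is not None:
            self.type_labels = np.asarray(self.type_labels)

    @property
    def n_cells(self) -> int:
        return self.centroids.shape[0]

    def subset(self, index: np.ndarray) -> "CellTable":
        """Row-subset of the table (keeps field alignment)."""
        return CellTable(
            cell_ids=self.cell_ids[index],
            centroids=self.centroids[index],
            morph_features=None
            if self.morph_features is None
            else self.morph_features[index],
            spot_assignment=None
            if self.spot_assignment is None
            else self.spot_assignment[index],
            type_labels=None if self.type_labels is None else self.type_labels[index],
        )


@dataclass
class CellExpression:
    """Cell-level expression matrix (cells x genes)."""

    cell_ids: np.ndarray
    matrix: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids)
        self.gene_ids = np.asarray(self.gene_ids)
        m = self.matrix
        if m.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError(
                f"matrix shape {m.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(self.gene_ids) == 0:
            raise ValidationError("empty gene list")
        dm = m.data if sp.issparse(m) else np.asarray(m)
        if dm.size and not np.all(np.isfinite(dm)):
            raise ValidationError("expression values must be finite")

    def dense(self) -> np.ndarray:
        m = self.matrix
        return m.toarray() if sp.issparse(m) else np.asarray(m)


@dataclass
class RunConfig:
    """Inference parameters.

    Defaults follow the method's reference settings: 5 nearest neighbours,
    forward smoothing scale lambda = 0.8, 20 diffusion steps.  The reverse
    inflation scale mu is negative with |mu| marginally above lambda so that
    the reverse step restores the variance the forward step removes.
    """

    n_neighbors: int = 5
    smoothing_scale: float = 0.8
    inflation_scale: float = -0.82
    alpha: float = 5.0
    kappa: float = 1.0
    n_iters: int = 20
    n_pcs: int = 10
    w_gen: float = 1.0
    w_geo: float = 1.0
    cutoff_distance: Optional[float] = None  # None -> spot diameter
    snn_threshold: Optional[float] = None  # None -> 1 / n_neighbors
    init_space: str = "lognorm"  # {"lognorm", "counts"}
    init_scale: str = "per_cell"  # {"per_cell", "aggregate"}; counts space only
    rescale: str = "minmax"  # {"minmax", "none"}
    heterogeneity: str = "cv"  # {"cv", "entropy"}
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_neighbors < 1:
            raise ValidationError("n_neighbors must satisfy k >= 1")
        if not 0.0 < self.smoothing_scale < 1.0:
            raise ValidationError("smoothing_scale must lie in (0, 1)")
        if not -1.0 < self.inflation_scale < 0.0:
            raise ValidationError("inflation_scale must lie in (-1, 0)")
        if self.alpha < 0:
            raise ValidationError("alpha must satisfy alpha >= 0")
        if self.kappa <= 0:
            raise ValidationError("kappa must satisfy kappa > 0")
        if self.n_iters < 0:
            raise ValidationError("n_iters must satisfy n >= 0")
        if self.n_pcs < 1:
            raise ValidationError("n_pcs must satisfy n_pcs >= 1")
        if self.w_gen < 0 or self.w_geo < 0:
            raise ValidationError("block weights w_gen, w_geo must be >= 0")
        if self.cutoff_distance is not None and self.cutoff_distance <= 0:
            raise ValidationError("cutoff_distance must be positive")
        if self.init_space not in ("lognorm", "counts"):
            raise ValidationError("init_space must be 'lognorm' or 'counts'")
        if self.init_scale not in ("per_cell", "aggregate"):
            raise ValidationError("init_scale must be 'per_cell' or 'aggregate'")
        if self.rescale not in ("minmax", "none"):
            raise ValidationError("rescale must be 'minmax' or 'none'")
        if self.heterogeneity not in ("cv", "entropy"):
            raise ValidationError("heterogeneity must be 'cv' or 'entropy'")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sidecar_paths(matrix_path: Path) -> tuple[Path, Path]:
    stem = matrix_path.with_suffix("")
    return Path(str(stem) + ".rows.txt"), Path(str(stem) + ".cols.txt")


def _read_matrix(matrix_path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an MTX triplet (+ sidecar ids) or a dense CSV.

    Returns (row_ids, matrix, col_ids) with the matrix dense float64.
    """
    if matrix_path.suffix.lower() == ".mtx":
        rows_path, cols_path = _sidecar_paths(matrix_path)
        for p in (matrix_path, rows_path, cols_path):
            if not p.exists():
                raise FileNotFoundError(p)
        mat = scipy.io.mmread(str(matrix_path))
        mat = np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=float)
        row_ids = np.loadtxt(rows_path, dtype=str, ndmin=1)
        col_ids = np.loadtxt(cols_path, dtype=str, ndmin=1)
        return row_ids, mat, col_ids
    if not matrix_path.exists():
        raise FileNotFoundError(matrix_path)
    df = pd.read_csv(matrix_path, index_col=0)
    return (
        df.index.astype(str).to_numpy(),
        df.to_numpy(dtype=float),
        df.columns.astype(str).to_numpy(),
    )


def read_spot_expression(
    matrix_path: str | Path, coords_path: str | Path, diameter: float
) -> SpotExpression:
    """Load a spot matrix and its coordinate table, matched by spot id.

    Spots lacking coordinates (and coordinates lacking spots) are dropped with
    a logged count; zero overlap or negative entries are rejected.
    """
    matrix_path, coords_path = Path(matrix_path), Path(coords_path)
    row_ids, mat, gene_ids = _read_matrix(matrix_path)
    if not coords_path.exists():
        raise FileNotFoundError(coords_path)
    coords_df = pd.read_csv(coords_path)
    for col in ("id", "x", "y"):
        if col not in coords_df.columns:
            raise ValidationError(f"coordinate table lacks required column '{col}'")
    coords_df = coords_df.set_index(coords_df["id"].astype(str))

    if mat.size and mat.min() < 0:
        raise ValidationError("negative entries in spot matrix")

    id_list = [str(i) for i in row_ids]
    keep = [i for i, sid in enumerate(id_list) if sid in coords_df.index]
    if not keep:
        raise ValidationError("no overlapping ids between matrix and coordinates")
    n_dropped_spots = len(id_list) - len(keep)
    n_extra_coords = len(coords_df) - len(keep)
    if n_dropped_spots:
        logger.warning("dropped %d spots lacking coordinates", n_dropped_spots)
    if n_extra_coords:
        logger.warning("ignored %d coordinate rows lacking spots", n_extra_coords)

    kept_ids = np.array([id_list[i] for i in keep])
    xy = coords_df.loc[kept_ids, ["x", "y"]].to_numpy(dtype=float)
    logger.info(
        "read_spot_expression: %d spots, %d genes (in=%d)",
        len(keep),
        mat.shape[1],
        len(id_list),
    )
    return SpotExpression(
        spot_ids=kept_ids,
        coords=xy,
        diameter=float(diameter),
        matrix=mat[keep],
        gene_ids=gene_ids,
    )


def read_cell_table(path: str | Path) -> CellTable:
    """Read a cell table CSV: ``cell_id,x,y[,type][,feature columns]``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in ("cell_id", "x", "y"):
        if col not in df.columns:
            raise ValidationError(f"cell table lacks required column '{col}'")
    feat_cols = [c for c in df.columns if c not in ("cell_id", "x", "y", "type")]
    return CellTable(
        cell_ids=df["cell_id"].astype(str).to_numpy(),
        centroids=df[["x", "y"]].to_numpy(dtype=float),
        morph_features=df[feat_cols].to_numpy(dtype=float) if feat_cols else None,
        type_labels=df["type"].to_numpy() if "type" in df.columns else None,
    )


def write_cell_expression(
    ce: CellExpression, out_path: str | Path, format: str = "mtx"
) -> Path:
    """Write a cell-level matrix as MTX (+ sidecar ids) or dense CSV.

    Round-tripping through :func:`read_cell_expression` preserves values to
    better than 1e-9.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    dense = ce.dense()
    if format == "mtx":
        rows_path, cols_path = _sidecar_paths(out_path)
        scipy.io.mmwrite(str(out_path), sp.coo_matrix(dense))
        np.savetxt(rows_path, ce.cell_ids, fmt="%s")
        np.savetxt(cols_path, ce.gene_ids, fmt="%s")
    elif format == "csv":
        pd.DataFrame(
            dense, index=ce.cell_ids.astype(str), columns=ce.gene_ids.astype(str)
        ).to_csv(out_path, float_format="%.12g")
    else:
        raise ValidationError(f"unknown format {format!r} (expected 'mtx' or 'csv')")
    logger.info("wrote %d x %d cell expression to %s", *dense.shape, out_path)
    return out_path


def read_cell_expression(path: str | Path) -> CellExpression:
    """Read back a matrix written by :func:`write_cell_expression`."""
    row_ids, mat, col_ids = _read_matrix(Path(path))
    return CellExpression(cell_ids=row_ids, matrix=mat, gene_ids=col_ids)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def load_config(path: Optional[str | Path] = None) -> RunConfig:
    """Load a YAML/JSON configuration; unset fields take the defaults.

    An empty / missing path returns the default configuration.  Out-of-range
    values raise :class:`ValidationError` naming the violated bound.
    """
    if path is None or str(path) == "":
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError("configuration must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown configuration keys: {sorted(unknown)}")
    return RunConfig(**data)


def config_to_dict(cfg: RunConfig) -> dict:
    return {f.name: getattr(cfg, f.name) for f in fields(cfg)}


def save_manifest(path: str | Path, payload: dict) -> Path:
    """Write a JSON manifest (seeds, parameters) next to generated outputs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
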