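"""Synthetic benchmark: layered cell maps, Poisson expression, grid spots.

The generator emulates a spatially organised tissue of three cell types
(modelled on the granular / oligodendrocyte / Purkinje layering of the
cerebellum): 6,579 cells scattered over a ~3 x 3 mm field in three
contiguous bands, 1,000 Poisson genes split 350/350/300 as markers of the
three types, marker means drawn Uniform(100, 200) and non-marker means
Uniform(10, 20).  Spots are laid on a square grid (default 100 um pitch)
and aggregate the counts of enclosed cells.  Three perturbations mimic real
failure modes: cell missouts (random removal), rewired graph connections,
and Splatter-style logistic transcript dropout.

Coordinates are in microns; the type label set is {1, 2, 3}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_io import CellTable, SpotExpression, ValidationError
from .graph import CellGraph, knn_to_snn

logger = logging.getLogger("celldiffuse")

N_CELLS_DEFAULT = 6579
N_GENES_DEFAULT = 1000
MARKERS_PER_TYPE_DEFAULT = (350, 350, 300)
# granular cells dominate, oligodendrocytes intermediate, Purkinje sparse
TYPE_PROPORTIONS_DEFAULT = (0.6, 0.25, 0.15)
FIELD_UM_DEFAULT = (3000.0, 3000.0)
MARKER_RANGE = (100.0, 200.0)
NONMARKER_RANGE = (10.0, 20.0)


@dataclass
class SimulationTruth:
    """Ground truth of the benchmark: positions, types, means, counts."""

    positions: np.ndarray  # (n, 2) um
    types: np.ndarray  # (n,) in {1, 2, 3}
    lambdas: np.ndarray  # (genes, n_types) Poisson means
    counts: np.ndarray  # (n, genes) sampled ground truth
    seed: int

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def n_genes(self) -> int:
        return self.lambdas.shape[0]

    def cell_means(self) -> np.ndarray:
        """Per-cell Poisson means (n, genes): the noise-free expression."""
        return self.lambdas[:, self.types - 1].T

    def to_cell_table(self, one_hot_features: bool = True) -> CellTable:
        """CellTable with one-hot type vectors as stand-in image features."""
        morph = None
        if one_hot_features:
            n_types = self.lambdas.shape[1]
            morph = np.zeros((self.n_cells, n_types))
            morph[np.arange(self.n_cells), self.types - 1] = 1.0
        return CellTable(
            cell_ids=np.array([f"cell{i}" for i in range(self.n_cells)]),
            centroids=self.positions.copy(),
            morph_features=morph,
            type_labels=self.types.copy(),
        )


@dataclass
class DropoutConfig:
    """Logistic dropout: P(zero) = 1 / (1 + exp(-shape * (x - mid))).

    ``mid`` is the covariate value at which half the entries drop out;
    ``shape`` must be negative so higher expression drops out less.  The
    covariate x is log(lambda + 1) by default (``covariate='log'``); raw
    lambda is available via ``covariate='raw'``.
    """

    mid: float
    shape: float
    covariate: str = "log"

    def __post_init__(self) -> None:
        if self.shape >= 0:
            raise ValidationError("dropout shape must be negative")
        if self.covariate not in ("log", "raw"):
            raise ValidationError("dropout covariate must be 'log' or 'raw'")


def dropout_probability(x, dcfg: DropoutConfig) -> np.ndarray:
    """P(zero) at covariate value x (vectorised logistic)."""
    return 1.0 / (1.0 + np.exp(-dcfg.shape * (np.asarray(x, dtype=float) - dcfg.mid)))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _type_counts(n_cells: int, proportions: Sequence[float]) -> np.ndarray:
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    counts = np.floor(p * n_cells).astype(int)
    counts[: n_cells - counts.sum()] += 1
    return counts


def generate_positions(
    n_cells: int = N_CELLS_DEFAULT,
    layout: str = "layers",
    seed: int = 0,
    proportions: Sequence[float] = TYPE_PROPORTIONS_DEFAULT,
    field: Sequence[float] = FIELD_UM_DEFAULT,
    path=None,
) -> CellTable:
    """Cell positions and type labels for the benchmark.

    ``layers`` stacks three contiguous horizontal bands (band heights
    proportional to the type proportions) with uniform scatter inside each;
    ``blobs`` draws Gaussian clusters; ``file`` loads positions and types
    from a CSV with columns ``cell_id,x,y,type``.
    """
    if n_cells < 3:
        raise ValidationError("need at least 3 cells")
    rng = np.random.default_rng(seed)
    width, height = float(field[0]), float(field[1])

    if layout == "file":
        if path is None:
            raise ValidationError("layout='file' requires a path")
        df = pd.read_csv(path)
        if "type" not in df.columns:
            raise ValidationError("position file lacks a 'type' column")
        return CellTable(
            cell_ids=df["cell_id"].astype(str).to_numpy()
            if "cell_id" in df.columns
            else np.array([f"cell{i}" for i in range(len(df))]),
            centroids=df[["x", "y"]].to_numpy(dtype=float),
            type_labels=df["type"].to_numpy(dtype=int),
        )

    counts = _type_counts(n_cells, proportions)
    xs, ys, types = [], [], []
    if layout == "layers":
        edges = np.concatenate([[0.0], np.cumsum(counts / n_cells)]) * height
        for t, c in enumerate(counts):
            xs.append(rng.uniform(0.0, width, c))
            ys.append(rng.uniform(edges[t], edges[t + 1], c))
            types.append(np.full(c, t + 1, dtype=int))
    elif layout == "blobs":
        centers = rng.uniform(0.2, 0.8, size=(len(counts), 2)) * [width, height]
        sd = 0.08 * min(width, height)
        for t, c in enumerate(counts):
            pts = rng.normal(centers[t], sd, size=(c, 2))
            xs.append(pts[:, 0])
            ys.append(pts[:, 1])
            types.append(np.full(c, t + 1, dtype=int))
    else:
        raise ValidationError(f"unknown layout {layout!r}")

    pos = np.column_stack([np.concatenate(xs), np.concatenate(ys)])
    types = np.concatenate(types)
    order = rng.permutation(n_cells)  # interleave types in the index order
    return CellTable(
        cell_ids=np.array([f"cell{i}" for i in range(n_cells)]),
        centroids=pos[order],
        type_labels=types[order],
    )


def sample_programs(
    n_genes: int = N_GENES_DEFAULT,
    markers_per_type: Sequence[int] = MARKERS_PER_TYPE_DEFAULT,
    seed: int = 0,
) -> np.ndarray:
    """Gene x type Poisson means: marker genes high, non-markers low."""
    markers = np.asarray(markers_per_type, dtype=int)
    if markers.sum() != n_genes:
        raise ValidationError(
            f"markers_per_type sums to {markers.sum()} but n_genes={n_genes}"
        )
    rng = np.random.default_rng(seed)
    n_types = len(markers)
    lam = rng.uniform(*NONMARKER_RANGE, size=(n_genes, n_types))
    marker_type = np.repeat(np.arange(n_types), markers)
    lam[np.arange(n_genes), marker_type] = rng.uniform(*MARKER_RANGE, size=n_genes)
    return lam


def sample_counts_truth(
    cells: CellTable, lambdas: np.ndarray, seed: int = 0
) -> SimulationTruth:
    """Poisson-sample ground-truth counts for every cell and gene."""
    if cells.type_labels is None:
        raise ValidationError("cell table needs type labels")
    types = np.asarray(cells.type_labels, dtype=int)
    rng = np.random.default_rng(seed)
    means = lambdas[:, types - 1].T  # (cells, genes)
    counts = rng.poisson(means).astype(np.int32)
    return SimulationTruth(
        positions=cells.centroids.copy(),
        types=types,
        lambdas=np.asarray(lambdas, dtype=float),
        counts=counts,
        seed=seed,
    )


def simulate_benchmark(
    n_cells: int = N_CELLS_DEFAULT,
    n_genes: int = N_GENES_DEFAULT,
    markers_per_type: Optional[Sequence[int]] = None,
    layout: str = "layers",
    seed: int = 0,
) -> SimulationTruth:
    """Positions + programs + counts in one call (seeded sub-streams).

    When ``markers_per_type`` is omitted it follows the reference 35/35/30%
    split of ``n_genes``.
    """
    if markers_per_type is None:
        if n_genes == N_GENES_DEFAULT:
            markers_per_type = MARKERS_PER_TYPE_DEFAULT
        else:
            markers_per_type = _type_counts(n_genes, MARKERS_PER_TYPE_DEFAULT)
    cells = generate_positions(n_cells, layout=layout, seed=seed)
    lam = sample_programs(n_genes, markers_per_type, seed=seed + 1)
    return sample_counts_truth(cells, lam, seed=seed + 2)


# ---------------------------------------------------------------------------
# spots
# ---------------------------------------------------------------------------


def make_spots(
    truth: SimulationTruth,
    diameter: float,
    pitch: float,
    counts: Optional[np.ndarray] = None,
    agg: str = "sum",
) -> SpotExpression:
    """Aggregate cell counts into grid spots.

    Spot centres form a square grid at ``pitch`` covering the cell bounding
    box; a cell is enclosed when its centroid lies strictly within
    diameter/2 of the centre.  Empty spots are dropped.  ``counts``
    overrides the aggregated matrix (e.g. dropout-perturbed counts).  With
    ``diameter <= pitch`` no cell can fall in two spots.
    """
    if diameter <= 0 or pitch <= 0:
        raise ValidationError("diameter and pitch must be positive")
    mat_cells = truth.counts if counts is None else np.asarray(counts)
    pos = truth.positions
    x0, y0 = pos.min(axis=0)
    x1, y1 = pos.max(axis=0)
    cx = np.arange(x0 + pitch / 2.0, x1 + pitch / 2.0, pitch)
    cy = np.arange(y0 + pitch / 2.0, y1 + pitch / 2.0, pitch)
    centers = np.array([(a, b) for b in cy for a in cx])
    tree = cKDTree(pos)
    radius = diameter / 2.0

    rows, ids, coords, per_spot, enclosed = [], [], [], [], []
    double = 0
    seen = np.zeros(truth.n_cells, dtype=bool)
    for s, c in enumerate(centers):
        members = tree.query_ball_point(c, radius)
        members = [m for m in members if np.linalg.norm(pos[m] - c) < radius]
        if not members:
            continue
        members = np.sort(np.asarray(members, dtype=int))
        double += int(seen[members].sum())
        seen[members] = True
        block = mat_cells[members]
        rows.append(block.mean(axis=0) if agg == "mean" else block.sum(axis=0))
        ids.append(f"spot{len(ids)}")
        coords.append(c)
        per_spot.append(len(members))
        enclosed.append(members)
    if diameter <= pitch:
        assert double == 0, "disjoint spots cannot share cells"
    if not rows:
        raise ValidationError("no spot encloses any cell")
    logger.info(
        "make_spots: %d non-empty spots (diameter=%g, pitch=%g)",
        len(rows),
        diameter,
        pitch,
    )
    return SpotExpression(
        spot_ids=np.array(ids),
        coords=np.array(coords),
        diameter=float(diameter),
        matrix=np.vstack(rows).astype(float),
        gene_ids=np.array([f"gene{g}" for g in range(mat_cells.shape[1])]),
        cells_per_spot=np.array(per_spot),
        enclosed_cells=enclosed,
    )


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------


def apply_missouts(cells: CellTable, fraction: float, seed: int = 0) -> CellTable:
    """Randomly remove floor(fraction * n) cells (spots stay untouched)."""
    if not 0.0 <= fraction < 1.0:
        raise ValidationError("missout fraction must lie in [0, 1)")
    n_drop = int(np.floor(fraction * cells.n_cells))
    if n_drop == 0:
        return cells
    rng = np.random.default_rng(seed)
    drop = rng.choice(cells.n_cells, size=n_drop, replace=False)
    keep = np.setdiff1d(np.arange(cells.n_cells), drop)
    logger.info("apply_missouts: removed %d / %d cells", n_drop, cells.n_cells)
    return cells.subset(keep)


def apply_rewiring(
    g: CellGraph, fraction: float, seed: int = 0, threshold: Optional[float] = None
) -> CellGraph:
    """Replace the KNN lists of ceil(fraction * n) cells with random cells.

    The SNN graph is recomputed afterwards, which is what makes the method
    robust: random neighbour lists share few neighbours with anyone and so
    acquire little SNN weight.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError("rewiring fraction must lie in [0, 1]")
    n, k = g.knn.shape
    n_affected = int(np.ceil(fraction * n))
    knn = g.knn.copy()
    if n_affected:
        rng = np.random.default_rng(seed)
        affected = rng.choice(n, size=n_affected, replace=False)
        for i in affected:
            pool = np.delete(np.arange(n), i)
            knn[i] = rng.choice(pool, size=k, replace=False)
        logger.info("apply_rewiring: randomized %d / %d cells", n_affected, n)
    if threshold is None:
        threshold = g.snn_threshold if g.snn_weights is not None else None
    return knn_to_snn(CellGraph(k=k, knn=knn), threshold)


def apply_dropout(
    truth: SimulationTruth, dcfg: DropoutConfig, seed: int = 0
) -> tuple[np.ndarray, float, str]:
    """Zero entries with logistic probability of the expression level.

    Returns (perturbed counts, realized zero fraction of the matrix, regime)
    where the regime classifies the zero fraction as ``low`` (<15%),
    ``moderate`` (15-40%) or ``high`` (>40%).
    """
    means = truth.cell_means()
    x = np.log(means + 1.0) if dcfg.covariate == "log" else means
    p = dropout_probability(x, dcfg)
    rng = np.random.default_rng(seed)
    dropped = rng.random(p.shape) < p
    counts = truth.counts.copy()
    counts[dropped] = 0
    zero_frac = float(np.mean(counts == 0))
    regime = "low" if zero_frac < 0.15 else ("moderate" if zero_frac <= 0.40 else "high")
    logger.info(
        "apply_dropout(mid=%g, shape=%g): zero fraction %.3f (%s)",
        dcfg.mid,
        dcfg.shape,
        zero_frac,
        regime,
    )
    return counts, zero_frac, regime
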