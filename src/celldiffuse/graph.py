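"""Combinatory feature space and the KNN -> SNN cell-cell graph.

Cells are embedded in three z-scored blocks — transcriptomic PC scores
inherited from the nearest spot, spatial coordinates, and morphological
features — and compared with the multimodal distance

    d_ij = sqrt(w_gen * d_gen^2 + w_geo * d_geo^2 + d_mor^2)

where each block distance is the Euclidean distance divided by the square
root of the block dimension, so blocks of unequal width contribute
comparably.  The k-nearest-neighbour graph under this metric is then
converted to a shared-nearest-neighbour graph whose edge weight is the
fraction of the k neighbour lists two cells have in common.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .core_io import CellTable, RunConfig, SpotExpression, ValidationError

logger = logging.getLogger("celldiffuse")


@dataclass
class FeatureSpace:
    """Per-cell feature blocks, each z-scored per column across cells."""

    gen_block: np.ndarray
    geo_block: np.ndarray
    mor_block: np.ndarray
    w_gen: float = 1.0
    w_geo: float = 1.0

    @property
    def n_cells(self) -> int:
        return self.geo_block.shape[0]

    def combined(self) -> np.ndarray:
        """Concatenated z-scored blocks (unweighted) — the 'combinatory features'."""
        blocks = [b for b in (self.gen_block, self.geo_block, self.mor_block) if b.size]
        return np.hstack(blocks)

    def weighted(self) -> np.ndarray:
        """Concatenation scaled so plain Euclidean distance on the result
        equals :func:`multimodal_distance`."""
        parts = []
        for block, w in (
            (self.gen_block, self.w_gen),
            (self.geo_block, self.w_geo),
            (self.mor_block, 1.0),
        ):
            if block.size:
                parts.append(block * np.sqrt(w / block.shape[1]))
        return np.hstack(parts)


@dataclass
class CellGraph:
    """KNN neighbour lists and the symmetric SNN weight matrix."""

    k: int
    knn: np.ndarray  # (n_cells, k) neighbour indices, self excluded
    snn_weights: Optional[sp.csr_matrix] = None
    snn_threshold: float = 0.0

    @property
    def n_cells(self) -> int:
        return self.knn.shape[0]


def log_normalize(matrix: np.ndarray, target: Optional[float] = None) -> np.ndarray:
    """Library-size normalisation to the median total, then log1p."""
    m = np.asarray(matrix, dtype=float)
    totals = m.sum(axis=1)
    if target is None:
        pos = totals[totals > 0]
        target = float(np.median(pos)) if pos.size else 1.0
    scale = np.divide(target, totals, out=np.ones_like(totals), where=totals > 0)
    return np.log1p(m * scale[:, None])


def zscore_columns(block: np.ndarray, name: str = "block") -> np.ndarray:
    """Z-score columns; zero-variance columns are dropped with a warning."""
    if block.size == 0:
        return block.reshape(block.shape[0], 0)
    mu = block.mean(axis=0)
    sd = block.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning(
            "zscore: dropped %d constant %s column(s)", int((~keep).sum()), name
        )
    if not keep.any():
        return np.zeros((block.shape[0], 0))
    return (block[:, keep] - mu[keep]) / sd[keep]


def build_feature_space(
    cells: CellTable, spots: SpotExpression, cfg: RunConfig
) -> FeatureSpace:
    """Assemble the combinatory feature space for a filtered cell table.

    The transcriptomic block is the first ``n_pcs`` principal-component
    scores of the log-normalised spot matrix, copied to each cell from its
    assigned spot; two cells sharing a spot therefore share a gen row.
    """
    if cells.spot_assignment is None or np.any(cells.spot_assignment < 0):
        raise ValidationError("every cell needs a spot assignment; filter first")
    if cfg.n_pcs >= spots.n_spots:
        raise ValidationError(
            f"n_pcs={cfg.n_pcs} must be smaller than the number of spots "
            f"({spots.n_spots})"
        )
    logn = log_normalize(spots.dense())
    pca = PCA(n_components=cfg.n_pcs, svd_solver="full")
    spot_scores = pca.fit_transform(logn)
    gen = spot_scores[cells.spot_assignment]

    mor = (
        cells.morph_features
        if cells.morph_features is not None
        else np.zeros((cells.n_cells, 0))
    )
    return FeatureSpace(
        gen_block=zscore_columns(gen, "transcriptomic"),
        geo_block=zscore_columns(cells.centroids, "geometric"),
        mor_block=zscore_columns(mor, "morphological"),
        w_gen=cfg.w_gen,
        w_geo=cfg.w_geo,
    )


def multimodal_distance(fs: FeatureSpace, i: int, j: int) -> float:
    """Weighted dimension-normalised distance between cells ``i`` and ``j``."""
    total = 0.0
    for block, w in (
        (fs.gen_block, fs.w_gen),
        (fs.geo_block, fs.w_geo),
        (fs.mor_block, 1.0),
    ):
        if block.shape[1]:
            diff = block[i] - block[j]
            total += w * float(diff @ diff) / block.shape[1]
    return float(np.sqrt(total))


def build_knn(fs: FeatureSpace, k: int, chunk: int = 512) -> CellGraph:
    """Exact k-nearest neighbours under the multimodal metric.

    Distance ties are broken toward the lower cell index; the cell itself is
    excluded.  Exhaustive chunked computation keeps the search exact.
    Squared distances are quantised at 1e-9 before the tie-break so that
    constructed equidistant configurations resolve deterministically despite
    floating-point rounding.
    """
    X = fs.weighted()
    n = X.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than the number of cells ({n})")
    sq = np.einsum("ij,ij->i", X, X)
    order = np.arange(n)
    knn = np.empty((n, k), dtype=int)
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (X[start:stop] @ X.T)
        np.maximum(d2, 0.0, out=d2)
        np.round(d2, 9, out=d2)
        for r, i in enumerate(range(start, stop)):
            row = d2[r]
            row[i] = np.inf  # exclude self
            # lexsort: primary key distance, secondary key index (stable ties)
            nearest = np.lexsort((order, row))[:k]
            knn[i] = nearest
    return CellGraph(k=k, knn=knn)


def knn_to_snn(g: CellGraph, threshold: Optional[float] = None) -> CellGraph:
    """Shared-nearest-neighbour weights w_ij = |NN(i) ∩ NN(j)| / k.

    Edges with weight below ``threshold`` are removed; the diagonal is not
    stored.  Neighbour sets exclude the cells themselves, so the overlap is
    not self-inflated.

    The default threshold is min(2, k)/k, i.e. at least two shared
    neighbours.  A single shared neighbour is not evidence of a shared
    neighbourhood: a spurious (e.g. randomised) neighbour list still
    overlaps some list somewhere by one member, so a 1/k threshold lets
    noise edges through and forfeits the noise robustness the SNN
    construction exists for.
    """
    n, k = g.knn.shape
    threshold = (min(2, k) / k) if threshold is None else float(threshold)
    rows = np.repeat(np.arange(n), k)
    cols = g.knn.ravel()
    A = sp.csr_matrix(
        (np.ones(n * k), (rows, cols)), shape=(n, n), dtype=np.float64
    )
    counts = A @ A.T  # (i, j) -> number of shared neighbours
    counts.setdiag(0)
    counts.eliminate_zeros()
    W = counts.multiply(1.0 / k).tocsr()
    if threshold > 0:
        W.data[W.data < threshold - 1e-12] = 0.0
        W.eliminate_zeros()
    return CellGraph(k=k, knn=g.knn, snn_weights=W, snn_threshold=threshold)


def apply_affinity_kernel(
    graph: CellGraph, fs: FeatureSpace, sigma: float
) -> CellGraph:
    """Optionally modulate SNN weights by exp(-d^2 / sigma^2).

    The transitions use the shared-neighbour fractions directly; this
    exponential modifier is off by default and provided for experimenting
    with distance-attenuated edges.
    """
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    if graph.snn_weights is None:
        raise ValidationError("SNN not built")
    W = graph.snn_weights.tocoo()
    d2 = np.array(
        [multimodal_distance(fs, i, j) ** 2 for i, j in zip(W.row, W.col)]
    )
    data = W.data * np.exp(-d2 / sigma**2)
    return CellGraph(
        k=graph.k,
        knn=graph.knn,
        snn_weights=sp.coo_matrix((data, (W.row, W.col)), shape=W.shape).tocsr(),
        snn_threshold=graph.snn_threshold,
    )


def n_components(graph: CellGraph) -> int:
    """Number of connected components of the SNN graph (warned if > 1)."""
    if graph.snn_weights is None:
        raise ValidationError("SNN not built")
    n, _ = sp.csgraph.connected_components(graph.snn_weights, directed=False)
    if n > 1:
        logger.warning("SNN graph has %d connected components", n)
    return n


def export_edges(graph: CellGraph, path) -> None:
    """Write the SNN graph as an edge-list CSV (i, j, w), upper triangle."""
    W = sp.triu(graph.snn_weights.tocoo())
    import pandas as pd

    pd.DataFrame({"i": W.row, "j": W.col, "w": W.data}).to_csv(path, index=False)


def import_edges(path, n_cells: int, k: int) -> CellGraph:
    """Read an adjacency edge list (i, j, w) as a symmetric SNN graph."""
    import pandas as pd

    df = pd.read_csv(path)
    W = sp.coo_matrix(
        (df["w"], (df["i"], df["j"])), shape=(n_cells, n_cells)
    )
    W = (W + W.T).tocsr()
    W.setdiag(0)
    W.eliminate_zeros()
    return CellGraph(k=k, knn=np.zeros((n_cells, 0), dtype=int), snn_weights=W)
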