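"""Per-cell morphological features from a histology image, and cell filters.

The image is used only through small square tiles centred on each nucleus
centroid; per tile and per channel we record the mean intensity, the
intensity standard deviation, and the Shannon entropy of a 256-bin histogram
of 8-bit-rescaled intensities (log base 2).  Tiles are clipped at the image
border rather than padded — padding would invent intensities.

Feature column order is fixed and documented: for channels c = 0..C-1 in
order, ``mean_c, std_c, entropy_c``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_io import CellTable, SpotExpression, ValidationError

logger = logging.getLogger("celldiffuse")


@dataclass
class TileFeatureSpec:
    """Tile geometry and histogram settings for feature extraction.

    ``radius`` is the tile half-width in pixels (tile is (2r+1) square).  The
    default radius used by :func:`default_tile_radius` is twice the mean
    nearest-centroid distance, floored at 4 px.
    """

    radius: int
    channels: Optional[list[int]] = None
    entropy_bins: int = 256

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValidationError("tile radius must be >= 1")
        if self.entropy_bins < 2:
            raise ValidationError("entropy_bins must be >= 2")


def read_image(path) -> np.ndarray:
    """Load a TIFF or PNG raster (8/16-bit, 1 or 3 channels)."""
    from pathlib import Path

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(str(path)))
    import imageio.v3 as iio

    return np.asarray(iio.imread(str(path)))


def default_tile_radius(cells: CellTable, floor: int = 4) -> int:
    """Twice the mean nearest-centroid distance, floored at ``floor`` px."""
    if cells.n_cells < 2:
        return floor
    tree = cKDTree(cells.centroids)
    d, _ = tree.query(cells.centroids, k=2)
    return max(floor, int(round(2.0 * float(np.mean(d[:, 1])))))


def nearest_spots(
    centroids: np.ndarray, spot_coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest spot index and distance per centroid; ties -> lowest index."""
    tree = cKDTree(spot_coords)
    dist, idx = tree.query(centroids)
    # resolve exact-distance ties deterministically toward the lowest index
    for i in range(len(centroids)):
        cand = tree.query_ball_point(centroids[i], dist[i] * (1 + 1e-12) + 1e-12)
        if len(cand) > 1:
            idx[i] = min(cand)
    return np.asarray(idx, dtype=int), np.asarray(dist, dtype=float)


def filter_cells_by_spots(
    cells: CellTable, spots: SpotExpression, cutoff: Optional[float] = None
) -> CellTable:
    """Drop cells whose centroid is farther than ``cutoff`` from every spot.

    The default cutoff is the spot diameter.  Kept cells are annotated with
    their nearest spot index (ties broken toward the lowest index).  The
    operation is idempotent: re-filtering an already filtered table is a
    no-op.
    """
    if spots.n_spots == 0:
        raise ValidationError("cannot filter against zero spots")
    cutoff = float(spots.diameter if cutoff is None else cutoff)
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    idx, dist = nearest_spots(cells.centroids, spots.coords)
    keep = dist <= cutoff
    out = cells.subset(np.flatnonzero(keep))
    out.spot_assignment = idx[keep]
    logger.info(
        "filter_cells_by_spots: kept %d / %d cells (cutoff=%g)",
        out.n_cells,
        cells.n_cells,
        cutoff,
    )
    return out


def remove_isolated_cells(
    cells: CellTable, min_neighbors: int, radius: float
) -> CellTable:
    """Drop cells with fewer than ``min_neighbors`` other centroids in ``radius``."""
    if radius <= 0:
        raise ValidationError("radius must be positive")
    if min_neighbors <= 0:
        return cells
    tree = cKDTree(cells.centroids)
    counts = np.array(
        [len(tree.query_ball_point(c, radius)) - 1 for c in cells.centroids]
    )
    keep = counts >= min_neighbors
    if not keep.any():
        logger.warning("remove_isolated_cells: all cells removed")
    else:
        logger.info(
            "remove_isolated_cells: dropped %d isolated cells", int((~keep).sum())
        )
    return cells.subset(np.flatnonzero(keep))


def _as_channels(image: np.ndarray) -> np.ndarray:
    """Normalise image shape to (H, W, C)."""
    img = np.asarray(image)
    if img.ndim == 2:
        return img[:, :, None]
    if img.ndim == 3:
        return img
    raise ValidationError("image must be 2D (grayscale) or 3D (multichannel)")


def _rescale_8bit(channel: np.ndarray) -> np.ndarray:
    lo, hi = float(channel.min()), float(channel.max())
    if hi <= lo:
        return np.zeros(channel.shape, dtype=np.uint8)
    return np.clip((channel - lo) * (255.0 / (hi - lo)), 0, 255).astype(np.uint8)


def _tile_entropy(tile8: np.ndarray, bins: int) -> float:
    hist, _ = np.histogram(tile8, bins=bins, range=(0, 256))
    p = hist[hist > 0] / hist.sum()
    return float(-(p * np.log2(p)).sum())


def extract_tile_features(
    image: np.ndarray, cells: CellTable, spec: TileFeatureSpec
) -> CellTable:
    """Append per-channel tile (mean, std, entropy) to ``morph_features``.

    Tiles are clipped at image borders; a cell whose tile is empty after
    clipping (centroid outside the image) is dropped with a warning.
    """
    img = _as_channels(image)
    h, w, n_ch = img.shape
    chans = spec.channels if spec.channels is not None else list(range(n_ch))
    img8 = np.stack([_rescale_8bit(img[:, :, c].astype(float)) for c in chans], axis=2)
    raw = np.stack([img[:, :, c].astype(float) for c in chans], axis=2)

    r = spec.radius
    feats = np.full((cells.n_cells, 3 * len(chans)), np.nan)
    ok = np.ones(cells.n_cells, dtype=bool)
    for i, (x, y) in enumerate(cells.centroids):
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(0, cx - r), min(w, cx + r + 1)
        y0, y1 = max(0, cy - r), min(h, cy + r + 1)
        if x0 >= x1 or y0 >= y1:
            ok[i] = False
            continue
        for ci in range(len(chans)):
            tile = raw[y0:y1, x0:x1, ci]
            tile8 = img8[y0:y1, x0:x1, ci]
            feats[i, 3 * ci] = float(tile.mean())
            feats[i, 3 * ci + 1] = float(tile.std())
            feats[i, 3 * ci + 2] = _tile_entropy(tile8, spec.entropy_bins)
    if not ok.all():
        logger.warning(
            "extract_tile_features: dropped %d cells with empty tiles",
            int((~ok).sum()),
        )
    out = cells.subset(np.flatnonzero(ok))
    new_feats = feats[ok]
    if out.morph_features is not None:
        new_feats = np.hstack([out.morph_features, new_feats])
    out.morph_features = new_feats
    return out


def load_external_cell_features(cells: CellTable, path) -> CellTable:
    """Join externally computed per-cell features (CSV keyed by cell_id).

    Cells without a matching feature row are dropped with a warning; zero
    overlap is rejected.
    """
    df = pd.read_csv(path)
    if "cell_id" not in df.columns:
        raise ValidationError("external feature table lacks 'cell_id' column")
    df = df.set_index(df["cell_id"].astype(str)).drop(columns=["cell_id"])
    ids = cells.cell_ids.astype(str)
    present = np.array([cid in df.index for cid in ids])
    if not present.any():
        raise ValidationError("no overlapping cell ids with external features")
    if not present.all():
        logger.warning(
            "load_external_cell_features: dropped %d cells without features",
            int((~present).sum()),
        )
    out = cells.subset(np.flatnonzero(present))
    feats = df.loc[ids[present]].to_numpy(dtype=float)
    if out.morph_features is not None:
        feats = np.hstack([out.morph_features, feats])
    out.morph_features = feats
    return out
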