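"""Accuracy metrics and reference baselines.

Per-gene NRMSE (RMSE divided by the ground-truth mean) is the headline
simulation metric; its median across genes summarises a run.  Cluster
separation uses the mean silhouette over repeated 3,000-cell subsamples and
the Calinski-Harabasz index, both in PCA space of z-scored genes.
Image-form comparison rasterises expression to a grayscale grid and applies
SSIM / RMSE.  The two reference baselines are nearest-spot copying and
k-nearest-neighbour smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.decomposition import PCA
from sklearn.metrics import (
    accuracy_score,
    calinski_harabasz_score,
    f1_score,
    jaccard_score,
    roc_auc_score,
    silhouette_score,
)
from skimage.metrics import structural_similarity

from .core_io import CellExpression, CellTable, SpotExpression, ValidationError
from .diffusion import initialize_from_spots
from .graph import zscore_columns

logger = logging.getLogger("celldiffuse")


@dataclass
class EvalReport:
    per_gene_nrmse: np.ndarray = field(default_factory=lambda: np.array([]))
    median_nrmse: float = np.nan
    silhouette_mean: float = np.nan
    silhouette_sd: float = np.nan
    calinski_harabasz: float = np.nan
    label_metrics: Optional[dict] = None

    def to_dict(self) -> dict:
        d = {
            "median_nrmse": self.median_nrmse,
            "silhouette_mean": self.silhouette_mean,
            "silhouette_sd": self.silhouette_sd,
            "calinski_harabasz": self.calinski_harabasz,
        }
        if self.label_metrics:
            d.update(self.label_metrics)
        return d


# ---------------------------------------------------------------------------
# NRMSE
# ---------------------------------------------------------------------------


def nrmse(pred: np.ndarray, truth: np.ndarray) -> float:
    """RMSE divided by the mean of the ground truth (one gene)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValidationError("pred and truth must have equal length")
    m = truth.mean()
    if m <= 0:
        raise ValidationError("ground-truth mean must be positive")
    return float(np.sqrt(np.mean((pred - truth) ** 2)) / m)


def per_gene_nrmse(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """NRMSE per gene (columns); genes with zero truth mean give NaN."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValidationError("pred and truth must have equal shapes")
    means = truth.mean(axis=0)
    rmse = np.sqrt(np.mean((pred - truth) ** 2, axis=0))
    out = np.full(truth.shape[1], np.nan)
    ok = means > 0
    if not ok.all():
        logger.warning("per_gene_nrmse: skipped %d zero-mean genes", int((~ok).sum()))
    out[ok] = rmse[ok] / means[ok]
    return out


def median_nrmse(pred: np.ndarray, truth: np.ndarray) -> float:
    """Median across genes of the per-gene NRMSE."""
    return float(np.nanmedian(per_gene_nrmse(pred, truth)))


def pooled_nrmse(pred: np.ndarray, truth: np.ndarray) -> float:
    """Single NRMSE over all entries (alternative summary)."""
    return nrmse(np.ravel(pred), np.ravel(truth))


def mae_vs_entropy(
    pred: np.ndarray,
    truth: np.ndarray,
    cells: CellTable,
    labels: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-cell MAE over genes, paired with the parent spot's type entropy."""
    if cells.spot_assignment is None:
        raise ValidationError("cells need spot assignments")
    labels = cells.type_labels if labels is None else labels
    if labels is None:
        raise ValidationError("type labels required for spot entropy")
    assign = cells.spot_assignment
    keep = assign >= 0
    mae = np.mean(np.abs(np.asarray(pred) - np.asarray(truth)), axis=1)
    ent = np.zeros(int(assign.max()) + 1)
    for s in np.unique(assign[keep]):
        lab = np.asarray(labels)[assign == s]
        _, counts = np.unique(lab, return_counts=True)
        p = counts / counts.sum()
        ent[s] = float(-(p * np.log(p)).sum())
    return pd.DataFrame(
        {
            "cell_id": cells.cell_ids[keep],
            "mae": mae[keep],
            "spot_entropy": ent[assign[keep]],
        }
    )


# ---------------------------------------------------------------------------
# cluster separation
# ---------------------------------------------------------------------------


def cluster_separation(
    expr: np.ndarray,
    labels: np.ndarray,
    n_subsample: int = 3000,
    n_repeats: int = 10,
    seed: int = 0,
    n_components: int = 50,
) -> tuple[float, float, float]:
    """Mean +/- sd silhouette over subsamples, and Calinski-Harabasz.

    The expression matrix is z-scored per gene and projected to at most
    ``n_components`` principal components; the silhouette is evaluated on
    ``n_repeats`` without-replacement subsamples of ``n_subsample`` cells
    (or on the full data when it is smaller).  Labels with fewer than two
    members are excluded with a warning.
    """
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    ok_labels = uniq[counts >= 2]
    if len(ok_labels) < 2:
        raise ValidationError("need at least two labels with >= 2 members")
    if len(ok_labels) < len(uniq):
        logger.warning(
            "cluster_separation: excluded %d singleton label(s)",
            len(uniq) - len(ok_labels),
        )
    keep = np.isin(labels, ok_labels)
    expr, labels = expr[keep], labels[keep]
    n = expr.shape[0]

    Z = zscore_columns(expr, "gene")
    n_comp = min(n_components, Z.shape[1], n - 1)
    emb = PCA(n_components=n_comp, svd_solver="auto", random_state=0).fit_transform(Z)

    rng = np.random.default_rng(seed)
    sils = []
    if n_subsample >= n:
        sils.append(silhouette_score(emb, labels))
    else:
        for _ in range(n_repeats):
            idx = rng.choice(n, size=n_subsample, replace=False)
            sils.append(silhouette_score(emb[idx], labels[idx]))
    ch = calinski_harabasz_score(emb, labels)
    return float(np.mean(sils)), float(np.std(sils)), float(ch)


# ---------------------------------------------------------------------------
# image-form comparison
# ---------------------------------------------------------------------------


def rasterize_expression(
    values: np.ndarray, coords: np.ndarray, pixel_size: float
) -> np.ndarray:
    """Bin per-unit values onto a grid, averaging collisions, min-max to [0,1]."""
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValidationError("coordinates must be finite")
    if pixel_size <= 0:
        raise ValidationError("pixel size must be positive")
    x0, y0 = coords.min(axis=0)
    ix = np.floor((coords[:, 0] - x0) / pixel_size).astype(int)
    iy = np.floor((coords[:, 1] - y0) / pixel_size).astype(int)
    w, h = ix.max() + 1, iy.max() + 1
    total = np.zeros((h, w))
    count = np.zeros((h, w))
    np.add.at(total, (iy, ix), values)
    np.add.at(count, (iy, ix), 1.0)
    img = np.divide(total, count, out=np.zeros_like(total), where=count > 0)
    lo, hi = img[count > 0].min(), img[count > 0].max()
    if hi > lo:
        img[count > 0] = (img[count > 0] - lo) / (hi - lo)
    else:
        img[count > 0] = 1.0
    return img


def image_similarity(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Standard SSIM (11x11 Gaussian window) and pixel RMSE."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("rasters must share a shape")
    rng = max(a.max(), b.max()) - min(a.min(), b.min())
    ssim = structural_similarity(
        a,
        b,
        win_size=11,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        data_range=rng if rng > 0 else 1.0,
    )
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    return float(ssim), rmse


def map_to_reference_cells(
    values: np.ndarray, unit_coords: np.ndarray, ref_coords: np.ndarray
) -> np.ndarray:
    """Each reference cell receives the value of its nearest source unit."""
    unit_coords = np.asarray(unit_coords, dtype=float)
    if unit_coords.shape[0] == 0:
        raise ValidationError("empty source")
    tree = cKDTree(unit_coords)
    _, idx = tree.query(np.asarray(ref_coords, dtype=float))
    return np.asarray(values)[idx]


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------


def baseline_nearest_spot(
    cells: CellTable,
    spots: SpotExpression,
    scale: str = "per_cell",
    space: str = "lognorm",
) -> CellExpression:
    """Each cell copies its nearest spot's vector (the diffusion's x0)."""
    x0 = initialize_from_spots(cells, spots, scale=scale, space=space)
    return CellExpression(cell_ids=cells.cell_ids, matrix=x0, gene_ids=spots.gene_ids)


def baseline_knn_smooth(
    cells: CellTable, x0: np.ndarray, k: int = 20
) -> CellExpression:
    """Average x0 over each cell's k spatially nearest cells (self included)."""
    n = cells.n_cells
    if k > n:
        logger.warning("baseline_knn_smooth: k=%d clamped to n=%d", k, n)
        k = n
    tree = cKDTree(cells.centroids)
    _, idx = tree.query(cells.centroids, k=k)
    idx = np.atleast_2d(idx)
    if idx.shape[1] != k:  # k == 1 returns a flat array
        idx = idx.reshape(n, k)
    smoothed = np.asarray(x0, dtype=float)[idx].mean(axis=1)
    return CellExpression(
        cell_ids=cells.cell_ids,
        matrix=smoothed,
        gene_ids=np.array([f"g{j}" for j in range(smoothed.shape[1])]),
    )


# ---------------------------------------------------------------------------
# label agreement
# ---------------------------------------------------------------------------


def majority_vote(
    cell_labels: np.ndarray, spot_assignment: np.ndarray, positive=1
) -> dict:
    """Per-spot majority label of its assigned cells; ties -> positive class."""
    out = {}
    labels = np.asarray(cell_labels)
    assign = np.asarray(spot_assignment)
    for s in np.unique(assign[assign >= 0]):
        lab = labels[assign == s]
        vals, counts = np.unique(lab, return_counts=True)
        best = counts.max()
        winners = vals[counts == best]
        out[int(s)] = positive if positive in winners else winners[0]
    return out


def label_agreement(
    pred_labels: np.ndarray,
    ref_labels: np.ndarray,
    scores: Optional[np.ndarray] = None,
) -> dict:
    """Binary accuracy, AUC (rank-based), F1, Jaccard.

    AUC requires continuous scores and a two-class reference; with a
    single-class reference it is omitted.
    """
    pred = np.asarray(pred_labels)
    ref = np.asarray(ref_labels)
    if pred.shape != ref.shape:
        raise ValidationError("label vectors must have equal length")
    out = {
        "accuracy": float(accuracy_score(ref, pred)),
        "f1": float(f1_score(ref, pred, zero_division=0.0)),
        "jaccard": float(jaccard_score(ref, pred, zero_division=0.0)),
    }
    if scores is not None:
        if len(np.unique(ref)) < 2:
            logger.warning("label_agreement: single-class reference, AUC omitted")
        else:
            out["auc"] = float(roc_auc_score(ref, np.asarray(scores)))
    return out
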