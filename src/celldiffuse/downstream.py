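"""Downstream operators on cell-level expression.

Semi-supervised ROI propagation (Pearson correlation against a seed region
in the combinatory feature space), Welch t-test differential expression
with Benjamini-Hochberg correction, bin-matched gene-set scoring, one-sided
Fisher-exact over-representation (ORA) and univariate-linear-model (ULM)
transcription-factor activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ValidationError
from .graph import FeatureSpace

logger = logging.getLogger("celldiffuse")


@dataclass
class ROISeed:
    """A curated seed region: a name and its member cell indices."""

    name: str
    member_cells: np.ndarray
    polygon: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.member_cells = np.asarray(self.member_cells, dtype=int)
        if self.member_cells.size == 0:
            raise ValidationError("ROI seed needs at least one member cell")


# ---------------------------------------------------------------------------
# ROI propagation
# ---------------------------------------------------------------------------


def propagate_roi(
    seed: ROISeed,
    fs: FeatureSpace,
    threshold: float,
    mode: str = "centroid",
) -> np.ndarray:
    """Label cells whose combinatory features correlate with the seed.

    Each cell's Pearson correlation between its combinatory feature vector
    and the seed representation (the mean seed feature vector, or in
    ``mode='max'`` the best-correlating seed cell) is compared against
    ``threshold``; seed cells are always members.  Cells with a
    zero-variance feature vector have undefined correlation and are
    excluded with a warning.
    """
    X = fs.combined()
    n = X.shape[0]
    if np.any(seed.member_cells >= n) or np.any(seed.member_cells < 0):
        raise ValidationError("seed cells outside the feature space")
    if X.shape[1] < 2:
        raise ValidationError("correlation needs at least two features")

    def _corr_against(v: np.ndarray) -> np.ndarray:
        vc = v - v.mean()
        nv = np.linalg.norm(vc)
        Xc = X - X.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Xc, axis=1)
        ok = (norms > 0) & (nv > 0)
        r = np.full(n, np.nan)
        r[ok] = (Xc[ok] @ vc) / (norms[ok] * nv)
        return r

    if mode == "centroid":
        r = _corr_against(X[seed.member_cells].mean(axis=0))
    elif mode == "max":
        rs = np.vstack([_corr_against(X[i]) for i in seed.member_cells])
        r = np.nanmax(rs, axis=0)
    else:
        raise ValidationError("mode must be 'centroid' or 'max'")

    undefined = np.isnan(r)
    if undefined.any():
        logger.warning(
            "propagate_roi: %d cells with undefined correlation excluded",
            int(undefined.sum()),
        )
    member = np.zeros(n, dtype=bool)
    member[~undefined] = r[~undefined] >= threshold
    member[seed.member_cells] = True
    return member


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def differential_expression(
    expr: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    gene_ids: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Welch t-test per gene between two cell groups.

    Fold change uses group means with a pseudocount of 1; p values get a
    Benjamini-Hochberg adjustment.  Genes with zero variance in both groups
    are reported with t = 0, p = 1.
    """
    expr = np.asarray(expr, dtype=float)
    a = expr[np.asarray(group_a, dtype=int)]
    b = expr[np.asarray(group_b, dtype=int)]
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValidationError("each group needs at least 3 cells")
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    log2fc = np.log2((a.mean(axis=0) + 1.0) / (b.mean(axis=0) + 1.0))
    p_adj = multipletests(p, method="fdr_bh")[1]
    if gene_ids is None:
        gene_ids = [f"gene{g}" for g in range(expr.shape[1])]
    return pd.DataFrame(
        {"gene": list(gene_ids), "log2fc": log2fc, "t": t, "p": p, "p_adj": p_adj}
    )


def filter_deg(
    table: pd.DataFrame, min_fold_change: float = 2.0, max_p_adj: float = 0.01
) -> pd.DataFrame:
    """Significant up-regulated genes at a fold-change / adjusted-p cut."""
    return table[
        (table["log2fc"] > np.log2(min_fold_change)) & (table["p_adj"] < max_p_adj)
    ].reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene-set score
# ---------------------------------------------------------------------------


def gene_set_score(
    expr: np.ndarray,
    signature: Sequence[int],
    n_bins: int = 25,
    control_size: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Signature mean minus bin-matched random-control mean, per cell.

    Genes are ranked by mean expression and split into ``n_bins`` bins of
    equal size; for each signature gene, ``control_size`` control genes are
    drawn from its bin (capped at the bin size).  The per-cell score is the
    mean over signature genes minus the mean over the pooled control set.
    """
    expr = np.asarray(expr, dtype=float)
    n_genes = expr.shape[1]
    signature = np.unique(np.asarray(signature, dtype=int))
    if signature.size == 0 or np.any(signature >= n_genes):
        raise ValidationError("signature must be non-empty, valid gene indices")
    means = expr.mean(axis=0)
    order = np.argsort(means, kind="stable")
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = np.minimum(
        (np.arange(n_genes) * n_bins) // max(n_genes, 1), n_bins - 1
    )
    rng = np.random.default_rng(seed)
    sig_set = set(signature.tolist())
    control: set[int] = set()
    for gsig in signature:
        pool = np.flatnonzero(bin_of == bin_of[gsig])
        pool = np.array([g for g in pool if g not in sig_set], dtype=int)
        if pool.size == 0:  # degenerate universe: the bin is all signature
            pool = np.flatnonzero(bin_of == bin_of[gsig])
        take = min(control_size, pool.size)
        control.update(rng.choice(pool, size=take, replace=False).tolist())
    ctrl = np.array(sorted(control), dtype=int)
    return expr[:, signature].mean(axis=1) - expr[:, ctrl].mean(axis=1)


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------


def ora_enrichment(
    top_genes: Sequence, gene_set: Sequence, universe: Sequence
) -> float:
    """-log10 one-sided Fisher p for the overlap of two gene sets.

    The p value is the hypergeometric upper tail of the observed overlap
    given the universe and set sizes.  An empty top set scores 0.
    """
    universe = set(universe)
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValidationError("gene set must be contained in the universe")
    top = set(top_genes) & universe
    if not top:
        return 0.0
    M, K, n = len(universe), len(gene_set), len(top)
    overlap = len(top & gene_set)
    p = float(stats.hypergeom.sf(overlap - 1, M, K, n))
    return float(-np.log10(max(p, np.finfo(float).tiny)))


def top_expressed_genes(expr_row: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Indices of the top ``fraction`` of a cell's nonzero genes by value."""
    expr_row = np.asarray(expr_row, dtype=float)
    nz = np.flatnonzero(expr_row > 0)
    if nz.size == 0:
        return nz
    n_top = max(1, int(round(fraction * nz.size)))
    order = nz[np.argsort(-expr_row[nz], kind="stable")]
    return order[:n_top]


def ora_per_cell(
    expr: np.ndarray,
    gene_set: Sequence[int],
    top_fraction: float = 0.05,
) -> np.ndarray:
    """Per-cell ORA score of one gene set against each cell's top genes."""
    expr = np.asarray(expr, dtype=float)
    universe = np.arange(expr.shape[1])
    return np.array(
        [
            ora_enrichment(top_expressed_genes(row, top_fraction), gene_set, universe)
            for row in expr
        ]
    )


# ---------------------------------------------------------------------------
# TF activity (univariate linear model)
# ---------------------------------------------------------------------------


def tf_activity_ulm(
    expr: np.ndarray, regulons: dict[str, tuple[np.ndarray, np.ndarray]]
) -> pd.DataFrame:
    """Slope t-statistic of each cell's expression regressed on TF weights.

    ``regulons`` maps a TF name to (target gene indices, weights); the
    regression design is the full-length weight vector with zeros at
    non-targets.  Positive activities indicate the TF's targets are
    coherently elevated.  Regulons with fewer than 3 targets present or a
    constant weight vector are skipped.
    """
    expr = np.asarray(expr, dtype=float)
    n_cells, n_genes = expr.shape
    out = {}
    for tf, (targets, weights) in regulons.items():
        targets = np.asarray(targets, dtype=int)
        weights = np.asarray(weights, dtype=float)
        if targets.size < 3:
            logger.warning("tf_activity_ulm: %s has < 3 targets, skipped", tf)
            continue
        w = np.zeros(n_genes)
        w[targets] = weights
        if np.std(w) == 0:
            logger.warning("tf_activity_ulm: %s weight vector constant, skipped", tf)
            continue
        wc = w - w.mean()
        ww = float(wc @ wc)
        Y = expr
        yc = Y - Y.mean(axis=1, keepdims=True)
        slope = (yc @ wc) / ww
        # residual variance of y on [1, w]; t = slope / se(slope)
        ss_tot = np.einsum("ij,ij->i", yc, yc)
        ss_reg = slope**2 * ww
        df = n_genes - 2
        sigma2 = np.maximum(ss_tot - ss_reg, 0.0) / df
        se = np.sqrt(sigma2 / ww)
        with np.errstate(divide="ignore", invalid="ignore"):
            # a perfect fit has zero residual: the statistic is unbounded
            t = np.where(se > 0, slope / se, np.sign(slope) * np.inf)
            t = np.where(slope == 0.0, 0.0, t)
        out[tf] = t
    return pd.DataFrame(out)
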