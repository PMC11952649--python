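"""Feature-preserving (anti-shrinking) Markov diffusion on the cell graph.

Spot-level expression is copied to each cell from its nearest spot and then
iteratively exchanged between connected cells.  Because plain graph
smoothing shrinks the transcriptome toward the mean, each forward smoothing
step (scale ``lambda`` in (0,1)) is followed by a reverse inflation step
(scale ``mu`` in (-1,0), |mu| marginally above lambda) — the pairing used in
Taubin-style surface smoothing — so iterated diffusion preserves expression
contrast.

Information flow is additionally biased by spot heterogeneity: cells mapped
to homogeneous spots (node weight G close to 1) broadcast their expression,
while cells in heterogeneous spots (G small) mostly receive.  The bias
enters through a sigmoid "latency" on node-weight differences.

Transition convention: matrices act on cell-expression matrices from the
left (x_{n+1} = T x_n), so row i of a transition matrix collects the
information arriving at cell i; the entry (i, j) uses the latency of the
j -> i flow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import scipy.sparse as sp

from .core_io import CellExpression, CellTable, RunConfig, SpotExpression, ValidationError
from .graph import CellGraph, FeatureSpace

logger = logging.getLogger("celldiffuse")


@dataclass
class HeterogeneityConfig:
    """How per-spot heterogeneity is measured.

    ``cv`` — mean coefficient of variation of the min-max-rescaled
    combinatory features of the spot's cells (no labels needed).
    ``entropy`` — Shannon entropy (nats) of the spot's cell-type proportions
    (requires labels).
    """

    mode: str = "cv"
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.mode not in ("cv", "entropy"):
            raise ValidationError("heterogeneity mode must be 'cv' or 'entropy'")
        if self.mode == "entropy" and self.labels is None:
            raise ValidationError("entropy heterogeneity requires cell type labels")


@dataclass
class DiffusionModel:
    """Assembled transition operators and their parameters."""

    G: np.ndarray  # per-cell node weight in (0, 1]
    S: np.ndarray  # per-spot heterogeneity
    eps: sp.csr_matrix  # row-normalised edge weights (diag = G before normalisation)
    F: sp.csr_matrix  # forward (smoothing) transition
    R: sp.csr_matrix  # reverse (inflation) transition
    T: sp.csr_matrix  # effective transition, row-normalised R @ F
    smoothing_scale: float
    inflation_scale: float
    alpha: float
    kappa: float
    n_iters: int


# ---------------------------------------------------------------------------
# heterogeneity and node weights
# ---------------------------------------------------------------------------


def spot_heterogeneity(
    cells: CellTable,
    fs: FeatureSpace,
    hcfg: Optional[HeterogeneityConfig] = None,
    n_spots: Optional[int] = None,
) -> np.ndarray:
    """Per-spot heterogeneity S of the cells assigned to each spot.

    Spots with at most one assigned cell get S = 0.  The returned array is
    indexed by spot index; spots without cells also get 0.
    """
    hcfg = hcfg or HeterogeneityConfig()
    if cells.spot_assignment is None or np.any(cells.spot_assignment < 0):
        raise ValidationError("every cell must be assigned to a spot")
    assign = cells.spot_assignment
    if n_spots is None:
        n_spots = int(assign.max()) + 1
    S = np.zeros(n_spots)

    if hcfg.mode == "entropy":
        labels = np.asarray(hcfg.labels)
        if labels.shape[0] != cells.n_cells:
            raise ValidationError("labels length != number of cells")
        for s in range(n_spots):
            lab = labels[assign == s]
            if lab.size <= 1:
                continue
            _, counts = np.unique(lab, return_counts=True)
            p = counts / counts.sum()
            S[s] = float(-(p * np.log(p)).sum())
        return S

    # cv mode: min-max rescale each combinatory feature column across all
    # cells, then average the per-column CV of each spot's cells
    X = fs.combined()
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    X01 = (X - lo) / span
    for s in range(n_spots):
        rows = X01[assign == s]
        if rows.shape[0] <= 1:
            continue
        mu = rows.mean(axis=0)
        sd = rows.std(axis=0)
        cv = np.divide(sd, mu, out=np.zeros_like(sd), where=mu > 0)
        S[s] = float(cv.mean())
    return S


def node_weights(S: np.ndarray, kappa: float) -> np.ndarray:
    """Exponential kernel G = exp(-kappa * S); homogeneous spots give G = 1."""
    if kappa <= 0:
        raise ValidationError("kappa must be positive")
    return np.exp(-kappa * np.asarray(S, dtype=float))


def latency(Gi, Gj, alpha: float):
    """Sigmoid latency of an i -> j information flow.

    L = 1 / (1 + exp(-alpha (Gi - Gj))) exceeds 0.5 exactly when the source
    i sits in a more homogeneous spot than the receiver j, so flow out of
    homogeneous spots is favoured.
    """
    if alpha < 0:
        raise ValidationError("alpha must be non-negative")
    return 1.0 / (1.0 + np.exp(-alpha * (np.asarray(Gi) - np.asarray(Gj))))


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------


def edge_weights(graph: CellGraph, G: np.ndarray, alpha: float) -> sp.csr_matrix:
    """Heterogeneity-biased edge weights, row-normalised.

    Entry (i, j), the weight of information arriving at i from j, is
    ``latency(G_j, G_i, alpha) * w_ij`` for SNN edges; the diagonal carries
    the node weight G_i.  Rows are then normalised to sum to 1 — the unique
    choice under which "probability of keeping the original expression
    = 1 - lambda" holds exactly in the forward transition.
    """
    if graph.snn_weights is None:
        raise ValidationError("SNN graph required (run knn_to_snn first)")
    G = np.asarray(G, dtype=float)
    if np.any(G <= 0) or np.any(G > 1):
        raise ValidationError("node weights must lie in (0, 1]")
    W = graph.snn_weights.tocoo()
    # source is the column j, receiver the row i
    lat = latency(G[W.col], G[W.row], alpha)
    eps = sp.coo_matrix((W.data * lat, (W.row, W.col)), shape=W.shape).tocsr()
    eps = eps + sp.diags(G)
    rowsum = np.asarray(eps.sum(axis=1)).ravel()
    assert np.all(rowsum > 0), "rows cannot vanish while G > 0"
    return sp.diags(1.0 / rowsum) @ eps


def build_transitions(
    eps: sp.csr_matrix, lam: float, mu: float
) -> tuple[sp.csr_matrix, sp.csr_matrix, sp.csr_matrix]:
    """Forward, reverse and effective transitions from row-stochastic eps.

    F = (1-lam) I + lam eps smooths; R = (1-mu) I + mu eps with mu < 0
    inflates; T = R F is re-normalised by its row sums as a numerical guard
    (analytically the rows already sum to 1).  T may contain negative
    entries — that is inherent to the inflation step and must not be
    clipped.
    """
    if not 0.0 < lam < 1.0:
        raise ValidationError("lambda must lie in (0, 1)")
    if not -1.0 < mu <= 0.0:
        raise ValidationError("mu must lie in (-1, 0]")
    if abs(mu) <= lam:
        logger.warning(
            "|mu|=%g <= lambda=%g: inflation may be insufficient", abs(mu), lam
        )
    n = eps.shape[0]
    rowsum = np.asarray(eps.sum(axis=1)).ravel()
    if not np.allclose(rowsum, 1.0, atol=1e-9):
        raise ValidationError("eps rows must sum to 1 (row-normalise first)")
    I = sp.identity(n, format="csr")
    F = ((1.0 - lam) * I + lam * eps).tocsr()
    R = ((1.0 - mu) * I + mu * eps).tocsr()
    T = (R @ F).tocsr()
    t_rowsum = np.asarray(T.sum(axis=1)).ravel()
    T = sp.diags(1.0 / t_rowsum) @ T
    return F, R, T.tocsr()


def build_diffusion_model(
    cells: CellTable,
    fs: FeatureSpace,
    graph: CellGraph,
    cfg: RunConfig,
    hcfg: Optional[HeterogeneityConfig] = None,
    n_spots: Optional[int] = None,
) -> DiffusionModel:
    """Assemble heterogeneity, node weights and transitions in one call."""
    S = spot_heterogeneity(cells, fs, hcfg, n_spots=n_spots)
    G = node_weights(S, cfg.kappa)[cells.spot_assignment]
    eps = edge_weights(graph, G, cfg.alpha)
    F, R, T = build_transitions(eps, cfg.smoothing_scale, cfg.inflation_scale)
    return DiffusionModel(
        G=G,
        S=S,
        eps=eps,
        F=F,
        R=R,
        T=T,
        smoothing_scale=cfg.smoothing_scale,
        inflation_scale=cfg.inflation_scale,
        alpha=cfg.alpha,
        kappa=cfg.kappa,
        n_iters=cfg.n_iters,
    )


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------


def initialize_from_spots(
    cells: CellTable,
    spots: SpotExpression,
    scale: str = "per_cell",
    space: str = "counts",
) -> np.ndarray:
    """Initial cell matrix x0: each cell copies its assigned spot's vector.

    ``space='lognorm'`` follows the standard preprocessing protocol: the
    spot matrix is library-size normalised to the median spot total and
    log1p-transformed before copying.  Because normalisation equalises spot
    totals, it converts the aggregate measurement to a per-cell scale
    implicitly and ``scale`` is ignored.

    In ``space='counts'`` the raw matrix is copied; ``scale='per_cell'``
    then divides each copied vector by the spot's enclosed cell count
    (falling back to the number of assigned cells), and ``'aggregate'``
    copies the raw sums.
    """
    if cells.spot_assignment is None or np.any(cells.spot_assignment < 0):
        raise ValidationError("cells must be assigned to spots")
    if space == "lognorm":
        from .graph import log_normalize

        return log_normalize(spots.dense())[cells.spot_assignment]
    if space != "counts":
        raise ValidationError("space must be 'lognorm' or 'counts'")
    x0 = spots.dense()[cells.spot_assignment].astype(float)
    if scale == "per_cell":
        if spots.cells_per_spot is not None:
            counts = np.asarray(spots.cells_per_spot, dtype=float)
        else:
            counts = np.bincount(cells.spot_assignment, minlength=spots.n_spots)
            counts = counts.astype(float)
        counts = np.maximum(counts, 1.0)
        x0 /= counts[cells.spot_assignment][:, None]
    elif scale != "aggregate":
        raise ValidationError("scale must be 'per_cell' or 'aggregate'")
    return x0


def _minmax_rescale(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Per-gene linear map of x onto the per-gene [min, max] range of ref."""
    lo, hi = x.min(axis=0), x.max(axis=0)
    rlo, rhi = ref.min(axis=0), ref.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    out = (x - lo) / span * (rhi - rlo) + rlo
    out = np.where(hi > lo, out, rlo + (rhi - rlo) / 2.0)
    return np.clip(out, rlo, rhi)


def diffuse(
    transition: Union[sp.spmatrix, np.ndarray, DiffusionModel],
    x0: np.ndarray,
    n: int,
    rescale: str = "minmax",
    rescale_ref: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Iterate x_{t+1} = T x_t for ``n`` steps and rescale per gene.

    A :class:`DiffusionModel` applies its factored form (R then F per step),
    which is sparser and equivalent to multiplying by T.  Negative
    intermediates are kept — clipping during iteration would cancel the
    inflation — and only the final matrix is rescaled (per-gene min-max onto
    the range of ``rescale_ref``, default the input x0) and clipped into
    that range.
    """
    if n < 0:
        raise ValidationError("number of diffusion steps must be >= 0")
    x = np.asarray(x0, dtype=float)
    ref = np.asarray(rescale_ref if rescale_ref is not None else x0, dtype=float)
    if isinstance(transition, DiffusionModel):
        for _ in range(n):
            x = transition.R @ (transition.F @ x)
    else:
        for _ in range(n):
            x = transition @ x
    if rescale == "minmax" and n > 0:
        x = _minmax_rescale(x, ref)
    elif rescale not in ("minmax", "none"):
        raise ValidationError("rescale must be 'minmax' or 'none'")
    return x


def sample_counts(ce: CellExpression, seed: int) -> CellExpression:
    """Optional stochastic read-off: Poisson draws at the inferred means."""
    means = ce.dense()
    if means.min() < 0:
        raise ValidationError("Poisson sampling requires non-negative means")
    rng = np.random.default_rng(seed)
    return CellExpression(
        cell_ids=ce.cell_ids,
        matrix=rng.poisson(means).astype(float),
        gene_ids=ce.gene_ids,
    )
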