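"""The reference simulation study: one battery of benchmark conditions.

Reproduces the full simulated evaluation of the method from scratch:

* unperturbed accuracy at 100 um spots (median per-gene NRMSE),
* robustness to 40% cell missouts, to 40% rewired neighbour lists, and to
  150 um spots,
* the nearest-spot and 20-NN smoothing baselines across the 25-150 um
  spot-diameter sweep,
* cluster separation (mean subsampled silhouette) of the ground truth and
  of diffusion-imputed expression under logistic dropout.

Everything operates on library-size-normalised log1p expression (spots
normalised to the median spot total; ground truth normalised to the same
target), the standard preprocessing the inference assumes.  NRMSE values
are reported against the Poisson-sampled ground-truth counts (the
noise-free means are computed alongside).
"""

from __future__ import annotations

import logging
import time
from typing import Optional

import numpy as np

from .core_io import RunConfig
from .evaluate import baseline_knn_smooth, cluster_separation, median_nrmse
from .graph import log_normalize
from .histology import nearest_spots
from .pipeline import run_benchmark, truth_matrices
from .simulate import (
    DropoutConfig,
    apply_dropout,
    apply_missouts,
    apply_rewiring,
    make_spots,
    simulate_benchmark,
)

logger = logging.getLogger("celldiffuse")

SWEEP_DIAMETERS = (25.0, 50.0, 100.0, 150.0)
DROPOUT_GRID = [(mid, shape) for mid in (1, 2, 3, 4, 5) for shape in (-1, -2, -5)]


def _pick_dropout(
    truth, lo: float, hi: float, seed: int
) -> tuple[DropoutConfig, np.ndarray, float]:
    """Grid point whose realized zero fraction falls in [lo, hi).

    Among qualifying (mid, shape) combinations the one with the highest
    realized zero fraction is taken — the hardest condition inside the
    regime — making the selection deterministic given the seed.
    """
    best = None
    for mid, shape in DROPOUT_GRID:
        dcfg = DropoutConfig(mid=mid, shape=shape)
        counts, frac, _ = apply_dropout(truth, dcfg, seed=seed)
        if lo <= frac < hi and (best is None or frac > best[2]):
            best = (dcfg, counts, frac)
    if best is None:
        raise RuntimeError(f"no dropout grid point lands in [{lo}, {hi})")
    return best


def target_battery(seed: int = 0, verbose: bool = True) -> tuple[dict, dict]:
    """Run every benchmark condition; return (targets, extras).

    ``targets`` maps short target names to ``{"value": float, "n": int}``;
    ``extras`` carries the companion quantities (means-mode NRMSE, the
    baseline sweep, dropout conditions, ordering table) for reporting.
    """
    t0 = time.perf_counter()

    def say(msg: str) -> None:
        if verbose:
            print(f"[{time.perf_counter() - t0:6.1f}s] {msg}", flush=True)

    truth = simulate_benchmark(seed=seed)
    cells_all = truth.to_cell_table()
    n = truth.n_cells
    targets: dict = {}
    extras: dict = {"seed": seed, "n_cells": n, "n_genes": truth.n_genes}

    # --- unperturbed accuracy, 100 um spots -------------------------------
    b1 = run_benchmark(truth=truth, seed=seed)
    targets["t1"] = {"value": b1.nrmse_vs_counts, "n": n}
    extras["t1_means_mode"] = b1.nrmse_vs_means
    say(
        f"unperturbed 100um: median NRMSE {b1.nrmse_vs_counts:.4f} (counts), "
        f"{b1.nrmse_vs_means:.4f} (means)"
    )

    # --- 40% cell missouts -------------------------------------------------
    b2 = run_benchmark(
        truth=truth, cells=apply_missouts(cells_all, 0.40, seed=seed + 11), seed=seed
    )
    targets["t2"] = {"value": b2.nrmse_vs_counts, "n": b2.cells.n_cells}
    extras["t2_means_mode"] = b2.nrmse_vs_means
    say(f"40% missouts: median NRMSE {b2.nrmse_vs_counts:.4f}")

    # --- 40% rewired neighbour lists ---------------------------------------
    g40 = apply_rewiring(b1.result.graph, 0.40, seed=seed + 12)
    b3 = run_benchmark(truth=truth, graph=g40, seed=seed)
    targets["t3"] = {"value": b3.nrmse_vs_counts, "n": n}
    extras["t3_means_mode"] = b3.nrmse_vs_means
    say(f"40% rewired: median NRMSE {b3.nrmse_vs_counts:.4f}")

    # --- 150 um spots -------------------------------------------------------
    b4 = run_benchmark(truth=truth, diameter=150.0, seed=seed)
    targets["t4"] = {"value": b4.nrmse_vs_counts, "n": n}
    extras["t4_means_mode"] = b4.nrmse_vs_means
    say(f"150um spots: median NRMSE {b4.nrmse_vs_counts:.4f}")

    # --- baselines across the diameter sweep -------------------------------
    thor_sweep = {100.0: b1.nrmse_vs_counts, 150.0: b4.nrmse_vs_counts}
    nearest_sweep, nearest_enclosed, knn_sweep = {}, {}, {}
    for diam in SWEEP_DIAMETERS:
        spots = make_spots(truth, diameter=diam, pitch=100.0)
        totals = spots.dense().sum(axis=1)
        target = float(np.median(totals[totals > 0]))
        idxs, dist = nearest_spots(truth.positions, spots.coords)
        x0 = log_normalize(spots.dense(), target=target)[idxs]
        tr_log, _ = truth_matrices(cells_all, truth, space="lognorm", target=target)
        nearest_sweep[diam] = median_nrmse(x0, tr_log)
        enclosed = dist < diam / 2.0
        nearest_enclosed[diam] = median_nrmse(x0[enclosed], tr_log[enclosed])
        knn_sweep[diam] = median_nrmse(
            baseline_knn_smooth(cells_all, x0, k=20).dense(), tr_log
        )
        if diam == 50.0:
            b50 = run_benchmark(truth=truth, diameter=50.0, seed=seed)
            thor_sweep[diam] = b50.nrmse_vs_counts
    targets["t5"] = {
        "value": nearest_enclosed[25.0],
        "n": int(np.sum(nearest_spots(truth.positions, make_spots(truth, 25.0, 100.0).coords)[1] < 12.5)),
    }
    targets["t6"] = {"value": float(np.median(list(knn_sweep.values()))), "n": n}
    extras["nearest_spot_sweep"] = nearest_sweep
    extras["nearest_spot_enclosed_sweep"] = nearest_enclosed
    extras["knn_smooth_sweep"] = knn_sweep
    extras["method_sweep"] = thor_sweep
    say(
        "baselines: nearest-spot 25um (enclosed) "
        f"{nearest_enclosed[25.0]:.4f}; 20-NN smoothing sweep "
        + ", ".join(f"{d:.0f}um={v:.4f}" for d, v in sorted(knn_sweep.items()))
    )
    for diam in (50.0, 100.0, 150.0):
        say(
            f"ordering at {diam:.0f}um: method {thor_sweep[diam]:.4f} vs "
            f"nearest {nearest_sweep[diam]:.4f}, 20-NN {knn_sweep[diam]:.4f}"
        )

    # --- cluster separation of the noise-free ground truth ------------------
    sil_truth, sil_sd, ch = cluster_separation(
        log_normalize(truth.counts.astype(float)), truth.types, seed=seed
    )
    targets["t7"] = {"value": sil_truth, "n": n}
    extras["t7_sd"] = sil_sd
    extras["t7_calinski_harabasz"] = ch
    say(f"ground-truth silhouette {sil_truth:.3f} +/- {sil_sd:.3f} (CH {ch:.0f})")

    # --- dropout study -------------------------------------------------------
    for tname, lo, hi in (("t8", 0.0, 0.15), ("t9", 0.15, 0.40)):
        dcfg, counts, frac = _pick_dropout(truth, lo, hi, seed=seed + 21)
        bd = run_benchmark(truth=truth, spot_counts=counts, seed=seed)
        sil_d, sd_d, _ = cluster_separation(
            bd.result.expression.dense(), bd.cells.type_labels, seed=seed
        )
        sil_raw, _, _ = cluster_separation(
            log_normalize(counts.astype(float)), truth.types, seed=seed
        )
        targets[tname] = {"value": sil_d, "n": n}
        extras[f"{tname}_condition"] = {
            "mid": dcfg.mid,
            "shape": dcfg.shape,
            "zero_fraction": frac,
        }
        extras[f"{tname}_truth_silhouette"] = sil_raw
        say(
            f"dropout mid={dcfg.mid} shape={dcfg.shape} (zeros {frac:.1%}): "
            f"imputed silhouette {sil_d:.3f} (degraded truth {sil_raw:.3f})"
        )

    say("battery complete")
    return targets, extras
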