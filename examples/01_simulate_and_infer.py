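"""Simulate a layered tissue, aggregate spots, and infer cell expression.

Builds a reduced version of the reference benchmark (2,000 cells in three
spatially layered types, 200 Poisson genes), aggregates 100 um grid spots,
runs the anti-shrinking diffusion with default parameters, and scores the
result with per-gene NRMSE against the simulated ground truth.
"""

import logging

from celldiffuse.pipeline import run_benchmark
from celldiffuse.simulate import generate_positions, sample_counts_truth, sample_programs

logging.basicConfig(level=logging.INFO, format="%(levelname)s: %(message)s")

# 2,000 cells on a 1.65 x 1.65 mm field: same density as the full benchmark
cells = generate_positions(n_cells=2000, layout="layers", seed=0, field=(1650.0, 1650.0))
lam = sample_programs(n_genes=200, markers_per_type=(70, 70, 60), seed=1)
truth = sample_counts_truth(cells, lam, seed=2)
bench = run_benchmark(truth=truth, diameter=100.0, pitch=100.0, seed=0)

print(f"\ncells: {bench.cells.n_cells}, spots: {bench.spots.n_spots}, "
      f"genes: {bench.truth.n_genes}")
print(f"median per-gene NRMSE vs sampled counts: {bench.nrmse_vs_counts:.4f}")
print(f"median per-gene NRMSE vs Poisson means:  {bench.nrmse_vs_means:.4f}")
print(
    "\nThe counts-mode NRMSE includes each cell's own Poisson sampling noise;"
    "\nthe means-mode NRMSE isolates the inference error. Values well below"
    "\n0.1 mean the diffusion recovered cell-level profiles from ~100 um"
    "\nspot aggregates."
)
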