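"""Recover clone identity from row/column pooled shotgun reads.

Clones on a 2x2 grid are sequenced as 2 row pools and 2 column pools.
Each read is then assigned to the unique grid cell whose opposite-axis
pool shares enough minimizers with it.
"""

from polysynt.pool_deconvolution import Grid, deconvolve
from polysynt.synthetic_data import (
    SimConfig,
    shear_and_pool,
    simulate_polyploid_clones,
    simulate_template,
)

cfg = SimConfig(
    n_chromosomes=4, chrom_length=30_000, insert_size_range=(18_000, 22_000),
    grid=(2, 2), coverage=24.0, read_length=500, gene_density=1 / 6_000,
    repeat_fraction_template=0.0, repeat_fraction_query=0.0,
    rearrangement_spectrum={}, expansion_bias=0.0, seed=19,
)
template, _features, truth = simulate_template(cfg)
clones = simulate_polyploid_clones(template, truth, cfg)
pools, read_truth = shear_and_pool(clones, cfg)
print("pools:", ", ".join(f"{p.pool_id} ({len(p.reads)} reads)" for p in pools))

grid = Grid(*cfg.grid)
result = deconvolve(pools, grid)
cells = {c.clone_id: grid.cell_of(i) for i, c in enumerate(clones)}
correct = sum(result.assignments.get(r) == cells[c] for r, c in read_truth.items())
print(f"assigned {len(result.assignments)}/{len(read_truth)} reads, "
      f"{len(result.ambiguous)} ambiguous, {len(result.unassigned)} unassigned")
print(f"accuracy against truth: {100 * correct / len(read_truth):.2f}%")
print()
print("With unique clone content every read intersects to a single cell;")
print("shared repeats would instead surface as 'ambiguous' and be excluded.")
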