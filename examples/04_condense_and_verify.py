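"""Condense a located collection to one mutant per gene, then verify it.

Runs a count-level simulation of a small progenitor collection, picks the
best representative for every disrupted gene (trading insertion position
against well co-occupancy), simulates re-pooling of the condensed plates, and
validates each destination well by pool-set intersection.
"""

from tnpool import (
    GridLayout,
    WellAddress,
    annotate_catalogue,
    build_table,
    generate_genome,
    pick_representatives,
    simulate_picking,
    simulate_pool_counts,
    solve_table,
    threshold_scan,
    verify_collection,
)
from tnpool.simulate import ReadCountModel
import pandas as pd

from tnpool.layout import pools_for_well

layout = GridLayout(n_rows=8, n_cols=12, n_plate_rows=2, n_plate_cols=3, n_plates=6)
genome = generate_genome(n_genes=150, seed=11)
truth = simulate_picking(
    genome, layout, n_picks=layout.n_plates * layout.usable_wells_per_plate,
    duplicate_rate=0.10, seed=12,
)
counts = simulate_pool_counts(truth, ReadCountModel(depth=20_000, crosstalk_rate=0.0),
                              seed=13)
table = build_table(counts)
t = threshold_scan(table).chosen_t
catalogue = annotate_catalogue(
    solve_table(table, t, layout, model=None).catalogue, genome.features
)

plan = pick_representatives(catalogue, genome.features)
print(f"{len(plan.plan)} loci get a representative: "
      f"{plan.n_rearray} re-arrayed from singly occupied wells, "
      f"{plan.n_colony_purify} colony purified "
      f"(2-10 colonies each, 85% success target)")

# emulate a perfect re-array/purification, re-pool the condensed plates
dest_layout = plan.destination_layout
contents = {
    WellAddress.from_label(r.destination_well): ("chr1", int(r.position))
    for r in plan.plan.itertuples(index=False)
}
rows = []
for well, (replicon, position) in contents.items():
    for p in pools_for_well(well, dest_layout):
        rows.append((replicon, position, p.axis.value, p.index, 50))
repool = (
    pd.DataFrame(rows, columns=["replicon", "position", "axis", "pool_index", "reads"])
    .groupby(["replicon", "position", "axis", "pool_index"], as_index=False)["reads"]
    .sum()
)
report = verify_collection({w: [c] for w, c in contents.items()}, repool, dest_layout)
s = report.summary
print(f"verification: {s['n_correct']}/{s['n_wells']} wells contain a predicted "
      f"mutant ({s['n_absent']} absent)")
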