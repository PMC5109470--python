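"""The four-axis pooling scheme and its address arithmetic.

Every well is dispatched to one row, one column, one plate-row and one
plate-column pool; the four pool identities jointly encode the well.
"""

from tnpool import (
    Axis,
    GridLayout,
    WellAddress,
    expected_template_ratio,
    plate_grid_position,
    pooling_operation_count,
    pools_for_well,
    well_for_pools,
)

layout = GridLayout()  # 8 x 12 plates on a 20 x 21 grid, 417 plates
print(f"{layout.n_plates} plates, {layout.pool_count} pools, "
      f"{pooling_operation_count(layout):,} pooling operations")

well = WellAddress.from_label("P394_H06")
print(f"plate 394 sits at grid position {plate_grid_position(394, layout)}")
pools = pools_for_well(well, layout)
print(f"well {well.label} feeds pools: " + ", ".join(p.name for p in pools))

coords = {p.axis: p.index for p in pools}
print(f"...and those four pools decode back to {well_for_pools(coords, layout).label}")

ratio = expected_template_ratio(Axis.COL, Axis.ROW, layout)
print(f"a mutant's expected column:row template (and read-count) ratio is "
      f"{ratio:.2f} -- column pools collect 8 wells per plate, row pools 12")
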