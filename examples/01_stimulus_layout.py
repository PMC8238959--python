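"""Build a RAN stimulus array and inspect its AOI tiling.

A run presents 36 items on a 4 x 9 grid; each item owns a rectangular area
of interest (AOI) extending to the midpoints between neighbouring items, so
the AOIs partition the grid without gaps or overlap.
"""

from ranevs import DEFAULT_SCREEN, StimulusType, aoi_at_point, build_array_layout

array = build_array_layout(StimulusType.COLOR, run_index=1)

print(f"screen: {DEFAULT_SCREEN.width_px} x {DEFAULT_SCREEN.height_px} px, "
      f"viewed at {DEFAULT_SCREEN.viewing_distance_cm} cm")
print(f"items: {array.n_rows} rows x {array.n_cols} cols "
      f"= {array.n_rows * array.n_cols} AOIs")

# serial order is row-major: item 9 starts the second row
print("item 0 label:", array.labels[0], "at",
      (round(array.centers_x[0]), round(array.centers_y[0])))
print("item 9 label:", array.labels[9], "at",
      (round(array.centers_x[9]), round(array.centers_y[9])))

# any on-grid gaze point resolves to exactly one serial index
x, y = array.centers_x[14] + 20.0, array.centers_y[14] - 10.0
print(f"gaze at ({x:.0f}, {y:.0f}) px -> item {aoi_at_point(array, x, y)}")
print("gaze off the grid ->", aoi_at_point(array, 5.0, 5.0))
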