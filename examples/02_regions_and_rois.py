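"""Turn the 81-point landmark template into 98 triangular facial regions
with centroid-centred square sampling rectangles.

The triangulation is mirror-symmetric: every region has a left/right
partner, and 38 quality-relevant meta-regions group into 6 anatomical areas
per face side, with region 20 (mid-forehead) as the timing reference.
"""

import facepulse as fp

landmarks = fp.generate_landmark_template(scale=1200.0, offset=(900.0, 1000.0),
                                          frame_size=(1800, 2000))
regions = fp.build_triangulation(landmarks)
rects = fp.build_roi_rects(regions, size=80, frame_size=(1800, 2000))

print(f"regions: {len(regions)} (non-degenerate, non-overlapping triangles)")
print(f"reference region 20 centroid: "
      f"({regions[20].centroid[0]:.0f}, {regions[20].centroid[1]:.0f}) px "
      "- the middle of the forehead")
clipped = [r.region_id for r in rects if r.clipped]
print(f"80x80 px rectangles: {len(rects)}, clipped at the frame edge: {clipped}")

mirror = fp.region_mirror_table()
print(f"mirror partner of region 20: {mirror[20]}")

table = fp.MetaRegionTable.canonical()
print(f"meta-regions: {len(table.meta_region_ids())} in "
      f"{2 * len(table.areas)} symmetric areas")
for area, pairs in table.pairs_by_area.items():
    print(f"  {area:16s} left {sorted(p[0] for p in pairs)} | "
          f"right {sorted(p[1] for p in pairs)}")
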