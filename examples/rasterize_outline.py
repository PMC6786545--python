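"""Rasterize a hand-placed point outline to a pixel mask.

An annotator's outline is an ordered list of (x, y) points; the implicitly
closed polygon is scanline-filled so that a pixel belongs to the segment
iff its center lies strictly inside (even-odd rule, half-open ties).
"""

from crowdseg import ImageGrid, OutlineRecord, Polygon, rasterize_polygon, rasterize_record

grid = ImageGrid(height=24, width=24, pixel_spacing=(0.49, 0.49))

# a rounded blob drawn with 8 clicks
blob = Polygon([(6, 4), (14, 3), (19, 8), (20, 14), (15, 20), (8, 20), (4, 15), (3, 9)])
mask = rasterize_polygon(blob, grid)
print(f"blob outline: {len(blob)} points -> {mask.area} pixels "
      f"({mask.area * 0.49 * 0.49:.1f} mm^2 at 0.49 mm/px)")

# a record may hold several regions; its mask is their union
thin = Polygon([(10, 19), (13, 19), (13, 23), (10, 23)])
record = OutlineRecord("annotator_demo", "img_demo", [blob, thin], session=1)
union = rasterize_record(record, grid)
print(f"with a second thin region: {union.area} pixels (union of both regions)")
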