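# ROI JSON schema

The native ROI dialect read and written by `bmsecq.core_io.read_roi_set` /
`write_roi_set`. One JSON object per file:

```json
{
 "schema": "bmsecq-roi",
 "version": 1,
 "rois": [
  {
   "name": "cell-z3",
   "kind": "polygon",
   "plane": 3,
   "coords": "um",
   "vertices": [[4.1, 5.0], [9.8, 4.7], [10.2, 11.3], [4.4, 11.0]]
  },
  {
   "name": "trailing",
   "kind": "polyline",
   "plane": "projection",
   "coords": "pixel",
   "line_width": 6,
   "vertices": [[120, 40], [180, 42]]
  }
 ]
}
```

Fields:

* `kind` — `"polygon"` (closed, simple, ≥ 3 vertices, area > 0; first
  vertex not repeated) or `"polyline"` (≥ 2 vertices; requires
  `line_width` > 0).
* `vertices` — ordered `[x, y]` pairs. With `"coords": "um"` (default)
  they are physical micrometres; with `"coords": "pixel"` they are
  multiplied by the `pixel_size_um` argument of `read_roi_set` (as is
  `line_width`).
* `plane` — integer z index, or `"projection"` for 2-D images and
  projections.
* Polygons are normalized to counter-clockwise vertex order on read;
  self-intersecting polygons are rejected with the ROI's name in the
  error.

ImageJ `.roi` / `.zip` files (polygon, freehand, traced, polyline,
freeline, line records) can be read with `dialect="imagej-roi"`; that
dialect is read-only and always pixel-based, so `pixel_size_um` must be
given. Writing always uses the native JSON dialect in µm.
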