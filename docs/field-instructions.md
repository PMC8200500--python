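# JSON field-parameter instructions (version 1)

`epidqa.load_field_instructions(path)` builds a `QAPlan` from a JSON
document.  Two forms exist and may not be mixed: a **parametric descriptor**
(forwarded to the matching builder, so the resulting plan is identical to
calling that builder directly) or **explicit beam tables**.

## Common keys

| key            | type   | default    | notes                                  |
|----------------|--------|------------|----------------------------------------|
| `test_type`    | string | *required* | one of `open`, `junction`, `lightrad`, `picketfence`, `dlg`, `winston_lutz`, `vmat_t1`, `vmat_t2`, `vmat_t3` |
| `energy`       | string | `"6X"`     | beam energy label                      |
| `machine_name` | string | `"LINAC1"` | treatment machine                      |

## Parametric form: `"params": { ... }`

Per test type (all lengths in mm, angles in degrees):

* `open` — `field_size_mm` `[x, y]` (default `[100, 100]`), `gantry_deg`.
* `junction` — `junction_axes` (subset of `["x", "y"]`, default both →
  four abutting quadrants), `half_size_mm` (60), `junction_error_mm`
  (signed, gap positive, |e| ≤ 10).
* `lightrad` — `field_size_mm` (`[150, 150]`), `inner_offset_mm` (5),
  `outer_offset_mm` (25).
* `picketfence` — `n_pickets` (9), `spacing_mm` (15), `gap_mm` (2),
  `leaf_offsets_mm` (scalar or one per active leaf pair; offsets move the
  delivered leaves only, expectations stay nominal).
* `dlg` — `gap_widths_mm` (list; one sweeping-gap beam per width).
* `winston_lutz` — `combos` (list of `[gantry, collimator, couch]`,
  default four cardinal gantry angles), `field_size_mm` (20).
* `vmat_t1` / `vmat_t2` / `vmat_t3` — `which` (`t1_static_dmlc`,
  `t1_rotating_picket`, `t2_doserate_gantry`, `t3_mlc_speed`; defaults per
  test type), `band_count` (T2: 7, T3: 4), `inject_mlc_errors` (bool).

Example:

```json
{"test_type": "picketfence", "params": {"n_pickets": 9, "spacing_mm": 15}}
```

## Explicit form: `"beams": [ ... ]`

Each beam: `name`, `mu` (default 100), and `control_points`, each control
point an object with required `meterset_weight` and `jaws` (`[X1, X2, Y1,
Y2]`) plus optional `gantry_deg`, `collimator_deg`, `couch_deg`, `mlc_a`,
`mlc_b` (per-leaf positions, both banks or neither).  An optional top-level
`metadata` object is copied into the plan.  Plans must satisfy the usual
invariants (≥ 2 control points, meterset from 0 to 1 non-decreasing,
`X1 ≤ X2`, `Y1 ≤ Y2`, bank A ≤ bank B); violations raise `SchemaError`
naming the failing key.

# Plain-grid sidecar image format (`epidqa-grid/1`)

A pair of files with the same stem: `<stem>.json` (header) and `<stem>.npy`
(the pixel grid, NumPy `.npy` v1, C-order float64, shape `(rows, cols)`).
Header fields:

```json
{
 "format": "epidqa-grid/1",
 "array": "<stem>.npy",
 "pixel_spacing_mm": [0.5, 0.5],
 "sid_mm": 1000.0,
 "sad_mm": 1000.0,
 "cax_pixel": [255.5, 255.5],
 "meta": {}
}
```

`pixel_spacing_mm` is `(row, col)` spacing at the detector plane;
`cax_pixel` is the fractional `(row, col)` index of the beam central axis
(grid center when omitted); `sid_mm`/`sad_mm` default to 1000.  The sidecar
round-trips `EPIDImage` objects losslessly, unlike the 16-bit DICOM
RT-Image path.
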