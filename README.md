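# epidqa

Vendor-independent toolkit for periodic linear-accelerator QA: it **builds**
the standard QA test plans as DICOM RT-Plan control-point sequences,
**renders** synthetic EPID (electronic portal imaging device) images of their
delivery with injectable errors, and **analyzes** portal images with
pass/fail evaluation — no treatment-planning-system or oncology-information-
system API required.

It is written for medical physicists and QA-software developers who want the
plan-generation and image-analysis half of linac QA as an open, scriptable
library: jaw-junction matching, light–radiation field coincidence, MLC picket
fence, Winston–Lutz, and VMAT dose-rate/gantry-speed and MLC-speed constancy,
plus a 2-D gamma evaluation.

## The test statistics

* **Jaw junction.** With `I_junc` the intensity at the match line, `I_BG` the
  background and `I_rad` the open-field reading,

      Junction = (I_junc − I_BG) / (I_rad − I_BG) − 1,

  passing within ±0.3 (a 30% change from the in-field intensity).  All four
  jaw junctions of an abutting-quadrant delivery are evaluated; the worst
  decides.
* **Light–radiation coincidence.** Eight ball bearings (BBs) sit on a
  phantom, two per field side; the inner four are nominally 5 mm inside the
  radiation edge.  BBs are detected as circular attenuation disks, the
  radiation edge as the 50% level of the background-subtracted plateau, and
  the per-BB deviation is `distance − 5 mm` (default tolerance 2 mm).
* **Picket fence.** A 2 mm DMLC slit dwells at 9 stops 15 mm apart.  For
  each leaf pair the stripe position is the sub-pixel maximum of the
  crossplane profile through that pair; the deviation is
  `expected − measured` against the plan's control points, a leaf passes
  within 1 mm, and per-gap picket spacings are reported.
* **VMAT bands.** For band `b`, the corrected reading is
  `R_b / R_open,b` (mean ROI value normalized to an open delivery to cancel
  beam shape); each band's percent difference from the mean corrected
  reading must stay within ±1.5%, and `Diff_ABS` is the mean absolute
  percent difference.
* **Gamma.** Global-normalization 2-D gamma (dose difference + distance to
  agreement, default 3%/3 mm, 10% low-dose cutoff) with sub-pixel search.

Coordinates follow IEC 61217: `x` crossplane (leaf travel), `y` inplane,
all positions in millimetres in the isocenter plane; detector pixels map
through the SAD/SID magnification.

## Worked example

```python
import numpy as np
from epidqa import (ErrorModel, analyze_picketfence, build_picketfence_plan,
                    render_picketfence_image, evaluate_tolerances)

plan = build_picketfence_plan()                       # 9 pickets, 15 mm apart
error = ErrorModel(leaf_offset_mm=1.5, noise_sigma=0.01, seed=11)
image = render_picketfence_image(plan, error=error)   # synthetic EPID delivery
result = analyze_picketfence(image, plan)
print(f"picket spacing [mm]: {np.round(result.picket_spacing_mm, 2)}")
print(f"mean leaf deviation [mm]: {np.nanmean(result.deviation_mm):.2f}")
print(f"leaves within 1 mm [%]: {result.percent_passing:.1f}")
print(f"overall: {'PASS' if evaluate_tolerances(result).passed else 'FAIL'}")
```

prints

```
picket spacing [mm]: [15.   14.99 15.01 15.   15.   15.01 14.99 15.  ]
mean leaf deviation [mm]: -1.50
leaves within 1 mm [%]: 0.0
overall: FAIL
```

The injected +1.5 mm leaf offset leaves the picket-to-picket spacing at its
nominal 15 mm (all leaves moved together) but shifts every stripe off its
expected control-point position, so the mean deviation reads −1.5 mm and no
leaf passes the 1 mm criterion.

The same flows are available from the shell:

```sh
epidqa build --test picketfence --out plan.dcm
epidqa synth --test picketfence --plan plan.dcm --leaf-offset 1.5 --noise 0.01 --out img.json
epidqa analyze --test picketfence --image img.json --plan plan.dcm --report report.json
epidqa batch --seed 1 --out sweep.json   # error-injection contingency tables
```

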