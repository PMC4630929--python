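# dirtcore

Automated trait extraction from field photographs of excavated root crowns
("shovelomics" images). From a single 2D photograph — a washed root imaged
against a dark diffuse background containing a light circular scale marker of
known diameter, with an optional identification tag above the root — the
package segments the scene, calibrates pixel size, builds the medial-axis
skeleton of the root silhouette and computes a registry of **78
root-system-architecture traits** in four families:

- **common** (31): projected area, median/maximum width, stem diameter,
  root top and bottom angle, skeleton extent, spatial distribution, and the
  cumulative width-depth profile D10…D90 with its slopes DS10…DS90;
- **monocot** (22): soil-tissue-angle and root-tip-angle statistics of
  fibrous crowns, dominant 10°-bin angles, central-path diameters;
- **dicot** (15): adventitious/basal/lateral counts and emergence angles,
  hypocotyl and taproot diameter, lateral branching frequency;
- **excised** (10): per-segment skeleton lengths, diameters and branching of
  detached root samples.

Results are written as Excel-compatible CSV (RFC 4180, `NA` for failed
traits) and RSML 1.0 XML, with a parallel batch runner that isolates
per-image failures and a synthetic-scene generator with analytic ground
truth that serves as the package's quantitative test surface.

## Method sketch

1. **Segmentation.** Global threshold *t* ∈ [0,1] (foreground iff intensity
   > *t*) followed by a single 3×3-cross binary opening; 8-connected
   components are classified by shape: the scale marker is the most circular
   component (isoperimetric quotient 4πA/P² ≥ 0.7), the tag a dense
   rectangle above the root, the root the largest remaining component.
2. **Calibration.** The marker's equivalent diameter d = 2√(A/π) together
   with its known physical diameter gives pixels per mm; without a marker
   all lengths are reported in px with a unit flag.
3. **Structure.** Exact Euclidean distance transform → topology-preserving
   thinning → skeleton graph of tips and junctions with spur pruning →
   collar (topmost tip) → minimum-arclength root-tip paths (RTPs) carrying
   per-point depth, medial radius and tangent angle.
4. **Traits.** Widths from per-row horizontal extents; angles as absolute
   degrees from horizontal in [0, 90] from total-least-squares fits to the
   side boundaries (top/bottom bands) or RTP tangents (monocot statistics);
   diameters as twice the medial radius.

## Worked example

```python
import numpy as np
from PIL import Image
import dirtcore as d

# render a protocol-compliant synthetic monocot fan (dark background,
# circular marker of 12 mm diameter, tag, fan crown) and save it as PNG
spec = d.SyntheticRootSpec(preset="monocot_fan", seed=7)
image, gt = d.render_scene(spec)
Image.fromarray((image.pixels * 255).astype(np.uint8)).save("fan_00007.png")

cfg = d.load_config(marker_diameter_mm=12.0, root_class="monocot")
result = d.process_image("fan_00007.png", cfg)
print("status:", result.status)
for tid in ("DIA_STM", "WIDTH_MED", "WIDTH_MAX", "ANG_TOP", "ANG_BTM", "RTP_COUNT"):
    print(f"{tid:12s} {result.record.numeric(tid):8.2f}")
```

prints

```
status: ok
DIA_STM          3.20
WIDTH_MED       35.04
WIDTH_MAX       76.69
ANG_TOP         72.91
ANG_BTM         65.05
RTP_COUNT        9.00
```

i.e. a 3.2 mm stem, a crown 35 mm wide at its median row and 76.7 mm at its
widest, top/bottom angles of 72.9°/65.1° from horizontal, and 9 root-tip
paths — matching the generator's analytic ground truth (16 px stem at
5 px/mm, ±25° fan, 9 strokes) to within a fraction of a millimetre/degree.

Batch use from the shell:

```bash
dirt-calibrate --image crown.png --thresholds 0.3,0.4,0.5,0.6   # pick a threshold visually
dirt-compute --input images/ --output results/ --threshold 0.5 \
             --marker-diameter 25.4 --root-class monocot --workers 4
dirt-synth --preset dicot_taproot --n 20 --seed 1 --output bench/
```

`dirt-compute` writes `traits.csv` (one row per image, 78 trait columns plus
any metadata columns), one RSML file and one mask PNG per image, and
`manifest.json` documenting the configuration and per-image status
(`ok`, `no-root`, `no-marker(px-units)`, `failed:<stage>`).

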