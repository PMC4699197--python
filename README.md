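# octenface

Semi-automated retinal layer segmentation and enface mapping for
spectral-domain optical coherence tomography (SDOCT) raster volumes, aimed
at quantifying diabetic-retinopathy pathology layer by layer.

Clinicians reading SDOCT B-scans see depth-resolved cross-sections, but the
spatial extent of pathology — cystoid macular edema, hard exudates, focal
laser scars, inner-retinal atrophy — is much easier to appreciate in the
coronal (enface / C-scan) plane, one layer at a time.  `octenface`
implements the full pipeline:

1. **Graph-based interface segmentation.**  Each B-scan becomes a graph with
   one node per pixel; an edge between vertically adjacent columns carries
   weight `w = 2 − (g_a + g_b) + w_min`, where `g` is the vertical intensity
   gradient rectified by polarity (dark→bright or bright→dark going deeper)
   and normalized to [0, 1] per B-scan, so strong transitions give small
   weights.  The minimum-weight column-monotone path (free endpoints,
   bounded step, deterministic tie-breaks) traces one interface.  Five
   interfaces — vitreous/ILM, INL/OPL, ONL/ISe, ISe/RPE, RPE/choroid — are
   found in a fixed order, each restricting the search region of the next.
   Operator corrections re-solve the path inside a narrow band around a
   drawn polyline.
2. **Enface products.**  Thickness maps (μm) and vertically averaged
   reflectance images of the total retina (TR = ILM→RPE/choroid), inner
   retina (IR = ILM→INL/OPL), outer retina (OR = INL/OPL→RPE/choroid) and
   the inner-segment-ellipsoid band (ISe = ONL/ISe→ISe/RPE).  By
   construction TR = IR + OR pixel for pixel.
3. **Normative atlases and deviation maps.**  Per-pixel mean, SD and a
   `mean ± 1.96·SD` normal interval from a control cohort; patient maps are
   classified below / within / above per pixel (blue / green / red).
4. **A seeded synthetic phantom** with layered reflectivity, foveal
   anatomy, speckle, and injectable pathologies, whose exact ground-truth
   surfaces validate every stage.

The native geometry is a Spectralis-like macular raster: 145 B-scans ×
768 A-scans, 496 depth rows at 3.9 μm, ~31 μm B-scan spacing over a 15°
square field.

## Worked example

```python
import numpy as np
from octenface import (PhantomSpec, ScanMetadata, generate_phantom,
                       segment_volume, all_enface_products, InterfaceId)

meta = ScanMetadata(n_bscans=24, n_depth=496, n_ascans=192)
vol, truth = generate_phantom(PhantomSpec(meta=meta, seed=42))
bs = segment_volume(vol)

for iid in InterfaceId:
    err = np.abs(bs[iid].rows - truth[iid].rows)[bs[iid].valid]
    print(f"{iid.value:13s} MAE {err.mean():.2f} px")

maps = all_enface_products(vol, bs)
tr = maps["TR"]["thickness"].values
cy, cx = meta.n_bscans // 2, meta.n_ascans // 2
print(f"TR thickness: fovea {tr[cy, cx]:.0f} um, parafovea {tr[cy, 24]:.0f} um")
ise = maps["ISE"]["reflectance"].values
print(f"ISe reflectance: fovea {ise[cy, cx]:.2f}, parafovea {ise[cy, 24]:.2f}")
```

prints

```
vitreous_ilm  MAE 0.31 px
inl_opl       MAE 0.44 px
onl_ise       MAE 0.27 px
ise_rpe       MAE 0.37 px
rpe_choroid   MAE 0.34 px
TR thickness: fovea 214 um, parafovea 292 um
ISe reflectance: fovea 0.73, parafovea 0.76
```

Sub-half-pixel mean boundary error under default speckle; the thickness
map shows the foveal depression (214 μm centrally vs 292 μm parafoveally).

The same pipeline runs from the shell:

```sh
octenface simulate --seed 7 --out run/
octenface segment run/volume.tiff --out run/boundaries.csv
octenface enface run/volume.tiff run/boundaries.csv --out run/maps/
octenface atlas control1.csv control2.csv ... --layer TR --out run/atlas/
octenface deviate patient_TR.csv run/atlas/ --out run/deviation
```

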