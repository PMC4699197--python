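# Methods

## Segmentation model

A B-scan is treated as a directed graph whose nodes are pixels and whose
edges connect nodes in adjacent A-scan columns with a bounded row change.
The edge weight between nodes with normalized gradients `g_a`, `g_b` is

    w = 2 − (g_a + g_b) + w_min,

the canonical gradient-based weighting for layer-boundary graph search:
weights are strictly positive and strictly decreasing in the gradient sum,
so the minimum-total-weight path across the image follows the strongest
transition of the chosen polarity.  `g` is the vertical central-difference
derivative of the (optionally Gaussian pre-smoothed) B-scan, rectified by
polarity — positive lobes for dark→bright interfaces, negated negative
lobes for bright→dark — and divided by its per-B-scan, per-polarity
maximum.  An all-zero rectified gradient stays all-zero rather than being
rescaled.

### Graph topology and solver

Paths are *column-monotone*: exactly one node per column, with
`|Δrow| ≤ max_step` between neighbours.  This guarantees a single-valued
boundary function per column, and makes exhaustive enumeration of all
feasible paths tractable on small instances, which the test suite uses as
an independent optimality oracle.  Endpoints are free: virtual zero-weight
start/end nodes attach to every admissible row of the first/last column.
The solver is a dynamic program over columns (equivalent to Dijkstra on
this layered DAG, but with a deterministic cost-to-go table): a backward
sweep computes, per node, the optimal remaining cost and — for
tie-breaking — the minimal remaining row sum among cost-optimal suffixes; a
forward sweep then picks, at each column, the topmost row consistent with
the optimum.  Among equal-cost paths this selects the smallest total row
sum, then the topmost row at the first differing column, so results are
fully reproducible.  Ties are compared by exact floating-point equality;
they arise in practice only in gradient-free (uniform) regions, where the
weights are bit-identical by construction.

### Five-interface protocol

Interfaces are found in a fixed order, each restricting the search region
of the next so the same machinery locks onto distinct transitions:

1. vitreous/ILM — dark→bright, full image (the largest dark→bright
   transition in a macular B-scan);
2. ONL/ISe — dark→bright, rows below the vitreous/ILM path;
3. RPE/choroid — bright→dark, rows below the ONL/ISe path;
4. INL/OPL — dark→bright, between vitreous/ILM and ONL/ISe;
5. ISe/RPE — bright→dark, between ONL/ISe and RPE/choroid.

The ISe/RPE polarity is a design choice: the hyper-reflective ISe band
sits above the dimmer outer-segment zone, so its lower border is a
bright→dark transition.

Restrictions are offset from the found paths: `exclude_margin = 3 px` when
restricting *below* a path and `between_margin = 3 px` on both sides of a
*between* restriction.  Both exist to keep the next search from re-detecting
the transition just found.  The between margin matters more than it might
appear: with ~1 px interface transitions and 1 px pre-smoothing the
gradient of a strong neighbouring transition decays like a Gaussian of
scale √2 px, and at 2 px it still rivals the weaker INL/OPL and ISe/RPE
peaks; 3 px suppresses it reliably while leaving the target transition
inside the band on the native depth profile.  On strongly reduced depth
profiles (≲ 250 rows) the fixed margins approach the scaled band
thicknesses and individual B-scans can become infeasible; such B-scans are
logged and marked invalid rather than aborting the volume.

### Parameters

| parameter              | default | units | role |
|------------------------|---------|-------|------|
| `w_min`                | 1e−5    | —     | strictly positive weight floor |
| `smooth_sigma`         | 1.0     | px    | speckle suppression before gradients; 0 disables |
| `max_step`             | 5       | px    | max row change per column; must exceed the steepest expected interface slope |
| `exclude_margin`       | 3       | px    | offset for "below" restrictions |
| `between_margin`       | 3       | px    | offset for "between" restrictions |
| `correction_halfwidth` | 5       | px    | half-height of the manual-correction band |

### Manual correction

Corrections enter as data (polylines of `(x, row)` vertices), not through a
GUI.  The polyline is linearly interpolated to every covered column, the
graph search region is restricted to `± correction_halfwidth` rows around
the interpolated line, and the path is re-solved there with the same
weights; columns outside the polyline's x-range are untouched.  With
half-width 0 the band has one row per column and the result is the rounded
polyline itself.  Corrected rows may be spliced into integer paths, so
boundary rows are stored as reals; the automated segmentation itself
returns integers.

## Enface products

Thickness at an enface pixel is `(lower_row − upper_row) ×
axial_um_per_px`, using raw (possibly sub-pixel) rows.  Reflectance is the
mean normalized intensity over the half-open rounded row band
`[round(upper), round(lower))` — half-open so the shared INL/OPL row is not
double-counted between IR and OR; an empty band falls back to the single
pixel at the upper row.  Averaging is done on linear normalized intensity:
log-compressed averaging would weight dark pixels differently, and linear
averaging keeps reflectance images exactly proportional under global
intensity rescaling, which the tests assert.  Validity masks propagate: a
pixel invalid in any contributing boundary is invalid in every derived
map.  No cross-B-scan smoothing of boundaries is applied before mapping.

## Normative statistics

The "95% interval" is the *population* normal range `mean ± z·SD`
(`z = Φ⁻¹(0.975) = 1.960`), with mean and sample SD (n−1) computed per
pixel over the subjects valid there.  A deviation map classifies an
individual patient map, so the interval must describe the spread of
individuals; the confidence interval of the cohort *mean* (SD/√n) is far
narrower and would flag most pixels of any healthy eye.  It remains
selectable (`interval="mean"`) for cohort-level comparisons.  Interval
endpoints classify as *within*.  Pixels valid in fewer than two subjects
are invalid.  No multiple-testing control is applied across pixels, and no
spatial registration between subjects beyond the fovea-centred acquisition;
an optional integer-pixel alignment of each map's smoothed minimum (the
foveal pit) to the grid centre is available but off by default.

Monte-Carlo check: with an atlas built from 10,000 per-pixel Gaussian
control maps and 100 fresh in-distribution maps, the pooled *within*
fraction must be 95% ± 0.5%; `scripts/acceptance.py` recomputes this (on a
48 × 48 grid whose mean surface is the phantom's true TR thickness and
SD = 12 μm, ~230k classified pixels, Monte-Carlo SE ≈ 0.07 points).

## Synthetic phantom

The phantom renders piecewise-constant reflectivity bands between smooth
interface surfaces, with Gaussian-shaped transitions of 1 px scale (so the
vertical gradient peaks exactly at the true surface depth), then applies
multiplicative unit-mean gamma speckle.  The default speckle shape 16
(σ = 0.25) approximates the residual contrast after 9-frame averaging;
fully developed single-look speckle would be exponential (shape 1), which
the phantom does not attempt.

Geometry (fractions of the depth so specs scale to reduced profiles;
pixel values quoted at the native 496-row depth): inner surface at
0.24 × depth; band thicknesses ILM→INL/OPL 30 px, INL/OPL→ONL/ISe 28 px,
ISe 8 px, ISe/RPE→choroid 10 px.  The foveal pit is a 2-D Gaussian
(σ = 1/6 of each lateral extent): the inner surface dips 22 px at the
centre while INL/OPL rises 2 px and ONL/ISe rises 3 px (the ISe thickening
term) — so the total and inner retina thin foveally while the outer retina
and ISe band thicken, matching normal macular anatomy on the derived maps.
Sub-bands not delimited by the five interfaces (dark INL, bright OPL, dim
outer-segment gap) are rendered so every interface presents the polarity
the protocol expects, with the vitreous→inner-retina step (0.02 → 0.62) the
largest positive transition and RPE→choroid (0.80 → 0.30) the largest
negative one.

Pathology injectors displace the true surfaces and/or modify intensities
inside a `cos²` footprint that is exactly 1 at the lesion centre and
exactly 0 at its radius, so displacement magnitudes are exact at the
centre and strictly local — properties the tests assert.  Cyst/edema push
the sub-INL/OPL surfaces deeper and insert hypo-reflective fluid; hard
exudates add a hyper-reflective inner-retinal blob and multiplicatively
attenuate everything beneath; laser scars move ISe/RPE toward ONL/ISe and
dim the band; vessel shadows attenuate below the inner surface; atrophy
moves the inner surface deeper.

Cohort simulation perturbs, per subject, a global axial offset (SD 3 px),
each band thickness (SD 1.2 px ≈ 4.7 μm), and the pit amplitude (SD 5%),
all from one seeded generator.  These offsets are constant across each
subject's map — between-subject anatomical variation, not measurement
noise — so cohort thickness maps are spatially smooth like real ones.

### What the phantom does and does not show

Passing the recovery tests shows the solver, protocol, restriction logic
and mapping arithmetic are correct under realistic geometry, contrast and
speckle.  It does not establish clinical accuracy: the phantom has no
motion artifacts, curvature/tilt, attenuation physics, instrument PSF, or
the irregular boundaries of severe disease — precisely the cases the
manual-correction pathway exists for.

## Problem sizes and numerical choices

The validation suite segments two full native-profile volumes
(145 × 496 × 768; one noiseless, one speckled) — about 90 s each — and uses
reduced lateral grids elsewhere.  Boundary recovery criteria: ≤ 1 px
everywhere (all five interfaces) on the noiseless native profile; mean
absolute error ≤ 2 px per interface under default speckle.  Solver
optimality is verified against exhaustive path enumeration on ≥ 100 random
instances up to 8 × 8.  The TR = IR + OR identity is exact in pixel units
(integer segmentation rows); in micrometres it holds to one ulp of the
scale factor, and tests assert both.  Intensity is normalized on load by
the integer dtype maximum; float input is taken as already normalized.
Degenerate inputs: empty search intervals raise an infeasible-region error
(caught per B-scan at volume level); an all-zero rectified gradient yields
a uniform-weight graph whose tie-break gives the topmost admissible flat
path.

## Known limitations

* Column-monotone paths cannot represent vertical or overhanging
  boundaries (max_step bounds the slope per column).
* Fixed pixel margins do not scale with depth sampling; strongly reduced
  depth profiles can make individual B-scans infeasible.
* Reflectance uses rounded row bands; sub-pixel band edges are not
  fractionally weighted.
* The normative model is unstratified (no age or axial-length adjustment)
  and assumes fovea-centred acquisition.
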