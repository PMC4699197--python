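"""Synthetic layered-retina SDOCT phantom with exported ground truth.

The phantom renders a Spectralis-like macular raster volume (by default 145
B-scans x 496 depth rows x 768 A-scans) as a stack of piecewise-constant
reflectivity bands separated by smooth interface surfaces, with:

* a foveal pit — the inner surface (vitreous/ILM) dips toward the outer
  retina at the scan centre, the inner retina thins to a few pixels, and the
  outer retina and ISe band thicken slightly, reproducing normal macular
  anatomy on the derived enface maps;
* Gaussian-shaped interface transitions (1 px scale), so that the vertical
  gradient peaks exactly at the true surface depth;
* multiplicative speckle: unit-mean gamma noise, shape ``1/sigma**2``
  (the default sigma of 0.25 corresponds to shape 16, roughly the residual
  speckle contrast after 9-frame averaging);
* injectable focal pathologies (cysts, oedema, hard exudates, laser scars,
  vessel shadows, inner-retinal atrophy) whose displacement of the true
  surfaces is exact and recorded in the returned ground truth.

Sub-bands that are not delimited by the five segmented interfaces (the dark
INL, the bright OPL, the dim outer-segment zone between ISe and RPE) are
rendered so that every segmented interface presents a transition of the
polarity the segmentation protocol expects, and the vitreous/ILM transition
is the largest dark-to-bright step in the image.

All randomness comes from one seeded generator; identical specs (including
the seed) produce bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import ndtr

from .core import (
    Boundary,
    BoundarySet,
    InterfaceId,
    OCTVolume,
    ScanMetadata,
    validate_boundary_set,
)

__all__ = [
    "LAYER_INTENSITIES",
    "PhantomSpec",
    "PathologySpec",
    "CohortVariability",
    "generate_phantom",
    "apply_pathology",
    "phantom_cohort",
]

#: Mean reflectivity (normalized intensity) of each rendered band, vitreous
#: side first.  The vitreous -> inner-retina step (0.60) is deliberately the
#: largest positive transition; RPE -> choroid (0.50) the largest negative.
LAYER_INTENSITIES: dict[str, float] = {
    "vitreous": 0.02,
    "inner_retina": 0.62,  # RNFL / GCL / IPL complex
    "inl": 0.25,
    "opl": 0.55,
    "onl": 0.18,
    "ise": 0.75,
    "outer_segments": 0.35,
    "rpe": 0.80,
    "choroid": 0.30,
}

PATHOLOGY_KINDS = ("cyst", "hard_exudate", "laser_scar", "vessel_shadow",
                   "edema", "atrophy")


@dataclass(frozen=True)
class PathologySpec:
    """A focal lesion with a smooth compact footprint.

    The footprint profile is ``cos^2(pi * d / (2 * radius))`` for grid
    distance ``d < radius`` and exactly zero outside, so every injector is
    strictly local and attains its full magnitude at the centre pixel.

    ``magnitude`` is kind-specific: added/removed thickness in micrometres
    for ``cyst``/``edema``/``laser_scar``/``atrophy``; the attenuation
    fraction in (0, 1] for ``hard_exudate`` shadowing and ``vessel_shadow``.
    """

    kind: str
    center: tuple[int, int]
    radius: float
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in PATHOLOGY_KINDS:
            raise ValueError(f"unknown pathology kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, reflectivity and noise of a synthetic volume.

    Surface depths are parameterized as fractions of ``meta.n_depth`` so the
    same spec scales to reduced test profiles.  ``pit_amp_px`` holds the
    foveal Gaussian surface displacement (positive = deeper) of the three
    inner interfaces; ``ise_thicken_px`` raises the ONL/ISe interface at the
    centre so the ISe band thickens foveally.
    """

    meta: ScanMetadata = field(default_factory=ScanMetadata)
    seed: int = 0
    speckle_sigma: float = 0.25
    ilm_frac: float = 0.24
    band_px: tuple[float, float, float, float] = (30.0, 28.0, 8.0, 10.0)
    #: (vitreous/ILM, INL/OPL, ONL/ISe) foveal displacement, px at n_depth=496
    pit_amp_px: tuple[float, float, float] = (22.0, -2.0, 0.0)
    ise_thicken_px: float = 3.0
    pit_sigma_frac: float = 1.0 / 6.0
    intensities: tuple[float, ...] = tuple(LAYER_INTENSITIES.values())
    transition_px: float = 1.0
    pathologies: tuple[PathologySpec, ...] = ()

    def __post_init__(self) -> None:
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be >= 0")
        if any(b <= 0 for b in self.band_px):
            raise ValueError("band thicknesses must be positive")
        if any(not 0 <= i <= 1 for i in self.intensities):
            raise ValueError("intensities must lie in [0, 1]")

    @property
    def depth_scale(self) -> float:
        """Pixel scale factor relative to the default 496-row profile."""
        return self.meta.n_depth / 496.0


def _pit_profile(meta: ScanMetadata, sigma_frac: float) -> np.ndarray:
    """Unit-amplitude 2-D Gaussian centred on the scan (the fovea)."""
    y = np.arange(meta.n_bscans)[:, None]
    x = np.arange(meta.n_ascans)[None, :]
    cy, cx = (meta.n_bscans - 1) / 2.0, (meta.n_ascans - 1) / 2.0
    sy, sx = sigma_frac * meta.n_bscans, sigma_frac * meta.n_ascans
    return np.exp(-0.5 * (((y - cy) / sy) ** 2 + ((x - cx) / sx) ** 2))


def true_surfaces(spec: PhantomSpec) -> dict[InterfaceId, np.ndarray]:
    """Ground-truth depth (row) of each interface on the (bscan, ascan) grid."""
    meta = spec.meta
    s = spec.depth_scale
    G = _pit_profile(meta, spec.pit_sigma_frac)
    b1, b2, b3, b4 = (b * s for b in spec.band_px)
    a_ilm, a_inl, a_onl = (a * s for a in spec.pit_amp_px)

    ilm = spec.ilm_frac * meta.n_depth + a_ilm * G
    inl = spec.ilm_frac * meta.n_depth + b1 + a_inl * G
    onl = spec.ilm_frac * meta.n_depth + b1 + b2 + (a_onl - spec.ise_thicken_px * s) * G
    ise = spec.ilm_frac * meta.n_depth + b1 + b2 + b3 + a_onl * G
    rpe = spec.ilm_frac * meta.n_depth + b1 + b2 + b3 + b4 + a_onl * G
    return {
        InterfaceId.VITREOUS_ILM: ilm,
        InterfaceId.INL_OPL: inl,
        InterfaceId.ONL_ISE: onl,
        InterfaceId.ISE_RPE: ise,
        InterfaceId.RPE_CHOROID: rpe,
    }


def _render_boundaries(
    surf: dict[InterfaceId, np.ndarray], spec: PhantomSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Sub-band transition depths and band intensities for rendering.

    Returns ``(z, I)`` where ``z`` has shape (8, n_bscans, n_ascans) — the
    ordered transition surfaces — and ``I`` the 9 band intensities.
    """
    ilm = surf[InterfaceId.VITREOUS_ILM]
    inl = surf[InterfaceId.INL_OPL]
    onl = surf[InterfaceId.ONL_ISE]
    ise = surf[InterfaceId.ISE_RPE]
    rpe = surf[InterfaceId.RPE_CHOROID]
    # Sub-bands inside the segmented bands: dark INL above the INL/OPL
    # interface, bright OPL below it, dim outer-segment zone between ISe/RPE
    # and the RPE proper.
    inl_top = inl - 0.35 * (inl - ilm)
    opl_bot = inl + np.minimum(0.30 * (onl - inl), 6.0 * spec.depth_scale)
    os_bot = ise + 0.40 * (rpe - ise)
    z = np.stack([ilm, inl_top, inl, opl_bot, onl, ise, os_bot, rpe])
    return z, np.asarray(spec.intensities, dtype=float)


def _render_volume(z: np.ndarray, I: np.ndarray, meta: ScanMetadata,
                   transition_px: float) -> np.ndarray:
    """Render smoothed piecewise-constant bands: I0 + sum dI * Phi((r-z)/s)."""
    n_b, n_d, n_a = meta.volume_shape
    depth = np.arange(n_d, dtype=float)[:, None]
    dI = np.diff(I)
    out = np.empty((n_b, n_d, n_a), dtype=np.float32)
    s = max(transition_px, 1e-6)
    for y in range(n_b):
        acc = np.full((n_d, n_a), I[0])
        for j in range(z.shape[0]):
            acc += dI[j] * ndtr((depth - z[j, y][None, :]) / s)
        out[y] = acc
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[OCTVolume, BoundarySet]:
    """Render a phantom volume and its exact ground-truth boundary set.

    Any pathologies in the spec are applied after the base rendering, in
    order.  Identical specs (same seed) yield bit-identical volumes.
    """
    surf = true_surfaces(spec)
    meta = spec.meta
    order = list(surf.values())
    for upper, lower in zip(order[:-1], order[1:]):
        if (upper >= lower).any():
            raise ValueError("phantom spec violates interface ordering")
    if order[0].min() < 1 or order[-1].max() > meta.n_depth - 2:
        raise ValueError("phantom surfaces fall outside the depth range")

    z, I = _render_boundaries(surf, spec)
    vol = _render_volume(z, I, meta, spec.transition_px)

    truth = BoundarySet(
        boundaries={iid: Boundary.full_valid(surf[iid]) for iid in InterfaceId},
        meta=meta,
    )

    rng = np.random.default_rng(spec.seed)
    octvol = OCTVolume(intensity=np.clip(vol, 0.0, 1.0), meta=meta)
    for p in spec.pathologies:
        octvol, truth = apply_pathology(octvol, truth, p)

    if spec.speckle_sigma > 0:
        shape = 1.0 / spec.speckle_sigma**2
        noise = rng.gamma(shape, 1.0 / shape, size=octvol.intensity.shape)
        noisy = np.clip(octvol.intensity * noise.astype(np.float32), 0.0, 1.0)
        octvol = OCTVolume(intensity=noisy, meta=meta)

    assert not validate_boundary_set(truth)
    return octvol, truth


def _footprint(meta: ScanMetadata, center: tuple[int, int],
               radius: float) -> np.ndarray:
    """cos^2 bump: 1 at the centre, smoothly 0 at and beyond the radius."""
    cy, cx = center
    y = np.arange(meta.n_bscans)[:, None]
    x = np.arange(meta.n_ascans)[None, :]
    d = np.hypot(y - cy, x - cx)
    prof = np.where(d < radius, np.cos(np.pi * d / (2.0 * radius)) ** 2, 0.0)
    return prof


def _shift_band_content(vol: np.ndarray, y_slice, x_mask, top, bot, value):
    """Overwrite rows in [top, bot) of masked columns with ``value``."""
    n_d = vol.shape[1]
    depth = np.arange(n_d)[:, None]
    for y in y_slice:
        m = x_mask[y]
        if not m.any():
            continue
        t = top[y][m][None, :]
        b = bot[y][m][None, :]
        band = (depth >= t) & (depth < b)
        sub = vol[y][:, m]
        sub[band] = value
        vol[y][:, m] = sub


def apply_pathology(
    vol: OCTVolume, bs: BoundarySet, p: PathologySpec
) -> tuple[OCTVolume, BoundarySet]:
    """Inject one lesion, returning modified copies of volume and truth.

    Sign conventions follow diabetic-retinopathy phenomenology: hard exudates
    are hyper-reflective in the inner retina and shadow everything beneath;
    laser scars thin the ISe band; cysts/oedema thicken the outer (or inner)
    retina and are hypo-reflective; vessel shadows attenuate all rows below
    the inner surface; atrophy thins the inner retina.
    """
    meta = vol.meta
    cy, cx = p.center
    if not (0 <= cy < meta.n_bscans and 0 <= cx < meta.n_ascans):
        raise ValueError("pathology centre outside the grid")
    prof = _footprint(meta, p.center, p.radius)
    x_mask = prof > 0
    ys = np.nonzero(x_mask.any(axis=1))[0]

    v = np.array(vol.intensity, copy=True)
    rows = {iid: np.array(bs[iid].rows, copy=True) for iid in InterfaceId}
    valid = {iid: np.array(bs[iid].valid, copy=True) for iid in InterfaceId}
    px = p.magnitude / meta.axial_um_per_px  # thickness magnitudes are um

    ilm, inl = rows[InterfaceId.VITREOUS_ILM], rows[InterfaceId.INL_OPL]
    onl, ise = rows[InterfaceId.ONL_ISE], rows[InterfaceId.ISE_RPE]
    rpe = rows[InterfaceId.RPE_CHOROID]
    dark = LAYER_INTENSITIES["vitreous"] + 0.04  # cystic fluid reflectivity

    if p.kind in ("edema", "cyst"):
        # Thicken the outer retina: boundaries below INL/OPL move deeper.
        d = px * prof
        for iid in (InterfaceId.ONL_ISE, InterfaceId.ISE_RPE,
                    InterfaceId.RPE_CHOROID):
            rows[iid] += d
        if rows[InterfaceId.RPE_CHOROID].max() > meta.n_depth - 2:
            raise ValueError("lesion magnitude pushes surfaces out of range")
        # Hypo-reflective fluid fills the stretched ONL region.
        if p.kind == "cyst":
            _shift_band_content(v, ys, x_mask & (prof > 0.3),
                                inl + 0.3 * (onl - inl), rows[InterfaceId.ONL_ISE] - 1,
                                dark)
        else:
            _shift_band_content(v, ys, x_mask & (prof > 0.3),
                                onl - d, rows[InterfaceId.ONL_ISE] - 1, dark)
    elif p.kind == "hard_exudate":
        # Hyper-reflective blob in the inner retina, shadowing all deeper rows.
        blob_top = ilm + 0.3 * (inl - ilm)
        blob_bot = ilm + 0.8 * (inl - ilm)
        for y in ys:
            m = x_mask[y]
            dcol = np.arange(meta.n_depth)[:, None]
            in_blob = (dcol >= blob_top[y][m]) & (dcol < blob_bot[y][m])
            sub = v[y][:, m]
            bright = 0.95 * prof[y][m] + sub * (1 - prof[y][m])
            sub = np.where(in_blob, np.maximum(sub, bright), sub)
            below = dcol >= blob_bot[y][m]
            atten = 1.0 - p.magnitude * prof[y][m]
            sub = np.where(below, sub * atten, sub)
            v[y][:, m] = sub
    elif p.kind == "laser_scar":
        # ISe/RPE moves up toward ONL/ISe: the ISe band thins by `magnitude`.
        d = px * prof
        new_ise = ise - d
        if ((new_ise - onl) <= 0.5).any():
            raise ValueError("laser scar magnitude collapses the ISe band")
        _shift_band_content(v, ys, x_mask, new_ise, ise,
                            LAYER_INTENSITIES["outer_segments"])
        rows[InterfaceId.ISE_RPE] = new_ise
        # Residual scar: dim the remaining ISe band locally.
        for y in ys:
            m = x_mask[y] & (prof[y] > 0.2)
            if not m.any():
                continue
            dcol = np.arange(meta.n_depth)[:, None]
            band = (dcol >= onl[y][m]) & (dcol < new_ise[y][m])
            sub = v[y][:, m]
            sub = np.where(band, sub * (1 - 0.4 * prof[y][m]), sub)
            v[y][:, m] = sub
    elif p.kind == "vessel_shadow":
        # Columnar attenuation of everything below the inner surface.
        for y in ys:
            m = x_mask[y]
            dcol = np.arange(meta.n_depth)[:, None]
            below = dcol >= (ilm[y][m] + 2)
            sub = v[y][:, m]
            sub = np.where(below, sub * (1 - p.magnitude * prof[y][m]), sub)
            v[y][:, m] = sub
    elif p.kind == "atrophy":
        # Inner retina thins: the inner surface recedes toward INL/OPL.
        d = px * prof
        new_ilm = ilm + d
        if ((inl - new_ilm) <= 0.5).any():
            raise ValueError("atrophy magnitude collapses the inner retina")
        _shift_band_content(v, ys, x_mask, ilm, new_ilm,
                            LAYER_INTENSITIES["vitreous"])
        rows[InterfaceId.VITREOUS_ILM] = new_ilm

    out_bs = BoundarySet(
        boundaries={iid: Boundary(rows=rows[iid], valid=valid[iid])
                    for iid in InterfaceId},
        meta=meta,
    )
    if validate_boundary_set(out_bs):
        raise ValueError("pathology magnitude violates interface ordering")
    return OCTVolume(intensity=np.clip(v, 0.0, 1.0), meta=meta), out_bs


@dataclass(frozen=True)
class CohortVariability:
    """Between-subject Gaussian perturbations of the default phantom spec.

    ``depth_shift_px``: SD of a global axial offset of all surfaces;
    ``band_px``: SD added independently to each of the four band thicknesses
    (constant over the map for a given subject);
    ``pit_rel``: SD of a multiplicative perturbation of the pit amplitudes.
    Defaults are realistic between-eye anatomical variation at 3.9 um/px
    (band SD 1.2 px ~ 4.7 um per band).
    """

    depth_shift_px: float = 3.0
    band_px: float = 1.2
    pit_rel: float = 0.05


def phantom_cohort(
    n: int,
    variability: CohortVariability = CohortVariability(),
    seed: int = 0,
    base: PhantomSpec | None = None,
) -> list[tuple[OCTVolume, BoundarySet]]:
    """Simulate a cohort of healthy-eye phantoms with anatomical variability.

    Per-subject surface parameters are Gaussian perturbations of the base
    spec; each subject also gets an independent speckle stream.  Seeded and
    reproducible.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    base = base or PhantomSpec()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        shift = rng.normal(0.0, variability.depth_shift_px) / base.depth_scale
        bands = tuple(
            max(b + rng.normal(0.0, variability.band_px) / base.depth_scale, 1.0)
            for b in base.band_px
        )
        pit_scale = 1.0 + rng.normal(0.0, variability.pit_rel)
        amps = tuple(a * pit_scale for a in base.pit_amp_px)
        spec = replace(
            base,
            seed=int(rng.integers(0, 2**31 - 1)),
            ilm_frac=base.ilm_frac + shift * base.depth_scale / base.meta.n_depth,
            band_px=bands,
            pit_amp_px=amps,
        )
        out.append(generate_phantom(spec))
    return out
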