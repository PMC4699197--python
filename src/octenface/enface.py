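"""Enface (C-scan plane) thickness maps and reflectance images.

Each segmented layer is the slab between two of the five interfaces:

======  ==================  ==================
layer   upper interface     lower interface
======  ==================  ==================
TR      vitreous/ILM        RPE/choroid
IR      vitreous/ILM        INL/OPL
OR      INL/OPL             RPE/choroid
ISE     ONL/ISe             ISe/RPE
======  ==================  ==================

Thickness at an enface pixel is the depth separation of the two interfaces
converted to micrometres; because IR and OR share the INL/OPL interface,
TR = IR + OR holds identically.  Reflectance is the mean normalized
intensity over the half-open row band ``[round(upper), round(lower))`` of
that A-scan — half-open so the shared interface row is not double-counted
between IR and OR; a degenerate (empty) band falls back to the single pixel
at the upper row.  Each B-scan contributes exactly one row of the enface
image.  Thickness uses the raw (possibly sub-pixel) boundary rows;
reflectance uses rounded rows.  Averaging is done on linear normalized
intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BoundarySet, EnfaceMap, InterfaceId, OCTVolume, ShapeError

__all__ = [
    "LayerDefinition",
    "LAYER_DEFINITIONS",
    "thickness_map",
    "reflectance_image",
    "all_enface_products",
]


@dataclass(frozen=True)
class LayerDefinition:
    """A named retinal slab bounded by two interfaces."""

    tag: str
    upper: InterfaceId
    lower: InterfaceId


LAYER_DEFINITIONS: dict[str, LayerDefinition] = {
    "TR": LayerDefinition("TR", InterfaceId.VITREOUS_ILM, InterfaceId.RPE_CHOROID),
    "IR": LayerDefinition("IR", InterfaceId.VITREOUS_ILM, InterfaceId.INL_OPL),
    "OR": LayerDefinition("OR", InterfaceId.INL_OPL, InterfaceId.RPE_CHOROID),
    "ISE": LayerDefinition("ISE", InterfaceId.ONL_ISE, InterfaceId.ISE_RPE),
}


def _lookup(layer: "LayerDefinition | str") -> LayerDefinition:
    if isinstance(layer, LayerDefinition):
        return layer
    try:
        return LAYER_DEFINITIONS[layer]
    except KeyError:
        raise ValueError(
            f"unknown layer {layer!r}; expected one of {list(LAYER_DEFINITIONS)}"
        ) from None


def thickness_map(
    bs: BoundarySet,
    layer: "LayerDefinition | str",
    axial_um_per_px: float | None = None,
) -> EnfaceMap:
    """Depth separation of a layer's two interfaces, in micrometres.

    A pixel is valid iff both interfaces are valid there.
    """
    ld = _lookup(layer)
    if axial_um_per_px is None:
        axial_um_per_px = bs.meta.axial_um_per_px
    upper, lower = bs[ld.upper], bs[ld.lower]
    valid = upper.valid & lower.valid
    values = np.where(valid, (lower.rows - upper.rows) * axial_um_per_px, 0.0)
    return EnfaceMap(values=values, kind="thickness_um", layer=ld.tag, valid=valid)


def reflectance_image(
    vol: OCTVolume,
    bs: BoundarySet,
    layer: "LayerDefinition | str",
) -> EnfaceMap:
    """Mean intensity over the layer's row band, per (bscan, ascan) pixel."""
    ld = _lookup(layer)
    if vol.meta.grid_shape != bs.meta.grid_shape:
        raise ShapeError("volume and boundary set are on different grids")
    n_depth = vol.meta.n_depth
    upper, lower = bs[ld.upper], bs[ld.lower]
    valid = upper.valid & lower.valid

    up = np.round(upper.rows).astype(int)
    lo = np.round(lower.rows).astype(int)
    if valid.any():
        if up[valid].min() < 0 or lo[valid].max() > n_depth:
            raise ValueError("rounded layer band falls outside the depth range")

    up_c = np.clip(up, 0, n_depth - 1)
    lo_c = np.clip(lo, 0, n_depth)
    # cumulative sum along depth with a leading zero: csum[z] = sum(rows < z)
    csum = np.zeros((vol.meta.n_bscans, n_depth + 1, vol.meta.n_ascans))
    np.cumsum(vol.intensity, axis=1, out=csum[:, 1:, :])
    take = lambda idx: np.take_along_axis(csum, idx[:, None, :], axis=1)[:, 0, :]
    band = (lo_c - up_c).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (take(lo_c) - take(up_c)) / band
    # degenerate band: the single pixel at the (rounded) upper row
    single = np.take_along_axis(vol.intensity, up_c[:, None, :], axis=1)[:, 0, :]
    values = np.where(band > 0, mean, single)
    values = np.where(valid, values, 0.0)
    return EnfaceMap(values=values, kind="reflectance", layer=ld.tag, valid=valid)


def all_enface_products(
    vol: OCTVolume, bs: BoundarySet
) -> dict[str, dict[str, EnfaceMap]]:
    """The four thickness maps and four reflectance images.

    Returns ``{layer: {"thickness": EnfaceMap, "reflectance": EnfaceMap}}``
    for TR, IR, OR and ISE; all grids are (n_bscans, n_ascans).
    """
    out: dict[str, dict[str, EnfaceMap]] = {}
    for tag, ld in LAYER_DEFINITIONS.items():
        out[tag] = {
            "thickness": thickness_map(bs, ld),
            "reflectance": reflectance_image(vol, bs, ld),
        }
    return out
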