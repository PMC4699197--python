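"""Shared data model for SDOCT volumes, layer boundaries and enface maps.

Coordinate conventions used throughout the package:

* ``y`` — B-scan index (slow raster axis), 0-based;
* ``z`` — depth row within a B-scan, 0-based, row 0 on the vitreous (inner)
  side;
* ``x`` — A-scan index within a B-scan, 0-based.

An :class:`OCTVolume` is therefore indexed ``intensity[y, z, x]``.  Boundary
rows are stored as real numbers in pixel units (sub-pixel values are allowed,
e.g. after manual correction); the automated segmentation itself returns
integer rows.  Invalid pixels are carried by explicit boolean validity masks,
never by sentinel values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple

import numpy as np

__all__ = [
    "OCTError",
    "ShapeError",
    "FormatError",
    "ConfigError",
    "InfeasibleRegionError",
    "ScanMetadata",
    "OCTVolume",
    "InterfaceId",
    "INTERFACE_ORDER",
    "Boundary",
    "BoundarySet",
    "EnfaceMap",
    "MAP_KINDS",
    "LAYER_TAGS",
    "OrderingViolation",
    "validate_boundary_set",
]


class OCTError(Exception):
    """Base class for errors raised by this package."""


class ShapeError(OCTError, ValueError):
    """Arrays that must share a grid do not."""


class FormatError(OCTError, ValueError):
    """An on-disk file does not match its declared format."""


class ConfigError(OCTError, ValueError):
    """Invalid or missing configuration."""


class InfeasibleRegionError(OCTError, ValueError):
    """A graph search region has no admissible row for some column."""


@dataclass(frozen=True)
class ScanMetadata:
    """Acquisition geometry of a raster SDOCT volume scan.

    The defaults describe a Spectralis-like high-density macular raster:
    145 horizontal B-scans of 768 A-scans each, 3.9 um axial sampling,
    ~31 um B-scan spacing over a 15 degree square field, 9 frames averaged
    per B-scan location.
    """

    n_bscans: int = 145
    n_ascans: int = 768
    n_depth: int = 496
    axial_um_per_px: float = 3.9
    bscan_spacing_um: float = 31.0
    field_deg: float = 15.0
    frames_averaged: int = 9

    def __post_init__(self) -> None:
        for name in ("n_bscans", "n_ascans", "n_depth", "frames_averaged"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        if not self.axial_um_per_px > 0:
            raise ConfigError("axial_um_per_px must be positive")
        if not self.bscan_spacing_um > 0 or not self.field_deg > 0:
            raise ConfigError("bscan_spacing_um and field_deg must be positive")

    @property
    def grid_shape(self) -> tuple[int, int]:
        """Shape of every enface product: (n_bscans, n_ascans)."""
        return (self.n_bscans, self.n_ascans)

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return (self.n_bscans, self.n_depth, self.n_ascans)

    def to_dict(self) -> dict:
        return {
            "n_bscans": self.n_bscans,
            "n_ascans": self.n_ascans,
            "n_depth": self.n_depth,
            "axial_um_per_px": self.axial_um_per_px,
            "bscan_spacing_um": self.bscan_spacing_um,
            "field_deg": self.field_deg,
            "frames_averaged": self.frames_averaged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanMetadata":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown ScanMetadata keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class OCTVolume:
    """A raster SDOCT volume: intensity[y, z, x] normalized to [0, 1]."""

    intensity: np.ndarray
    meta: ScanMetadata

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ShapeError("intensity must be a 3-D array (bscan, depth, ascan)")
        if self.intensity.shape != self.meta.volume_shape:
            raise ShapeError(
                f"intensity shape {self.intensity.shape} does not match metadata "
                f"{self.meta.volume_shape}"
            )
        lo = float(self.intensity.min())
        hi = float(self.intensity.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"intensity must lie in [0, 1], found range [{lo}, {hi}]")

    @property
    def n_bscans(self) -> int:
        return self.meta.n_bscans

    def bscan(self, y: int) -> np.ndarray:
        """The 2-D (depth x ascan) image of B-scan ``y``."""
        return self.intensity[y]


class InterfaceId(Enum):
    """The five segmented retinal interfaces, in anatomical depth order."""

    VITREOUS_ILM = "vitreous_ilm"
    INL_OPL = "inl_opl"
    ONL_ISE = "onl_ise"
    ISE_RPE = "ise_rpe"
    RPE_CHOROID = "rpe_choroid"


#: Anatomical depth order, vitreous side first.
INTERFACE_ORDER: tuple[InterfaceId, ...] = (
    InterfaceId.VITREOUS_ILM,
    InterfaceId.INL_OPL,
    InterfaceId.ONL_ISE,
    InterfaceId.ISE_RPE,
    InterfaceId.RPE_CHOROID,
)

MAP_KINDS = ("thickness_um", "reflectance")
LAYER_TAGS = ("TR", "IR", "OR", "ISE")


@dataclass
class Boundary:
    """Depth-row values of one interface on the (bscan, ascan) grid."""

    rows: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.rows.ndim != 2:
            raise ShapeError("boundary rows must be 2-D (bscan, ascan)")
        if self.valid.shape != self.rows.shape:
            raise ShapeError("validity mask shape must match rows")

    @classmethod
    def full_valid(cls, rows: np.ndarray) -> "Boundary":
        rows = np.asarray(rows, dtype=float)
        return cls(rows=rows, valid=np.ones(rows.shape, dtype=bool))


@dataclass
class BoundarySet:
    """One :class:`Boundary` per interface, on a common grid."""

    boundaries: dict[InterfaceId, Boundary]
    meta: ScanMetadata

    def __post_init__(self) -> None:
        missing = set(INTERFACE_ORDER) - set(self.boundaries)
        if missing:
            raise ValueError(f"missing interfaces: {sorted(i.value for i in missing)}")
        shape = self.meta.grid_shape
        for iid, b in self.boundaries.items():
            if b.rows.shape != shape:
                raise ShapeError(
                    f"boundary {iid.value} has shape {b.rows.shape}, expected {shape}"
                )
            rows = b.rows[b.valid]
            if rows.size and (rows.min() < 0 or rows.max() > self.meta.n_depth - 1):
                raise ValueError(
                    f"boundary {iid.value} has valid rows outside "
                    f"[0, {self.meta.n_depth - 1}]"
                )

    def __getitem__(self, iid: InterfaceId) -> Boundary:
        return self.boundaries[iid]

    @property
    def joint_valid(self) -> np.ndarray:
        """Pixels where all five interfaces are valid."""
        v = np.ones(self.meta.grid_shape, dtype=bool)
        for b in self.boundaries.values():
            v &= b.valid
        return v


@dataclass
class EnfaceMap:
    """An enface (C-scan plane) product: one value per (bscan, ascan) pixel.

    ``kind`` is ``"thickness_um"`` (values >= 0, micrometres) or
    ``"reflectance"`` (mean normalized intensity in [0, 1]).  ``layer`` is one
    of TR / IR / OR / ISE.
    """

    values: np.ndarray
    kind: str
    layer: str
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.ndim != 2:
            raise ShapeError("enface values must be 2-D (bscan, ascan)")
        if self.valid.shape != self.values.shape:
            raise ShapeError("validity mask shape must match values")
        if self.kind not in MAP_KINDS:
            raise ValueError(f"kind must be one of {MAP_KINDS}, got {self.kind!r}")
        if self.layer not in LAYER_TAGS:
            raise ValueError(f"layer must be one of {LAYER_TAGS}, got {self.layer!r}")
        vals = self.values[self.valid]
        if vals.size:
            if self.kind == "thickness_um" and vals.min() < 0:
                raise ValueError("thickness values must be >= 0")
            if self.kind == "reflectance" and (vals.min() < 0 or vals.max() > 1):
                raise ValueError("reflectance values must lie in [0, 1]")


class OrderingViolation(NamedTuple):
    """A pixel where two anatomically ordered interfaces cross."""

    upper: InterfaceId
    lower: InterfaceId
    bscan: int
    ascan: int


def validate_boundary_set(bs: BoundarySet) -> list[OrderingViolation]:
    """Check the anatomical depth-ordering invariant of a boundary set.

    At every pixel where both members of a consecutive interface pair are
    valid, the shallower interface must not lie below the deeper one
    (``rows_upper <= rows_lower``).  Returns one record per violating
    (interface pair, bscan, ascan); an empty list means the invariant holds.
    """
    shape = bs.meta.grid_shape
    for b in bs.boundaries.values():
        if b.rows.shape != shape:
            raise ShapeError("boundaries are not on a common grid")
    violations: list[OrderingViolation] = []
    for upper, lower in zip(INTERFACE_ORDER[:-1], INTERFACE_ORDER[1:]):
        bu, bl = bs[upper], bs[lower]
        both = bu.valid & bl.valid
        bad = both & (bu.rows > bl.rows)
        for y, x in zip(*np.nonzero(bad)):
            violations.append(OrderingViolation(upper, lower, int(y), int(x)))
    return violations
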