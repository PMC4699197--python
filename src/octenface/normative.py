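"""Normative thickness atlases and tri-level deviation maps.

A normative atlas summarizes a control cohort's thickness maps per enface
pixel: mean, sample SD (n-1 denominator), and a normal-range interval

    mean +/- z * SD,   z = Phi^-1((1 + coverage) / 2)

(z = 1.960 for the default 95% coverage).  This is the *population* interval
— the range expected to contain a fraction ``coverage`` of healthy
individual eyes — which is what classifying a single patient map requires.
The narrower confidence interval of the cohort mean (SD replaced by
SD/sqrt(n)) is selectable with ``interval="mean"``.

A deviation map labels each valid patient pixel below / within / above the
atlas interval (interval endpoints inclusive, so boundary ties classify as
within), with the conventional palette blue / green / red and gray for
invalid pixels.

No spatial registration is applied between subjects: scans are assumed
fovea-centred on a common grid.  An optional integer-pixel translation that
aligns each map's (smoothed) minimum — the foveal pit — to the grid centre
is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .core import EnfaceMap, ShapeError

__all__ = [
    "NormativeAtlas",
    "DeviationLabel",
    "DeviationMap",
    "PALETTE",
    "build_atlas",
    "deviation_map",
    "coverage_check",
    "simulate_gaussian_maps",
]


class DeviationLabel(IntEnum):
    BELOW = 0
    WITHIN = 1
    ABOVE = 2
    INVALID = 3


#: Render palette (RGB) for deviation maps.
PALETTE: dict[DeviationLabel, tuple[int, int, int]] = {
    DeviationLabel.BELOW: (0, 0, 255),
    DeviationLabel.WITHIN: (0, 255, 0),
    DeviationLabel.ABOVE: (255, 0, 0),
    DeviationLabel.INVALID: (128, 128, 128),
}


@dataclass
class NormativeAtlas:
    """Per-pixel normal statistics of a control cohort's thickness maps."""

    mean: np.ndarray
    sd: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    valid: np.ndarray
    n_subjects: int
    coverage: float
    layer: str

    def __post_init__(self) -> None:
        shape = self.mean.shape
        for name in ("sd", "lower", "upper", "valid"):
            if getattr(self, name).shape != shape:
                raise ShapeError(f"atlas field {name} shape mismatch")
        if self.n_subjects < 2:
            raise ValueError("an atlas needs at least 2 subjects")
        v = self.valid
        if v.any():
            if (self.sd[v] < 0).any():
                raise ValueError("sd must be >= 0")
            if ((self.lower[v] > self.mean[v]) | (self.mean[v] > self.upper[v])).any():
                raise ValueError("atlas must satisfy lower <= mean <= upper")


@dataclass
class DeviationMap:
    """Tri-level classification of a patient map against an atlas."""

    labels: np.ndarray  # DeviationLabel values
    layer: str
    coverage: float

    @property
    def valid(self) -> np.ndarray:
        return self.labels != DeviationLabel.INVALID

    def fraction(self, label: DeviationLabel) -> float:
        """Fraction of valid pixels carrying ``label``."""
        v = self.valid
        if not v.any():
            return float("nan")
        return float(np.mean(self.labels[v] == label))

    def to_rgb(self) -> np.ndarray:
        """(H, W, 3) uint8 image using the fixed palette."""
        rgb = np.zeros(self.labels.shape + (3,), dtype=np.uint8)
        for label, color in PALETTE.items():
            rgb[self.labels == label] = color
        return rgb


def _foveal_shift(values: np.ndarray, valid: np.ndarray,
                  sigma: float = 3.0) -> tuple[int, int]:
    """Integer offset of the smoothed map minimum from the grid centre."""
    sm = gaussian_filter(np.where(valid, values, np.nanmax(values)), sigma)
    iy, ix = np.unravel_index(np.argmin(sm), sm.shape)
    cy, cx = (values.shape[0] - 1) // 2, (values.shape[1] - 1) // 2
    return int(cy - iy), int(cx - ix)


def _translate(values: np.ndarray, valid: np.ndarray,
               dy: int, dx: int) -> tuple[np.ndarray, np.ndarray]:
    out_v = np.zeros_like(values)
    out_m = np.zeros_like(valid)
    h, w = values.shape
    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    out_v[dst_y, dst_x] = values[src_y, src_x]
    out_m[dst_y, dst_x] = valid[src_y, src_x]
    return out_v, out_m


def build_atlas(
    maps: list[EnfaceMap],
    coverage: float = 0.95,
    interval: str = "population",
    align: bool = False,
) -> NormativeAtlas:
    """Aggregate control thickness maps into a normative atlas.

    Per pixel, over the subjects valid there: mean, sample SD, and the
    coverage interval.  Pixels valid in fewer than 2 subjects are invalid.
    ``align=True`` applies an integer-pixel translation bringing each map's
    smoothed minimum (the foveal pit) to the grid centre before aggregating.
    """
    if len(maps) < 2:
        raise ValueError("building an atlas requires at least 2 maps")
    layer = maps[0].layer
    shape = maps[0].values.shape
    for m in maps:
        if m.kind != "thickness_um":
            raise ValueError("atlases are built from thickness maps")
        if m.layer != layer:
            raise ValueError(f"mixed layer tags: {m.layer} vs {layer}")
        if m.values.shape != shape:
            raise ShapeError("maps are on different grids")
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    if interval not in ("population", "mean"):
        raise ValueError("interval must be 'population' or 'mean'")

    vals = np.stack([m.values for m in maps])
    mask = np.stack([m.valid for m in maps])
    if align:
        for i, m in enumerate(maps):
            dy, dx = _foveal_shift(m.values, m.valid)
            vals[i], mask[i] = _translate(m.values, m.valid, dy, dx)

    n = mask.sum(axis=0)
    valid = n >= 2
    safe_n = np.maximum(n, 1)
    w = np.where(mask, vals, 0.0)
    mean = w.sum(axis=0) / safe_n
    ss = np.where(mask, (vals - mean) ** 2, 0.0).sum(axis=0)
    sd = np.sqrt(ss / np.maximum(n - 1, 1))
    z = norm.ppf(0.5 + coverage / 2.0)
    spread = sd if interval == "population" else sd / np.sqrt(safe_n)
    atlas = NormativeAtlas(
        mean=np.where(valid, mean, 0.0),
        sd=np.where(valid, sd, 0.0),
        lower=np.where(valid, mean - z * spread, 0.0),
        upper=np.where(valid, mean + z * spread, 0.0),
        valid=valid,
        n_subjects=len(maps),
        coverage=coverage,
        layer=layer,
    )
    return atlas


def deviation_map(patient: EnfaceMap, atlas: NormativeAtlas) -> DeviationMap:
    """Classify each valid patient pixel against the atlas interval."""
    if patient.values.shape != atlas.mean.shape:
        raise ShapeError(
            f"patient grid {patient.values.shape} does not match atlas "
            f"{atlas.mean.shape}"
        )
    if patient.layer != atlas.layer:
        raise ValueError(f"layer mismatch: patient {patient.layer}, "
                         f"atlas {atlas.layer}")
    valid = patient.valid & atlas.valid
    labels = np.full(patient.values.shape, int(DeviationLabel.INVALID), dtype=np.int8)
    v = patient.values
    labels[valid & (v < atlas.lower)] = int(DeviationLabel.BELOW)
    labels[valid & (v > atlas.upper)] = int(DeviationLabel.ABOVE)
    labels[valid & (v >= atlas.lower) & (v <= atlas.upper)] = int(
        DeviationLabel.WITHIN
    )
    return DeviationMap(labels=labels, layer=patient.layer,
                        coverage=atlas.coverage)


def coverage_check(atlas: NormativeAtlas, fresh_maps: list[EnfaceMap]) -> float:
    """Pooled fraction of valid pixels labelled 'within' over fresh maps.

    When the fresh maps are drawn i.i.d. from the distribution the atlas was
    built from, this converges to the nominal coverage as the cohort and the
    number of fresh maps grow.
    """
    within = 0
    total = 0
    for m in fresh_maps:
        dm = deviation_map(m, atlas)
        v = dm.valid
        within += int(np.sum(dm.labels[v] == DeviationLabel.WITHIN))
        total += int(v.sum())
    if total == 0:
        return float("nan")
    return within / total


def simulate_gaussian_maps(
    mean_map: np.ndarray,
    sd_map: np.ndarray,
    n: int,
    rng: np.random.Generator,
    layer: str = "TR",
) -> list[EnfaceMap]:
    """Draw i.i.d. thickness maps from a per-pixel Gaussian model.

    A convenience for Monte-Carlo validation of the atlas/deviation pipeline:
    every map is ``mean_map + sd_map * N(0, 1)`` drawn independently per
    pixel and per subject, clipped at zero (thickness cannot be negative).
    """
    mean_map = np.asarray(mean_map, dtype=float)
    sd_map = np.broadcast_to(np.asarray(sd_map, dtype=float), mean_map.shape)
    out = []
    for _ in range(n):
        vals = np.clip(rng.normal(mean_map, sd_map), 0.0, None)
        out.append(EnfaceMap(values=vals, kind="thickness_um", layer=layer,
                             valid=np.ones(mean_map.shape, dtype=bool)))
    return out
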