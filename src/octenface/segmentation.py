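"""Graph-based retinal interface segmentation.

Each B-scan is modelled as a graph with one node per pixel and edges between
nodes in adjacent A-scan columns.  Edge weights are derived from the signed
vertical intensity gradient so that large gradients of the sought polarity
(dark-to-bright or bright-to-dark going downward) produce small weights; the
minimum-weight column-monotone path across the image then traces a layer
interface.  Weights follow the canonical form

    w = 2 - (g_a + g_b) + w_min

with ``g`` the rectified vertical gradient normalized to [0, 1] per B-scan
and per polarity, and ``w_min`` a small positive floor keeping all weights
strictly positive.

Paths visit exactly one node per column with a bounded row step between
neighbouring columns, which guarantees a single-valued boundary function and
keeps exhaustive enumeration tractable for verification.  Endpoints are free:
virtual zero-weight start/end nodes connect to every admissible row of the
first/last column.  Ties between equal-cost paths are broken deterministically
(smallest total row sum, then topmost row at the first differing column).

The five interfaces are segmented in a fixed order, each restricting the
search region of the next, which makes the otherwise identical shortest-path
problems find distinct anatomical transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import gaussian_filter

from .core import (
    Boundary,
    BoundarySet,
    InfeasibleRegionError,
    InterfaceId,
    OCTVolume,
    ShapeError,
)

__all__ = [
    "Polarity",
    "SearchRegion",
    "GraphParams",
    "vertical_gradient",
    "normalized_gradient",
    "edge_weight",
    "min_weight_path",
    "shortest_path_boundary",
    "segment_five_interfaces",
    "segment_volume",
    "apply_manual_correction",
]

log = logging.getLogger(__name__)


class Polarity(Enum):
    """Sign of the vertical transition an interface presents."""

    DARK_TO_BRIGHT = "dark_to_bright"  # positive vertical gradient
    BRIGHT_TO_DARK = "bright_to_dark"  # negative vertical gradient


#: Transition polarity of each of the five interfaces.  The vitreous/ILM,
#: INL/OPL and ONL/ISe interfaces are dark-above/bright-below; the RPE/choroid
#: interface is bright-above/dark-below.  The ISe/RPE interface is treated as
#: bright-to-dark because the hyper-reflective ISe band sits above the dimmer
#: outer-segment zone.
INTERFACE_POLARITY: dict[InterfaceId, Polarity] = {
    InterfaceId.VITREOUS_ILM: Polarity.DARK_TO_BRIGHT,
    InterfaceId.INL_OPL: Polarity.DARK_TO_BRIGHT,
    InterfaceId.ONL_ISE: Polarity.DARK_TO_BRIGHT,
    InterfaceId.ISE_RPE: Polarity.BRIGHT_TO_DARK,
    InterfaceId.RPE_CHOROID: Polarity.BRIGHT_TO_DARK,
}


@dataclass(frozen=True)
class SearchRegion:
    """Per-column admissible row interval [min_row, max_row) for one B-scan."""

    min_row: np.ndarray
    max_row: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "min_row", np.asarray(self.min_row, dtype=int))
        object.__setattr__(self, "max_row", np.asarray(self.max_row, dtype=int))
        if self.min_row.shape != self.max_row.shape or self.min_row.ndim != 1:
            raise ShapeError("min_row/max_row must be 1-D arrays of equal length")
        if (self.min_row < 0).any():
            raise InfeasibleRegionError("min_row must be >= 0")
        if (self.min_row >= self.max_row).any():
            bad = int(np.nonzero(self.min_row >= self.max_row)[0][0])
            raise InfeasibleRegionError(f"empty search interval at column {bad}")

    @property
    def n_cols(self) -> int:
        return self.min_row.size

    @classmethod
    def full(cls, n_rows: int, n_cols: int) -> "SearchRegion":
        return cls(np.zeros(n_cols, dtype=int), np.full(n_cols, n_rows, dtype=int))

    @classmethod
    def below(cls, path: np.ndarray, margin: int, n_rows: int) -> "SearchRegion":
        """Rows strictly below ``path`` offset by ``margin``."""
        lo = np.asarray(np.floor(path), dtype=int) + margin
        return cls(lo, np.full(lo.size, n_rows, dtype=int))

    @classmethod
    def between(
        cls, upper: np.ndarray, lower: np.ndarray, margin: int
    ) -> "SearchRegion":
        """Rows between two found paths, offset inward by ``margin``."""
        lo = np.asarray(np.floor(upper), dtype=int) + margin
        hi = np.asarray(np.ceil(lower), dtype=int) - margin + 1
        return cls(lo, hi)

    @classmethod
    def band(
        cls, center: np.ndarray, halfwidth: int, n_rows: int
    ) -> "SearchRegion":
        """Rows within ``halfwidth`` of a (rounded) center line, clipped."""
        c = np.asarray(np.round(center), dtype=int)
        lo = np.clip(c - halfwidth, 0, n_rows - 1)
        hi = np.clip(c + halfwidth + 1, 1, n_rows)
        return cls(lo, hi)


@dataclass(frozen=True)
class GraphParams:
    """Tunable constants of the segmentation graph.

    w_min:
        strictly positive weight floor added to every edge.
    smooth_sigma:
        Gaussian pre-smoothing of each B-scan (px) before gradients;
        0 disables.
    max_step:
        maximum |row change| between adjacent columns of a path.
    exclude_margin:
        row offset applied when restricting the search strictly below an
        already-found path, preventing re-detection of the same transition.
    between_margin:
        row offset applied on both sides when restricting between two paths.
    correction_halfwidth:
        half-height (px) of the band around an operator-drawn line within
        which a corrected path is re-solved.
    """

    w_min: float = 1e-5
    smooth_sigma: float = 1.0
    max_step: int = 5
    exclude_margin: int = 3
    between_margin: int = 3
    correction_halfwidth: int = 5

    def __post_init__(self) -> None:
        if not self.w_min > 0:
            raise ValueError("w_min must be > 0")
        if self.max_step < 1:
            raise ValueError("max_step must be >= 1")
        if self.exclude_margin < 0 or self.between_margin < 0:
            raise ValueError("margins must be >= 0")
        if self.smooth_sigma < 0:
            raise ValueError("smooth_sigma must be >= 0")
        if self.correction_halfwidth < 0:
            raise ValueError("correction_halfwidth must be >= 0")


def vertical_gradient(bscan: np.ndarray, smooth_sigma: float = 1.0) -> np.ndarray:
    """Signed vertical (depth-axis) derivative of a B-scan.

    Central differences along the row axis after optional Gaussian smoothing;
    positive where intensity increases downward (dark above, bright below).
    """
    bscan = np.asarray(bscan, dtype=float)
    if bscan.ndim != 2 or bscan.shape[0] < 3:
        raise ShapeError("bscan must be 2-D with at least 3 rows")
    if smooth_sigma > 0:
        bscan = gaussian_filter(bscan, sigma=smooth_sigma, mode="nearest")
    return np.gradient(bscan, axis=0)


def normalized_gradient(grad: np.ndarray, polarity: Polarity) -> np.ndarray:
    """Rectify a signed gradient by polarity and rescale to [0, 1].

    The rectified gradient is divided by its maximum over the B-scan (per
    polarity); an all-zero rectified gradient maps to an all-zero output.
    """
    grad = np.asarray(grad, dtype=float)
    if not np.isfinite(grad).all():
        raise ValueError("gradient must be finite")
    if polarity is Polarity.DARK_TO_BRIGHT:
        g = np.clip(grad, 0.0, None)
    else:
        g = np.clip(-grad, 0.0, None)
    m = g.max()
    if m > 0:
        g = g / m
    return g


def edge_weight(g_a, g_b, w_min: float = 1e-5):
    """Weight of the edge between two nodes with normalized gradients g_a, g_b.

    Strictly positive and strictly decreasing in g_a + g_b, so that strong
    transitions of the sought polarity attract the minimum-weight path.
    """
    return 2.0 - (np.asarray(g_a) + np.asarray(g_b)) + w_min


def min_weight_path(
    g: np.ndarray,
    region: SearchRegion,
    w_min: float = 1e-5,
    max_step: int = 5,
) -> tuple[np.ndarray, float]:
    """Minimum-total-weight column-monotone path over a normalized-gradient grid.

    Returns ``(rows, cost)`` where ``rows[x]`` is the chosen depth row for
    column ``x`` (inside its region interval, with ``|rows[x+1] - rows[x]| <=
    max_step``) and ``cost`` is the summed edge weight.  Endpoints are free.
    Ties are broken by smallest total row sum, then by the topmost row at the
    first differing column, making the result fully deterministic.
    """
    g = np.asarray(g, dtype=float)
    if g.ndim != 2:
        raise ShapeError("gradient grid must be 2-D")
    n_rows, n_cols = g.shape
    if region.n_cols != n_cols:
        raise ShapeError("region length must equal number of columns")
    if (region.max_row > n_rows).any():
        raise InfeasibleRegionError("region exceeds image depth")

    lo, hi = region.min_row, region.max_row

    if n_cols == 1:
        r = int(lo[0])  # single column: zero cost; tie-break picks topmost row
        return np.array([r]), 0.0

    # Restrict the DP to the rows any column can use.
    r0, r1 = int(lo.min()), int(hi.max())
    g_full = g
    g = g[r0:r1]
    lo = lo - r0
    hi = hi - r0
    n_rows = r1 - r0
    rows_idx = np.arange(n_rows)

    INF = np.inf
    width = 2 * max_step + 1
    # Suffix DP. cost[x, r]: minimal remaining edge weight from (x, r) to the
    # last column; srow[x, r]: the minimal remaining row sum among cost-optimal
    # suffixes (used for tie-breaking), excluding row r itself.
    cost = np.full((n_cols, n_rows), INF)
    srow = np.full((n_cols, n_rows), INF)
    in_region = (rows_idx >= lo[:, None]) & (rows_idx < hi[:, None])

    cost[n_cols - 1, in_region[n_cols - 1]] = 0.0
    srow[n_cols - 1, in_region[n_cols - 1]] = 0.0

    const = 2.0 + w_min
    for x in range(n_cols - 2, -1, -1):
        # D[r'] = cost[x+1, r'] - g[r', x+1]; transition adds const - g[r, x]
        d = cost[x + 1] - g[:, x + 1]
        s_next = srow[x + 1] + rows_idx  # row sum including r'
        d_pad = np.pad(d, max_step, constant_values=INF)
        s_pad = np.pad(s_next, max_step, constant_values=INF)
        d_win = sliding_window_view(d_pad, width)  # (n_rows, width)
        s_win = sliding_window_view(s_pad, width)
        d_min = d_win.min(axis=1)
        tie = d_win == d_min[:, None]
        s_min = np.where(tie, s_win, INF).min(axis=1)
        ok = in_region[x] & np.isfinite(d_min)
        cost[x, ok] = (const - g[:, x] + d_min)[ok]
        srow[x, ok] = s_min[ok]
        if not ok.any():
            raise InfeasibleRegionError(
                f"no feasible transition into column {x} (max_step too small?)"
            )

    # Forward reconstruction: greedily pick the smallest row consistent with
    # the optimal (cost, row-sum) suffix at every column.
    path = np.empty(n_cols, dtype=int)
    cand = np.nonzero(in_region[0] & np.isfinite(cost[0]))[0]
    if cand.size == 0:
        raise InfeasibleRegionError("no feasible path from the first column")
    c0 = cost[0, cand]
    best = cand[c0 == c0.min()]
    s0 = srow[0, best] + best
    best = best[s0 == s0.min()]
    path[0] = best.min()

    for x in range(n_cols - 1):
        r = path[x]
        w_lo = max(r - max_step, 0)
        w_hi = min(r + max_step + 1, n_rows)
        rr = np.arange(w_lo, w_hi)
        c_next = cost[x + 1, rr] - g[rr, x + 1]  # + const - g[r, x], same for all
        feas = np.isfinite(c_next) & in_region[x + 1][rr]
        rr, c_next = rr[feas], c_next[feas]
        sel = rr[c_next == c_next.min()]
        s_next = srow[x + 1, sel] + sel
        sel = sel[s_next == s_next.min()]
        path[x + 1] = sel.min()

    total = float(
        np.sum(edge_weight(g[path[:-1], np.arange(n_cols - 1)],
                           g[path[1:], np.arange(1, n_cols)], w_min))
    )
    return path + r0, total


def shortest_path_boundary(
    bscan: np.ndarray,
    polarity: Polarity,
    region: SearchRegion | None = None,
    params: GraphParams = GraphParams(),
) -> np.ndarray:
    """Trace one interface across a B-scan as a minimum-weight path.

    Returns an integer row per column, each inside its region interval.
    """
    bscan = np.asarray(bscan, dtype=float)
    grad = vertical_gradient(bscan, params.smooth_sigma)
    g = normalized_gradient(grad, polarity)
    if region is None:
        region = SearchRegion.full(bscan.shape[0], bscan.shape[1])
    rows, _ = min_weight_path(g, region, params.w_min, params.max_step)
    return rows


def segment_five_interfaces(
    bscan: np.ndarray,
    params: GraphParams = GraphParams(),
) -> dict[InterfaceId, np.ndarray]:
    """Segment the five retinal interfaces of one B-scan in the set order.

    1. vitreous/ILM: dark-to-bright over the full image (the largest
       dark-to-bright transition);
    2. ONL/ISe: dark-to-bright, restricted to rows below the vitreous/ILM
       path (offset by ``exclude_margin``);
    3. RPE/choroid: bright-to-dark, restricted below the ONL/ISe path;
    4. INL/OPL: dark-to-bright, restricted between vitreous/ILM and ONL/ISe;
    5. ISe/RPE: bright-to-dark, restricted between ONL/ISe and RPE/choroid.

    Raises :class:`InfeasibleRegionError` if the image is too shallow to host
    the restriction margins.  The returned paths satisfy the anatomical depth
    ordering at every column by construction.
    """
    bscan = np.asarray(bscan, dtype=float)
    n_rows, n_cols = bscan.shape
    grad = vertical_gradient(bscan, params.smooth_sigma)
    g_pos = normalized_gradient(grad, Polarity.DARK_TO_BRIGHT)
    g_neg = normalized_gradient(grad, Polarity.BRIGHT_TO_DARK)
    wm, ms = params.w_min, params.max_step

    full = SearchRegion.full(n_rows, n_cols)
    ilm, _ = min_weight_path(g_pos, full, wm, ms)

    below_ilm = SearchRegion.below(ilm, params.exclude_margin, n_rows)
    onl_ise, _ = min_weight_path(g_pos, below_ilm, wm, ms)

    below_onl = SearchRegion.below(onl_ise, params.exclude_margin, n_rows)
    rpe_cho, _ = min_weight_path(g_neg, below_onl, wm, ms)

    between_inner = SearchRegion.between(ilm, onl_ise, params.between_margin)
    inl_opl, _ = min_weight_path(g_pos, between_inner, wm, ms)

    between_outer = SearchRegion.between(onl_ise, rpe_cho, params.between_margin)
    ise_rpe, _ = min_weight_path(g_neg, between_outer, wm, ms)

    return {
        InterfaceId.VITREOUS_ILM: ilm,
        InterfaceId.INL_OPL: inl_opl,
        InterfaceId.ONL_ISE: onl_ise,
        InterfaceId.ISE_RPE: ise_rpe,
        InterfaceId.RPE_CHOROID: rpe_cho,
    }


def segment_volume(
    vol: OCTVolume,
    params: GraphParams = GraphParams(),
) -> BoundarySet:
    """Apply the five-interface protocol independently to every B-scan.

    B-scans on which the protocol fails (infeasible restriction regions) are
    logged and marked invalid in the resulting :class:`BoundarySet` instead of
    aborting the volume.
    """
    meta = vol.meta
    shape = meta.grid_shape
    rows = {iid: np.zeros(shape) for iid in InterfaceId}
    valid = {iid: np.zeros(shape, dtype=bool) for iid in InterfaceId}
    for y in range(meta.n_bscans):
        try:
            paths = segment_five_interfaces(vol.bscan(y), params)
        except InfeasibleRegionError as exc:
            log.warning("B-scan %d: segmentation failed (%s); marked invalid", y, exc)
            continue
        for iid, p in paths.items():
            rows[iid][y] = p
            valid[iid][y] = True
    boundaries = {
        iid: Boundary(rows=rows[iid], valid=valid[iid]) for iid in InterfaceId
    }
    return BoundarySet(boundaries=boundaries, meta=meta)


def apply_manual_correction(
    bscan: np.ndarray,
    current: np.ndarray,
    polyline: Sequence[tuple[float, float]],
    polarity: Polarity,
    params: GraphParams = GraphParams(),
) -> np.ndarray:
    """Re-solve a boundary inside a narrow band around an operator-drawn line.

    The polyline (a list of ``(x, row)`` vertices spanning a contiguous
    x-range) is linearly interpolated to every column it covers; the graph
    search is then restricted to rows within ``correction_halfwidth`` of the
    interpolated line on those columns and the revised segment is spliced
    into ``current``.  Columns outside the polyline's x-range are unchanged.
    """
    bscan = np.asarray(bscan, dtype=float)
    n_rows, n_cols = bscan.shape
    pts = sorted((float(x), float(r)) for x, r in polyline)
    if len(pts) < 1:
        raise ValueError("polyline must have at least one vertex")
    xs = np.array([p[0] for p in pts])
    rs = np.array([p[1] for p in pts])
    if xs.min() < 0 or xs.max() > n_cols - 1 or rs.min() < 0 or rs.max() > n_rows - 1:
        raise ValueError("polyline vertices outside the image")

    x0 = int(np.ceil(xs.min()))
    x1 = int(np.floor(xs.max()))
    cols = np.arange(x0, x1 + 1)
    interp = np.interp(cols, xs, rs)

    grad = vertical_gradient(bscan, params.smooth_sigma)
    g = normalized_gradient(grad, polarity)  # normalized over the full B-scan
    region = SearchRegion.band(interp, params.correction_halfwidth, n_rows)
    seg, _ = min_weight_path(g[:, x0 : x1 + 1], region, params.w_min, params.max_step)

    revised = np.array(current, dtype=float, copy=True)
    revised[x0 : x1 + 1] = seg
    return revised
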