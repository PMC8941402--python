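"""Sensitivity contours: iso-deflection level sets and membership queries.

A sensitivity contour of hair h is the locus of point-charge positions
at which |Delta theta_h| equals the sensory threshold theta_s.  Positive
branches (Delta theta = +theta_s) mark charge locations inducing
positive (toward +x) deflections; negative branches mark negative
deflections.  Charges inside a branch deflect the hair beyond threshold;
outside, below.  Contours are extracted from a sampled deflection field
by marching squares with linear in-cell interpolation; exact membership
queries bypass the grid entirely with a fresh quasi-static solve, and
serve as the oracle for all area metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .deflection import FieldGrid, solve_charges
from .equilibrium import EquilibriumState
from .exceptions import InvalidParameterError
from .model_core import ArrayConfig

__all__ = [
    "ContourBranch",
    "SensitivityContour",
    "extract_contours",
    "region_membership",
    "contour_extent",
]


@dataclass(frozen=True)
class ContourBranch:
    """One polyline of an iso-deflection level set.

    ``vertices`` is an (n, 2) array of nondimensional (x, y) points;
    ``sign`` is '+' for the +theta_s level and '-' for -theta_s;
    ``clipped`` is True when the branch is open because it meets the
    domain boundary (the sensitive region extends beyond the grid).
    """

    vertices: np.ndarray
    sign: str
    clipped: bool

    @property
    def closed(self) -> bool:
        return not self.clipped


@dataclass(frozen=True)
class SensitivityContour:
    """All threshold-level branches for one hair."""

    hair_id: int
    branches: tuple[ContourBranch, ...]
    threshold: float

    @property
    def is_empty(self) -> bool:
        return len(self.branches) == 0

    def all_vertices(self) -> np.ndarray:
        if self.is_empty:
            return np.empty((0, 2))
        return np.vstack([b.vertices for b in self.branches])


def _grid_to_xy(rc: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Map marching-squares (row, col) vertices to (x, y) coordinates."""
    dx = xs[1] - xs[0]
    dy = ys[1] - ys[0]
    x = xs[0] + rc[:, 1] * dx
    y = ys[0] + rc[:, 0] * dy
    return np.column_stack([x, y])


def extract_contours(fieldgrid: FieldGrid, threshold: float | None = None
                     ) -> list[SensitivityContour]:
    """Marching-squares level sets at +/- threshold, one contour set per hair.

    Masked cells are set to NaN so level sets never cross them.  A
    threshold exceeding max |Delta theta| yields an empty contour set.
    Warns when the narrowest detected lobe spans fewer than 3 cells.
    """
    xs, ys = fieldgrid.x_coords, fieldgrid.y_coords
    if threshold is None:
        raise InvalidParameterError("threshold is required")
    if not (threshold > 0):
        raise InvalidParameterError("threshold must be positive")

    out = []
    for h in range(fieldgrid.values.shape[0]):
        vals = np.where(fieldgrid.mask, fieldgrid.values[h], np.nan)
        branches = []
        for level, sign in ((threshold, "+"), (-threshold, "-")):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                polylines = measure.find_contours(vals, level)
            for rc in polylines:
                verts = _grid_to_xy(rc, xs, ys)
                open_poly = not np.allclose(rc[0], rc[-1])
                # 'clipped' marks branches truncated by the domain edge;
                # branches cut by interior masked cells stay unflagged
                # (they close around the excluded zone).
                on_edge = False
                for end in (rc[0], rc[-1]):
                    on_edge |= bool(
                        end[0] < 0.5 or end[0] > len(ys) - 1.5
                        or end[1] < 0.5 or end[1] > len(xs) - 1.5)
                branches.append(ContourBranch(vertices=verts, sign=sign,
                                              clipped=open_poly and on_edge))
        contour = SensitivityContour(hair_id=h, branches=tuple(branches),
                                     threshold=float(threshold))
        if not contour.is_empty:
            widths = [np.ptp(b.vertices[:, 0]) for b in contour.branches]
            cell = xs[1] - xs[0]
            if min(widths) < 3 * cell:
                warnings.warn(
                    f"hair {h}: narrowest contour lobe spans fewer than 3 grid "
                    f"cells; increase resolution", stacklevel=2)
        out.append(contour)
    return out


def region_membership(config: ArrayConfig, equilibrium: EquilibriumState,
                      points, charge_magnitude: float,
                      threshold: float | None = None):
    """Exact per-hair membership |Delta theta_h| >= theta_s at query points.

    Every query is a fresh quasi-static solve (no grid interpolation);
    this is the oracle against which gridded areas and contours are
    validated.  Returns ``(member, valid)`` with ``member`` of shape
    (M, N) boolean and ``valid`` (M,) flagging converged, non-singular
    queries; singular points are excluded (False) with a warning.
    """
    if threshold is None:
        threshold = config.threshold
    delta, valid = solve_charges(config, equilibrium, points, charge_magnitude)
    if not np.all(valid):
        warnings.warn(f"{int(np.sum(~valid))} membership queries did not "
                      f"converge and are excluded", stacklevel=2)
    member = (np.abs(delta) >= threshold) & valid[:, None]
    return member, valid


def contour_extent(contour: SensitivityContour):
    """Horizontal and vertical spans (max - min) over all branch vertices.

    Returns ``(x_extent, y_extent)``, or ``(None, None)`` for an empty
    contour set.
    """
    if contour.is_empty:
        return None, None
    verts = contour.all_vertices()
    return float(np.ptp(verts[:, 0])), float(np.ptp(verts[:, 1]))
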