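"""Sensory-coverage metrics for hair arrays.

Four metrics quantify what electrostatic hair-hair coupling does to an
array's sensing performance, all defined on the deflection-from-
equilibrium field of an external point charge:

* total sensory area — measure of charge locations where at least one
  hair deflects to at least the threshold (in squared hair lengths);
* overlap ratio — fraction of that area where two or more hairs reach
  threshold simultaneously (the region where location/magnitude
  inference is feasible);
* directional areas — a hair's own sensitive area split left/right of
  the vertical through its base, against an uncoupled reference hair
  rested at the coupled equilibrium orientation (so differences reflect
  coupling, not geometry);
* coupling parameter kappa = (theta_uc - theta_c)/theta_uc comparing an
  uncoupled hair's deflection with the coupled hair's at the same charge
  location: negative values mean the neighbour enhances sensitivity,
  positive values mean it inhibits.

Areas are computed by midpoint cell-counting on the gridded membership
field (robust to clipped or degenerate regions); a polygon-based
cross-check is available when all contour branches close.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .contours import SensitivityContour, extract_contours
from .deflection import FieldGrid, deflection_field, solve_charges
from .equilibrium import EquilibriumState, solve_equilibrium
from .exceptions import InvalidParameterError
from .model_core import ArrayConfig

__all__ = [
    "MetricsReport",
    "total_sensory_area",
    "overlap_ratio",
    "directional_areas",
    "coupling_parameter",
    "kappa_profile",
    "contour_polygon_area",
    "compute_metrics",
]

#: Direction bins for the kappa profile: 2.5-degree bins over [-pi/2, pi/2].
DEFAULT_KAPPA_BINS = 73


@dataclass(frozen=True)
class MetricsReport:
    """Coverage metrics of one configuration (areas in squared hair lengths)."""

    total_area: float
    overlap_area: float
    overlap_ratio: float | None
    left_area: float
    right_area: float
    kappa_profile: list[tuple[float, float]]
    clipped: bool
    provenance: dict


def _membership(fieldgrid: FieldGrid, threshold: float):
    """(N, ny, nx) boolean membership, masked cells excluded."""
    return (np.abs(fieldgrid.values) >= threshold) & fieldgrid.mask[None, :, :]


def _check_clipped(member_any: np.ndarray) -> bool:
    """True when the sensitive region touches the grid boundary."""
    return bool(
        member_any[0, :].any() or member_any[-1, :].any()
        or member_any[:, 0].any() or member_any[:, -1].any()
    )


def _field(config, charge_magnitude, threshold, bounds, nx, ny, equilibrium):
    if equilibrium is None:
        equilibrium = solve_equilibrium(config)
    fg = deflection_field(config, charge_magnitude, bounds=bounds, nx=nx, ny=ny,
                          equilibrium=equilibrium)
    return fg, equilibrium


def total_sensory_area(config: ArrayConfig, charge_magnitude: float,
                       threshold: float | None = None, bounds=None,
                       nx: int = 301, ny: int = 301,
                       equilibrium: EquilibriumState | None = None) -> float:
    """Area where at least one hair deflects to at least the threshold.

    Midpoint cell counting over the deflection grid, in squared hair
    lengths.  Warns (and the value is a lower bound) when the sensitive
    region is clipped by the grid.
    """
    if threshold is None:
        threshold = config.threshold
    if charge_magnitude == 0.0:
        return 0.0
    fg, _ = _field(config, charge_magnitude, threshold, bounds, nx, ny, equilibrium)
    member = _membership(fg, threshold)
    any_h = member.any(axis=0)
    if _check_clipped(any_h):
        warnings.warn("sensitive region reaches the grid boundary; "
                      "total area is a lower bound", stacklevel=2)
    return float(np.sum(any_h)) * fg.cell_area


def overlap_ratio(config: ArrayConfig, charge_magnitude: float,
                  threshold: float | None = None, bounds=None,
                  nx: int = 301, ny: int = 301,
                  equilibrium: EquilibriumState | None = None) -> float | None:
    """Fraction of the total sensory area where >= 2 hairs reach threshold.

    ``None`` when the total area vanishes.
    """
    if threshold is None:
        threshold = config.threshold
    fg, _ = _field(config, charge_magnitude, threshold, bounds, nx, ny, equilibrium)
    member = _membership(fg, threshold)
    n_sensing = member.sum(axis=0)
    total = int(np.sum(n_sensing >= 1))
    if total == 0:
        return None
    both = int(np.sum(n_sensing >= 2))
    return both / total


def directional_areas(config: ArrayConfig, hair_id: int, charge_magnitude: float,
                      threshold: float | None = None, bounds=None,
                      nx: int = 301, ny: int = 301,
                      reference: str = "coupled",
                      equilibrium: EquilibriumState | None = None):
    """Sensitive area of one hair split left/right of its base.

    ``reference='coupled'`` measures the hair inside the full array;
    ``reference='uncoupled_rotated'`` measures an isolated copy of the
    hair whose resting angle equals the coupled equilibrium angle, so the
    comparison isolates coupling effects from orientation effects.
    Returns ``(left_area, right_area)`` in squared hair lengths.
    """
    if threshold is None:
        threshold = config.threshold
    if equilibrium is None:
        equilibrium = solve_equilibrium(config)
    if bounds is None:
        from .deflection import estimate_domain
        bounds = estimate_domain(config, charge_magnitude, threshold)

    if reference == "coupled":
        fg = deflection_field(config, charge_magnitude, bounds=bounds,
                              nx=nx, ny=ny, equilibrium=equilibrium)
        member = _membership(fg, threshold)[hair_id]
    elif reference == "uncoupled_rotated":
        solo = config.single_hair(hair_id,
                                  resting_angle=equilibrium.angles[hair_id])
        solo_eq = solve_equilibrium(solo)
        fg = deflection_field(solo, charge_magnitude, bounds=bounds,
                              nx=nx, ny=ny, equilibrium=solo_eq)
        member = _membership(fg, threshold)[0]
    else:
        raise InvalidParameterError(
            f"reference must be 'coupled' or 'uncoupled_rotated', got {reference!r}")

    split_x = config.hairs[hair_id].base_x
    left_cols = fg.x_coords < split_x
    left = float(np.sum(member[:, left_cols])) * fg.cell_area
    right = float(np.sum(member[:, ~left_cols])) * fg.cell_area
    return left, right


def coupling_parameter(theta_uncoupled: float, theta_coupled: float) -> float | None:
    """kappa = (theta_uc - theta_c) / theta_uc; None when theta_uc is zero.

    Negative kappa: the neighbour enhances the hair's deflection
    (coupled exceeds uncoupled); positive kappa: it inhibits.
    """
    if theta_uncoupled == 0.0:
        return None
    return (theta_uncoupled - theta_coupled) / theta_uncoupled


def kappa_profile(config: ArrayConfig, charge_magnitude: float,
                  threshold: float | None = None,
                  n_bins: int = DEFAULT_KAPPA_BINS,
                  bounds=None, nx: int = 401, ny: int = 401,
                  equilibrium: EquilibriumState | None = None):
    """Directional profile of the coupling parameter.

    Charge positions on each hair's coupled sensitivity contour (where
    the coupled deflection is exactly +/- theta_s) are binned by sensory
    direction — the angle between the charge and the array centroid,
    taken from the vertical, in [-pi/2, pi/2].  At each contour point the
    uncoupled deflection theta_uc is a fresh solve of that hair isolated
    and rested at its coupled equilibrium angle.  Per bin, kappa is
    averaged per hair and the minimum over hairs is reported; empty bins
    are NaN.

    Returns a list of ``(bin_center_direction, kappa)`` pairs.
    """
    if threshold is None:
        threshold = config.threshold
    if equilibrium is None:
        equilibrium = solve_equilibrium(config)
    fg = deflection_field(config, charge_magnitude, bounds=bounds, nx=nx, ny=ny,
                          equilibrium=equilibrium)
    contour_sets = extract_contours(fg, threshold)
    cx, cy = config.centroid()

    edges = np.linspace(-np.pi / 2, np.pi / 2, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    per_hair = np.full((config.n_hairs, n_bins), np.nan)

    for h, cset in enumerate(contour_sets):
        if cset.is_empty:
            continue
        pts = []
        signs = []
        for br in cset.branches:
            pts.append(br.vertices)
            sgn = 1.0 if br.sign == "+" else -1.0
            signs.append(np.full(len(br.vertices), sgn))
        pts = np.vstack(pts)
        signs = np.concatenate(signs)

        # Validate vertices against the membership oracle: the coupled
        # deflection is re-solved at each vertex, and vertices whose
        # solved deflection strays from +/- theta_s (interpolation
        # artefacts in steep near-hair regions) are dropped.  The solved
        # value, not the nominal level, enters kappa.
        delta_c, ok_c = solve_charges(config, equilibrium, pts, charge_magnitude)
        theta_c = delta_c[:, h]
        on_contour = (ok_c
                      & (np.sign(theta_c) == signs)
                      & (np.abs(theta_c) >= 0.8 * threshold)
                      & (np.abs(theta_c) <= 1.25 * threshold))

        # Uncoupled reference: this hair alone, rested at its coupled
        # equilibrium angle; its equilibrium is that resting angle.
        solo = config.single_hair(h, resting_angle=equilibrium.angles[h])
        solo_eq = solve_equilibrium(solo)
        delta_uc, ok = solve_charges(solo, solo_eq, pts, charge_magnitude)
        theta_uc = delta_uc[:, 0]

        direction = np.arctan2(pts[:, 0] - cx, pts[:, 1] - cy)
        keep = (ok & on_contour
                & (np.abs(direction) <= np.pi / 2) & (theta_uc != 0.0))
        if not np.any(keep):
            continue
        kappa = (theta_uc[keep] - theta_c[keep]) / theta_uc[keep]
        which = np.clip(np.digitize(direction[keep], edges) - 1, 0, n_bins - 1)
        for b in range(n_bins):
            sel = which == b
            if np.any(sel):
                per_hair[h, b] = float(np.mean(kappa[sel]))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        combined = np.nanmin(per_hair, axis=0)
    return [(float(c), float(k)) for c, k in zip(centers, combined)]


def contour_polygon_area(contour: SensitivityContour) -> float | None:
    """Polygonized area of a hair's sensitive region (cross-check).

    Union of the regions enclosed by the closed branches; ``None`` when
    any branch is clipped by the domain (the polygonization would
    undercount).
    """
    if contour.is_empty:
        return 0.0
    if any(br.clipped for br in contour.branches):
        return None
    polys = [Polygon(br.vertices).buffer(0) for br in contour.branches
             if len(br.vertices) >= 4]
    if not polys:
        return 0.0
    return float(unary_union(polys).area)


def compute_metrics(config: ArrayConfig, charge_magnitude: float,
                    threshold: float | None = None, bounds=None,
                    nx: int = 301, ny: int = 301,
                    hair_id: int = 0,
                    kappa_bins: int = DEFAULT_KAPPA_BINS) -> MetricsReport:
    """Assemble the full metrics report for one configuration."""
    if threshold is None:
        threshold = config.threshold
    equilibrium = solve_equilibrium(config)
    if bounds is None:
        from .deflection import estimate_domain
        bounds = estimate_domain(config, charge_magnitude, threshold)
    fg = deflection_field(config, charge_magnitude, bounds=bounds, nx=nx, ny=ny,
                          equilibrium=equilibrium)
    member = _membership(fg, threshold)
    n_sensing = member.sum(axis=0)
    total_cells = int(np.sum(n_sensing >= 1))
    overlap_cells = int(np.sum(n_sensing >= 2))
    total = total_cells * fg.cell_area
    overlap = overlap_cells * fg.cell_area
    ratio = overlap / total if total_cells > 0 else None
    clipped = _check_clipped(n_sensing >= 1)

    split_x = config.hairs[hair_id].base_x
    left_cols = fg.x_coords < split_x
    left = float(np.sum(member[hair_id][:, left_cols])) * fg.cell_area
    right = float(np.sum(member[hair_id][:, ~left_cols])) * fg.cell_area

    profile = kappa_profile(config, charge_magnitude, threshold,
                            n_bins=kappa_bins, bounds=bounds, nx=nx, ny=ny,
                            equilibrium=equilibrium)
    return MetricsReport(
        total_area=total, overlap_area=overlap, overlap_ratio=ratio,
        left_area=left, right_area=right, kappa_profile=profile,
        clipped=clipped,
        provenance={
            "K": config.K, "threshold": threshold,
            "charge_magnitude": charge_magnitude,
            "bounds": tuple(float(b) for b in bounds), "nx": nx, "ny": ny,
            "n_hairs": config.n_hairs,
        },
    )
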