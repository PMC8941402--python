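"""Parameter sweeps over (K, delta[, length ratio]) grids.

Reproduces the standard study layout for two-hair rows: per sweep cell,
the coupled equilibrium (and optionally contours and coverage metrics),
plus one tidy summary table of equilibrium angles and metrics against
spacing, per K — the raw material for equilibrium-versus-spacing curves
and the coverage/overlap/directionality trends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .contours import extract_contours
from .deflection import deflection_field, estimate_domain
from .equilibrium import solve_equilibrium
from .exceptions import InvalidParameterError
from .io import write_results
from .metrics import compute_metrics
from .model_core import make_row_array

__all__ = ["SweepSpec", "run_sweep", "contours_to_records"]

log = logging.getLogger("hairfield")


@dataclass(frozen=True)
class SweepSpec:
    """Axes and settings of a two-hair sweep.

    ``length_ratios`` are L1:L2 ratios with L1 + L2 = 2 (None for
    identical unit hairs).  Grid settings apply per cell.
    """

    K_values: tuple[float, ...]
    delta_values: tuple[float, ...]
    length_ratios: tuple[float, ...] | None = None
    charge_magnitude: float = 10.0
    threshold: float = 1e-3
    nx: int = 201
    ny: int = 201
    n_hairs: int = 2
    with_metrics: bool = False
    with_contours: bool = False
    output_dir: str | None = None

    def __post_init__(self):
        if not self.K_values or not self.delta_values:
            raise InvalidParameterError("K_values and delta_values must be non-empty")
        if any(k <= 0 for k in self.K_values):
            raise InvalidParameterError("K values must be positive")
        if any(d <= 0 for d in self.delta_values):
            raise InvalidParameterError("delta values must be positive")
        if self.length_ratios is not None and any(r <= 0 for r in self.length_ratios):
            raise InvalidParameterError("length ratios must be positive")


def _cell_name(K, delta, ratio=None):
    name = f"K{K:g}_d{delta:g}"
    if ratio is not None:
        name += f"_r{ratio:g}"
    return name


def _cell_config(spec: SweepSpec, K, delta, ratio):
    if ratio is None:
        return make_row_array(spec.n_hairs, delta=delta, K=K,
                              threshold=spec.threshold)
    L2 = 2.0 / (1.0 + ratio)
    lengths = [ratio * L2, L2]
    return make_row_array(2, delta=delta, lengths=lengths, K=K,
                          threshold=spec.threshold)


def contours_to_records(contour_sets):
    """Flatten contour sets to (hair_id, branch_id, sign, vertex_index, x, y)."""
    records = []
    for cset in contour_sets:
        for b, branch in enumerate(cset.branches):
            for v, (x, y) in enumerate(branch.vertices):
                records.append({
                    "hair_id": cset.hair_id, "branch_id": b,
                    "sign": branch.sign, "vertex_index": v,
                    "x": float(x), "y": float(y),
                })
    return records


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run every (K, delta[, ratio]) cell; returns the tidy summary table.

    Per-cell equilibrium records (and contour CSVs / metrics when
    enabled) are written under ``output_dir`` when set.  Cell failures
    are logged and flagged in the summary, and the sweep continues.
    """
    ratios = spec.length_ratios if spec.length_ratios is not None else [None]
    out_dir = Path(spec.output_dir) if spec.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for ratio in ratios:
        for K in spec.K_values:
            for delta in spec.delta_values:
                name = _cell_name(K, delta, ratio)
                row = {"K": K, "delta": delta, "ratio": ratio, "cell": name}
                try:
                    cfg = _cell_config(spec, K, delta, ratio)
                    state = solve_equilibrium(cfg)
                    row["valid"] = state.valid
                    row["residual_norm"] = state.residual_norm
                    for h, ang in enumerate(state.angles):
                        row[f"theta_e_{h}"] = float(ang)
                    cell_dir = None
                    if out_dir:
                        cell_dir = out_dir / name
                        cell_dir.mkdir(exist_ok=True)
                        write_results(
                            [{"hair_id": h, "theta_e": float(a),
                              "tip_x": float(t[0]), "tip_y": float(t[1]),
                              "residual_norm": state.residual_norm,
                              "valid": state.valid}
                             for h, (a, t) in enumerate(zip(state.angles, state.tips))],
                            cell_dir / "equilibrium.csv")
                    if spec.with_contours or spec.with_metrics:
                        bounds = estimate_domain(cfg, spec.charge_magnitude,
                                                 spec.threshold)
                        if spec.with_contours:
                            fg = deflection_field(
                                cfg, spec.charge_magnitude, bounds=bounds,
                                nx=spec.nx, ny=spec.ny, equilibrium=state)
                            csets = extract_contours(fg, spec.threshold)
                            if cell_dir:
                                write_results(contours_to_records(csets),
                                              cell_dir / "contours.csv")
                        if spec.with_metrics:
                            rep = compute_metrics(
                                cfg, spec.charge_magnitude, spec.threshold,
                                bounds=bounds, nx=spec.nx, ny=spec.ny)
                            row.update(
                                total_area=rep.total_area,
                                overlap_area=rep.overlap_area,
                                overlap_ratio=rep.overlap_ratio,
                                left_area=rep.left_area,
                                right_area=rep.right_area,
                                clipped=rep.clipped,
                            )
                    log.info("cell %s: theta_e=%s iterations=%d valid=%s",
                             name, np.array2string(state.angles, precision=6),
                             state.iterations, state.valid)
                except Exception as exc:  # per-cell failures do not stop the sweep
                    log.warning("cell %s failed: %s", name, exc)
                    row["valid"] = False
                    row["error"] = str(exc)
                rows.append(row)

    summary = pd.DataFrame(rows)
    if out_dir:
        summary.to_csv(out_dir / "summary.csv", index=False)
    return summary
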