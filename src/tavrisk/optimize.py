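"""Inverse design: choose prosthesis size and vacancy angle for a patient.

The design problem is solved by exhaustive enumeration over the small
feasible grid (available nominal sizes x integer vacancy angles): for every
candidate the full forward pipeline runs (boundary condition -> elastic solve
-> conduction-zone features -> risk prediction) and the design minimizing the
distance between predicted risk and the target risk (0 = no conduction block)
is returned.  Ties resolve to the smallest vacancy angle, then to the size
closest to the conventional 15% annulus oversize.  The optimal loading force
follows from the force law, and the same law inverts force back to a
continuous size that is snapped to the available sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import fem
from .forward import ForwardModel
from .materials import LoadingForce, loading_force
from .model import VBPRModel, assemble_features, predict_risk
from .records import PatientRecord
from .valves import AVAILABLE_SIZES, ValveDesign, snap_size

__all__ = ["OptimizationResult", "optimize_design", "force_to_size"]


@dataclass
class OptimizationResult:
    """Outcome of one exhaustive design-grid search."""

    best: ValveDesign
    predicted_risk: float
    optimal_force: float  # N, from the force law at the optimal size
    sizes: np.ndarray
    thetas: np.ndarray
    risk_grid: np.ndarray  # (n_sizes, n_thetas)
    objective_grid: np.ndarray
    target_risk: float


def optimize_design(
    patient: PatientRecord,
    model: VBPRModel,
    resolution: tuple[int, int, int] = fem.DEFAULT_RESOLUTION,
    band_height: float = 4.0,
    half_angle_deg: float = 45.0,
    sizes: tuple[float, ...] = AVAILABLE_SIZES,
    theta_max_deg: float = 15.0,
    theta_step_deg: float = 1.0,
    target_risk: float = 0.0,
    oversize_ratio: float = 1.15,
    force_thickness: float | None = None,
) -> OptimizationResult:
    """Exhaustively search (size, theta) for the minimum-risk-distance design.

    ``force_thickness`` is the calcium thickness d used in the scalar force
    law for the reported optimal force (defaults to the patient's maximum
    remodeled deposit thickness).
    """
    sizes_arr = np.asarray(sorted(sizes), dtype=float)
    thetas = np.arange(0.0, theta_max_deg + 1e-9, theta_step_deg)
    if sizes_arr.size == 0 or thetas.size == 0:
        raise ValueError("empty design grid")

    fm = ForwardModel(
        patient.geometry,
        patient.deposits,
        resolution=resolution,
        band_height=band_height,
        half_angle_deg=half_angle_deg,
    )
    # template features: everything after the stress block is design-invariant
    template = assemble_features(
        patient, resolution, band_height, half_angle_deg, forward=fm
    )
    n_stress = fm.feature_node_ids.size

    risk_grid = np.empty((sizes_arr.size, thetas.size))
    for j, theta in enumerate(thetas):
        for i, size in enumerate(sizes_arr):
            stress = fm.features(ValveDesign(size=float(size), theta_deg=float(theta)))
            x = template.copy()
            x[:n_stress] = stress
            risk_grid[i, j] = predict_risk(model, x)
    objective = np.abs(target_risk - risk_grid)

    best_obj = objective.min()
    ii, jj = np.where(objective <= best_obj + 1e-12)
    # tie-break: smallest theta, then size closest to the conventional oversize
    target_size = oversize_ratio * 2.0 * patient.geometry.inner_radius
    order = np.lexsort(
        (sizes_arr[ii], np.abs(sizes_arr[ii] - target_size), thetas[jj])
    )
    i_best, j_best = int(ii[order[0]]), int(jj[order[0]])
    best = ValveDesign(size=float(sizes_arr[i_best]), theta_deg=float(thetas[j_best]))

    d_force = (
        force_thickness
        if force_thickness is not None
        else fm.max_remodeled_thickness
    )
    f_star = loading_force(
        patient.geometry.wall_stiffness,
        best.size,
        patient.geometry.annulus_circumference,
        d_force,
    ).force
    return OptimizationResult(
        best=best,
        predicted_risk=float(risk_grid[i_best, j_best]),
        optimal_force=float(f_star),
        sizes=sizes_arr,
        thetas=thetas,
        risk_grid=risk_grid,
        objective_grid=objective,
        target_risk=target_risk,
    )


def force_to_size(
    force: float,
    stiffness: float,
    annulus_circumference: float,
    calcium_thickness: float,
    available: tuple[float, ...] = AVAILABLE_SIZES,
) -> tuple[float, float]:
    """Invert the force law to a continuous size, then snap to nominal sizes.

    Exact inverse of :func:`tavrisk.materials.loading_force` before snapping.
    A continuous size below the smallest available device triggers a warning
    and clamps to that smallest size.
    """
    if not stiffness > 0:
        raise ValueError(f"wall stiffness must be positive, got {stiffness}")
    r_radius = force / stiffness + annulus_circumference / (2.0 * np.pi) - calcium_thickness
    continuous = 2.0 * r_radius
    smallest = min(available)
    if continuous < smallest:
        warnings.warn(
            f"continuous size {continuous:.2f} mm below smallest available device "
            f"({smallest:.0f} mm); clamping",
            stacklevel=2,
        )
        return continuous, float(smallest)
    return continuous, snap_size(continuous, available)
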