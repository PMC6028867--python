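"""Analytic macroscopic torsion layer model and micro-macro combination.

The embedded cylinder (diameter 3 mm, embedded depth 9 mm in the bench
geometry) is treated as an elastic shaft with its bottom cross-section fixed:
under an applied top rotation Θ the twist varies linearly with height, so the
tangential surface displacement of layer ``j`` (evaluated at the layer's mean
height, 20 layers of 0.45 mm by default) is

    u_j = r · Θ_rad · z_j / L,        z_j = L − (j − 1/2) h_layer .

The removal torque at rotation Θ is the layer-wise sum of the micro unit-cell
reaction force interpolated at each layer's displacement, upscaled by the
ratio of the layer's lateral area ``π d h_layer`` to the unit-cell footprint
area, times the cylinder radius:

    T(Θ) = Σ_j  r · (π d h_layer / A_cell) · F_micro(u_j(Θ)) .

This macroscopic stage is purely analytic (no FEM); the micro curve carries
all the interfacial mechanics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fracture import ForceDisplacementCurve

__all__ = [
    "MacroModel",
    "TorqueCurve",
    "layer_displacements",
    "top_bottom_displacement_difference",
    "layer_displacement_step",
    "micro_force_at",
    "combine_torque",
    "peak_torque",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MacroModel:
    """Geometry of the macroscopic torsion layer model (bench defaults)."""

    cylinder_diameter_mm: float = 3.0
    embedded_depth_mm: float = 9.0
    n_layers: int = 20
    layer_height_mm: float = 0.45
    block_mm: tuple[float, float, float] = (15.0, 15.0, 10.0)
    unit_cell_area_um2: float = 3.15 * 6.3

    def __post_init__(self) -> None:
        if self.cylinder_diameter_mm <= 0 or self.embedded_depth_mm <= 0:
            raise ValueError("cylinder diameter and embedded depth must be > 0")
        if self.n_layers < 1 or self.layer_height_mm <= 0:
            raise ValueError("need at least one layer of positive height")
        if abs(self.n_layers * self.layer_height_mm - self.embedded_depth_mm) > 1e-9:
            raise ValueError(
                f"layer count x layer height = "
                f"{self.n_layers * self.layer_height_mm} mm must equal the "
                f"embedded depth {self.embedded_depth_mm} mm")
        if self.unit_cell_area_um2 <= 0:
            raise ValueError("unit_cell_area_um2 must be > 0")

    @property
    def radius_mm(self) -> float:
        return self.cylinder_diameter_mm / 2.0

    @property
    def layer_area_ratio(self) -> float:
        """Layer lateral area π·d·h_layer over the unit-cell footprint area."""
        area_layer_um2 = (math.pi * self.cylinder_diameter_mm
                          * self.layer_height_mm) * 1e6  # mm² -> µm²
        return area_layer_um2 / self.unit_cell_area_um2


def layer_displacements(model: MacroModel, rotation_deg: float) -> np.ndarray:
    """Tangential surface displacement (µm) of each layer at its mean height
    under a top rotation; index 0 is the top layer, where the torque is
    applied, and the profile decreases linearly to the fixed bottom."""
    if rotation_deg < 0:
        raise ValueError("rotation must be >= 0")
    theta = math.radians(rotation_deg)
    L = model.embedded_depth_mm
    j = np.arange(model.n_layers)
    z_mid = L - (j + 0.5) * model.layer_height_mm  # height above the fixed bottom
    u_mm = model.radius_mm * theta * z_mid / L
    return u_mm * 1e3  # mm -> µm


def top_bottom_displacement_difference(model: MacroModel,
                                       rotation_deg: float) -> float:
    """Difference (µm) between the tangential surface displacement at the top
    and at the bottom of the embedded length: r·Θ (the bottom is fixed)."""
    theta = math.radians(rotation_deg)
    return model.radius_mm * theta * 1e3


def layer_displacement_step(model: MacroModel, rotation_deg: float) -> float:
    """The constant displacement difference (µm) between successive layers."""
    u = layer_displacements(model, rotation_deg)
    if len(u) < 2:
        return 0.0
    steps = -np.diff(u)
    return float(steps.mean())


def micro_force_at(curve: ForceDisplacementCurve, displacement_um) -> np.ndarray:
    """Piecewise-linear interpolation of the micro reaction force (mN).

    Beyond the last recorded sample the last force value is held (and a
    warning is logged once per call): the micro curve should span the
    displacements the macro combination needs.
    """
    d = np.atleast_1d(np.asarray(displacement_um, dtype=float))
    if np.any(d < 0):
        raise ValueError("displacement must be >= 0")
    if np.any(d > curve.displacement_um[-1] * (1 + 1e-12)):
        log.warning("micro curve queried beyond its last sample "
                    "(%.4g µm > %.4g µm): holding the last force value",
                    float(d.max()), float(curve.displacement_um[-1]))
    return np.interp(d, curve.displacement_um, curve.force_mn)


@dataclass
class TorqueCurve:
    """Removal-torque-vs-rotation prediction with per-layer contributions.

    ``layer_forces_mn[i, j]`` is the area-upscaled reaction force (mN) of
    layer ``j`` at rotation sample ``i``; the torque is their moment sum.
    """

    rotation_deg: np.ndarray
    torque_nmm: np.ndarray
    layer_forces_mn: np.ndarray
    gap_nm: float | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation_deg, dtype=float)
        if np.any(np.diff(r) <= 0):
            raise ValueError("rotation samples must be strictly increasing")
        if len(r) and r[0] == 0.0 and abs(self.torque_nmm[0]) > 1e-12:
            raise ValueError("torque at zero rotation must be 0")

    @property
    def torque_ncm(self) -> np.ndarray:
        return self.torque_nmm / 10.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "rotation_deg": self.rotation_deg,
            "torque_Nmm": self.torque_nmm,
            "torque_Ncm": self.torque_ncm,
        })
        for j in range(self.layer_forces_mn.shape[1]):
            df[f"layer_{j + 1:02d}_force_mN"] = self.layer_forces_mn[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def combine_torque(curve: ForceDisplacementCurve, model: MacroModel,
                   rotations_deg: np.ndarray) -> TorqueCurve:
    """Layer-wise summation of the micro reaction forces into removal torque.

    For each rotation the per-layer displacements (with their linear
    top-to-bottom delay) sample the micro curve; forces are upscaled by the
    layer-to-cell area ratio and converted to torque with the cylinder radius.
    """
    rotations = np.asarray(rotations_deg, dtype=float)
    ratio = model.layer_area_ratio
    r_mm = model.radius_mm
    layer_forces = np.empty((len(rotations), model.n_layers))
    for i, rot in enumerate(rotations):
        u = layer_displacements(model, float(rot))
        layer_forces[i] = ratio * micro_force_at(curve, u)
    torque_nmm = (r_mm * layer_forces).sum(axis=1) * 1e-3  # mN·mm -> N·mm
    return TorqueCurve(rotations, torque_nmm, layer_forces, gap_nm=curve.gap_nm)


def peak_torque(curve: TorqueCurve) -> tuple[float, float]:
    """Rotation (deg) and value (N·mm) of the torque maximum; ties broken by
    the smallest rotation."""
    if len(curve.rotation_deg) == 0:
        raise ValueError("empty torque curve")
    i = int(np.argmax(curve.torque_nmm))
    return float(curve.rotation_deg[i]), float(curve.torque_nmm[i])
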