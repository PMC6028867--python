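"""Canonical test-input generation.

Writes the small, deterministic inputs the verification suite uses: fixture
meshes (single element, block, cantilever), flat and cone height maps, and
synthetic linear force-displacement curves.  Everything is plain text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .fracture import ForceDisplacementCurve
from .hexmesh import build_fixture_mesh, export_msh, export_vtk
from .surface import ConeFeature, UnitCell, render_height_map, write_height_map

__all__ = ["generate_fixtures", "FIXTURE_KINDS", "linear_curve"]

FIXTURE_KINDS = ("meshes", "height_maps", "linear_curves")


def linear_curve(stiffness_mn_per_um: float, max_displacement_um: float,
                 n_samples: int = 11, gap_nm: float = 0.0) -> ForceDisplacementCurve:
    """Synthetic exactly linear force-displacement curve F = k·u."""
    d = np.linspace(0.0, max_displacement_um, n_samples)
    return ForceDisplacementCurve(d, stiffness_mn_per_um * d,
                                  np.zeros(n_samples, dtype=int),
                                  np.zeros(n_samples), gap_nm)


def generate_fixtures(kind: str, destination) -> list[Path]:
    """Write the canonical fixtures of the given kind; returns the paths."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of "
                         f"{FIXTURE_KINDS}")
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if kind == "meshes":
        for name, args in (
                ("single_element", {}),
                ("block", {"dims": (2.0, 2.0, 2.0), "divisions": (2, 2, 2)}),
                ("cantilever", {}),
        ):
            mesh, _ = build_fixture_mesh(name, **args)
            vtk = dest / f"{name}.vtk"
            export_vtk(mesh, vtk)
            msh = dest / f"{name}.msh"
            export_msh(mesh, msh)
            written += [vtk, msh]

    elif kind == "height_maps":
        cell = UnitCell(3.15, 6.3)
        flat = render_height_map(ConeFeature(0.0, 0.0), cell, 33)
        cone = render_height_map(ConeFeature(1.2765, 2.9953), cell, 129)
        for name, hm in (("flat_map.csv", flat), ("cone_map.csv", cone)):
            path = dest / name
            write_height_map(hm, path)
            written.append(path)

    else:  # linear_curves
        for name, k, umax in (("linear_stiff.csv", 2.0, 3.0),
                              ("linear_soft.csv", 0.5, 3.0)):
            path = dest / name
            linear_curve(k, umax).to_csv(path)
            written.append(path)

    return written
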