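"""Roughness-derived conical unit-cell surfaces.

The micro model of an acid-etched implant surface is a single conical feature
standing on an otherwise flat plane inside a small rectangular unit cell.  This
module builds that geometry from target areal roughness parameters and provides
both closed-form and discrete (height-map) evaluation of the three parameters
used to characterize the surface:

``Sa``
    arithmetic mean deviation of the surface from its mean plane (nm),
``Sdq``
    root-mean-square slope, expressed here as the corresponding angle in
    degrees (``arctan`` of the dimensionless RMS gradient),
``Sdr``
    developed interfacial area ratio, the percentage by which the true
    (developed) surface area exceeds the projected area.

It also produces the rigid *master* contact surface used by the FEM contact
solver: the conical feature offset inward by a uniform interfacial gap, with a
continuous signed-distance/normal evaluator (optionally periodic in the
tangential displacement direction so the translated feature wraps around the
unit cell the way a uniform feature array would).

Units follow the interface convention of the package: lengths in µm unless a
name says otherwise (``*_nm``), angles in degrees, Sdr in percent.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Literal, Protocol

import numpy as np
from scipy import optimize

__all__ = [
    "RoughnessSpec",
    "RoughnessValues",
    "UnitCell",
    "ConeFeature",
    "HeightMap",
    "ConeFit",
    "GeometryError",
    "InfeasibleFitError",
    "RigidSurface",
    "ConeSurface",
    "PlaneSurface",
    "closed_form_cone_roughness",
    "roughness_from_height_map",
    "fit_cone",
    "render_height_map",
    "offset_surface",
    "read_height_map",
    "write_height_map",
]

FitMode = Literal["sa+sdq", "sdq+sdr", "least-squares-all"]
FIT_MODES: tuple[str, ...] = ("sa+sdq", "sdq+sdr", "least-squares-all")


class GeometryError(ValueError):
    """A geometric precondition is violated (feature does not fit, etc.)."""


class InfeasibleFitError(GeometryError):
    """No cone inside the cell can satisfy the requested roughness targets."""


@dataclass(frozen=True)
class RoughnessSpec:
    """Target areal roughness triple for the surface to be modeled.

    Parameters
    ----------
    sa_nm : float
        Arithmetic mean deviation, nm.  Must be >= 0.
    sdq_deg : float
        RMS slope as an angle, degrees, in [0, 90).
    sdr_pct : float
        Developed area excess, percent.  Must be >= 0.
    """

    sa_nm: float
    sdq_deg: float
    sdr_pct: float

    def __post_init__(self) -> None:
        if self.sa_nm < 0:
            raise ValueError(f"sa_nm must be >= 0, got {self.sa_nm}")
        if not 0.0 <= self.sdq_deg < 90.0:
            raise ValueError(f"sdq_deg must be in [0, 90), got {self.sdq_deg}")
        if self.sdr_pct < 0:
            raise ValueError(f"sdr_pct must be >= 0, got {self.sdr_pct}")


@dataclass(frozen=True)
class RoughnessValues:
    """Achieved roughness triple (same fields and units as `RoughnessSpec`)."""

    sa_nm: float
    sdq_deg: float
    sdr_pct: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.sa_nm, self.sdq_deg, self.sdr_pct)


@dataclass(frozen=True)
class UnitCell:
    """Rectangular unit-cell footprint with the polymer substrate below it.

    ``width_um`` is the extent along the enforced tangential displacement
    direction (x), ``length_um`` the transverse extent (y), and
    ``substrate_depth_um`` the extent of polymer below the feature plane.
    """

    width_um: float
    length_um: float
    substrate_depth_um: float = 6.0

    def __post_init__(self) -> None:
        for name in ("width_um", "length_um", "substrate_depth_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def area_um2(self) -> float:
        """Projected (footprint) area in µm²."""
        return self.width_um * self.length_um


@dataclass(frozen=True)
class ConeFeature:
    """A right circular cone standing on the flat reference plane.

    ``apex_xy_um`` is the in-plane apex position; ``None`` means the cell
    center wherever a cell is available.
    """

    base_radius_um: float
    height_um: float
    apex_xy_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.base_radius_um < 0:
            raise ValueError("base_radius_um must be >= 0")
        if self.height_um < 0:
            raise ValueError("height_um must be >= 0")

    @property
    def flank_angle_deg(self) -> float:
        """Flank slope angle arctan(height / base_radius), degrees."""
        if self.base_radius_um == 0:
            return 90.0 if self.height_um > 0 else 0.0
        return math.degrees(math.atan2(self.height_um, self.base_radius_um))

    def apex_in(self, cell: UnitCell) -> tuple[float, float]:
        if self.apex_xy_um is not None:
            return self.apex_xy_um
        return (cell.width_um / 2.0, cell.length_um / 2.0)


def _check_cone_fits(cone: ConeFeature, cell: UnitCell) -> None:
    cx, cy = cone.apex_in(cell)
    a = cone.base_radius_um
    if (cx - a < -1e-12 or cx + a > cell.width_um + 1e-12
            or cy - a < -1e-12 or cy + a > cell.length_um + 1e-12):
        raise GeometryError(
            f"cone base circle (radius {a} µm at ({cx}, {cy})) does not fit "
            f"inside the {cell.width_um} x {cell.length_um} µm cell footprint")


@dataclass(frozen=True)
class HeightMap:
    """Surface heights on a regular grid over the cell footprint.

    ``heights_nm[i, j]`` is the height at x-index ``i``, y-index ``j``; the
    grid spacing is ``dx_nm`` / ``dy_nm``.  Heights are measured from the flat
    reference plane (>= 0 for protruding features).
    """

    heights_nm: np.ndarray
    dx_nm: float
    dy_nm: float

    def __post_init__(self) -> None:
        z = np.asarray(self.heights_nm, dtype=float)
        if z.ndim != 2 or z.shape[0] < 2 or z.shape[1] < 2:
            raise ValueError(f"height map must be at least 2x2, got shape {z.shape}")
        if not np.all(np.isfinite(z)):
            raise ValueError("height map contains non-finite values")
        if self.dx_nm <= 0 or self.dy_nm <= 0:
            raise ValueError("grid spacing must be > 0")
        object.__setattr__(self, "heights_nm", z)


# ---------------------------------------------------------------------------
# Closed-form roughness of a single cone on a flat cell
# ---------------------------------------------------------------------------

def closed_form_cone_roughness(cone: ConeFeature, cell: UnitCell) -> RoughnessValues:
    """Exact Sa/Sdq/Sdr of one cone of radius ``a`` and height ``h`` in a cell.

    With projected cell area ``A`` and mean plane ``z̄ = π a² h / (3 A)``:

    * ``Sa = (1/A) ∫ |z − z̄| dA`` — the integral over the flat part is
      ``z̄ (A − π a²)``; over the cone it splits at the radius
      ``r* = a (1 − z̄/h)`` where the flank crosses the mean plane.
    * ``Sdq = arctan sqrt((1/A) ∫ |∇z|² dA)``; the gradient magnitude is
      ``h/a`` on the flank and 0 elsewhere, so the RMS gradient is
      ``h sqrt(π / A)`` — independent of the base radius.
    * ``Sdr = π a (sqrt(a² + h²) − a) / A`` — the lateral cone area minus its
      projection, relative to the cell area.
    """
    _check_cone_fits(cone, cell)
    a = cone.base_radius_um
    h = cone.height_um
    A = cell.area_um2
    if a == 0.0 or h == 0.0:
        return RoughnessValues(0.0, 0.0, 0.0)

    pa2 = math.pi * a * a
    zbar = pa2 * h / (3.0 * A)
    rstar = a * (1.0 - zbar / h)
    i_above = 2.0 * math.pi * ((h - zbar) * rstar**2 / 2.0 - h * rstar**3 / (3.0 * a))
    i_below = 2.0 * math.pi * ((zbar - h) * (a * a - rstar**2) / 2.0
                               + h * (a**3 - rstar**3) / (3.0 * a))
    sa_um = (zbar * (A - pa2) + i_above + i_below) / A

    rms_grad = h * math.sqrt(math.pi / A)
    sdq_deg = math.degrees(math.atan(rms_grad))

    sdr_pct = 100.0 * math.pi * a * (math.hypot(a, h) - a) / A
    return RoughnessValues(sa_um * 1000.0, sdq_deg, sdr_pct)


# ---------------------------------------------------------------------------
# Discrete roughness from a height map
# ---------------------------------------------------------------------------

def roughness_from_height_map(hm: HeightMap) -> RoughnessValues:
    """Numerical Sa/Sdq/Sdr of a gridded surface.

    Sa is the mean absolute deviation from the grid mean.  The gradient uses
    central differences in the interior and one-sided differences at the
    borders (``numpy.gradient``).  The developed area for Sdr triangulates
    each grid quad into two planar facets.
    """
    z = hm.heights_nm
    dx, dy = hm.dx_nm, hm.dy_nm

    sa_nm = float(np.mean(np.abs(z - z.mean())))

    gx, gy = np.gradient(z, dx, dy)
    rms_grad = float(np.sqrt(np.mean(gx * gx + gy * gy)))
    sdq_deg = math.degrees(math.atan(rms_grad))

    # developed area: split each quad (i,j)-(i+1,j)-(i+1,j+1)-(i,j+1) into two
    # triangles along the main diagonal
    z00 = z[:-1, :-1]
    z10 = z[1:, :-1]
    z01 = z[:-1, 1:]
    z11 = z[1:, 1:]
    # triangle (00,10,11): cross([dx,0,z10-z00],[dx,dy,z11-z00])
    a1 = 0.5 * np.sqrt((-dy * (z10 - z00)) ** 2
                       + (dx * (z10 - z00) - dx * (z11 - z00)) ** 2
                       + (dx * dy) ** 2)
    # triangle (00,11,01): cross([dx,dy,z11-z00],[0,dy,z01-z00])
    a2 = 0.5 * np.sqrt((dy * (z11 - z00) - dy * (z01 - z00)) ** 2
                       + (-dx * (z01 - z00)) ** 2
                       + (dx * dy) ** 2)
    developed = float(np.sum(a1 + a2))
    projected = dx * dy * (z.shape[0] - 1) * (z.shape[1] - 1)
    sdr_pct = 100.0 * (developed - projected) / projected
    return RoughnessValues(sa_nm, sdq_deg, sdr_pct)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_height_map(cone: ConeFeature, cell: UnitCell, resolution: int) -> HeightMap:
    """Sample the cone/flat surface on a cell-centered ``resolution²`` grid.

    Grid points sit at pixel centers ``((i + 1/2) w / n, (j + 1/2) l / n)``,
    so the map is exact on the flat region and on the flank away from the
    base circle; with an odd resolution the central sample coincides with a
    centered apex.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    _check_cone_fits(cone, cell)
    n = int(resolution)
    dx = cell.width_um / n
    dy = cell.length_um / n
    x = (np.arange(n) + 0.5) * dx
    y = (np.arange(n) + 0.5) * dy
    cx, cy = cone.apex_in(cell)
    r = np.hypot(x[:, None] - cx, y[None, :] - cy)
    if cone.base_radius_um > 0:
        z_um = np.maximum(0.0, cone.height_um * (1.0 - r / cone.base_radius_um))
    else:
        z_um = np.zeros_like(r)
    return HeightMap(z_um * 1000.0, dx * 1000.0, dy * 1000.0)


# ---------------------------------------------------------------------------
# Fitting the cone to roughness targets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConeFit:
    """Result of `fit_cone`: the cone plus the achieved roughness triple."""

    cone: ConeFeature
    achieved: RoughnessValues
    mode: str
    spec: RoughnessSpec


def _max_radius(cell: UnitCell) -> float:
    return min(cell.width_um, cell.length_um) / 2.0


def _height_from_sdq(spec: RoughnessSpec, cell: UnitCell) -> float:
    # RMS gradient of a single cone is h*sqrt(pi/A), independent of radius.
    return math.tan(math.radians(spec.sdq_deg)) * math.sqrt(cell.area_um2 / math.pi)


def fit_cone(spec: RoughnessSpec, cell: UnitCell, mode: FitMode = "sa+sdq") -> ConeFit:
    """Find cone dimensions matching a roughness spec inside the cell.

    Modes
    -----
    ``"sa+sdq"``
        Match Sa and Sdq exactly (relative tolerance 1e-6).  Sdq determines
        the height in closed form; the radius is then bracketed on
        ``(0, min(w, l)/2]`` where Sa is monotonically increasing.
    ``"sdq+sdr"``
        Match Sdq and Sdr exactly, same strategy (Sdr is also monotonically
        increasing in the radius at fixed height).
    ``"least-squares-all"``
        Minimize the sum of squared relative errors over all three parameters
        subject to the base circle fitting inside the cell.

    Raises
    ------
    InfeasibleFitError
        If no cone with the base circle inside the cell footprint can reach
        the targets, naming the violated bound.
    """
    if mode not in FIT_MODES:
        raise ValueError(f"unknown fitting mode {mode!r}; expected one of {FIT_MODES}")

    a_max = _max_radius(cell)

    if spec.sa_nm == 0.0 and spec.sdq_deg == 0.0 and spec.sdr_pct == 0.0:
        cone = ConeFeature(0.0, 0.0)
        return ConeFit(cone, RoughnessValues(0.0, 0.0, 0.0), mode, spec)

    def achieved(a: float, h: float) -> RoughnessValues:
        return closed_form_cone_roughness(ConeFeature(a, h), cell)

    if mode in ("sa+sdq", "sdq+sdr"):
        h = _height_from_sdq(spec, cell)
        if h == 0.0:
            raise InfeasibleFitError(
                "sdq target is 0 (flat surface) but a nonzero sa/sdr target was given")
        if mode == "sa+sdq":
            target_name, target = "sa_nm", spec.sa_nm
            value = lambda a: achieved(a, h).sa_nm  # noqa: E731
        else:
            target_name, target = "sdr_pct", spec.sdr_pct
            value = lambda a: achieved(a, h).sdr_pct  # noqa: E731
        vmax = value(a_max)
        if target > vmax * (1.0 + 1e-12):
            raise InfeasibleFitError(
                f"target {target_name}={target:g} exceeds the maximum {vmax:g} "
                f"achievable with the base radius bounded by min(width, length)/2 "
                f"= {a_max:g} µm at the height {h:g} µm fixed by the sdq target")
        if target == 0.0:
            a = 0.0
        else:
            a = optimize.brentq(lambda aa: value(aa) - target, 1e-9 * a_max, a_max,
                                xtol=1e-14 * a_max, rtol=8.9e-16)
        cone = ConeFeature(a, h)
        return ConeFit(cone, achieved(a, h), mode, spec)

    # least-squares over all three, relative errors with floor scales to keep
    # zero targets well defined
    scales = (max(spec.sa_nm, 1.0), max(spec.sdq_deg, 1.0), max(spec.sdr_pct, 1.0))

    def residuals(p: np.ndarray) -> np.ndarray:
        a, h = p
        vals = achieved(a, h).as_tuple()
        tgts = (spec.sa_nm, spec.sdq_deg, spec.sdr_pct)
        return np.array([(v - t) / s for v, t, s in zip(vals, tgts, scales)])

    h0 = _height_from_sdq(spec, cell) or 0.1 * a_max
    best = None
    for a0 in (0.25 * a_max, 0.5 * a_max, 0.9 * a_max):
        res = optimize.least_squares(
            residuals, x0=[a0, h0], bounds=([1e-9, 0.0], [a_max, np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or res.cost < best.cost:
            best = res
    a, h = best.x
    cone = ConeFeature(float(a), float(h))
    return ConeFit(cone, achieved(a, h), mode, spec)


# ---------------------------------------------------------------------------
# Rigid master contact surface
# ---------------------------------------------------------------------------

class RigidSurface(Protocol):
    """Signed-distance contract for a rigid master surface.

    ``signed_distance(points)`` takes an ``(n, 3)`` array of points in µm and
    returns ``(d, normals)``: the signed distance in µm (positive outside the
    rigid solid, i.e. in the polymer) and the unit outward normal (gradient of
    the distance field) at each point.
    """

    def signed_distance(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]: ...


@dataclass(frozen=True)
class PlaneSurface:
    """Rigid half-space ``{p : n·p <= c}``; used by verification fixtures."""

    normal: tuple[float, float, float]
    offset_um: float

    def signed_distance(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = pts @ n - self.offset_um
        return d, np.broadcast_to(n, pts.shape).copy()


@dataclass(frozen=True)
class ConeSurface:
    """Rigid conical feature (cone plus its supporting half-space) with a
    uniform-gap offset.

    The solid is ``{(ρ, z) : z <= f(ρ)}`` in meridian coordinates around the
    apex axis, where ``f(ρ) = h (1 − ρ/a)`` under the base circle and 0
    outside — i.e. the titanium feature protruding into the polymer (+z is
    depth into the polymer).  ``gap_nm`` shrinks the solid by a uniform
    normal clearance: the signed distance is the distance to the nominal
    surface **plus** the gap, so every point of the nominal flank evaluates to
    exactly ``+gap``.

    ``x_period_um`` (optional) makes the feature periodic along x with the
    given pitch, so that large tangential translations of the master wrap
    around the unit cell as a uniform feature array would.
    """

    cone: ConeFeature
    gap_nm: float = 0.0
    apex_xy_um: tuple[float, float] = (0.0, 0.0)
    x_period_um: float | None = None

    def __post_init__(self) -> None:
        if self.gap_nm < 0:
            raise GeometryError("gap must be >= 0")
        # the offset flank vanishes when the gap exceeds the inradius of the
        # meridian triangle; guard against a degenerate master
        a, h = self.cone.base_radius_um, self.cone.height_um
        if a > 0 and h > 0:
            inradius_um = a * h / (a + h + math.hypot(a, h))
            if self.gap_nm * 1e-3 >= inradius_um:
                raise GeometryError(
                    f"gap {self.gap_nm} nm >= meridian inradius "
                    f"{inradius_um * 1e3:.1f} nm: offset cone degenerates")

    def signed_distance(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        shifts = [0.0]
        if self.x_period_um:
            shifts += [self.x_period_um, -self.x_period_um]
        best_d = None
        best_n = None
        for s in shifts:
            d, nrm = self._signed_distance_single(pts, self.apex_xy_um[0] + s)
            if best_d is None:
                best_d, best_n = d, nrm
            else:
                take = d < best_d
                best_d = np.where(take, d, best_d)
                best_n = np.where(take[:, None], nrm, best_n)
        return best_d + self.gap_nm * 1e-3, best_n

    def _signed_distance_single(
            self, pts: np.ndarray, cx: float) -> tuple[np.ndarray, np.ndarray]:
        a = self.cone.base_radius_um
        h = self.cone.height_um
        cy = self.apex_xy_um[1]
        dx = pts[:, 0] - cx
        dy = pts[:, 1] - cy
        z = pts[:, 2]
        rho = np.hypot(dx, dy)

        if a == 0.0 or h == 0.0:
            # flat master: solid is the half-space z <= 0
            d = z.copy()
            nrm = np.zeros_like(pts)
            nrm[:, 2] = 1.0
            return d, nrm

        # meridian polyline: apex (0, h) -> base (a, 0) -> ray (rho >= a, 0)
        # closest point on segment apex->base
        ex, ez = a, -h
        seg_len2 = ex * ex + ez * ez
        t = np.clip(((rho - 0.0) * ex + (z - h) * ez) / seg_len2, 0.0, 1.0)
        qs_r = t * ex
        qs_z = h + t * ez
        ds = np.hypot(rho - qs_r, z - qs_z)
        # closest point on the base ray
        qr_r = np.maximum(rho, a)
        dr = np.hypot(rho - qr_r, z)

        use_seg = ds <= dr
        q_r = np.where(use_seg, qs_r, qr_r)
        q_z = np.where(use_seg, qs_z, 0.0)
        dist = np.where(use_seg, ds, dr)

        # inside test: below the graph f(rho)
        f = np.where(rho <= a, h * (1.0 - rho / a), 0.0)
        sign = np.where(z < f, -1.0, 1.0)

        # meridian unit direction from closest point to p, oriented outward
        with np.errstate(invalid="ignore", divide="ignore"):
            m_r = (rho - q_r) / dist
            m_z = (z - q_z) / dist
        # on-surface points: use the analytic outward normal of the facet
        L = math.hypot(a, h)
        on_surf = dist < 1e-12
        m_r = np.where(on_surf, np.where(use_seg, h / L, 0.0), m_r) * sign
        m_z = np.where(on_surf, np.where(use_seg, a / L, 1.0), m_z) * sign

        e_rx = np.where(rho > 0, dx / np.where(rho > 0, rho, 1.0), 1.0)
        e_ry = np.where(rho > 0, dy / np.where(rho > 0, rho, 1.0), 0.0)
        nrm = np.stack([m_r * e_rx, m_r * e_ry, m_z], axis=1)
        return sign * dist, nrm


def offset_surface(cone: ConeFeature, gap_nm: float,
                   cell: UnitCell | None = None,
                   periodic_x: bool = True) -> ConeSurface:
    """Build the rigid master surface: the cone shrunk by a uniform gap.

    When a cell is given, the apex is placed at the cell center (or the cone's
    own apex position) and, with ``periodic_x``, the surface repeats with the
    cell width as pitch so tangential translations wrap periodically.
    """
    if gap_nm < 0:
        raise GeometryError("gap must be >= 0")
    if cell is not None:
        apex = cone.apex_in(cell)
        period = cell.width_um if periodic_x else None
    else:
        apex = cone.apex_xy_um or (0.0, 0.0)
        period = None
    return ConeSurface(cone=cone, gap_nm=gap_nm, apex_xy_um=apex, x_period_um=period)


# ---------------------------------------------------------------------------
# Height-map plain-text I/O
# ---------------------------------------------------------------------------

def write_height_map(hm: HeightMap, path) -> None:
    """Write a height map as a CSV matrix with '#' header comments (units nm)."""
    header = (f"# torquecell height map\n"
              f"# units: nm\n"
              f"# dx_nm: {hm.dx_nm!r}\n"
              f"# dy_nm: {hm.dy_nm!r}\n")
    buf = io.StringIO()
    np.savetxt(buf, hm.heights_nm, delimiter=",", fmt="%.10g")
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(buf.getvalue())


def read_height_map(path) -> HeightMap:
    """Read a height map written by `write_height_map`."""
    meta: dict[str, float] = {}
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    try:
                        meta[key.strip()] = float(val)
                    except ValueError:
                        pass
            elif line.strip():
                rows.append(line)
    if "dx_nm" not in meta or "dy_nm" not in meta:
        raise ValueError(f"{path}: missing dx_nm/dy_nm header comments")
    z = np.loadtxt(io.StringIO("".join(rows)), delimiter=",", ndmin=2)
    return HeightMap(z, meta["dx_nm"], meta["dy_nm"])
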