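"""Cross-section and duct-profile geometry.

All lengths are micrometres, areas μm², second moments μm⁴. A duct is an
ordered series of planar cross sections, each a simple polygon in its own
local frame, positioned by arc length ``z`` along an (assumed straight)
centerline. Centerline-curvature effects are negligible for the target
application — pial perivascular flows have Dean numbers of order 1e-4 — so
no curved-axis corrections are applied (see :func:`dean_number`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from shapely.geometry import Polygon

__all__ = [
    "WATER_37C",
    "FluidProps",
    "CrossSection",
    "DuctProfile",
    "GeometryError",
    "polygon_descriptors",
    "equivalent_ellipse_aspect",
    "area_derivatives",
    "dean_number",
]

#: Dynamic viscosity of water at 37 °C, Pa·s.
WATER_37C = 6.91e-4

#: Default axial resampling interval, μm (one pixel of the source imaging).
DEFAULT_DZ = 0.7


class GeometryError(ValueError):
    """Raised for degenerate or invalid cross-section geometry."""


@dataclass(frozen=True)
class FluidProps:
    """Newtonian fluid properties.

    Parameters
    ----------
    mu : float
        Dynamic viscosity in Pa·s. Default is water at 37 °C.
    """

    mu: float = WATER_37C

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"viscosity must be positive, got {self.mu}")


@dataclass(frozen=True)
class CrossSection:
    """One planar polygonal slice with derived scalar geometry.

    Vertices are stored counter-clockwise, first vertex not repeated.
    Second moments ``Ixx = ∫y²dA``, ``Iyy = ∫x²dA``, ``Ixy = ∫xy dA`` are
    central (about the centroid); ``Ip = Ixx + Iyy`` is the polar moment.
    ``beta`` is the aspect ratio of the ellipse with the same central second
    moments, always ≥ 1.
    """

    z: float
    vertices: np.ndarray
    A: float
    P: float
    req: float
    Dh: float
    centroid: tuple[float, float]
    Ixx: float
    Iyy: float
    Ixy: float
    Ip: float
    beta: float
    #: Optional analytic tag set by generators, e.g. {"kind": "circle",
    #: "r": 5.0} or {"kind": "ellipse", "b": 8.0, "c": 4.0}; enables
    #: closed-form (SUA) resistance evaluation.
    shape_info: dict | None = field(default=None, compare=False)

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


def _shoelace_cross(v: np.ndarray) -> np.ndarray:
    """Per-edge cross products x_i*y_{i+1} - x_{i+1}*y_i."""
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return x * yn - xn * y


def polygon_descriptors(
    vertices,
    z: float = 0.0,
    shape_info: dict | None = None,
    index: int | None = None,
) -> CrossSection:
    """Compute all scalar descriptors of a simple polygon.

    Area by the shoelace rule; centroid and second moments by the exact
    polygon formulas, evaluated about the centroid. Orientation is
    normalized internally to counter-clockwise, so all signs are independent
    of the input winding.

    Parameters
    ----------
    vertices : (N, 2) array_like
        Ordered boundary points in μm, implicitly closed, N ≥ 3.
    z : float
        Axial position of the slice, μm.
    shape_info : dict, optional
        Analytic tag propagated to the section (see :class:`CrossSection`).
    index : int, optional
        Slice index used in diagnostics when validating profile input.

    Raises
    ------
    GeometryError
        For N < 3, zero area, or a self-intersecting boundary.
    """
    where = "" if index is None else f" (slice {index})"
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise GeometryError(f"polygon needs >= 3 planar vertices{where}")
    # drop an explicitly repeated closing vertex
    if np.allclose(v[0], v[-1]):
        v = v[:-1]
    if v.shape[0] < 3:
        raise GeometryError(f"polygon needs >= 3 distinct vertices{where}")

    cross = _shoelace_cross(v)
    signed_area = 0.5 * cross.sum()
    if signed_area < 0:  # normalize to counter-clockwise
        v = v[::-1]
        cross = _shoelace_cross(v)
        signed_area = 0.5 * cross.sum()
    A = signed_area
    if not A > 0:
        raise GeometryError(f"degenerate polygon with zero area{where}")

    poly = Polygon(v)
    if not poly.is_valid:
        raise GeometryError(f"self-intersecting polygon boundary{where}")

    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cx = ((x + xn) * cross).sum() / (6.0 * A)
    cy = ((y + yn) * cross).sum() / (6.0 * A)
    # second moments about the origin (standard exact polygon formulas)
    Ixx_o = ((y * y + y * yn + yn * yn) * cross).sum() / 12.0
    Iyy_o = ((x * x + x * xn + xn * xn) * cross).sum() / 12.0
    Ixy_o = ((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross).sum() / 24.0
    # parallel-axis shift to the centroid
    Ixx = Ixx_o - A * cy * cy
    Iyy = Iyy_o - A * cx * cx
    Ixy = Ixy_o - A * cx * cy

    P = float(np.hypot(xn - x, yn - y).sum())
    req = float(np.sqrt(A / np.pi))
    Dh = float(4.0 * A / P)
    beta = _aspect_from_moments(Ixx, Iyy, Ixy, where)

    return CrossSection(
        z=float(z),
        vertices=v,
        A=float(A),
        P=P,
        req=req,
        Dh=Dh,
        centroid=(float(cx), float(cy)),
        Ixx=float(Ixx),
        Iyy=float(Iyy),
        Ixy=float(Ixy),
        Ip=float(Ixx + Iyy),
        beta=beta,
        shape_info=shape_info,
    )


def _aspect_from_moments(Ixx: float, Iyy: float, Ixy: float, where: str = "") -> float:
    """β = sqrt(λmax/λmin) from the central second-moment tensor."""
    mean = 0.5 * (Ixx + Iyy)
    dev = np.hypot(0.5 * (Ixx - Iyy), Ixy)
    lam_min, lam_max = mean - dev, mean + dev
    if not lam_min > 0:
        raise GeometryError(f"degenerate (collinear) boundary: lambda_min <= 0{where}")
    return float(np.sqrt(lam_max / lam_min))


def equivalent_ellipse_aspect(cross_section: CrossSection) -> float:
    """Aspect ratio of the ellipse with the same central second moments.

    The 2×2 moment tensor is diagonalized; β = sqrt(λmax/λmin) ≥ 1, which
    for an ellipse with semi-axes b ≥ c equals b/c.
    """
    return _aspect_from_moments(
        cross_section.Ixx, cross_section.Iyy, cross_section.Ixy
    )


def area_derivatives(
    z: np.ndarray,
    A: np.ndarray,
    dz_grid: float = DEFAULT_DZ,
    smoothing: int | None = None,
):
    """Resample the area function on a uniform grid and differentiate.

    The area samples are interpolated with a shape-preserving (PCHIP) cubic,
    resampled at ``dz_grid`` spacing, optionally smoothed with a symmetric
    moving window, and differentiated with central differences in the
    interior and one-sided second-order differences at the ends. With all
    lengths in μm, ``dA_dz`` has units μm and ``d2A_dz2`` is dimensionless.

    Parameters
    ----------
    z, A : array_like
        Axial positions (strictly increasing) and areas, ≥ 5 samples.
    dz_grid : float
        Uniform resampling interval, μm (default one imaging pixel, 0.7).
    smoothing : int, optional
        Odd window length for a moving-average smoothing of the resampled
        area before differentiation. Off by default; pixelized boundaries
        make the second derivative noisy, and this is the knob for it.

    Returns
    -------
    z_grid, A_grid, dA_dz, d2A_dz2 : ndarray
    """
    z = np.asarray(z, float)
    A = np.asarray(A, float)
    if z.size < 5:
        raise GeometryError("area_derivatives needs >= 5 sections")
    if not np.all(np.diff(z) > 0):
        raise GeometryError("axial positions must be strictly increasing")
    if dz_grid > np.mean(np.diff(z)) * (1.0 + 1e-9):
        warnings.warn(
            "resampling interval is larger than the mean section spacing",
            stacklevel=2,
        )
    interp = PchipInterpolator(z, A)
    n = max(int(round((z[-1] - z[0]) / dz_grid)) + 1, 5)
    z_grid = z[0] + dz_grid * np.arange(n)
    z_grid = z_grid[z_grid <= z[-1] + 1e-9 * dz_grid]
    A_grid = interp(z_grid)
    if smoothing is not None:
        if smoothing < 1 or smoothing % 2 == 0:
            raise ValueError("smoothing window must be a positive odd integer")
        if smoothing > 1:
            kernel = np.ones(smoothing) / smoothing
            pad = smoothing // 2
            padded = np.concatenate(
                [np.full(pad, A_grid[0]), A_grid, np.full(pad, A_grid[-1])]
            )
            A_grid = np.convolve(padded, kernel, mode="valid")
    dA_dz = np.gradient(A_grid, dz_grid, edge_order=2)
    d2A_dz2 = np.gradient(dA_dz, dz_grid, edge_order=2)
    return z_grid, A_grid, dA_dz, d2A_dz2


@dataclass(frozen=True)
class DuctProfile:
    """Ordered series of cross sections with a resampled area function.

    ``A_grid``, ``dA_dz`` and ``d2A_dz2`` live on the uniform ``z_grid``
    (spacing ``dz_grid``); they are ``None`` when the profile has fewer than
    five sections.
    """

    sections: tuple[CrossSection, ...]
    dz_grid: float = DEFAULT_DZ
    z_grid: np.ndarray | None = field(default=None, compare=False)
    A_grid: np.ndarray | None = field(default=None, compare=False)
    dA_dz: np.ndarray | None = field(default=None, compare=False)
    d2A_dz2: np.ndarray | None = field(default=None, compare=False)

    @classmethod
    def from_sections(
        cls,
        sections,
        dz_grid: float = DEFAULT_DZ,
        smoothing: int | None = None,
    ) -> "DuctProfile":
        sections = tuple(sections)
        if not sections:
            raise GeometryError("profile needs at least one section")
        z = np.array([s.z for s in sections])
        if not np.all(np.diff(z) > 0):
            raise GeometryError("section z positions must be strictly increasing")
        grids = (None, None, None, None)
        if len(sections) >= 5:
            A = np.array([s.A for s in sections])
            grids = area_derivatives(z, A, dz_grid=dz_grid, smoothing=smoothing)
        return cls(sections, dz_grid, *grids)

    @property
    def z(self) -> np.ndarray:
        return np.array([s.z for s in self.sections])

    @property
    def areas(self) -> np.ndarray:
        return np.array([s.A for s in self.sections])

    @property
    def L(self) -> float:
        """Total length z_last − z_first, μm."""
        return float(self.sections[-1].z - self.sections[0].z)

    def __len__(self) -> int:
        return len(self.sections)

    def d2A_at_sections(self) -> np.ndarray:
        """Second area derivative interpolated back onto the section grid."""
        if self.d2A_dz2 is None:
            raise GeometryError("profile too short for area derivatives")
        return np.interp(self.z, self.z_grid, self.d2A_dz2)


def dean_number(Re: float, A: float, rc: float) -> float:
    """Dean number De = Re·sqrt(re/rc) with re = sqrt(A/π).

    Measures the importance of centerline curvature (radius ``rc``, μm) for
    a duct of cross-sectional area ``A`` (μm²) at Reynolds number ``Re``.
    """
    if Re < 0:
        raise ValueError("Reynolds number must be non-negative")
    if not A > 0:
        raise ValueError("area must be positive")
    if not rc > 0:
        raise ValueError("radius of curvature must be positive")
    re = np.sqrt(A / np.pi)
    return float(Re * np.sqrt(re / rc))
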