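"""Series-unidirectional hydraulic resistance.

A nonuniform duct is modeled as a series of uniform ducts, one per cross
section, each carrying purely axial pressure-driven Stokes flow. On each
section the axial momentum balance is a Poisson problem

    ∇²φ = −1  in the section interior,   φ = 0  on the boundary,

where φ is the axial velocity per unit (−dp/dz)/μ. The resistance per unit
length follows as ℛ = μ / ∫φ dA, a pure geometry/viscosity property — no
flow rate needs to be prescribed. Solving numerically per section is the
"SUN" method; closed forms for circles and ellipses give "SUA".

The solver discretizes with finite differences on a Cartesian grid, using
Shortley–Weller stencils at boundary-cut links so the no-slip boundary is
honored to second order on arbitrary simple polygons. The flux integral
uses midpoint quadrature with boundary cells clipped to the polygon, which
preserves the overall O(h²) convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve
from shapely.geometry import LineString, Polygon, box

from .geometry import CrossSection, DuctProfile, FluidProps

__all__ = [
    "PoissonSolution",
    "ResistanceProfile",
    "SolverError",
    "solve_section_resistance",
    "resistance_circle_analytic",
    "resistance_ellipse_analytic",
    "profile_resistance",
    "total_resistance",
    "compare_profiles",
    "to_mmhg_min_per_ml_m",
    "from_mmhg_min_per_ml_m",
]

#: Exact conversion from Pa·s/μm⁴ to mmHg·min/(mL·m):
#: 1 mmHg = 133.322 Pa, 1 mL = 1e12 μm³, 1 m = 1e6 μm.
PAS_PER_UM4_TO_MMHG_MIN_PER_ML_M = 1e18 / (133.322 * 60.0)

#: Relative change between successive grid refinements at which the
#: adaptive solver stops.
REFINE_RTOL = 2e-3


class SolverError(RuntimeError):
    """Raised when a cross-section Poisson solve cannot be performed."""


def to_mmhg_min_per_ml_m(R):
    """Convert resistance per unit length from Pa·s/μm⁴ to mmHg·min/(mL·m)."""
    return np.asarray(R, float) * PAS_PER_UM4_TO_MMHG_MIN_PER_ML_M


def from_mmhg_min_per_ml_m(R):
    """Inverse of :func:`to_mmhg_min_per_ml_m` (exact round trip)."""
    return np.asarray(R, float) / PAS_PER_UM4_TO_MMHG_MIN_PER_ML_M


@dataclass(frozen=True)
class PoissonSolution:
    """Solution of the unit-gradient Poisson problem on one cross section.

    ``phi`` holds the field at the interior nodes ``points``; the axial
    velocity for an actual pressure gradient G = −dp/dz is ``G·phi/mu``.
    ``Qphi = ∫φ dA`` (μm⁴) and ``R = mu/Qphi`` (Pa·s/μm⁴).
    """

    points: np.ndarray
    phi: np.ndarray
    Qphi: float
    R: float
    h: float
    n_nodes: int
    residual: float


@dataclass(frozen=True)
class ResistanceProfile:
    """Per-slice resistance values from one method.

    ``R`` is in Pa·s/μm⁴ internally; :func:`to_mmhg_min_per_ml_m` converts
    to the physiological bookkeeping unit mmHg·min/(mL·m).
    """

    z: np.ndarray
    R: np.ndarray
    method: str
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "z", np.asarray(self.z, float))
        object.__setattr__(self, "R", np.asarray(self.R, float))
        if self.z.shape != self.R.shape:
            raise ValueError("z and R must have the same length")
        if self.R.size and not np.all(self.R > 0):
            raise ValueError("resistance values must be positive")

    def __len__(self) -> int:
        return self.z.size


def resistance_circle_analytic(r: float, fluid: FluidProps) -> float:
    """Hagen–Poiseuille resistance per unit length, R = 8μ/(πr⁴)."""
    if not r > 0:
        raise ValueError(f"radius must be positive, got {r}")
    return 8.0 * fluid.mu / (np.pi * r**4)


def resistance_ellipse_analytic(b: float, c: float, fluid: FluidProps) -> float:
    """Elliptical-duct resistance per unit length, R = 4μ(b²+c²)/(πb³c³).

    Symmetric in (b, c); reduces to Hagen–Poiseuille for b = c.
    """
    if not (b > 0 and c > 0):
        raise ValueError(f"semi-axes must be positive, got b={b}, c={c}")
    return 4.0 * fluid.mu * (b**2 + c**2) / (np.pi * b**3 * c**3)


def _boundary_fraction(boundary, x0, y0, dx, dy, h) -> float:
    """Fraction of the step h from (x0, y0) at which the boundary is cut."""
    seg = LineString([(x0, y0), (x0 + dx * h, y0 + dy * h)])
    inter = seg.intersection(boundary)
    if inter.is_empty:  # grazing-corner degeneracy: treat as a full leg
        return 1.0
    d = shapely.distance(shapely.points([(x0, y0)]), inter)
    theta = float(np.min(d)) / h
    return float(min(max(theta, 1e-3), 1.0))


def _solve_on_grid(poly: Polygon, h: float) -> PoissonSolution:
    """One Shortley–Weller finite-difference solve at grid spacing h."""
    minx, miny, maxx, maxy = poly.bounds
    xs = np.arange(minx - h, maxx + 2 * h, h)
    ys = np.arange(miny - h, maxy + 2 * h, h)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    inside = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
    n_in = int(inside.sum())
    if n_in == 0:
        raise SolverError("no interior nodes: resolution too coarse for section")

    idx = -np.ones(X.shape, dtype=np.int64)
    idx[inside] = np.arange(n_in)
    boundary = poly.boundary

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    ii, jj = np.nonzero(inside)
    inv_h2 = 1.0 / (h * h)
    for k in range(n_in):
        i, j = ii[k], jj[k]
        x0, y0 = X[i, j], Y[i, j]
        diag = 0.0
        # axes: x legs (±1, 0) and y legs (0, ±1)
        for dplus, dminus in (((1, 0), (-1, 0)), ((0, 1), (0, -1))):
            legs = []
            for di, dj in (dplus, dminus):
                ni, nj = i + di, j + dj
                if inside[ni, nj]:
                    legs.append((1.0, idx[ni, nj]))
                else:
                    theta = _boundary_fraction(boundary, x0, y0, di, dj, h)
                    legs.append((theta, -1))
            (tp, np_), (tm, nm_) = legs
            diag += 2.0 * inv_h2 / (tp * tm)
            if np_ >= 0:
                rows.append(k)
                cols.append(np_)
                vals.append(-2.0 * inv_h2 / (tp * (tp + tm)))
            if nm_ >= 0:
                rows.append(k)
                cols.append(nm_)
                vals.append(-2.0 * inv_h2 / (tm * (tp + tm)))
        rows.append(k)
        cols.append(k)
        vals.append(diag)

    A = csr_matrix((vals, (rows, cols)), shape=(n_in, n_in))
    rhs = np.ones(n_in)
    phi = spsolve(A, rhs)
    residual = float(np.max(np.abs(A @ phi - rhs)))

    # quadrature weights: full cells h², boundary-adjacent cells clipped
    weights = np.full(n_in, h * h)
    # nodes that could own a boundary-crossing cell: within h of the boundary
    pts = shapely.points(np.column_stack([X[inside], Y[inside]]))
    near = shapely.dwithin(pts, boundary, h)
    for k in np.nonzero(near)[0]:
        x0, y0 = X[ii[k], jj[k]], Y[ii[k], jj[k]]
        cell = box(x0 - h / 2, y0 - h / 2, x0 + h / 2, y0 + h / 2)
        weights[k] = cell.intersection(poly).area
    Qphi = float(np.dot(weights, phi))

    return PoissonSolution(
        points=np.column_stack([X[inside], Y[inside]]),
        phi=phi,
        Qphi=Qphi,
        R=np.nan,  # filled by caller once viscosity is known
        h=h,
        n_nodes=n_in,
        residual=residual,
    )


def solve_section_resistance(
    cross_section: CrossSection,
    fluid: FluidProps,
    resolution: float | None = None,
) -> PoissonSolution:
    """Solve the unit-gradient Poisson problem on one cross section (SUN).

    Parameters
    ----------
    cross_section : CrossSection
        Validated polygonal section.
    fluid : FluidProps
        Viscosity enters only through the final scaling R = μ/∫φ dA.
    resolution : float, optional
        Fixed grid spacing in μm. By default the grid is refined (halving
        the spacing) until two successive solves agree within 0.2%, with a
        floor of req/100 on the spacing.

    Returns
    -------
    PoissonSolution
        With ``R`` in Pa·s/μm⁴ at the final grid.
    """
    poly = cross_section.polygon()
    minx, miny, maxx, maxy = poly.bounds
    narrow = min(maxx - minx, maxy - miny)
    if resolution is not None:
        if not resolution > 0:
            raise ValueError("resolution must be positive")
        if narrow / resolution < 10:
            warnings.warn(
                "fewer than ~10 nodes across the narrowest dimension; "
                "resistance may be poorly resolved",
                stacklevel=2,
            )
        sol = _solve_on_grid(poly, resolution)
        return _with_R(sol, fluid)

    h = narrow / 24.0
    floor = cross_section.req / 100.0
    sol = _solve_on_grid(poly, h)
    while True:
        if h / 2.0 < floor:
            break
        h /= 2.0
        new = _solve_on_grid(poly, h)
        change = abs(new.Qphi - sol.Qphi) / new.Qphi
        sol = new
        if change < REFINE_RTOL:
            break
    return _with_R(sol, fluid)


def _with_R(sol: PoissonSolution, fluid: FluidProps) -> PoissonSolution:
    if not sol.Qphi > 0:
        raise SolverError("non-positive flux integral: degenerate solve")
    return PoissonSolution(
        points=sol.points,
        phi=sol.phi,
        Qphi=sol.Qphi,
        R=fluid.mu / sol.Qphi,
        h=sol.h,
        n_nodes=sol.n_nodes,
        residual=sol.residual,
    )


def _section_analytic(section: CrossSection, fluid: FluidProps) -> float:
    info = section.shape_info
    if not info:
        raise SolverError(
            "SUA needs sections tagged circular/elliptical (shape_info); "
            f"slice at z={section.z} is untagged"
        )
    kind = info.get("kind")
    if kind == "circle":
        return resistance_circle_analytic(info["r"], fluid)
    if kind == "ellipse":
        return resistance_ellipse_analytic(info["b"], info["c"], fluid)
    raise SolverError(f"unknown analytic shape kind {kind!r} at z={section.z}")


def profile_resistance(
    profile: DuctProfile,
    fluid: FluidProps,
    method: str = "SUN",
    trim_end: int = 0,
    resolution: float | None = None,
) -> ResistanceProfile:
    """Per-section resistance along a duct (series-unidirectional).

    ``method`` is "SUN" (numerical Poisson solve per section) or "SUA"
    (closed forms, requiring sections tagged circular/elliptical).
    ``trim_end`` drops that many trailing sections, mirroring the outlet
    exclusion used when post-processing 3D reference simulations; default 0.
    """
    method = method.upper()
    if method not in ("SUN", "SUA"):
        raise ValueError(f"unknown series-unidirectional method {method!r}")
    sections = profile.sections
    if trim_end < 0:
        raise ValueError("trim_end must be >= 0")
    if trim_end:
        if trim_end >= len(sections):
            raise ValueError("trim_end leaves no sections")
        sections = sections[: len(sections) - trim_end]

    z = np.array([s.z for s in sections])
    R = np.empty(z.size)
    for i, sec in enumerate(sections):
        try:
            if method == "SUN":
                R[i] = solve_section_resistance(sec, fluid, resolution).R
            else:
                R[i] = _section_analytic(sec, fluid)
        except Exception as exc:
            raise SolverError(f"section {i} (z={sec.z:g}) failed: {exc}") from exc
    meta = {"viscosity_Pa_s": fluid.mu, "resolution_um": resolution, "trim_end": trim_end}
    return ResistanceProfile(z=z, R=R, method=method, meta=meta)


def total_resistance(rp: ResistanceProfile, L: float) -> float:
    """Total resistance R_total = mean(ℛ)·L of a duct of length L (μm)."""
    if len(rp) == 0:
        raise ValueError("empty resistance profile")
    return float(np.mean(rp.R) * L)


def compare_profiles(test: ResistanceProfile, reference: ResistanceProfile):
    """Percent error of ``test`` against ``reference`` on a shared z grid.

    Returns ``(mean_error_pct, rms_error_pct, per_section_error_pct)`` with
    per-section error 100·(R_test − R_ref)/R_ref. Grids must match exactly;
    no implicit resampling is performed.
    """
    if len(test) != len(reference) or not np.allclose(
        test.z, reference.z, rtol=0, atol=1e-9
    ):
        raise ValueError("profiles are on different z grids")
    err = 100.0 * (test.R - reference.R) / reference.R
    return float(np.mean(err)), float(np.sqrt(np.mean(err**2))), err
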