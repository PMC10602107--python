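"""Synthetic duct geometries for testing and benchmarking.

Generators for the standard test shapes: the sinusoidal circular duct, a
circular-equivalent duct matching an arbitrary area profile, analytic
elliptical ducts, and randomized perivascular-like "lobe" fixtures.

The lobe fixtures emulate segmented pial perivascular cross sections:
crescent-shaped lobes (an off-center disc subtracted from a disc) with
low-order Fourier boundary perturbations, smooth axial modulation of area
and aspect ratio, and optional pixel quantization at 0.7 μm — the imaging
resolution of the data they stand in for. They are a stated emulation
target (areas ≈ 100 μm², equivalent-ellipse aspect ratios ≈ 1.1–2, slice
spacing ≈ 0.7 μm, |d²A/dz²| mostly below 2), not a claim of statistical
realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import shapely
from shapely.geometry import Point
from skimage import measure

from .geometry import (
    CrossSection,
    DuctProfile,
    GeometryError,
    polygon_descriptors,
)
from .lubrication import EllipseDuct

__all__ = [
    "DuctSpec",
    "sinusoidal_duct",
    "circular_duct_from_area",
    "ellipse_duct",
    "lobe_fixture",
]

#: Boundary vertex count for polygonized analytic sections. A 256-gon's
#: area deficit relative to the true circle is ~1e-4 relative.
DEFAULT_N_VERTICES = 256


def _circle_polygon(r: float, n: int) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def sinusoidal_duct(
    r0: float = 50.0,
    amp: float = 1.5,
    wavelength: float = 50.0,
    length: float = 100.0,
    dz: float = 0.7,
    n_vertices: int = DEFAULT_N_VERTICES,
) -> DuctProfile:
    """Circular duct with radius r(z) = r0 + amp·sin(2πz/wavelength).

    The default length covers two wavelengths so period averages are well
    defined. Sections are tagged circular for analytic (SUA) evaluation.
    """
    if not amp < r0:
        raise ValueError("amplitude must be smaller than the mean radius")
    n = max(int(np.floor(length / dz + 1e-9)) + 1, 2)
    z = dz * np.arange(n)
    sections = []
    for i, zi in enumerate(z):
        r = r0 + amp * np.sin(2.0 * np.pi * zi / wavelength)
        sections.append(
            polygon_descriptors(
                _circle_polygon(r, n_vertices),
                z=zi,
                shape_info={"kind": "circle", "r": float(r)},
                index=i,
            )
        )
    return DuctProfile.from_sections(sections, dz_grid=dz)


def circular_duct_from_area(
    profile: DuctProfile,
    n_vertices: int = DEFAULT_N_VERTICES,
) -> DuctProfile:
    """Circular-equivalent duct: same axial area variation, circular slices.

    Each section is replaced by a circle of radius sqrt(A/π) at the same z.
    Already-circular sections keep their tagged radius (idempotence).
    """
    sections = []
    for i, sec in enumerate(profile.sections):
        if sec.shape_info and sec.shape_info.get("kind") == "circle":
            r = sec.shape_info["r"]
        else:
            r = np.sqrt(sec.A / np.pi)
        sections.append(
            polygon_descriptors(
                _circle_polygon(r, n_vertices),
                z=sec.z,
                shape_info={"kind": "circle", "r": float(r)},
                index=i,
            )
        )
    return DuctProfile.from_sections(sections, dz_grid=profile.dz_grid)


def ellipse_duct(
    b_fn: Callable,
    c_fn: Callable,
    length: float,
    dz: float = 0.7,
    n_vertices: int = DEFAULT_N_VERTICES,
):
    """Elliptical duct from semi-axis functions b(z), c(z).

    Returns ``(DuctProfile, EllipseDuct)``: polygonized sections (tagged
    elliptical, for SUA/SUN) plus the analytic object for the lubrication
    module.
    """
    n = max(int(np.floor(length / dz + 1e-9)) + 1, 2)
    z = dz * np.arange(n)
    th = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    sections = []
    for i, zi in enumerate(z):
        b = float(np.asarray(b_fn(zi)))
        c = float(np.asarray(c_fn(zi)))
        if not (b > 0 and c > 0):
            raise ValueError(f"semi-axes must be positive at z={zi}")
        verts = np.column_stack([b * np.cos(th), c * np.sin(th)])
        sections.append(
            polygon_descriptors(
                verts,
                z=zi,
                shape_info={"kind": "ellipse", "b": b, "c": c},
                index=i,
            )
        )
    duct = EllipseDuct.from_callables(
        lambda zz: np.vectorize(b_fn)(zz), lambda zz: np.vectorize(c_fn)(zz), length
    )
    return DuctProfile.from_sections(sections, dz_grid=dz), duct


# --- lobe fixtures ---------------------------------------------------------


def _crescent(ri_frac: float, tip_frac: float, n: int = 360) -> np.ndarray:
    """Unit-scale crescent: disc minus an offset disc cutting into it.

    ``ri_frac`` is the cutter radius relative to the outer disc;
    ``tip_frac`` controls how deep the cutter pokes through the outer
    boundary (larger → thinner, hornier crescent).
    """
    Ro = 1.0
    Ri = ri_frac * Ro
    # cutter center offset: Ri + d > Ro guarantees a simply connected lobe
    d = (Ro - Ri) + tip_frac * 2.0 * Ri
    outer = Point(0.0, 0.0).buffer(Ro, quad_segs=n // 4)
    inner = Point(0.0, d).buffer(Ri, quad_segs=n // 4)
    lobe = outer.difference(inner)
    verts = np.asarray(lobe.exterior.coords)[:-1]
    return verts


def _resample_closed(verts: np.ndarray, n: int) -> np.ndarray:
    ring = shapely.geometry.Polygon(verts).exterior
    s = np.linspace(0.0, ring.length, n, endpoint=False)
    pts = shapely.line_interpolate_point(ring, s)
    return shapely.get_coordinates(pts)


def _adjust_beta(verts: np.ndarray, beta_target: float, iters: int = 4) -> np.ndarray:
    """Scale along x to push the equivalent-ellipse aspect toward target.

    The crescent base is symmetric about the y axis, so its principal axes
    are essentially coordinate-aligned and a pure x-scaling controls β.
    """
    v = verts.copy()
    for _ in range(iters):
        cs = polygon_descriptors(v)
        elongated_x = cs.Iyy >= cs.Ixx
        s = beta_target / cs.beta
        if elongated_x:
            v = np.column_stack([v[:, 0] * s, v[:, 1]])
        else:
            v = np.column_stack([v[:, 0], v[:, 1] * s])
    return v


def _quantize(verts: np.ndarray, pixel: float) -> np.ndarray:
    """Pixelate a section the way mask segmentation would.

    Rasterize on a fixed, origin-aligned grid of the given pixel size and
    re-extract the boundary with marching squares. The grid is global (not
    per-slice), so quantization errors vary smoothly from slice to slice
    as the underlying shape does.
    """
    minx, miny, maxx, maxy = shapely.geometry.Polygon(verts).bounds
    i0 = int(np.floor(minx / pixel)) - 2
    j0 = int(np.floor(miny / pixel)) - 2
    i1 = int(np.ceil(maxx / pixel)) + 2
    j1 = int(np.ceil(maxy / pixel)) + 2
    xs = (np.arange(i0, i1 + 1) + 0.5) * pixel
    ys = (np.arange(j0, j1 + 1) + 0.5) * pixel
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    poly = shapely.geometry.Polygon(verts)
    mask = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise GeometryError("section vanished under pixel quantization")
    contour = max(contours, key=len)
    # (row, col) indices -> physical coordinates of pixel centers
    vx = (contour[:, 0] + i0 + 0.5) * pixel
    vy = (contour[:, 1] + j0 + 0.5) * pixel
    out = np.column_stack([vx, vy])
    if np.allclose(out[0], out[-1]):
        out = out[:-1]
    return out


@dataclass(frozen=True)
class _LobeParams:
    ri_frac: float
    tip_frac: float
    fourier_amp: np.ndarray
    fourier_phase: np.ndarray
    fourier_mod_amp: np.ndarray
    fourier_mod_phase: np.ndarray
    fourier_mod_wl: np.ndarray
    area_eps: np.ndarray
    area_wl: np.ndarray
    area_phase: np.ndarray
    beta0: float
    beta_amp: float
    beta_wl: float
    beta_phase: float


def _draw_params(rng: np.random.Generator) -> _LobeParams:
    k = np.arange(2, 6)
    return _LobeParams(
        ri_frac=rng.uniform(0.55, 0.75),
        tip_frac=rng.uniform(0.25, 0.45),
        fourier_amp=rng.uniform(0.0, 0.03, size=k.size),
        fourier_phase=rng.uniform(0.0, 2 * np.pi, size=k.size),
        fourier_mod_amp=rng.uniform(0.0, 0.3, size=k.size),
        fourier_mod_phase=rng.uniform(0.0, 2 * np.pi, size=k.size),
        fourier_mod_wl=rng.uniform(25.0, 45.0, size=k.size),
        area_eps=np.array([rng.uniform(0.05, 0.10), rng.uniform(0.02, 0.05)]),
        area_wl=np.array([rng.uniform(25.0, 45.0), rng.uniform(15.0, 25.0)]),
        area_phase=rng.uniform(0.0, 2 * np.pi, size=2),
        beta0=rng.uniform(1.25, 1.75),
        beta_amp=rng.uniform(0.05, 0.15),
        beta_wl=rng.uniform(25.0, 45.0),
        beta_phase=rng.uniform(0.0, 2 * np.pi),
    )


def lobe_fixture(
    seed: int,
    n_sections: int = 40,
    mean_area: float = 100.0,
    beta_range: tuple[float, float] = (1.1, 2.0),
    dz: float = 0.7,
    quantize: bool = True,
    jitter_dz: float = 0.0,
) -> DuctProfile:
    """Randomized perivascular-like lobe duct.

    Parameters
    ----------
    seed : int
        Seeds a private generator; identical seeds give identical output.
    n_sections : int
        Number of slices (default 40, ≈ 27 μm of duct at 0.7 μm spacing).
    mean_area : float
        Axial mean of the target area, μm².
    beta_range : (lo, hi)
        Admissible band for per-slice equivalent-ellipse aspect ratios;
        targets are drawn from its interior so quantization noise stays in
        band.
    dz : float
        Slice spacing, μm.
    quantize : bool
        Pixelate boundaries at 0.7 μm via rasterize + marching squares,
        emulating mask segmentation.
    jitter_dz : float
        Optional relative jitter of the slice spacing (e.g. 0.15 for the
        "approximately 0.7 μm, but varying" spacing of real section
        series), exercising the nonuniform-z resampling path.
    """
    rng = np.random.default_rng(seed)
    params = _draw_params(rng)
    blo, bhi = beta_range
    margin = 0.1 * (bhi - blo)

    if jitter_dz:
        steps = dz * (1.0 + rng.uniform(-jitter_dz, jitter_dz, size=n_sections - 1))
        z = np.concatenate([[0.0], np.cumsum(steps)])
    else:
        z = dz * np.arange(n_sections)

    base = _resample_closed(_crescent(params.ri_frac, params.tip_frac), 240)
    centroid = base.mean(axis=0)
    rel = base - centroid
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    radii = np.hypot(rel[:, 0], rel[:, 1])

    sections = []
    for i, zi in enumerate(z):
        A_t = mean_area * (
            1.0
            + np.sum(
                params.area_eps
                * np.sin(2 * np.pi * zi / params.area_wl + params.area_phase)
            )
        )
        beta_t = params.beta0 + params.beta_amp * np.sin(
            2 * np.pi * zi / params.beta_wl + params.beta_phase
        )
        beta_t = float(np.clip(beta_t, blo + margin, bhi - margin))

        for attempt in range(6):
            shrink = 0.5**attempt
            amps = params.fourier_amp * shrink * (
                1.0
                + params.fourier_mod_amp
                * np.sin(2 * np.pi * zi / params.fourier_mod_wl + params.fourier_mod_phase)
            )
            pert = np.ones_like(theta)
            for kk, (a, ph) in enumerate(zip(amps, params.fourier_phase), start=2):
                pert += a * np.cos(kk * theta + ph)
            verts = centroid + np.column_stack(
                [radii * pert * np.cos(theta), radii * pert * np.sin(theta)]
            )
            if shapely.geometry.Polygon(verts).is_valid:
                break
        else:
            raise GeometryError(f"could not build a simple lobe boundary (slice {i})")

        verts = _adjust_beta(verts, beta_t)
        cs = polygon_descriptors(verts)
        verts = (verts - cs.centroid) * np.sqrt(A_t / cs.A)  # uniform area rescale
        if quantize:
            verts = _quantize(verts, 0.7)
        sections.append(polygon_descriptors(verts, z=zi, index=i))

    return DuctProfile.from_sections(sections, dz_grid=dz)


@dataclass(frozen=True)
class DuctSpec:
    """Declarative duct description (for configs and the CLI).

    ``kind`` is one of "sinusoid", "circular_from_area", "ellipse", "lobe";
    ``parameters`` holds the kind-specific keyword arguments of the
    corresponding generator.
    """

    kind: str
    parameters: dict = field(default_factory=dict)

    def build(self, base_profile: DuctProfile | None = None):
        if self.kind == "sinusoid":
            return sinusoidal_duct(**self.parameters)
        if self.kind == "circular_from_area":
            if base_profile is None:
                raise ValueError("circular_from_area needs a base profile")
            return circular_duct_from_area(base_profile, **self.parameters)
        if self.kind == "ellipse":
            p = dict(self.parameters)
            b0, c0 = p.pop("b0"), p.pop("c0")
            db, dc = p.pop("db", 0.0), p.pop("dc", 0.0)
            length = p.pop("length")
            profile, _ = ellipse_duct(
                lambda z: b0 + db * z, lambda z: c0 + dc * z, length, **p
            )
            return profile
        if self.kind == "lobe":
            return lobe_fixture(**self.parameters)
        raise ValueError(f"unknown duct kind {self.kind!r}")
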