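"""Extended lubrication theory for nonuniform elliptical and circular ducts.

The Stokes flow in a long, slowly varying duct admits a perturbation
expansion in the squared transverse-to-axial aspect ratio. At leading
order every cross section behaves as a uniform duct (the basis of the
series-unidirectional approximation); the second-order term captures the
effect of axial wall slope and curvature on the resistance.

For an elliptical duct x²/b(z)² + y²/c(z)² = 1 the orders are closed-form:

    ℛ0 = 4μ(b²+c²)/(πb³c³)
    ℛ2 = −μ/(6πb⁴c⁴)·[3c⁴b′c′ + b³c(2b′² − 7cc″ + 8c′²)
          + bc³(8b′² − cc″ + 2c′²) + b⁴(3b′c′ − cb″) + b²c²(6b′c′ − 7cb″)]

with ℛ_total = ℛ0 + ℛ2. Everything here is evaluated dimensionally: with
all lengths sharing one unit (μm), A′ and A″ are dimensionless and no
separate aspect-ratio bookkeeping is needed at the interface.

The fractional error of the uniform-duct (0th-order) approximation is
E = ℛ2/(ℛ0 + ℛ2); E > 0 means the true resistance exceeds the 0th-order
estimate, so the series-unidirectional percent error is −100·E. When the
area variation is small the second derivative dominates:
E ≈ f(β)·A″ with f(β) = (β⁴+14β²+1)/(48πβ(β²+1)), and f(1) = 1/(6π).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.interpolate import CubicSpline

from .geometry import FluidProps
from .unidirectional import ResistanceProfile

__all__ = [
    "EllipseDuct",
    "EltResult",
    "r0",
    "r2",
    "r2_fixed_beta",
    "error_fraction",
    "beta_prefactor",
    "elt_profile",
]


@dataclass(frozen=True)
class EllipseDuct:
    """Analytic duct defined by semi-axis functions b(z), c(z) in μm.

    Derivative callables may be supplied analytically; otherwise they are
    produced by spline differentiation of sampled axes. ``alpha`` is the
    global slenderness sqrt(b0·c0)/L; the expansion assumes it is small.
    """

    b: Callable[[np.ndarray], np.ndarray]
    c: Callable[[np.ndarray], np.ndarray]
    db: Callable[[np.ndarray], np.ndarray]
    dc: Callable[[np.ndarray], np.ndarray]
    d2b: Callable[[np.ndarray], np.ndarray]
    d2c: Callable[[np.ndarray], np.ndarray]
    length: float

    @property
    def alpha(self) -> float:
        z0 = np.array([0.0])
        b0 = float(self.b(z0)[0])
        c0 = float(self.c(z0)[0])
        return float(np.sqrt(b0 * c0) / self.length)

    @classmethod
    def from_callables(cls, b, c, length, db=None, dc=None, d2b=None, d2c=None):
        """Build from axis callables, differentiating numerically if needed."""

        def fd1(f):
            def d(z, f=f):
                z = np.asarray(z, float)
                h = max(length * 1e-6, 1e-9)
                return (f(z + h) - f(z - h)) / (2 * h)

            return d

        def fd2(f):
            def d(z, f=f):
                z = np.asarray(z, float)
                h = max(length * 1e-4, 1e-6)
                return (f(z + h) - 2 * f(z) + f(z - h)) / (h * h)

            return d

        return cls(
            b=lambda z: np.asarray(b(np.asarray(z, float)), float),
            c=lambda z: np.asarray(c(np.asarray(z, float)), float),
            db=db or fd1(b),
            dc=dc or fd1(c),
            d2b=d2b or fd2(b),
            d2c=d2c or fd2(c),
            length=float(length),
        )

    @classmethod
    def from_samples(cls, z, b, c) -> "EllipseDuct":
        """C² cubic spline through sampled semi-axes.

        A twice continuously differentiable interpolant is required here
        because the second-order resistance needs b″ and c″; a merely C¹
        shape-preserving interpolant produces spurious curvature spikes.
        """
        z = np.asarray(z, float)
        sb = CubicSpline(z, np.asarray(b, float))
        sc = CubicSpline(z, np.asarray(c, float))
        return cls(
            b=sb,
            c=sc,
            db=sb.derivative(1),
            dc=sc.derivative(1),
            d2b=sb.derivative(2),
            d2c=sc.derivative(2),
            length=float(z[-1] - z[0]),
        )

    @classmethod
    def from_radius_profile(cls, z, r) -> "EllipseDuct":
        """Circular duct b(z) = c(z) = r(z) from sampled radii."""
        return cls.from_samples(z, r, r)


@dataclass(frozen=True)
class EltResult:
    """Per-station extended-lubrication resistances and error fraction."""

    z: np.ndarray
    R0: np.ndarray
    R2: np.ndarray
    R_total: np.ndarray
    E: np.ndarray


def r0(b, c, mu: float):
    """0th-order (uniform elliptical duct) resistance, ℛ0 = 4μ(b²+c²)/(πb³c³)."""
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    if np.any(b <= 0) or np.any(c <= 0):
        raise ValueError("semi-axes must be positive")
    return 4.0 * mu * (b**2 + c**2) / (np.pi * b**3 * c**3)


def r2(b, c, db, dc, d2b, d2c, mu: float):
    """Second-order resistance correction for a nonuniform elliptical duct.

    Vanishes for a uniform duct, is invariant under the simultaneous swap
    (b, b′, b″) ↔ (c, c′, c″), and reduces to :func:`r2_fixed_beta` when
    b/c is constant in z — all three properties are enforced as test
    guards on the transcription of the polynomial.
    """
    symbolic = any(hasattr(v, "free_symbols") for v in (b, c, db, dc, d2b, d2c))
    if symbolic:
        from sympy import pi  # exact arithmetic for algebraic verification
    else:
        pi = np.pi
        b = np.asarray(b, float)
        c = np.asarray(c, float)
        db = np.asarray(db, float)
        dc = np.asarray(dc, float)
        d2b = np.asarray(d2b, float)
        d2c = np.asarray(d2c, float)
        if np.any(b <= 0) or np.any(c <= 0):
            raise ValueError("semi-axes must be positive")
    bracket = (
        3 * c**4 * db * dc
        + b**3 * c * (2 * db**2 - 7 * c * d2c + 8 * dc**2)
        + b * c**3 * (8 * db**2 - c * d2c + 2 * dc**2)
        + b**4 * (3 * db * dc - c * d2b)
        + b**2 * c**2 * (6 * db * dc - 7 * c * d2b)
    )
    return -mu / (6 * pi * b**4 * c**4) * bracket


def r2_fixed_beta(A, dA, d2A, beta: float, mu: float):
    """ℛ2 for a self-similar duct (fixed aspect ratio β, dβ/dz = 0).

    ℛ2 = −μ/(12β²A²)·[3(A′²/A)(1+6β²+β⁴) − A″(1+14β²+β⁴)].
    Invariant under β → 1/β.
    """
    if not any(hasattr(v, "free_symbols") for v in (A, dA, d2A, beta)):
        A = np.asarray(A, float)
        dA = np.asarray(dA, float)
        d2A = np.asarray(d2A, float)
        if np.any(A <= 0):
            raise ValueError("area must be positive")
    b2 = beta * beta
    return (
        -mu
        / (12 * b2 * A**2)
        * (3 * dA**2 / A * (1 + 6 * b2 + b2 * b2) - d2A * (1 + 14 * b2 + b2 * b2))
    )


def beta_prefactor(beta) -> np.ndarray | float:
    """Aspect-ratio prefactor f(β) = (β⁴+14β²+1)/(48πβ(β²+1)).

    The leading coefficient of A″ in the fractional-error formula.
    Satisfies f(β) = f(1/β) and f(1) = 1/(6π) ≈ 0.05305; it is a weak
    function of β, staying within 13.3% of f(1) for β < 7.
    """
    beta = np.asarray(beta, float)
    if np.any(beta <= 0):
        raise ValueError("beta must be positive")
    out = (beta**4 + 14.0 * beta**2 + 1.0) / (48.0 * np.pi * beta * (beta**2 + 1.0))
    return float(out) if out.ndim == 0 else out


def error_fraction(A, dA, d2A, beta):
    """Fractional error E of the uniform-duct (0th-order) approximation.

    E = [−3(A′²/A)(6β²+β⁴+1) + A″(β⁴+14β²+1)] / (48πβ(β²+1)), evaluated
    with dimensional area derivatives (lengths in one common unit). For
    small area variation E ≈ f(β)·A″; at β = 1 with A′ = 0, E = A″/(6π)
    exactly. E > 0 means the true resistance exceeds the 0th-order
    estimate, so the series-unidirectional percent error is −100·E.
    """
    A = np.asarray(A, float)
    dA = np.asarray(dA, float)
    d2A = np.asarray(d2A, float)
    beta = np.asarray(beta, float)
    if np.any(A <= 0):
        raise ValueError("area must be positive")
    b2 = beta * beta
    num = -3.0 * dA**2 / A * (6.0 * b2 + b2 * b2 + 1.0) + d2A * (b2 * b2 + 14.0 * b2 + 1.0)
    out = num / (48.0 * np.pi * beta * (b2 + 1.0))
    return float(out) if out.ndim == 0 else out


def elt_profile(
    duct: EllipseDuct,
    fluid: FluidProps,
    z: np.ndarray | None = None,
    dz: float = 0.7,
):
    """Extended-lubrication resistance along an elliptical (or circular) duct.

    Returns ``(ResistanceProfile, EltResult)`` where the profile carries
    ℛ_total = ℛ0 + ℛ2 (method label "ELT") and the result additionally
    holds the per-station error fraction E of the series-unidirectional
    approximation (its predicted percent error is −100·E).

    Warns when |E| exceeds 0.5 anywhere: the perturbation expansion is
    unreliable for such strong axial variation.
    """
    if z is None:
        n = max(int(round(duct.length / dz)) + 1, 2)
        z = np.linspace(0.0, duct.length, n)
    z = np.asarray(z, float)
    b = duct.b(z)
    c = duct.c(z)
    R0 = r0(b, c, fluid.mu)
    R2 = r2(b, c, duct.db(z), duct.dc(z), duct.d2b(z), duct.d2c(z), fluid.mu)
    R_total = R0 + R2
    if np.any(R_total <= 0):
        raise ValueError("non-positive total resistance: duct outside expansion validity")
    E = R2 / R_total
    if np.max(np.abs(E)) > 0.5:
        warnings.warn(
            "|E| > 0.5 somewhere along the duct; the second-order expansion "
            "is unreliable there",
            stacklevel=2,
        )
    rp = ResistanceProfile(
        z=z, R=R_total, method="ELT", meta={"viscosity_Pa_s": fluid.mu, "alpha": duct.alpha}
    )
    return rp, EltResult(z=z, R0=R0, R2=R2, R_total=R_total, E=E)
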