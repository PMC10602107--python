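"""Second-derivative error correction for series-unidirectional resistance.

The percent error of the series-unidirectional approximation correlates
with d²A/dz², the second axial derivative of the cross-sectional area (the
leading prediction of extended lubrication theory). Fitting a line

    err% ≈ slope·d²A/dz² + intercept

against a trusted reference yields a multiplicative correction

    λ = 1 / (1 + err%/100),      ℛ_corrected = ℛ_SU · λ,

which inverts the predicted relative error. Two fitted presets are
shipped: ``realistic`` (slope −1.8, intercept −3.2) for lobe-shaped
perivascular sections and ``circular`` (slope −4.4, intercept 0.22) for
circular-equivalent ducts, both estimated against full 3D Navier–Stokes
references on mouse pial perivascular geometries; re-deriving them needs
that external data and solver. The λ form itself is an interpretation: the
error is defined relative to the reference, so dividing by (1 + err)
undoes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry import DuctProfile
from .unidirectional import ResistanceProfile

__all__ = [
    "CorrectionFit",
    "FIT_PRESETS",
    "fit_error_line",
    "lambda_factor",
    "apply_correction",
]


@dataclass(frozen=True)
class CorrectionFit:
    """Linear fit of percent error against d²A/dz² with percentile bands.

    ``slope`` is % per unit d²A/dz², ``intercept`` %. The optional band
    arrays hold binned conditional statistics (bin centers with 5th, 50th
    and 95th percentiles of the error in each equal-count bin).
    ``pearson_r``/``p_value`` quantify the correlation; note that
    neighboring sections are spatially autocorrelated, which the p-value
    does not account for.
    """

    slope: float
    intercept: float
    source: str = "custom"
    bin_centers: np.ndarray | None = field(default=None, compare=False)
    band_lo: np.ndarray | None = field(default=None, compare=False)
    band_median: np.ndarray | None = field(default=None, compare=False)
    band_hi: np.ndarray | None = field(default=None, compare=False)
    pearson_r: float | None = None
    p_value: float | None = None
    stderr: float | None = None

    def predict(self, d2A_dz2):
        """Predicted percent error at the given d²A/dz²."""
        return self.slope * np.asarray(d2A_dz2, float) + self.intercept


#: Fitted presets from 3D reference simulations of mouse pial PVS
#: geometries (not re-derivable at desk scale; shipped verbatim).
FIT_PRESETS = {
    "realistic": CorrectionFit(slope=-1.8, intercept=-3.2, source="realistic"),
    "circular": CorrectionFit(slope=-4.4, intercept=0.22, source="circular"),
}


def fit_error_line(errors_pct, d2A_dz2, n_bins: int = 10) -> CorrectionFit:
    """Least-squares line through percent error vs d²A/dz².

    Also reports the Pearson correlation with its two-sided p-value and
    binned conditional statistics: the data are split into ``n_bins``
    equal-count bins of d²A/dz² and the 5th/50th/95th percentiles of the
    error recorded per bin (binned conditional confidence bands).
    """
    err = np.asarray(errors_pct, float)
    x = np.asarray(d2A_dz2, float)
    if err.shape != x.shape or err.ndim != 1:
        raise ValueError("errors and d2A/dz2 must be equal-length 1-D arrays")
    if err.size < 3:
        raise ValueError("need at least 3 points to fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: d2A/dz2 is constant")

    res = stats.linregress(x, err)

    n_bins = int(min(n_bins, max(err.size // 2, 1)))
    order = np.argsort(x)
    splits_x = np.array_split(x[order], n_bins)
    splits_e = np.array_split(err[order], n_bins)
    centers = np.array([np.median(s) for s in splits_x])
    lo = np.array([np.percentile(s, 5) for s in splits_e])
    med = np.array([np.percentile(s, 50) for s in splits_e])
    hi = np.array([np.percentile(s, 95) for s in splits_e])

    return CorrectionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        source="custom",
        bin_centers=centers,
        band_lo=lo,
        band_median=med,
        band_hi=hi,
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
    )


def lambda_factor(d2A_dz2, fit: CorrectionFit):
    """Correction factor λ = 1/(1 + e/100) from the predicted error e%.

    λ is monotone decreasing in e, equals 1 at e = 0, and is rejected for
    predicted errors at or below −100% (a nonphysical sign flip).
    """
    e = fit.predict(d2A_dz2)
    if np.any(e <= -100.0):
        raise ValueError("predicted error <= -100%: correction is nonphysical")
    out = 1.0 / (1.0 + e / 100.0)
    return float(out) if np.ndim(out) == 0 else out


def apply_correction(
    rp: ResistanceProfile, profile: DuctProfile, fit: CorrectionFit
) -> ResistanceProfile:
    """Apply the λ correction per section: ℛ_corrected = ℛ·λ(d²A/dz²).

    ``rp`` and ``profile`` must share the section z grid; the area second
    derivative is interpolated from the profile's uniform grid back onto
    the sections. The method label gains a ".λ" suffix.
    """
    z_sections = profile.z
    if len(rp) != z_sections.size or not np.allclose(
        rp.z, z_sections, rtol=0, atol=1e-9
    ):
        raise ValueError("resistance profile and duct profile are on different z grids")
    d2A = profile.d2A_at_sections()
    lam = lambda_factor(d2A, fit)
    return ResistanceProfile(
        z=rp.z,
        R=rp.R * lam,
        method=rp.method + ".λ",
        meta={**rp.meta, "fit_source": fit.source, "fit": (fit.slope, fit.intercept)},
    )
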