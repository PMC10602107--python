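"""Readers and writers for cross-section series and resistance tables.

Canonical on-disk formats, all lengths in μm:

* JSON cross-section series::

      {"unit": "um", "sections": [{"z": 0.0, "vertices": [[x, y], ...]}, ...]}

  (a bare list of section objects is also accepted);
* long-format CSV with columns ``section_id, z_um, x_um, y_um``;
* TIFF binary mask stacks, converted to per-slice boundary polygons by
  marching-squares contour extraction.

Resistance output is a CSV with the axial grid quantities and one pair of
columns per method (Pa·s/μm⁴ and mmHg·min/(mL·m)), plus a JSON metadata
sidecar recording viscosity, resolution, units and software version.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import DuctProfile, GeometryError, polygon_descriptors
from .unidirectional import ResistanceProfile, to_mmhg_min_per_ml_m

__all__ = [
    "read_sections",
    "write_sections",
    "read_sections_tiff",
    "write_resistance",
]


def _profile_from_records(records, dz_grid: float, smoothing=None) -> DuctProfile:
    sections = []
    for i, rec in enumerate(records):
        try:
            z = float(rec["z"])
            verts = np.asarray(rec["vertices"], float)
        except (KeyError, TypeError, ValueError) as exc:
            raise GeometryError(f"slice {i}: malformed section record ({exc})") from exc
        sections.append(
            polygon_descriptors(verts, z=z, shape_info=rec.get("shape"), index=i)
        )
    return DuctProfile.from_sections(sections, dz_grid=dz_grid, smoothing=smoothing)


def read_sections(
    path,
    format: str | None = None,
    dz_grid: float = 0.7,
    smoothing: int | None = None,
    slice_spacing: float | None = None,
    pixel_size: float | None = None,
) -> DuctProfile:
    """Read a cross-section series into a validated :class:`DuctProfile`.

    ``format`` is inferred from the suffix when omitted ("json", "csv" or
    "tiff"). ``slice_spacing`` and ``pixel_size`` (μm) apply to TIFF mask
    stacks only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".json": "json", ".csv": "csv", ".tif": "tiff", ".tiff": "tiff"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")

    if format == "json":
        with open(path) as fh:
            data = json.load(fh)
        if isinstance(data, dict):
            unit = data.get("unit", "um")
            if unit not in ("um", "micrometre", "micrometer", "micron"):
                raise ValueError(f"unsupported length unit {unit!r}; expected um")
            records = data["sections"]
        else:
            records = data
        return _profile_from_records(records, dz_grid, smoothing)

    if format == "csv":
        df = pd.read_csv(path)
        required = {"section_id", "z_um", "x_um", "y_um"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"CSV is missing columns: {sorted(missing)}")
        records = []
        for sid, grp in df.groupby("section_id", sort=True):
            zvals = grp["z_um"].unique()
            if zvals.size != 1:
                raise GeometryError(f"slice {sid}: mixed z values within one section")
            records.append(
                {"z": float(zvals[0]), "vertices": grp[["x_um", "y_um"]].to_numpy()}
            )
        records.sort(key=lambda r: r["z"])
        return _profile_from_records(records, dz_grid, smoothing)

    if format == "tiff":
        if slice_spacing is None or pixel_size is None:
            raise ValueError("TIFF input needs slice_spacing and pixel_size (um)")
        return read_sections_tiff(
            path, slice_spacing, pixel_size, dz_grid=dz_grid, smoothing=smoothing
        )

    raise ValueError(f"unknown format {format!r}")


def read_sections_tiff(
    path,
    slice_spacing: float,
    pixel_size: float,
    dz_grid: float = 0.7,
    smoothing: int | None = None,
) -> DuctProfile:
    """Extract per-slice boundary polygons from a binary TIFF mask stack.

    Each page is thresholded at 0.5 and its longest marching-squares
    contour taken as the section boundary; pixel indices are scaled by
    ``pixel_size`` and slice index by ``slice_spacing``.
    """
    import tifffile
    from skimage import measure

    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    records = []
    for i, page in enumerate(stack):
        mask = np.pad((np.asarray(page) > 0).astype(float), 1)
        contours = measure.find_contours(mask, 0.5)
        if not contours:
            raise GeometryError(f"slice {i}: empty mask page")
        contour = max(contours, key=len)
        verts = (contour[:, ::-1] - 1.0) * pixel_size  # (row,col) -> (x,y)
        records.append({"z": i * slice_spacing, "vertices": verts})
    return _profile_from_records(records, dz_grid, smoothing)


def write_sections(profile: DuctProfile, path) -> None:
    """Write a profile as the canonical JSON cross-section series."""
    path = Path(path)
    records = []
    for s in profile.sections:
        rec = {"z": s.z, "vertices": np.asarray(s.vertices, float).tolist()}
        if s.shape_info is not None:  # keep analytic tags (enables SUA/ELT)
            rec["shape"] = s.shape_info
        records.append(rec)
    data = {"unit": "um", "sections": records}
    with open(path, "w") as fh:
        json.dump(data, fh)


def write_resistance(
    profiles: list[ResistanceProfile],
    profile: DuctProfile,
    path,
    meta: dict | None = None,
) -> pd.DataFrame:
    """Write per-section resistance columns plus geometry to CSV.

    Columns: ``z_um, area_um2, dA_dz, d2A_dz2`` then, per method,
    ``R_<method>_Pa_s_per_um4`` and ``R_<method>_mmHg_min_per_mL_m``.
    A JSON sidecar ``<path>.meta.json`` records run metadata. Returns the
    written DataFrame.
    """
    path = Path(path)
    z = profile.z
    if profile.z_grid is not None:
        dA = np.interp(z, profile.z_grid, profile.dA_dz)
        d2A = np.interp(z, profile.z_grid, profile.d2A_dz2)
    else:
        dA = np.full(z.size, np.nan)
        d2A = np.full(z.size, np.nan)
    df = pd.DataFrame({"z_um": z, "area_um2": profile.areas, "dA_dz": dA, "d2A_dz2": d2A})
    if not profiles:
        warnings.warn("no methods were run; writing a geometry-only table", stacklevel=2)
    all_meta = {"software": f"pvshydro {__version__}", "unit_system": "um-s-Pa"}
    for rp in profiles:
        if len(rp) != z.size or not np.allclose(rp.z, z, rtol=0, atol=1e-9):
            raise ValueError(f"method {rp.method}: grid mismatch with duct profile")
        tag = rp.method.replace(".", "_")
        df[f"R_{tag}_Pa_s_per_um4"] = rp.R
        df[f"R_{tag}_mmHg_min_per_mL_m"] = to_mmhg_min_per_ml_m(rp.R)
        all_meta[rp.method] = {k: v for k, v in rp.meta.items() if _jsonable(v)}
    if meta:
        all_meta.update(meta)
    df.to_csv(path, index=False, float_format="%.12g")
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(all_meta, fh, indent=1, default=str)
    return df


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
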