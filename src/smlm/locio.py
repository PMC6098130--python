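"""Localization-table I/O, rendering, and ROI selection.

A localization table is a :class:`pandas.DataFrame` with the canonical
columns ``frame`` (int, 1-based), ``x``, ``y`` (nm, origin at the top-left
of the field, y increasing downward), ``uncertainty`` (nm, > 0),
``intensity`` (photons), and ``channel`` (small integer label).  Extra
columns (e.g. ``fiducial`` flags added by the simulator) are carried along
untouched by every operation in this package.

CSV dialects follow the ThunderSTORM export convention by default
(``"x [nm]"`` style headers); a registry maps alternative header sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "COLUMNS",
    "FieldGeometry",
    "ROI",
    "DIALECTS",
    "make_table",
    "read_localizations",
    "write_localizations",
    "render_localizations",
    "select_roi",
]

#: canonical column order of a localization table
COLUMNS = ["frame", "x", "y", "uncertainty", "intensity", "channel"]


@dataclass(frozen=True)
class FieldGeometry:
    """Physical geometry of an imaged field.

    ``camera_pixel`` is the physical camera pixel (101.5 nm for the EMCCD
    setup emulated here); ``render_pixel`` the super-resolution rendering
    pixel (20 nm).
    """

    width: float
    height: float
    camera_pixel: float = 101.5
    render_pixel: float = 20.0

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("field dimensions must be positive")
        if self.camera_pixel <= 0 or self.render_pixel <= 0:
            raise ValueError("pixel sizes must be positive")


@dataclass(frozen=True)
class ROI:
    """Square region of interest, ``side`` nm on edge (default 3 µm)."""

    x0: float = 0.0
    y0: float = 0.0
    side: float = 3000.0

    def __post_init__(self):
        if self.side <= 0:
            raise ValueError("ROI side must be positive")

    @property
    def area(self) -> float:
        return self.side * self.side

    def contains(self, x, y):
        """Half-open membership test: ``x0 <= x < x0+side`` (same for y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x0)
            & (x < self.x0 + self.side)
            & (y >= self.y0)
            & (y < self.y0 + self.side)
        )


class FormatError(ValueError):
    """Raised when a localization file lacks a required column."""


#: header dialects: canonical name -> (header name, unit scale to nm)
DIALECTS = {
    "thunderstorm": {
        "frame": ("frame", 1.0),
        "x": ("x [nm]", 1.0),
        "y": ("y [nm]", 1.0),
        "uncertainty": ("uncertainty [nm]", 1.0),
        "intensity": ("intensity [photon]", 1.0),
        "channel": ("channel", 1.0),
    },
    "thunderstorm_um": {
        "frame": ("frame", 1.0),
        "x": ("x [um]", 1000.0),
        "y": ("y [um]", 1000.0),
        "uncertainty": ("uncertainty [nm]", 1.0),
        "intensity": ("intensity [photon]", 1.0),
        "channel": ("channel", 1.0),
    },
    "plain": {
        "frame": ("frame", 1.0),
        "x": ("x", 1.0),
        "y": ("y", 1.0),
        "uncertainty": ("uncertainty", 1.0),
        "intensity": ("intensity", 1.0),
        "channel": ("channel", 1.0),
    },
}

_OPTIONAL_DEFAULTS = {"intensity": 0.0, "channel": 1}


def make_table(
    frame, x, y, uncertainty, intensity=None, channel=None, **extra
) -> pd.DataFrame:
    """Assemble a canonical localization table, sorted by frame."""
    frame = np.asarray(frame, dtype=int)
    n = len(frame)
    if intensity is None:
        intensity = np.zeros(n)
    if channel is None:
        channel = np.ones(n, dtype=int)
    df = pd.DataFrame(
        {
            "frame": frame,
            "x": np.asarray(x, dtype=float),
            "y": np.asarray(y, dtype=float),
            "uncertainty": np.asarray(uncertainty, dtype=float),
            "intensity": np.asarray(intensity, dtype=float),
            "channel": np.asarray(channel, dtype=int),
        }
    )
    for k, v in extra.items():
        df[k] = v
    _validate(df)
    return df.sort_values("frame", kind="stable").reset_index(drop=True)


def _validate(df: pd.DataFrame) -> None:
    if len(df) == 0:
        return
    if (df["frame"] < 1).any():
        raise ValueError("frame indices must be >= 1")
    u = df["uncertainty"].to_numpy()
    if not np.all(np.isfinite(u)) or (u <= 0).any():
        raise ValueError("uncertainties must be finite and positive")


def read_localizations(path, dialect: str = "thunderstorm") -> pd.DataFrame:
    """Read a localization CSV.

    Missing ``intensity``/``channel`` columns are filled with defaults
    (0 photons, channel 1) with a warning; missing coordinate, frame, or
    uncertainty columns raise :class:`FormatError`.
    """
    cols = DIALECTS[dialect]
    try:
        raw = pd.read_csv(path)
    except ValueError as exc:  # pragma: no cover - pandas message pass-through
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    data = {}
    for canon, (header, scale) in cols.items():
        if header in raw.columns:
            col = pd.to_numeric(raw[header], errors="coerce")
            bad = col.isna() & raw[header].notna()
            if bad.any():
                idx = int(np.flatnonzero(bad.to_numpy())[0])
                raise FormatError(
                    f"non-numeric value in column {header!r} at data row {idx}"
                )
            data[canon] = col.to_numpy(dtype=float) * scale
        elif canon in _OPTIONAL_DEFAULTS:
            warnings.warn(
                f"column {header!r} missing; filling {canon} with "
                f"{_OPTIONAL_DEFAULTS[canon]}",
                stacklevel=2,
            )
            data[canon] = np.full(len(raw), _OPTIONAL_DEFAULTS[canon], dtype=float)
        else:
            raise FormatError(f"required column {header!r} missing in {path}")
    return make_table(
        data["frame"].astype(int),
        data["x"],
        data["y"],
        data["uncertainty"],
        data["intensity"],
        data["channel"].astype(int),
    )


def write_localizations(table: pd.DataFrame, path, dialect: str = "thunderstorm"):
    """Write a localization table as CSV readable by :func:`read_localizations`."""
    cols = DIALECTS[dialect]
    out = pd.DataFrame()
    for canon, (header, scale) in cols.items():
        out[header] = table[canon].to_numpy() / scale
    out.to_csv(path, index=False, float_format="%.4f")
    return path


def render_localizations(
    table: pd.DataFrame,
    geom: FieldGeometry,
    mode: str = "histogram",
    out_of_field: str = "clip",
) -> np.ndarray:
    """Render localizations to a super-resolution image at ``render_pixel``.

    ``histogram`` mode bins each localization into the pixel covering it
    (pixel (i, j) covers the half-open square [j*p, (j+1)*p) x [i*p, (i+1)*p));
    ``gaussian`` mode spreads each localization as a unit-mass Gaussian with
    sd equal to its localization uncertainty, integrated over pixels.

    ``out_of_field`` is ``"clip"`` (drop localizations outside the field) or
    ``"error"``.
    """
    p = geom.render_pixel
    ny = int(np.ceil(geom.height / p))
    nx = int(np.ceil(geom.width / p))
    img = np.zeros((ny, nx))
    if len(table) == 0:
        return img
    x = table["x"].to_numpy()
    y = table["y"].to_numpy()
    inside = (x >= 0) & (x < geom.width) & (y >= 0) & (y < geom.height)
    if not inside.all():
        if out_of_field == "error":
            raise ValueError("localization outside field bounds")
        x, y = x[inside], y[inside]
    if mode == "histogram":
        j = (x / p).astype(int)
        i = (y / p).astype(int)
        np.add.at(img, (i, j), 1.0)
        return img
    if mode != "gaussian":
        raise ValueError(f"unknown render mode {mode!r}")
    sd = table["uncertainty"].to_numpy()
    if not inside.all():
        sd = sd[inside]
    edges_x = np.arange(nx + 1) * p
    edges_y = np.arange(ny + 1) * p
    for xi, yi, s in zip(x, y, sd):
        # integrate the 2-D Gaussian over pixels in a +-6 sd window and
        # renormalize so each localization contributes exactly unit mass
        j0 = max(0, int((xi - 6 * s) / p))
        j1 = min(nx, int((xi + 6 * s) / p) + 1)
        i0 = max(0, int((yi - 6 * s) / p))
        i1 = min(ny, int((yi + 6 * s) / p) + 1)
        cx = 0.5 * (
            special.erf((edges_x[j0 : j1 + 1] - xi) / (np.sqrt(2) * s))
        )
        cy = 0.5 * (
            special.erf((edges_y[i0 : i1 + 1] - yi) / (np.sqrt(2) * s))
        )
        kx = np.diff(cx)
        ky = np.diff(cy)
        patch = np.outer(ky, kx)
        mass = patch.sum()
        if mass > 0:
            img[i0:i1, j0:j1] += patch / mass
    return img


def select_roi(table: pd.DataFrame, roi: ROI) -> pd.DataFrame:
    """Cut a square ROI from a table; coordinates re-expressed from the ROI origin.

    Membership is half-open: points on the lower/left edges are included,
    points on the upper/right edges excluded, so tiling ROIs partition the
    field. Idempotent when re-applied with the zero-origin ROI of the same
    side.
    """
    keep = roi.contains(table["x"].to_numpy(), table["y"].to_numpy())
    out = table.loc[keep].copy()
    out["x"] = out["x"] - roi.x0
    out["y"] = out["y"] - roi.y0
    return out.reset_index(drop=True)
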