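"""Localization-table and image I/O for rendered SMLM data.

Localization tables follow the ThunderSTORM CSV dialect: a header row with
unit-annotated column names (``"x [nm]"``, ``"y [nm]"``, ...) and one row per
localization.  Images are plain TIFF (2D or multi-page 3D); the physical
pixel size is always an explicit parameter and never guessed, because a
silent nm/px mix-up is the dominant failure mode of profile-width analysis.

Coordinate convention used throughout the package: x maps to columns, y to
rows, the origin sits at the top-left pixel *corner*, and the center of
pixel ``(i, j)`` lies at ``((j + 0.5) * px, (i + 0.5) * px)`` in nm.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("exmprofiler")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

#: Default ThunderSTORM-style column names.
DEFAULT_DIALECT: dict[str, str] = {
    "frame": "frame",
    "x": "x [nm]",
    "y": "y [nm]",
    "z": "z [nm]",
    "intensity": "intensity [photon]",
    "uncertainty": "uncertainty [nm]",
}

#: Default rendering pixel size in nm/px; keeps >=3 px across a 32 nm profile.
DEFAULT_PIXEL_SIZE = 10.0


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


@dataclass
class LocalizationTable:
    """Point emitters with nm coordinates.

    Parameters
    ----------
    frame : integer array, the acquisition frame of each localization.
    x, y : float arrays, lateral coordinates in nm.
    z : optional float array, axial coordinate in nm (all records or none).
    intensity : optional float array, photon counts.
    uncertainty : optional float array, localization precision in nm.
    """

    frame: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: Optional[np.ndarray] = None
    intensity: Optional[np.ndarray] = None
    uncertainty: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        for name in ("z", "intensity", "uncertainty"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        n = len(self.frame)
        for name in ("x", "y", "z", "intensity", "uncertainty"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"column {name!r} has length {len(v)} != {n}")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")
        if self.z is not None and not np.isfinite(self.z).all():
            raise ValueError("z coordinates must be finite")
        if self.uncertainty is not None and (self.uncertainty < 0).any():
            raise ValueError("uncertainty must be nonnegative")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def has_z(self) -> bool:
        return self.z is not None

    def to_dataframe(self, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
        dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
        cols: dict[str, np.ndarray] = {dialect["frame"]: self.frame,
                                       dialect["x"]: self.x,
                                       dialect["y"]: self.y}
        if self.z is not None:
            cols[dialect["z"]] = self.z
        if self.intensity is not None:
            cols[dialect["intensity"]] = self.intensity
        if self.uncertainty is not None:
            cols[dialect["uncertainty"]] = self.uncertainty
        return pd.DataFrame(cols)


@dataclass
class SRImage:
    """Intensity grid with physical pixel size metadata.

    ``values`` is 2D (rows, cols) or 3D (planes, rows, cols); intensities are
    nonnegative.  ``pixel_size_xy`` is nm/px in the lateral plane;
    ``pixel_size_z`` is nm per plane and mandatory for 3D grids.
    """

    values: np.ndarray
    pixel_size_xy: float
    pixel_size_z: Optional[float] = None
    origin: tuple[float, float] = field(default=(0.0, 0.0))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim not in (2, 3):
            raise ValueError("image must be 2D or 3D")
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be > 0")
        if self.values.ndim == 3:
            if self.pixel_size_z is None or self.pixel_size_z <= 0:
                raise ValueError("3D images require pixel_size_z > 0")

    @property
    def is_3d(self) -> bool:
        return self.values.ndim == 3

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def read_localizations(path: str | Path,
                       dialect: Mapping[str, str] | None = None) -> LocalizationTable:
    """Read a ThunderSTORM-style CSV into a :class:`LocalizationTable`.

    ``dialect`` maps canonical field names (``frame``, ``x``, ``y``, ``z``,
    ``intensity``, ``uncertainty``) to the column names actually present; it
    is merged over the ThunderSTORM defaults.  ``frame``, ``x`` and ``y`` are
    mandatory, the rest are picked up when present.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file without header") from exc
    for key in ("frame", "x", "y"):
        if dialect[key] not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {dialect[key]!r}")
    def col(key: str, required: bool = False) -> Optional[np.ndarray]:
        name = dialect[key]
        if name not in df.columns:
            if required:
                raise FormatError(f"{path}: missing mandatory column {name!r}")
            return None
        series = pd.to_numeric(df[name], errors="coerce")
        bad = series.isna() & df[name].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"{path}: non-numeric value in column {name!r}, row {row + 2}")
        if series.isna().any():
            row = int(np.flatnonzero(series.isna().to_numpy())[0])
            raise FormatError(f"{path}: missing value in column {name!r}, row {row + 2}")
        return series.to_numpy()

    frame = col("frame", required=True)
    return LocalizationTable(
        frame=frame if len(df) else np.empty(0, dtype=np.int64),
        x=col("x", required=True) if len(df) else np.empty(0),
        y=col("y", required=True) if len(df) else np.empty(0),
        z=col("z") if len(df) else None,
        intensity=col("intensity") if len(df) else None,
        uncertainty=col("uncertainty") if len(df) else None,
    )


def write_localizations(table: LocalizationTable, path: str | Path,
                        dialect: Mapping[str, str] | None = None) -> None:
    """Write a localization table as unit-annotated CSV (lossless at 1e-6 nm)."""
    df = table.to_dataframe(dialect)
    df.to_csv(path, index=False, float_format="%.9g")


def render_histogram(table: LocalizationTable, pixel_size: float = DEFAULT_PIXEL_SIZE,
                     mode: str = "counts", blur_sigma: float = 0.0,
                     margin: float = 100.0,
                     bounds: tuple[float, float, float, float] | None = None) -> SRImage:
    """Render localizations to a 2D histogram image.

    ``counts`` mode bins localizations so the image sum equals the number of
    in-bounds localizations.  ``gaussian`` mode additionally convolves the
    count histogram with a Gaussian of ``blur_sigma`` nm, spreading each
    localization's unit mass.  The field of view covers the bounding box of
    the localizations plus ``margin`` nm on every side unless explicit
    ``bounds`` (x0, y0, x1, y1) are given.  The image origin (top-left pixel
    corner, in nm) is recorded so traces map back to table coordinates.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if len(table) == 0:
        raise ValueError("nothing to render: empty localization table")
    if mode not in ("counts", "gaussian"):
        raise ValueError(f"unknown rendering mode {mode!r}")
    if bounds is None:
        x0 = table.x.min() - margin
        y0 = table.y.min() - margin
        x1 = table.x.max() + margin
        y1 = table.y.max() + margin
    else:
        x0, y0, x1, y1 = bounds
    ncols = max(1, int(np.ceil((x1 - x0) / pixel_size)))
    nrows = max(1, int(np.ceil((y1 - y0) / pixel_size)))
    cols = np.floor((table.x - x0) / pixel_size).astype(int)
    rows = np.floor((table.y - y0) / pixel_size).astype(int)
    ok = (cols >= 0) & (cols < ncols) & (rows >= 0) & (rows < nrows)
    img = np.zeros((nrows, ncols), dtype=float)
    np.add.at(img, (rows[ok], cols[ok]), 1.0)
    if mode == "gaussian" and blur_sigma > 0:
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(img, blur_sigma / pixel_size, mode="constant")
    return SRImage(img, pixel_size_xy=pixel_size, origin=(x0, y0))


def write_image(image: SRImage, path: str | Path) -> None:
    """Write an image as TIFF; pixel size is stored in the resolution tags."""
    res = 1.0e7 / image.pixel_size_xy  # pixels per cm
    tifffile.imwrite(path, image.values, resolution=(res, res),
                     resolutionunit="CENTIMETER")


def read_image(path: str | Path, pixel_size: float | None = None,
               pixel_size_z: float | None = None) -> SRImage:
    """Read a TIFF image.

    The lateral pixel size is taken from the TIFF resolution tags when
    present; otherwise ``pixel_size`` (nm/px) must be given explicitly.  An
    explicit value always wins over tags.
    """
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        if pixel_size is None:
            page = tif.pages[0]
            try:
                xres = page.tags["XResolution"].value
                unit = page.tags["ResolutionUnit"].value
                num, den = xres
                if num > 0 and int(unit) == 3:  # pixels per centimeter
                    pixel_size = 1.0e7 * den / num
            except KeyError:
                pass
    if pixel_size is None or pixel_size <= 0:
        raise ValueError(
            f"{path}: no pixel-size metadata; pass pixel_size explicitly (nm/px)")
    if values.ndim == 3 and pixel_size_z is None:
        raise ValueError(f"{path}: 3D stack requires explicit pixel_size_z (nm/plane)")
    return SRImage(values, pixel_size_xy=pixel_size, pixel_size_z=pixel_size_z)


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: top level of config must be a mapping")
    return cfg


def save_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
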