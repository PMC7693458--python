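"""Reflectance, sensitivity and irradiance spectra: containers, IO and standard curves.

A :class:`Spectrum` is a wavelength-indexed nonnegative curve on a strictly
increasing grid in nanometres.  The working range of the package is the bee
visible band 300–700 nm; field-spectrophotometer exports covering a wider
range are truncated on read (receptor sensitivities are essentially zero
outside it).
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: default working grid, 300–700 nm at 1 nm
DEFAULT_GRID = np.arange(300.0, 701.0, 1.0)

#: rows outside this range are dropped on read (instrument stray-light region)
INSTRUMENT_RANGE = (250.0, 750.0)

#: reflectance slightly above 1 is a common instrument artifact; beyond this it is an error
REFLECTANCE_CEILING = 1.2


class SpectrumError(ValueError):
    """Raised when a spectrum violates its invariants."""


@dataclass(frozen=True)
class Spectrum:
    """A nonnegative curve sampled on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)
        if wl.ndim != 1 or v.ndim != 1 or wl.size != v.size:
            raise SpectrumError("wavelengths and values must be 1-D arrays of equal length")
        if wl.size < 2:
            raise SpectrumError("a spectrum needs at least two samples")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(v))):
            raise SpectrumError("spectrum contains non-finite entries")
        d = np.diff(wl)
        if np.any(d <= 0):
            i = int(np.argmax(d <= 0))
            raise SpectrumError(
                f"wavelengths must be strictly increasing; violation at row {i + 1} "
                f"({wl[i]:g} -> {wl[i + 1]:g} nm)"
            )
        if np.any(v < 0):
            raise SpectrumError("spectrum values must be nonnegative")

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def value_at(self, wavelength: float) -> float:
        """Linearly interpolated value at one wavelength (inside the hull)."""
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not lo <= wavelength <= hi:
            raise SpectrumError(f"{wavelength:g} nm outside the spectrum hull [{lo:g}, {hi:g}]")
        return float(np.interp(wavelength, self.wavelengths, self.values))

    def resample(self, grid: np.ndarray, extrapolate: bool = False) -> "Spectrum":
        """Linear interpolation onto ``grid``.

        Without ``extrapolate`` the grid must lie inside the closed hull of the
        spectrum; with it, end values are held constant outside the hull.
        """
        grid = np.asarray(grid, dtype=float)
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not extrapolate and (grid[0] < lo - 1e-9 or grid[-1] > hi + 1e-9):
            raise SpectrumError(
                f"grid [{grid[0]:g}, {grid[-1]:g}] nm outside spectrum hull [{lo:g}, {hi:g}] "
                "(pass extrapolate=True for constant-end extension)"
            )
        return Spectrum(grid, np.interp(grid, self.wavelengths, self.values))


def resample(s: Spectrum, grid: np.ndarray, extrapolate: bool = False) -> Spectrum:
    """Functional alias of :meth:`Spectrum.resample`."""
    return s.resample(grid, extrapolate=extrapolate)


def read_spectrum(
    source,
    dialect: str = "fraction",
    wavelength_column: int = 0,
    value_column: int = 1,
    delimiter: str | None = None,
) -> Spectrum:
    """Read a two-column (wavelength nm, reflectance) text export.

    ``dialect`` must be declared explicitly: ``"fraction"`` for reflectance in
    [0, 1], ``"percent"`` for 0–100 exports (divided by 100).  A single header
    row is tolerated; rows outside the instrument range are dropped with a
    logged count; small negative values are clipped to zero and values in
    (1, 1.2] are kept but flagged.
    """
    if dialect not in ("fraction", "percent"):
        raise SpectrumError(f"unknown dialect {dialect!r}; use 'fraction' or 'percent'")
    raw = pd.read_csv(
        source,
        sep=delimiter if delimiter is not None else None,
        engine="python",
        header=None,
        comment="#",
        skip_blank_lines=True,
    )
    if raw.shape[1] <= max(wavelength_column, value_column):
        raise SpectrumError("source must have at least two columns")
    cols = raw.iloc[:, [wavelength_column, value_column]].apply(pd.to_numeric, errors="coerce")
    # a single non-numeric leading row is a header
    if cols.iloc[0].isna().any() and not cols.iloc[1:].isna().any().any():
        cols = cols.iloc[1:]
    if cols.isna().any().any():
        bad = int(cols.isna().any(axis=1).idxmax())
        raise SpectrumError(f"non-numeric entry at row {bad}")
    wl = cols.iloc[:, 0].to_numpy(float)
    v = cols.iloc[:, 1].to_numpy(float)

    keep = (wl >= INSTRUMENT_RANGE[0]) & (wl <= INSTRUMENT_RANGE[1])
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropped %d rows outside %s nm", dropped, INSTRUMENT_RANGE)
    wl, v = wl[keep], v[keep]
    if wl.size < 10:
        raise SpectrumError(f"only {wl.size} usable rows in {INSTRUMENT_RANGE} nm (need >= 10)")
    d = np.diff(wl)
    if np.any(d <= 0):
        i = int(np.argmax(d <= 0))
        raise SpectrumError(
            f"non-monotone or duplicated wavelengths at row {i + 1} ({wl[i]:g} -> {wl[i + 1]:g} nm)"
        )
    if dialect == "percent":
        v = v / 100.0
    n_neg = int((v < 0).sum())
    if n_neg:
        if v.min() < -0.05:
            raise SpectrumError(f"reflectance {v.min():.3f} too negative to be an instrument artifact")
        log.warning("clipped %d slightly negative reflectance values to 0", n_neg)
        v = np.clip(v, 0.0, None)
    if v.max() > REFLECTANCE_CEILING:
        raise SpectrumError(
            f"reflectance {v.max():.3f} exceeds {REFLECTANCE_CEILING} after dialect conversion "
            "(wrong dialect?)"
        )
    if v.max() > 1.0:
        log.warning("reflectance exceeds 1 (max %.3f); kept as instrument artifact", v.max())
    return Spectrum(wl, v)


def write_spectrum(s: Spectrum, dest, header: bool = True) -> None:
    """Write a spectrum as two-column CSV (fraction dialect, 6 decimals)."""
    close = False
    if isinstance(dest, (str, os.PathLike)):
        dest = open(dest, "w")
        close = True
    try:
        if header:
            dest.write("wavelength_nm,reflectance\n")
        for wl, v in zip(s.wavelengths, s.values):
            dest.write(f"{wl:.6f},{v:.6f}\n")
    finally:
        if close:
            dest.close()


def receptor_template(
    lambda_max: float, grid: np.ndarray | None = None, beta_band: bool = False
) -> Spectrum:
    """A1 visual-pigment absorbance nomogram, normalised to peak 1.

    The alpha band follows the widely used rhodopsin template
    (Govardovskii-type), parameterised only by the peak wavelength; the small
    beta band is off by default.  Used as a configurable stand-in for measured
    bumblebee (UV/blue/green) receptor sensitivities.
    """
    if not 300.0 <= lambda_max <= 700.0:
        raise SpectrumError(f"lambda_max {lambda_max:g} nm outside [300, 700]")
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    x = lambda_max / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    s = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    if beta_band:
        lm_b = 189.0 + 0.315 * lambda_max
        bw = -40.5 + 0.195 * lambda_max
        s = s + 0.26 * np.exp(-(((grid - lm_b) / bw) ** 2))
    s = s / s.max()
    return Spectrum(grid, s)


# CIE standard illuminant D65, relative spectral power at 10 nm steps (300–700 nm).
_D65_WAVELENGTHS = np.arange(300.0, 701.0, 10.0)
_D65_VALUES = np.array(
    [
        0.03, 3.29, 20.24, 37.05, 39.95, 44.91, 46.64, 52.09, 50.00, 54.65,
        82.75, 91.49, 93.43, 86.68, 104.86, 117.01, 117.81, 114.86, 115.92,
        108.81, 109.35, 107.80, 104.79, 107.69, 104.41, 104.05, 100.00,
        96.33, 95.79, 88.69, 90.01, 89.60, 87.70, 83.29, 83.70, 80.03,
        80.21, 82.28, 78.28, 69.72, 71.61,
    ]
)


def _green_leaf_values(grid: np.ndarray) -> np.ndarray:
    # Parametric green-leaf reflectance: low UV/blue, chlorophyll "green bump"
    # peaking near 550 nm, moderate rise toward the red edge.
    #   R(l) = 0.05 + 0.22 exp(-(l-550)^2 / (2*40^2)) + 0.30 / (1 + exp(-(l-710)/20))
    return (
        0.05
        + 0.22 * np.exp(-((grid - 550.0) ** 2) / (2.0 * 40.0**2))
        + 0.30 / (1.0 + np.exp(-(grid - 710.0) / 20.0))
    )


def standard_curves(name: str, grid: np.ndarray | None = None) -> Spectrum:
    """Packaged standard curves on a grid.

    ``"D65"``: the CIE standard-daylight table, linearly interpolated and
    normalised to 100 at 560 nm.  ``"green_leaf"``: a documented parametric
    leaf reflectance used as the adapting background; users with a measured
    leaf standard should supply their own file instead.
    """
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    if name == "D65":
        scale = 100.0 / np.interp(560.0, _D65_WAVELENGTHS, _D65_VALUES)
        return Spectrum(grid, scale * np.interp(grid, _D65_WAVELENGTHS, _D65_VALUES))
    if name == "green_leaf":
        return Spectrum(grid, _green_leaf_values(grid))
    raise SpectrumError(f"unknown standard curve {name!r}; available: 'D65', 'green_leaf'")


def read_manifest(manifest_path) -> pd.DataFrame:
    """Read a manifest CSV mapping spectrum files to (plant_id, structure, position)."""
    m = pd.read_csv(manifest_path)
    required = {"file", "plant_id", "structure", "position"}
    missing = required - set(m.columns)
    if missing:
        raise SpectrumError(f"manifest missing columns: {sorted(missing)}")
    bad_s = set(m["structure"]) - {"sepal", "petal", "labellum"}
    bad_p = set(m["position"]) - {"tip", "base"}
    if bad_s or bad_p:
        raise SpectrumError(f"unknown structure/position labels: {sorted(bad_s | bad_p)}")
    return m


def load_dataset(
    manifest_path,
    grid: np.ndarray | None = None,
    dialect: str = "fraction",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Load every spectrum named by a manifest, resampled to the working grid.

    Returns ``(R, labels)`` where ``R`` is an (n_spectra, n_wavelengths)
    reflectance matrix and ``labels`` the manifest rows (plant_id, structure,
    position) aligned with its rows.
    """
    if grid is None:
        grid = DEFAULT_GRID
    manifest = read_manifest(manifest_path)
    base = os.path.dirname(os.fspath(manifest_path)) if isinstance(
        manifest_path, (str, os.PathLike)
    ) else "."
    rows = []
    for f in manifest["file"]:
        path = f if os.path.isabs(f) else os.path.join(base, f)
        s = read_spectrum(path, dialect=dialect)
        rows.append(s.resample(grid, extrapolate=True).values)
    labels = manifest[["plant_id", "structure", "position"]].copy()
    return np.vstack(rows), labels
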