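"""Colour descriptors in the hexagon: hue angle, chromatic contrast, spectral purity.

Spectral purity (saturation) of a colour locus is its hexagon radius divided
by the radius of the maximal-saturation boundary along the same hue ray.  The
boundary is the spectrum locus — the curve traced by monochromatic lights —
closed by the purple line between its 300 and 700 nm endpoints.

Because excitation is a saturating function of intensity (E = P/(P+1)), a
monochromatic light's hexagon position depends on its intensity.  The
packaged convention scales each monochromatic light so that its most
strongly excited receptor reaches a fixed adapted quantum catch
(``peak_catch``, default 10, i.e. excitation ~0.91): bright lights near
receptor saturation, as in the familiar rounded-triangle bee spectrum locus
passing close to the receptor vertices.  Under this scaling the hue of the
locus is monotone in wavelength and every monochromatic locus lies on the
outer boundary, so each has spectral purity exactly 1 by construction;
``peak_catch`` is exposed for users who prefer another convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .vision import ViewingContext, VisionError, hexagon_coords

log = logging.getLogger(__name__)

#: loci closer to the origin than this have undefined hue and purity 0
RADIUS_EPS = 1e-9


@dataclass(frozen=True)
class SpectrumLocus:
    """Closed polygon of maximal-saturation loci (monochromatic + purple line)."""

    wavelengths: np.ndarray  # (k,)
    vertices: np.ndarray  # (k, 2), ordered by wavelength; closed implicitly

    def __post_init__(self) -> None:
        if self.vertices.shape != (self.wavelengths.size, 2):
            raise VisionError("vertices must be (k, 2) matching wavelengths")
        if np.any(np.hypot(*self.vertices.T) > 1.0 + 1e-9):
            raise VisionError("spectrum-locus vertices outside the unit hexagon radius")
        if not _origin_inside(self.vertices):
            raise VisionError("origin not strictly inside the spectrum locus (degenerate context)")

    def boundary_radius(self, xy: np.ndarray) -> np.ndarray:
        """Radius at which the ray from the origin through each point exits the polygon."""
        return _ray_exit_radius(self.vertices, np.atleast_2d(xy))


def _origin_inside(vertices: np.ndarray) -> bool:
    # even-odd rule along the +x axis
    x, y = vertices[:, 0], vertices[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    crosses = (y > 0) != (y2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = x + (0.0 - y) * (x2 - x) / (y2 - y)
    n = int(np.sum(crosses & (xint > 0)))
    return n % 2 == 1


def _ray_exit_radius(vertices: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """For each point, the distance from the origin to the polygon boundary
    along the ray through that point (largest crossing, robust to grazing)."""
    p = vertices
    q = np.roll(vertices, -1, axis=0)
    d = q - p  # (k, 2) edges
    out = np.full(pts.shape[0], np.nan)
    for i, xy in enumerate(pts):
        r = np.hypot(xy[0], xy[1])
        if r < RADIUS_EPS:
            continue
        u = xy / r
        denom = u[0] * d[:, 1] - u[1] * d[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (p[:, 0] * d[:, 1] - p[:, 1] * d[:, 0]) / denom
            s = (p[:, 0] * u[1] - p[:, 1] * u[0]) / denom
        ok = (np.abs(denom) > 1e-15) & (t > RADIUS_EPS) & (s >= -1e-9) & (s <= 1.0 + 1e-9)
        if not np.any(ok):  # impossible for a closed polygon around the origin
            raise VisionError("hue ray intersects no spectrum-locus segment")
        out[i] = float(t[ok].max())
    return out


#: default adapted quantum catch of the dominant receptor for boundary lights
DEFAULT_PEAK_CATCH = 10.0


def _monochromatic_loci(
    ctx: ViewingContext, wavelengths: np.ndarray, peak_catch: float = DEFAULT_PEAK_CATCH
) -> np.ndarray:
    """Hexagon loci of bright monochromatic lights, one per wavelength.

    A monochromatic light at wavelength l yields adapted catches proportional
    to c_i = S_i(l) / Q_i(background); its intensity is set so that
    max_i P_i = ``peak_catch`` (default 10, excitation ~0.91 — near receptor
    saturation, where the locus approaches the hexagon's receptor vertices).
    """
    qb = ctx.background_catches()
    idx = np.searchsorted(ctx.grid, wavelengths)
    c = np.stack([r.values[idx] / qb[j] for j, r in enumerate(ctx.receptors)], axis=1)  # (k, 3)
    P = peak_catch * c / c.max(axis=1, keepdims=True)
    return hexagon_coords(P / (P + 1.0))


def build_spectrum_locus(
    ctx: ViewingContext, step: float = 1.0, peak_catch: float = DEFAULT_PEAK_CATCH
) -> SpectrumLocus:
    """Spectrum locus polygon from 300 to 700 nm at ``step`` nm, purple-line closed."""
    grid_step = float(ctx.grid[1] - ctx.grid[0])
    if abs(step / grid_step - round(step / grid_step)) > 1e-9:
        raise VisionError(f"locus step {step} nm must be a multiple of the grid step {grid_step} nm")
    wavelengths = np.arange(300.0, 700.0 + step / 2, step)
    vertices = _monochromatic_loci(ctx, wavelengths, peak_catch=peak_catch)
    return SpectrumLocus(wavelengths, vertices)


def hue_angle(xy: np.ndarray) -> np.ndarray:
    """Hue in degrees [0, 360) counterclockwise from the +x axis; NaN when undefined."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    r = np.hypot(xy[:, 0], xy[:, 1])
    theta = np.degrees(np.arctan2(xy[:, 1], xy[:, 0])) % 360.0
    theta[r < RADIUS_EPS] = np.nan
    return theta


def chromatic_contrast(xy: np.ndarray) -> np.ndarray:
    """Distance of each locus from the hexagon centre (the adapted background)."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    return np.hypot(xy[:, 0], xy[:, 1])


def spectral_purity(xy: np.ndarray, locus: SpectrumLocus) -> np.ndarray:
    """Radius of each locus divided by the boundary radius along its hue ray.

    The exact origin (the background) has purity 0 by convention; values are
    clamped into [0, 1] with a logged count if any exceed 1.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    r = np.hypot(xy[:, 0], xy[:, 1])
    purity = np.zeros(xy.shape[0])
    defined = r >= RADIUS_EPS
    if np.any(defined):
        boundary = locus.boundary_radius(xy[defined])
        purity[defined] = r[defined] / boundary
    n_clamped = int(np.sum(purity > 1.0 + 1e-9))
    if n_clamped:
        log.warning("clamped %d purity values above 1 (max %.4f)", n_clamped, purity.max())
    return np.clip(purity, 0.0, 1.0)
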