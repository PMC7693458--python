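"""Trichromatic bee vision: quantum catches, von Kries adaptation, hexagon projection.

The colour-hexagon model maps a reflectance spectrum to three photoreceptor
excitations and a 2-D chromaticity point.  For receptor *i* with sensitivity
S_i(l), stimulus reflectance I_S(l), adapting background I_B(l) and
illuminant D(l):

    raw catch     Q_i  = integral I_S(l) S_i(l) D(l) dl        (trapezoid rule)
    adapted catch P_i  = Q_i / Q_i(background)                  (von Kries)
    excitation    E_i  = P_i / (P_i + 1)                        in [0, 1)

so the background itself excites every receptor to exactly 0.5.  Hexagon
coordinates place the three receptor axes 120 degrees apart:

    x = (sqrt(3)/2) (E_green - E_uv)
    y = E_blue - (E_uv + E_green) / 2

which sends the adapted background to the origin and a pure-receptor triple
(one excitation 1, the others 0) to a vertex at radius exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import DEFAULT_GRID, Spectrum, receptor_template, standard_curves

RECEPTOR_LABELS = ("uv", "blue", "green")

#: default nomogram peaks (nm) for the UV, blue and green receptors of a
#: *Bombus terrestris*-like trichromat; override per analysis if measured
#: sensitivities are available.
DEFAULT_LAMBDA_MAX = (328.0, 428.0, 536.0)


class VisionError(ValueError):
    """Raised for invalid viewing contexts or mismatched grids."""


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty_like(grid)
    w[1:-1] = (grid[2:] - grid[:-2]) / 2.0
    w[0] = (grid[1] - grid[0]) / 2.0
    w[-1] = (grid[-1] - grid[-2]) / 2.0
    return w


@dataclass(frozen=True)
class ViewingContext:
    """Everything needed to map a reflectance to a colour locus.

    All four curves must share the identical wavelength grid, which must span
    at least the bee-visible band 300–700 nm.
    """

    grid: np.ndarray
    illuminant: Spectrum
    background: Spectrum
    receptors: tuple[Spectrum, Spectrum, Spectrum]
    labels: tuple[str, str, str] = RECEPTOR_LABELS

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        if grid[0] > 300.0 or grid[-1] < 700.0:
            raise VisionError(f"grid [{grid[0]:g}, {grid[-1]:g}] must span [300, 700] nm")
        if len(self.receptors) != 3 or len(set(self.labels)) != 3:
            raise VisionError("exactly three receptors with unique labels required")
        for curve in (self.illuminant, self.background, *self.receptors):
            if not np.array_equal(curve.wavelengths, grid):
                raise VisionError("all context curves must share the identical grid")

    @classmethod
    def default(
        cls,
        lambda_max: tuple[float, float, float] = DEFAULT_LAMBDA_MAX,
        grid: np.ndarray | None = None,
        illuminant: Spectrum | str = "D65",
        background: Spectrum | str = "green_leaf",
    ) -> "ViewingContext":
        """Packaged context: D65 daylight, green-leaf background, nomogram receptors."""
        if grid is None:
            grid = DEFAULT_GRID
        grid = np.asarray(grid, dtype=float)
        if isinstance(illuminant, str):
            illuminant = standard_curves(illuminant, grid)
        else:
            illuminant = illuminant.resample(grid, extrapolate=True)
        if isinstance(background, str):
            background = standard_curves(background, grid)
        else:
            background = background.resample(grid, extrapolate=True)
        if sorted(lambda_max) != list(lambda_max):
            raise VisionError("lambda_max must be ordered UV -> blue -> green")
        receptors = tuple(receptor_template(lm, grid) for lm in lambda_max)
        return cls(grid, illuminant, background, receptors)

    def catch_kernel(self) -> np.ndarray:
        """(n_wavelengths, 3) kernel K with raw catch Q = R @ K for reflectance rows R."""
        w = _trapezoid_weights(self.grid) * self.illuminant.values
        return np.stack([w * r.values for r in self.receptors], axis=1)

    def background_catches(self) -> np.ndarray:
        q = self.background.values @ self.catch_kernel()
        if np.any(q <= 0):
            raise VisionError("background quantum catch is zero for some receptor (degenerate adaptation)")
        return q


def raw_catch(stimulus: Spectrum, sensitivity: Spectrum, illuminant: Spectrum) -> float:
    """Trapezoid integral of stimulus x sensitivity x illuminant over the shared grid."""
    if not (
        np.array_equal(stimulus.wavelengths, sensitivity.wavelengths)
        and np.array_equal(stimulus.wavelengths, illuminant.wavelengths)
    ):
        raise VisionError("raw_catch requires all three curves on the identical grid")
    return float(
        np.trapezoid(stimulus.values * sensitivity.values * illuminant.values, stimulus.wavelengths)
    )


def excitation_matrix(reflectance: np.ndarray, ctx: ViewingContext) -> np.ndarray:
    """Excitations E in [0, 1) for an (n, n_wavelengths) reflectance matrix."""
    R = np.atleast_2d(np.asarray(reflectance, dtype=float))
    if R.shape[1] != ctx.grid.size:
        raise VisionError(f"reflectance has {R.shape[1]} samples; context grid has {ctx.grid.size}")
    P = (R @ ctx.catch_kernel()) / ctx.background_catches()
    return P / (P + 1.0)


def excitation_triple(stimulus: Spectrum, ctx: ViewingContext) -> np.ndarray:
    """UV/blue/green excitations of one stimulus; the background maps to (0.5, 0.5, 0.5)."""
    if not np.array_equal(stimulus.wavelengths, ctx.grid):
        raise VisionError("stimulus must be on the context grid")
    return excitation_matrix(stimulus.values[None, :], ctx)[0]


def hexagon_coords(excitations: np.ndarray) -> np.ndarray:
    """Hexagon (x, y) for excitation triples of shape (..., 3)."""
    e = np.asarray(excitations, dtype=float)
    x = (np.sqrt(3.0) / 2.0) * (e[..., 2] - e[..., 0])
    y = e[..., 1] - (e[..., 0] + e[..., 2]) / 2.0
    return np.stack([x, y], axis=-1)
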