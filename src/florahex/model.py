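"""The hexagon colour model as an sklearn-style transformer.

``HexagonColorModel`` turns a matrix of floral reflectance spectra (one row
per patch measurement, one column per wavelength of the working grid) into
bee-view colour features: the three photoreceptor excitations, hexagon
coordinates, hue angle, spectral purity and chromatic contrast against the
adapting background.  It composes with sklearn pipelines; ``fit`` ignores
``y`` and only builds the viewing context and the spectrum-locus boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .descriptors import build_spectrum_locus, chromatic_contrast, hue_angle, spectral_purity
from .spectra import DEFAULT_GRID, Spectrum
from .vision import DEFAULT_LAMBDA_MAX, ViewingContext, excitation_matrix, hexagon_coords

FEATURE_NAMES = ("E_uv", "E_blue", "E_green", "x", "y", "hue_deg", "purity", "contrast")


class HexagonColorModel(TransformerMixin, BaseEstimator):
    """Map reflectance spectra into bee hexagon colour descriptors.

    Parameters
    ----------
    lambda_max : triple of float
        Nomogram peaks (nm) of the UV, blue and green receptors.
    illuminant, background : str or Spectrum
        Packaged curve name (``"D65"``, ``"green_leaf"``) or a user spectrum.
    grid : 1-D array or None
        Working wavelength grid; defaults to 300–700 nm at 1 nm.
    locus_step : float
        Wavelength step (nm) of the spectrum-locus boundary polygon.
    locus_peak_catch : float
        Adapted quantum catch of the dominant receptor for the monochromatic
        boundary lights (default 10: bright, near receptor saturation).
    rotation_deg : float
        Optional rotation of the hexagon axes.  Hue shifts by exactly this
        angle; purity, contrast and all pairwise distances are invariant.
    """

    def __init__(
        self,
        lambda_max: tuple[float, float, float] = DEFAULT_LAMBDA_MAX,
        illuminant: str | Spectrum = "D65",
        background: str | Spectrum = "green_leaf",
        grid: np.ndarray | None = None,
        locus_step: float = 1.0,
        locus_peak_catch: float = 10.0,
        rotation_deg: float = 0.0,
    ):
        self.lambda_max = lambda_max
        self.illuminant = illuminant
        self.background = background
        self.grid = grid
        self.locus_step = locus_step
        self.locus_peak_catch = locus_peak_catch
        self.rotation_deg = rotation_deg

    def fit(self, X=None, y=None) -> "HexagonColorModel":
        grid = DEFAULT_GRID if self.grid is None else np.asarray(self.grid, dtype=float)
        self.context_ = ViewingContext.default(
            lambda_max=tuple(self.lambda_max),
            grid=grid,
            illuminant=self.illuminant,
            background=self.background,
        )
        self.spectrum_locus_ = build_spectrum_locus(
            self.context_, step=self.locus_step, peak_catch=self.locus_peak_catch
        )
        self.n_features_in_ = grid.size
        return self

    def transform(self, X) -> np.ndarray:
        """Reflectance rows -> (n, 8) array of colour features (see FEATURE_NAMES)."""
        check_is_fitted(self, "context_")
        X = check_array(X, dtype=float, ensure_2d=True)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} wavelength samples; the fitted grid has {self.n_features_in_}"
            )
        E = excitation_matrix(X, self.context_)
        xy = hexagon_coords(E)
        purity = spectral_purity(xy, self.spectrum_locus_)
        contrast = chromatic_contrast(xy)
        if self.rotation_deg:
            a = np.radians(self.rotation_deg)
            rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            xy = xy @ rot.T
        hue = hue_angle(xy)
        return np.column_stack([E, xy, hue, purity, contrast])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)

    def color_table(self, X, labels: pd.DataFrame) -> pd.DataFrame:
        """Tidy patch-colour table: manifest labels + colour features per row."""
        feats = self.transform(X)
        labels = labels.reset_index(drop=True)
        out = pd.concat([labels, pd.DataFrame(feats, columns=list(FEATURE_NAMES))], axis=1)
        n_undef = int(out["hue_deg"].isna().sum())
        if n_undef:
            import logging

            logging.getLogger(__name__).warning(
                "%d loci at the background origin: hue undefined, excluded from circular statistics",
                n_undef,
            )
        return out


def patch_color_table(
    reflectance: np.ndarray, labels: pd.DataFrame, **model_params
) -> pd.DataFrame:
    """One-call convenience wrapper over :class:`HexagonColorModel`."""
    return HexagonColorModel(**model_params).fit().color_table(reflectance, labels)
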