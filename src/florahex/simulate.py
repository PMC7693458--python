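"""Seeded synthetic floral reflectance datasets with planted modular covariance.

The generator emulates a Cattleya-like orchid measured at six floral patches
(tip/base of sepal, petal, labellum) across plants:

* pink patches (sepals, petals, labellum tip) reflect in a blue band plus a
  red shoulder; the labellum tip's band is stronger and shifted toward the
  UV-blue, giving it the highest spectral purity;
* the labellum base is a yellow, UV-absorbing patch (reflectance below 0.10
  under 400 nm, sigmoidal rise near 520 nm into a green+red plateau) with the
  lowest hue jitter among individuals;
* among-individual covariance is planted through latent pigment-amplitude
  factors shared within each of three modules — {sepals + petals},
  {labellum tip}, {labellum base} — a mechanistic stand-in for coordinated
  pigment accumulation.

``generate_null_dataset`` produces matched data whose 18 patch x receptor
excitation columns are (near-)independent: no shared module factors, no
coherent amplitude noise, and instead three spectrally localised perturbation
bumps per patch — one per receptor channel, with independent amplitudes — so
that no deformation moves two receptors together.  This is the reference
condition for the type-I-error suites of the permutation tests.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import PATCHES
from .modularity import DEFAULT_PATCH_MODULES
from .spectra import DEFAULT_GRID, write_spectrum, Spectrum

log = logging.getLogger(__name__)


def _gauss(grid, center, sd):
    return np.exp(-((grid - center) ** 2) / (2.0 * sd**2))


def _sigmoid(grid, center, scale):
    return 1.0 / (1.0 + np.exp(-(grid - center) / scale))


#: per-patch template parameters (reflectance fractions, nm):
#: base pedestal, Gaussian blue band (center, sd, amplitude), sigmoidal
#: long-wavelength rise (center, scale, amplitude).  Chosen so that, through
#: the default viewing context, sepals/petals land in the hexagon's blue
#: sector at purity ~0.25-0.32 (petal base lowest), the labellum tip in the
#: UV-blue sector at the highest purity (~0.6), and the yellow UV-absorbing
#: labellum base in the blue-green sector at intermediate purity (~0.44).
TEMPLATE_PARAMS = {
    ("sepal", "tip"): dict(base=0.04, band=(447.0, 28.0, 0.13), red=(600.0, 33.0, 0.47)),
    ("sepal", "base"): dict(base=0.04, band=(449.0, 28.0, 0.11), red=(600.0, 33.0, 0.47)),
    ("petal", "tip"): dict(base=0.04, band=(446.0, 28.0, 0.15), red=(598.0, 34.0, 0.46)),
    ("petal", "base"): dict(base=0.04, band=(448.0, 28.0, 0.095), red=(602.0, 32.0, 0.47)),
    ("labellum", "tip"): dict(base=0.07, band=(410.0, 25.0, 0.50), red=(645.0, 15.0, 0.35)),
    # yellow UV-absorbing: no blue band; sigmoidal rise into a green+red plateau
    ("labellum", "base"): dict(base=0.02, band=None, red=(484.0, 24.0, 0.55)),
}

#: channel-localised perturbation bumps (center nm, sd nm), one per receptor
CHANNEL_BUMPS = ((340.0, 13.0), (425.0, 13.0), (575.0, 13.0))


def _channel_profiles(grid: np.ndarray) -> np.ndarray:
    """(3, n_wavelengths) spectral perturbations, one per receptor channel.

    Raw Gaussian bumps at the CHANNEL_BUMPS positions still leak between
    receptor classes where the nomograms overlap (mostly 425 nm into the
    green receptor's short-wavelength limb), which would correlate the
    excitation columns the null generator promises to keep independent.  The
    bumps are therefore orthogonalised through the adapted-catch response
    matrix of the default viewing context: profile c changes only receptor
    c's quantum catch, exactly, at the linear level.  Profiles are rescaled
    to unit peak so amplitude SDs stay in reflectance units.
    """
    from .vision import ViewingContext

    ctx = ViewingContext.default(grid=grid)
    B = np.stack([_gauss(grid, c, sd) for c, sd in CHANNEL_BUMPS])  # (3, m)
    K = ctx.catch_kernel() / ctx.background_catches()  # (m, 3) adapted-catch kernel
    P = np.linalg.solve(B @ K, B)  # P @ K = I
    return P / np.abs(P).max(axis=1, keepdims=True)


def cattleya_templates(grid: np.ndarray | None = None) -> dict:
    """The six noise-free patch reflectance templates on the working grid."""
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    out = {}
    for patch, p in TEMPLATE_PARAMS.items():
        out[patch] = Spectrum(grid, _template_values(grid, p, amp_scale=1.0, shift=0.0))
    return out


def _template_values(grid, p, amp_scale, shift):
    amp_scale = np.asarray(amp_scale, dtype=float)
    shift = np.asarray(shift, dtype=float)
    if amp_scale.ndim > 0:  # one spectrum per plant, broadcast over wavelengths
        amp_scale = amp_scale[:, None]
        shift = shift[:, None]
    v = 0.0
    if p["band"] is not None:
        c, sd, amp = p["band"]
        v = v + amp * amp_scale * _gauss(grid, c + shift, sd)
    c, sc, amp = p["red"]
    v = v + amp * amp_scale * _sigmoid(grid, c + shift, sc)
    return p["base"] + v


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the default synthetic experiment.

    SDs are unitless multipliers on pigment-band amplitude except
    ``hue_jitter_sd_nm`` (a per-patch wavelength shift of the chromatic
    bands, nm) and the two reflectance-scale noise SDs.
    """

    n_plants: int = 30
    seed: int | None = None
    module_factor_sd: float = 0.20  # shared within-module amplitude factor
    patch_noise_sd: float = 0.10  # patch-specific amplitude noise (half the factor SD)
    hue_jitter_sd_nm: dict = field(
        default_factory=lambda: {
            ("sepal", "tip"): 6.0,
            ("sepal", "base"): 6.0,
            ("petal", "tip"): 6.0,
            ("petal", "base"): 6.0,
            ("labellum", "tip"): 4.0,
            ("labellum", "base"): 1.5,
        }
    )
    channel_noise_sd: float = 0.008  # per-receptor bump amplitude, reflectance units
    null_channel_noise_sd: float = 0.035  # ditto, sole variation source of the null generator
    measurement_noise_sd: float = 0.003  # iid per-wavelength instrument noise
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())

    def __post_init__(self) -> None:
        if self.n_plants < 2:
            raise ValueError("n_plants must be >= 2")
        sds = [self.module_factor_sd, self.patch_noise_sd, self.channel_noise_sd,
               self.null_channel_noise_sd, self.measurement_noise_sd,
               *self.hue_jitter_sd_nm.values()]
        if any(s < 0 for s in sds):
            raise ValueError("all SDs must be nonnegative")


@dataclass
class SyntheticDataset:
    """In-memory dataset: reflectance rows aligned with manifest labels."""

    reflectance: np.ndarray  # (n_plants*6, n_wavelengths)
    labels: pd.DataFrame  # plant_id, structure, position
    grid: np.ndarray
    ground_truth: dict
    config: GeneratorConfig

    def write(self, out_dir) -> str:
        """Write per-spectrum CSVs, a manifest and the ground truth; returns the manifest path."""
        os.makedirs(out_dir, exist_ok=True)
        files = []
        for i, row in self.labels.iterrows():
            fname = f"plant{int(row.plant_id):03d}_{row.structure}_{row.position}.csv"
            write_spectrum(Spectrum(self.grid, self.reflectance[i]), os.path.join(out_dir, fname))
            files.append(fname)
        manifest = self.labels.copy()
        manifest.insert(0, "file", files)
        manifest_path = os.path.join(out_dir, "manifest.csv")
        manifest.to_csv(manifest_path, index=False)
        with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
            json.dump(self.ground_truth, fh, indent=2, sort_keys=True)
        return manifest_path


def _labels(n_plants: int) -> pd.DataFrame:
    rows = [
        {"plant_id": p, "structure": s, "position": pos}
        for p in range(1, n_plants + 1)
        for s, pos in PATCHES
    ]
    return pd.DataFrame(rows)


def generate_dataset(config: GeneratorConfig | None = None, seed=None) -> SyntheticDataset:
    """Modular dataset: shared latent amplitude factor per module per plant."""
    return _generate(config, seed, null=False)


def generate_null_dataset(config: GeneratorConfig | None = None, seed=None) -> SyntheticDataset:
    """Matched non-modular dataset with near-independent excitation columns."""
    return _generate(config, seed, null=True)


def _generate(config, seed, null: bool) -> SyntheticDataset:
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    grid = np.asarray(config.grid, dtype=float)
    n = config.n_plants
    factors = rng.normal(0.0, 1.0, size=(n, 3))  # one latent factor per module per plant
    bumps = _channel_profiles(grid)  # (3, m), orthogonal in adapted-catch space
    spectra = np.empty((n * len(PATCHES), grid.size))
    labels = _labels(n)
    module_of = {p: DEFAULT_PATCH_MODULES[p] - 1 for p in PATCHES}
    clipped = 0
    for j, patch in enumerate(PATCHES):
        p = TEMPLATE_PARAMS[patch]
        if null:
            amp_scale = np.ones(n)
            shift = np.zeros(n)
            beta = rng.normal(0.0, config.null_channel_noise_sd, size=(n, 3))
        else:
            amp_scale = (
                1.0
                + config.module_factor_sd * factors[:, module_of[patch]]
                + rng.normal(0.0, config.patch_noise_sd, size=n)
            )
            amp_scale = np.clip(amp_scale, 0.05, None)
            shift = rng.normal(0.0, config.hue_jitter_sd_nm[patch], size=n)
            beta = rng.normal(0.0, config.channel_noise_sd, size=(n, 3))
        v = _template_values(grid, p, amp_scale, shift)
        v = v + beta @ bumps
        v = v + rng.normal(0.0, config.measurement_noise_sd, size=v.shape)
        clipped += int(np.sum((v < 0) | (v > 1)))
        v = np.clip(v, 0.0, 1.0)
        idx = labels.index[(labels.structure == patch[0]) & (labels.position == patch[1])]
        spectra[idx] = v
    if clipped:
        log.info("clipped %d reflectance samples into [0, 1]", clipped)
    truth = {
        "modular": not null,
        "module_factors": factors.tolist() if not null else None,
        "patch_modules": {f"{s}_{pos}": m for (s, pos), m in DEFAULT_PATCH_MODULES.items()},
        "n_plants": n,
    }
    return SyntheticDataset(spectra, labels, grid, truth, config)
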