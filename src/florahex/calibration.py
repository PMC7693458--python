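"""Monte-Carlo calibration suites: type-I error and power of the package's tests.

Each function simulates many replicate datasets under a stated condition and
returns the rejection rate of one test.  These are the properties the
synthetic generator is designed to support: under the matched null the
permutation CR test, the Watson–Williams circular ANOVA and Watson's U2 keep
their nominal size; under the default planted-modularity conditions the CR
test and the purity blocked ANOVA have the stated power.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .distances import PATCHES
from .model import HexagonColorModel
from .modularity import cr_permutation_test, default_module_assignment, normalize_excitations
from .simulate import GeneratorConfig, generate_dataset, generate_null_dataset
from .stats import circular_anova, purity_block_anova, watson_u2
from .vision import excitation_matrix


def _excitation_table(ds, model) -> pd.DataFrame:
    E = excitation_matrix(ds.reflectance, model.context_)
    out = ds.labels.copy()
    out[["E_uv", "E_blue", "E_green"]] = E
    return out


def _cr_rejection_rate(generator, n_datasets, n_perm, seed, alpha, n_plants) -> float:
    model = HexagonColorModel().fit()
    root = np.random.default_rng(seed)
    rejections = 0
    assignment = default_module_assignment()
    for _ in range(n_datasets):
        ds = generator(GeneratorConfig(n_plants=n_plants), seed=int(root.integers(2**31)))
        X = normalize_excitations(_excitation_table(ds, model)).to_numpy()
        res = cr_permutation_test(X, assignment, n_perm=n_perm, rng=root)
        rejections += res.p_value < alpha
    return rejections / n_datasets


def cr_type1(n_datasets: int = 200, n_perm: int = 500, seed: int = 0,
             alpha: float = 0.05, n_plants: int = 30) -> float:
    """Rejection rate of the CR test on null-generator datasets (nominal: alpha)."""
    return _cr_rejection_rate(generate_null_dataset, n_datasets, n_perm, seed, alpha, n_plants)


def cr_power(n_datasets: int = 200, n_perm: int = 500, seed: int = 0,
             alpha: float = 0.05, n_plants: int = 30) -> float:
    """Power of the CR test against the default planted three-module structure."""
    return _cr_rejection_rate(generate_dataset, n_datasets, n_perm, seed, alpha, n_plants)


def purity_anova_null_pvalues(n_datasets: int = 200, seed: int = 0,
                              n_plants: int = 30, sd: float = 1.0) -> np.ndarray:
    """Interaction p-values of the blocked ANOVA under zero patch effects."""
    rng = np.random.default_rng(seed)
    labels = pd.DataFrame(
        [(p, s, pos) for p in range(n_plants) for s, pos in PATCHES],
        columns=["plant_id", "structure", "position"],
    )
    out = np.empty(n_datasets)
    for i in range(n_datasets):
        y = rng.normal(0, 1, n_plants).repeat(len(PATCHES)) + rng.normal(0, sd, len(labels))
        table = labels.assign(purity=y)
        out[i] = purity_block_anova(table).loc["structure:position", "p"]
    return out


def purity_anova_power(n_datasets: int = 200, seed: int = 0, n_plants: int = 30,
                       shift_sd: float = 3.0, alpha: float = 0.01, **_) -> float:
    """Power to detect a labellum-tip shift of ``shift_sd`` within-plant SDs."""
    rng = np.random.default_rng(seed)
    labels = pd.DataFrame(
        [(p, s, pos) for p in range(n_plants) for s, pos in PATCHES],
        columns=["plant_id", "structure", "position"],
    )
    bump = ((labels.structure == "labellum") & (labels.position == "tip")).to_numpy() * shift_sd
    rejections = 0
    for _i in range(n_datasets):
        y = rng.normal(0, 1, n_plants).repeat(len(PATCHES)) + rng.normal(0, 1.0, len(labels)) + bump
        table = labels.assign(purity=y)
        rejections += purity_block_anova(table).loc["structure:position", "p"] < alpha
    return rejections / n_datasets


def circular_anova_type1(n_datasets: int = 500, seed: int = 0, kappa: float = 20.0,
                         n_per_group: int = 30, alpha: float = 0.05, **_) -> float:
    """Size of the Watson–Williams test: two groups from one von Mises distribution."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _i in range(n_datasets):
        a = np.degrees(sps.vonmises.rvs(kappa, size=n_per_group, random_state=rng))
        b = np.degrees(sps.vonmises.rvs(kappa, size=n_per_group, random_state=rng))
        rejections += circular_anova([a, b]).p_value < alpha
    return rejections / n_datasets


def circular_anova_power(n_datasets: int = 500, seed: int = 0, kappa: float = 20.0,
                         n_per_group: int = 30, separation_deg: float = 90.0,
                         alpha: float = 0.001) -> float:
    """Power of Watson–Williams for mean directions ``separation_deg`` apart."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _i in range(n_datasets):
        a = np.degrees(sps.vonmises.rvs(kappa, size=n_per_group, random_state=rng))
        b = separation_deg + np.degrees(sps.vonmises.rvs(kappa, size=n_per_group, random_state=rng))
        rejections += circular_anova([a, b]).p_value < alpha
    return rejections / n_datasets


def watson_type1(n_datasets: int = 500, n_perm: int = 500, seed: int = 0,
                 kappa: float = 20.0, n_per_group: int = 30, alpha: float = 0.05) -> float:
    """Size of the permutation Watson U2 test under a shared von Mises distribution."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _i in range(n_datasets):
        a = np.degrees(sps.vonmises.rvs(kappa, size=n_per_group, random_state=rng))
        b = np.degrees(sps.vonmises.rvs(kappa, size=n_per_group, random_state=rng))
        rejections += watson_u2(a, b, n_perm=n_perm, rng=rng).p_value < alpha
    return rejections / n_datasets


def watson_power(n_datasets: int = 200, n_perm: int = 1999, seed: int = 0,
                 kappa: float = 20.0, n_per_group: int = 30,
                 separation_deg: float = 180.0, alpha: float = 0.001) -> float:
    """Power of Watson U2 for concentrated samples ``separation_deg`` apart."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _i in range(n_datasets):
        a = np.degrees(sps.vonmises.rvs(kappa, size=n_per_group, random_state=rng))
        b = separation_deg + np.degrees(sps.vonmises.rvs(kappa, size=n_per_group, random_state=rng))
        rejections += watson_u2(a, b, n_perm=n_perm, rng=rng).p_value <= alpha
    return rejections / n_datasets
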