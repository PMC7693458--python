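"""Covariance-ratio (CR) test of intrafloral colour modularity.

The hypothesis: floral patches fall into colour modules whose photoreceptor
excitations covary more within modules than between them.  Variables are the
z-scored UV/blue/green excitations of each patch (18 variables for the
default 6-patch design), observed across plants.  For two modules A and B
with covariance blocks S_AB (between) and S_AA, S_BB (within, with diagonals
zeroed, written S~):

    CR_AB = sqrt( tr(S_AB S_BA) / sqrt( tr(S~_AA S~_AA) tr(S~_BB S~_BB) ) )

and for k > 2 modules the overall CR is the mean over all module pairs.
CR below 1 indicates modularity (less between- than within-module
covariation).  Significance: variables are randomly reassigned to modules
(sizes preserved); the p-value is the proportion of permuted CR values at or
below the observed one, with the add-one convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .distances import PATCHES

#: patch -> module of the three-module hypothesis:
#: {sepals + petals}, {labellum tip}, {labellum base}
DEFAULT_PATCH_MODULES = {
    ("sepal", "tip"): 1,
    ("sepal", "base"): 1,
    ("petal", "tip"): 1,
    ("petal", "base"): 1,
    ("labellum", "tip"): 2,
    ("labellum", "base"): 3,
}

RECEPTORS = ("E_uv", "E_blue", "E_green")


def default_module_assignment() -> np.ndarray:
    """Module label per variable for the default 18-column excitation matrix."""
    return np.array([DEFAULT_PATCH_MODULES[p] for p in PATCHES for _ in RECEPTORS])


def _validate_assignment(labels: np.ndarray, n_vars: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape != (n_vars,):
        raise ValueError(f"assignment must label each of the {n_vars} variables exactly once")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 modules")
    if np.any(counts < 1):
        raise ValueError("every module must be non-empty")
    return labels


def normalize_excitations(table: pd.DataFrame) -> pd.DataFrame:
    """Plants x (patch, receptor) matrix of z-scored excitations.

    Requires a complete design (every plant measured in all six patches).
    Columns are ordered patch-major (sepal tip UV, sepal tip blue, ...), named
    ``structure_position:receptor``.  Zero-variance columns are an error.
    """
    wide = table.pivot_table(
        index="plant_id", columns=["structure", "position"], values=list(RECEPTORS), observed=True
    )
    cols = {}
    for structure, position in PATCHES:
        for rec in RECEPTORS:
            key = (rec, structure, position)
            if key not in wide.columns or wide[key].isna().any():
                raise ValueError(f"incomplete design: missing {structure} {position} {rec}")
            cols[f"{structure}_{position}:{rec}"] = wide[key].to_numpy(float)
    X = pd.DataFrame(cols, index=wide.index)
    sd = X.std(ddof=1)
    dead = sd[sd < 1e-12].index.tolist()
    if dead:
        raise ValueError(f"zero-variance variable(s): {dead}")
    return (X - X.mean()) / sd


def _cr_from_cov(S: np.ndarray, labels: np.ndarray) -> float:
    mods = np.unique(labels)
    tr_within = {}
    for m in mods:
        idx = labels == m
        Sm = S[np.ix_(idx, idx)].copy()
        np.fill_diagonal(Sm, 0.0)
        tr_within[m] = float(np.sum(Sm * Sm))  # tr(S~ S~) for symmetric S~
    crs = []
    for m1, m2 in combinations(mods, 2):
        i1, i2 = labels == m1, labels == m2
        B = S[np.ix_(i1, i2)]
        num = float(np.sum(B * B))  # tr(S12 S21)
        den = np.sqrt(tr_within[m1] * tr_within[m2])
        if den <= 0:
            raise ValueError(
                "degenerate within-module covariance (a module has no off-diagonal covariation)"
            )
        crs.append(np.sqrt(num / den))
    return float(np.mean(crs))


def cr_statistic(X, assignment) -> float:
    """Covariance ratio of a data matrix (rows = plants) under a module assignment."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 rows")
    labels = _validate_assignment(assignment, X.shape[1])
    S = np.cov(X, rowvar=False)
    return _cr_from_cov(S, labels)


@dataclass
class CRResult:
    """Observed CR with its permutation null, p-value and bootstrap CI."""

    observed_cr: float
    perm_values: np.ndarray
    p_value: float
    ci_low: float
    ci_high: float
    n_perm: int
    seed: object
    assignment: np.ndarray


def cr_permutation_test(
    X,
    assignment,
    n_perm: int = 10000,
    rng: np.random.Generator | int | None = None,
    n_boot: int = 0,
) -> CRResult:
    """Permutation test of modularity: p = (1 + #{CR_perm <= CR_obs}) / (n_perm + 1).

    Permutations reassign individual variables to modules with module sizes
    preserved.  Pass ``n_boot > 0`` to also compute the bootstrap CI.
    """
    X = np.asarray(X, dtype=float)
    labels = _validate_assignment(assignment, X.shape[1])
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is too small for stable p-values", stacklevel=2)
    seed = rng
    rng = np.random.default_rng(rng)
    S = np.cov(X, rowvar=False)
    observed = _cr_from_cov(S, labels)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        perm[i] = _cr_from_cov(S, rng.permutation(labels))
    p = float((1 + np.sum(perm <= observed + 1e-15)) / (n_perm + 1))
    ci_low = ci_high = np.nan
    if n_boot > 0:
        ci_low, ci_high = cr_bootstrap_ci(X, labels, n_boot=n_boot, rng=rng)
    return CRResult(
        observed_cr=observed,
        perm_values=perm,
        p_value=p,
        ci_low=ci_low,
        ci_high=ci_high,
        n_perm=n_perm,
        seed=seed,
        assignment=labels,
    )


def cr_bootstrap_ci(
    X,
    assignment,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Nonparametric bootstrap CI of CR over resampled plants (rows)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("bootstrap needs at least 10 rows")
    labels = _validate_assignment(assignment, X.shape[1])
    rng = np.random.default_rng(rng)
    vals = np.empty(n_boot)
    for i in range(n_boot):
        for attempt in range(10):
            idx = rng.integers(0, X.shape[0], size=X.shape[0])
            try:
                vals[i] = cr_statistic(X[idx], labels)
                break
            except ValueError:
                if attempt == 9:
                    raise
    lo = (1.0 - level) / 2.0
    return float(np.quantile(vals, lo)), float(np.quantile(vals, 1.0 - lo))


class CovarianceRatio(BaseEstimator):
    """sklearn-style estimator for the CR modularity permutation test.

    Parameters
    ----------
    modules : array-like or None
        Module label per column of X; ``None`` uses the default three-module
        hypothesis for an 18-column patch x receptor matrix.
    n_permutations, n_bootstrap : int
        Sizes of the permutation null and the bootstrap CI resample.
    random_state : int, Generator or None
        Seed for both resampling schemes.

    Attributes (after ``fit``)
    --------------------------
    cr_ : observed covariance ratio.
    p_value_ : permutation p (proportion of permuted CR at or below observed).
    ci_ : (low, high) 95% bootstrap bounds over resampled plants.
    null_distribution_ : the permuted CR values.
    """

    def __init__(
        self,
        modules=None,
        n_permutations: int = 10000,
        n_bootstrap: int = 1000,
        random_state=None,
    ):
        self.modules = modules
        self.n_permutations = n_permutations
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    def fit(self, X, y=None) -> "CovarianceRatio":
        X = check_array(X, dtype=float)
        labels = (
            default_module_assignment() if self.modules is None else np.asarray(self.modules)
        )
        res = cr_permutation_test(
            X,
            labels,
            n_perm=self.n_permutations,
            rng=self.random_state,
            n_boot=self.n_bootstrap,
        )
        self.n_features_in_ = X.shape[1]
        self.assignment_ = res.assignment
        self.cr_ = res.observed_cr
        self.p_value_ = res.p_value
        self.ci_ = (res.ci_low, res.ci_high)
        self.null_distribution_ = res.perm_values
        self.result_ = res
        return self

    def score(self, X=None, y=None) -> float:
        check_is_fitted(self, "cr_")
        return -self.cr_
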