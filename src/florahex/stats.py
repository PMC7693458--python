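"""Inferential statistics for intrafloral colour patterns.

Linear part
-----------
The purity and distance models of the analysis are linear mixed models with a
random intercept per plant (or per plant pair).  For the balanced complete
designs this package requires (every block observed in every structure x
position cell exactly once), those models are *exactly* equivalent to the
randomized-complete-block ANOVA, so the F tests here come from the textbook
closed-form sum-of-squares decomposition with the block effect removed; the
module refuses unbalanced layouts rather than silently approximating REML
output.

Circular part
-------------
Hue is an angle, so patch comparisons use a Watson–Williams one-way circular
ANOVA (high-concentration F approximation with the standard kappa correction)
and Watson's two-sample U-squared homogeneity test with a permutation null,
since printed critical-value tables do not resolve the conservative 0.001
level used for the post hoc comparisons.  Angles are degrees at every
interface and radians internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_fdr",
    "block_anova",
    "purity_block_anova",
    "sqrt_distance_anova",
    "pairwise_patch_tests",
    "circular_anova",
    "watson_u2",
    "circ_r",
    "circ_mean_deg",
    "circ_sd_deg",
    "estimate_kappa",
    "compact_letters",
]


# ---------------------------------------------------------------------------
# multiple testing

def bh_fdr(pvals, q: float = 0.05):
    """Benjamini–Hochberg step-up: (adjusted p-values, reject flags at q)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


# ---------------------------------------------------------------------------
# balanced randomized-complete-block ANOVA

def block_anova(
    table: pd.DataFrame,
    response: str,
    block: str = "plant_id",
    factor_a: str = "structure",
    factor_b: str = "position",
) -> pd.DataFrame:
    """Two-factor ANOVA with a block term, exact for balanced complete layouts.

    Returns an ANOVA table (sum_sq, df, F, p) with rows for the block, the two
    factors, their interaction, and the residual.  Raises on any imbalance:
    drop incomplete blocks before calling.
    """
    for col in (response, block, factor_a, factor_b):
        if col not in table:
            raise ValueError(f"missing column {col!r}")
    counts = table.groupby([block, factor_a, factor_b], observed=True).size()
    a_levels = table[factor_a].nunique()
    b_levels = table[factor_b].nunique()
    n_blocks = table[block].nunique()
    if len(counts) != n_blocks * a_levels * b_levels or counts.nunique() != 1 or counts.iloc[0] != 1:
        raise ValueError(
            "unbalanced layout: every block must contain every "
            f"{factor_a} x {factor_b} cell exactly once — drop incomplete blocks first"
        )
    y = table[response].to_numpy(float)
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))

    def _ss(groupers) -> float:
        means = table.groupby(groupers, observed=True)[response].mean()
        per = len(y) / means.size
        return float(per * np.sum((means.to_numpy() - grand) ** 2))

    ss_block = _ss(block)
    ss_a = _ss(factor_a)
    ss_b = _ss(factor_b)
    ss_cells = _ss([factor_a, factor_b])
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = ss_total - ss_block - ss_cells
    df_a = a_levels - 1
    df_b = b_levels - 1
    df_ab = df_a * df_b
    df_block = n_blocks - 1
    df_err = (len(y) - 1) - df_block - (df_a + df_b + df_ab)
    ms_err = ss_err / df_err
    eps = 1e-12 * (ss_total + 1.0)  # treat round-off as exact zero
    rows = {}
    for name, ss, df in (
        (block, ss_block, df_block),
        (factor_a, ss_a, df_a),
        (factor_b, ss_b, df_b),
        (f"{factor_a}:{factor_b}", ss_ab, df_ab),
    ):
        f = max(ss, 0.0) / df / ms_err if ms_err > eps else (0.0 if ss <= eps else np.inf)
        rows[name] = (ss, df, f, float(sps.f.sf(f, df, df_err)) if np.isfinite(f) else 0.0)
    rows["residual"] = (ss_err, df_err, np.nan, np.nan)
    out = pd.DataFrame(rows, index=["sum_sq", "df", "F", "p"]).T
    out["df"] = out["df"].astype(int)
    return out


def purity_block_anova(table: pd.DataFrame, response: str = "purity") -> pd.DataFrame:
    """Spectral purity ~ structure * position with plant as the block term."""
    return block_anova(table, response=response, block="plant_id")


def sqrt_distance_anova(records: pd.DataFrame) -> pd.DataFrame:
    """sqrt(Euclidean distance) ~ structure * position with the plant pair as block.

    The returned table carries back-transformed (squared) patch means of the
    square-root response in ``.attrs["patch_means_backtransformed"]`` for
    plotting on the original distance scale.
    """
    rec = records.copy()
    rec["pair"] = rec["plant_a"].astype(str) + "|" + rec["plant_b"].astype(str)
    rec["sqrt_euclidean"] = np.sqrt(rec["euclidean"].to_numpy(float))
    out = block_anova(rec, response="sqrt_euclidean", block="pair")
    means = rec.groupby(["structure", "position"], observed=True)["sqrt_euclidean"].mean() ** 2
    out.attrs["patch_means_backtransformed"] = means.to_dict()
    return out


# ---------------------------------------------------------------------------
# pairwise paired t tests with FDR

def _patch_label(structure: str, position: str) -> str:
    return f"{structure}_{position}"


def pairwise_patch_tests(
    table: pd.DataFrame, response: str = "purity", alpha: float = 0.05
) -> pd.DataFrame:
    """All C(6,2) = 15 paired t tests between patches, BH-adjusted at ``alpha``.

    Pairs with zero within-plant difference variance are flagged and excluded
    from the adjustment.  A compact-letter display over patches is attached as
    ``.attrs["letters"]``.
    """
    wide = table.pivot_table(
        index="plant_id", columns=["structure", "position"], values=response, observed=True
    )
    patches = list(wide.columns)
    rows = []
    for (sa, pa), (sb, pb) in combinations(patches, 2):
        da = wide[(sa, pa)].to_numpy(float)
        db = wide[(sb, pb)].to_numpy(float)
        diff = da - db
        if np.std(diff, ddof=1) < 1e-12:
            rows.append((_patch_label(sa, pa), _patch_label(sb, pb), diff.mean(), 0.0,
                         len(diff) - 1, 1.0 if np.allclose(diff, 0) else np.nan, True))
            continue
        t, p = sps.ttest_rel(da, db)
        rows.append((_patch_label(sa, pa), _patch_label(sb, pb), diff.mean(), float(t),
                     len(diff) - 1, float(p), False))
    out = pd.DataFrame(
        rows, columns=["patch_a", "patch_b", "mean_diff", "t", "df", "p_raw", "degenerate"]
    )
    valid = out["p_raw"].notna() & ~out["degenerate"]
    p_adj = np.full(len(out), np.nan)
    reject = np.zeros(len(out), dtype=bool)
    if valid.any():
        p_adj[valid], reject[valid] = bh_fdr(out.loc[valid, "p_raw"].to_numpy(), q=alpha)
    out["p_adj"] = p_adj
    out["reject"] = reject
    labels = [_patch_label(s, p) for s, p in patches]
    sig = {(a, b) for a, b, r in zip(out["patch_a"], out["patch_b"], out["reject"]) if r}
    out.attrs["letters"] = compact_letters(labels, sig)
    return out


def compact_letters(labels: list[str], significant_pairs: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact-letter display: groups sharing a letter do not differ."""
    sig = {frozenset(p) for p in significant_pairs}
    letter_sets: list[set[str]] = [set(labels)]
    for pair in sig:
        a, b = tuple(pair)
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                for drop in (a, b):
                    cand = s - {drop}
                    if not any(cand <= other for other in letter_sets):
                        letter_sets.append(cand)
    letter_sets.sort(key=lambda s: sorted(labels.index(x) for x in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for i, s in enumerate(letter_sets):
        for lab in labels:
            if lab in s:
                out[lab] += alphabet[i]
    return out


# ---------------------------------------------------------------------------
# circular statistics (degrees in, degrees out)

def circ_r(theta_deg) -> float:
    """Mean resultant length of angles in degrees (NaN-dropping)."""
    t = np.radians(np.asarray(theta_deg, dtype=float))
    t = t[np.isfinite(t)]
    if t.size == 0:
        raise ValueError("no defined angles")
    return float(np.hypot(np.sin(t).mean(), np.cos(t).mean()))


def circ_mean_deg(theta_deg) -> float:
    t = np.radians(np.asarray(theta_deg, dtype=float))
    t = t[np.isfinite(t)]
    return float(np.degrees(np.arctan2(np.sin(t).mean(), np.cos(t).mean())) % 360.0)


def circ_sd_deg(theta_deg) -> float:
    """Circular standard deviation sqrt(-2 ln r), in degrees."""
    r = circ_r(theta_deg)
    if r <= 0:
        return float("inf")
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


def estimate_kappa(r: float) -> float:
    """Fisher's approximation to the von Mises concentration from resultant length."""
    r = min(r, 1.0 - 1e-12)  # r = 1 (all angles identical) would divide by zero
    if r < 0.53:
        return 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    return 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)


@dataclass
class CircularTestResult:
    """Result of a circular ANOVA or two-sample homogeneity test."""

    statistic: float
    p_value: float
    df: tuple
    group_labels: list
    resultant_lengths: list
    method: str
    reject: bool | None = None
    n_perm: int | None = None


def circular_anova(groups: list, labels: list | None = None) -> CircularTestResult:
    """Watson–Williams one-way circular ANOVA on hue angles in degrees.

    Valid for concentrated samples; warns when the pooled concentration
    estimate falls below 1.  Errors if any group's mean direction is
    undefined (resultant length ~ 0).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    clean = []
    for g in groups:
        t = np.asarray(g, dtype=float)
        t = t[np.isfinite(t)]
        if t.size < 2:
            raise ValueError("each group needs at least 2 defined hues")
        clean.append(np.radians(t))
    labels = labels if labels is not None else list(range(len(clean)))
    k = len(clean)
    n = np.array([t.size for t in clean])
    N = int(n.sum())
    R_i = np.array([np.hypot(np.sin(t).sum(), np.cos(t).sum()) for t in clean])
    rbar_i = R_i / n
    if np.any(rbar_i < 1e-9):
        raise ValueError("a group has resultant length ~ 0: mean direction undefined")
    pooled = np.concatenate(clean)
    R = float(np.hypot(np.sin(pooled).sum(), np.cos(pooled).sum()))
    rbar_w = float(R_i.sum() / N)
    kappa = estimate_kappa(rbar_w)
    if kappa < 1.0:
        warnings.warn(
            f"estimated concentration kappa={kappa:.2f} < 1: the Watson-Williams "
            "F approximation is unreliable for dispersed samples",
            stacklevel=2,
        )
    K = 1.0 + 3.0 / (8.0 * kappa)
    num = R_i.sum() - R
    den = N - R_i.sum()
    if den < 1e-12:  # all angles identical within groups
        F = 0.0 if num < 1e-12 else np.inf
    else:
        F = float(K * (N - k) * num / ((k - 1) * den))
    p = float(sps.f.sf(F, k - 1, N - k)) if np.isfinite(F) else 0.0
    return CircularTestResult(
        statistic=F,
        p_value=p,
        df=(k - 1, N - k),
        group_labels=list(labels),
        resultant_lengths=list(rbar_i),
        method="Watson-Williams F",
    )


def _watson_u2_from_sorted_labels(z: np.ndarray, n_a: int, n_b: int) -> np.ndarray:
    """U^2 for label matrices z (…, N) over the pooled sorted sample (1 = sample a)."""
    N = n_a + n_b
    d = np.cumsum(z, axis=-1) / n_a - np.cumsum(1 - z, axis=-1) / n_b
    return (n_a * n_b / N**2) * (np.sum(d**2, axis=-1) - np.sum(d, axis=-1) ** 2 / N)


def watson_u2(
    sample_a,
    sample_b,
    n_perm: int = 10000,
    alpha: float = 0.001,
    rng: np.random.Generator | int | None = None,
) -> CircularTestResult:
    """Watson's two-sample U-squared test of homogeneity on the circle.

    The statistic compares the two empirical CDFs around the circle and is
    origin-invariant; the p-value comes from a seeded random-permutation null
    with the add-one convention, with rejection flagged at ``alpha``.
    """
    a = np.asarray(sample_a, dtype=float) % 360.0
    b = np.asarray(sample_b, dtype=float) % 360.0
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 8 or b.size < 8:
        raise ValueError(f"samples too small ({a.size}, {b.size}); need >= 8 each")
    rng = np.random.default_rng(rng)
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    z0 = np.zeros(pooled.size)
    z0[: a.size] = 1.0
    z_sorted = z0[order]
    observed = float(_watson_u2_from_sorted_labels(z_sorted, a.size, b.size))
    perm_z = rng.permuted(np.tile(z_sorted, (n_perm, 1)), axis=1)
    null = _watson_u2_from_sorted_labels(perm_z, a.size, b.size)
    p = float((1 + np.sum(null >= observed - 1e-15)) / (n_perm + 1))
    return CircularTestResult(
        statistic=observed,
        p_value=p,
        df=(a.size, b.size),
        group_labels=["a", "b"],
        resultant_lengths=[circ_r(a), circ_r(b)],
        method="Watson two-sample U2 (permutation)",
        reject=p <= alpha,
        n_perm=n_perm,
    )
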