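"""End-to-end analysis: spectra -> excitations -> descriptors -> distances -> statistics -> modularity.

``run_pipeline`` executes every stage of the intrafloral colour analysis from
a :class:`~florahex.config.RunConfig`, writes tidy CSV tables plus a JSON
summary and a run log into the output directory, and returns the in-memory
results.  All randomness flows from one seeded root generator, so a config +
seed pair reproduces every table bit-identically.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .config import RunConfig
from .distances import PATCHES, pairwise_distances
from .model import HexagonColorModel
from .modularity import DEFAULT_PATCH_MODULES, CovarianceRatio, normalize_excitations
from .simulate import GeneratorConfig, generate_dataset
from .spectra import load_dataset
from .stats import (
    circ_sd_deg,
    circular_anova,
    pairwise_patch_tests,
    purity_block_anova,
    sqrt_distance_anova,
    watson_u2,
)

log = logging.getLogger(__name__)


def _patch_key(row) -> str:
    return f"{row[0]}_{row[1]}"


def _hue_groups(table: pd.DataFrame) -> tuple[list, list]:
    groups, labels = [], []
    for s, p in PATCHES:
        hue = table[(table.structure == s) & (table.position == p)]["hue_deg"].dropna()
        groups.append(hue.to_numpy())
        labels.append(f"{s}_{p}")
    return groups, labels


def _watson_posthoc(groups, labels, alpha, n_perm, rng) -> pd.DataFrame:
    rows = []
    for (ga, la), (gb, lb) in combinations(zip(groups, labels), 2):
        res = watson_u2(ga, gb, n_perm=n_perm, alpha=alpha, rng=rng)
        rows.append({"patch_a": la, "patch_b": lb, "u2": res.statistic,
                     "p": res.p_value, "reject": res.reject})
    return pd.DataFrame(rows)


def _circ_table(result, alpha) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "statistic": [result.statistic],
            "df1": [result.df[0]],
            "df2": [result.df[1]],
            "p": [result.p_value],
            "method": [result.method],
            "significant": [result.p_value < alpha],
        }
    )


def run_pipeline(config: RunConfig, out_dir: str | None = None) -> dict:
    """Run the full analysis; returns a dict of tables/results, writing them to disk."""
    config.validate()
    out = out_dir if out_dir is not None else config.out_dir
    os.makedirs(out, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("florahex")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    rng = np.random.default_rng(config.seed)
    stage = "setup"
    try:
        log.info("florahex %s, seed=%s, config=%s", __version__, config.seed, asdict(config))

        stage = "input"
        grid = np.arange(config.grid[0], config.grid[1] + config.grid[2] / 2, config.grid[2])
        if config.manifest is not None:
            R, labels = load_dataset(config.manifest, grid=grid, dialect=config.dialect)
        else:
            gen = GeneratorConfig(**{"grid": grid, **config.generator})
            ds = generate_dataset(gen, seed=int(rng.integers(2**31)))
            R, labels = ds.reflectance, ds.labels

        stage = "color model"
        model = HexagonColorModel(
            lambda_max=config.lambda_max,
            illuminant=config.illuminant,
            background=config.background,
            grid=grid,
            locus_step=config.locus_step,
            rotation_deg=config.rotation_deg,
        ).fit()
        table = model.color_table(R, labels)
        table.to_csv(os.path.join(out, "patch_colors.csv"), index=False)

        stage = "distances"
        dist = pairwise_distances(table)
        dist.to_csv(os.path.join(out, "distances.csv"), index=False)

        stage = "purity statistics"
        r_pc, p_pc = sps.pearsonr(table["purity"], table["contrast"])
        anova = purity_block_anova(table)
        anova.to_csv(os.path.join(out, "purity_anova.csv"))
        pairwise = pairwise_patch_tests(table, alpha=config.alpha)
        pairwise["letters_a"] = pairwise["patch_a"].map(pairwise.attrs["letters"])
        pairwise.to_csv(os.path.join(out, "purity_pairwise.csv"), index=False)

        stage = "circular statistics"
        groups, glabels = _hue_groups(table)
        hue_anova = circular_anova(groups, glabels)
        _circ_table(hue_anova, config.alpha).to_csv(
            os.path.join(out, "hue_circular_anova.csv"), index=False
        )
        hue_posthoc = _watson_posthoc(groups, glabels, config.circular_alpha, config.n_perm, rng)
        hue_posthoc.to_csv(os.path.join(out, "hue_watson_pairwise.csv"), index=False)

        stage = "distance statistics"
        dist_anova = sqrt_distance_anova(dist)
        dist_anova.to_csv(os.path.join(out, "distance_anova.csv"))
        ang_groups = [
            dist[(dist.structure == s) & (dist.position == p)]["angular"].dropna().to_numpy()
            for s, p in PATCHES
        ]
        ang_anova = circular_anova(ang_groups, glabels)
        _circ_table(ang_anova, config.alpha).to_csv(
            os.path.join(out, "angular_circular_anova.csv"), index=False
        )

        stage = "modularity"
        X = normalize_excitations(table)
        cr = CovarianceRatio(
            n_permutations=config.n_perm,
            n_bootstrap=config.n_boot,
            random_state=int(rng.integers(2**31)),
        ).fit(X.to_numpy())

        stage = "report"
        hue_sd = {
            f"{s}_{p}": circ_sd_deg(
                table[(table.structure == s) & (table.position == p)]["hue_deg"]
            )
            for s, p in PATCHES
        }
        summary = {
            "version": __version__,
            "seed": config.seed,
            "n_plants": int(table["plant_id"].nunique()),
            "n_patch_records": int(len(table)),
            "n_distance_records": int(len(dist)),
            "purity_contrast_pearson_r": float(r_pc),
            "purity_contrast_pearson_p": float(p_pc),
            "purity_anova": {
                term: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for term, row in anova.T.to_dict().items()
            },
            "hue_circular_anova_F": hue_anova.statistic,
            "hue_circular_anova_p": hue_anova.p_value,
            "hue_circular_sd_deg": hue_sd,
            "mean_purity": {
                f"{s}_{p}": float(
                    table[(table.structure == s) & (table.position == p)]["purity"].mean()
                )
                for s, p in PATCHES
            },
            "cr": {
                "observed": cr.cr_,
                "p_value": cr.p_value_,
                "ci_low": cr.ci_[0],
                "ci_high": cr.ci_[1],
                "n_perm": config.n_perm,
                "n_boot": config.n_boot,
                "modules": {f"{s}_{p}": int(m) for (s, p), m in DEFAULT_PATCH_MODULES.items()},
            },
        }
        with open(os.path.join(out, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        log.info("pipeline complete: %s", out)
        return {
            "table": table,
            "distances": dist,
            "purity_anova": anova,
            "purity_pairwise": pairwise,
            "hue_anova": hue_anova,
            "hue_posthoc": hue_posthoc,
            "distance_anova": dist_anova,
            "angular_anova": ang_anova,
            "cr": cr,
            "summary": summary,
        }
    except Exception:
        log.exception("pipeline failed at stage: %s", stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
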