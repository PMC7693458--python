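"""Among-individual colour distances within floral patches.

For every unordered pair of plants and every floral patch, the Euclidean
distance between the two hexagon loci (a proxy for chromatic contrast between
the individuals) and the angular distance between their hues (the difference
in colour hue, in [0, 180] degrees).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PATCHES = [
    ("sepal", "tip"),
    ("sepal", "base"),
    ("petal", "tip"),
    ("petal", "base"),
    ("labellum", "tip"),
    ("labellum", "base"),
]


def angular_distance(theta_a, theta_b):
    """Shortest angular separation on the circle, in degrees [0, 180]."""
    d = np.abs(np.asarray(theta_a, dtype=float) - np.asarray(theta_b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def _complete_plants(table: pd.DataFrame) -> list:
    want = set(PATCHES)
    ok = []
    for plant, g in table.groupby("plant_id"):
        have = set(zip(g["structure"], g["position"]))
        if want <= have and len(g) == len(want):
            ok.append(plant)
        else:
            log.warning("dropping plant %r with incomplete patch set", plant)
    return ok


def pairwise_distances(table: pd.DataFrame) -> pd.DataFrame:
    """One record per unordered plant pair per patch: n(n-1)/2 records per patch.

    Plants missing any of the six patches are dropped with a warning; pairs
    where either hue is undefined get NaN angular distance (flagged, excluded
    from circular statistics downstream).
    """
    plants = sorted(_complete_plants(table))
    if len(plants) < 2:
        raise ValueError(f"need at least 2 complete plants, have {len(plants)}")
    table = table[table["plant_id"].isin(plants)]
    records = []
    for structure, position in PATCHES:
        sub = (
            table[(table["structure"] == structure) & (table["position"] == position)]
            .set_index("plant_id")
            .loc[plants]
        )
        xy = sub[["x", "y"]].to_numpy(float)
        hue = sub["hue_deg"].to_numpy(float)
        ia, ib = np.triu_indices(len(plants), k=1)
        eu = np.hypot(*(xy[ia] - xy[ib]).T)
        ang = angular_distance(hue[ia], hue[ib])
        records.append(
            pd.DataFrame(
                {
                    "structure": structure,
                    "position": position,
                    "plant_a": np.asarray(plants)[ia],
                    "plant_b": np.asarray(plants)[ib],
                    "euclidean": eu,
                    "angular": ang,
                }
            )
        )
    out = pd.concat(records, ignore_index=True)
    n_undef = int(out["angular"].isna().sum())
    if n_undef:
        log.warning("%d pairs with undefined hue excluded from angular distances", n_undef)
    return out
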