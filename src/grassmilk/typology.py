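"""Farm feeding typologies from seasonal GRASS-probability profiles.

Each farm-year with full calendar coverage contributes one 12-dimensional
profile (mean GRASS probability per month).  Profiles are grouped by
agglomerative hierarchical clustering under the Ward.D2 convention
(the merge criterion minimises the within-cluster variance increase,
computed from unsquared Euclidean inter-profile distances).  Cluster
summaries mirror the standard descriptive table: record counts, milk yield,
fat and protein content, and the saturated / monounsaturated / long-chain
fatty-acid fractions of milk fat.

A cluster whose mean fat content is near zero corresponds to farms that
submit skimmed milk for analysis: the milk matrix is altered and the model
probabilities are meaningless there, so such clusters are flagged and
excluded from feeding interpretation.  The remaining clusters are mapped to
an intensive (−1) / extensive (+1) dichotomy; summing a farm's yearly
values yields an intensity index separating always-intensive,
always-extensive and intermediate farms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import ConfigurationError, InputError

__all__ = [
    "FarmProfileSet",
    "ClusterSolution",
    "build_profiles",
    "ward_d2_cluster",
    "cut_and_summarize",
    "flag_skimmed",
    "intensity_index",
]

logger = logging.getLogger(__name__)

MONTH_COLUMNS = [f"m{m:02d}" for m in range(1, 13)]

#: traits summarised per cluster; FA fractions are re-expressed per 100 g fat
SUMMARY_TRAITS = ("milk_yield", "fat", "protein")
SUMMARY_FA = ("SFA", "MUFA", "LCFA")


@dataclass
class FarmProfileSet:
    """Farm-year × 12-month probability profiles plus exclusion bookkeeping."""

    profiles: pd.DataFrame  # columns: farm_id, year, m01..m12
    n_excluded: int

    @property
    def matrix(self) -> np.ndarray:
        return self.profiles[MONTH_COLUMNS].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.profiles)


def build_profiles(predictions: pd.DataFrame) -> FarmProfileSet:
    """Average probabilities into farm × year × month profiles.

    Farm-years covering fewer than 12 distinct months are excluded (logged
    and counted), so every retained profile is a complete seasonal curve.
    """
    required = {"farm_id", "year", "month", "probability"}
    missing = required - set(predictions.columns)
    if missing:
        raise InputError(f"predictions missing columns {sorted(missing)}")
    monthly = (
        predictions.groupby(["farm_id", "year", "month"], as_index=False)[
            "probability"
        ].mean()
    )
    wide = monthly.pivot_table(
        index=["farm_id", "year"], columns="month", values="probability"
    )
    complete = wide.dropna(axis=0, how="any")
    n_excluded = len(wide) - len(complete)
    if n_excluded:
        logger.info(
            "excluded %d farm-year(s) without full 12-month coverage", n_excluded
        )
    complete = complete.reindex(columns=range(1, 13))
    out = complete.reset_index()
    out.columns = ["farm_id", "year", *MONTH_COLUMNS]
    return FarmProfileSet(profiles=out, n_excluded=n_excluded)


def ward_d2_cluster(profiles: FarmProfileSet | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Ward.D2 hierarchical clustering of the 12-month profiles.

    Returns a SciPy linkage matrix; merge heights are the Ward.D2
    inter-cluster distances (nondecreasing along the agglomeration).
    """
    X = _profile_matrix(profiles)
    if len(X) < 2:
        raise InputError("need at least 2 profiles to cluster")
    return linkage(X, method="ward")


def _profile_matrix(profiles) -> np.ndarray:
    if isinstance(profiles, FarmProfileSet):
        return profiles.matrix
    if isinstance(profiles, pd.DataFrame):
        return profiles[MONTH_COLUMNS].to_numpy(dtype=float)
    return np.asarray(profiles, dtype=float)


@dataclass
class ClusterSolution:
    """A cut of the Ward tree with per-cluster curves and trait summaries."""

    linkage: np.ndarray
    k: int
    assignments: pd.DataFrame      # farm_id, year, cluster (1..k)
    monthly_curves: pd.DataFrame   # cluster, m01..m12
    trait_summary: pd.DataFrame    # cluster, n_records, share, milk/fat/protein, FA per 100 g fat

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.assignments["cluster"].value_counts().sort_index()


def cut_and_summarize(
    tree: np.ndarray,
    k: int,
    profiles: FarmProfileSet,
    records: pd.DataFrame | None = None,
) -> ClusterSolution:
    """Cut the dendrogram into ``k`` clusters and summarise each.

    Monthly curves average the member profiles.  If ``records`` (the trait
    table) is given, per-cluster means of milk yield, fat, protein and the
    SFA/MUFA/LCFA fractions of fat (g/100 g fat, i.e. the g/dL trait over
    the fat content times 100) are reported for the records of the member
    farm-years, unweighted.
    """
    n = len(profiles)
    if not 1 <= k <= n:
        raise InputError(f"k must lie in 1..{n}")
    labels = fcluster(tree, t=k, criterion="maxclust")
    assignments = profiles.profiles[["farm_id", "year"]].copy()
    assignments["cluster"] = labels

    prof = profiles.profiles.copy()
    prof["cluster"] = labels
    monthly_curves = (
        prof.groupby("cluster", as_index=False)[MONTH_COLUMNS].mean()
    )

    if records is not None:
        merged = records.merge(assignments, on=["farm_id", "year"], how="inner")
        rows = []
        total = len(merged)
        for cluster, grp in merged.groupby("cluster"):
            row: dict[str, float] = {
                "cluster": cluster,
                "n_records": len(grp),
                "share_pct": 100.0 * len(grp) / total,
            }
            for trait in SUMMARY_TRAITS:
                if trait in grp.columns:
                    row[trait] = float(grp[trait].mean())
            if "fat" in grp.columns:
                for trait in SUMMARY_FA:
                    if trait in grp.columns:
                        row[f"{trait}_per100g_fat"] = float(
                            (100.0 * grp[trait] / grp["fat"]).mean()
                        )
            rows.append(row)
        trait_summary = pd.DataFrame(rows)
    else:
        trait_summary = pd.DataFrame({"cluster": sorted(set(labels))})

    return ClusterSolution(
        linkage=tree,
        k=k,
        assignments=assignments,
        monthly_curves=monthly_curves,
        trait_summary=trait_summary,
    )


def flag_skimmed(solution: ClusterSolution, fat_threshold: float = 1.0) -> list[int]:
    """Clusters whose mean fat content falls below the threshold (g/100 g).

    Those clusters gather skimmed-milk submissions; their probabilities are
    artefacts of the altered milk matrix and are excluded from feeding
    interpretation.
    """
    if "fat" not in solution.trait_summary.columns:
        raise InputError("trait summary lacks a fat column; pass records when cutting")
    summary = solution.trait_summary
    return [
        int(c)
        for c, f in zip(summary["cluster"], summary["fat"])
        if f < fat_threshold
    ]


def intensity_index(
    assignments: pd.DataFrame,
    group_map: dict[int, int],
    flagged: list[int] | None = None,
) -> pd.DataFrame:
    """Per-farm intensity index from yearly cluster membership.

    ``group_map`` maps each (non-flagged) cluster to −1 (intensive) or +1
    (extensive); flagged clusters' farm-years are skipped.  Per farm, yearly
    values are summed, and the farm is categorised ``always-intensive`` if
    every year scored −1, ``always-extensive`` if every year scored +1, and
    ``intermediate`` otherwise.
    """
    flagged_set = set(flagged or [])
    used = assignments[~assignments["cluster"].isin(flagged_set)]
    unmapped = sorted(set(used["cluster"]) - set(group_map))
    if unmapped:
        raise ConfigurationError(f"clusters without a group mapping: {unmapped}")
    bad = {c: v for c, v in group_map.items() if v not in (-1, 1)}
    if bad:
        raise ConfigurationError(f"group values must be -1 or +1, got {bad}")
    used = used.copy()
    used["value"] = used["cluster"].map(group_map)
    rows = []
    for farm, grp in used.groupby("farm_id"):
        values = grp["value"].to_numpy()
        total = int(values.sum())
        if np.all(values == -1):
            category = "always-intensive"
        elif np.all(values == 1):
            category = "always-extensive"
        else:
            category = "intermediate"
        rows.append(
            {
                "farm_id": farm,
                "n_years": len(values),
                "sum": total,
                "category": category,
            }
        )
    return pd.DataFrame(rows)
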