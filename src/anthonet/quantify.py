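"""Internal-standard relative quantification of metabolite peak areas.

Quantification follows the standard spiked-internal-standard protocol: each
compound is quantified by the summed areas of its two most abundant fragment
ions, divided by the internal-standard (IS) area of the same sample, giving a
dimensionless fold-over-IS value.  Per-stage summaries (mean, sample SD,
percent composition) and a row-directed hierarchical clustering of compound
profiles complete the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "DEFAULT_IS_NAME",
    "AbundanceTable",
    "StageSummary",
    "HclResult",
    "normalize_to_is",
    "stage_summary",
    "hcl_rows",
]

#: Default internal-standard compound (an isoflavone absent from petals).
DEFAULT_IS_NAME = "formononetin"

AREA_COLUMNS = ("compound_id", "sample_id", "stage", "replicate", "fragment_rank", "area")


@dataclass
class AbundanceTable:
    """Fold-over-IS abundances: compounds x samples, plus sample metadata."""

    values: pd.DataFrame  # index: compound_id, columns: sample_id
    sample_meta: pd.DataFrame  # index: sample_id, columns: stage, replicate

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("abundances must be non-negative")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")


@dataclass
class StageSummary:
    """Per-stage replicate statistics and percent composition."""

    mean: pd.DataFrame  # compounds x stages
    sd: pd.DataFrame  # compounds x stages (sample SD, ddof=1; 0 for n=1)
    percent: pd.DataFrame  # compounds x stages, columns sum to 100 (or 0)
    n_replicates: pd.Series  # per stage


@dataclass
class HclResult:
    """Agglomerative clustering of compound rows."""

    linkage: np.ndarray  # scipy linkage matrix
    row_order: list[str]  # leaf order (compound ids)
    newick: str
    metric: str
    method: str


def _validate_area_table(areas: pd.DataFrame) -> None:
    missing = set(AREA_COLUMNS) - set(areas.columns)
    if missing:
        raise ValueError(f"area table missing columns: {sorted(missing)}")
    if (areas["area"] < 0).any():
        raise ValueError("peak areas must be non-negative")


def normalize_to_is(
    areas: pd.DataFrame, is_name: str = DEFAULT_IS_NAME
) -> AbundanceTable:
    """Fold-over-IS abundances from a long-format peak-area table.

    Per compound and sample the quantifier is the sum of the fragment-ion
    areas (the two most abundant fragments by protocol); dividing by the IS
    area of the same sample cancels run-to-run intensity variation.
    Compounds absent from a sample get abundance 0.

    Raises if the internal standard is missing or non-positive in any sample.
    """
    _validate_area_table(areas)
    totals = (
        areas.groupby(["compound_id", "sample_id"], sort=True)["area"].sum().unstack(
            fill_value=0.0
        )
    )
    if is_name not in totals.index:
        raise ValueError(f"internal standard {is_name!r} not found in area table")
    is_areas = totals.loc[is_name]
    bad = is_areas[is_areas <= 0]
    if not bad.empty:
        raise ValueError(
            f"internal standard area must be positive; offending samples: "
            f"{sorted(bad.index)}"
        )
    folds = totals.drop(index=is_name).div(is_areas, axis=1)
    meta = (
        areas[["sample_id", "stage", "replicate"]]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
        .loc[folds.columns]
    )
    return AbundanceTable(values=folds, sample_meta=meta)


def stage_summary(ab: AbundanceTable) -> StageSummary:
    """Mean, sample SD and percent composition per developmental stage.

    Percent composition is computed from stage means: each compound's share
    of the summed mean abundance at that stage.  A stage where every compound
    is zero yields an all-zero percent column.
    """
    stages = ab.sample_meta["stage"]
    counts = stages.value_counts()
    if (counts < 1).any():  # pragma: no cover - value_counts never yields 0
        raise ValueError("every stage needs at least one replicate")
    grouped = ab.values.T.groupby(stages)
    mean = grouped.mean().T
    sd = grouped.std(ddof=1).fillna(0.0).T
    col_sums = mean.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = mean.div(col_sums, axis=1) * 100.0
    percent = percent.fillna(0.0)
    # Keep a deterministic stage order as encountered in the metadata.
    stage_order = list(dict.fromkeys(stages))
    return StageSummary(
        mean=mean[stage_order],
        sd=sd[stage_order],
        percent=percent[stage_order],
        n_replicates=counts[stage_order],
    )


def _scipy_tree_to_newick(node: hierarchy.ClusterNode, labels: list[str]) -> str:
    """Serialize a scipy cluster tree to Newick with merge-height branch lengths."""

    def recurse(n: hierarchy.ClusterNode, parent_dist: float) -> str:
        length = parent_dist - n.dist
        if n.is_leaf():
            return f"{labels[n.id]}:{length:.10g}"
        left = recurse(n.get_left(), n.dist)
        right = recurse(n.get_right(), n.dist)
        return f"({left},{right}):{length:.10g}"

    return recurse(node, node.dist) + ";"


def hcl_rows(
    ab: AbundanceTable | pd.DataFrame,
    metric: str = "correlation",
    method: str = "average",
) -> HclResult:
    """Row-directed hierarchical clustering of compound profiles.

    Default distance is 1 - Pearson correlation between compound rows with
    average linkage, the common choice for metabolite-profile heatmaps.
    Rows are sorted by compound id before clustering so leaf order is
    deterministic under input permutation.
    """
    values = ab.values if isinstance(ab, AbundanceTable) else ab
    if len(values.index) < 2:
        raise ValueError("row clustering needs at least 2 compounds")
    values = values.sort_index()
    if metric == "correlation":
        constant = values.std(axis=1, ddof=0) == 0
        if constant.any():
            raise ValueError(
                "constant rows have undefined correlation distance "
                f"({sorted(values.index[constant])}); use metric='euclidean'"
            )
    dists = pdist(values.to_numpy(float), metric=metric)
    linkage = hierarchy.linkage(dists, method=method)
    labels = list(values.index)
    order = [labels[i] for i in hierarchy.leaves_list(linkage)]
    tree = hierarchy.to_tree(linkage)
    newick = _scipy_tree_to_newick(tree, labels)
    return HclResult(
        linkage=linkage, row_order=order, newick=newick, metric=metric, method=method
    )
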