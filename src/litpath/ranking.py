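"""Pathway rankings: strata, yearly trajectories, clustering, comparisons.

A pathway's *study count* in a stratum is the number of distinct records
associated with it at the configured levels (default: full associations
only).  Rank 1 is the most-studied pathway; ties receive average ranks so
that Spearman comparisons between strata are well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .config import DEFAULT_CONFIG, PipelineConfig


def _parse_stratum(stratum) -> tuple[str, float | int | None]:
    if isinstance(stratum, tuple):
        return stratum
    s = str(stratum)
    if s in ("all", "ad"):
        return (s, None)
    if ":" in s:
        kind, value = s.split(":", 1)
        if kind == "impact":
            return ("impact", float(value))
        if kind == "year":
            return ("year", int(value))
    raise ValueError(f"unrecognized stratum {stratum!r}")


def _filter_stratum(
    associations: pd.DataFrame, stratum, config: PipelineConfig
) -> pd.DataFrame:
    df = associations[associations["level"].isin(config.count_levels)]
    kind, value = _parse_stratum(stratum)
    if kind == "all":
        return df
    if kind == "ad":
        return df[df["dementia_label"] == "AD"]
    if kind == "impact":
        return df[df["impact"].notna() & (df["impact"] > value)]
    if kind == "year":
        return df[df["year"] == value]
    raise ValueError(f"unrecognized stratum {stratum!r}")


def rank_pathways(
    associations: pd.DataFrame,
    stratum="all",
    config: PipelineConfig = DEFAULT_CONFIG,
    pathways=None,
) -> pd.DataFrame:
    """Rank pathways by study count within a stratum.

    ``stratum`` is ``"all"``, ``"ad"`` (records whose dementia label is AD),
    ``"impact:τ"`` (records from journals with impact > τ; impact-less
    records are excluded), or ``"year:y"``.  ``pathways`` optionally fixes
    the pathway universe so that zero-count pathways appear in the table;
    by default the universe is every pathway with a qualifying association
    anywhere in the (unstratified) table.

    Returns a DataFrame with columns pathway_id / study_count / rank and the
    stratum recorded in ``.attrs``.
    """
    df = _filter_stratum(associations, stratum, config)
    if pathways is None:
        base = associations[associations["level"].isin(config.count_levels)]
        pathways = sorted(base["pathway_id"].unique())
    counts = (
        df.groupby("pathway_id")["record_id"].nunique().reindex(pathways).fillna(0)
    )
    if df.empty:
        warnings.warn(f"stratum {stratum!r} is empty")
    table = pd.DataFrame(
        {
            "pathway_id": counts.index,
            "study_count": counts.astype(int).values,
        }
    )
    table["rank"] = (
        table["study_count"].rank(ascending=False, method="average").values
    )
    table = table.sort_values("rank", kind="mergesort").reset_index(drop=True)
    table.attrs["stratum"] = str(stratum)
    table.attrs["count_levels"] = tuple(config.count_levels)
    return table


@dataclass
class SpecificityResult:
    pathway_id: str
    pct_ad: float
    breakdown: dict[str, int]  # dementia label -> distinct record count
    n_records: int


def specificity_percentage(
    associations: pd.DataFrame,
    pathway_id: str,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> SpecificityResult:
    """Percentage of a pathway's associated records carrying the AD label,
    with the full four-class breakdown."""
    df = associations[
        (associations["pathway_id"] == pathway_id)
        & associations["level"].isin(config.count_levels)
    ]
    per_record = df.drop_duplicates("record_id")
    n = len(per_record)
    if n == 0:
        raise ValueError(f"pathway {pathway_id!r} has no associated records")
    breakdown = {
        label: int((per_record["dementia_label"] == label).sum())
        for label in ("AD", "dementia", "related", "unrelated")
    }
    return SpecificityResult(pathway_id, 100.0 * breakdown["AD"] / n, breakdown, n)


def mean_ad_word_scores(associations: pd.DataFrame) -> pd.Series:
    """Mean AD word score (AD-specific term hits per record) per pathway."""
    per = associations.drop_duplicates(["record_id", "pathway_id"])
    return per.groupby("pathway_id")["ad_word_score"].mean()


# ---------------------------------------------------------------------------
# Yearly ranks
# ---------------------------------------------------------------------------

@dataclass
class YearlyRankMatrix:
    """Pathways × years matrix of yearly ranks with an inclusion mask.

    ``ranks`` and ``counts`` cover every pathway; ``included`` marks
    pathways that meet the yearly-volume criterion.  ``masked_ranks``
    restricts the matrix to included pathways.
    """

    ranks: pd.DataFrame
    counts: pd.DataFrame
    included: pd.Series  # bool per pathway

    @property
    def masked_ranks(self) -> pd.DataFrame:
        return self.ranks.loc[self.included]

    def to_tsv(self, path) -> None:
        self.ranks.to_csv(path, sep="\t")


def yearly_rank_matrix(
    associations: pd.DataFrame,
    min_per_year: int | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
    start_year: int = 1990,
) -> YearlyRankMatrix:
    """Per-year pathway ranks from ``start_year`` onward.

    Each year is ranked independently over the full pathway set.  Under the
    default rule a pathway is masked out of the matrix when its count stays
    below ``min_per_year`` in every year (it remains in full rank tables);
    the ``"mean"`` rule masks on the mean yearly count instead.
    """
    if min_per_year is None:
        min_per_year = config.min_per_year
    df = associations[
        associations["level"].isin(config.count_levels)
        & associations["year"].notna()
        & (associations["year"] >= start_year)
    ]
    years = sorted(df["year"].unique())
    pathways = sorted(
        associations[associations["level"].isin(config.count_levels)][
            "pathway_id"
        ].unique()
    )
    counts = (
        df.drop_duplicates(["record_id", "pathway_id"])
        .groupby(["pathway_id", "year"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=pathways, columns=years, fill_value=0)
    )
    ranks = counts.rank(ascending=False, method="average", axis=0)
    if config.yearly_rule == "mean":
        included = counts.mean(axis=1) >= min_per_year
    else:  # "every_year": masked iff below the threshold in every year
        included = (counts >= min_per_year).any(axis=1)
    return YearlyRankMatrix(ranks=ranks, counts=counts, included=included)


@dataclass
class ClusterResult:
    pathway_ids: list[str]
    linkage: np.ndarray
    labels: dict[str, int]
    distance: str
    linkage_method: str

    def to_flat_tsv(self, path) -> None:
        pd.DataFrame(
            {"pathway_id": self.pathway_ids, "cluster": [self.labels[p] for p in self.pathway_ids]}
        ).to_csv(path, sep="\t", index=False)


def cluster_yearly(
    matrix: YearlyRankMatrix,
    n_clusters: int = 2,
    distance: str = "spearman",
    linkage_method: str = "average",
) -> ClusterResult:
    """Hierarchically cluster yearly rank trajectories.

    Distance between two included pathways is 1 − Spearman correlation of
    their rank trajectories (``distance="euclidean"`` is also accepted);
    linkage defaults to average.  Deterministic for a given matrix.
    """
    rows = matrix.masked_ranks
    if len(rows) < 2:
        raise ValueError("clustering needs at least two included pathways")
    if rows.isna().any().any():
        raise ValueError("rank matrix contains missing values")
    if distance == "spearman":
        corr = rows.T.corr(method="spearman")
        dmat = (1.0 - corr).to_numpy()
        np.fill_diagonal(dmat, 0.0)
        dmat = np.clip((dmat + dmat.T) / 2.0, 0.0, None)
        condensed = squareform(dmat, checks=False)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist

        condensed = pdist(rows.to_numpy())
    else:
        raise ValueError(f"unknown distance {distance!r}")
    Z = hierarchy.linkage(condensed, method=linkage_method)
    flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    ids = list(rows.index)
    return ClusterResult(
        pathway_ids=ids,
        linkage=Z,
        labels=dict(zip(ids, (int(x) for x in flat))),
        distance=distance,
        linkage_method=linkage_method,
    )


# ---------------------------------------------------------------------------
# Rank comparisons
# ---------------------------------------------------------------------------

@dataclass
class SpearmanResult:
    rho: float
    p: float
    n_shared: int


def compare_ranks(rank_a: pd.DataFrame, rank_b: pd.DataFrame) -> SpearmanResult:
    """Tie-corrected Spearman rank-order correlation over shared pathways."""
    merged = rank_a.merge(rank_b, on="pathway_id", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError("need at least three shared pathways")
    rho, p = stats.spearmanr(merged["rank_a"], merged["rank_b"])
    return SpearmanResult(float(rho), float(p), len(merged))


def rank_change_report(
    rank_a: pd.DataFrame,
    rank_b: pd.DataFrame,
    top_n: int,
    min_change: float = 0.0,
) -> pd.DataFrame:
    """Pathways within the top ``top_n`` of ``rank_a`` with the largest
    absolute rank change versus ``rank_b``; ties broken alphabetically."""
    merged = rank_a.merge(rank_b, on="pathway_id", suffixes=("_a", "_b"))
    missing = set(rank_a["pathway_id"]) - set(rank_b["pathway_id"])
    if missing:
        raise ValueError(f"rank_b does not cover: {sorted(missing)}")
    top = merged[merged["rank_a"] <= top_n].copy()
    top["change"] = (top["rank_a"] - top["rank_b"]).abs()
    top = top[top["change"] > min_change]
    top = top.sort_values(
        ["change", "pathway_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return top[["pathway_id", "rank_a", "rank_b", "change"]]
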