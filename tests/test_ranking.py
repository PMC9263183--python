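import numpy as np
import pandas as pd
import pytest
from scipy import stats

from litpath import (
    cluster_yearly,
    compare_ranks,
    rank_change_report,
    rank_pathways,
    specificity_percentage,
    yearly_rank_matrix,
)
from litpath.config import DEFAULT_CONFIG
from litpath.ranking import YearlyRankMatrix


def assoc_frame(rows):
    """rows: (record_id, pathway_id, level, dementia_label, year, impact)"""
    return pd.DataFrame(
        rows,
        columns=["record_id", "pathway_id", "level", "dementia_label", "year",
                 "impact"],
    ).assign(ad_word_score=0, journal="J")


def counts_frame(counts, **extra):
    rows = []
    i = 0
    for pid, n in counts.items():
        for _ in range(n):
            rows.append((f"r{i}", pid, "full", extra.get("label", "AD"), 2000, None))
            i += 1
    return assoc_frame(rows)


def test_tie_averaging_and_rank_sum():
    table = rank_pathways(counts_frame({"A": 10, "B": 5, "C": 5}))
    got = dict(zip(table.pathway_id, table["rank"]))
    assert got == {"A": 1.0, "B": 2.5, "C": 2.5}
    n = len(table)
    assert table["rank"].sum() == pytest.approx(n * (n + 1) / 2)


def test_single_pathway_rank_one():
    table = rank_pathways(counts_frame({"solo": 4}))
    assert list(table["rank"]) == [1.0]


def test_empty_stratum_warns():
    df = counts_frame({"A": 3})
    with pytest.warns(UserWarning, match="empty"):
        table = rank_pathways(df, ("year", 1955))
    assert (table["study_count"] == 0).all()


def test_partial_associations_respect_count_levels():
    df = assoc_frame([
        ("r0", "A", "full", "AD", 2000, None),
        ("r1", "A", "partial", "AD", 2000, None),
        ("r2", "B", "full", "AD", 2000, None),
    ])
    full_only = rank_pathways(df)
    assert dict(zip(full_only.pathway_id, full_only.study_count)) == {"A": 1, "B": 1}
    both = rank_pathways(df, config=DEFAULT_CONFIG.with_(count_levels=("full", "partial")))
    assert dict(zip(both.pathway_id, both.study_count)) == {"A": 2, "B": 1}


def test_specificity_percentage_breakdown():
    rows = [(f"r{i}", "P", "full", "AD", 2000, None) for i in range(19)]
    rows.append(("r19", "P", "full", "related", 2000, None))
    result = specificity_percentage(assoc_frame(rows), "P")
    assert result.pct_ad == pytest.approx(95.0)
    assert result.breakdown == {"AD": 19, "dementia": 0, "related": 1, "unrelated": 0}
    with pytest.raises(ValueError):
        specificity_percentage(assoc_frame(rows), "missing")


def test_yearly_matrix_masks_low_volume_and_shows_crossover():
    rows = []
    i = 0
    # pathway "hi": 30/year, "lo": 25 then 20 after 2000, "rare": 5/year
    for year in (1999, 2000):
        for pid, n in (("hi", 30 if year == 1999 else 10),
                       ("lo", 25), ("rare", 5)):
            for _ in range(n):
                rows.append((f"r{i}", pid, "full", "AD", year, None))
                i += 1
    matrix = yearly_rank_matrix(assoc_frame(rows), min_per_year=20)
    assert bool(matrix.included["rare"]) is False
    assert bool(matrix.included["hi"]) is True
    # ranks cross in 2000
    assert matrix.ranks.loc["hi", 1999] < matrix.ranks.loc["lo", 1999]
    assert matrix.ranks.loc["hi", 2000] > matrix.ranks.loc["lo", 2000]


def _naive_average_linkage(dmat, ids):
    """O(n³) agglomerative average-linkage oracle; returns merge heights."""
    clusters = {i: [i] for i in range(len(ids))}
    d = {(i, j): dmat[i, j] for i in range(len(ids)) for j in range(len(ids)) if i < j}
    heights = []
    next_id = len(ids)
    while len(clusters) > 1:
        (a, b), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        merged = clusters[a] + clusters[b]
        del clusters[a], clusters[b]
        d = {k: v for k, v in d.items() if a not in k and b not in k}
        for c in clusters:
            pts = clusters[c]
            val = np.mean([dmat[x, y] for x in merged for y in pts])
            d[(min(c, next_id), max(c, next_id))] = val
        clusters[next_id] = merged
        next_id += 1
    return heights


def test_cluster_yearly_matches_naive_agglomeration_oracle():
    rng = np.random.default_rng(5)
    years = list(range(1990, 2010))
    base = np.vstack([
        np.linspace(1, 6, len(years)),
        np.linspace(1.2, 6.2, len(years)),
        np.linspace(6, 1, len(years)),
        np.linspace(6.4, 0.8, len(years)),
        np.full(len(years), 3.0) + rng.normal(0, 0.1, len(years)),
        rng.permutation(len(years)).astype(float),
    ])
    ranks = pd.DataFrame(base, index=[f"p{i}" for i in range(6)], columns=years)
    counts = pd.DataFrame(100, index=ranks.index, columns=years)
    matrix = YearlyRankMatrix(ranks=ranks, counts=counts,
                              included=pd.Series(True, index=ranks.index))
    result = cluster_yearly(matrix, n_clusters=3)

    corr = ranks.T.corr(method="spearman").to_numpy()
    dmat = 1.0 - corr
    np.fill_diagonal(dmat, 0.0)
    oracle_heights = _naive_average_linkage(dmat, list(ranks.index))
    assert np.allclose(sorted(result.linkage[:, 2]), sorted(oracle_heights),
                       atol=1e-12)
    # identical trajectories ~ merged first; opposite ones far apart
    labels = result.labels
    assert labels["p0"] == labels["p1"]
    assert labels["p2"] == labels["p3"]
    assert labels["p0"] != labels["p2"]


def test_cluster_requires_two_pathways():
    ranks = pd.DataFrame([[1.0, 1.0]], index=["only"], columns=[1990, 1991])
    matrix = YearlyRankMatrix(ranks=ranks, counts=ranks,
                              included=pd.Series([True], index=["only"]))
    with pytest.raises(ValueError):
        cluster_yearly(matrix)


def rank_table(ranks):
    return pd.DataFrame(
        {"pathway_id": list(ranks), "study_count": 0, "rank": list(ranks.values())}
    )


def test_compare_ranks_hand_cases():
    a = rank_table({"p1": 1, "p2": 2, "p3": 3, "p4": 4, "p5": 5})
    assert compare_ranks(a, a).rho == pytest.approx(1.0)
    rev = rank_table({"p1": 5, "p2": 4, "p3": 3, "p4": 2, "p5": 1})
    assert compare_ranks(a, rev).rho == pytest.approx(-1.0)
    b = rank_table({"p1": 1, "p2": 3, "p3": 2, "p4": 5, "p5": 4})
    # 1 - 6*4/(5*24) = 0.8
    assert compare_ranks(a, b).rho == pytest.approx(0.8)
    with pytest.raises(ValueError):
        compare_ranks(rank_table({"p1": 1, "p2": 2}), rank_table({"p1": 1, "p2": 2}))


def test_rank_change_report_orders_by_change_then_name():
    a = rank_table({f"p{i:02d}": i for i in range(1, 31)})
    b_ranks = {f"p{i:02d}": i for i in range(1, 31)}
    b_ranks["p19"] = 66  # the headline mover
    b_ranks["p05"] = 10  # change 5
    b_ranks["p07"] = 12  # change 5 (tie, later alphabetically)
    b = rank_table(b_ranks)
    report = rank_change_report(a, b, top_n=30)
    assert list(report["pathway_id"][:3]) == ["p19", "p05", "p07"]
    assert report["change"].iloc[0] == pytest.approx(47.0)
    empty = rank_change_report(a, a, top_n=30)
    assert empty.empty


def test_split_half_rank_stability(medium_corpus, lexicons):
    """Two disjoint halves of a planted corpus agree on the pathway order."""
    _, _, result = medium_corpus
    assoc = result.associations
    records = sorted(result.records.record_id)
    half = set(records[::2])
    a = rank_pathways(assoc[assoc.record_id.isin(half)])
    b = rank_pathways(assoc[~assoc.record_id.isin(half)])
    assert compare_ranks(a, b).rho >= 0.9


def test_impact_stratification_preserves_order(medium_corpus):
    """Planted mention rates are impact-independent, so impact-stratified
    ranks should agree with the unstratified table."""
    _, _, result = medium_corpus
    all_ranks = rank_pathways(result.associations)
    impact5 = rank_pathways(result.associations, "impact:5")
    assert compare_ranks(all_ranks, impact5).rho >= 0.9
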