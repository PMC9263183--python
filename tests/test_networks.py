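import math

import numpy as np
import pandas as pd
import pytest

from litpath import (
    GeneSetCollection,
    bh_fdr,
    coexpression_network,
    enriched_vs_rank_test,
    fisher_overlap,
    gene_list_enrichment,
    overlap_network,
    pathway_summary,
    pcxn_edge,
)
from litpath.synth import GeneSetConfig, gen_expression, gen_gene_sets


def hypergeom_tail_oracle(k, n_a, n_b, n):
    """Exact enrichment tail P(overlap >= k) by integer-comb summation."""
    total = 0
    denom = math.comb(n, n_b)
    for j in range(k, min(n_a, n_b) + 1):
        if n_b - j > n - n_a:
            continue
        total += math.comb(n_a, j) * math.comb(n - n_a, n_b - j)
    return total / denom


def test_fisher_overlap_exact_small_case():
    universe = [f"g{i}" for i in range(20)]
    a = set(universe[:5])
    res = fisher_overlap(a, a, universe)
    assert res.overlap_size == 5
    assert res.p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)


def test_fisher_depletion_is_not_enrichment():
    universe = [f"g{i}" for i in range(40)]
    a, b = set(universe[:15]), set(universe[15:30])
    res = fisher_overlap(a, b, universe)
    assert res.overlap_size == 0
    assert res.p >= 0.5


def test_fisher_matches_comb_oracle_on_moderate_grid():
    universe_pool = [f"g{i}" for i in range(15)]
    for n in range(2, 16):
        universe = universe_pool[:n]
        for n_a in range(1, n + 1):
            for n_b in range(1, n + 1):
                k_min = max(0, n_a + n_b - n)
                a = set(universe[:n_a])
                for k in range(k_min, min(n_a, n_b) + 1):
                    b = set(universe[n_a - k:n_a]) | set(
                        universe[n_a:n_a + n_b - k])
                    res = fisher_overlap(a, b, universe)
                    assert res.overlap_size == k
                    assert res.p == pytest.approx(
                        hypergeom_tail_oracle(k, n_a, n_b, n), abs=1e-12)


def test_fisher_symmetry_and_errors():
    universe = [f"g{i}" for i in range(30)]
    a, b = set(universe[:12]), set(universe[6:20])
    ab = fisher_overlap(a, b, universe)
    ba = fisher_overlap(b, a, universe)
    assert ab.p == pytest.approx(ba.p) and ab.overlap_size == ba.overlap_size
    with pytest.raises(ValueError):
        fisher_overlap(a, b, [])
    with pytest.raises(ValueError):
        fisher_overlap({"not-there"}, b, universe)


def naive_bh(p):
    """O(m²) step-up oracle straight from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        candidates = [
            min(1.0, m * p[j] / ranks[j]) for j in range(m) if p[j] >= p[i]
        ]
        q[i] = min(candidates)
    return q


def test_bh_hand_case_and_single():
    assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert bh_fdr([0.37]) == pytest.approx([0.37])
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_fdr([-0.1])


def test_bh_equals_naive_oracle_exactly():
    rng = np.random.default_rng(3)
    for _ in range(60):
        m = int(rng.integers(1, 120))
        p = rng.random(m)
        if rng.random() < 0.3:  # inject ties
            p = np.round(p, 2)
        assert np.array_equal(bh_fdr(p), naive_bh(p))


def test_bh_cross_checks_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(4)
    p = rng.random(200)
    assert np.allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1],
                       atol=1e-12)


def _rank_table(ids):
    return pd.DataFrame({
        "pathway_id": ids,
        "study_count": list(range(len(ids), 0, -1)),
        "rank": [float(i + 1) for i in range(len(ids))],
    })


def test_overlap_network_identical_vs_disjoint_sets():
    universe = [f"g{i}" for i in range(100)]
    sets = {
        "twin1": universe[:20],
        "twin2": universe[:20],
        "loner": universe[40:60],
    }
    gene_sets = GeneSetCollection(sets, universe=universe)
    net = overlap_network(gene_sets, _rank_table(["twin1", "twin2", "loner"]),
                          top_k=3)
    assert len(net.edges) == 1
    assert {net.edges.iloc[0]["a"], net.edges.iloc[0]["b"]} == {"twin1", "twin2"}
    assert net.edges.iloc[0]["weight"] == pytest.approx(
        -math.log10(net.edges.iloc[0]["q"]))
    # no self edges, symmetric by construction (a < b once per pair)
    assert (net.edges["a"] != net.edges["b"]).all()


def test_overlap_network_disjoint_sets_have_no_edges():
    universe = [f"g{i}" for i in range(90)]
    sets = {f"p{i}": universe[30 * i:30 * (i + 1)] for i in range(3)}
    net = overlap_network(GeneSetCollection(sets, universe=universe),
                          _rank_table(sorted(sets)), top_k=3)
    assert net.edges.empty


def test_overlap_network_warns_when_topk_exceeds_available():
    universe = [f"g{i}" for i in range(40)]
    sets = {"a": universe[:15], "b": universe[10:25]}
    with pytest.warns(UserWarning, match="top_k"):
        net = overlap_network(GeneSetCollection(sets, universe=universe),
                              _rank_table(["a", "b"]), top_k=30)
    assert len(net.nodes) == 2


def test_gene_list_enrichment_self_and_planted():
    gene_sets, _ = gen_gene_sets(GeneSetConfig(n_pathways=6, universe_size=500,
                                               size_range=(20, 30)), seed=2)
    target = sorted(gene_sets["P002"])
    result = gene_list_enrichment(target, gene_sets)
    assert result.iloc[0]["pathway_id"] == "P002"

    rng = np.random.default_rng(0)
    outside = sorted(gene_sets.universe - gene_sets["P002"])
    planted = target[:16] + [outside[i] for i in rng.choice(len(outside), 4,
                                                            replace=False)]
    assert gene_list_enrichment(planted, gene_sets).iloc[0]["pathway_id"] == "P002"

    with pytest.warns(UserWarning, match="outside"):
        res = gene_list_enrichment(target + ["NOT_A_GENE"], gene_sets)
    assert res.iloc[0]["pathway_id"] == "P002"
    with pytest.raises(ValueError):
        gene_list_enrichment(["NOT_A_GENE"], gene_sets)


def test_enriched_vs_rank_exact_small_case():
    enrichment = pd.DataFrame({
        "pathway_id": [f"p{i}" for i in range(6)],
        "q": [0.01, 0.01, 0.01, 0.5, 0.5, 0.5],
    })
    ranks = _rank_table([f"p{i}" for i in range(6)])
    res = enriched_vs_rank_test(enrichment, ranks)
    assert res.method == "exact"
    assert res.p == pytest.approx(0.1)  # 2 / C(6,3) extremes


def test_enriched_vs_rank_null_and_errors():
    enrichment = pd.DataFrame({
        "pathway_id": [f"p{i}" for i in range(8)],
        "q": [0.01, 0.5] * 4,
    })
    ranks = _rank_table([f"p{i}" for i in range(8)])
    # enriched ranks 1,3,5,7 vs 2,4,6,8: nearly identical distributions
    assert enriched_vs_rank_test(enrichment, ranks).p > 0.5
    with pytest.raises(ValueError):
        enriched_vs_rank_test(enrichment.assign(q=1.0), ranks)


def test_pathway_summary_centering_and_duplicates():
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(rng.normal(size=(5, 12)),
                        index=[f"g{i}" for i in range(5)],
                        columns=[f"s{i}" for i in range(12)])
    expr.loc["g1"] = expr.loc["g0"]  # duplicate expression profile
    summary = pathway_summary(expr, ["g0", "g1"])
    z0 = (expr.loc["g0"] - expr.loc["g0"].mean()) / expr.loc["g0"].std(ddof=1)
    assert np.allclose(summary, z0)

    # direct-formula oracle on a random pathway
    genes = ["g0", "g2", "g4"]
    z = expr.loc[genes].sub(expr.loc[genes].mean(axis=1), axis=0).div(
        expr.loc[genes].std(axis=1, ddof=1), axis=0)
    assert np.allclose(pathway_summary(expr, genes), z.mean(axis=0))

    with pytest.raises(ValueError):
        pathway_summary(expr, ["g0"])


def test_pcxn_edge_cross_checks_pingouin():
    import pingouin as pg

    rng = np.random.default_rng(8)
    n = 80
    genes = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)] + \
            [f"c{i}" for i in range(4)]
    expr = pd.DataFrame(rng.normal(size=(len(genes), n)), index=genes)
    set_a = {f"a{i}" for i in range(6)} | {f"c{i}" for i in range(4)}
    set_b = {f"b{i}" for i in range(6)} | {f"c{i}" for i in range(4)}
    edge = pcxn_edge(expr, set_a, set_b)
    assert edge.conditioned

    df = pd.DataFrame({
        "x": pathway_summary(expr, set_a - set_b),
        "y": pathway_summary(expr, set_b - set_a),
        "z": pathway_summary(expr, set_a & set_b),
    })
    ref = pg.partial_corr(data=df, x="x", y="y", covar="z")
    assert edge.partial_corr == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    assert edge.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)


def test_pcxn_edge_disjoint_uses_pearson_and_symmetry():
    rng = np.random.default_rng(9)
    genes = [f"g{i}" for i in range(12)]
    expr = pd.DataFrame(rng.normal(size=(12, 50)), index=genes)
    a, b = set(genes[:6]), set(genes[6:])
    edge = pcxn_edge(expr, a, b)
    assert not edge.conditioned
    flipped = pcxn_edge(expr, b, a)
    assert edge.partial_corr == pytest.approx(flipped.partial_corr)
    assert edge.p == pytest.approx(flipped.p)


def test_pcxn_edge_error_when_disjoint_part_too_small():
    rng = np.random.default_rng(10)
    genes = [f"g{i}" for i in range(10)]
    expr = pd.DataFrame(rng.normal(size=(10, 30)), index=genes)
    a = set(genes)
    b = set(genes[1:])  # A \ B has a single gene
    with pytest.raises(ValueError, match="disjoint"):
        pcxn_edge(expr, a, b)


def test_pcxn_recovers_planted_latent_correlation():
    """Disjoint pathways driven by correlated latents: the edge estimate
    averages close to the planted r=0.7 over replicates."""
    config = GeneSetConfig(n_pathways=2, universe_size=200, size_range=(20, 20),
                           blocks=({"n_members": 2, "size": 20, "overlap": 0.0,
                                    "disjoint": True},))
    estimates = []
    for rep in range(20):
        gene_sets, _ = gen_gene_sets(config, seed=100 + rep)
        corr = pd.DataFrame([[1.0, 0.7], [0.7, 1.0]],
                            index=["P000", "P001"], columns=["P000", "P001"])
        expr, _ = gen_expression(gene_sets, corr, noise_sd=0.5, n_samples=200,
                                 seed=200 + rep)
        estimates.append(
            pcxn_edge(expr, gene_sets["P000"], gene_sets["P001"]).partial_corr)
    # attenuation from gene-level noise: expected r ~ 0.7 / (1 + sd²/m)
    expected = 0.7 / (1 + 0.25 / 20)
    assert np.mean(estimates) == pytest.approx(expected, abs=0.05)


def test_pcxn_corrects_overlap_only_correlation():
    """Two pathways whose summaries correlate only because they share genes
    (the shared genes' measurements enter both summaries): the corrected
    statistic collapses toward zero while the raw summary correlation
    stays clearly positive."""
    from scipy.stats import pearsonr

    m, n = 10, 400
    a_only = {f"a{i}" for i in range(m)}
    b_only = {f"b{i}" for i in range(m)}
    shared = {f"c{i}" for i in range(m)}
    all_genes = sorted(a_only | b_only | shared)
    set_a, set_b = a_only | shared, b_only | shared
    raw, corrected = [], []
    for seed in range(25):
        rng = np.random.default_rng(seed)
        expr = pd.DataFrame(rng.normal(size=(len(all_genes), n)),
                            index=all_genes)
        raw.append(pearsonr(pathway_summary(expr, set_a),
                            pathway_summary(expr, set_b))[0])
        corrected.append(pcxn_edge(expr, set_a, set_b).partial_corr)
    assert np.mean(raw) > 0.2
    assert abs(np.mean(corrected)) < abs(np.mean(raw))
    assert abs(np.mean(corrected)) < 0.05


def test_coexpression_network_null_edge_rate_matches_nominal_level():
    """Independent latents: the fraction of significant edges over many
    replicates stays near the nominal 5% level."""
    config = GeneSetConfig(n_pathways=2, universe_size=300, size_range=(15, 15),
                           blocks=({"n_members": 2, "size": 15, "overlap": 0.0,
                                    "disjoint": True},))
    n_sig = 0
    reps = 100
    for rep in range(reps):
        gene_sets, _ = gen_gene_sets(config, seed=1000 + rep)
        pids = sorted(gene_sets.sets)
        corr = pd.DataFrame(np.eye(2), index=pids, columns=pids)
        expr, _ = gen_expression(gene_sets, corr, noise_sd=1.0, n_samples=60,
                                 seed=2000 + rep)
        net = coexpression_network(expr, gene_sets, _rank_table(pids), top_k=2)
        n_sig += len(net.edges)
        if rep == 0:
            assert list(net.nodes["pathway_id"]) == pids
    # nominal 0.05 with MC sd ~0.022 over 100 reps
    assert n_sig / reps < 0.12
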