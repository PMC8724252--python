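"""Sampling-based enrichment, term clustering, and per-variant weights."""

import numpy as np
import pandas as pd
import pytest

from adlongevity import synthetic_data as synth
from adlongevity.annotation import (
    celltype_weights,
    cluster_terms,
    enrich,
    group_enrichment_tests,
    impute_mapping,
    sample_gene_lists,
    variant_pathway_mapping,
)
from adlongevity.stats_core import ValidationError, hypergeom_tail


def _vg(mapping):
    rows = [
        {"variant": v, "gene": g, "evidence": "coding"}
        for v, genes in mapping.items()
        for g in genes
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene-list sampling


def test_single_gene_variants_give_identical_lists():
    vg = _vg({"a": ["g1"], "b": ["g2"]})
    lists = sample_gene_lists(vg, iterations=5, seed=0)
    assert all(lst == ["g1", "g2"] for lst in lists)


def test_two_gene_variant_splits_evenly():
    vg = _vg({"a": ["g1", "g2"]})
    lists = sample_gene_lists(vg, iterations=10_000, seed=1)
    frac = np.mean([lst == ["g1"] for lst in lists])
    assert frac == pytest.approx(0.5, abs=0.02)


def test_sampling_reproducible_and_warns_on_empty():
    vg = _vg({"a": ["g1", "g2"], "b": ["g3"]})
    assert sample_gene_lists(vg, 3, seed=2) == sample_gene_lists(vg, 3, seed=2)
    with pytest.raises(ValidationError):
        sample_gene_lists(vg, 0)


# ---------------------------------------------------------------------------
# enrichment


def test_planted_term_dominates():
    genes = [f"g{i}" for i in range(5)]
    bg = {f"g{i}" for i in range(100)}
    gmt = {"planted": genes, "other": [f"g{i}" for i in range(90, 95)]}
    lists = [genes] * 20
    res = {r.term: r for r in enrich(lists, gmt, background=bg)}
    assert res["planted"].combined_p < 1e-6 and res["planted"].enriched
    assert not res["other"].enriched


def test_single_iteration_equals_plain_hypergeometric():
    gmt = {"t": ["g1", "g2", "g3"]}
    bg = {f"g{i}" for i in range(1, 21)}
    lst = ["g1", "g2", "g5", "g6"]
    res = enrich([lst], gmt, background=bg)
    assert res[0].combined_p == pytest.approx(hypergeom_tail(2, 4, 3, 20), rel=1e-9)


def test_enrichment_order_invariance():
    gmt = {"t1": ["g1", "g2"], "t2": ["g3", "g4"]}
    bg = {f"g{i}" for i in range(1, 11)}
    lists = [["g1", "g3"], ["g2", "g4"]]
    a = enrich(lists, gmt, background=bg)
    b = enrich([sorted(l, reverse=True) for l in lists[::-1]],
               dict(reversed(list(gmt.items()))), background=bg)
    pa = {r.term: r.combined_p for r in a}
    pb = {r.term: r.combined_p for r in b}
    assert pa == pytest.approx(pb)


# ---------------------------------------------------------------------------
# clustering


def test_planted_blocks_are_recovered(annotation_resources):
    res = annotation_resources
    terms = list(res.similarity.index)
    found = cluster_terms(res.similarity, terms, k=4)
    planted = res.term_clusters_true
    # same partition up to label names
    pairs = {(found[t], planted[t]) for t in terms}
    assert len(pairs) == 4


def test_cluster_k1_and_validation(annotation_resources):
    sim = annotation_resources.similarity
    terms = list(sim.index)[:6]
    assert set(cluster_terms(sim, terms, k=1).values()) == {0}
    with pytest.raises(ValidationError):
        cluster_terms(sim, terms[:2], k=5)


def test_cluster_permutation_invariance(annotation_resources, rng):
    sim = annotation_resources.similarity
    terms = list(sim.index)
    base = cluster_terms(sim, terms, k=4)
    for _ in range(10):
        perm = list(rng.permutation(terms))
        again = cluster_terms(sim, perm, k=4)
        assert again == base


# ---------------------------------------------------------------------------
# variant-pathway mapping


def test_mapping_single_cluster_gene():
    vg = _vg({"v": ["g1"]})
    gmt = {"t1": ["g1"], "t2": ["g9"]}
    clusters = {"t1": 0, "t2": 1}
    m = variant_pathway_mapping(vg, gmt, clusters, ["t1", "t2"])
    np.testing.assert_allclose(m.weights.loc["v"], [1.0, 0.0])


def test_mapping_two_clusters_split():
    vg = _vg({"v": ["g1"]})
    gmt = {"t1": ["g1"], "t2": ["g1"], "t3": ["g7"], "t4": ["g8"]}
    clusters = {"t1": 0, "t2": 1, "t3": 2, "t4": 3}
    m = variant_pathway_mapping(vg, gmt, clusters, list(clusters))
    np.testing.assert_allclose(m.weights.loc["v"], [0.5, 0.5, 0.0, 0.0])


def test_unannotatable_variants_are_flagged(annotation_resources):
    res = annotation_resources
    enriched = [t for t, c in res.term_clusters_true.items()]
    clusters = res.term_clusters_true
    m = variant_pathway_mapping(res.variant_gene, res.gmt, clusters, enriched)
    unannotated = set(m.weights.index[~m.annotated])
    assert unannotated == set(res.unannotatable)
    # annotated rows sum to one
    sums = m.weights.loc[m.annotated].sum(axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)


def test_imputation_mean_row_and_noop():
    vg = _vg({"a": ["g1"], "b": ["g2"], "c": ["g9"]})
    gmt = {"t1": ["g1"], "t2": ["g2"]}
    clusters = {"t1": 0, "t2": 1}
    m = variant_pathway_mapping(vg, gmt, clusters, ["t1", "t2"])
    filled = impute_mapping(m)
    np.testing.assert_allclose(filled.weights.loc["c"], [0.5, 0.5])
    assert filled.imputed.loc["c"] and not filled.imputed.loc["a"]
    np.testing.assert_allclose(filled.weights.sum(axis=1), 1.0, atol=1e-9)
    # all-annotated mapping is returned unchanged
    m2 = variant_pathway_mapping(_vg({"a": ["g1"]}), gmt, clusters, ["t1"])
    pd.testing.assert_frame_equal(impute_mapping(m2).weights, m2.weights)


def test_imputation_requires_an_annotated_variant():
    vg = _vg({"c": ["g9"]})
    gmt = {"t1": ["g1"]}
    m = variant_pathway_mapping(vg, gmt, {"t1": 0}, ["t1"])
    with pytest.raises(ValidationError):
        impute_mapping(m)


def test_removing_the_only_gene_moves_variant_to_unannotated():
    gmt = {"t1": ["g1"]}
    m = variant_pathway_mapping(_vg({"a": ["g1"], "b": ["g2"]}), gmt,
                                {"t1": 0}, ["t1"])
    assert not m.annotated.loc["b"] and m.annotated.loc["a"]


# ---------------------------------------------------------------------------
# cell-type weights


def test_celltype_single_gene_one_hot():
    expr = pd.DataFrame(
        [[0, 0, 5.0, 0, 0]], index=["g1"],
        columns=["astro", "oligo", "microglia", "endo", "neuron"],
    )
    w = celltype_weights(_vg({"v": ["g1"]}), expr)
    np.testing.assert_allclose(w.loc["v"], [0, 0, 1.0, 0, 0])


def test_celltype_uniform_genes_and_scale_invariance():
    cols = list("abcde")
    expr = pd.DataFrame([[1.0] * 5, [2.0] * 5], index=["g1", "g2"], columns=cols)
    w = celltype_weights(_vg({"v": ["g1", "g2"]}), expr)
    np.testing.assert_allclose(w.loc["v"], [0.2] * 5)
    w10 = celltype_weights(_vg({"v": ["g1", "g2"]}), expr * 10)
    pd.testing.assert_frame_equal(w, w10)


def test_celltype_skips_unknown_and_zero_genes():
    cols = list("abcde")
    expr = pd.DataFrame([[1, 0, 0, 0, 0], [0] * 5], index=["g1", "g2"],
                        columns=cols, dtype=float)
    with pytest.warns(UserWarning):
        w = celltype_weights(_vg({"v": ["g1", "g2", "g3"]}), expr)
    np.testing.assert_allclose(w.loc["v"], [1, 0, 0, 0, 0])


# ---------------------------------------------------------------------------
# within-group tests


def test_concentrated_group_yields_minimal_p_for_its_cluster():
    weights = pd.DataFrame(
        [[1.0, 0, 0, 0]] * 5 + [[0.25] * 4] * 5,
        index=[f"v{i}" for i in range(10)],
        columns=[f"c{i}" for i in range(4)],
    )
    groups = {f"v{i}": ("G1" if i < 5 else "G2") for i in range(10)}
    out = group_enrichment_tests(weights, groups)
    g1 = out[out["group"] == "G1"].set_index("category")
    assert g1.loc["c0", "p"] == g1["p"].min()


def test_uniform_weights_give_no_signal():
    weights = pd.DataFrame(
        [[0.25] * 4] * 6, index=[f"v{i}" for i in range(6)],
        columns=[f"c{i}" for i in range(4)],
    )
    groups = {f"v{i}": "G" for i in range(6)}
    out = group_enrichment_tests(weights, groups)
    assert (out["p"] == 1.0).all()


def test_small_groups_are_recorded_as_na():
    weights = pd.DataFrame([[0.5, 0.5]], index=["v0"], columns=["c0", "c1"])
    out = group_enrichment_tests(weights, {"v0": "solo"})
    assert out["p"].isna().all()


def test_planted_group_weight_is_the_only_significant_call(rng):
    """A Longevity-like group with ~0.7 weight on one cluster is detected
    as the single significant cell in >= 90% of simulations.

    The comparison groups carry flat (uninformative) weight profiles: for
    any exchangeable noise around the uniform profile the rank-sum null
    p-values are uniform, so some null cell would cross the step-up
    threshold in ~10% of runs regardless of the method — flat profiles
    isolate the power-and-specificity property actually being claimed."""
    hits = 0
    n_sims = 100
    for s in range(n_sims):
        r = np.random.default_rng(2000 + s)
        # mean weight 0.7 on cluster 0 for the planted group
        lon = r.dirichlet([14.0, 2.0, 2.0, 2.0], size=11)
        ad = np.full((17, 4), 0.25)
        unex = np.full((10, 4), 0.25)
        weights = pd.DataFrame(
            np.vstack([lon, ad, unex]),
            index=[f"v{i}" for i in range(38)],
            columns=[f"c{i}" for i in range(4)],
        )
        groups = {}
        for i in range(38):
            groups[f"v{i}"] = "Longevity" if i < 11 else ("AD" if i < 28 else "Unex")
        out = group_enrichment_tests(weights, groups)
        sig = out[out["significant"].fillna(False)]
        if len(sig) == 1 and sig.iloc[0]["group"] == "Longevity" \
                and sig.iloc[0]["category"] == "c0":
            hits += 1
    assert hits >= 90
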