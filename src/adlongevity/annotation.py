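"""Functional layer: enrichment, term clustering, and per-variant weights.

The downstream consequences of GWAS variants are uncertain: a variant may
plausibly act through several genes. The annotation layer propagates that
uncertainty with a sampling scheme — each iteration picks one candidate
gene per variant at random, the resulting gene list is tested for gene-set
enrichment with a hypergeometric tail, and per-term p-values are combined
across iterations by their arithmetic mean. Enriched terms are clustered
on a semantic-similarity matrix (average linkage on 1 − similarity) into a
small number of functional clusters.

Two per-variant weight matrices summarise the layer: the variant-pathway
mapping (how much of a variant's genes' enriched-term membership falls in
each functional cluster) and the brain cell-type weights (mean normalized
expression of the variant's genes across astrocytes, oligodendrocytes,
microglia, endothelial cells and neurons). Within each effect-direction
group, one-sided rank-sum tests ask whether a cluster or cell type carries
more weight than the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .stats_core import (
    ValidationError,
    fdr_adjust,
    hypergeom_tail,
    wilcoxon_rank_sum,
)


@dataclass
class EnrichmentResult:
    term: str
    combined_p: float
    q: float = np.nan
    enriched: bool = False
    iteration_p: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class VariantPathwayMapping:
    weights: pd.DataFrame             # variant × cluster, rows sum to 1
    annotated: pd.Series              # bool per variant
    imputed: pd.Series                # bool per variant
    excluded: list[str]               # variants with no usable genes


# ---------------------------------------------------------------------------
# sampling + enrichment


def sample_gene_lists(
    variant_gene: pd.DataFrame, iterations: int, seed: int = 0
) -> list[list[str]]:
    """One gene per variant per iteration, chosen uniformly at random.

    Variants with an empty gene list are skipped with a warning; duplicate
    genes within an iteration's list are collapsed.
    """
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    genes_of = {
        v: list(g["gene"]) for v, g in variant_gene.groupby("variant", sort=True)
    }
    empty = [v for v, g in genes_of.items() if not g]
    if empty:
        warnings.warn(f"variants without genes skipped: {empty}")
    rng = np.random.default_rng(seed)
    lists = []
    for _ in range(iterations):
        picked = {
            genes[rng.integers(len(genes))]
            for genes in genes_of.values()
            if genes
        }
        lists.append(sorted(picked))
    return lists


def enrich(
    lists: list[list[str]],
    gmt: dict[str, list[str]],
    background: set[str] | None = None,
    fdr_level: float = 0.05,
    keep_iteration_p: bool = False,
) -> list[EnrichmentResult]:
    """Sampling-based gene-set enrichment.

    Per iteration and term, a hypergeometric upper-tail p-value on the
    overlap between the sampled gene list and the term; per term, the
    combined p is the arithmetic mean of iteration p-values (order
    invariant and conservative); Benjamini–Hochberg across terms; enriched
    means q < ``fdr_level``.
    """
    if background is None:
        background = set().union(*gmt.values()) if gmt else set()
    bg = set(background)
    n_bg = len(bg)
    terms, term_sets = [], []
    for term, members in gmt.items():
        members_bg = set(members) & bg
        if not members_bg:
            warnings.warn(f"term {term} has no background genes; skipped")
            continue
        terms.append(term)
        term_sets.append(members_bg)
    if not terms:
        raise ValidationError("no testable terms")

    psum = np.zeros(len(terms))
    kept = np.empty((len(lists), len(terms))) if keep_iteration_p else None
    for it, glist in enumerate(lists):
        gset = set(glist) & bg
        n_list = len(gset)
        for t, members in enumerate(term_sets):
            p = hypergeom_tail(len(gset & members), n_list, len(members), n_bg)
            psum[t] += p
            if kept is not None:
                kept[it, t] = p
    combined = psum / len(lists)
    q = fdr_adjust(list(np.clip(combined, 0.0, 1.0))).values
    return [
        EnrichmentResult(
            term=terms[t],
            combined_p=float(combined[t]),
            q=float(q[t]),
            enriched=bool(q[t] < fdr_level),
            iteration_p=kept[:, t] if kept is not None else np.empty(0),
        )
        for t in range(len(terms))
    ]


# ---------------------------------------------------------------------------
# clustering + weights


def cluster_terms(
    similarity: pd.DataFrame, terms: list[str], k: int = 4
) -> dict[str, int]:
    """Average-linkage clustering of terms on distance = 1 − similarity.

    Cluster labels are renumbered 0..k−1 by first appearance in term-id
    sorted order, so the partition is independent of input ordering.
    """
    terms = sorted(terms)
    if k > len(terms):
        raise ValidationError(f"k={k} exceeds the {len(terms)} enriched terms")
    if k == 1 or len(terms) == 1:
        return {t: 0 for t in terms}
    sim = similarity.loc[terms, terms].to_numpy(dtype=float)
    if not np.allclose(sim, sim.T, atol=1e-8):
        raise ValidationError("similarity matrix must be symmetric")
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    labels = fcluster(linkage(squareform(dist, checks=False), method="average"),
                      t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    out = {}
    for t, lab in zip(terms, labels):
        out[t] = remap.setdefault(int(lab), len(remap))
    return out


def variant_pathway_mapping(
    variant_gene: pd.DataFrame,
    gmt: dict[str, list[str]],
    clusters: dict[str, int],
    enriched_terms: list[str],
) -> VariantPathwayMapping:
    """Per-variant weights over the functional clusters.

    Per gene: the fraction of its enriched-term memberships in each
    cluster. Per variant: the unweighted mean of its genes' fractions
    (genes with no enriched term are ignored), renormalized to sum 1.
    Variants none of whose genes touch an enriched term are flagged
    unannotated.
    """
    if not enriched_terms:
        raise ValidationError("no enriched terms to map against")
    n_clusters = max(clusters.values()) + 1
    term_of_gene: dict[str, np.ndarray] = {}
    for term in enriched_terms:
        c = clusters[term]
        for g in gmt.get(term, ()):
            term_of_gene.setdefault(g, np.zeros(n_clusters))[c] += 1.0

    variants = sorted(variant_gene["variant"].unique())
    genes_of = {v: list(g["gene"]) for v, g in variant_gene.groupby("variant")}
    rows, annotated, excluded = {}, {}, []
    for v in variants:
        genes = genes_of.get(v, [])
        if not genes:
            excluded.append(v)
            continue
        fracs = [
            term_of_gene[g] / term_of_gene[g].sum()
            for g in genes
            if g in term_of_gene
        ]
        if fracs:
            w = np.mean(fracs, axis=0)
            rows[v] = w / w.sum()
            annotated[v] = True
        else:
            rows[v] = np.zeros(n_clusters)
            annotated[v] = False
    weights = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"cluster_{c}" for c in range(n_clusters)]
    )
    ann = pd.Series(annotated).reindex(weights.index)
    return VariantPathwayMapping(
        weights=weights,
        annotated=ann,
        imputed=pd.Series(False, index=weights.index),
        excluded=excluded,
    )


def impute_mapping(mapping: VariantPathwayMapping) -> VariantPathwayMapping:
    """Fill unannotated variants with the mean profile of annotated ones."""
    if not mapping.annotated.any():
        raise ValidationError("cannot impute: no annotated variants")
    mean_row = mapping.weights.loc[mapping.annotated].mean(axis=0)
    mean_row = mean_row / mean_row.sum()
    weights = mapping.weights.copy()
    imputed = mapping.imputed.copy()
    for v in weights.index[~mapping.annotated]:
        weights.loc[v] = mean_row
        imputed.loc[v] = True
    return VariantPathwayMapping(
        weights=weights,
        annotated=mapping.annotated,
        imputed=imputed,
        excluded=list(mapping.excluded),
    )


def celltype_weights(
    variant_gene: pd.DataFrame, expression: pd.DataFrame
) -> pd.DataFrame:
    """Per-variant normalized mean expression across brain cell types.

    Each gene's expression vector is normalized to sum 1 across cell types
    (so the weights are scale-free); a variant's row is the mean over its
    mapped genes, renormalized. Genes missing from the matrix or with
    all-zero expression are skipped with a warning.
    """
    rows = {}
    for v, g in variant_gene.groupby("variant"):
        profs = []
        for gene in g["gene"]:
            if gene not in expression.index:
                warnings.warn(f"gene {gene} absent from expression matrix; skipped")
                continue
            e = expression.loc[gene].to_numpy(dtype=float)
            if (e < 0).any():
                raise ValidationError(f"gene {gene} has negative expression")
            if e.sum() == 0:
                warnings.warn(f"gene {gene} has all-zero expression; skipped")
                continue
            profs.append(e / e.sum())
        if profs:
            w = np.mean(profs, axis=0)
            rows[v] = w / w.sum()
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(expression.columns)
    ).sort_index()


# ---------------------------------------------------------------------------
# within-group comparisons


def group_enrichment_tests(
    weights: pd.DataFrame,
    groups: dict[str, str],
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Within-group one-sided rank-sum tests per category.

    For each variant group G and weight category c, tests whether
    {weight(v, c): v in G} is stochastically greater than the pooled
    weights of the *other* categories within the same group. P-values are
    Benjamini–Hochberg adjusted across the full group × category table.
    Groups with fewer than two variants are recorded as NA.
    """
    rows = []
    for grp in sorted(set(groups.values())):
        members = [v for v, g in groups.items() if g == grp and v in weights.index]
        for cat in weights.columns:
            if len(members) < 2:
                rows.append(
                    {"group": grp, "category": cat, "n": len(members),
                     "p": np.nan, "exact": False}
                )
                continue
            x = weights.loc[members, cat].to_numpy()
            other = [c for c in weights.columns if c != cat]
            y = weights.loc[members, other].to_numpy().ravel()
            res = wilcoxon_rank_sum(x, y, alternative="greater")
            rows.append(
                {"group": grp, "category": cat, "n": len(members),
                 "p": res.pvalue, "exact": res.exact}
            )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = fdr_adjust(list(out.loc[ok, "p"])).values
    out["q"] = q
    out["significant"] = out["q"] < fdr_level
    return out
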