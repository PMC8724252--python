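"""Synthetic inputs emulating a centenarian case-control study of AD variants.

Everything the pipeline consumes can be generated here: a panel of
AD-associated variants with known ("true") effects on AD and on longevity, a
genotyped cohort of cognitively healthy centenarians (cases) versus
population subjects (controls), published-style AD summary statistics, a
parental-longevity replication table, and the functional-annotation
resources (variant→gene map, GMT gene sets, a term semantic-similarity
matrix, and a brain cell-type expression matrix).

The default conditions mirror the emulated study design: 343 cases and
2,905 controls; a panel of 41 candidate variants of which 3 are too rare to
analyse (minor allele frequency below 1%), leaving 38; two APOE-like
variants with large effects on both traits; 28 of the 38 common variants
with a longevity effect in the expected (negative) direction; replication
statistics available for 34 of the 38; four functional clusters and five
brain cell types in the annotation layer.

Case status is assigned by a logistic model inside a larger latent pool and
the requested numbers of cases and controls are then subsampled. Because
case-control subsampling changes only the intercept of a logistic model,
the per-variant dosage log-odds-ratio estimated downstream is consistent
for the planted ``beta_lgv`` — which is what makes parameter recovery a
meaningful end-to-end check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _st

from .longevity_assoc import PC_COLUMNS, CohortGenotypes
from .stats_core import ValidationError


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class VariantSpec:
    """Ground truth for one synthetic variant.

    ``beta_ad`` is the log-OR on AD of the effect allele (positive by
    construction: the panel is pre-oriented to the risk allele).
    ``beta_lgv`` is the true log-OR on centenarian status of that same
    allele; negative means the expected direction. The ``replication_*``
    fields are the truth of the parental-longevity layer.
    """

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    maf_control: float
    beta_ad: float
    se_ad: float
    beta_lgv: float
    replication_beta: float = 0.0
    replication_se: float = 0.1
    replication_available: bool = True
    apoe_like: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_control <= 0.5):
            raise ValidationError(f"{self.id}: maf_control must be in (0, 0.5]")
        if self.se_ad <= 0:
            raise ValidationError(f"{self.id}: se_ad must be positive")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.id}: alleles must differ")


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int = 343
    n_controls: int = 2_905
    variants: tuple[VariantSpec, ...] = ()
    n_pcs: int = 5
    seed: int = 0
    base_population_multiplier: float = 6.0
    base_rate: float = 0.15           # case probability at the pool average
    pc_loadings: tuple[float, ...] = ()   # confounding loadings, default none

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("n_cases and n_controls must be >= 1")
        if self.base_population_multiplier <= 1:
            raise ValidationError("base_population_multiplier must exceed 1")


@dataclass(frozen=True)
class AnnotationResourceSpec:
    """Shape of the synthetic functional-annotation resources.

    With ``planted_cluster`` set (the default), the resource carries a
    recoverable functional structure: each cluster owns a small "core" of
    genes that both its terms and the variants' gene maps concentrate on,
    and the planted cluster is assigned ``planted_extra`` more variants
    than the others (so it carries the largest pathway weight, like the
    endocytosis/immune-signaling cluster of the emulated study). With
    ``planted_cluster=None`` the resource is a calibration null: terms and
    variant-gene links are drawn uniformly at random, so no term is truly
    enriched.
    """

    n_genes: int = 162
    n_terms: int = 60
    n_clusters: int = 4
    cell_types: tuple[str, ...] = (
        "astrocytes", "oligodendrocytes", "microglia", "endothelial", "neurons",
    )
    variant_ids: tuple[str, ...] = ()
    seed: int = 0
    planted_cluster: int | None = 2
    planted_extra: int = 6        # extra variants assigned to the planted cluster
    core_size: int = 8            # genes per cluster that variants map onto
    term_own_frac: float = 0.8    # fraction of a term's genes from its own core
    signal_term_frac: float = 0.5  # fraction of terms per cluster that are core-rich
    n_unannotatable: int = 2

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValidationError("n_clusters must be >= 2")
        if self.n_genes < self.n_clusters * self.core_size + self.n_unannotatable:
            raise ValidationError("n_genes too small for the cluster cores")


# ---------------------------------------------------------------------------
# the default panel

# (label, chrom, pos, maf, beta_ad, se_ad, beta_lgv) — effects already
# oriented to the AD-risk allele. Three rare (MAF < 1%) coding variants
# mirror TREM2/ABI3-class candidates dropped by the frequency filter; two
# APOE-like variants carry the large effects on both traits.
_PANEL_ROWS: list[tuple[str, str, int, float, float, float, float]] = [
    # --- APOE-like (AD-group: median imbalance near -1/2) ---
    ("APOE_like_1",  "19", 45411941, 0.16, 1.10, 0.02, -0.95),
    ("APOE_like_2",  "19", 45412079, 0.07, 0.45, 0.03, -0.40),
    # --- rare coding stand-ins, excluded by the MAF > 1% filter ---
    ("TREM2_like_1", "6",  41129252, 0.005, 0.45, 0.08, -0.20),
    ("TREM2_like_2", "6",  41129195, 0.003, 0.55, 0.10, -0.25),
    ("ABI3_like",    "17", 47297297, 0.008, 0.30, 0.07, -0.10),
    # --- AD-group: expected direction, larger effect on AD (15) ---
    ("BIN1_like",    "2",  127892810, 0.40, 0.17, 0.01, -0.14),
    ("CR1_like",     "1",  207692049, 0.20, 0.15, 0.02, -0.05),
    ("PICALM_like",  "11", 85867875, 0.36, 0.14, 0.01, -0.06),
    ("MS4A6A_like",  "11", 59923508, 0.39, 0.11, 0.01, -0.04),
    ("CD33_like",    "19", 51727962, 0.31, 0.09, 0.02, -0.03),
    ("SLC24A4_like", "14", 92926952, 0.22, 0.09, 0.02, -0.04),
    ("PILRA_like",   "7",  99971834, 0.32, 0.10, 0.01, -0.05),
    ("SCIMP_like",   "17", 5138980,  0.12, 0.11, 0.02, -0.03),
    ("APP_like",     "21", 27473875, 0.45, 0.08, 0.01, -0.02),
    ("PLCG2_like_1", "16", 81942028, 0.41, 0.08, 0.01, -0.04),
    ("PLCG2_like_2", "16", 81908423, 0.15, 0.10, 0.02, -0.05),
    ("TREML2_like",  "6",  41158506, 0.30, 0.09, 0.02, -0.03),
    ("ACE_like",     "17", 61538148, 0.38, 0.08, 0.01, -0.05),
    ("APH1B_like",   "15", 63569902, 0.13, 0.10, 0.02, -0.06),
    ("FERMT2_like",  "14", 53391680, 0.09, 0.11, 0.02, -0.04),
    # --- Longevity-group: expected direction, larger effect on longevity (11) ---
    ("SHARPIN_like_1", "8", 145158607, 0.057, 0.14, 0.03, -0.45),
    ("SHARPIN_like_2", "8", 145154222, 0.085, 0.12, 0.03, -0.30),
    ("HS3ST1_like",  "4",  11026028, 0.29, 0.07, 0.01, -0.18),
    ("EPHA1_like",   "7",  143110762, 0.34, 0.06, 0.01, -0.15),
    ("IQCK_like",    "16", 19808163, 0.171, 0.06, 0.01, -0.14),
    ("PRKD3_like",   "2",  37482320, 0.130, 0.07, 0.01, -0.28),
    ("CD2AP_like",   "6",  47487762, 0.27, 0.08, 0.01, -0.24),
    ("PLCG2_like_3", "16", 81786798, 0.06, 0.09, 0.03, -0.35),
    ("SPI1_like",    "11", 47380340, 0.33, 0.06, 0.01, -0.16),
    ("HLA_like",     "6",  32578530, 0.104, 0.08, 0.02, -0.22),
    ("ECHDC3_like",  "10", 11720308, 0.37, 0.06, 0.01, -0.13),
    # --- Unex-group: unexpected direction (10) ---
    ("PTK2B_like",   "8",  27195121, 0.37, 0.09, 0.01, 0.05),
    ("CLU_like",     "8",  27467686, 0.40, 0.13, 0.01, 0.06),
    ("KANSL1_like",  "17", 44353222, 0.12, 0.11, 0.02, 0.04),
    ("INPP5D_like",  "2",  234068476, 0.35, 0.08, 0.01, 0.05),
    ("ABCA7_like",   "19", 1063443,  0.19, 0.11, 0.02, 0.06),
    ("CHRNE_like",   "17", 4802194,  0.08, 0.12, 0.03, 0.10),
    ("SORL1_like",   "11", 121435587, 0.29, 0.08, 0.01, 0.04),
    ("IL34_like",    "16", 70660097, 0.11, 0.09, 0.02, 0.08),
    ("ADAM10_like",  "15", 59022615, 0.30, 0.08, 0.01, 0.06),
    ("CASS4_like",   "20", 54998544, 0.09, 0.10, 0.02, 0.07),
]

# replication layer: planted strongly significant loci (|z| > 6 in the
# parental-longevity table) and the four loci with no replication record
_REP_SIGNIFICANT = {
    "APOE_like_1", "APOE_like_2", "PRKD3_like", "CD2AP_like",
    "BIN1_like", "APH1B_like",
}
_REP_MISSING = {"PLCG2_like_3", "SPI1_like", "KANSL1_like", "INPP5D_like"}

_ALLELES = [("A", "G"), ("C", "T"), ("T", "C"), ("G", "A")]


def default_panel() -> list[VariantSpec]:
    """The default 41-variant candidate panel with planted truths.

    Deterministic: repeated calls return identical specs. Three variants
    are rare (MAF < 1%) and fall to the frequency filter; two are
    APOE-like with large effects on both AD and longevity.
    """
    specs: list[VariantSpec] = []
    for i, (label, chrom, pos, maf, b_ad, se_ad, b_lgv) in enumerate(_PANEL_ROWS):
        ea, oa = _ALLELES[i % len(_ALLELES)]
        if label in _REP_SIGNIFICANT:
            rep_beta, rep_se = 0.9 * b_lgv, 0.12 * abs(b_lgv) + 1e-3
        else:
            # weak, non-significant replication signal
            rep_beta, rep_se = 0.5 * b_lgv, max(0.06, 0.8 * abs(b_lgv))
        specs.append(
            VariantSpec(
                id=f"rs9{100_000 + 37 * i}",
                chrom=chrom,
                pos=pos,
                effect_allele=ea,
                other_allele=oa,
                maf_control=maf,
                beta_ad=b_ad,
                se_ad=se_ad,
                beta_lgv=b_lgv,
                replication_beta=rep_beta,
                replication_se=rep_se,
                replication_available=label not in _REP_MISSING,
                apoe_like=label.startswith("APOE"),
                label=label,
            )
        )
    return specs


def panel_manifest(panel: list[VariantSpec]) -> pd.DataFrame:
    """Truth manifest as a flat table (one row per variant)."""
    return pd.DataFrame([vars(v) | {} for v in (replace(s) for s in panel)])


# ---------------------------------------------------------------------------
# cohort simulation


def simulate_cohort(cfg: SimulationConfig) -> CohortGenotypes:
    """Draw a case-control cohort with planted per-variant longevity effects.

    Controls' genotypes follow Hardy–Weinberg at the configured control
    MAF; centenarian status is assigned in a latent pool of
    ``base_population_multiplier × (n_cases + n_controls)`` individuals via
    a logistic model with linear predictor
    ``logit(base_rate) + Σ_v beta_lgv_v (d_v − 2 maf_v) + PC loadings``,
    then exactly ``n_cases`` cases and ``n_controls`` controls are
    subsampled.
    """
    if not cfg.variants:
        raise ValidationError("config carries no variants")
    rng = np.random.default_rng(cfg.seed)
    pool_n = int(cfg.base_population_multiplier * (cfg.n_cases + cfg.n_controls))
    mafs = np.array([v.maf_control for v in cfg.variants])
    betas = np.array([v.beta_lgv for v in cfg.variants])

    dosages = rng.binomial(2, mafs, size=(pool_n, len(mafs))).astype(np.int8)
    pcs = rng.standard_normal((pool_n, cfg.n_pcs))
    loadings = np.zeros(cfg.n_pcs)
    if cfg.pc_loadings:
        loadings[: len(cfg.pc_loadings)] = cfg.pc_loadings

    lp = (
        np.log(cfg.base_rate / (1 - cfg.base_rate))
        + (dosages - 2 * mafs) @ betas
        + pcs @ loadings
    )
    case = rng.random(pool_n) < 1.0 / (1.0 + np.exp(-lp))

    case_pool = np.flatnonzero(case)
    ctrl_pool = np.flatnonzero(~case)
    if case_pool.size < cfg.n_cases or ctrl_pool.size < cfg.n_controls:
        raise ValidationError(
            f"latent pool too small ({case_pool.size} cases, {ctrl_pool.size} "
            "controls); raise base_population_multiplier"
        )
    take = np.concatenate(
        [
            rng.choice(case_pool, cfg.n_cases, replace=False),
            rng.choice(ctrl_pool, cfg.n_controls, replace=False),
        ]
    )
    phenotype = np.concatenate(
        [np.ones(cfg.n_cases, np.int8), np.zeros(cfg.n_controls, np.int8)]
    )
    sample_ids = [f"S{i:05d}" for i in range(take.size)]
    covariates = pd.DataFrame(
        pcs[take][:, : len(PC_COLUMNS)], columns=list(PC_COLUMNS), index=sample_ids
    )
    return CohortGenotypes(
        sample_ids=sample_ids,
        phenotype=phenotype,
        dosages=dosages[take],
        variant_ids=[v.id for v in cfg.variants],
        counted_allele=[v.effect_allele for v in cfg.variants],
        other_allele=[v.other_allele for v in cfg.variants],
        covariates=covariates,
        chrom=[v.chrom for v in cfg.variants],
        pos=[v.pos for v in cfg.variants],
    )


def write_vcf(cohort: CohortGenotypes, path: str | Path) -> None:
    """Emit unphased GT genotypes as an uncompressed VCF 4.2 file.

    The REF allele is the variant's *other* allele and ALT the counted
    (risk) allele, so an ALT-dosage reader recovers the dosage matrix.
    """
    path = Path(path)
    gt = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(set(cohort.chrom), key=str):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.sample_ids)
            + "\n"
        )
        for j, vid in enumerate(cohort.variant_ids):
            row = [
                cohort.chrom[j],
                str(cohort.pos[j]),
                vid,
                cohort.other_allele[j],
                cohort.counted_allele[j],
                ".",
                "PASS",
                ".",
                "GT",
            ] + [gt[int(d)] for d in cohort.dosages[:, j]]
            fh.write("\t".join(row) + "\n")


def write_phenotypes(cohort: CohortGenotypes, path: str | Path) -> None:
    df = cohort.covariates.copy()
    df.insert(0, "phenotype", np.where(cohort.phenotype == 1, "case", "control"))
    df.insert(0, "sample_id", cohort.sample_ids)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# summary-statistics tables


def simulate_ad_summary(
    panel: list[VariantSpec], noise: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Published-style AD summary statistics for the panel.

    ``beta = beta_ad + noise · se_ad · ε`` with ε standard normal, so
    ``noise=0`` reproduces the truth exactly and ``noise=1`` emulates one
    GWAS realisation.
    """
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(len(panel)) if noise else np.zeros(len(panel))
    return pd.DataFrame(
        {
            "id": [v.id for v in panel],
            "chrom": [v.chrom for v in panel],
            "pos": [v.pos for v in panel],
            "effect_allele": [v.effect_allele for v in panel],
            "other_allele": [v.other_allele for v in panel],
            "beta": [v.beta_ad + noise * v.se_ad * e for v, e in zip(panel, eps)],
            "se": [v.se_ad for v in panel],
        }
    )


def simulate_replication_summary(
    panel: list[VariantSpec],
    concordance: float = 0.81,
    seed: int = 0,
) -> pd.DataFrame:
    """Parental-longevity-style summary statistics for the panel.

    Each available variant's emitted sign agrees with the sign of its true
    longevity effect with probability ``concordance``; variants flagged
    unavailable are omitted. The default concordance reflects the direction
    agreement observed between a centenarian study and a parental-longevity
    GWAS (about 8 in 10).
    """
    if not (0.0 <= concordance <= 1.0):
        raise ValidationError("concordance must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for v in panel:
        if not v.replication_available:
            continue
        agree = rng.random() < concordance
        sign = np.sign(v.beta_lgv) if agree else -np.sign(v.beta_lgv)
        beta = sign * abs(v.replication_beta)
        p = 2.0 * _st.norm.sf(abs(beta) / v.replication_se)
        rows.append(
            {
                "id": v.id,
                "chrom": v.chrom,
                "pos": v.pos,
                "effect_allele": v.effect_allele,
                "other_allele": v.other_allele,
                "beta": beta,
                "se": v.replication_se,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# annotation resources


@dataclass
class AnnotationResources:
    variant_gene: pd.DataFrame        # variant, gene, evidence
    gmt: dict[str, list[str]]         # term -> genes
    term_clusters_true: dict[str, int]
    similarity: pd.DataFrame          # term × term in [0, 1]
    expression: pd.DataFrame          # gene × cell type, non-negative
    unannotatable: list[str]          # variants mapping only to term-free genes


def simulate_annotation_resources(spec: AnnotationResourceSpec) -> AnnotationResources:
    """Generate the variant→gene map, GMT, similarity and expression resources.

    Structured mode (``planted_cluster`` set): the gene universe is split
    into equal per-cluster pools, each with a small core; every annotatable
    variant is assigned a primary cluster (the planted cluster receiving
    ``planted_extra`` extra variants) and its genes cycle through that
    cluster's core, so each core is fully covered by the variant map. GMT
    terms draw ``term_own_frac`` of their genes from their own cluster's
    core and the rest from the cluster pool; the term-similarity matrix is
    block-diagonal by cluster; each gene's expression peaks in one brain
    cell type. Variant gene counts follow the emulated study's profile
    (mostly one gene, a tail up to seven). The first ``n_unannotatable``
    variants map only to genes absent from every term, exercising the
    imputation path.

    Null mode (``planted_cluster=None``): terms and variant-gene links are
    uniform over the gene universe, so per-term enrichment p-values are
    honest nulls.
    """
    rng = np.random.default_rng(spec.seed)
    variant_ids = list(spec.variant_ids) or [f"v{i:02d}" for i in range(38)]
    n_var = len(variant_ids)
    genes = [f"g{i:03d}" for i in range(spec.n_genes)]
    n_free = spec.n_unannotatable
    term_genes = genes[: spec.n_genes - n_free]
    free_genes = genes[spec.n_genes - n_free:]

    ncl = spec.n_clusters
    per_pool = len(term_genes) // ncl
    pools = [term_genes[c * per_pool: (c + 1) * per_pool] for c in range(ncl)]
    cores = [pool[: spec.core_size] for pool in pools]
    structured = spec.planted_cluster is not None
    planted = (spec.planted_cluster % ncl) if structured else 0

    # ---- GMT terms with planted block structure
    gmt: dict[str, list[str]] = {}
    term_clusters: dict[str, int] = {}
    term_ids: list[str] = []
    for c in range(ncl):
        n_c = spec.n_terms // ncl + (1 if c < spec.n_terms % ncl else 0)
        n_signal = int(round(spec.signal_term_frac * n_c))
        for t in range(n_c):
            term = f"T{c}_{t:02d}"
            size = int(rng.integers(10, 16))
            if structured and t < n_signal:
                # core-rich "signal" term: truly enriched in the variant map
                n_own = min(int(spec.term_own_frac * size), spec.core_size)
                members = set(rng.choice(cores[c], n_own, replace=False))
                members |= set(rng.choice(pools[c], size - n_own, replace=False))
            elif structured:
                # peripheral term: same cluster pool but outside the cores
                members = set(rng.choice(pools[c][spec.core_size:], size,
                                         replace=False))
            else:
                members = set(rng.choice(term_genes, size, replace=False))
            gmt[term] = sorted(members)
            term_clusters[term] = c
            term_ids.append(term)

    # ---- variant → gene map
    profile = [1] * 21 + [2] * 10 + [3] * 2 + [4] + [5] * 2 + [6, 7]
    counts = [profile[i % len(profile)] for i in range(n_var)]
    n_annot = n_var - n_free
    assign: list[int] = []
    base = max(0, (n_annot - spec.planted_extra) // ncl) if structured else 0
    if structured:
        for c in range(ncl):
            assign += [c] * (base + (spec.planted_extra if c == planted else 0))
        while len(assign) < n_annot:
            assign.append(int(rng.integers(ncl)))
        assign = assign[:n_annot]
        rng.shuffle(assign)

    rows = []
    unannotatable = []
    evid = ["coding", "intronic-eQTL", "intergenic-proximity"]
    counters = [0] * ncl
    for i, (vid, k) in enumerate(zip(variant_ids, counts)):
        if i < n_free:
            rows.append({"variant": vid, "gene": free_genes[i], "evidence": "coding"})
            unannotatable.append(vid)
            continue
        picked: list[str] = []
        if structured:
            c = assign[i - n_free]
            while len(picked) < min(k, spec.core_size):
                g = cores[c][counters[c] % spec.core_size]
                counters[c] += 1
                if g not in picked:
                    picked.append(g)
        else:
            picked = list(rng.choice(term_genes, size=min(k, len(term_genes)),
                                     replace=False))
        for g in picked:
            rows.append({"variant": vid, "gene": g, "evidence": evid[i % len(evid)]})
    variant_gene = pd.DataFrame(rows)

    # ---- block-diagonal semantic similarity
    sim = np.full((len(term_ids), len(term_ids)), 0.10)
    for a, ta in enumerate(term_ids):
        for b, tb in enumerate(term_ids):
            if term_clusters[ta] == term_clusters[tb]:
                sim[a, b] = 0.85
    sim += rng.uniform(-0.05, 0.05, sim.shape)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    similarity = pd.DataFrame(sim, index=term_ids, columns=term_ids)

    # ---- cell-type expression: each gene peaks in one cell type
    gene_ct = {g: i % len(spec.cell_types) for i, g in enumerate(genes)}
    expr = rng.uniform(0.5, 1.5, size=(spec.n_genes, len(spec.cell_types)))
    for i, g in enumerate(genes):
        expr[i, gene_ct[g]] += rng.uniform(4.0, 6.0)
    expression = pd.DataFrame(expr, index=genes, columns=list(spec.cell_types))

    return AnnotationResources(
        variant_gene=variant_gene,
        gmt=gmt,
        term_clusters_true=term_clusters,
        similarity=similarity,
        expression=expression,
        unannotatable=unannotatable,
    )


def write_annotation_resources(res: AnnotationResources, out_dir: str | Path) -> dict[str, Path]:
    """Write the four resource files (TSV ×3 + GMT) and return their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "variant_gene": out / "variant_gene.tsv",
        "gmt": out / "terms.gmt",
        "similarity": out / "similarity.tsv",
        "expression": out / "expression.tsv",
    }
    res.variant_gene.to_csv(paths["variant_gene"], sep="\t", index=False)
    with paths["gmt"].open("w") as fh:
        for term, members in res.gmt.items():
            fh.write("\t".join([term, f"synthetic term {term}", *members]) + "\n")
    res.similarity.to_csv(paths["similarity"], sep="\t")
    res.expression.to_csv(paths["expression"], sep="\t")
    return paths


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    gmt: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                gmt[parts[0]] = parts[2:]
    return gmt
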