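"""End-to-end orchestration: simulate → associate → IED → replicate → annotate.

Each stage is a plain function over file paths so it can run (and be
tested) in isolation; ``run_all`` chains them, writes every output as a
TSV with a header, and records a manifest (config values, seed, package
version) sufficient to reproduce the run bit-for-bit. All randomness flows
from one master seed via fixed per-stage offsets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotation as anno
from . import ied as ied_mod
from . import longevity_assoc as assoc
from . import replication as repl
from . import synthetic_data as synth
from .stats_core import ValidationError

# fixed substream offsets per stage (master seed + offset)
_STAGE_SEED = {"simulate": 11, "boot": 23, "ied": 37, "replication": 51, "annotation": 67}


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_run"
    seed: int = 0
    # stage sizes; defaults are the emulated study's constants
    n_ied_samples: int = 10_000     # S
    n_boot: int = 10_000            # B
    n_enrich_iterations: int = 1_000  # R
    k_clusters: int = 4
    maf_threshold: float = 0.01
    fdr_level: float = 0.05
    # inputs; empty strings mean "generate synthetically"
    vcf: str = ""
    pheno: str = ""
    ad_summary: str = ""
    replication: str = ""
    variant_gene: str = ""
    gmt: str = ""
    similarity: str = ""
    expression: str = ""
    simulate: bool = True
    replication_concordance: float = 0.81
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        extras = {k: v for k, v in raw.items() if k not in cls.__dataclass_fields__}
        known.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**known, extras=extras) if "extras" not in known else cls(**known)


def _seed(cfg: PipelineConfig, stage: str) -> int:
    return (cfg.seed + _STAGE_SEED[stage]) % (2**31 - 1)


# ---------------------------------------------------------------------------
# validation


def validate_inputs(cfg: PipelineConfig) -> list[str]:
    """Check declared input files without mutating anything.

    Returns a list of human-readable violations (empty = clean).
    """
    issues: list[str] = []
    for name in ("vcf", "pheno", "ad_summary", "replication",
                 "variant_gene", "gmt", "similarity", "expression"):
        p = getattr(cfg, name)
        if p and not Path(p).exists():
            issues.append(f"{name}: file not found: {p}")

    if cfg.ad_summary and Path(cfg.ad_summary).exists():
        ad = pd.read_csv(cfg.ad_summary, sep="\t")
        for col in ("id", "effect_allele", "other_allele", "beta", "se"):
            if col not in ad.columns:
                issues.append(f"ad_summary: missing column {col!r}")

    if cfg.vcf and Path(cfg.vcf).exists():
        with open(cfg.vcf) as fh:
            for ln, line in enumerate(fh, 1):
                if line.startswith("#"):
                    continue
                parts = line.split("\t", 6)
                if len(parts) > 4 and ("," in parts[4] or parts[4] == "."):
                    issues.append(f"vcf line {ln}: non-biallelic record")

    if cfg.pheno and Path(cfg.pheno).exists():
        ph = pd.read_csv(cfg.pheno, sep="\t")
        missing = {"sample_id", "phenotype", *assoc.PC_COLUMNS} - set(ph.columns)
        if missing:
            issues.append(f"pheno: missing columns {sorted(missing)}")
        elif ph[list(assoc.PC_COLUMNS)].isna().any().any():
            issues.append("pheno: incomplete covariates")
    return issues


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig) -> dict[str, Path]:
    """Generate the full synthetic input bundle under out_dir/data."""
    data = Path(cfg.out_dir) / "data"
    data.mkdir(parents=True, exist_ok=True)
    panel = synth.default_panel()
    sim_cfg = synth.SimulationConfig(variants=tuple(panel), seed=_seed(cfg, "simulate"))
    cohort = synth.simulate_cohort(sim_cfg)
    synth.write_vcf(cohort, data / "cohort.vcf")
    synth.write_phenotypes(cohort, data / "phenotypes.tsv")
    synth.panel_manifest(panel).to_csv(data / "panel_manifest.tsv", sep="\t", index=False)
    synth.simulate_ad_summary(panel).to_csv(data / "ad_summary.tsv", sep="\t", index=False)

    retained, _ = assoc.maf_filter(synth.panel_manifest(panel)[["id", "maf_control"]],
                                   cfg.maf_threshold)
    post = [v for v in panel if v.id in set(retained)]
    synth.simulate_replication_summary(
        post, cfg.replication_concordance, _seed(cfg, "simulate") + 1
    ).to_csv(data / "replication.tsv", sep="\t", index=False)

    res = synth.simulate_annotation_resources(
        synth.AnnotationResourceSpec(
            variant_ids=tuple(v.id for v in post), seed=_seed(cfg, "simulate") + 2
        )
    )
    paths = synth.write_annotation_resources(res, data)
    paths |= {
        "vcf": data / "cohort.vcf",
        "pheno": data / "phenotypes.tsv",
        "ad_summary": data / "ad_summary.tsv",
        "replication": data / "replication.tsv",
        "manifest": data / "panel_manifest.tsv",
    }
    return paths


def stage_assoc(cfg: PipelineConfig, paths: dict[str, Path]) -> pd.DataFrame:
    """Harmonize, filter, fit, bootstrap, and FDR-call every variant."""
    out = Path(cfg.out_dir)
    cohort = assoc.load_cohort(str(paths["vcf"]), str(paths["pheno"]))
    ad = pd.read_csv(paths["ad_summary"], sep="\t")
    ad_oriented, cohort = assoc.orient_to_ad_risk(ad, cohort)

    retained, excl = assoc.maf_filter(cohort, cfg.maf_threshold)
    excl.to_csv(out / "maf_exclusions.tsv", sep="\t", index=False)

    apoe_like: set[str] = set()
    if "manifest" in paths:
        man = pd.read_csv(paths["manifest"], sep="\t")
        if "apoe_like" in man.columns:
            apoe_like = set(man.loc[man["apoe_like"], "id"])

    fits, boots, reps = [], [], {}
    for vid in retained:
        fits.append(assoc.fit_longevity_effect(cohort, vid))
        bt = assoc.bootstrap_effects(cohort, vid, cfg.n_boot, _seed(cfg, "boot"))
        boots.append(bt)
        reps[vid] = bt.betas
    pairs = assoc.adjust_and_call(fits, boots, ad_oriented, apoe_like, cfg.fdr_level)
    eff = assoc.effects_frame(pairs)
    eff.to_csv(out / "longevity_effects.tsv", sep="\t", index=False)
    n = max(len(b) for b in reps.values())
    pd.DataFrame(
        {v: np.pad(b, (0, n - len(b)), constant_values=np.nan) for v, b in reps.items()}
    ).to_csv(out / "bootstrap_betas.tsv", sep="\t", index=False)
    return eff


def _pairs_from_frame(eff: pd.DataFrame) -> list[assoc.VariantEffectPair]:
    return [
        assoc.VariantEffectPair(
            variant=r.variant, e_ad=r.e_ad, se_ad=r.se_ad, e_lgv=r.e_lgv,
            se_lgv=r.se_lgv, p_lgv=r.p, q_lgv=r.q, ci_low=r.ci_low,
            ci_high=r.ci_high, apoe_like=bool(r.apoe_like),
            significant=bool(r.significant),
        )
        for r in eff.itertuples()
    ]


def stage_ied(cfg: PipelineConfig, eff: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """IED distributions, grouping, and direction binomial tests."""
    out = Path(cfg.out_dir)
    pairs = _pairs_from_frame(eff)
    dists = [
        ied_mod.build_ied_distribution(p, cfg.n_ied_samples, _seed(cfg, "ied"))
        for p in pairs
    ]
    table = ied_mod.ied_table(dists)
    table.to_csv(out / "ied_groups.tsv", sep="\t", index=False)

    # plain-text histogram of each variant's alpha distribution
    edges = np.linspace(-2, 2, 81)
    hist = pd.DataFrame(
        {d.variant: np.histogram(d.alphas, bins=edges)[0] for d in dists},
        index=[f"{lo:.2f}" for lo in edges[:-1]],
    )
    hist.to_csv(out / "ied_histograms.tsv", sep="\t")

    with_apoe, without_apoe = ied_mod.direction_test(pairs)
    tests = {
        "all": vars(with_apoe),
        "excluding_apoe": vars(without_apoe),
    }
    pd.DataFrame(tests).T.to_csv(out / "direction_tests.tsv", sep="\t")
    return table, tests


def stage_replicate(
    cfg: PipelineConfig, eff: pd.DataFrame, paths: dict[str, Path]
) -> pd.DataFrame:
    out = Path(cfg.out_dir)
    pairs = _pairs_from_frame(eff)
    # alleles of the oriented panel: re-read the AD summary and orient
    ad = pd.read_csv(paths["ad_summary"], sep="\t")
    ad_oriented, _ = assoc.orient_to_ad_risk(ad, ad.copy())
    ad_oriented = ad_oriented[ad_oriented["id"].isin(set(eff["variant"]))]

    rep = pd.read_csv(paths["replication"], sep="\t")
    records, missing = repl.align_replication(ad_oriented, rep)
    records = repl.replication_significance(records, cfg.fdr_level)
    records.to_csv(out / "replication_records.tsv", sep="\t", index=False)

    groups = pd.read_csv(out / "ied_groups.tsv", sep="\t")
    dists = [
        ied_mod.IedDistribution(r.variant, np.empty(0), r.median,
                                r.frac_unexpected, r.group)
        for r in groups.itertuples()
    ]
    conc = repl.concordance_summary(dists, records)
    conc_df = pd.DataFrame([vars(c) for c in conc])
    conc_df["n_missing"] = len(missing)
    conc_df.to_csv(out / "replication_concordance.tsv", sep="\t", index=False)
    repl.forest_table(pairs, records).to_csv(
        out / "forest_effects.tsv", sep="\t", index=False
    )
    return conc_df


def stage_annotate(cfg: PipelineConfig, paths: dict[str, Path]) -> pd.DataFrame:
    out = Path(cfg.out_dir)
    vg = pd.read_csv(paths["variant_gene"], sep="\t")
    gmt = synth.read_gmt(paths["gmt"])
    sim = pd.read_csv(paths["similarity"], sep="\t", index_col=0)
    expr = pd.read_csv(paths["expression"], sep="\t", index_col=0)
    groups_df = pd.read_csv(out / "ied_groups.tsv", sep="\t")
    groups = dict(zip(groups_df["variant"], groups_df["group"]))

    lists = anno.sample_gene_lists(vg, cfg.n_enrich_iterations, _seed(cfg, "annotation"))
    results = anno.enrich(lists, gmt, fdr_level=cfg.fdr_level)
    enr = pd.DataFrame(
        {
            "term": [r.term for r in results],
            "combined_p": [r.combined_p for r in results],
            "q": [r.q for r in results],
            "enriched": [r.enriched for r in results],
        }
    )
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    enriched_terms = list(enr.loc[enr["enriched"], "term"])
    if not enriched_terms:
        raise ValidationError("annotation stage found no enriched terms")

    clusters = anno.cluster_terms(sim, enriched_terms, cfg.k_clusters)
    pd.Series(clusters, name="cluster").rename_axis("term").to_csv(
        out / "term_clusters.tsv", sep="\t"
    )
    mapping = anno.variant_pathway_mapping(vg, gmt, clusters, enriched_terms)
    mapping = anno.impute_mapping(mapping)
    mp = mapping.weights.copy()
    mp["annotated"] = mapping.annotated
    mp["imputed"] = mapping.imputed
    mp.rename_axis("variant").to_csv(out / "variant_pathway_mapping.tsv", sep="\t")

    ct = anno.celltype_weights(vg, expr)
    ct.rename_axis("variant").to_csv(out / "celltype_weights.tsv", sep="\t")

    usable = mapping.weights.index[mapping.annotated | mapping.imputed]
    path_tests = anno.group_enrichment_tests(
        mapping.weights.loc[usable], groups, cfg.fdr_level
    ).assign(layer="pathway")
    ct_tests = anno.group_enrichment_tests(ct, groups, cfg.fdr_level).assign(
        layer="celltype"
    )
    tests = pd.concat([path_tests, ct_tests], ignore_index=True)
    tests.to_csv(out / "group_tests.tsv", sep="\t", index=False)
    return tests


def _write_report(cfg: PipelineConfig, eff, ied_table, dir_tests, conc, tests) -> Path:
    out = Path(cfg.out_dir)
    lines = ["# Pipeline report", ""]
    lines.append(f"Variants analysed: {len(eff)}")
    lines.append(
        f"FDR<{int(cfg.fdr_level*100)}% longevity associations: "
        f"{', '.join(eff.loc[eff.significant, 'variant']) or 'none'}"
    )
    lines.append("")
    lines.append("## Direction binomial tests")
    for name, t in dir_tests.items():
        lines.append(
            f"- {name}: {t['n_expected']}/{t['n_total']} expected direction, "
            f"p = {t['pvalue']:.4g}"
        )
    lines.append("")
    lines.append("## Group sizes")
    for g, n in ied_table["group"].value_counts().items():
        lines.append(f"- {g}-group: {n}")
    lines.append("")
    lines.append("## Replication concordance")
    for r in conc.itertuples():
        lines.append(
            f"- {r.group_class}: {r.concordant}/{r.total} "
            f"({r.percent:.0f}%), p = {r.pvalue:.3g}"
        )
    lines.append("")
    sig = tests[tests["significant"].fillna(False)]
    lines.append("## Significant within-group annotation calls")
    for r in sig.itertuples():
        lines.append(f"- {r.layer}: {r.group}-group enriched for {r.category} "
                     f"(q = {r.q:.3g})")
    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns a summary dict and writes a manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.simulate:
        paths = stage_simulate(cfg)
    else:
        paths = {
            k: Path(getattr(cfg, k))
            for k in ("vcf", "pheno", "ad_summary", "replication",
                      "variant_gene", "gmt", "similarity", "expression")
        }
        issues = validate_inputs(cfg)
        if issues:
            raise ValidationError("; ".join(issues))

    eff = stage_assoc(cfg, paths)
    table, dir_tests = stage_ied(cfg, eff)
    conc = stage_replicate(cfg, eff, paths)
    tests = stage_annotate(cfg, paths)
    report = _write_report(cfg, eff, table, dir_tests, conc, tests)

    manifest = {
        "config": {k: v for k, v in asdict(cfg).items() if k != "extras"},
        "version": __version__,
        "report_sha256": hashlib.sha256(report.read_bytes()).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "effects": eff,
        "ied": table,
        "direction_tests": dir_tests,
        "concordance": conc,
        "group_tests": tests,
        "manifest": manifest,
    }
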