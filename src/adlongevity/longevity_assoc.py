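"""Per-variant longevity effect estimation in a centenarian case-control design.

The cases are cognitively healthy centenarians and the controls are
population subjects; each variant's effect on longevity is the dosage
log-odds-ratio from a logistic regression adjusted for the first five
genotype principal components. All effect sizes — on Alzheimer's disease
(AD, from published summary statistics) and on longevity (estimated here) —
are expressed with respect to the allele that increases AD risk, so the AD
effect is positive by construction and a *negative* longevity effect is the
"expected" direction.

Uncertainty on the longevity effect comes from a stratified nonparametric
bootstrap (resampling individuals within cases and within controls), whose
replicate standard deviation feeds the downstream effect-direction sampler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .stats_core import ValidationError, fdr_adjust

PC_COLUMNS = ("PC1", "PC2", "PC3", "PC4", "PC5")

MISSING = -1  # sentinel for a missing dosage


class HarmonizationError(ValueError):
    """Alleles in two tables cannot be reconciled by a simple swap."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class CohortGenotypes:
    """Sample-by-variant dosage matrix with phenotype and covariates.

    ``dosages[i, j]`` counts copies of the *counted allele* of variant ``j``
    carried by sample ``i`` (0/1/2, or ``MISSING``). After
    :func:`orient_to_ad_risk` the counted allele is the AD-risk-increasing
    allele for every variant.
    """

    sample_ids: list[str]
    phenotype: np.ndarray            # 1 = case (centenarian), 0 = control
    dosages: np.ndarray              # (n_samples, n_variants) int8
    variant_ids: list[str]
    counted_allele: list[str]        # allele whose copies `dosages` counts
    other_allele: list[str]
    covariates: pd.DataFrame         # indexed like sample_ids, PC columns
    chrom: list[str] = field(default_factory=list)
    pos: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n, v = self.dosages.shape
        if len(self.sample_ids) != n or len(self.phenotype) != n:
            raise ValidationError("sample dimension mismatch")
        if len(self.variant_ids) != v:
            raise ValidationError("variant dimension mismatch")
        if not set(np.unique(self.phenotype)) <= {0, 1}:
            raise ValidationError("phenotype must be binary 0/1")

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.phenotype).sum())

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant {variant_id!r}") from None

    def allele_freq(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Frequency of the counted allele per variant, over `mask` samples."""
        d = self.dosages if mask is None else self.dosages[mask]
        valid = d != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(
                valid.sum(axis=0) > 0,
                np.where(valid, d, 0).sum(axis=0) / (2.0 * valid.sum(axis=0)),
                np.nan,
            )


@dataclass
class FitResult:
    variant: str
    beta: float
    se: float
    pvalue: float
    n_used: int
    converged: bool
    separated: bool


@dataclass
class BootstrapResult:
    variant: str
    betas: np.ndarray          # converged replicate estimates
    se: float                  # SD of converged replicates
    ci_low: float
    ci_high: float
    n_nonconverged: int


@dataclass
class VariantEffectPair:
    """Oriented effect sizes of one variant on AD and on longevity."""

    variant: str
    e_ad: float
    se_ad: float
    e_lgv: float
    se_lgv: float
    p_lgv: float = np.nan
    q_lgv: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    apoe_like: bool = False
    significant: bool = False

    def __post_init__(self) -> None:
        if self.e_ad <= 0:
            raise ValidationError(
                f"{self.variant}: e_ad must be positive after orientation"
            )
        if self.se_ad <= 0 or self.se_lgv <= 0:
            raise ValidationError(f"{self.variant}: standard errors must be positive")


# ---------------------------------------------------------------------------
# loading


def load_cohort(vcf_path: str, pheno_path: str) -> CohortGenotypes:
    """Read genotypes (VCF 4.2, GT field) and a phenotype/covariate TSV.

    The phenotype table must provide ``sample_id``, ``phenotype`` in
    {case, control} and the PC columns; samples are aligned to the VCF
    column order. Dosages count ALT alleles until reoriented.
    """
    from cyvcf2 import VCF

    pheno = pd.read_csv(pheno_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "phenotype", *PC_COLUMNS}
    missing_cols = required - set(pheno.columns)
    if missing_cols:
        raise ValidationError(f"phenotype table missing columns: {sorted(missing_cols)}")
    pheno = pheno.set_index("sample_id")

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in pheno.index]
    if unknown:
        raise ValidationError(f"samples absent from phenotype table: {unknown[:5]}")
    pheno = pheno.loc[samples]

    ids, ref, alt, chrom, pos, rows = [], [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValidationError(f"non-biallelic record at {rec.CHROM}:{rec.POS}")
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        chrom.append(str(rec.CHROM))
        pos.append(int(rec.POS))
        gt = np.asarray(rec.gt_types)  # 0=hom-ref 1=het 2=unknown 3=hom-alt
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        rows.append(dos.astype(np.int8))

    phenotype = (pheno["phenotype"].to_numpy() == "case").astype(np.int8)
    return CohortGenotypes(
        sample_ids=samples,
        phenotype=phenotype,
        dosages=np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), np.int8),
        variant_ids=ids,
        counted_allele=alt,
        other_allele=ref,
        covariates=pheno[list(PC_COLUMNS)].astype(float),
        chrom=chrom,
        pos=pos,
    )


# ---------------------------------------------------------------------------
# harmonization and filtering


def orient_to_ad_risk(
    ad_summary: pd.DataFrame,
    target: "CohortGenotypes | pd.DataFrame",
) -> tuple[pd.DataFrame, "CohortGenotypes | pd.DataFrame"]:
    """Express all effects and dosages relative to the AD-risk allele.

    Variants whose published AD beta is negative have their effect/other
    alleles swapped and the beta negated, so ``beta > 0`` for every variant
    afterwards. The second argument is either a cohort (dosages recoded to
    count the risk allele) or a summary-statistics table with
    ``effect_allele``/``other_allele``/``beta`` columns (betas flipped where
    the alleles are swapped relative to the oriented AD table). The
    operation is idempotent.
    """
    ad = ad_summary.copy().reset_index(drop=True)
    flip = ad["beta"].to_numpy() < 0
    ea = ad["effect_allele"].to_numpy().copy()
    oa = ad["other_allele"].to_numpy().copy()
    ea[flip], oa[flip] = oa[flip], ea[flip].copy()
    ad["effect_allele"], ad["other_allele"] = ea, oa
    ad["beta"] = np.abs(ad["beta"].to_numpy())

    lookup = ad.set_index("id")

    if isinstance(target, CohortGenotypes):
        cohort = target
        dosages = cohort.dosages.copy()
        counted = list(cohort.counted_allele)
        other = list(cohort.other_allele)
        for j, vid in enumerate(cohort.variant_ids):
            if vid not in lookup.index:
                continue
            risk, alt_other = lookup.loc[vid, ["effect_allele", "other_allele"]]
            if counted[j] == risk and other[j] == alt_other:
                continue
            if counted[j] == alt_other and other[j] == risk:
                m = dosages[:, j] != MISSING
                dosages[m, j] = 2 - dosages[m, j]
                counted[j], other[j] = risk, alt_other
            else:
                raise HarmonizationError(
                    f"{vid}: cohort alleles {counted[j]}/{other[j]} do not match "
                    f"summary alleles {risk}/{alt_other}"
                )
        oriented = CohortGenotypes(
            sample_ids=cohort.sample_ids,
            phenotype=cohort.phenotype,
            dosages=dosages,
            variant_ids=cohort.variant_ids,
            counted_allele=counted,
            other_allele=other,
            covariates=cohort.covariates,
            chrom=cohort.chrom,
            pos=cohort.pos,
        )
        return ad, oriented

    table = target.copy().reset_index(drop=True)
    betas = table["beta"].to_numpy(dtype=float).copy()
    t_ea = table["effect_allele"].to_numpy().copy()
    t_oa = table["other_allele"].to_numpy().copy()
    for i, vid in enumerate(table["id"]):
        if vid not in lookup.index:
            continue
        risk, alt_other = lookup.loc[vid, ["effect_allele", "other_allele"]]
        if t_ea[i] == risk and t_oa[i] == alt_other:
            continue
        if t_ea[i] == alt_other and t_oa[i] == risk:
            betas[i] = -betas[i]
            t_ea[i], t_oa[i] = risk, alt_other
        else:
            raise HarmonizationError(
                f"{vid}: table alleles {t_ea[i]}/{t_oa[i]} do not match "
                f"summary alleles {risk}/{alt_other}"
            )
    table["beta"], table["effect_allele"], table["other_allele"] = betas, t_ea, t_oa
    return ad, table


def maf_filter(
    source: "CohortGenotypes | pd.DataFrame",
    threshold: float = 0.01,
) -> tuple[list[str], pd.DataFrame]:
    """Keep variants with minor allele frequency strictly above `threshold`
    in every cohort separately.

    Accepts either a :class:`CohortGenotypes` (frequencies computed within
    cases and within controls) or a manifest-like DataFrame with an ``id``
    column and one or more ``maf*`` frequency columns. Returns the retained
    variant ids and an exclusion log naming each dropped variant, its
    frequencies, and the reason (``low_maf`` or ``monomorphic``).
    """
    if isinstance(source, CohortGenotypes):
        cases = source.phenotype == 1
        freqs = pd.DataFrame(
            {
                "id": source.variant_ids,
                "maf_control": source.allele_freq(~cases),
                "maf_case": source.allele_freq(cases),
            }
        )
    else:
        cols = [c for c in source.columns if c.startswith("maf")]
        if not cols:
            raise ValidationError("manifest has no maf* columns")
        freqs = source[["id", *cols]].copy()

    freq_cols = [c for c in freqs.columns if c != "id"]
    folded = freqs[freq_cols].apply(lambda f: np.minimum(f, 1.0 - f))
    min_maf = folded.min(axis=1)
    mono = (min_maf <= 0) | min_maf.isna()
    low = (~mono) & (min_maf <= threshold)

    retained = freqs.loc[~(mono | low), "id"].tolist()
    log = freqs.loc[mono | low].copy()
    log["reason"] = np.where(mono[mono | low], "monomorphic", "low_maf")
    return retained, log.reset_index(drop=True)


# ---------------------------------------------------------------------------
# logistic fitting


def _irls_logit(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, bool, bool]:
    """Newton/IRLS maximum-likelihood logistic fit.

    Returns (coefficients, standard errors, converged, separated). The
    separation heuristic flags fits whose fitted probabilities all collapse
    to 0/1 on one of the outcome classes or whose coefficients diverge.
    Cross-checked in the test suite against statsmodels GLM.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        # damp degenerate weights so the normal equations stay solvable
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            return beta, np.full(p, np.nan), False, True
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1e-12):
            converged = True
            break
        ll_old = ll
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    separated = bool(np.any(np.abs(beta) > 15) or not np.all(np.isfinite(se)))
    return beta, se, converged and not separated, separated


def _design(cohort: CohortGenotypes, j: int) -> tuple[np.ndarray, np.ndarray]:
    d = cohort.dosages[:, j].astype(float)
    keep = d != MISSING
    X = np.column_stack(
        [
            np.ones(keep.sum()),
            d[keep],
            cohort.covariates.to_numpy()[keep],
        ]
    )
    y = cohort.phenotype[keep].astype(float)
    return X, y


def fit_longevity_effect(cohort: CohortGenotypes, variant_id: str) -> FitResult:
    """Logistic regression of centenarian status on dosage + PC1–PC5.

    Missing dosages are dropped per variant (complete-case). Perfect
    separation yields a flagged estimate, not an exception.
    """
    j = cohort.variant_index(variant_id)
    X, y = _design(cohort, j)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValidationError(f"{variant_id}: need at least 2 samples per class")
    d = X[:, 1]
    if np.all(d == d[0]):
        raise ValidationError(f"{variant_id}: monomorphic in the analysis set")
    beta, se, converged, separated = _irls_logit(X, y)
    b, s = float(beta[1]), float(se[1])
    p = float(2.0 * _st.norm.sf(abs(b / s))) if s > 0 and np.isfinite(s) else np.nan
    return FitResult(variant_id, b, s, p, int(len(y)), converged, separated)


def bootstrap_effects(
    cohort: CohortGenotypes,
    variant_id: str,
    n_boot: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Stratified bootstrap of the longevity log-OR.

    Individuals are resampled with replacement within cases and within
    controls, preserving the fixed case-control design; the model is refit
    per replicate. The replicate SD is the bootstrap SE and the 2.5/97.5
    percentiles form the confidence interval. Non-convergent replicates are
    excluded from the summaries and counted.
    """
    if n_boot < 50:
        raise ValidationError("n_boot must be at least 50")
    j = cohort.variant_index(variant_id)
    X, y = _design(cohort, j)
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    betas = np.empty(n_boot)
    bad = 0
    for b in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(case_idx, size=case_idx.size, replace=True),
                rng.choice(ctrl_idx, size=ctrl_idx.size, replace=True),
            ]
        )
        coef, _, converged, separated = _irls_logit(X[idx], y[idx])
        if converged and not separated:
            betas[b] = coef[1]
        else:
            betas[b] = np.nan
            bad += 1
    ok = betas[np.isfinite(betas)]
    if bad > 0.10 * n_boot:
        warnings.warn(
            f"{variant_id}: {bad}/{n_boot} bootstrap replicates did not converge"
        )
    lo, hi = np.percentile(ok, [2.5, 97.5])
    return BootstrapResult(
        variant_id, ok, float(ok.std(ddof=1)), float(lo), float(hi), bad
    )


def adjust_and_call(
    fits: list[FitResult],
    boots: list[BootstrapResult],
    ad_oriented: pd.DataFrame,
    apoe_like: set[str] | None = None,
    fdr_level: float = 0.05,
) -> list[VariantEffectPair]:
    """Assemble oriented effect pairs with FDR-adjusted significance calls."""
    if not fits:
        raise ValidationError("no fitted effects to adjust")
    apoe_like = apoe_like or set()
    ad = ad_oriented.set_index("id")
    q = fdr_adjust([f.pvalue for f in fits]).values
    pairs = []
    for f, bt, qv in zip(fits, boots, q):
        pairs.append(
            VariantEffectPair(
                variant=f.variant,
                e_ad=float(ad.loc[f.variant, "beta"]),
                se_ad=float(ad.loc[f.variant, "se"]),
                e_lgv=f.beta,
                se_lgv=bt.se,
                p_lgv=f.pvalue,
                q_lgv=float(qv),
                ci_low=bt.ci_low,
                ci_high=bt.ci_high,
                apoe_like=f.variant in apoe_like,
                significant=bool(qv < fdr_level),
            )
        )
    return pairs


def effects_frame(pairs: list[VariantEffectPair]) -> pd.DataFrame:
    """Flat table of effect pairs (the module's main output artifact)."""
    return pd.DataFrame(
        {
            "variant": [p.variant for p in pairs],
            "e_ad": [p.e_ad for p in pairs],
            "se_ad": [p.se_ad for p in pairs],
            "e_lgv": [p.e_lgv for p in pairs],
            "se_lgv": [p.se_lgv for p in pairs],
            "p": [p.p_lgv for p in pairs],
            "q": [p.q_lgv for p in pairs],
            "ci_low": [p.ci_low for p in pairs],
            "ci_high": [p.ci_high for p in pairs],
            "apoe_like": [p.apoe_like for p in pairs],
            "significant": [p.significant for p in pairs],
        }
    )
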