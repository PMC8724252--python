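"""Harmonization, filtering, logistic fitting and bootstrap behaviour."""

import math

import numpy as np
import pandas as pd
import pytest

from adlongevity import synthetic_data as synth
from adlongevity.longevity_assoc import (
    MISSING,
    CohortGenotypes,
    HarmonizationError,
    VariantEffectPair,
    _irls_logit,
    adjust_and_call,
    bootstrap_effects,
    fit_longevity_effect,
    maf_filter,
    orient_to_ad_risk,
)
from adlongevity.stats_core import ValidationError

from conftest import single_variant_cohort


def _toy_cohort(dosages, phenotype, counted="A", other="G"):
    n = len(phenotype)
    return CohortGenotypes(
        sample_ids=[f"s{i}" for i in range(n)],
        phenotype=np.asarray(phenotype, dtype=np.int8),
        dosages=np.asarray(dosages, dtype=np.int8).reshape(n, -1),
        variant_ids=["v1"],
        counted_allele=[counted],
        other_allele=[other],
        covariates=pd.DataFrame(
            np.random.default_rng(0).standard_normal((n, 5)),
            columns=["PC1", "PC2", "PC3", "PC4", "PC5"],
        ),
        chrom=["1"],
        pos=[100],
    )


# ---------------------------------------------------------------------------
# orientation


def test_orientation_flips_negative_betas():
    ad = pd.DataFrame(
        {
            "id": ["v1"],
            "effect_allele": ["A"],
            "other_allele": ["G"],
            "beta": [-0.10],
            "se": [0.02],
        }
    )
    cohort = _toy_cohort([0, 1, 2, 2], [1, 0, 1, 0])
    oriented_ad, oriented = orient_to_ad_risk(ad, cohort)
    assert oriented_ad.loc[0, "beta"] == pytest.approx(0.10)
    assert oriented_ad.loc[0, "effect_allele"] == "G"
    assert list(oriented.dosages[:, 0]) == [2, 1, 0, 0]
    # idempotence
    ad2, oriented2 = orient_to_ad_risk(oriented_ad, oriented)
    assert ad2.loc[0, "beta"] == pytest.approx(0.10)
    assert list(oriented2.dosages[:, 0]) == list(oriented.dosages[:, 0])


def test_orientation_leaves_positive_betas_untouched():
    ad = pd.DataFrame(
        {"id": ["v1"], "effect_allele": ["A"], "other_allele": ["G"],
         "beta": [0.25], "se": [0.02]}
    )
    cohort = _toy_cohort([0, 1, 2], [1, 0, 1])
    oriented_ad, oriented = orient_to_ad_risk(ad, cohort)
    assert oriented_ad.loc[0, "beta"] == 0.25
    assert list(oriented.dosages[:, 0]) == [0, 1, 2]


def test_orientation_mismatch_raises():
    ad = pd.DataFrame(
        {"id": ["v1"], "effect_allele": ["A"], "other_allele": ["C"],
         "beta": [0.25], "se": [0.02]}
    )
    with pytest.raises(HarmonizationError, match="v1"):
        orient_to_ad_risk(ad, _toy_cohort([0, 1], [1, 0]))


def test_orientation_invariance_of_the_fit():
    """Relabelling a variant's alleles everywhere leaves e_lgv unchanged."""
    cohort = single_variant_cohort(-0.4, maf=0.25, seed=3, n_cases=150,
                                   n_controls=600)
    ad = pd.DataFrame(
        {"id": ["v1"], "effect_allele": ["A"], "other_allele": ["G"],
         "beta": [0.1], "se": [0.02]}
    )
    _, straight = orient_to_ad_risk(ad, cohort)
    b1 = fit_longevity_effect(straight, "v1").beta

    flipped = CohortGenotypes(
        sample_ids=cohort.sample_ids,
        phenotype=cohort.phenotype,
        dosages=(2 - cohort.dosages).astype(np.int8),
        variant_ids=cohort.variant_ids,
        counted_allele=cohort.other_allele,
        other_allele=cohort.counted_allele,
        covariates=cohort.covariates,
        chrom=cohort.chrom,
        pos=cohort.pos,
    )
    flipped_ad = ad.assign(effect_allele="G", other_allele="A", beta=-0.1)
    _, reoriented = orient_to_ad_risk(flipped_ad, flipped)
    b2 = fit_longevity_effect(reoriented, "v1").beta
    assert b1 == pytest.approx(b2, abs=1e-10)


# ---------------------------------------------------------------------------
# MAF filter


def test_maf_filter_boundary_and_monomorphic():
    manifest = pd.DataFrame(
        {
            "id": ["a", "b", "c", "d"],
            "maf_control": [0.01, 0.3, 0.0, 0.011],
            "maf_case": [0.05, 0.3, 0.0, 0.02],
        }
    )
    retained, log = maf_filter(manifest, threshold=0.01)
    assert retained == ["b", "d"]
    reasons = dict(zip(log["id"], log["reason"]))
    assert reasons == {"a": "low_maf", "c": "monomorphic"}


def test_maf_filter_on_cohort_counts_each_cohort():
    # frequency fine in controls but monomorphic in cases -> dropped
    dosages = np.array([[0], [0], [1], [1], [2], [0]], dtype=np.int8)
    phen = [1, 1, 0, 0, 0, 0]
    cohort = _toy_cohort(dosages, phen)
    retained, log = maf_filter(cohort, threshold=0.01)
    assert retained == []
    assert log.loc[0, "reason"] == "monomorphic"


def test_maf_filter_all_common():
    manifest = pd.DataFrame({"id": list("abc"), "maf_control": [0.3, 0.3, 0.3]})
    retained, log = maf_filter(manifest)
    assert retained == list("abc") and log.empty


# ---------------------------------------------------------------------------
# logistic fit


def test_irls_matches_closed_form_allelic_or():
    """With a binary covariate and no PCs the MLE equals the 2x2 log-OR."""
    # 30 exposed cases, 20 exposed controls, 10 unexposed cases, 40 unexposed
    d = np.array([1] * 50 + [0] * 50, dtype=float)
    y = np.array([1] * 30 + [0] * 20 + [1] * 10 + [0] * 40, dtype=float)
    X = np.column_stack([np.ones(100), d])
    beta, se, converged, separated = _irls_logit(X, y)
    expected = math.log((30 * 40) / (20 * 10))
    assert converged and not separated
    assert beta[1] == pytest.approx(expected, abs=1e-6)
    expected_se = math.sqrt(1 / 30 + 1 / 20 + 1 / 10 + 1 / 40)
    assert se[1] == pytest.approx(expected_se, rel=1e-4)


def test_irls_matches_statsmodels(small_cohort):
    import statsmodels.api as sm

    from adlongevity.longevity_assoc import _design

    X, y = _design(small_cohort, 0)
    ours = _irls_logit(X, y)
    ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(ours[0], ref.params, atol=1e-6)
    np.testing.assert_allclose(ours[1], ref.bse, rtol=1e-4)


def test_fit_recovers_planted_effect(small_cohort):
    fit = fit_longevity_effect(small_cohort, "v1")
    assert fit.converged
    assert fit.beta == pytest.approx(-0.3, abs=0.25)
    assert fit.se > 0 and 0 <= fit.pvalue <= 1


def test_fit_null_pvalues_are_calibrated():
    """Type-I error of the Wald test stays near the nominal 5%."""
    n_seeds = 400
    hits = 0
    for s in range(n_seeds):
        cohort = single_variant_cohort(0.0, maf=0.2, seed=s)
        if fit_longevity_effect(cohort, "v1").pvalue < 0.05:
            hits += 1
    assert 0.02 <= hits / n_seeds <= 0.08


def test_perfect_separation_is_flagged_not_raised():
    d = np.array([2] * 10 + [0] * 10, dtype=np.int8)
    phen = [1] * 10 + [0] * 10
    cohort = _toy_cohort(d, phen)
    fit = fit_longevity_effect(cohort, "v1")
    assert fit.separated and not fit.converged


def test_case_control_swap_flips_the_sign(small_cohort):
    fit = fit_longevity_effect(small_cohort, "v1")
    swapped = CohortGenotypes(
        sample_ids=small_cohort.sample_ids,
        phenotype=(1 - small_cohort.phenotype).astype(np.int8),
        dosages=small_cohort.dosages,
        variant_ids=small_cohort.variant_ids,
        counted_allele=small_cohort.counted_allele,
        other_allele=small_cohort.other_allele,
        covariates=small_cohort.covariates,
        chrom=small_cohort.chrom,
        pos=small_cohort.pos,
    )
    fit2 = fit_longevity_effect(swapped, "v1")
    assert fit.beta == pytest.approx(-fit2.beta, abs=1e-6)


def test_missing_dosages_are_dropped(small_cohort):
    dosages = small_cohort.dosages.copy()
    dosages[:10, 0] = MISSING
    cohort = CohortGenotypes(
        sample_ids=small_cohort.sample_ids,
        phenotype=small_cohort.phenotype,
        dosages=dosages,
        variant_ids=small_cohort.variant_ids,
        counted_allele=small_cohort.counted_allele,
        other_allele=small_cohort.other_allele,
        covariates=small_cohort.covariates,
        chrom=small_cohort.chrom,
        pos=small_cohort.pos,
    )
    fit = fit_longevity_effect(cohort, "v1")
    assert fit.n_used == len(small_cohort.sample_ids) - 10


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_is_deterministic(small_cohort):
    a = bootstrap_effects(small_cohort, "v1", n_boot=60, seed=9)
    b = bootstrap_effects(small_cohort, "v1", n_boot=60, seed=9)
    np.testing.assert_array_equal(a.betas, b.betas)


def test_bootstrap_se_close_to_wald(small_cohort):
    fit = fit_longevity_effect(small_cohort, "v1")
    boot = bootstrap_effects(small_cohort, "v1", n_boot=500, seed=4)
    assert boot.se == pytest.approx(fit.se, rel=0.25)
    assert boot.ci_low < fit.beta < boot.ci_high


def test_bootstrap_minimum_replicates(small_cohort):
    with pytest.raises(ValidationError):
        bootstrap_effects(small_cohort, "v1", n_boot=10)


# ---------------------------------------------------------------------------
# FDR calls


def _pair(v, e_lgv, p, apoe=False):
    return VariantEffectPair(
        variant=v, e_ad=0.1, se_ad=0.02, e_lgv=e_lgv, se_lgv=0.08, p_lgv=p
    )


def test_single_variant_q_equals_p():
    from adlongevity.longevity_assoc import BootstrapResult, FitResult

    fits = [FitResult("v1", -0.3, 0.1, 0.04, 100, True, False)]
    boots = [BootstrapResult("v1", np.array([-0.3]), 0.1, -0.5, -0.1, 0)]
    ad = pd.DataFrame({"id": ["v1"], "beta": [0.1], "se": [0.02]})
    pairs = adjust_and_call(fits, boots, ad)
    assert pairs[0].q_lgv == pytest.approx(0.04)
    assert pairs[0].significant


def test_planted_large_effects_are_the_only_flags():
    """Two variants with |beta_lgv| = 1 among 38 dominate the FDR calls."""
    panel = synth.default_panel()
    common = [v for v in panel if v.maf_control > 0.01]
    boosted = []
    for i, v in enumerate(common):
        b = -1.0 if v.apoe_like else (0.02 if v.beta_lgv > 0 else -0.02)
        boosted.append(synth.VariantSpec(**{**vars(v), "beta_lgv": b}))
    hits = 0
    n_seeds = 10
    for s in range(n_seeds):
        cfg = synth.SimulationConfig(variants=tuple(boosted), seed=600 + s)
        cohort = synth.simulate_cohort(cfg)
        flagged = set()
        from adlongevity.longevity_assoc import BootstrapResult, FitResult

        fits = [fit_longevity_effect(cohort, v.id) for v in boosted]
        boots = [
            BootstrapResult(v.id, np.array([f.beta]), max(f.se, 1e-3),
                            f.beta - 2 * f.se, f.beta + 2 * f.se, 0)
            for v, f in zip(boosted, fits)
        ]
        ad = pd.DataFrame(
            {"id": [v.id for v in boosted], "beta": [v.beta_ad for v in boosted],
             "se": [v.se_ad for v in boosted]}
        )
        pairs = adjust_and_call(fits, boots, ad)
        flagged = {p.variant for p in pairs if p.significant}
        want = {v.id for v in boosted if v.apoe_like}
        if flagged == want:
            hits += 1
    assert hits >= 9
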