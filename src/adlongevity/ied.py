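"""Imbalance of effect direction (IED): the study's core statistic.

A variant with oriented effects (e_ad > 0 on Alzheimer's disease, e_lgv on
longevity) is a point in the (AD, longevity) effect plane. Its normalized
angle

    alpha = atan2(e_lgv, e_ad) / (pi / 2)

captures the *imbalance* between the two effects: alpha < 0 means the
expected direction (risk allele lowers the odds of becoming a cognitively
healthy centenarian), alpha > 0 the unexpected direction. Two anchors give
the grouping cutoffs their meaning: alpha = -1/2 exactly when the longevity
effect mirrors the AD effect (e_lgv = -e_ad), and alpha = 0 exactly when
there is no longevity effect.

Because both effects are noisy estimates, each variant gets a *sampling
distribution* of alpha: S independent Gaussian draws centred on the point
estimates with the estimated standard errors, each mapped through the
angle. Variants are summarised by the median alpha and grouped:

    Longevity-group   median <= -1/2   (longevity effect dominates)
    AD-group          -1/2 < median <= 0
    Unex-group        median > 0       (unexpected direction)

Sampled AD effects may cross zero for weakly-estimated variants; the angle
is then outside [-1, 1] (its full range is (-2, 2]). Draws are kept at
their raw value rather than clamped so the distribution honestly shows the
sign-flip mass; grouping uses the median only.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .longevity_assoc import VariantEffectPair
from .stats_core import CountPair, ValidationError, binom_exact_two_sided

GROUP_LONGEVITY = "Longevity"
GROUP_AD = "AD"
GROUP_UNEX = "Unex"


@dataclass
class IedDistribution:
    variant: str
    alphas: np.ndarray
    median: float
    frac_unexpected: float
    group: str


def ied_angle(e_ad: float, e_lgv: float) -> float:
    """Normalized angle of an (e_ad, e_lgv) effect point.

    Scale-invariant and, for e_ad > 0, strictly increasing and
    antisymmetric in e_lgv.
    """
    if e_ad == 0.0 and e_lgv == 0.0:
        raise ValidationError("angle undefined at the origin (0, 0)")
    return float(np.arctan2(e_lgv, e_ad) / (np.pi / 2.0))


def _variant_rng(seed: int, variant_id: str) -> np.random.Generator:
    # stable per-variant substream: adding or removing a variant never
    # perturbs the draws of any other variant
    return np.random.default_rng([seed, zlib.crc32(variant_id.encode())])


def build_ied_distribution(
    pair: VariantEffectPair, n_samples: int = 10_000, seed: int = 0
) -> IedDistribution:
    """Sample the IED distribution of one variant.

    Draws ``n_samples`` independent pairs from Normal(e_ad, se_ad²) ×
    Normal(e_lgv, se_lgv²) and maps each through :func:`ied_angle`.
    Deterministic given (seed, variant id).
    """
    if n_samples < 100:
        raise ValidationError("n_samples must be at least 100")
    if pair.se_ad <= 0 or pair.se_lgv <= 0:
        raise ValidationError(f"{pair.variant}: standard errors must be positive")
    rng = _variant_rng(seed, pair.variant)
    e_ad = rng.normal(pair.e_ad, pair.se_ad, n_samples)
    e_lgv = rng.normal(pair.e_lgv, pair.se_lgv, n_samples)
    alphas = np.arctan2(e_lgv, e_ad) / (np.pi / 2.0)
    median = float(np.median(alphas))
    return IedDistribution(
        variant=pair.variant,
        alphas=alphas,
        median=median,
        frac_unexpected=float(np.mean(alphas > 0.0)),
        group=assign_group(median),
    )


def assign_group(median: float) -> str:
    """Three-way grouping by median IED with closed cutoffs at -1/2 and 0."""
    if not np.isfinite(median):
        raise ValidationError("median must be finite")
    if median <= -0.5:
        return GROUP_LONGEVITY
    if median <= 0.0:
        return GROUP_AD
    return GROUP_UNEX


@dataclass
class DirectionTest:
    n_expected: int
    n_total: int
    pvalue: float


def direction_test(
    pairs: list[VariantEffectPair],
) -> tuple[DirectionTest, DirectionTest]:
    """Binomial tests on the count of expected-direction variants.

    A variant is in the expected direction when its point-estimate
    longevity effect is negative (the AD effect is positive by
    orientation). Under the null each direction is equally likely
    (Bernoulli p = 0.5). Returns the test over all variants and the test
    excluding APOE-flagged variants.
    """
    if not pairs:
        raise ValidationError("no classified variants")

    def _test(sub: list[VariantEffectPair]) -> DirectionTest:
        k = sum(1 for p in sub if p.e_lgv < 0.0)
        n = len(sub)
        pv = binom_exact_two_sided(CountPair(k, n), 0.5) if n else float("nan")
        return DirectionTest(k, n, pv)

    return _test(pairs), _test([p for p in pairs if not p.apoe_like])


def ied_table(dists: list[IedDistribution]) -> "pd.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame(
        {
            "variant": [d.variant for d in dists],
            "median": [d.median for d in dists],
            "frac_unexpected": [d.frac_unexpected for d in dists],
            "group": [d.group for d in dists],
        }
    )
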