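"""Statistical primitives shared by every stage of the pipeline.

Everything here is a thin, validated façade over scipy/statsmodels with the
exact conventions the rest of the package relies on:

* FDR correction is Benjamini–Hochberg step-up (the standard reading of
  "FDR" in GWAS follow-up work), applied across whatever panel the caller
  assembles.
* The binomial direction test is exact and two-sided with the
  minimum-likelihood summation rule, which at p0 = 0.5 equals the doubled
  smaller tail (capped at 1).
* Rank-sum comparisons use the exact Mann–Whitney null when the combined
  sample is small and tie-free, and the tie-corrected normal approximation
  with continuity correction otherwise; the result records which path ran.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class PValueVector:
    """An ordered collection of p-values with aligned labels.

    Labels must be unique so that error messages and downstream joins can
    name the offending test.
    """

    values: tuple[float, ...]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        labs = tuple(self.labels) if self.labels else tuple(
            f"p{i}" for i in range(len(vals))
        )
        if len(vals) == 0:
            raise ValidationError("PValueVector requires at least one value")
        if len(labs) != len(vals):
            raise ValidationError("labels and values must have equal length")
        if len(set(labs)) != len(labs):
            raise ValidationError("labels must be unique")
        for lab, v in zip(labs, vals):
            if not (0.0 <= v <= 1.0) or not np.isfinite(v):
                raise ValidationError(
                    f"p-value for {lab!r} is {v}, outside [0, 1]"
                )
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", labs)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CountPair:
    """Successes out of trials, e.g. variants with the expected direction."""

    successes: int
    trials: int

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValidationError("trials must be a positive integer")
        if not (0 <= self.successes <= self.trials):
            raise ValidationError(
                f"successes={self.successes} outside [0, trials={self.trials}]"
            )


@dataclass(frozen=True)
class RankSumResult:
    pvalue: float
    statistic: float
    exact: bool  # True when the exact enumeration path was used


# ---------------------------------------------------------------------------
# operations


def fdr_adjust(p: PValueVector | Sequence[float]) -> PValueVector:
    """Benjamini–Hochberg step-up adjustment, order-preserving.

    Returns a :class:`PValueVector` in the same order as the input; adjusted
    values are monotone in the raw values and never smaller than them.
    """
    if not isinstance(p, PValueVector):
        p = PValueVector(tuple(p))
    adjusted = multipletests(p.values, alpha=0.05, method="fdr_bh")[1]
    return PValueVector(tuple(float(q) for q in adjusted), p.labels)


def binom_exact_two_sided(c: CountPair, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value (minimum-likelihood summation).

    Sums P(k') over all counts k' whose point probability does not exceed
    that of the observed count. For p0 = 0.5 this equals the doubled smaller
    tail, capped at 1.
    """
    if not isinstance(c, CountPair):
        c = CountPair(*c)
    if not (0.0 < p0 < 1.0):
        raise ValidationError(f"null probability p0={p0} must lie in (0, 1)")
    return float(
        _st.binomtest(c.successes, c.trials, p0, alternative="two-sided").pvalue
    )


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_max_n: int = 25,
) -> RankSumResult:
    """Wilcoxon/Mann–Whitney rank-sum test.

    Uses the exact null distribution when the combined sample size is at
    most ``exact_max_n`` and there are no ties across the pooled data;
    otherwise the normal approximation with midranks, tie-corrected
    variance, and continuity correction. ``RankSumResult.exact`` records
    which path was taken.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    use_exact = (pooled.size <= exact_max_n) and not has_ties
    res = _st.mannwhitneyu(
        x, y, alternative=alternative,
        method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    return RankSumResult(float(res.pvalue), float(res.statistic), use_exact)


def hypergeom_tail(
    overlap: int, list_size: int, term_size: int, background_size: int
) -> float:
    """Upper-tail P(X >= overlap) for the hypergeometric enrichment null.

    ``X`` counts how many of ``list_size`` genes drawn without replacement
    from ``background_size`` fall inside a term of ``term_size`` genes.
    """
    if background_size < 1:
        raise ValidationError("background_size must be positive")
    if term_size > background_size or list_size > background_size:
        raise ValidationError(
            "term_size and list_size cannot exceed background_size"
        )
    if not (0 <= overlap <= min(list_size, term_size)):
        raise ValidationError(
            f"overlap={overlap} inconsistent with list_size={list_size}, "
            f"term_size={term_size}"
        )
    return float(_st.hypergeom.sf(overlap - 1, background_size, term_size, list_size))


def significant(q: PValueVector | Sequence[float], level: float = 0.05) -> np.ndarray:
    """Boolean significance calls at a strict FDR level (q < level)."""
    vals = q.values if isinstance(q, PValueVector) else q
    return np.asarray(vals, dtype=float) < level
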