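"""Direction concordance against an external parental-longevity GWAS.

The replication layer asks a deliberately modest question: do the variants
we called expected/unexpected in the centenarian cohort show the same
*direction* of effect in an independent proxy-longevity GWAS? Magnitudes
are ignored — proxy designs (parental age at death regressed on offspring
genotype) are on a different effect scale — so concordance is a sign
comparison after orienting the replication betas to the AD-risk allele,
and chance agreement is a fair coin (binomial p0 = 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ied import GROUP_UNEX, IedDistribution
from .longevity_assoc import VariantEffectPair, orient_to_ad_risk
from .stats_core import CountPair, ValidationError, binom_exact_two_sided, fdr_adjust


@dataclass
class ConcordanceTest:
    group_class: str          # "expected" or "unexpected"
    concordant: int
    total: int
    percent: float
    pvalue: float


def align_replication(
    ad_oriented: pd.DataFrame, replication: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Match replication records to the panel and orient them to the risk allele.

    Matching is by variant id, with a chrom:pos + allele-pair fallback for
    records whose id differs between resources. Returns the oriented
    records (with ``direction_expected = beta < 0``) and the list of panel
    variants with no replication record.
    """
    rep = replication.copy().reset_index(drop=True)
    panel_ids = list(ad_oriented["id"])

    if not rep.empty and "id" in rep.columns:
        by_id = rep["id"].isin(panel_ids)
    else:
        by_id = pd.Series(False, index=rep.index)
    unmatched_rows = rep.loc[~by_id]
    if not unmatched_rows.empty and {"chrom", "pos"} <= set(rep.columns):
        key = ad_oriented.set_index(
            ad_oriented["chrom"].astype(str) + ":" + ad_oriented["pos"].astype(str)
        )["id"]
        for i in unmatched_rows.index:
            k = f"{rep.at[i, 'chrom']}:{rep.at[i, 'pos']}"
            if k in key.index:
                hit = key.loc[[k]]
                if len(hit) > 1:
                    raise ValidationError(f"ambiguous positional match at {k}")
                rep.at[i, "id"] = hit.iloc[0]
                by_id.at[i] = True
    matched = rep.loc[by_id].reset_index(drop=True)

    if matched.empty:
        return matched.assign(direction_expected=pd.Series(dtype=bool)), panel_ids

    _, oriented = orient_to_ad_risk(ad_oriented, matched)
    oriented["direction_expected"] = oriented["beta"] < 0.0
    missing = [v for v in panel_ids if v not in set(oriented["id"])]
    return oriented, missing


def concordance_summary(
    dists: list[IedDistribution],
    records: pd.DataFrame,
) -> list[ConcordanceTest]:
    """Direction agreement between the study's groups and the replication layer.

    Expected-direction variants (Longevity- and AD-groups) are concordant
    when the replication beta is also negative; Unex-group variants when it
    is also positive. Each class's concordant count is tested against a
    fair-coin binomial null.
    """
    if records.empty:
        raise ValidationError("no matched replication records")
    group_of = {d.variant: d.group for d in dists}
    rec = records.set_index("id")

    out = []
    for cls, want_expected in (("expected", True), ("unexpected", False)):
        ids = [
            v
            for v, g in group_of.items()
            if (g != GROUP_UNEX) == want_expected and v in rec.index
        ]
        conc = sum(
            1 for v in ids if bool(rec.at[v, "direction_expected"]) == want_expected
        )
        total = len(ids)
        pv = binom_exact_two_sided(CountPair(conc, total), 0.5) if total else np.nan
        pct = 100.0 * conc / total if total else np.nan
        out.append(ConcordanceTest(cls, conc, total, pct, pv))
    return out


def replication_significance(
    records: pd.DataFrame, fdr_level: float = 0.05
) -> pd.DataFrame:
    """FDR-adjust replication p-values across the looked-up panel only."""
    if "p" not in records.columns:
        raise ValidationError("replication records carry no p column")
    out = records.copy()
    out["q"] = fdr_adjust(list(out["p"])).values
    out["significant"] = out["q"] < fdr_level
    return out


def forest_table(
    pairs: list[VariantEffectPair], records: pd.DataFrame
) -> pd.DataFrame:
    """Long-format effects table (study + replication) for reporting."""
    study = pd.DataFrame(
        {
            "variant": [p.variant for p in pairs],
            "source": "centenarian_study",
            "beta": [p.e_lgv for p in pairs],
            "se": [p.se_lgv for p in pairs],
        }
    )
    rep = records.rename(columns={"id": "variant"})[["variant", "beta", "se"]].assign(
        source="parental_longevity_gwas"
    )
    return pd.concat([study, rep], ignore_index=True)[
        ["variant", "source", "beta", "se"]
    ]
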