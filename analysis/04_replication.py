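#!/usr/bin/env python
"""Test direction concordance against the parental-longevity layer.

Aligns the replication summary statistics (available for 34 of the 38
variants) to the AD-risk allele, counts direction agreement within the
expected-direction (Longevity+AD) and unexpected-direction (Unex) classes,
tests each count against a fair-coin binomial null, and FDR-adjusts the
replication p-values across the looked-up panel.
"""

from pathlib import Path

import pandas as pd

from adlongevity.pipeline import PipelineConfig, stage_replicate

ROOT = Path(__file__).resolve().parents[1]
SEED = 2026

cfg = PipelineConfig(out_dir=str(ROOT / "scratch" / "run"), seed=SEED)
data = Path(cfg.out_dir) / "data"
eff = pd.read_csv(ROOT / "results" / "longevity_effects.tsv", sep="\t")
conc = stage_replicate(cfg, eff, {
    "ad_summary": data / "ad_summary.tsv",
    "replication": data / "replication.tsv",
})

results = ROOT / "results"
conc.to_csv(results / "replication_concordance.tsv", sep="\t", index=False)
rec = pd.read_csv(Path(cfg.out_dir) / "replication_records.tsv", sep="\t")
rec.to_csv(results / "replication_records.tsv", sep="\t", index=False)

print(f"replication records matched: {len(rec)} (missing: {int(conc['n_missing'][0])})")
for r in conc.itertuples():
    print(f"  {r.group_class}: {r.concordant}/{r.total} concordant "
          f"({r.percent:.0f}%), binomial p = {r.pvalue:.3g}")
print(f"FDR<5% in the replication layer: "
      f"{', '.join(rec.loc[rec['significant'], 'id']) or 'none'}")
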