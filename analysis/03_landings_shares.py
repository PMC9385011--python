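"""Filter landings receipts and derive per-community revenue shares.

Applies the cascade (confidentiality cut, small-miscellaneous drop,
unidentified-group expansion, top-90%-by-weight retention) and writes the
revenue shares p_{i,c} used to weight species risk into community exposure.
"""

import pandas as pd

from coastvuln.config import load_config
from coastvuln.io import read_bundle, write_table
from coastvuln.landings import prepare_revenue_shares

cfg = load_config("results/run_config.yaml")
bundle = read_bundle("scratch/inputs")
scored = set(pd.read_csv("results/eco_scores_per_species.csv")["species"])
shares, log = prepare_revenue_shares(
    bundle.receipts, group_map=bundle.group_map, scored_species=scored,
    confidential_threshold=cfg.thresholds.confidential,
    misc_threshold=cfg.thresholds.misc,
    top_share=cfg.thresholds.top_share,
    weighting=cfg.policies.share_weighting)
write_table(shares, "results/revenue_shares.csv")

print(f"{shares['community'].nunique()} communities with shares over "
      f"{shares['species'].nunique()} species")
print(f"removed for confidentiality: {log['removed_confidential'] or 'none'}")
print(f"flagged for large miscellaneous catch: {log['flagged_misc'] or 'none'}")
print("per-community share sums all equal 1:",
      bool(shares.groupby('community')['p'].sum().round(9).eq(1.0).all()))
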