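"""Community exposure, sensitivity, and risk.

Weights species risk by revenue shares (percent-ranked to E), percent-ranks
the reliance index to S, and combines them as R = sqrt(E^2 + S^2).
"""

import pandas as pd

from coastvuln.community import community_exposure, community_risk, community_sensitivity
from coastvuln.io import read_bundle, write_table

bundle = read_bundle("scratch/inputs")
theta = pd.read_csv("results/eco_scores_per_species.csv")
shares = pd.read_csv("results/revenue_shares.csv")

expo = community_exposure(theta, shares)
sens = community_sensitivity(bundle.reliance)
scores = community_risk(expo.merge(sens, on="community"))
write_table(scores, "results/community_risk.csv")

top = scores.nlargest(3, "R")
print("highest community risk:")
for _, row in top.iterrows():
    print(f"  {row['community']}: R={row['R']:.3f} "
          f"(E={row['E']:.2f}, S={row['S']:.2f})")
n_zero = int((scores["S"] == 0).sum())
print(f"{n_zero} communities tied at the lowest reliance (S = 0)")
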