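"""Adaptive capacity from tract-level social indicators.

Averages the 15 metrics from tracts to communities, percent-ranks each
metric (reversing per-capita income), sums, and re-ranks into AC in [0, 1]
(1 = least able to adapt). Also reports which metrics correlate most with
the final index.
"""

from coastvuln.adaptive import (
    composite_ac,
    rank_and_reverse,
    theme_correlations,
    tracts_to_communities,
)
from coastvuln.io import read_bundle, write_table

bundle = read_bundle("scratch/inputs")
comm_metrics = tracts_to_communities(bundle.tracts, bundle.mapping)
ranked = rank_and_reverse(comm_metrics)
ac = composite_ac(ranked)
corr = theme_correlations(ranked, ac)
write_table(ac, "results/adaptive_capacity.csv", index=True)
write_table(corr.to_frame(), "results/ac_correlations.csv", index=True)

print(f"adaptive capacity computed for {len(ac)} communities")
print("metrics most correlated with low adaptive capacity:")
for name, r in corr.drop([c for c in corr.index if c.startswith("theme_")]) \
        .nlargest(3).items():
    print(f"  {name}: r={r:.2f}")
themes = corr[[c for c in corr.index if c.startswith("theme_")]]
print(f"dominant theme: {themes.idxmax()} (r={themes.max():.2f})")
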