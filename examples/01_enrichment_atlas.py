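"""Build an organ-enrichment atlas from a simulated developmental RPKM matrix.

Simulates a 2,000-gene x 7-organ x 14-stage atlas with 50 planted
organ-enriched genes per organ, then calls each gene enriched in at most one
organ from its per-organ mean expression.
"""

from regdiscover.enrichment import call_enrichment
from regdiscover.synthetic_data import AtlasSimConfig, simulate_atlas

atlas, truth = simulate_atlas(AtlasSimConfig(seed=1))
calls = call_enrichment(atlas)

counts: dict[str, int] = {}
for c in calls:
    if c.organ:
        counts[c.organ] = counts.get(c.organ, 0) + 1

print("enriched genes per organ (planted: 50 each):")
for organ, n in counts.items():
    print(f"  {organ:<12s} {n}")

called = {c.gene: c.organ for c in calls if c.organ}
agree = sum(1 for g, o in truth.enriched.items() if called.get(g) == o)
print(f"recovered {agree}/{len(truth.enriched)} planted assignments, "
      f"{sum(1 for g in called if g not in truth.enriched)} false calls")
# Each count is the number of genes whose top-organ mean clears the
# expression floor at >= 2-fold over the runner-up organ.
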