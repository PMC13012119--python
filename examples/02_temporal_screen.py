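"""Screen cerebellum-enriched regulators for perinatal-high candidates and
classify them by outgroup (lamprey) evidence.

The screen keeps genes with mean RPKM > 1 and a P0/P63 expression ratio > 8;
candidates are then labeled type I (related non-orthologous outgroup
counterpart), type II (no similar outgroup gene) or conserved.
"""

from regdiscover.evo_classify import OrthologEvidence, category_counts, classify_candidates
from regdiscover.synthetic_data import AtlasSimConfig, simulate_atlas
from regdiscover.temporal_screen import high_expression_flag, screen_candidates

atlas, truth = simulate_atlas(AtlasSimConfig(seed=1))
genes = sorted(g for g, o in truth.enriched.items() if o == "cerebellum")
records = screen_candidates(atlas, "cerebellum", genes)

passing = [r for r in records if r.passes]
print(f"screened {len(records)} cerebellum-enriched genes, "
      f"{len(passing)} pass the mean > 1 and P0/P63 > 8 filter:")
for r in passing:
    hi = " (high: mean RPKM > 10)" if high_expression_flag(r) else ""
    print(f"  {r.gene}: mean {r.mean_rpkm:.1f} RPKM, "
          f"P0/P63 ratio {r.ratio:.1f}{hi}")

evidence = [OrthologEvidence(g, "sea_lamprey",
                             {"type_I": "related_nonortholog",
                              "type_II": "absent",
                              "conserved": "ortholog"}[truth.evo_category[g]])
            for r in passing for g in [r.gene]]
classes = classify_candidates([r.gene for r in passing], evidence)
print("evolutionary categories:", category_counts(classes))
# The ratio compares expression at birth (P0) against adulthood (P63);
# a large ratio marks regulators active in the perinatal window.
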