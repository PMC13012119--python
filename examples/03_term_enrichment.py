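"""Hypergeometric over-representation analysis with BH FDR control.

Tests whether an organ's enriched regulators are over-represented in
term-to-gene annotations, against an explicit background universe.
"""

from regdiscover.ontology_enrich import TermAnnotation, enrich_terms, top_terms
from regdiscover.synthetic_data import AtlasSimConfig, simulate_atlas

atlas, truth = simulate_atlas(AtlasSimConfig(seed=1))
universe = set(atlas.genes)

annotations = [
    TermAnnotation(f"ORGAN_{o.upper()}", f"{o} development program",
                   frozenset(g for g, org in truth.enriched.items() if org == o))
    for o in atlas.organs
]
query = {g for g, o in truth.enriched.items() if o == "cerebellum"}

results = top_terms(enrich_terms(query, annotations, universe), 3)
print(f"query: {len(query)} cerebellum-enriched genes; "
      f"universe: {len(universe)} genes")
print("top enriched terms (k/K overlap, hypergeometric p, BH q):")
for r in results:
    print(f"  {r.term:<18s} k={r.overlap_k}/{r.term_size_K} "
          f"p={r.p_value:.3g} q={r.q_value:.3g}")
# The cerebellum program term should dominate: the query IS its gene set,
# so p is the probability of drawing all 50 members by chance.
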