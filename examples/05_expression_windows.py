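"""Cross-species expression windows from single-cell dot-plot summaries.

Simulates per-cell counts for a granule-progenitor cluster with a planted
E12 -> P10 window of Tox3 expression, summarizes the fraction of cells
expressing per stage, extracts the expression window (stages where >= 20%
of cells express) and normalizes its duration to the species lifespan.
"""

from regdiscover.core_io import SpeciesTimeline, parse_stage
from regdiscover.expression_windows import (extract_window, normalize_duration,
                                            summarize_dotplot)
from regdiscover.synthetic_data import simulate_cluster_counts

stages = ["E10", "E12", "E14", "E17", "P0", "P4", "P10", "P14"]
counts = simulate_cluster_counts(seed=1, species="mouse", stages=stages,
                                 n_cells_per_stage=500,
                                 genes=["Tox3", "Atoh1"],
                                 planted_windows={"Tox3": ("E12", "P10")},
                                 p_in=0.5, p_out=0.02)
summary = summarize_dotplot(counts, ["Tox3"])
print("fraction of GNP cells expressing Tox3 per stage:")
rows = {r.stage: r for r in summary.table.itertuples()}
for stage in stages:
    r = rows[stage]
    print(f"  {stage:<4s} {r.fraction_expressing:.3f}  (n={r.n_cells})")

window = extract_window(summary, "Tox3", "GNP", stages, min_fraction=0.2)
timeline = SpeciesTimeline.from_mouse_stages(
    "mouse", gestation_days=19, lifespan_days=730,
    stages=[parse_stage(s) for s in stages])
window = normalize_duration(window, timeline)
print(f"expression window: {window.first_stage} -> {window.last_stage} "
      f"({window.duration_days:.0f} days, "
      f"{100 * window.normalized_duration:.2f}% of the mouse lifespan)")
# The normalized duration makes expression spans comparable across species
# with very different lifespans.
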