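"""Organ-enrichment calls for regulator genes.

Each gene is summarized by its per-organ mean developmental expression
(arithmetic mean over available stages).  A gene is called enriched in its
top organ when that mean clears an expression floor and the pseudocounted
fold over the second-highest organ clears a fold threshold; otherwise the
gene is unassigned.  Each gene is assigned to at most one organ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_io import ExpressionAtlas

__all__ = ["EnrichmentConfig", "EnrichmentCall", "organ_mean_profile",
           "call_enrichment", "grouped_heatmap_table", "write_calls"]


@dataclass(frozen=True)
class EnrichmentConfig:
    """Thresholds of the organ-enrichment rule.

    expr_floor : minimum top-organ mean RPKM for an enrichment call.
    fold_min   : minimum pseudocounted fold of the top over the runner-up organ.
    pseudocount: RPKM added to numerator and denominator of the fold, bounding
                 scores when the runner-up mean is near zero.
    """

    expr_floor: float = 1.0
    fold_min: float = 2.0
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        if self.expr_floor <= 0 or self.pseudocount <= 0:
            raise ValueError("expr_floor and pseudocount must be positive")
        if self.fold_min < 1:
            raise ValueError("fold_min must be >= 1")


@dataclass(frozen=True)
class EnrichmentCall:
    gene: str
    organ: str | None          # None = not enriched anywhere
    score: float               # pseudocounted fold of top over runner-up organ
    organ_means: dict[str, float] = field(default_factory=dict, hash=False)


def organ_mean_profile(atlas: ExpressionAtlas, gene: str) -> dict[str, float]:
    """Per-organ arithmetic mean RPKM over *available* stages only.

    Organs with no available stage for the gene are absent from the result.
    """
    if gene not in set(atlas.genes):
        raise KeyError(f"unknown gene {gene!r}")
    out: dict[str, float] = {}
    for organ in atlas.organs:
        vals = list(atlas.organ_stage_values(gene, organ).values())
        if vals:
            out[organ] = sum(vals) / len(vals)
    return out


def call_enrichment(atlas: ExpressionAtlas, cfg: EnrichmentConfig | None = None
                    ) -> list[EnrichmentCall]:
    """Call each gene enriched in at most one organ.

    With organ means m* (max) and m2 (runner-up), the score is
    ``(m* + pc) / (m2 + pc)``; the gene is enriched in the argmax organ iff
    ``m* >= expr_floor`` and ``score >= fold_min``.  Output is deterministic:
    enriched genes grouped by organ in declared organ order, within organ by
    descending top mean (ties by gene id), followed by unassigned genes.
    """
    cfg = cfg or EnrichmentConfig()
    if len(atlas.organs) < 2:
        raise ValueError("call_enrichment requires >= 2 organs (fold undefined)")

    calls: list[EnrichmentCall] = []
    for gene in atlas.genes:
        means = organ_mean_profile(atlas, gene)
        if not means:
            calls.append(EnrichmentCall(gene, None, 0.0, means))
            continue
        # argmax with deterministic tie-break by declared organ order
        top_organ = max(means, key=lambda o: (means[o], -atlas.organs.index(o)))
        m_star = means[top_organ]
        others = [v for o, v in means.items() if o != top_organ]
        m2 = max(others) if others else 0.0
        score = (m_star + cfg.pseudocount) / (m2 + cfg.pseudocount)
        if m_star >= cfg.expr_floor and score >= cfg.fold_min:
            calls.append(EnrichmentCall(gene, top_organ, score, means))
        else:
            calls.append(EnrichmentCall(gene, None, score, means))

    organ_rank = {o: i for i, o in enumerate(atlas.organs)}

    def sort_key(c: EnrichmentCall):
        if c.organ is None:
            return (1, 0, 0.0, c.gene)
        return (0, organ_rank[c.organ], -c.organ_means[c.organ], c.gene)

    return sorted(calls, key=sort_key)


def grouped_heatmap_table(calls: list[EnrichmentCall], atlas: ExpressionAtlas
                          ) -> pd.DataFrame:
    """Ordered per-stage table of enriched genes, mirroring the atlas heatmap.

    Rows are grouped by enriched organ in declared organ order and within an
    organ sorted by descending mean expression in that organ (ties broken
    lexicographically by gene id).  Columns are ``gene, organ`` followed by
    one column per (organ, stage) in atlas order; unavailable cells are NA.
    """
    organ_rank = {o: i for i, o in enumerate(atlas.organs)}
    enriched = [c for c in calls if c.organ is not None]
    enriched.sort(key=lambda c: (organ_rank[c.organ], -c.organ_means[c.organ], c.gene))

    stage_cols = [
        f"{organ}:{st.label}" for organ in atlas.organs for st in atlas.stages[organ]
    ]
    rows = []
    for c in enriched:
        row: dict[str, object] = {"gene": c.gene, "organ": c.organ}
        for organ in atlas.organs:
            for st in atlas.stages[organ]:
                row[f"{organ}:{st.label}"] = atlas.get(c.gene, organ, st.label)
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene", "organ", *stage_cols])


def write_calls(calls: list[EnrichmentCall], atlas: ExpressionAtlas, path) -> None:
    """TSV export: gene, organ, score, one column per organ mean."""
    rows = []
    for c in calls:
        row: dict[str, object] = {
            "gene": c.gene,
            "organ": c.organ if c.organ is not None else "none",
            "score": f"{c.score:.6g}",
        }
        for organ in atlas.organs:
            m = c.organ_means.get(organ)
            row[f"mean_{organ}"] = "" if m is None else f"{m:.6g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
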