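"""Temporal candidate screen over organ-enriched regulators.

The screen keeps genes with an average RPKM above a floor (mean over the
available stages of the screened organ) and a perinatal-over-adult
expression ratio above a fold threshold; by default the ratio compares
postnatal day 0 against P63, with a small pseudocount guarding against zero
denominators.  Both inequalities are strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import DevStage, ExpressionAtlas, parse_stage

__all__ = ["ScreenConfig", "CandidateRecord", "screen_candidates",
           "high_expression_flag", "write_candidates"]


@dataclass(frozen=True)
class ScreenConfig:
    min_mean_rpkm: float = 1.0       # strict >
    min_ratio: float = 8.0           # strict >
    numerator_stage: DevStage = parse_stage("P0")
    denominator_stage: DevStage = parse_stage("P63")
    ratio_pseudocount: float = 0.01
    # optional restriction of the averaging window to a stage-label subset
    mean_stages: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.min_mean_rpkm <= 0 or self.min_ratio <= 0:
            raise ValueError("thresholds must be positive")
        if self.numerator_stage == self.denominator_stage:
            raise ValueError("numerator and denominator stages must differ")


@dataclass(frozen=True)
class CandidateRecord:
    gene: str
    mean_rpkm: float
    numerator_value: float | None
    denominator_value: float | None
    ratio: float
    passes: bool
    reason: str = ""


def screen_candidates(atlas: ExpressionAtlas, organ: str, genes, cfg: ScreenConfig | None = None
                      ) -> list[CandidateRecord]:
    """Screen ``genes`` in one organ; one record per gene, sorted by
    descending ratio (ties by gene id).

    Genes missing either boundary stage are emitted with ``passes=False``
    and a flagged reason rather than dropped.
    """
    cfg = cfg or ScreenConfig()
    if organ not in atlas.organs:
        raise ValueError(f"organ not in atlas: {organ!r}")
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    atlas_genes = set(atlas.genes)
    unknown = [g for g in genes if g not in atlas_genes]
    if unknown:
        raise ValueError(f"genes not in atlas: {unknown[:5]}")

    num_label = cfg.numerator_stage.label
    den_label = cfg.denominator_stage.label
    eps = cfg.ratio_pseudocount

    records: list[CandidateRecord] = []
    for gene in genes:
        stage_vals = atlas.organ_stage_values(gene, organ)
        if cfg.mean_stages is not None:
            mean_vals = [v for s, v in stage_vals.items() if s in cfg.mean_stages]
        else:
            mean_vals = list(stage_vals.values())
        mean_rpkm = sum(mean_vals) / len(mean_vals) if mean_vals else 0.0

        num = stage_vals.get(num_label)
        den = stage_vals.get(den_label)
        if num is None or den is None:
            missing = [l for l, v in ((num_label, num), (den_label, den)) if v is None]
            records.append(CandidateRecord(
                gene, mean_rpkm, num, den, ratio=0.0, passes=False,
                reason=f"missing stage {','.join(missing)}"))
            continue
        ratio = (num + eps) / (den + eps)
        passes = mean_rpkm > cfg.min_mean_rpkm and ratio > cfg.min_ratio
        records.append(CandidateRecord(gene, mean_rpkm, num, den, ratio, passes))

    records.sort(key=lambda r: (-r.ratio, r.gene))
    return records


def high_expression_flag(record: CandidateRecord, floor: float = 10.0) -> bool:
    """True iff the candidate's mean RPKM strictly exceeds ``floor``
    (default 10, the perinatal high-expression mark)."""
    return record.mean_rpkm > floor


def write_candidates(records: list[CandidateRecord], cfg: ScreenConfig, path) -> None:
    num, den = cfg.numerator_stage.label, cfg.denominator_stage.label
    df = pd.DataFrame([{
        "gene": r.gene,
        "mean_rpkm": f"{r.mean_rpkm:.6g}",
        num: "" if r.numerator_value is None else f"{r.numerator_value:.6g}",
        den: "" if r.denominator_value is None else f"{r.denominator_value:.6g}",
        "ratio": f"{r.ratio:.6g}",
        "passes": str(r.passes).lower(),
        "reason": r.reason,
    } for r in records])
    df.to_csv(path, sep="\t", index=False)
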