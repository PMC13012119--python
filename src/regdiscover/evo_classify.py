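"""Evolutionary classification of candidates by outgroup evidence.

Candidates are labeled by what the outgroup (e.g. sea lamprey) genome
contains: a true ortholog (``conserved``), an evolutionarily related but
non-orthologous counterpart (``type_I``), no similar gene at all
(``type_II``), or no evidence record (``unclassified``).  Orthology
inference itself is upstream input, not a computation here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

__all__ = ["OrthologEvidence", "EvoClass", "read_ortholog_evidence",
           "classify_candidates", "category_counts"]

_STATUS_TO_CATEGORY = {
    "ortholog": "conserved",
    "related_nonortholog": "type_I",
    "absent": "type_II",
}

VALID_STATUSES = frozenset(_STATUS_TO_CATEGORY)


@dataclass(frozen=True)
class OrthologEvidence:
    gene: str
    outgroup_taxon: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUSES:
            raise ValueError(f"unknown ortholog status {self.status!r}")


@dataclass(frozen=True)
class EvoClass:
    gene: str
    category: str  # conserved | type_I | type_II | unclassified


def read_ortholog_evidence(path) -> list[OrthologEvidence]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("gene", "outgroup_taxon", "status"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [OrthologEvidence(r.gene, r.outgroup_taxon, r.status) for r in df.itertuples()]


def classify_candidates(candidates, evidence: list[OrthologEvidence]) -> list[EvoClass]:
    """One :class:`EvoClass` per candidate, in input order.

    Duplicate consistent evidence rows are tolerated; conflicting rows for
    one gene are an error.
    """
    status: dict[str, str] = {}
    for ev in evidence:
        prev = status.get(ev.gene)
        if prev is not None and prev != ev.status:
            raise ValueError(f"conflicting evidence for gene {ev.gene!r}: "
                             f"{prev!r} vs {ev.status!r}")
        status[ev.gene] = ev.status
    return [
        EvoClass(g, _STATUS_TO_CATEGORY.get(status.get(g, ""), "unclassified"))
        for g in candidates
    ]


def category_counts(classes: list[EvoClass]) -> dict[str, int]:
    counts = Counter(c.category for c in classes)
    return {cat: counts.get(cat, 0)
            for cat in ("conserved", "type_I", "type_II", "unclassified")}
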