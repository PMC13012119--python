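"""Domain types and readers/writers for the regulator-discovery pipeline.

The central substrate is a genes x (organ, developmental stage) expression
matrix in RPKM units, stored sparsely so that *unavailable* measurements are
representable and distinct from zero expression.  Developmental stages follow
the mouse convention: ``E<d>`` for embryonic days post conception and
``P<d>`` for days after birth, with every embryonic stage preceding every
postnatal stage.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DevStage",
    "ExpressionAtlas",
    "RegulatorCatalog",
    "SpeciesTimeline",
    "StageParseError",
    "parse_stage",
    "read_expression_atlas",
    "write_expression_atlas",
    "read_regulator_catalog",
    "read_species_timeline",
    "restrict_to_catalog",
]


class StageParseError(ValueError):
    """Raised when a developmental-stage label does not match the grammar."""


_STAGE_RE = re.compile(r"^([EP])(\d+(?:\.\d+)?)$")


@functools.total_ordering
@dataclass(frozen=True)
class DevStage:
    """A developmental stage: embryonic (days post conception) or postnatal
    (days after birth).

    The total order places every embryonic stage before every postnatal one,
    and orders by day value within a phase.
    """

    phase: str  # "embryonic" | "postnatal"
    value: float

    def __post_init__(self) -> None:
        if self.phase not in ("embryonic", "postnatal"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.value < 0:
            raise ValueError("stage value must be non-negative")

    @property
    def _key(self) -> tuple[int, float]:
        return (0 if self.phase == "embryonic" else 1, self.value)

    def __lt__(self, other: "DevStage") -> bool:
        if not isinstance(other, DevStage):
            return NotImplemented
        return self._key < other._key

    @property
    def label(self) -> str:
        prefix = "E" if self.phase == "embryonic" else "P"
        v = self.value
        return f"{prefix}{int(v)}" if v == int(v) else f"{prefix}{v:g}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_stage(label: str) -> DevStage:
    """Parse an ``E<number>``/``P<number>`` stage label.

    Cross-species units (dpf, wpc) are deliberately not handled here; they
    are mapped to absolute ages through :class:`SpeciesTimeline`.
    """
    m = _STAGE_RE.match(label.strip())
    if m is None:
        raise StageParseError(f"malformed stage label: {label!r}")
    phase = "embryonic" if m.group(1) == "E" else "postnatal"
    return DevStage(phase, float(m.group(2)))


@dataclass
class ExpressionAtlas:
    """Sparse genes x (organ, stage) RPKM matrix.

    ``values`` maps ``(gene, organ, stage_label)`` to RPKM; keys absent from
    the mapping are *unavailable* measurements, never implicit zeros.
    Per-organ stage sequences are kept strictly increasing under the
    :class:`DevStage` order.
    """

    genes: list[str]
    organs: list[str]
    stages: dict[str, list[DevStage]]  # organ -> ordered stages
    values: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.organs)) != len(self.organs):
            raise ValueError("duplicate organ labels")
        for organ, seq in self.stages.items():
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ValueError(f"stage sequence for {organ!r} not strictly increasing")
        gene_set, organ_set = set(self.genes), set(self.organs)
        stage_sets = {o: {s.label for s in seq} for o, seq in self.stages.items()}
        for (g, o, s), v in self.values.items():
            if g not in gene_set:
                raise ValueError(f"value keyed by undeclared gene {g!r}")
            if o not in organ_set:
                raise ValueError(f"value keyed by undeclared organ {o!r}")
            if s not in stage_sets.get(o, ()):
                raise ValueError(f"value keyed by undeclared stage {s!r} for organ {o!r}")
            if v < 0:
                raise ValueError(f"negative RPKM for ({g}, {o}, {s})")

    def get(self, gene: str, organ: str, stage: str) -> float | None:
        """RPKM for a cell, or ``None`` when the measurement is unavailable."""
        return self.values.get((gene, organ, stage))

    def organ_stage_values(self, gene: str, organ: str) -> dict[str, float]:
        """Available (stage label -> RPKM) for one gene in one organ, in stage order."""
        out: dict[str, float] = {}
        for st in self.stages.get(organ, ()):
            v = self.values.get((gene, organ, st.label))
            if v is not None:
                out[st.label] = v
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format view with columns gene, organ, stage, rpkm."""
        rows = [
            {"gene": g, "organ": o, "stage": s, "rpkm": v}
            for (g, o, s), v in sorted(
                self.values.items(),
                key=lambda kv: (kv[0][0], kv[0][1], parse_stage(kv[0][2])._key),
            )
        ]
        return pd.DataFrame(rows, columns=["gene", "organ", "stage", "rpkm"])


@dataclass(frozen=True)
class RegulatorCatalog:
    """Gene -> regulator class (``transcription_factor`` or ``cofactor``)."""

    entries: Mapping[str, str]

    VALID_CLASSES = frozenset({"transcription_factor", "cofactor"})

    def __post_init__(self) -> None:
        bad = set(self.entries.values()) - self.VALID_CLASSES
        if bad:
            raise ValueError(f"unknown regulator class tokens: {sorted(bad)}")

    @property
    def genes(self) -> set[str]:
        return set(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class SpeciesTimeline:
    """Maps a species' stage labels to absolute age in days.

    Embryonic stages map to their days-post-conception value; postnatal
    stages map to ``gestation_days + value``.  Lifespan is used to normalize
    expression-window durations across species.
    """

    species: str
    gestation_days: float
    lifespan_days: float
    stage_map: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.gestation_days < 0:
            raise ValueError("gestation_days must be >= 0")
        if self.lifespan_days <= self.gestation_days:
            raise ValueError("lifespan_days must exceed gestation_days")

    def age_days(self, stage_label: str) -> float:
        try:
            return self.stage_map[stage_label]
        except KeyError:
            raise KeyError(
                f"stage {stage_label!r} not in timeline for {self.species}"
            ) from None

    @classmethod
    def from_mouse_stages(
        cls, species: str, gestation_days: float, lifespan_days: float,
        stages: Iterable[DevStage],
    ) -> "SpeciesTimeline":
        """Build a timeline from E/P stage labels using the phase convention."""
        smap = {
            st.label: (st.value if st.phase == "embryonic" else gestation_days + st.value)
            for st in stages
        }
        return cls(species, gestation_days, lifespan_days, smap)


# ---------------------------------------------------------------------------
# Readers / writers.  All TSV, UTF-8, '.' decimal separator, '#' comments.
# ---------------------------------------------------------------------------

def _read_tsv(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_expression_atlas(path) -> ExpressionAtlas:
    """Read a long-format atlas TSV with header ``gene organ stage rpkm``."""
    df = _read_tsv(path, ["gene", "organ", "stage", "rpkm"])
    if df.empty:
        raise ValueError(f"{path}: no records")
    df["rpkm"] = pd.to_numeric(df["rpkm"], errors="raise")
    neg = df.index[df["rpkm"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative rpkm at data row {neg[0] + 1}")
    dup = df.duplicated(subset=["gene", "organ", "stage"])
    if dup.any():
        g, o, s = df.loc[dup.idxmax(), ["gene", "organ", "stage"]]
        raise ValueError(f"{path}: duplicate (gene, organ, stage) row ({g}, {o}, {s})")

    genes = sorted(df["gene"].unique())
    organs = list(dict.fromkeys(df["organ"]))
    stages = {
        organ: sorted({parse_stage(s) for s in sub["stage"]})
        for organ, sub in df.groupby("organ", sort=False)
    }
    values = {
        (r.gene, r.organ, parse_stage(r.stage).label): float(r.rpkm)
        for r in df.itertuples()
    }
    return ExpressionAtlas(genes=genes, organs=organs, stages=stages, values=values)


def write_expression_atlas(atlas: ExpressionAtlas, path) -> None:
    atlas.to_frame().to_csv(path, sep="\t", index=False)


def read_regulator_catalog(path) -> RegulatorCatalog:
    """Read a ``gene<TAB>class`` TSV; duplicate consistent rows are deduplicated,
    conflicting duplicates are an error."""
    df = _read_tsv(path, ["gene", "class"])
    entries: dict[str, str] = {}
    for r in df.itertuples():
        cls = r[2]  # 'class' is a keyword; positional access
        if cls not in RegulatorCatalog.VALID_CLASSES:
            raise ValueError(f"{path}: unknown regulator class {cls!r} for gene {r.gene}")
        if r.gene in entries and entries[r.gene] != cls:
            raise ValueError(
                f"{path}: conflicting class for gene {r.gene}: "
                f"{entries[r.gene]!r} vs {cls!r}"
            )
        entries[r.gene] = cls
    return RegulatorCatalog(entries)


def read_species_timeline(species_path, stage_map_path) -> dict[str, SpeciesTimeline]:
    """Read timelines: ``species gestation_days lifespan_days`` plus a
    stage-map TSV ``species stage age_days``."""
    sp = _read_tsv(species_path, ["species", "gestation_days", "lifespan_days"])
    sm = _read_tsv(stage_map_path, ["species", "stage", "age_days"])
    out: dict[str, SpeciesTimeline] = {}
    for r in sp.itertuples():
        sub = sm[sm["species"] == r.species]
        stage_map = {s: float(a) for s, a in zip(sub["stage"], sub["age_days"])}
        out[r.species] = SpeciesTimeline(
            species=r.species,
            gestation_days=float(r.gestation_days),
            lifespan_days=float(r.lifespan_days),
            stage_map=stage_map,
        )
    return out


def restrict_to_catalog(atlas: ExpressionAtlas, catalog: RegulatorCatalog) -> ExpressionAtlas:
    """Restrict the atlas to genes present in the regulator catalog.

    Surviving values are untouched; organs/stages are kept as declared.
    """
    keep = set(atlas.genes) & catalog.genes
    if not keep:
        raise ValueError("no regulators present in atlas")
    return ExpressionAtlas(
        genes=[g for g in atlas.genes if g in keep],
        organs=list(atlas.organs),
        stages={o: list(s) for o, s in atlas.stages.items()},
        values={k: v for k, v in atlas.values.items() if k[0] in keep},
    )
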