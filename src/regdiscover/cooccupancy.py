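"""Peak-level co-binding analysis for two transcription factors.

Covers proximity overlap between two ChIP peak sets (the "peaks of A
overlapping or near peaks of B" fraction), nearest-anchor gene assignment
(anchor = a per-gene coordinate such as the translation start site),
shared-target extraction, and E-box motif scanning with per-species
presence calls across orthologous enhancer sequences.

Coordinates are 0-based half-open throughout, matching BED.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = ["GenomicInterval", "GeneAnchorTable", "MotifQuery", "MotifHit",
           "read_bed", "read_gene_anchors", "read_fasta_by_species",
           "proximity_overlap", "nearest_gene", "shared_targets",
           "scan_motif", "species_motif_presence"]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneAnchorTable:
    """One anchor coordinate per gene: (chrom, position, strand)."""

    records: dict[str, tuple[str, int, str]]

    def __post_init__(self) -> None:
        for gene, (chrom, pos, strand) in self.records.items():
            if pos < 0:
                raise ValueError(f"negative anchor for gene {gene!r}")


@dataclass(frozen=True)
class MotifQuery:
    pattern: str = "CANNTG"       # canonical bHLH E-box
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.pattern.upper()) - set(ambiguous_dna_values)
        if bad:
            raise ValueError(f"non-IUPAC codes in pattern: {sorted(bad)}")


@dataclass(frozen=True)
class MotifHit:
    position: int     # 0-based start on the + strand of the scanned sequence
    strand: str       # "+" | "-"
    matched: str


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 (tab-separated); input order preserved."""
    out: list[GenomicInterval] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else None
            strand = f[5] if len(f) > 5 else None
            out.append(GenomicInterval(f[0], start, end, name, score, strand))
    return out


def read_gene_anchors(path) -> GeneAnchorTable:
    """TSV ``gene chrom anchor strand`` -> :class:`GeneAnchorTable`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("gene", "chrom", "anchor", "strand"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"{path}: duplicate anchor for gene {dup!r}")
    return GeneAnchorTable({
        r.gene: (r.chrom, int(r.anchor), r.strand) for r in df.itertuples()
    })


def read_fasta_by_species(path) -> dict[str, str]:
    """FASTA with one record per species (record id = species label)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _gap(a: GenomicInterval, b: GenomicInterval) -> int:
    # half-open gap: 0 when the intervals touch or overlap
    return max(0, b.start - a.end, a.start - b.end)


def proximity_overlap(set_a: list[GenomicInterval], set_b: list[GenomicInterval],
                      window: int) -> tuple[list[bool], float]:
    """Flag each A interval with a same-chromosome B interval within
    ``window`` bases (gap <= window), and return the flagged fraction of A.

    Implemented as a per-chromosome sorted sweep; the result is independent
    of input order.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if not set_a:
        raise ValueError("empty A set: fraction undefined")

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in set_b:
        by_chrom.setdefault(b.chrom, []).append((b.start, b.end))
    starts_by_chrom: dict[str, tuple[list[int], np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = [s for s, _ in ivs]
        # running max of ends, so a binary search on starts suffices
        max_ends = np.maximum.accumulate([e for _, e in ivs])
        starts_by_chrom[chrom] = (starts, max_ends)

    flags: list[bool] = []
    for a in set_a:
        hit = False
        entry = starts_by_chrom.get(a.chrom)
        if entry is not None:
            starts, max_ends = entry
            # candidates with b.start <= a.end + window
            hi = bisect.bisect_right(starts, a.end + window)
            if hi > 0 and max_ends[hi - 1] >= a.start - window:
                hit = True
        flags.append(hit)
    return flags, sum(flags) / len(flags)


def nearest_gene(peaks: list[GenomicInterval], anchors: GeneAnchorTable
                 ) -> list[str | None]:
    """Per peak, the same-chromosome gene whose anchor is closest to the
    peak midpoint (floor of (start+end)/2); ties broken lexicographically by
    gene id; None when the chromosome has no anchors."""
    if not anchors.records:
        raise ValueError("empty anchor table")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gene, (chrom, pos, _strand) in anchors.records.items():
        by_chrom.setdefault(chrom, []).append((pos, gene))
    for lst in by_chrom.values():
        lst.sort()

    out: list[str | None] = []
    for peak in peaks:
        lst = by_chrom.get(peak.chrom)
        if not lst:
            out.append(None)
            continue
        mid = peak.midpoint
        i = bisect.bisect_left(lst, (mid, ""))
        best: tuple[int, str] | None = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(lst):
                pos, gene = lst[j]
                cand = (abs(pos - mid), gene)
                if best is None or cand < best:
                    best = cand
        # equal-distance neighbours beyond the immediate pair share the same
        # |pos - mid|, so scan outward while distances tie
        dist = best[0]
        for j in range(i - 2, -1, -1):
            if abs(lst[j][0] - mid) > dist:
                break
            best = min(best, (dist, lst[j][1]))
        for j in range(i + 2, len(lst)):
            if abs(lst[j][0] - mid) > dist:
                break
            best = min(best, (dist, lst[j][1]))
        out.append(best[1])
    return out


def shared_targets(targets_a, targets_b) -> tuple[set[str], float]:
    """Intersection of two target-gene sets and the co-targeting fraction
    |A ∩ B| / |A| (0 when A is empty)."""
    a, b = set(targets_a), set(targets_b)
    inter = a & b
    return inter, (len(inter) / len(a) if a else 0.0)


def _iupac_table() -> dict[str, frozenset[str]]:
    return {code: frozenset(bases) for code, bases in ambiguous_dna_values.items()}


_IUPAC = _iupac_table()


def _matches(seq: str, pos: int, pattern: str) -> bool:
    for off, code in enumerate(pattern):
        if seq[pos + off] not in _IUPAC[code]:
            return False
    return True


def scan_motif(seq: str, query: MotifQuery | None = None) -> list[MotifHit]:
    """All IUPAC-pattern matches on the + strand and, when requested, the -
    strand (reported at + coordinates); sorted by position then strand.

    ``N`` in the sequence matches nothing except pattern positions that are
    themselves fully ambiguous ``N``.
    """
    query = query or MotifQuery()
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotide at offset "
                         f"{min(s.index(c) for c in bad)}: {sorted(bad)}")
    pattern = query.pattern.upper()
    rc_pattern = str(Seq(pattern).reverse_complement())
    L = len(pattern)
    hits: list[MotifHit] = []
    for pos in range(len(s) - L + 1):
        window = s[pos:pos + L]
        if _matches(s, pos, pattern):
            hits.append(MotifHit(pos, "+", window))
        if query.both_strands and _matches(s, pos, rc_pattern):
            # matched is reported as read on the - strand, so it satisfies
            # the pattern itself
            hits.append(MotifHit(pos, "-", str(Seq(window).reverse_complement())))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def species_motif_presence(seqs: dict[str, str], query: MotifQuery | None = None
                           ) -> dict[str, dict]:
    """Per-species motif presence over orthologous sequences.

    Returns, per species in declared order, a dict with ``present`` (>= 1
    hit) and the hit position list.
    """
    if not seqs:
        raise ValueError("at least one species required")
    out: dict[str, dict] = {}
    for species, seq in seqs.items():
        if not seq:
            raise ValueError(f"empty sequence for species {species!r}")
        hits = scan_motif(seq, query)
        out[species] = {
            "present": bool(hits),
            "positions": [h.position for h in hits],
        }
    return out
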