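"""Interval proximity, nearest-gene assignment, shared targets and IUPAC
motif scanning, each against a brute-force oracle."""

import numpy as np
import pytest
from Bio.Seq import Seq

from regdiscover.cooccupancy import (GeneAnchorTable, GenomicInterval, MotifQuery,
                                     nearest_gene, proximity_overlap, read_bed,
                                     scan_motif, shared_targets,
                                     species_motif_presence)


def iv(start, end, chrom="chr1", name=None):
    return GenomicInterval(chrom, start, end, name=name)


# ---------------------------------------------------------------- BED parsing

def test_read_bed3_and_bed6(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t200\nchr2\t5\t50\tpeak1\t13.5\t-\n")
    a, b = read_bed(p)
    assert (a.chrom, a.start, a.end) == ("chr1", 100, 200)
    assert (b.name, b.score, b.strand) == ("peak1", 13.5, "-")


@pytest.mark.parametrize("line,match", [
    ("chr1\t200\t100\n", "start >= end"),
    ("chr1\tx\t100\n", "non-numeric"),
    ("chr1\t100\n", ">= 3 columns"),
])
def test_read_bed_errors_carry_line_number(tmp_path, line, match):
    p = tmp_path / "a.bed"
    p.write_text(line)
    with pytest.raises(ValueError, match=match):
        read_bed(p)


# ---------------------------------------------------------- proximity overlap

def gap(a, b):
    return max(0, b.start - a.end, a.start - b.end)


def test_direct_overlap_flagged():
    flags, frac = proximity_overlap([iv(100, 200)], [iv(150, 250)], window=0)
    assert flags == [True] and frac == 1.0


def test_gap_window_arithmetic():
    a, b = [iv(100, 200)], [iv(210, 220)]
    assert proximity_overlap(a, b, window=5)[0] == [False]   # gap = 10 > 5
    assert proximity_overlap(a, b, window=10)[0] == [True]   # gap = 10 <= 10


def test_different_chromosomes_never_near():
    flags, _ = proximity_overlap([iv(0, 10)], [iv(0, 10, chrom="chr2")], 10 ** 9)
    assert flags == [False]


def test_empty_a_rejected():
    with pytest.raises(ValueError, match="fraction undefined"):
        proximity_overlap([], [iv(0, 10)], 0)


def random_intervals(rng, n, chroms=("chr1", "chr2")):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, 100_000))
        out.append(iv(s, s + int(rng.integers(1, 500)),
                      chrom=str(rng.choice(chroms))))
    return out


def test_flags_match_quadratic_oracle():
    rng = np.random.default_rng(11)
    A = random_intervals(rng, 1000)
    B = random_intervals(rng, 1000)
    window = 300
    flags, frac = proximity_overlap(A, B, window)
    want = [any(a.chrom == b.chrom and gap(a, b) <= window for b in B) for a in A]
    assert flags == want
    assert frac == sum(want) / len(want)


def test_flag_logic_symmetric():
    rng = np.random.default_rng(12)
    A = random_intervals(rng, 200)
    B = random_intervals(rng, 200)
    window = 150
    fa, _ = proximity_overlap(A, B, window)
    fb, _ = proximity_overlap(B, A, window)
    # an A is near some B iff that B is near some A: pairwise relation symmetric
    for i, a in enumerate(A):
        assert fa[i] == any(fb[j] and a.chrom == B[j].chrom and gap(a, B[j]) <= window
                            for j in range(len(B)))


def test_result_independent_of_input_order():
    rng = np.random.default_rng(13)
    A = random_intervals(rng, 100)
    B = random_intervals(rng, 100)
    _, f1 = proximity_overlap(A, B, 100)
    _, f2 = proximity_overlap(A, B[::-1], 100)
    assert f1 == f2


# ------------------------------------------------------------- nearest gene

def anchors(d):
    return GeneAnchorTable({g: (c, p, "+") for g, (c, p) in d.items()})


def test_nearest_by_midpoint_distance():
    table = anchors({"near": ("chr1", 400), "far": ("chr1", 700)})
    (g,) = nearest_gene([iv(400, 600)], table)  # midpoint 500
    assert g == "near"


def test_anchor_at_midpoint_and_no_anchor_chrom():
    table = anchors({"hit": ("chr1", 500)})
    assert nearest_gene([iv(400, 600)], table) == ["hit"]
    assert nearest_gene([iv(0, 10, chrom="chrX")], table) == [None]


def test_equidistant_tie_lexicographic():
    table = anchors({"b_gene": ("chr1", 400), "a_gene": ("chr1", 600)})
    assert nearest_gene([iv(450, 550)], table) == ["a_gene"]  # both at 100


def test_nearest_matches_brute_force():
    rng = np.random.default_rng(21)
    table = anchors({f"g{i:03d}": (str(rng.choice(["chr1", "chr2"])),
                                   int(rng.integers(0, 50_000)))
                     for i in range(150)})
    peaks = random_intervals(rng, 300)
    got = nearest_gene(peaks, table)
    for peak, g in zip(peaks, got):
        cands = [(abs(p - peak.midpoint), name)
                 for name, (c, p, _s) in table.records.items() if c == peak.chrom]
        want = min(cands)[1] if cands else None
        assert g == want
        if g is not None:  # assigned distance minimal among same-chrom anchors
            d = abs(table.records[g][1] - peak.midpoint)
            assert all(d <= c[0] for c in cands)


# ------------------------------------------------------------ shared targets

def test_shared_targets_fraction():
    inter, frac = shared_targets({"x", "y", "z"}, {"y", "z", "w"})
    assert inter == {"y", "z"} and frac == pytest.approx(2 / 3)
    inter, frac = shared_targets({"x"}, {"y"})
    assert inter == set() and frac == 0.0


# -------------------------------------------------------------- motif scan

def naive_scan(seq, pattern, both):
    from Bio.Data.IUPACData import ambiguous_dna_values as tab
    seq = seq.upper()
    rc = str(Seq(pattern).reverse_complement())
    hits = []
    for pos in range(len(seq) - len(pattern) + 1):
        w = seq[pos:pos + len(pattern)]
        if all(c in tab[p] for c, p in zip(w, pattern)):
            hits.append((pos, "+"))
        if both and all(c in tab[p] for c, p in zip(w, rc)):
            hits.append((pos, "-"))
    return sorted(hits)


def test_palindromic_ebox_hit():
    hits = scan_motif("ACAGCTGT", MotifQuery("CANNTG"))
    assert [(h.position, h.strand) for h in hits] == [(1, "+"), (1, "-")]
    assert hits[0].matched == "CAGCTG"


def test_no_hits_in_homopolymer():
    assert scan_motif("AAAAAA", MotifQuery("CANNTG")) == []


def test_invalid_nucleotide_reports_offset():
    with pytest.raises(ValueError, match="offset 3"):
        scan_motif("ACGXT", MotifQuery("CANNTG"))


def test_scan_matches_sliding_window_oracle():
    rng = np.random.default_rng(31)
    for _ in range(5):
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        for pattern in ("CANNTG", "GGWCC", "TATAWAW"):
            got = [(h.position, h.strand)
                   for h in scan_motif(seq, MotifQuery(pattern))]
            assert got == naive_scan(seq, pattern, both=True)


def test_revcomp_mirror_symmetry():
    rng = np.random.default_rng(32)
    seq = "".join(rng.choice(list("ACGT"), size=500))
    q = MotifQuery("CACGTG")
    fwd = {(h.position, h.strand) for h in scan_motif(seq, q)}
    rc = str(Seq(seq).reverse_complement())
    L = len(seq) - len(q.pattern)
    mirrored = {(L - p, {"+": "-", "-": "+"}[s])
                for p, s in ((h.position, h.strand) for h in scan_motif(rc, q))}
    assert fwd == mirrored


# --------------------------------------------------- per-species presence

def test_species_presence_planted_ablation():
    rng = np.random.default_rng(41)
    base = "".join(rng.choice(list("AT"), size=200))  # no C/G: motif-free
    seqs = {
        "zebrafish": base[:100] + "CAGCTG" + base[100:],
        "mouse": base[:50] + "CACCTG" + base[50:],
        "lamprey": base,
    }
    table = species_motif_presence(seqs, MotifQuery("CANNTG"))
    assert list(table) == ["zebrafish", "mouse", "lamprey"]  # declared order
    assert table["zebrafish"]["present"] and table["mouse"]["present"]
    assert not table["lamprey"]["present"]
    with pytest.raises(ValueError, match="empty sequence"):
        species_motif_presence({"x": ""})
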