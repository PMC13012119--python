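"""Dot-plot summaries, envelope expression windows and lifespan
normalization."""

import numpy as np
import pandas as pd
import pytest

from regdiscover.core_io import SpeciesTimeline, parse_stage
from regdiscover.expression_windows import (CellByGeneCounts, ClusterStageSummary,
                                            ExpressionWindow, extract_window,
                                            normalize_duration, read_counts_mtx,
                                            summarize_dotplot, write_counts_mtx)
from regdiscover.synthetic_data import simulate_cluster_counts


def make_counts(matrix, stages, cluster="GNP", species="mouse", genes=None):
    matrix = np.asarray(matrix)
    cells = [f"c{i}" for i in range(matrix.shape[0])]
    genes = genes or [f"g{j}" for j in range(matrix.shape[1])]
    meta = pd.DataFrame({"cell": cells, "cluster": cluster,
                         "stage": stages, "species": species}).set_index("cell")
    return CellByGeneCounts(matrix, cells, genes, meta)


def test_fraction_and_mean_direct_arithmetic():
    counts = make_counts([[0], [1], [2], [0]], stages=["E10"] * 4)
    summary = summarize_dotplot(counts, ["g0"])
    row = summary.lookup("g0", "GNP", "E10")
    assert row["fraction_expressing"] == 0.5
    assert row["mean_expression"] == 0.75
    assert row["n_cells"] == 4


def test_all_zero_group():
    counts = make_counts([[0], [0]], stages=["P0"] * 2)
    row = summarize_dotplot(counts, ["g0"]).lookup("g0", "GNP", "P0")
    assert row["fraction_expressing"] == 0.0 and row["mean_expression"] == 0.0


def test_unknown_gene_errors():
    counts = make_counts([[1]], stages=["P0"])
    with pytest.raises(KeyError, match="not in matrix"):
        summarize_dotplot(counts, ["nope"])


def test_summary_matches_group_loop_oracle():
    rng = np.random.default_rng(5)
    stages = [str(s) for s in rng.choice(["E10", "E12", "P0"], size=500)]
    mat = rng.poisson(0.7, size=(500, 4))
    counts = make_counts(mat, stages)
    summary = summarize_dotplot(counts, counts.genes)
    for r in summary.table.itertuples():
        idx = [i for i, s in enumerate(stages) if s == r.stage]
        col = mat[idx, counts.genes.index(r.gene)]
        assert r.fraction_expressing == pytest.approx(np.mean(col > 0))
        assert r.mean_expression == pytest.approx(col.mean())
        assert r.n_cells == len(idx)


def test_fraction_invariant_to_count_scaling():
    rng = np.random.default_rng(6)
    mat = rng.poisson(0.5, size=(100, 2))
    stages = ["E10"] * 100
    f1 = summarize_dotplot(make_counts(mat, stages), ["g0"]).table
    f2 = summarize_dotplot(make_counts(mat * 7, stages), ["g0"]).table
    assert f1["fraction_expressing"].tolist() == f2["fraction_expressing"].tolist()


def summary_from_fractions(fracs, gene="Tox3", cluster="GNP"):
    rows = [{"gene": gene, "cluster": cluster, "stage": s,
             "fraction_expressing": f, "mean_expression": f, "n_cells": 100}
            for s, f in fracs.items()]
    return ClusterStageSummary(pd.DataFrame(rows))


STAGE_ORDER = ["E10", "E12", "E14", "P0", "P4", "P10", "P14"]


def test_envelope_window_with_interior_dip():
    fracs = {"E10": 0.05, "E12": 0.5, "E14": 0.6, "P0": 0.3,
             "P4": 0.25, "P10": 0.21, "P14": 0.1}
    w = extract_window(summary_from_fractions(fracs), "Tox3", "GNP",
                       STAGE_ORDER, min_fraction=0.2)
    assert (w.first_stage, w.last_stage, w.dip_count) == ("E12", "P10", 0)
    # a dip below threshold inside the envelope is counted, not split
    fracs["P0"] = 0.1
    w = extract_window(summary_from_fractions(fracs), "Tox3", "GNP",
                       STAGE_ORDER, min_fraction=0.2)
    assert (w.first_stage, w.last_stage, w.dip_count) == ("E12", "P10", 1)


def test_no_qualifying_stage_returns_none():
    fracs = {s: 0.01 for s in STAGE_ORDER}
    assert extract_window(summary_from_fractions(fracs), "Tox3", "GNP",
                          STAGE_ORDER, 0.2) is None


def test_single_stage_zero_duration_window():
    fracs = {s: (0.5 if s == "P0" else 0.0) for s in STAGE_ORDER}
    w = extract_window(summary_from_fractions(fracs), "Tox3", "GNP",
                       STAGE_ORDER, 0.2)
    assert w.first_stage == w.last_stage == "P0"
    tl = SpeciesTimeline.from_mouse_stages(
        "mouse", 19, 730, [parse_stage(s) for s in STAGE_ORDER])
    done = normalize_duration(w, tl)
    assert done.duration_days == 0 and done.normalized_duration == 0


def test_timeline_arithmetic():
    tl = SpeciesTimeline.from_mouse_stages(
        "mouse", 19, 730, [parse_stage(s) for s in ["E12", "P10"]])
    w = ExpressionWindow("Tox3", "GNP", "mouse", "E12", "P10")
    done = normalize_duration(w, tl)
    assert done.duration_days == pytest.approx((19 + 10) - 12)  # 17 days
    assert done.normalized_duration == pytest.approx(17 / 730)
    # doubling lifespan halves the normalized duration exactly
    tl2 = SpeciesTimeline("mouse", 19, 1460, tl.stage_map)
    assert normalize_duration(w, tl2).normalized_duration == pytest.approx(17 / 1460)


def test_widening_window_never_decreases_duration():
    tl = SpeciesTimeline.from_mouse_stages(
        "mouse", 19, 730, [parse_stage(s) for s in STAGE_ORDER])
    narrow = normalize_duration(
        ExpressionWindow("g", "GNP", "mouse", "E12", "P4"), tl)
    wide = normalize_duration(
        ExpressionWindow("g", "GNP", "mouse", "E10", "P10"), tl)
    assert wide.normalized_duration >= narrow.normalized_duration


def test_missing_stage_named_in_error():
    tl = SpeciesTimeline("mouse", 19, 730, {"E12": 12})
    with pytest.raises(KeyError, match="P10"):
        normalize_duration(ExpressionWindow("g", "GNP", "mouse", "E12", "P10"), tl)


def test_mtx_round_trip(tmp_path):
    counts = simulate_cluster_counts(3, "mouse", ["E10", "P0"], 20,
                                     ["Tox3", "Atoh1"],
                                     {"Tox3": ("E10", "P0")})
    paths = [tmp_path / n for n in ("c.mtx", "g.tsv", "ce.tsv", "m.tsv")]
    write_counts_mtx(counts, *paths)
    back = read_counts_mtx(*paths)
    assert np.array_equal(back.matrix, counts.matrix)
    assert back.genes == counts.genes and back.cells == counts.cells
    assert back.cell_meta.loc[back.cells, "stage"].tolist() == \
        counts.cell_meta.loc[counts.cells, "stage"].tolist()
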