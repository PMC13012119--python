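"""Seeded generators for every pipeline input, with planted ground truth.

Each generator is a pure function of (seed, config): identical calls yield
byte-identical files.  The generated data mimic the *structure* of the real
resources — a multi-organ developmental RPKM atlas with organ-enriched
regulators, a subset of which carry a perinatal-high temporal profile; two
ChIP peak sets with a planted co-occupied fraction; per-cell counts with a
planted stage window of expression — not their gene-level distributions.

Planted effect sizes default to comfortable multiples of the decision
thresholds so recovery is sharp:

* organ-enrichment fold 8 against a fold threshold of 2;
* perinatal P0/P63 mean ratio 32 against a ratio threshold of 8.

Both are 4x their thresholds.  The ratio margin matters because the screen
compares two *single-stage* measurements: with multiplicative noise of
coefficient of variation c per stage, the observed log-ratio has standard
deviation ~ c*sqrt(2), so a 4x margin keeps a mis-sorted verdict below the
1e-6 level at c = 0.2, whereas organ means average ~14 stages and need far
less margin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import DevStage, ExpressionAtlas, parse_stage
from .cooccupancy import GenomicInterval

__all__ = ["AtlasSimConfig", "TruthLabels", "DEFAULT_ORGANS", "DEFAULT_STAGES",
           "simulate_atlas", "simulate_peaks", "simulate_cluster_counts",
           "write_fixture"]

DEFAULT_ORGANS = ["brain", "cerebellum", "heart", "kidney", "liver", "ovary",
                  "testis"]
# 14 developmental stages per organ, embryonic through adult
DEFAULT_STAGES = ["E10.5", "E11.5", "E12.5", "E13.5", "E14.5", "E15.5",
                  "E16.5", "E17.5", "P0", "P3", "P7", "P14", "P28", "P63"]


@dataclass(frozen=True)
class AtlasSimConfig:
    seed: int = 1
    n_genes: int = 2000
    organs: tuple[str, ...] = tuple(DEFAULT_ORGANS)
    stages: tuple[str, ...] = tuple(DEFAULT_STAGES)
    n_enriched_per_organ: int = 50
    enrichment_fold: float = 8.0
    perinatal_peak_fraction: float = 0.1
    perinatal_ratio: float = 32.0     # planted P0/P63 mean ratio of pass genes
    baseline_rpkm: float = 5.0
    noise_cv: float = 0.2
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.n_enriched_per_organ * len(self.organs) > self.n_genes:
            raise ValueError("more planted enriched genes than genes")
        if not 0 <= self.perinatal_peak_fraction <= 1:
            raise ValueError("perinatal_peak_fraction must lie in [0, 1]")
        if self.enrichment_fold <= 1:
            raise ValueError("enrichment_fold must exceed 1")
        if self.noise_cv < 0 or not 0 <= self.missing_rate < 1:
            raise ValueError("invalid noise_cv or missing_rate")


@dataclass
class TruthLabels:
    """Planted ground truth accompanying generated data."""

    enriched: dict[str, str] = field(default_factory=dict)       # gene -> organ
    temporal_pass: set[str] = field(default_factory=set)
    evo_category: dict[str, str] = field(default_factory=dict)   # gene -> category
    planted_window: dict[str, tuple[str, str]] = field(default_factory=dict)
    co_occupied_fraction: float | None = None

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["temporal_pass"] = sorted(self.temporal_pass)
        payload["planted_window"] = {g: list(w) for g, w in self.planted_window.items()}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "TruthLabels":
        d = json.loads(Path(path).read_text())
        return cls(
            enriched=d.get("enriched", {}),
            temporal_pass=set(d.get("temporal_pass", [])),
            evo_category=d.get("evo_category", {}),
            planted_window={g: tuple(w) for g, w in d.get("planted_window", {}).items()},
            co_occupied_fraction=d.get("co_occupied_fraction"),
        )


def _temporal_profile(stages: list[DevStage], ratio: float) -> np.ndarray:
    """Relative per-stage means: embryonic ramp to a P0 peak, geometric
    decay to 1/ratio at the last stage.  Normalized to mean 1."""
    labels = [s.label for s in stages]
    try:
        peak_i = labels.index("P0")
    except ValueError:
        peak_i = next(i for i, s in enumerate(stages) if s.phase == "postnatal")
    w = np.empty(len(stages))
    # embryonic ramp 0.25 -> 1.0
    if peak_i > 0:
        w[:peak_i] = np.linspace(0.25, 0.9, peak_i)
    w[peak_i] = 1.0
    n_post = len(stages) - peak_i - 1
    if n_post > 0:
        w[peak_i + 1:] = ratio ** (-np.arange(1, n_post + 1) / n_post)
    return w / w.mean()


def simulate_atlas(cfg: AtlasSimConfig) -> tuple[ExpressionAtlas, TruthLabels]:
    """Generate an RPKM atlas with planted organ-enriched genes, a fraction
    of which carry a perinatal-high P0-peaking temporal profile.

    Noise is multiplicative log-normal with the configured coefficient of
    variation and unit mean, so ``noise_cv = 0`` reproduces the planted
    means exactly.  Entries are masked at ``missing_rate``, except the
    screen's boundary stages (P0, P63) of planted temporal-pass genes in
    their target organ, which would otherwise erase the planted truth.
    """
    rng = np.random.default_rng(cfg.seed)
    organs = list(cfg.organs)
    stages = sorted(parse_stage(s) for s in cfg.stages)
    stage_labels = [s.label for s in stages]
    n_stage = len(stages)
    width = len(str(cfg.n_genes))
    genes = [f"g{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]

    truth = TruthLabels()
    # first n_enriched_per_organ * n_organs genes are planted, organ by organ
    gi = 0
    temporal_per_organ = round(cfg.n_enriched_per_organ * cfg.perinatal_peak_fraction)
    profile = _temporal_profile(stages, cfg.perinatal_ratio)
    flat = np.ones(n_stage)

    # planted per-stage means, shape (gene, organ, stage)
    means = np.full((cfg.n_genes, len(organs), n_stage), cfg.baseline_rpkm)
    for oi, organ in enumerate(organs):
        for j in range(cfg.n_enriched_per_organ):
            g = genes[gi]
            truth.enriched[g] = organ
            shape = profile if j < temporal_per_organ else flat
            if j < temporal_per_organ:
                truth.temporal_pass.add(g)
            means[gi, oi, :] = cfg.enrichment_fold * cfg.baseline_rpkm * shape
            gi += 1

    if cfg.noise_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.noise_cv ** 2))
        noise = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=means.shape)
    else:
        noise = 1.0
    values_arr = means * noise

    mask = rng.random(means.shape) < cfg.missing_rate
    # never mask the screen's boundary stages of planted temporal genes
    protected = {"P0", "P63"}
    prot_idx = [i for i, l in enumerate(stage_labels) if l in protected]
    for gi_, g in enumerate(genes):
        if g in truth.temporal_pass:
            oi = organs.index(truth.enriched[g])
            mask[gi_, oi, prot_idx] = False

    values = {
        (genes[i], organs[o], stage_labels[s]): round(float(values_arr[i, o, s]), 6)
        for i in range(cfg.n_genes)
        for o in range(len(organs))
        for s in range(n_stage)
        if not mask[i, o, s]
    }
    atlas = ExpressionAtlas(
        genes=genes, organs=organs,
        stages={o: list(stages) for o in organs},
        values=values,
    )

    # evolutionary categories for temporal-pass genes, in the 12:10:4
    # type_I : type_II : conserved proportion
    for organ in organs:
        organ_pass = sorted(g for g in truth.temporal_pass
                            if truth.enriched[g] == organ)
        for j, g in enumerate(organ_pass):
            r = j % 26
            truth.evo_category[g] = ("type_I" if r < 12
                                     else "type_II" if r < 22 else "conserved")
    return atlas, truth


def simulate_peaks(seed: int, n_a: int = 500, n_b: int = 600,
                   co_fraction: float = 0.6, genome_length: int = 50_000_000,
                   window: int = 1000, peak_len: int = 200,
                   ) -> tuple[list[GenomicInterval], list[GenomicInterval], TruthLabels]:
    """Two peak sets on one chromosome with an exact planted co-occupied
    fraction of A peaks.

    Exactly ``round(co_fraction * n_a)`` A peaks are placed with a B peak
    within ``window`` bases (gap <= window); the rest are placed with every
    B peak farther than ``2 * window`` away.
    """
    if not 0 <= co_fraction <= 1:
        raise ValueError("co_fraction must lie in [0, 1]")
    n_co = round(co_fraction * n_a)
    if n_co > n_b:
        raise ValueError("co_fraction * n_A exceeds available B peaks")
    n_far = n_a - n_co
    pitch = 6 * window + 4 * peak_len
    n_slots = n_b + n_far
    if (n_slots + 1) * pitch > genome_length:
        raise ValueError("genome_length too small for requested peak counts")

    rng = np.random.default_rng(seed)
    chrom = "chr1"
    b_peaks: list[GenomicInterval] = []
    a_peaks: list[GenomicInterval] = []
    for i in range(n_b):
        start = (i + 1) * pitch
        b_peaks.append(GenomicInterval(chrom, start, start + peak_len,
                                       name=f"B{i + 1:05d}"))
    for j in range(n_co):
        b = b_peaks[j]
        gap = int(rng.integers(0, window + 1))
        start = b.end + gap
        a_peaks.append(GenomicInterval(chrom, start, start + peak_len,
                                       name=f"A{j + 1:05d}"))
    for j in range(n_far):
        # slots beyond all B peaks; pitch >> 2*window keeps them far
        start = (n_b + 1 + j) * pitch
        a_peaks.append(GenomicInterval(chrom, start, start + peak_len,
                                       name=f"A{n_co + j + 1:05d}"))

    truth = TruthLabels(co_occupied_fraction=n_co / n_a if n_a else 0.0)
    return a_peaks, b_peaks, truth


def simulate_cluster_counts(seed: int, species: str, stages: list[str],
                            n_cells_per_stage: int, genes: list[str],
                            planted_windows: dict[str, tuple[str, str]],
                            p_in: float = 0.5, p_out: float = 0.02,
                            cluster: str = "GNP", mean_extra: float = 2.0):
    """Per-cell counts with a planted per-gene expression window over stages.

    Within a gene's planted window each cell expresses the gene (count >= 1,
    1 + Poisson(mean_extra)) with probability ``p_in``; outside, with
    probability ``p_out``.
    """
    from .expression_windows import CellByGeneCounts  # local import: no cycle

    if p_in <= p_out:
        raise ValueError("p_in must exceed p_out")
    rng = np.random.default_rng(seed)
    stage_idx = {s: i for i, s in enumerate(stages)}
    n_cells = n_cells_per_stage * len(stages)
    cells = [f"{species}_{st}_c{i + 1:04d}"
             for st in stages for i in range(n_cells_per_stage)]
    cell_stage = np.repeat(np.arange(len(stages)), n_cells_per_stage)

    mat = np.zeros((n_cells, len(genes)), dtype=int)
    for gj, gene in enumerate(genes):
        win = planted_windows.get(gene)
        if win is not None:
            lo, hi = stage_idx[win[0]], stage_idx[win[1]]
            p = np.where((cell_stage >= lo) & (cell_stage <= hi), p_in, p_out)
        else:
            p = np.full(n_cells, p_out)
        expressing = rng.random(n_cells) < p
        mat[expressing, gj] = 1 + rng.poisson(mean_extra, size=int(expressing.sum()))

    meta = pd.DataFrame({
        "cell": cells,
        "cluster": cluster,
        "stage": [stages[i] for i in cell_stage],
        "species": species,
    }).set_index("cell")
    return CellByGeneCounts(mat, cells, list(genes), meta)


# ---------------------------------------------------------------------------
# Complete fixture directory
# ---------------------------------------------------------------------------

_EBOX = "CAGCTG"
_FIXTURE_SPECIES = ["zebrafish", "frog", "lizard", "mouse", "human", "lamprey"]


def _random_seq_without_ebox(rng: np.random.Generator, length: int) -> str:
    """Random sequence with every CANNTG occurrence (palindromic pattern, so
    both strands at once) broken by mutating its first base."""
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=length))
    changed = True
    while changed:
        changed = False
        s = "".join(seq)
        for i in range(len(s) - 5):
            if s[i] == "C" and s[i + 4] == "T" and s[i + 5] == "G" and s[i + 1] == "A":
                seq[i] = "G"
                changed = True
    return "".join(seq)


def write_fixture(out_dir, seed: int = 1, atlas_cfg: AtlasSimConfig | None = None,
                  co_fraction: float = 0.6, n_peaks_a: int = 500,
                  n_peaks_b: int = 600, peak_window: int = 1000,
                  sc_stages: list[str] | None = None,
                  n_cells_per_stage: int = 500) -> TruthLabels:
    """Emit a complete fixture directory (atlas, catalog, evidence, GMT,
    BEDs, anchors, FASTA, MTX bundle, timelines) plus ``truth.json``."""
    from . import core_io
    from .expression_windows import write_counts_mtx

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = atlas_cfg or AtlasSimConfig(seed=seed)
    rng = np.random.default_rng(seed + 10_007)

    atlas, truth = simulate_atlas(cfg)
    core_io.write_expression_atlas(atlas, out / "atlas.tsv")

    # catalog: every atlas gene, alternating regulator class
    pd.DataFrame({
        "gene": atlas.genes,
        "class": ["transcription_factor" if i % 2 == 0 else "cofactor"
                  for i in range(len(atlas.genes))],
    }).to_csv(out / "catalog.tsv", sep="\t", index=False)

    # ortholog evidence mirrors the planted evolutionary categories
    cat_to_status = {"conserved": "ortholog", "type_I": "related_nonortholog",
                     "type_II": "absent"}
    pd.DataFrame([
        {"gene": g, "outgroup_taxon": "sea_lamprey",
         "status": cat_to_status[c]}
        for g, c in sorted(truth.evo_category.items())
    ]).to_csv(out / "evidence.tsv", sep="\t", index=False)

    # GMT: one signal term per organ (its planted enriched genes) plus
    # random background terms
    with open(out / "terms.gmt", "w", encoding="utf-8") as fh:
        for organ in atlas.organs:
            members = sorted(g for g, o in truth.enriched.items() if o == organ)
            fh.write("\t".join([f"ORGAN_{organ.upper()}",
                                f"{organ} development program", *members]) + "\n")
        for t in range(10):
            members = sorted(rng.choice(atlas.genes, size=40, replace=False))
            fh.write("\t".join([f"RANDOM_{t:02d}", "background term",
                                *members]) + "\n")

    a_peaks, b_peaks, peak_truth = simulate_peaks(
        seed + 1, n_a=n_peaks_a, n_b=n_peaks_b, co_fraction=co_fraction,
        window=peak_window)
    truth.co_occupied_fraction = peak_truth.co_occupied_fraction
    for name, peaks in (("peaks_a.bed", a_peaks), ("peaks_b.bed", b_peaks)):
        with open(out / name, "w", encoding="utf-8") as fh:
            for p in peaks:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\n")

    # gene anchors: one target gene at each B-peak midpoint
    pd.DataFrame([
        {"gene": f"t{i + 1:05d}", "chrom": p.chrom, "anchor": p.midpoint,
         "strand": "+"} for i, p in enumerate(b_peaks)
    ]).to_csv(out / "anchors.tsv", sep="\t", index=False)

    # orthologous enhancer FASTA: E-box present in all species but lamprey
    with open(out / "enhancers.fasta", "w", encoding="utf-8") as fh:
        for sp in _FIXTURE_SPECIES:
            seq = _random_seq_without_ebox(rng, 500)
            if sp != "lamprey":
                pos = int(rng.integers(100, 400))
                seq = seq[:pos] + _EBOX + seq[pos + len(_EBOX):]
            fh.write(f">{sp}\n{seq}\n")

    # single-cell counts with a planted mouse GNP window E12.5 -> P10
    stages = sc_stages or ["E10.5", "E11.5", "E12.5", "E13.5", "E14.5",
                           "E15.5", "E16.5", "E17.5", "P0", "P4", "P10"]
    sc_genes = ["Tox3", "Atoh1", "Mki67", "Neurod1"]
    windows = {"Tox3": ("E12.5", "P10"), "Atoh1": ("E12.5", "P10"),
               "Mki67": ("E10.5", "P10")}
    truth.planted_window = dict(windows)
    counts = simulate_cluster_counts(seed + 2, "mouse", stages,
                                     n_cells_per_stage, sc_genes, windows)
    write_counts_mtx(counts, out / "counts.mtx", out / "sc_genes.tsv",
                     out / "sc_cells.tsv", out / "sc_meta.tsv")

    # species timelines (gestation and mean lifespan in days; fixture values)
    pd.DataFrame([
        {"species": "zebrafish", "gestation_days": 0, "lifespan_days": 1278},
        {"species": "mouse", "gestation_days": 19, "lifespan_days": 730},
        {"species": "human", "gestation_days": 280, "lifespan_days": 29200},
    ]).to_csv(out / "species.tsv", sep="\t", index=False)
    stage_rows = []
    for st in stages:
        ds = parse_stage(st)
        age = ds.value if ds.phase == "embryonic" else 19 + ds.value
        stage_rows.append({"species": "mouse", "stage": st, "age_days": age})
    pd.DataFrame(stage_rows).to_csv(out / "stage_map.tsv", sep="\t", index=False)

    truth.to_json(out / "truth.json")
    return truth
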