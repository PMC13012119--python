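"""End-to-end orchestration: screen, co-binding and expression-window runs.

Each run reads a YAML config, executes the corresponding module chain and
writes TSV tables plus a JSON report carrying a provenance block (config
hash, seed, input digests, tool version).  Data outputs contain no
timestamps; identical config and inputs produce byte-identical outputs.
All files are written to a temporary name and atomically renamed, so a
failed run never leaves a partial report behind.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import sys
import time
from pathlib import Path

import yaml

from . import __version__
from .core_io import (parse_stage, read_expression_atlas, read_regulator_catalog,
                      read_species_timeline, restrict_to_catalog)
from .enrichment import EnrichmentConfig, call_enrichment, grouped_heatmap_table, write_calls
from .temporal_screen import ScreenConfig, screen_candidates, write_candidates
from .evo_classify import category_counts, classify_candidates, read_ortholog_evidence
from .ontology_enrich import enrich_terms, read_gmt, top_terms, write_results
from .cooccupancy import (MotifQuery, nearest_gene, proximity_overlap, read_bed,
                          read_fasta_by_species, read_gene_anchors, shared_targets,
                          species_motif_presence)
from .expression_windows import (extract_window, normalize_duration,
                                 read_counts_mtx, summarize_dotplot)

log = logging.getLogger("regdiscover")

__all__ = ["run_screen", "run_cobind", "run_windows", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input path."""

    def __init__(self, stage: str, path, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {path}: {cause}")
        self.stage = stage


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _provenance(config: dict, seed: int | None, input_paths: dict) -> dict:
    return {
        "tool_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()).hexdigest(),
        "input_sha256": {k: _sha256(v) for k, v in input_paths.items()},
    }


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


class _AtomicDir:
    """Collects outputs and renames them into place only if the run succeeds."""

    def __init__(self, out_dir: Path):
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.staged: list[tuple[Path, Path]] = []

    def path(self, name: str) -> Path:
        tmp = self.out / (name + ".tmp")
        self.staged.append((tmp, self.out / name))
        return tmp

    def commit(self) -> None:
        for tmp, final in self.staged:
            os.replace(tmp, final)

    def abort(self) -> None:
        for tmp, _ in self.staged:
            tmp.unlink(missing_ok=True)


def _timed(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: %.2f s", stage, time.perf_counter() - self.t0)
            return False
    return _T()


def _load_config(config_path) -> dict:
    with open(config_path, encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def run_screen(config_path, out_dir, seed: int | None = None) -> dict:
    """Regulator screen: restrict atlas to catalog, call organ enrichment,
    apply the temporal screen per configured organ, classify candidates by
    outgroup evidence and test term enrichment of each organ's enriched set.
    """
    config = _load_config(config_path)
    sec = config.get("screen", {})
    inputs = {k: sec[k] for k in ("atlas", "catalog") if k in sec}
    for opt in ("evidence", "gmt"):
        if opt in sec:
            inputs[opt] = sec[opt]
    outdir = _AtomicDir(Path(out_dir))
    report: dict = {"provenance": _provenance(config, seed, inputs)}

    try:
        with _timed("read_inputs"):
            atlas = _stage("read_atlas", sec.get("atlas"), read_expression_atlas,
                           sec["atlas"])
            catalog = _stage("read_catalog", sec.get("catalog"),
                             read_regulator_catalog, sec["catalog"])
        with _timed("restrict_to_catalog"):
            atlas = _stage("restrict_to_catalog", sec.get("atlas"),
                           restrict_to_catalog, atlas, catalog)

        ecfg = EnrichmentConfig(**sec.get("enrichment", {}))
        with _timed("call_enrichment"):
            calls = _stage("call_enrichment", sec.get("atlas"),
                           call_enrichment, atlas, ecfg)
        write_calls(calls, atlas, outdir.path("enrichment_calls.tsv"))
        heat = grouped_heatmap_table(calls, atlas)
        heat.to_csv(outdir.path("heatmap_table.tsv"), sep="\t", index=False)
        enriched_by_organ = {
            organ: [c.gene for c in calls if c.organ == organ]
            for organ in atlas.organs
        }
        report["enriched_counts"] = {o: len(g) for o, g in enriched_by_organ.items()}

        t = dict(sec.get("temporal", {}))
        for key in ("numerator_stage", "denominator_stage"):
            if key in t:
                t[key] = parse_stage(t[key])
        scfg = ScreenConfig(**t)
        organs = sec.get("organs") or list(atlas.organs)
        all_passing: list[str] = []
        report["screen"] = {}
        for organ in organs:
            if organ not in atlas.organs:
                raise StageError("screen_candidates", sec.get("atlas"),
                                 ValueError(f"organ not in atlas: {organ!r}"))
            genes = enriched_by_organ.get(organ, [])
            if not genes:
                report["screen"][organ] = {"n_screened": 0, "n_pass": 0}
                continue
            with _timed(f"screen_candidates[{organ}]"):
                records = _stage("screen_candidates", sec.get("atlas"),
                                 screen_candidates, atlas, organ, genes, scfg)
            write_candidates(records, scfg,
                             outdir.path(f"candidates_{organ}.tsv"))
            passing = [r.gene for r in records if r.passes]
            all_passing.extend(passing)
            report["screen"][organ] = {"n_screened": len(records),
                                       "n_pass": len(passing)}

        if "evidence" in sec:
            with _timed("classify_candidates"):
                evidence = _stage("read_evidence", sec["evidence"],
                                  read_ortholog_evidence, sec["evidence"])
                classes = _stage("classify_candidates", sec["evidence"],
                                 classify_candidates, sorted(all_passing), evidence)
            lines = "gene\tcategory\n" + "".join(
                f"{c.gene}\t{c.category}\n" for c in classes)
            _write_text(outdir, "evo_classes.tsv", lines)
            report["evo_counts"] = category_counts(classes)

        if "gmt" in sec:
            with _timed("enrich_terms"):
                annotations = _stage("read_gmt", sec["gmt"], read_gmt, sec["gmt"])
                universe = set(atlas.genes)
                report["term_enrichment"] = {}
                for organ in organs:
                    query = set(enriched_by_organ.get(organ, []))
                    if not query:
                        continue
                    results = _stage("enrich_terms", sec["gmt"], enrich_terms,
                                     query, annotations, universe)
                    results = top_terms(results, int(sec.get("top_terms", 10)))
                    write_results(results,
                                  outdir.path(f"terms_{organ}.tsv"))
                    report["term_enrichment"][organ] = [
                        {"term": r.term, "k": r.overlap_k, "p": r.p_value,
                         "q": r.q_value} for r in results
                    ]

        _write_text(outdir, "report.json",
                    json.dumps(report, indent=1, sort_keys=True) + "\n")
        outdir.commit()
    except Exception:
        outdir.abort()
        raise
    return report


def run_cobind(config_path, out_dir, seed: int | None = None) -> dict:
    """Co-binding analysis of two peak sets: proximity fraction, nearest
    anchor genes, shared targets, optional term enrichment of shared targets
    and optional per-species E-box presence."""
    config = _load_config(config_path)
    sec = config.get("cobind", {})
    inputs = {k: sec[k] for k in ("peaks_a", "peaks_b", "anchors", "gmt", "fasta")
              if k in sec}
    outdir = _AtomicDir(Path(out_dir))
    report: dict = {"provenance": _provenance(config, seed, inputs)}
    window = int(sec.get("window", 1000))

    try:
        peaks_a = _stage("read_bed", sec.get("peaks_a"), read_bed, sec["peaks_a"])
        peaks_b = _stage("read_bed", sec.get("peaks_b"), read_bed, sec["peaks_b"])
        if peaks_b:
            with _timed("proximity_overlap"):
                flags, fraction = _stage("proximity_overlap", sec.get("peaks_a"),
                                         proximity_overlap, peaks_a, peaks_b, window)
        else:
            log.warning("empty B peak set; co-occupancy fraction set to 0")
            flags, fraction = [False] * len(peaks_a), 0.0
        report["cooccupancy"] = {"n_A": len(peaks_a), "n_B": len(peaks_b),
                                 "window": window, "fraction_near": fraction}
        lines = ["peak\tchrom\tstart\tend\tnear_B"]
        for p, f in zip(peaks_a, flags):
            lines.append(f"{p.name or '.'}\t{p.chrom}\t{p.start}\t{p.end}"
                         f"\t{str(f).lower()}")
        _write_text(outdir, "proximity_flags.tsv", "\n".join(lines) + "\n")

        if "anchors" in sec:
            anchors = _stage("read_anchors", sec["anchors"], read_gene_anchors,
                             sec["anchors"])
            with _timed("nearest_gene"):
                genes_a = _stage("nearest_gene", sec.get("peaks_a"),
                                 nearest_gene, peaks_a, anchors)
                genes_b = _stage("nearest_gene", sec.get("peaks_b"),
                                 nearest_gene, peaks_b, anchors)
            targets_a = {g for g in genes_a if g}
            targets_b = {g for g in genes_b if g}
            shared, co_frac = shared_targets(targets_a, targets_b)
            report["shared_targets"] = {"n_A_targets": len(targets_a),
                                        "n_B_targets": len(targets_b),
                                        "n_shared": len(shared),
                                        "fraction_of_A": co_frac}
            _write_text(outdir, "shared_targets.tsv",
                        "gene\n" + "".join(f"{g}\n" for g in sorted(shared)))
            if "gmt" in sec and shared:
                annotations = read_gmt(sec["gmt"])
                universe = set(anchors.records)
                results = enrich_terms(shared, annotations, universe)
                results = top_terms(results, int(sec.get("top_terms", 6)))
                write_results(results, outdir.path("shared_target_terms.tsv"))

        if "fasta" in sec:
            seqs = read_fasta_by_species(sec["fasta"])
            query = MotifQuery(pattern=sec.get("motif", "CANNTG"))
            presence = species_motif_presence(seqs, query)
            report["motif_presence"] = {
                sp: {"present": d["present"], "n_hits": len(d["positions"])}
                for sp, d in presence.items()
            }
            lines = ["species\tpresent\tpositions"]
            for sp, d in presence.items():
                lines.append(f"{sp}\t{str(d['present']).lower()}\t"
                             + ",".join(map(str, d["positions"])))
            _write_text(outdir, "motif_presence.tsv", "\n".join(lines) + "\n")

        _write_text(outdir, "report.json",
                    json.dumps(report, indent=1, sort_keys=True) + "\n")
        outdir.commit()
    except Exception:
        outdir.abort()
        raise
    return report


def run_windows(config_path, out_dir, seed: int | None = None) -> dict:
    """Dot-plot summaries and lifespan-normalized expression windows."""
    config = _load_config(config_path)
    sec = config.get("windows", {})
    inputs = {k: sec[k] for k in ("mtx", "genes", "cells", "meta",
                                  "species_table", "stage_map") if k in sec}
    outdir = _AtomicDir(Path(out_dir))
    report: dict = {"provenance": _provenance(config, seed, inputs)}

    try:
        counts = _stage("read_counts", sec.get("mtx"), read_counts_mtx,
                        sec["mtx"], sec["genes"], sec["cells"], sec["meta"])
        goi = sec.get("genes_of_interest") or counts.genes
        with _timed("summarize_dotplot"):
            summary = _stage("summarize_dotplot", sec.get("mtx"),
                             summarize_dotplot, counts, goi)
        summary.table.to_csv(outdir.path("dotplot_summary.tsv"),
                             sep="\t", index=False, float_format="%.6g")

        stage_order = sec.get("stage_order")
        if stage_order is None:
            observed = counts.cell_meta["stage"].unique().tolist()
            stage_order = sorted(observed, key=lambda s: parse_stage(s)._key)
        cluster = sec.get("cluster", "GNP")
        min_fraction = float(sec.get("min_fraction", 0.2))

        timelines = {}
        if "species_table" in sec:
            timelines = read_species_timeline(sec["species_table"],
                                              sec["stage_map"])
        species = sec.get("species", "")
        windows_out = []
        for gene in goi:
            w = extract_window(summary, gene, cluster, stage_order,
                               min_fraction, species=species)
            if w is None:
                windows_out.append({"gene": gene, "window": None})
                continue
            if species in timelines:
                w = normalize_duration(w, timelines[species])
            windows_out.append({
                "gene": gene, "first_stage": w.first_stage,
                "last_stage": w.last_stage, "dip_count": w.dip_count,
                "duration_days": w.duration_days,
                "normalized_duration": w.normalized_duration,
            })
        report["windows"] = windows_out
        report["min_fraction"] = min_fraction
        _write_text(outdir, "windows.json",
                    json.dumps(windows_out, indent=1, sort_keys=True) + "\n")
        _write_text(outdir, "report.json",
                    json.dumps(report, indent=1, sort_keys=True) + "\n")
        outdir.commit()
    except Exception:
        outdir.abort()
        raise
    return report


def _stage(name: str, path, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, path, exc) from exc


def _write_text(outdir: _AtomicDir, name: str, text: str) -> None:
    outdir.path(name).write_text(text)


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(stream=sys.stderr, level=logging.INFO if verbose else
                        logging.WARNING, format="%(levelname)s %(message)s")
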