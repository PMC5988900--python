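"""End-to-end orchestration: simulate/ingest -> classify -> scan -> count ->
targets -> network, with a reproducibility manifest.

A single YAML/dict config drives the run; every analysis constant (scan
threshold 0.6, promoter window 100/50, top-100 candidate list, p < 0.05,
fold-change gate 4, minimum peak 5) is a config key with its default.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .io import read_catalog, read_fasta, read_peaks, read_pwm, write_hits_bed
from .motifs import (
    count_peak_overlaps,
    count_sites_in_window,
    match_degenerate,
    promoter_window,
    scan_genome,
)
from .network import build_network, export_network, multiregulated
from .phases import classify_catalog, count_by_phase, select_study_set
from .targets import (
    annotate_targets,
    cellcycle_fraction,
    confirmed_targets,
    read_annotation,
    read_predictions,
)

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_PARAMS", "run_all"]

DEFAULT_PARAMS = {
    "rel_threshold": 0.6,
    "upstream": 100,
    "downstream": 50,
    "top_n": 100,
    "p_max": 0.05,
    "fold_threshold": 4.0,
    "min_peak": 5.0,
    "circular": True,
    "iupac_motifs": ["GANTC"],
    "multiregulated_k": 2,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    """Context manager that re-raises any failure tagged with the stage name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        logger.info("stage %s: done", self.name)
        return False


def run_all(config: dict, out_dir: str | Path, force: bool = False) -> dict:
    """Run every configured stage and write outputs plus a manifest.

    Returns the manifest dict.  ``config`` keys: ``seed``, ``params``
    (defaults in :data:`DEFAULT_PARAMS`), ``simulate`` (a SimulationConfig
    field dict; generates the inputs) and/or ``inputs`` (paths: genome,
    catalog, pwms, peaks, predator, copra, targetrna2, annotation).
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True to overwrite)")
    out.mkdir(parents=True, exist_ok=True)

    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    seed = int(config.get("seed", 0))
    inputs = dict(config.get("inputs", {}))
    counts_log: dict[str, object] = {}

    if "simulate" in config:
        with _Stage("simulate"):
            from .simulate import SimulationConfig, write_all

            sim_cfg = SimulationConfig(seed=seed, **config["simulate"])
            sim_paths = write_all(sim_cfg, out / "sim")
            for key in ("genome", "catalog", "peaks", "predator", "copra",
                        "targetrna2", "annotation"):
                inputs.setdefault(key, str(sim_paths[key]))
            inputs.setdefault("pwm_files", [])

    with _Stage("classify"):
        catalog = read_catalog(inputs["catalog"])
        study, report = select_study_set(catalog)
        classified = classify_catalog(
            study, fold_threshold=params["fold_threshold"], min_peak=params["min_peak"]
        )
        # keep curated phases where the catalog provides them
        curated = {
            (r.id, r.tss_position): r.phase for r in study if r.phase is not None
        }
        from dataclasses import replace

        classified = [
            replace(r, phase=curated.get((r.id, r.tss_position), r.phase))
            for r in classified
        ]
        tss_tally = count_by_phase(classified, level="tss")
        ncrna_tally = count_by_phase(classified, level="ncrna")
        counts_log["filter_chain"] = report.__dict__
        counts_log["phase_tally_tss"] = tss_tally
        counts_log["phase_tally_ncrna"] = ncrna_tally
        logger.info("phase tallies (TSS rows): %s", tss_tally)
        logger.info("phase tallies (distinct ncRNAs): %s", ncrna_tally)
        from .simulate import catalog_to_tsv

        catalog_to_tsv(classified, out / "catalog_classified.tsv")

    site_count_rows: list[dict] = []
    if "genome" in inputs:
        with _Stage("scan"):
            genome = read_fasta(inputs["genome"], circular=params["circular"])
            pwms = [read_pwm(p) for p in inputs.get("pwm_files", [])]
            hit_sets = {}
            for pwm in pwms:
                hits = scan_genome(pwm, genome, rel_threshold=params["rel_threshold"])
                hit_sets[pwm.motif_id] = hits
                write_hits_bed(hits, out / f"hits_{pwm.motif_id}.bed", chrom=genome.name)
            for pattern in params["iupac_motifs"]:
                hits = match_degenerate(pattern, genome)
                hit_sets[pattern] = hits
                write_hits_bed(hits, out / f"hits_{pattern}.bed", chrom=genome.name)
            peaks = read_peaks(inputs["peaks"]) if "peaks" in inputs else []
            n = len(genome)
            for rec in classified:
                win = promoter_window(
                    rec, upstream=params["upstream"], downstream=params["downstream"],
                    genome_length=n, circular=params["circular"], chrom=genome.name,
                )
                row = {"ccna": rec.id, "tss": rec.tss_position, "strand": rec.strand}
                for motif_id, hits in hit_sets.items():
                    row[motif_id] = count_sites_in_window(hits, win, genome_length=n)
                row["peaks"] = count_peak_overlaps(peaks, win, genome_length=n)
                site_count_rows.append(row)
            pd.DataFrame(site_count_rows).to_csv(
                out / "promoter_counts.tsv", sep="\t", index=False
            )
            counts_log["scan_hits"] = {m: len(h) for m, h in hit_sets.items()}

    pairs: list[tuple[str, str]] = []
    categories: dict[str, tuple[set, set]] = {}
    if all(k in inputs for k in ("predator", "copra", "targetrna2")):
        with _Stage("targets"):
            predator = read_predictions(inputs["predator"], "predator")
            copra = read_predictions(inputs["copra"], "copra")
            tr2 = read_predictions(inputs["targetrna2"], "targetrna2")
            pairs = confirmed_targets(
                predator, copra, tr2, top_n=params["top_n"], p_max=params["p_max"]
            )
            counts_log["confirmed_pairs"] = len(pairs)
            if "annotation" in inputs:
                annotation = read_annotation(inputs["annotation"])
                categories = annotate_targets(pairs, annotation)
                phase_by_id: dict[str, str | None] = {}
                for r in classified:
                    if r.phase is not None or r.id not in phase_by_id:
                        phase_by_id[r.id] = r.phase
                rows = [
                    (rid, phase_by_id.get(rid), categories.get(rid, (set(), set()))[0])
                    for rid in sorted({r.id for r in classified})
                ]
                fractions = cellcycle_fraction(rows)
                counts_log["cellcycle_fraction"] = {
                    k: list(v) for k, v in fractions.items()
                }
                table2 = pd.DataFrame(
                    [
                        {
                            "ccna": rid,
                            "phase": phase if phase is not None else "/",
                            "functions": ", ".join(sorted(cats)),
                            "significant_genes": ", ".join(
                                sorted(categories.get(rid, (set(), set()))[1])
                            ),
                        }
                        for rid, phase, cats in rows
                    ]
                )
                table2.to_csv(out / "target_functions.tsv", sep="\t", index=False)

    with _Stage("network"):
        if site_count_rows:
            counts_df = pd.DataFrame(site_count_rows).rename(
                columns={"GANTC": "ccrm", "peaks": "gcra_peaks"}
            )
            for col in ("ctra_full", "ctra_half", "ccrm", "dnaa", "gcra_peaks"):
                if col not in counts_df.columns:
                    counts_df[col] = 0
        else:
            counts_df = pd.DataFrame(
                {"ccna": sorted({r.id for r in classified}),
                 "ctra_full": 0, "ctra_half": 0, "ccrm": 0, "dnaa": 0, "gcra_peaks": 0}
            )
        net = build_network(counts_df, pairs, catalog_ids={r.id for r in classified})
        export_network(net, "sif", out / "network.sif")
        export_network(net, "graphml", out / "network.graphml")
        export_network(net, "tsv", out / "network.tsv")
        counts_log["network"] = {
            "nodes": net.number_of_nodes(),
            "edges": net.number_of_edges(),
            "multiregulated": multiregulated(net, k=params["multiregulated_k"]),
        }

    with _Stage("manifest"):
        manifest = {
            "tool": "cyclereg",
            "version": __version__,
            "seed": seed,
            "config": {"params": params, "inputs": {k: str(v) for k, v in inputs.items()}},
            "counts": counts_log,
            "outputs": {
                p.name: _sha256(p)
                for p in sorted(out.rglob("*"))
                if p.is_file() and p.name != "manifest.json"
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
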