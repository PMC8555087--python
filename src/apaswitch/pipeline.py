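"""End-to-end orchestration: simulate/ingest -> call -> filter -> assign ->
differential APA & DE, with a reproducibility manifest.

A single config (YAML) drives every stage; all thresholds of the
analysis are collected in :class:`PipelineParams`. Outputs are plain
TSV/BED/JSON so a run is diffable; rerunning with the same config and
seed reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass

import pandas as pd
import yaml
from Bio import SeqIO

from . import diff_apa, gene_assign, pas_calling, pas_filters, simdata

log = logging.getLogger("apaswitch")

__all__ = ["PipelineParams", "analyze_dataset", "run_pipeline", "load_genome_fasta"]


@dataclass(frozen=True)
class PipelineParams:
    """All tunable constants of the analysis with their defaults."""

    w: int = 25
    ip_window: tuple[int, int] = (-30, 10)
    ip_run_length: int = 7
    signal_window: tuple[int, int] = (-30, 0)
    utr_extension_cap: int = 5000
    min_pas_count: int = 10
    apa_fdr: float = 0.05
    de_fdr: float = 0.01
    de_fc: float = 2.0
    seed: int = 0


def load_genome_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _clusters_to_bed(clusters, path: str) -> None:
    with open(path, "w") as fh:
        for cl in clusters:
            fh.write(
                f"{cl.chrom}\t{cl.seed_site}\t{cl.seed_site + 1}\t{cl.pas_id}"
                f"\t{cl.total_count}\t{cl.strand}\n"
            )


def analyze_dataset(
    genome: dict[str, str],
    annotation: pd.DataFrame,
    events: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    params: PipelineParams | None = None,
) -> dict:
    """Run call -> filter -> assign -> test -> switch/DE calls in memory.

    Returns a dict with the intermediate objects of every stage:
    clusters, kept, removal_log, extended, assigned, unassigned,
    apa_genes, matrix, results (per-PAS test table with gene_id and
    rank), switches, gene_counts, de.
    """
    params = params or PipelineParams()
    clusters = pas_calling.cluster_events(events, w=params.w)
    fparams = pas_filters.FilterParams(
        ip_window=params.ip_window,
        ip_run_length=params.ip_run_length,
        signal_window=params.signal_window,
    )
    kept, removal_log = pas_filters.filter_pas(clusters, genome, fparams)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    extended = gene_assign.extend_3p(annotation, chrom_lengths, cap=params.utr_extension_cap)
    assigned, unassigned = gene_assign.assign_pas(kept, extended)
    assigned, apa_genes = gene_assign.rank_pas(assigned)
    matrix = pas_calling.build_count_matrix(assigned, sample_sheet)
    results = diff_apa.nb_test(matrix.counts, matrix.sample_meta, min_total=params.min_pas_count)
    meta_cols = pd.DataFrame(
        {"gene_id": [cl.gene_id for cl in assigned], "rank": [cl.rank for cl in assigned]},
        index=pd.Index([cl.pas_id for cl in assigned], name="pas_id"),
    )
    results = results.join(meta_cols, how="left")
    switches = diff_apa.call_apa_switches(results, alpha=params.apa_fdr)
    gene_counts = matrix.counts.groupby(
        pd.Series({cl.pas_id: cl.gene_id for cl in assigned})
    ).sum()
    gene_counts.index.name = "gene_id"
    de = diff_apa.call_de_genes(
        gene_counts, matrix.sample_meta, fdr=params.de_fdr, fc=params.de_fc,
        min_total=params.min_pas_count,
    )
    return {
        "clusters": clusters,
        "kept": kept,
        "removal_log": removal_log,
        "extended": extended,
        "assigned": assigned,
        "unassigned": unassigned,
        "apa_genes": apa_genes,
        "matrix": matrix,
        "results": results,
        "switches": switches,
        "gene_counts": gene_counts,
        "de": de,
    }


def run_pipeline(config: str | dict, outdir: str) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    ``config`` is a YAML path or an equivalent dict with optional keys
    ``params`` (PipelineParams overrides), and either ``simulate``
    (SimConfig overrides; the synthetic generator provides the inputs)
    or ``inputs`` with ``genome``, ``annotation`` and ``samples`` (sample
    sheet TSV with columns sample, path, group, replicate).
    """
    if isinstance(config, str):
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
        cfg_path = config
    else:
        cfg, cfg_path = dict(config), None
    params = PipelineParams(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in (cfg.get("params") or {}).items()})
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {"params": asdict(params), "inputs": {}, "counts": {}}

    truth = None
    if "simulate" in cfg:
        sim_cfg = simdata.SimConfig(**{**(cfg["simulate"] or {}), "seed": cfg.get("simulate", {}).get("seed", params.seed)})
        log.info("simulating dataset: %d genes, seed %d", sim_cfg.n_genes, sim_cfg.seed)
        genome, annotation, truth, samples, sheet = simdata.simulate_dataset(sim_cfg)
        events = pd.concat(
            [df.assign(sample=sid) for sid, df in samples.items()], ignore_index=True
        )[pas_calling.EVENT_COLUMNS]
        manifest["inputs"]["simulate"] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(sim_cfg).items()
        }
        chrom_lengths = {c: len(s) for c, s in genome.items()}
    elif "inputs" in cfg:
        inp = cfg["inputs"]
        genome = load_genome_fasta(inp["genome"])
        annotation = pd.read_csv(inp["annotation"], sep="\t")
        sheet = pd.read_csv(inp["samples"], sep="\t")
        events = pas_calling.read_events(dict(zip(sheet["sample"], sheet["path"])))
        for key in ("genome", "annotation", "samples"):
            manifest["inputs"][key] = {"path": inp[key], "sha256": _sha256(inp[key])}
        chrom_lengths = {c: len(s) for c, s in genome.items()}
    else:
        raise ValueError("config must contain either 'simulate' or 'inputs'")
    manifest["seed"] = params.seed
    if cfg_path:
        manifest["config"] = {"path": cfg_path, "sha256": _sha256(cfg_path)}
    manifest["counts"]["events_in"] = int(len(events))

    stages = analyze_dataset(genome, annotation, events, sheet, params)
    manifest["counts"]["clusters"] = len(stages["clusters"])
    _clusters_to_bed(stages["clusters"], os.path.join(outdir, "pas.bed"))
    manifest["counts"]["removed_by_filter"] = len(stages["removal_log"])
    manifest["counts"]["kept_after_filter"] = len(stages["kept"])
    _clusters_to_bed(stages["kept"], os.path.join(outdir, "pas_filtered.bed"))
    stages["removal_log"].to_csv(os.path.join(outdir, "removal_log.tsv"), sep="\t", index=False)
    manifest["counts"]["assigned"] = len(stages["assigned"])
    manifest["counts"]["unassigned"] = len(stages["unassigned"])
    manifest["counts"]["apa_genes"] = len(stages["apa_genes"])
    pd.DataFrame(
        [(cl.pas_id, cl.gene_id, cl.rank, cl.seed_site) for cl in stages["assigned"]],
        columns=["pas_id", "gene_id", "rank", "seed_site"],
    ).to_csv(os.path.join(outdir, "assignment.tsv"), sep="\t", index=False)
    stages["matrix"].counts.to_csv(os.path.join(outdir, "counts.tsv"), sep="\t")
    stages["results"].to_csv(os.path.join(outdir, "pas_results.tsv"), sep="\t")
    manifest["counts"]["tested_pas"] = int(len(stages["results"]))
    switches = stages["switches"]
    switches.to_csv(os.path.join(outdir, "switches.tsv"), sep="\t", index=False)
    manifest["counts"]["switch_genes"] = int(len(switches))
    manifest["counts"]["switch_class_I"] = int((switches["apa_class"] == "I").sum())
    manifest["counts"]["switch_class_II"] = int((switches["apa_class"] == "II").sum())
    de = stages["de"]
    de.to_csv(os.path.join(outdir, "de_genes.tsv"), sep="\t")
    manifest["counts"]["cool_up"] = int((de["category"] == "CoolUp").sum())
    manifest["counts"]["cool_down"] = int((de["category"] == "CoolDown").sum())

    if truth is not None:
        truth.switch_genes.to_csv(os.path.join(outdir, "truth_switches.tsv"), sep="\t", index=False)

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
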