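"""End-to-end orchestration: simulate -> DE -> scan -> enrich -> isoforms -> report.

A single global seed fans out deterministically to per-stage child seeds
(simulation and the shuffled-miRNA null), so identical config + seed gives
byte-identical output tables; a run manifest records every threshold, the
stage seeds, the package version and a SHA-256 of each emitted file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffexpr import build_groups, groups_to_frame
from .enrichment import compute_enrichment, composition_from_counts
from .io import (
    PipelineConfig,
    read_fasta_regions,
    read_matrix,
    read_mirna,
    read_table,
    write_fasta_regions,
    write_matrix,
    write_table,
)
from .isoforms import find_inverse_pairs, pairs_to_frame
from .motifs import build_tables, count_catalogue, enumerate_motifs
from .synth import SynthConfig, generate_dataset

logger = logging.getLogger("mirmotif")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds (< 2**31) from the global seed."""
    state = np.random.SeedSequence(seed).generate_state(2, dtype=np.uint64)
    return {
        "simulate": int(state[0] % (2**31)),
        "enrich": int(state[1] % (2**31)),
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    synth_config: SynthConfig | None = None,
) -> Path:
    """Run every stage and return the report directory.

    With ``config.simulate`` (the default) the inputs come from the synthetic
    generator (``synth_config`` overrides its defaults; its seed is replaced
    by the pipeline's simulate child seed).  Otherwise the configured input
    paths are read.  Emits groups, DE, catalogue, counts, enrichment, region
    summary, composition and pairs tables plus ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str):
        path = out / name
        write_table(df, path)
        written.append(path)

    stage = "simulate"
    try:
        if config.simulate:
            scfg = replace(synth_config or SynthConfig(), seed=seeds["simulate"])
            annotation, truth, matrix, samples = generate_dataset(scfg)
            mirna = scfg.mirna
            write_fasta_regions(annotation, out / "regions.fasta")
            written.append(out / "regions.fasta")
            emit(annotation.table, "regions.tsv")
            write_matrix(matrix, out / "matrix.tsv")
            written.append(out / "matrix.tsv")
            emit(samples, "samples.tsv")
            emit(truth.transcripts, "truth_transcripts.tsv")
        else:
            if not (config.fasta_path and config.matrix_path
                    and config.samples_path and config.mirna_path):
                raise PipelineError(
                    "stage simulate/load: fasta_path, matrix_path, samples_path "
                    "and mirna_path are required when simulate is false"
                )
            table = read_table(config.regions_path) if config.regions_path else None
            annotation = read_fasta_regions(config.fasta_path, table)
            matrix = read_matrix(config.matrix_path)
            samples = read_table(config.samples_path)
            mirna = read_mirna(config.mirna_path)

        stage = "de"
        groups, de_table = build_groups(
            matrix, samples,
            fc_up=config.fc_up, fc_down=config.fc_down, alpha=config.alpha,
            min_lines=config.min_lines, reference=config.reference,
            welch=config.welch,
        )
        emit(de_table, "de.tsv")
        emit(groups_to_frame(groups), "groups.tsv")

        stage = "scan"
        motifs = enumerate_motifs(mirna, config.k_min, config.k_max)
        emit(
            pd.DataFrame(
                {
                    "motif": [m.subsequence for m in motifs],
                    "k": [m.k for m in motifs],
                    "start_1based": [m.start_1based for m in motifs],
                    "origin_class": [m.origin_class for m in motifs],
                    "target_site": [m.target_site for m in motifs],
                }
            ),
            "catalogue.tsv",
        )
        tables = build_tables(
            annotation.sequences, groups, ks=range(config.k_min, config.k_max + 1)
        )
        if tables.n_missing:
            logger.warning(
                "%d grouped transcripts missing from the annotation", tables.n_missing
            )
        counts = count_catalogue(tables, motifs)
        emit(counts.to_frame(), "counts.tsv")

        stage = "enrich"
        result = compute_enrichment(
            tables, mirna,
            n_shuffles=config.n_shuffles, seed=seeds["enrich"],
            k_min=config.k_min, k_max=config.k_max,
            threshold=config.ratio_threshold, pseudocount=config.pseudocount,
            mode=config.counting_mode,
        )
        emit(result.motif_table, "enrichment.tsv")
        emit(result.region_summary, "region_summary.tsv")
        if config.k_min <= 8 <= config.k_max:
            emit(composition_from_counts(counts, region="UTR5", k=8), "composition.tsv")

        stage = "isoforms"
        pairs = find_inverse_pairs(
            de_table, annotation.gene_of(),
            min_lines=config.min_lines, fc_up=config.fc_up,
            fc_down=config.fc_down, alpha=config.alpha,
        )
        emit(pairs_to_frame(pairs), "pairs.tsv")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    stage = "report"
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "pseudocount": result.pseudocount,
        "group_sizes": dict(tables.group_sizes),
        "n_missing_transcripts": tables.n_missing,
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out
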