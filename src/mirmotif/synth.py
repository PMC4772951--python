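"""Synthetic transcriptome and expression-matrix generator with known truth.

Emulates the study design the pipeline targets: three cell cultures, each
transfected in replicate with a miRNA inhibitor, a non-targeting control
oligonucleotide, or mock-treated, profiled as log2 intensities.  Each gene
carries one or more transcript isoforms with 5'UTR / CDS / 3'UTR region
sequences drawn i.i.d. at a configured GC content.  A configurable fraction
of transcripts receives a positive or negative treatment effect (derepressed
or repressed upon miRNA inhibition), a chosen (region, DE group) combination
receives planted miRNA target sites at an elevated rate, and a set of genes
gets an inverse isoform pair (one isoform up, one down) as splice-switch
ground truth.

Everything is driven by one seed: identical config + seed reproduces
byte-identical sequences, truth and matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Annotation
from .motifs import (
    GROUPS,
    MIR10B,
    REGIONS,
    MatureMiRNA,
    enumerate_motifs,
    normalize_sequence,
)

DIRECTION_TO_CLASS = {1: "up", -1: "down", 0: "unchanged"}
CONDITIONS = ("inhibitor", "control", "mock")


class ConfigError(ValueError):
    """A SynthConfig field violates its invariant (the message names it)."""


class PlacementError(RuntimeError):
    """Requested site copies cannot be placed without overlap."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Region lengths are drawn per transcript from a normal distribution
    (mean, sd) in nt, floored at a minimum; the CDS is rounded up to a
    multiple of 3.  ``plant_rate_target`` / ``plant_rate_background`` are
    Poisson means of planted sites per transcript for the targeted
    (plant_region, plant_group) combination versus everywhere else.  Planted
    site sequences default to the target sites of the miRNA's 3'-end-derived
    ``plant_k``-mer windows; override with ``plant_sites``.
    """

    seed: int = 0
    n_genes: int = 1000
    isoforms_per_gene: tuple[int, int] = (1, 2)
    region_lengths: dict = field(
        default_factory=lambda: {
            "UTR5": (200.0, 60.0),
            "CDS": (1200.0, 300.0),
            "UTR3": (800.0, 250.0),
        }
    )
    min_region_length: int = 30
    gc_content: float = 0.45
    n_cell_lines: int = 3
    n_replicates_per_condition: int = 2
    noise_sd: float = 0.25
    frac_up: float = 0.10
    frac_down: float = 0.10
    effect_log2fc: float = 1.0
    plant_region: str = "UTR5"
    plant_group: str = "up"
    plant_rate_target: float = 1.5
    plant_rate_background: float = 0.5
    n_switch_genes: int = 20
    mirna_name: str = MIR10B.name
    mirna_sequence: str = MIR10B.sequence
    plant_k: int = 8
    plant_origin_class: str = "threeprime"
    plant_sites: tuple[str, ...] | None = None
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0

    def __post_init__(self):
        def check(cond: bool, fieldname: str, msg: str):
            if not cond:
                raise ConfigError(f"{fieldname}: {msg}")

        check(self.n_genes >= 1, "n_genes", "must be >= 1")
        lo, hi = self.isoforms_per_gene
        check(1 <= lo <= hi, "isoforms_per_gene", "need 1 <= min <= max")
        check(0.0 < self.gc_content < 1.0, "gc_content", "must be in (0, 1)")
        check(self.n_cell_lines >= 1, "n_cell_lines", "must be >= 1")
        check(
            self.n_replicates_per_condition >= 2,
            "n_replicates_per_condition",
            "must be >= 2 (a two-sample test needs replicates)",
        )
        check(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        check(self.frac_up >= 0, "frac_up", "must be >= 0")
        check(self.frac_down >= 0, "frac_down", "must be >= 0")
        check(self.frac_up + self.frac_down <= 1, "frac_up", "frac_up + frac_down <= 1")
        check(self.plant_rate_target >= 0, "plant_rate_target", "must be >= 0")
        check(self.plant_rate_background >= 0, "plant_rate_background", "must be >= 0")
        check(self.n_switch_genes >= 0, "n_switch_genes", "must be >= 0")
        check(self.plant_region in REGIONS, "plant_region", f"must be one of {REGIONS}")
        check(self.plant_group in GROUPS, "plant_group", f"must be one of {GROUPS}")
        check(
            self.n_switch_genes <= self.n_genes,
            "n_switch_genes",
            "cannot exceed n_genes",
        )
        for region in REGIONS:
            check(
                region in self.region_lengths,
                "region_lengths",
                f"missing entry for {region}",
            )

    @property
    def mirna(self) -> MatureMiRNA:
        return MatureMiRNA(self.mirna_name, self.mirna_sequence)

    def planted_site_sequences(self) -> tuple[str, ...]:
        """Target-site strings planted into transcripts (deduplicated, ordered)."""
        if self.plant_sites is not None:
            return tuple(normalize_sequence(s) for s in self.plant_sites)
        sites = []
        for m in enumerate_motifs(self.mirna, self.plant_k, self.plant_k):
            if m.origin_class == self.plant_origin_class and m.target_site not in sites:
                sites.append(m.target_site)
        if not sites:
            raise ConfigError(
                "plant_origin_class: no miRNA window of the requested class"
            )
        return tuple(sites)

    def cell_lines(self) -> list[str]:
        return [f"line{i + 1}" for i in range(self.n_cell_lines)]


@dataclass
class GroundTruth:
    """What was planted: per-transcript effects, site positions, switch pairs."""

    transcripts: pd.DataFrame  # transcript_id, gene_id, direction, consensus_class
    line_classes: pd.DataFrame  # index transcript_id, one column per cell line
    planted: pd.DataFrame  # transcript_id, region, site, position
    switch_pairs: list  # (gene_id, transcript_up, transcript_down)

    def planted_counts(self) -> pd.DataFrame:
        """Planted-site count per (transcript, region), zero rows included."""
        idx = pd.MultiIndex.from_product(
            [self.transcripts["transcript_id"], REGIONS],
            names=["transcript_id", "region"],
        )
        counts = (
            self.planted.groupby(["transcript_id", "region"]).size()
            if len(self.planted)
            else pd.Series(dtype=int)
        )
        return counts.reindex(idx, fill_value=0).rename("n_planted").reset_index()

    def class_sets(self) -> dict[str, set]:
        t = self.transcripts
        return {
            g: set(t.loc[t["consensus_class"] == g, "transcript_id"]) for g in GROUPS
        }


def plant_sites(sequence: str, site: str, n: int, rng: np.random.Generator) -> str:
    """Overwrite ``n`` non-overlapping copies of ``site`` into ``sequence``.

    Length is preserved (sites replace background bases in place).  Raises
    :class:`PlacementError` when ``n`` copies cannot be placed.
    """
    new_seq, _ = _plant_many(sequence, [(site, n)], rng)
    return new_seq


def _plant_many(
    sequence: str,
    site_counts: list[tuple[str, int]],
    rng: np.random.Generator,
    best_effort: bool = False,
) -> tuple[str, list[tuple[str, int]]]:
    """Plant several (site, n) requests without any pairwise overlap.

    Returns the new sequence and the [(site, position)] placements made.
    With ``best_effort`` a request that cannot be fully honoured (sequence
    too short / too crowded) places as many copies as fit instead of
    raising; the returned placements are the ground truth either way.
    """
    seq = list(sequence)
    L = len(seq)
    occupied: list[tuple[int, int]] = []  # half-open [start, end)
    placements: list[tuple[str, int]] = []
    for site, n in site_counts:
        if n < 0:
            raise ValueError("site count must be >= 0")
        if n == 0:
            continue
        m = len(site)
        if m > L:
            if best_effort:
                continue
            raise PlacementError(f"site of length {m} exceeds sequence length {L}")
        candidates = rng.permutation(L - m + 1)
        placed = 0
        for pos in candidates:
            if placed == n:
                break
            pos = int(pos)
            if any(pos < e and pos + m > s for s, e in occupied):
                continue
            seq[pos : pos + m] = site
            occupied.append((pos, pos + m))
            placements.append((site, pos))
            placed += 1
        if placed < n and not best_effort:
            raise PlacementError(
                f"could only place {placed}/{n} copies of {site!r} "
                f"in a {L}-nt sequence without overlap"
            )
    return "".join(seq), placements


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A, C, G, T
    return "".join(rng.choice(np.array(["A", "C", "G", "T"]), size=length, p=p))


def _region_length(region: str, config: SynthConfig, rng: np.random.Generator) -> int:
    mean, sd = config.region_lengths[region]
    length = max(config.min_region_length, int(round(rng.normal(mean, sd))))
    if region == "CDS":
        length = max(90, length + (-length) % 3)  # multiple of 3
    return length


def generate_transcriptome(config: SynthConfig) -> tuple[Annotation, GroundTruth]:
    """Generate region sequences, the region table and the planted truth."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    sites = config.planted_site_sequences()

    # gene/isoform structure; the first n_switch_genes genes carry the
    # planted inverse isoform pairs (exactly two isoforms, +effect / -effect)
    lo, hi = config.isoforms_per_gene
    records = []  # (transcript_id, gene_id, direction)
    switch_pairs = []
    for gi in range(config.n_genes):
        gene_id = f"g{gi:05d}"
        if gi < config.n_switch_genes:
            t_up, t_down = f"{gene_id}.t1", f"{gene_id}.t2"
            records += [(t_up, gene_id, 1), (t_down, gene_id, -1)]
            switch_pairs.append((gene_id, t_up, t_down))
        else:
            n_iso = int(rng.integers(lo, hi + 1))
            for j in range(n_iso):
                u = rng.random()
                direction = 1 if u < config.frac_up else (
                    -1 if u < config.frac_up + config.frac_down else 0
                )
                records.append((f"{gene_id}.t{j + 1}", gene_id, direction))

    transcripts = pd.DataFrame(records, columns=["transcript_id", "gene_id", "direction"])
    transcripts["consensus_class"] = transcripts["direction"].map(DIRECTION_TO_CLASS)

    sequences: dict[tuple[str, str], str] = {}
    table_rows = []
    planted_rows = []
    for tid, gene_id, direction in records:
        cls = DIRECTION_TO_CLASS[direction]
        for region in REGIONS:
            length = _region_length(region, config, rng)
            seq = _random_sequence(length, config.gc_content, rng)
            rate = (
                config.plant_rate_target
                if (region == config.plant_region and cls == config.plant_group)
                else config.plant_rate_background
            )
            if rate > 0:
                n_total = int(rng.poisson(rate))
                if n_total:
                    chosen = rng.integers(0, len(sites), size=n_total)
                    requests = [
                        (sites[s], int(c))
                        for s, c in zip(*np.unique(chosen, return_counts=True))
                    ]
                    seq, placements = _plant_many(seq, requests, rng, best_effort=True)
                    planted_rows += [
                        {"transcript_id": tid, "region": region, "site": st, "position": p}
                        for st, p in placements
                    ]
            sequences[(tid, region)] = seq
            table_rows.append(
                {"transcript_id": tid, "gene_id": gene_id, "region": region,
                 "length": length}
            )

    annotation = Annotation(sequences=sequences, table=pd.DataFrame(table_rows))
    line_classes = pd.DataFrame(
        {ln: transcripts["consensus_class"].to_numpy() for ln in config.cell_lines()},
        index=transcripts["transcript_id"],
    )
    truth = GroundTruth(
        transcripts=transcripts,
        line_classes=line_classes,
        planted=pd.DataFrame(
            planted_rows, columns=["transcript_id", "region", "site", "position"]
        ),
        switch_pairs=switch_pairs,
    )
    return annotation, truth


def generate_expression(
    annotation: Annotation, truth: GroundTruth, config: SynthConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2 intensity matrix (transcripts x samples) plus its sample sheet.

    inhibitor-minus-control expectation per transcript equals
    ``effect_log2fc * direction``; mock is generated identically to control.
    """
    tids = truth.transcripts["transcript_id"].tolist()
    if set(tids) != {t for t, _ in annotation.sequences}:
        raise ConfigError("seed: annotation and truth describe different transcripts")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])

    sheet_rows = []
    for line in config.cell_lines():
        for cond in CONDITIONS:
            for rep in range(1, config.n_replicates_per_condition + 1):
                sheet_rows.append(
                    {
                        "sample_id": f"{line}_{cond}_r{rep}",
                        "cell_line": line,
                        "condition": cond,
                        "replicate": rep,
                    }
                )
    samples = pd.DataFrame(sheet_rows)

    direction = truth.transcripts["direction"].to_numpy()
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=len(tids))
    values = np.empty((len(tids), len(samples)))
    for j, row in samples.iterrows():
        effect = config.effect_log2fc * direction if row["condition"] == "inhibitor" else 0.0
        noise = rng.normal(0.0, config.noise_sd, size=len(tids)) if config.noise_sd > 0 else 0.0
        values[:, j] = baseline + effect + noise
    matrix = pd.DataFrame(values, index=pd.Index(tids, name="transcript_id"),
                          columns=samples["sample_id"])
    return matrix, samples


def generate_dataset(config: SynthConfig):
    """Convenience: (annotation, truth, matrix, samples) in one call."""
    annotation, truth = generate_transcriptome(config)
    matrix, samples = generate_expression(annotation, truth, config)
    return annotation, truth, matrix, samples
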