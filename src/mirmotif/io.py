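"""File formats, pipeline configuration and logging.

Interchange formats are deliberately plain: FASTA for sequences (headers
``transcriptID|REGION`` with REGION in {UTR5, CDS, UTR3}) and tab-separated
tables with a header row, UTF-8, '.' decimal.  Round-trips are bit-exact,
which the test suite relies on for determinism checks.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import REGIONS, MatureMiRNA, normalize_sequence

logger = logging.getLogger("mirmotif")


class FormatError(ValueError):
    """Malformed input file (message carries the file and line/record)."""


@dataclass
class Annotation:
    """Transcript region sequences plus the region table.

    ``sequences`` maps (transcript_id, region) -> DNA sequence (uppercase,
    sense strand, 5'->3'); ``table`` has columns transcript_id, gene_id,
    region, length.
    """

    sequences: dict
    table: pd.DataFrame

    def transcript_ids(self) -> list[str]:
        seen = dict.fromkeys(t for t, _ in self.sequences)
        return list(seen)

    def gene_of(self) -> dict:
        return dict(zip(self.table["transcript_id"], self.table["gene_id"]))


def _header_line_number(path, header: str) -> int | None:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.rstrip("\n") == f">{header}":
                return i
    return None


def read_fasta_regions(path, table: pd.DataFrame | None = None) -> Annotation:
    """Read region sequences from FASTA with ``transcriptID|REGION`` headers.

    Lowercase and RNA (U) input is normalized to uppercase DNA.  Malformed or
    duplicate headers raise :class:`FormatError` naming the offending line.
    When no region ``table`` is supplied, one is reconstructed from the
    records (gene_id falls back to the transcript id).
    """
    sequences: dict = {}
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.id.split("|")
        if len(parts) != 2 or parts[1] not in REGIONS or not parts[0]:
            line = _header_line_number(path, record.description)
            raise FormatError(
                f"{path}: malformed FASTA header {record.id!r} at line {line}; "
                f"expected transcriptID|REGION with REGION in {REGIONS}"
            )
        key = (parts[0], parts[1])
        if key in sequences:
            line = _header_line_number(path, record.description)
            raise FormatError(
                f"{path}: duplicate (transcript, region) {key} at line {line}"
            )
        sequences[key] = normalize_sequence(str(record.seq))
    if table is None:
        table = pd.DataFrame(
            [
                {"transcript_id": t, "gene_id": t.rsplit(".", 1)[0], "region": r,
                 "length": len(s)}
                for (t, r), s in sequences.items()
            ]
        )
    return Annotation(sequences=sequences, table=table)


def write_fasta_regions(annotation: Annotation, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=f"{tid}|{region}", description="")
        for (tid, region), seq in annotation.sequences.items()
    ]
    handle = path if hasattr(path, "write") else str(path)
    SeqIO.write(records, handle, "fasta")


def read_mirna(path) -> MatureMiRNA:
    """Read a mature miRNA from FASTA (first record) or bare-sequence text."""
    text = Path(path).read_text().strip()
    if text.startswith(">"):
        record = next(SeqIO.parse(str(path), "fasta"))
        return MatureMiRNA(record.id, str(record.seq))
    return MatureMiRNA(Path(path).stem, "".join(text.split()))


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6f")


@dataclass(frozen=True)
class PipelineConfig:
    """Every threshold and seed of the end-to-end run, with study defaults.

    Defaults are the published procedure's constants: fold-change bounds
    1.2 / 0.8, alpha 0.05, consensus in >= 2 cell lines, motif lengths 6-9,
    enrichment-ratio criterion 1.5, and 1000 miRNA shuffles for the null.
    """

    fc_up: float = 1.2
    fc_down: float = 0.8
    alpha: float = 0.05
    min_lines: int = 2
    k_min: int = 6
    k_max: int = 9
    ratio_threshold: float = 1.5
    n_shuffles: int = 1000
    seed: int = 0
    counting_mode: str = "occurrences"  # or "presence"
    pseudocount: float | None = None  # None -> 1/max(group size)
    reference: tuple[str, ...] = ("control", "mock")
    welch: bool = False
    out_dir: str = "mirmotif_out"
    mirna_path: str | None = None
    fasta_path: str | None = None
    regions_path: str | None = None
    matrix_path: str | None = None
    samples_path: str | None = None
    simulate: bool = True

    def __post_init__(self):
        if not (0 < self.k_min <= self.k_max):
            raise ValueError("need 0 < k_min <= k_max")
        for name in ("fc_up", "fc_down", "alpha", "ratio_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.counting_mode not in ("occurrences", "presence"):
            raise ValueError("counting_mode must be 'occurrences' or 'presence'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        if "reference" in raw and isinstance(raw["reference"], list):
            raw["reference"] = tuple(raw["reference"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reference"] = list(self.reference)
        return d


def setup_logging(level: int = logging.INFO) -> logging.Logger:
    root = logging.getLogger("mirmotif")
    if not root.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        root.addHandler(handler)
    root.setLevel(level)
    return root
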