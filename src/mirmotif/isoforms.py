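"""Inverse isoform-pair (splice-switch) detection.

A gene whose distinct transcripts (or probe sets) move in opposite directions
under miRNA inhibition indicates a splicing-pattern shift rather than a plain
expression change.  A pair qualifies when one member is consistently
up-regulated (fold change > 1.2, p < 0.05 in >= min_lines cell lines) and
another is consistently down-regulated (fold change < 0.8, p < 0.05 in
>= min_lines lines).  The thresholds and consensus machinery are exactly the
ones used for the expression grouping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .diffexpr import (
    ALPHA_DEFAULT,
    FC_DOWN_DEFAULT,
    FC_UP_DEFAULT,
    MIN_LINES_DEFAULT,
)

logger = logging.getLogger("mirmotif")


@dataclass(frozen=True)
class IsoformPair:
    """One inversely regulated isoform pair of a gene."""

    gene_id: str
    transcript_up: str
    transcript_down: str
    up_stats: tuple  # per-line (cell_line, fold_change, p_value) for the up member
    down_stats: tuple

    def __post_init__(self):
        if self.transcript_up == self.transcript_down:
            raise ValueError("a pair needs two distinct transcripts")


def find_inverse_pairs(
    de_table: pd.DataFrame,
    probe_to_gene: dict,
    min_lines: int = MIN_LINES_DEFAULT,
    fc_up: float = FC_UP_DEFAULT,
    fc_down: float = FC_DOWN_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    same_lines: bool = False,
) -> list[IsoformPair]:
    """All gene-internal (up, down) isoform pairs meeting both member criteria.

    ``de_table`` is the per-line table from :func:`mirmotif.diffexpr.build_groups`
    (columns transcript_id, cell_line, fold_change, p_value).  A gene with m
    qualifying up members and n qualifying down members yields m*n pairs,
    ordered by (gene_id, transcript_up, transcript_down).  With
    ``same_lines=True`` both members must pass in >= min_lines of the *same*
    cell lines.  Transcripts without a gene mapping are excluded with a
    logged warning.
    """
    missing = sorted(set(de_table["transcript_id"]) - set(probe_to_gene))
    if missing:
        logger.warning(
            "%d transcripts lack a gene mapping and are excluded (first: %s)",
            len(missing), missing[:5],
        )

    up_lines: dict[str, set] = {}
    down_lines: dict[str, set] = {}
    stats: dict[str, list] = {}
    for row in de_table.itertuples(index=False):
        tid = row.transcript_id
        if tid not in probe_to_gene:
            continue
        stats.setdefault(tid, []).append(
            (row.cell_line, float(row.fold_change), float(row.p_value))
        )
        if row.p_value < alpha:
            if row.fold_change > fc_up:
                up_lines.setdefault(tid, set()).add(row.cell_line)
            elif row.fold_change < fc_down:
                down_lines.setdefault(tid, set()).add(row.cell_line)

    by_gene_up: dict[str, list] = {}
    by_gene_down: dict[str, list] = {}
    for tid, lines in up_lines.items():
        if len(lines) >= min_lines:
            by_gene_up.setdefault(probe_to_gene[tid], []).append(tid)
    for tid, lines in down_lines.items():
        if len(lines) >= min_lines:
            by_gene_down.setdefault(probe_to_gene[tid], []).append(tid)

    pairs = []
    for gene in sorted(set(by_gene_up) & set(by_gene_down)):
        for t_up in sorted(by_gene_up[gene]):
            for t_down in sorted(by_gene_down[gene]):
                if same_lines and len(up_lines[t_up] & down_lines[t_down]) < min_lines:
                    continue
                pairs.append(
                    IsoformPair(
                        gene_id=gene,
                        transcript_up=t_up,
                        transcript_down=t_down,
                        up_stats=tuple(sorted(stats[t_up])),
                        down_stats=tuple(sorted(stats[t_down])),
                    )
                )
    return pairs


def pairs_to_frame(pairs: list[IsoformPair]) -> pd.DataFrame:
    """Flat table: gene, members, and per-line fc/p columns for both members."""
    rows = []
    for p in pairs:
        row = {
            "gene_id": p.gene_id,
            "transcript_up": p.transcript_up,
            "transcript_down": p.transcript_down,
        }
        for line, fc, pv in p.up_stats:
            row[f"up_fc_{line}"] = fc
            row[f"up_p_{line}"] = pv
        for line, fc, pv in p.down_stats:
            row[f"down_fc_{line}"] = fc
            row[f"down_p_{line}"] = pv
        rows.append(row)
    cols = ["gene_id", "transcript_up", "transcript_down"]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=cols)
    return df[cols + [c for c in df.columns if c not in cols]]
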