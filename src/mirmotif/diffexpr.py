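"""Fold-change / p-value transcript classification and the cell-line consensus.

Expression input is a log2 intensity matrix (transcripts x samples) with a
sample sheet assigning each column a cell line, a condition (inhibitor,
control or mock) and a replicate.  Per cell line, each transcript gets a
geometric fold change 2^(mean log2 inhibitor - mean log2 reference) and a
two-sided unpaired Student's t-test p-value; it is classified ``up`` when
fold change > 1.2 and p < 0.05, ``down`` when fold change < 0.8 and p < 0.05,
and ``unchanged`` otherwise (strict inequalities; ties fall to unchanged).
A transcript's consensus class requires the same call in at least
``min_lines`` of the cell lines (default 2 of 3).

The reference group defaults to the pooled control and mock samples of the
line (inhibitor versus non-targeting control or mock); restrict with
``reference=("control",)`` or ``("mock",)``.  No multiple-testing correction
is applied by default, matching the raw p < 0.05 grouping; Benjamini-Hochberg
is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mirmotif")

CLASSES = ("up", "down", "unchanged")

FC_UP_DEFAULT = 1.2
FC_DOWN_DEFAULT = 0.8
ALPHA_DEFAULT = 0.05
MIN_LINES_DEFAULT = 2


class InputError(ValueError):
    """Expression matrix / sample sheet inconsistent with the requested design."""


def fold_change(log2_treated_mean: float, log2_control_mean: float) -> float:
    """Geometric (linear-scale) fold change 2^(treated - control)."""
    return float(2.0 ** (np.asarray(log2_treated_mean) - np.asarray(log2_control_mean)))


def ddct_fold_change(
    ct_target_treated: float,
    ct_reference_treated: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """Relative qPCR quantification: fold change = 2^-ddCt.

    ddCt = (Ct_target - Ct_reference)_treated - (Ct_target - Ct_reference)_control.
    Lower cycle numbers mean more template, hence the negative exponent.
    """
    ddct = (ct_target_treated - ct_reference_treated) - (
        ct_target_control - ct_reference_control
    )
    return float(2.0**-ddct)


def two_sample_test(group_a, group_b, welch: bool = False) -> float:
    """Two-sided unpaired t-test p-value (Student's pooled test by default).

    Degenerate convention when both groups have zero variance: p = 1 for equal
    means, p = 0 for unequal means (an infinite-t limit); logged at debug.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs >= 2 values for a two-sample test")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        logger.debug("degenerate zero-variance t-test, returning p=%s", p)
        return p
    return float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)


def _ttest_rows(a: np.ndarray, b: np.ndarray, welch: bool = False) -> np.ndarray:
    """Row-wise two-sided t-test on matrices (transcripts x replicates)."""
    import warnings

    with warnings.catch_warnings():
        # zero-variance rows warn and yield nan; the convention below covers them
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=float)
    # zero-variance rows yield nan; apply the stated degenerate convention
    degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    if degenerate.any():
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
        logger.debug("%d degenerate zero-variance tests", int(degenerate.sum()))
    return p


def classify(
    fc: float,
    p_value: float,
    fc_up: float = FC_UP_DEFAULT,
    fc_down: float = FC_DOWN_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
) -> str:
    """up iff fc > fc_up and p < alpha; down iff fc < fc_down and p < alpha."""
    if fc <= 0:
        raise ValueError("fold change must be positive")
    if p_value < alpha:
        if fc > fc_up:
            return "up"
        if fc < fc_down:
            return "down"
    return "unchanged"


def consensus(classes_per_line, min_lines: int = MIN_LINES_DEFAULT) -> str:
    """Consensus call: a class wins when >= min_lines lines agree on it.

    With min_lines > n_lines/2 at most one directional class can win; if a
    permissive min_lines lets both up and down reach the bar, the call falls
    back to unchanged (logged).
    """
    classes = list(classes_per_line)
    if len(classes) < min_lines:
        raise ValueError(
            f"{len(classes)} line calls cannot satisfy min_lines={min_lines}"
        )
    n_up = classes.count("up")
    n_down = classes.count("down")
    if n_up >= min_lines and n_down >= min_lines:
        logger.warning("both up and down reach min_lines=%d; calling unchanged", min_lines)
        return "unchanged"
    if n_up >= min_lines:
        return "up"
    if n_down >= min_lines:
        return "down"
    return "unchanged"


@dataclass(frozen=True)
class TranscriptGroups:
    """The up / down / unchanged partition of all tested transcripts."""

    up: frozenset
    down: frozenset
    unchanged: frozenset
    min_lines: int = MIN_LINES_DEFAULT
    n_lines: int = 3

    def __post_init__(self):
        if self.up & self.down or self.up & self.unchanged or self.down & self.unchanged:
            raise ValueError("DE groups must be pairwise disjoint")

    @property
    def all_transcripts(self) -> frozenset:
        return self.up | self.down | self.unchanged

    def as_dict(self) -> dict:
        return {"up": self.up, "down": self.down, "unchanged": self.unchanged}


def _line_columns(samples: pd.DataFrame, line: str, conditions) -> list[str]:
    mask = (samples["cell_line"] == line) & samples["condition"].isin(conditions)
    return samples.loc[mask, "sample_id"].tolist()


def build_groups(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    fc_up: float = FC_UP_DEFAULT,
    fc_down: float = FC_DOWN_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    min_lines: int = MIN_LINES_DEFAULT,
    reference: tuple[str, ...] = ("control", "mock"),
    welch: bool = False,
    pooled_lines: bool = False,
    bh_correct: bool = False,
) -> tuple[TranscriptGroups, pd.DataFrame]:
    """Per-line DE classification and the cross-line consensus grouping.

    Returns ``(groups, de_table)`` where ``de_table`` has one row per
    (transcript, cell line) with log2fc, fold_change, p_value and class.
    ``pooled_lines=True`` instead runs one test pooling all lines' samples
    (reported under cell_line ``"pooled"``, consensus = its single call).
    ``bh_correct=True`` applies Benjamini-Hochberg within each line before
    classification (off by default: grouping uses raw p-values).
    """
    required = {"sample_id", "cell_line", "condition"}
    if not required <= set(samples.columns):
        raise InputError(f"sample sheet must have columns {sorted(required)}")
    unknown = set(samples["sample_id"]) - set(matrix.columns)
    if unknown:
        raise InputError(f"sample sheet rows not in matrix columns: {sorted(unknown)}")

    lines = sorted(samples["cell_line"].unique())
    if pooled_lines:
        line_groups = {"pooled": samples}
    else:
        line_groups = {ln: samples[samples["cell_line"] == ln] for ln in lines}

    records = []
    per_line_class: dict[str, pd.Series] = {}
    for line, sheet in line_groups.items():
        treated_cols = sheet.loc[sheet["condition"] == "inhibitor", "sample_id"].tolist()
        ref_cols = sheet.loc[sheet["condition"].isin(reference), "sample_id"].tolist()
        if len(treated_cols) < 2:
            raise InputError(f"cell line {line!r}: need >= 2 inhibitor replicates")
        if len(ref_cols) < 2:
            raise InputError(
                f"cell line {line!r}: need >= 2 reference replicates "
                f"(conditions {reference})"
            )
        a = matrix[treated_cols].to_numpy(dtype=float)
        b = matrix[ref_cols].to_numpy(dtype=float)
        log2fc = a.mean(axis=1) - b.mean(axis=1)
        p = _ttest_rows(a, b, welch=welch)
        if bh_correct:
            p = _benjamini_hochberg(p)
        fc = 2.0**log2fc
        cls = np.full(len(matrix), "unchanged", dtype=object)
        sig = p < alpha
        cls[sig & (fc > fc_up)] = "up"
        cls[sig & (fc < fc_down)] = "down"
        per_line_class[line] = pd.Series(cls, index=matrix.index)
        records.append(
            pd.DataFrame(
                {
                    "transcript_id": matrix.index,
                    "cell_line": line,
                    "log2fc": log2fc,
                    "fold_change": fc,
                    "p_value": p,
                    "class": cls,
                }
            )
        )
    de_table = pd.concat(records, ignore_index=True)

    class_matrix = pd.DataFrame(per_line_class)
    if pooled_lines:
        cons = class_matrix["pooled"]
    else:
        cons = class_matrix.apply(lambda row: consensus(row.tolist(), min_lines), axis=1)
    groups = TranscriptGroups(
        up=frozenset(cons.index[cons == "up"]),
        down=frozenset(cons.index[cons == "down"]),
        unchanged=frozenset(cons.index[cons == "unchanged"]),
        min_lines=min_lines,
        n_lines=len(line_groups),
    )
    return groups, de_table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def groups_to_frame(groups: TranscriptGroups) -> pd.DataFrame:
    rows = [
        {"transcript_id": t, "consensus_class": g}
        for g in CLASSES
        for t in sorted(getattr(groups, g))
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "consensus_class"])
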