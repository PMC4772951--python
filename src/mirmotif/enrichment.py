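"""Group-normalized motif frequencies, enrichment ratios and the shuffled null.

For every motif and transcript region, occurrence counts are normalized by
the number of transcripts in each DE group, and two enrichment ratios are
formed: up-regulated versus down-regulated, and up-regulated versus
unchanged.  The null model repeats the identical procedure for randomly
shuffled (composition-preserving) permutations of the mature miRNA: each
shuffle regenerates the full 6-9-mer catalogue, rescans all regions through
the same code path, and recomputes the ratios.  A ratio is called enriched
when it exceeds the criterion (default 1.5) and the empirical probability of
a shuffled ratio exceeding that criterion is below 0.05.

Two empirical probabilities are reported per statistic: ``p_chance``, the
+1-smoothed tail frequency of null ratios above the 1.5 criterion (gated on
the observed ratio itself exceeding it, else 1), and ``p_rank``, the
+1-smoothed fraction of null ratios at or above the observed value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motifs import (
    GROUPS,
    REGIONS,
    CollapsedMotif,
    MatureMiRNA,
    RegionGroupTables,
    collapse_motifs,
    encode_site,
    enumerate_motifs,
    shuffle_mirna,
)

logger = logging.getLogger("mirmotif")

RATIO_THRESHOLD_DEFAULT = 1.5
N_SHUFFLES_DEFAULT = 1000


class UndefinedGroupError(ValueError):
    """A frequency was requested for an empty transcript group."""


def normalized_frequency(occurrences: int, group_size: int) -> float:
    """Occurrences per transcript of the group."""
    if group_size <= 0:
        raise UndefinedGroupError("group size must be > 0 to normalize a frequency")
    return occurrences / group_size


def enrichment_ratio(freq_num: float, freq_den: float, pseudocount: float = 0.0) -> float:
    """(freq_num + c) / (freq_den + c); c > 0 guards the zero-frequency case."""
    if freq_num < 0 or freq_den < 0:
        raise ValueError("frequencies must be >= 0")
    if freq_den + pseudocount == 0:
        return np.inf if freq_num > 0 else 1.0
    return (freq_num + pseudocount) / (freq_den + pseudocount)


def default_pseudocount(group_sizes) -> float:
    """1 / max(group size): one pseudo-occurrence spread over the largest group."""
    sizes = [s for s in dict(group_sizes).values() if s > 0]
    if not sizes:
        raise UndefinedGroupError("all transcript groups are empty")
    return 1.0 / max(sizes)


def empirical_probability(
    observed_ratio: float,
    null_ratios,
    threshold: float = RATIO_THRESHOLD_DEFAULT,
) -> tuple[float, float]:
    """(p_chance, p_rank) of an observed enrichment ratio against its null.

    p_chance = (1 + #{null > threshold}) / (1 + n) when the observed ratio
    itself exceeds the threshold, else 1 (not significant by the criterion).
    p_rank = (1 + #{null >= observed}) / (1 + n), always reported.
    """
    null = np.asarray(null_ratios, dtype=float)
    if null.size == 0:
        raise ValueError("null_ratios must be non-empty")
    n = null.size
    p_rank = (1 + int((null >= observed_ratio).sum())) / (1 + n)
    if observed_ratio > threshold:
        p_chance = (1 + int((null > threshold).sum())) / (1 + n)
    else:
        p_chance = 1.0
    return p_chance, p_rank


# ---------------------------------------------------------------------------
# vectorized catalogue counting against pre-built tables
# ---------------------------------------------------------------------------


def _counts_matrix(
    tables: RegionGroupTables,
    collapsed: list[CollapsedMotif],
    mode: str = "occurrences",
) -> dict[tuple[str, str], np.ndarray]:
    """Per-(region, group) vector of counts aligned with ``collapsed``."""
    by_k: dict[int, tuple[list[int], list[int]]] = {}
    for i, m in enumerate(collapsed):
        k, code = encode_site(m.target_site)
        by_k.setdefault(k, ([], []))
        by_k[k][0].append(i)
        by_k[k][1].append(code)
    out = {}
    for (region, group), table in tables.tables.items():
        vec = np.zeros(len(collapsed), dtype=np.int64)
        for k, (idx, codes) in by_k.items():
            src = table.occ[k] if mode == "occurrences" else table.presence[k]
            vec[np.array(idx)] = src[np.array(codes)]
        out[(region, group)] = vec
    return out


def _region_stats(
    tables: RegionGroupTables,
    collapsed: list[CollapsedMotif],
    pseudocount: float,
    mode: str,
):
    """Per-motif and region-aggregate frequencies and ratios for one catalogue.

    Returns (freqs, ratios, agg) where ``freqs[(region, group)]`` is a
    per-motif frequency vector, ``ratios[(region, pair)]`` a per-motif ratio
    vector for pair in {"up_down", "up_unchanged"}, and ``agg[(region, pair)]``
    the region-aggregate (summed-occurrence) ratio.  Regions where a needed
    group is empty get NaN entries (logged once by the caller).
    """
    counts = _counts_matrix(tables, collapsed, mode)
    freqs, ratios, agg = {}, {}, {}
    for region in REGIONS:
        sizes = {g: tables.region_group_sizes[(region, g)] for g in GROUPS}
        for g in GROUPS:
            c = counts[(region, g)]
            freqs[(region, g)] = c / sizes[g] if sizes[g] > 0 else np.full(len(c), np.nan)
        for pair, den_group in (("up_down", "down"), ("up_unchanged", "unchanged")):
            fu, fd = freqs[(region, "up")], freqs[(region, den_group)]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios[(region, pair)] = (fu + pseudocount) / (fd + pseudocount)
            if sizes["up"] > 0 and sizes[den_group] > 0:
                au = counts[(region, "up")].sum() / sizes["up"]
                ad = counts[(region, den_group)].sum() / sizes[den_group]
                agg[(region, pair)] = enrichment_ratio(au, ad, pseudocount)
            else:
                agg[(region, pair)] = np.nan
    return freqs, ratios, agg


@dataclass
class NullDistributions:
    """Shuffled-miRNA null ratios: per region aggregate and pooled per-motif."""

    region: dict  # (region, pair) -> np.ndarray of n_shuffles aggregate ratios
    motif_pool: dict  # (region, k, pair) -> np.ndarray pooled over shuffles+windows
    n_shuffles: int


def permutation_null(
    tables: RegionGroupTables,
    mirna: MatureMiRNA,
    n_shuffles: int = N_SHUFFLES_DEFAULT,
    seed: int | np.random.Generator = 0,
    k_min: int = 6,
    k_max: int = 9,
    pseudocount: float | None = None,
    mode: str = "occurrences",
) -> NullDistributions:
    """Null enrichment-ratio distributions from shuffled miRNA catalogues.

    Every shuffle runs the identical catalogue -> scan -> normalize -> ratio
    path as the observed miRNA (the tables are fixed; only the catalogue
    changes).  Same seed gives an identical null.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if pseudocount is None:
        pseudocount = default_pseudocount(tables.group_sizes)

    region_null = {(r, p): np.empty(n_shuffles) for r in REGIONS
                   for p in ("up_down", "up_unchanged")}
    pool: dict[tuple, list] = {}
    for s in range(n_shuffles):
        shuffled = shuffle_mirna(mirna, rng)
        collapsed = collapse_motifs(enumerate_motifs(shuffled, k_min, k_max))
        _, ratios, agg = _region_stats(tables, collapsed, pseudocount, mode)
        ks = np.array([m.k for m in collapsed])
        for (region, pair), vec in ratios.items():
            region_null[(region, pair)][s] = agg[(region, pair)]
            for k in range(k_min, k_max + 1):
                pool.setdefault((region, k, pair), []).append(vec[ks == k])
    motif_pool = {key: np.concatenate(vals) for key, vals in pool.items()}
    return NullDistributions(region=region_null, motif_pool=motif_pool,
                             n_shuffles=n_shuffles)


@dataclass
class EnrichmentOutput:
    """Observed enrichment next to its permutation null."""

    motif_table: pd.DataFrame
    region_summary: pd.DataFrame
    null: NullDistributions
    pseudocount: float
    threshold: float


def compute_enrichment(
    tables: RegionGroupTables,
    mirna: MatureMiRNA,
    n_shuffles: int = N_SHUFFLES_DEFAULT,
    seed: int | np.random.Generator = 0,
    k_min: int = 6,
    k_max: int = 9,
    threshold: float = RATIO_THRESHOLD_DEFAULT,
    pseudocount: float | None = None,
    mode: str = "occurrences",
) -> EnrichmentOutput:
    """Full enrichment analysis: observed ratios, null, per-motif and region table."""
    if pseudocount is None:
        pseudocount = default_pseudocount(tables.group_sizes)
    collapsed = collapse_motifs(enumerate_motifs(mirna, k_min, k_max))
    freqs, ratios, agg = _region_stats(tables, collapsed, pseudocount, mode)
    empty = [rg for rg, n in tables.region_group_sizes.items() if n == 0]
    if empty:
        logger.warning("empty (region, group) combinations dropped: %s", empty)

    null = permutation_null(
        tables, mirna, n_shuffles=n_shuffles, seed=seed, k_min=k_min, k_max=k_max,
        pseudocount=pseudocount, mode=mode,
    )

    rows = []
    for region in REGIONS:
        for i, m in enumerate(collapsed):
            r_ud = ratios[(region, "up_down")][i]
            r_uu = ratios[(region, "up_unchanged")][i]
            pool_uu = null.motif_pool[(region, m.k, "up_unchanged")]
            pool_ud = null.motif_pool[(region, m.k, "up_down")]
            p_uu = empirical_probability(r_uu, pool_uu, threshold)
            p_ud = empirical_probability(r_ud, pool_ud, threshold)
            rows.append(
                {
                    "motif": m.subsequence,
                    "k": m.k,
                    "region": region,
                    "origin_class": m.origin_label,
                    "target_site": m.target_site,
                    "freq_up": freqs[(region, "up")][i],
                    "freq_down": freqs[(region, "down")][i],
                    "freq_unchanged": freqs[(region, "unchanged")][i],
                    "ratio_up_down": r_ud,
                    "ratio_up_unchanged": r_uu,
                    "p_chance": p_uu[0],
                    "p_rank": p_uu[1],
                    "p_chance_up_down": p_ud[0],
                    "p_rank_up_down": p_ud[1],
                    "n_shuffles": n_shuffles,
                }
            )
    motif_table = pd.DataFrame(rows)

    region_summary = region_enrichment_summary(
        motif_table, {key: agg[key] for key in agg}, null, threshold
    )
    return EnrichmentOutput(
        motif_table=motif_table,
        region_summary=region_summary,
        null=null,
        pseudocount=pseudocount,
        threshold=threshold,
    )


def region_enrichment_summary(
    motif_table: pd.DataFrame,
    region_aggregates: dict,
    null: NullDistributions,
    threshold: float = RATIO_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Per-region headline table: significant-motif counts and aggregate ratios.

    A region is flagged ``enriched`` when its aggregate up/unchanged ratio
    exceeds the criterion with aggregate p_chance < 0.05.  Deterministic given
    inputs and invariant to motif row order.
    """
    rows = []
    for region in REGIONS:
        sub = motif_table[motif_table["region"] == region]
        agg_uu = region_aggregates[(region, "up_unchanged")]
        agg_ud = region_aggregates[(region, "up_down")]
        if np.isnan(agg_uu):
            p_uu = (np.nan, np.nan)
            p_ud = (np.nan, np.nan)
        else:
            p_uu = empirical_probability(agg_uu, null.region[(region, "up_unchanged")],
                                         threshold)
            p_ud = empirical_probability(agg_ud, null.region[(region, "up_down")],
                                         threshold)
        rows.append(
            {
                "region": region,
                "n_motifs": len(sub),
                "n_ratio_above": int((sub["ratio_up_unchanged"] > threshold).sum()),
                "n_significant": int(
                    ((sub["ratio_up_unchanged"] > threshold)
                     & (sub["p_chance"] < 0.05)).sum()
                ),
                "agg_ratio_up_down": agg_ud,
                "agg_ratio_up_unchanged": agg_uu,
                "agg_p_chance": p_uu[0],
                "agg_p_rank": p_uu[1],
                "agg_p_chance_up_down": p_ud[0],
                "enriched": bool(agg_uu > threshold and p_uu[0] < 0.05)
                if not np.isnan(agg_uu)
                else False,
            }
        )
    return pd.DataFrame(rows)


def motif_composition(
    up_counts: dict,
    down_counts: dict,
    k: int = 8,
    origin_classes: dict | None = None,
) -> pd.DataFrame:
    """Relative motif-composition comparison between the up and down sets.

    ``up_counts`` / ``down_counts`` map each length-k motif to its occurrence
    count in the respective group's region.  Relative frequencies are raw
    count shares (each column sums to 1 when its total is nonzero); the
    up/down composition ratio uses add-one smoothing on the raw counts so
    that sparse motifs do not produce divisions by zero.
    """
    motifs = sorted(set(up_counts) | set(down_counts))
    motifs = [m for m in motifs if len(m) == k]
    if not motifs:
        raise ValueError(f"no motifs of length k={k} in the counts")
    cu = np.array([up_counts.get(m, 0) for m in motifs], dtype=float)
    cd = np.array([down_counts.get(m, 0) for m in motifs], dtype=float)
    tot_u, tot_d = cu.sum(), cd.sum()
    rel_u = cu / tot_u if tot_u > 0 else np.zeros_like(cu)
    rel_d = cd / tot_d if tot_d > 0 else np.zeros_like(cd)
    n = len(motifs)
    smoothed = ((cu + 1) / (tot_u + n)) / ((cd + 1) / (tot_d + n))
    return pd.DataFrame(
        {
            "motif": motifs,
            "origin_class": [
                (origin_classes or {}).get(m, "") for m in motifs
            ],
            "rel_freq_up": rel_u,
            "rel_freq_down": rel_d,
            "ratio": smoothed,
        }
    )


def composition_from_counts(counts, region: str = "UTR5", k: int = 8) -> pd.DataFrame:
    """Composition table straight from a :class:`~mirmotif.motifs.MotifCounts`."""
    up, down, origin = {}, {}, {}
    for m in counts.motifs:
        if m.k != k:
            continue
        up[m.subsequence] = counts.occurrences[(m.subsequence, region, "up")]
        down[m.subsequence] = counts.occurrences[(m.subsequence, region, "down")]
        origin[m.subsequence] = m.origin_label
    return motif_composition(up, down, k=k, origin_classes=origin)
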