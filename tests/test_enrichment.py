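"""Enrichment ratios, the shuffled-miRNA null, and composition comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mirmotif import (
    MIR10B,
    empirical_probability,
    enrichment_ratio,
    motif_composition,
    normalized_frequency,
    permutation_null,
)
from mirmotif.enrichment import (
    UndefinedGroupError,
    _region_stats,
    compute_enrichment,
    default_pseudocount,
    region_enrichment_summary,
)
from mirmotif.motifs import build_tables, collapse_motifs, enumerate_motifs


class TestNormalizedFrequency:
    @pytest.mark.parametrize("occ,size,expected", [(10, 5, 2.0), (0, 7, 0.0)])
    def test_examples(self, occ, size, expected):
        assert normalized_frequency(occ, size) == expected

    def test_inverse_identity(self, rng):
        for _ in range(20):
            occ, size = int(rng.integers(0, 100)), int(rng.integers(1, 50))
            assert normalized_frequency(occ, size) * size == pytest.approx(occ)

    def test_empty_group_rejected(self):
        with pytest.raises(UndefinedGroupError):
            normalized_frequency(3, 0)


class TestEnrichmentRatio:
    @pytest.mark.parametrize(
        "num,den,c,expected",
        [(0.3, 0.2, 0.0, 1.5), (0.0, 0.0, 0.01, 1.0), (0.4, 0.4, 0.1, 1.0)],
    )
    def test_examples(self, num, den, c, expected):
        assert enrichment_ratio(num, den, c) == pytest.approx(expected)

    def test_zero_denominator_without_pseudocount(self):
        assert enrichment_ratio(0.5, 0.0, 0.0) == np.inf
        assert enrichment_ratio(0.0, 0.0, 0.0) == 1.0

    def test_default_pseudocount_is_reciprocal_max_group(self):
        assert default_pseudocount({"up": 10, "down": 40, "unchanged": 25}) == 1 / 40


class TestEmpiricalProbability:
    def test_all_null_below_threshold(self):
        null = np.full(1000, 1.2)
        p_chance, _ = empirical_probability(2.0, null)
        assert p_chance == pytest.approx(1 / 1001)

    def test_observed_below_threshold_not_significant(self):
        null = np.full(100, 3.0)
        p_chance, p_rank = empirical_probability(1.4, null)
        assert p_chance == 1.0
        assert p_rank == pytest.approx(1.0)  # (1 + 100) / 101

    def test_rank_probability_counts_ties(self):
        null = np.array([1.0, 2.0, 2.0, 3.0])
        _, p_rank = empirical_probability(2.0, null)
        assert p_rank == pytest.approx((1 + 3) / 5)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_probability(2.0, [])


def planted_tables(rng, n_up=40, n_other=60, length=120, site="AAATTCGG", rate=2):
    """Annotation with `site` copies concentrated in up-group 5'UTRs."""
    ann, groups = {}, {"up": set(), "down": set(), "unchanged": set()}
    for i in range(n_up + 2 * n_other):
        tid = f"t{i:03d}"
        group = "up" if i < n_up else ("down" if i < n_up + n_other else "unchanged")
        groups[group].add(tid)
        for region in ("UTR5", "CDS", "UTR3"):
            seq = "".join(rng.choice(list("ACGT"), size=length))
            if region == "UTR5" and group == "up":
                for _ in range(rate):
                    pos = int(rng.integers(0, length - len(site)))
                    seq = seq[:pos] + site + seq[pos + len(site):]
            ann[(tid, region)] = seq
    return build_tables(ann, groups), groups


class TestPermutationNull:
    def test_same_seed_identical_null(self, rng):
        tables, _ = planted_tables(rng)
        n1 = permutation_null(tables, MIR10B, n_shuffles=20, seed=3)
        n2 = permutation_null(tables, MIR10B, n_shuffles=20, seed=3)
        for key in n1.region:
            assert np.array_equal(n1.region[key], n2.region[key], equal_nan=True)

    def test_shuffled_catalogues_conserve_size(self, rng):
        # the observed-path identity: feeding the true miRNA as "shuffle 0"
        # reproduces the observed ratios exactly, because the null reuses the
        # identical catalogue -> count -> normalize -> ratio code path
        tables, _ = planted_tables(rng)
        collapsed = collapse_motifs(enumerate_motifs(MIR10B, 6, 9))
        c = default_pseudocount(tables.group_sizes)
        _, _, agg_obs = _region_stats(tables, collapsed, c, "occurrences")
        result = compute_enrichment(tables, MIR10B, n_shuffles=10, seed=1)
        summary = result.region_summary.set_index("region")
        for region in ("UTR5", "CDS", "UTR3"):
            assert summary.loc[region, "agg_ratio_up_unchanged"] == pytest.approx(
                agg_obs[(region, "up_unchanged")]
            )

    def test_sampled_null_matches_exhaustive_permutation_oracle(self, rng):
        # tiny instance: every distinct letter permutation of a short miRNA is
        # enumerated and the exceedance probability of the UTR5 aggregate
        # ratio computed exactly; the sampled null must agree within 2 SD
        mirna_seq = "AAAAACCGT"  # 9!/(5!2!) = 1512 distinct arrangements
        tables, _ = planted_tables(rng, n_up=6, n_other=6, site="ACGGTT", rate=1)
        c = default_pseudocount(tables.group_sizes)

        distinct = {"".join(p) for p in itertools.permutations(mirna_seq)}
        exceed = 0
        for seq in sorted(distinct):
            collapsed = collapse_motifs(enumerate_motifs(seq, 6, 7))
            _, _, agg = _region_stats(tables, collapsed, c, "occurrences")
            if agg[("UTR5", "up_unchanged")] > 1.5:
                exceed += 1
        p_exact = exceed / len(distinct)

        from mirmotif import MatureMiRNA

        n_shuffles = 400
        null = permutation_null(
            tables, MatureMiRNA("tiny", mirna_seq), n_shuffles=n_shuffles,
            seed=8, k_min=6, k_max=7,
        )
        p_sampled = (null.region[("UTR5", "up_unchanged")] > 1.5).mean()
        sd = np.sqrt(p_exact * (1 - p_exact) / n_shuffles)
        assert abs(p_sampled - p_exact) <= max(2 * sd, 2 / n_shuffles)


class TestComputeEnrichment:
    def test_planted_site_enriched_in_utr5(self, rng):
        # group sizes and region lengths chosen large enough that null
        # aggregate ratios concentrate near 1 (the 1.5 criterion's regime)
        tables, _ = planted_tables(rng, n_up=150, n_other=200, length=300, rate=2)
        result = compute_enrichment(tables, MIR10B, n_shuffles=100, seed=2)
        summary = result.region_summary.set_index("region")
        assert summary.loc["UTR5", "agg_ratio_up_unchanged"] > 1.5
        assert summary.loc["UTR5", "agg_p_chance"] < 0.05
        assert bool(summary.loc["UTR5", "enriched"])

    def test_scale_invariance_of_ratios(self, rng):
        # duplicating every transcript doubles counts and group sizes and
        # leaves all pseudocount-free ratios unchanged
        rng3 = np.random.default_rng(999)
        ann = {}
        groups3 = {"up": set(), "down": set(), "unchanged": set()}
        for i in range(30):
            tid = f"t{i}"
            g = ("up", "down", "unchanged")[i % 3]
            groups3[g].add(tid)
            for region in ("UTR5", "CDS", "UTR3"):
                ann[(tid, region)] = "".join(rng3.choice(list("ACGT"), size=90))
        doubled = dict(ann)
        groups_doubled = {g: set(s) for g, s in groups3.items()}
        for (tid, region), seq in ann.items():
            doubled[(tid + "_copy", region)] = seq
        for g in groups_doubled:
            groups_doubled[g] |= {t + "_copy" for t in groups3[g]}
        collapsed = collapse_motifs(enumerate_motifs(MIR10B, 6, 7))
        t1 = build_tables(ann, groups3, ks=(6, 7))
        t2 = build_tables(doubled, groups_doubled, ks=(6, 7))
        _, r1, a1 = _region_stats(t1, collapsed, 0.0, "occurrences")
        _, r2, a2 = _region_stats(t2, collapsed, 0.0, "occurrences")
        for key in a1:
            assert a1[key] == pytest.approx(a2[key], nan_ok=True)
        for key in r1:
            assert np.allclose(r1[key], r2[key], equal_nan=True)

    def test_summary_zero_significant_when_all_below_threshold(self, rng):
        # unplanted annotation: ratios hover near 1, nothing clears 1.5+null
        ann, groups = {}, {"up": set(), "down": set(), "unchanged": set()}
        for i in range(90):
            tid = f"t{i}"
            groups[("up", "down", "unchanged")[i % 3]].add(tid)
            for region in ("UTR5", "CDS", "UTR3"):
                ann[(tid, region)] = "".join(rng.choice(list("ACGT"), size=200))
        tables = build_tables(ann, groups)
        result = compute_enrichment(tables, MIR10B, n_shuffles=60, seed=4)
        assert not result.region_summary["enriched"].any()

    def test_summary_invariant_to_motif_row_order(self, rng):
        tables, _ = planted_tables(rng)
        result = compute_enrichment(tables, MIR10B, n_shuffles=30, seed=6)
        agg = {
            (r, p): result.region_summary.set_index("region").loc[r, c]
            for r, p, c in [
                ("UTR5", "up_unchanged", "agg_ratio_up_unchanged"),
                ("UTR5", "up_down", "agg_ratio_up_down"),
                ("CDS", "up_unchanged", "agg_ratio_up_unchanged"),
                ("CDS", "up_down", "agg_ratio_up_down"),
                ("UTR3", "up_unchanged", "agg_ratio_up_unchanged"),
                ("UTR3", "up_down", "agg_ratio_up_down"),
            ]
        }
        shuffled_table = result.motif_table.sample(frac=1.0, random_state=0)
        summary2 = region_enrichment_summary(shuffled_table, agg, result.null)
        pd.testing.assert_frame_equal(
            result.region_summary.drop(columns=["agg_p_chance_up_down"]),
            summary2.drop(columns=["agg_p_chance_up_down"]),
        )


class TestMotifComposition:
    def test_single_nonzero_octamer_has_relative_frequency_one(self):
        table = motif_composition({"AAAATTTT": 5}, {"AAAATTTT": 2}, k=8)
        assert table["rel_freq_up"].tolist() == [1.0]
        assert table["rel_freq_down"].tolist() == [1.0]

    def test_relative_frequencies_sum_to_one(self, rng):
        motifs = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(12)]
        up = {m: int(rng.integers(0, 20)) for m in motifs}
        down = {m: int(rng.integers(0, 20)) for m in motifs}
        up[motifs[0]] += 1  # ensure nonzero totals
        down[motifs[1]] += 1
        table = motif_composition(up, down, k=8)
        assert table["rel_freq_up"].sum() == pytest.approx(1.0, abs=1e-12)
        assert table["rel_freq_down"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_smoothed_ratio_finite_at_zero_down_counts(self):
        table = motif_composition({"A" * 8: 10, "C" * 8: 0}, {"A" * 8: 0, "C" * 8: 0}, k=8)
        assert np.isfinite(table["ratio"]).all()

    def test_wrong_length_motifs_rejected(self):
        with pytest.raises(ValueError):
            motif_composition({"ACGTAC": 1}, {"ACGTAC": 1}, k=8)
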