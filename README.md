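# mirmotif

Tools for discovering **non-canonical miRNA target sites** from perturbation
transcriptomics — the analysis pattern in which a miRNA is inhibited with an
antisense oligonucleotide (ASO) in several cell cultures, transcripts are
grouped by their expression response, and the sequence content of their
5′UTR / CDS / 3′UTR regions is tested for enrichment of motifs complementary
to *any* part of the mature miRNA, not just the seed.

The motivating biology: canonical miRNA targeting pairs the seed (miRNA
nucleotides 2–7) to 3′UTRs. In glioblastoma stem-like cells, inhibiting
miR-10b derepresses transcripts whose **5′UTRs** carry sites complementary
to the miRNA's **3′ end** — a non-canonical mode invisible to seed-based
target predictors. `mirmotif` packages that discovery procedure as a tested,
reusable pipeline, together with a synthetic-data generator that plants
known signal so every stage can be validated end to end.

## The method

Given a mature miRNA of length L (miR-10b: 5′-UACCCUGUAGAACCGAAUUUGUG-3′,
L = 23, the reverse complement of its inhibitor
5′-CACAAATTCGGTTCTACAGGGTA-3′):

1. **Transcript grouping.** For each cell line, a transcript's fold change is
   FC = 2^(mean log2 inhibitor − mean log2 reference) with a two-sided
   unpaired Student's *t*-test; it is *up* if FC > 1.2 and p < 0.05, *down*
   if FC < 0.8 and p < 0.05, else *unchanged*. The consensus call requires
   agreement in ≥ 2 of the 3 cell lines.
2. **Motif catalogue.** All subsequences of the miRNA with length k ∈ [6, 9]
   — Σₖ (L − k + 1) = 66 windows for L = 23 — each classified by origin:
   *seed* (covers nucleotides 2–7), *3′-end* (entirely within the 3′ half),
   or *central*. The reverse complement of each window is a candidate
   binding site.
3. **Region scanning.** Overlapping exact occurrences of every site are
   counted in the 5′UTR, CDS and 3′UTR of every grouped transcript and
   normalized by group size: f(motif, region, group) = occurrences / n_group.
4. **Enrichment ratios and the shuffled null.** For each motif and region,
   R = f_up / f_down and R = f_up / f_unchanged. The identical procedure is
   repeated for shuffled (composition-preserving) permutations of the miRNA
   (default 1000), and the pipeline reports the empirical probability that a
   ratio exceeds the criterion R > 1.5 by chance.
5. **Isoform switches.** Genes with one transcript/probe consensus-up and
   another consensus-down (same thresholds) are reported as inversely
   regulated isoform pairs — a splicing-shift readout.

## Worked example

```python
from mirmotif import (MIR10B, SynthConfig, generate_dataset, build_groups,
                      enumerate_motifs, compute_enrichment)
from mirmotif.motifs import build_tables

# synthetic study: 3 cell lines, duplicates, 1200 transcripts; 3'-end octamer
# sites planted into up-group 5'UTRs at 3x the background rate
cfg = SynthConfig(seed=11, n_genes=1200, isoforms_per_gene=(1, 1),
                  n_switch_genes=0, frac_up=0.30, frac_down=0.20,
                  plant_rate_target=1.5, plant_rate_background=0.5)
annotation, truth, matrix, samples = generate_dataset(cfg)

groups, de = build_groups(matrix, samples)
print({g: len(getattr(groups, g)) for g in ("up", "down", "unchanged")})
# {'up': 354, 'down': 234, 'unchanged': 612}

tables = build_tables(annotation.sequences, groups)
result = compute_enrichment(tables, MIR10B, n_shuffles=200, seed=5)
print(result.region_summary[["region", "agg_ratio_up_unchanged",
                             "agg_p_chance", "enriched"]].to_string(index=False))
# region  agg_ratio_up_unchanged  agg_p_chance  enriched
#   UTR5                2.392607        0.0199      True
#    CDS                1.041963        1.0000     False
#   UTR3                0.900631        1.0000     False
```

The up-group 5′UTRs carry miRNA-complementary sites at 2.4× the rate of
unchanged transcripts; only 3 of 200 shuffled-miRNA catalogues produce a
ratio above 1.5, so the enrichment is unlikely to be a sequence-composition
artifact — while CDS and 3′UTR, where sites were planted evenly, stay quiet.

The same analysis is available from the shell:

```bash
mirmotif run --out results_dir --seed 11        # full pipeline
mirmotif simulate --out sim --seed 1            # individual stages
mirmotif de --matrix sim/matrix.tsv --samples sim/samples.tsv --out de_out
```

Each run writes TSV tables (groups, per-line DE, motif catalogue, counts,
enrichment, region summary, octamer composition, isoform pairs) and a
`manifest.json` recording every threshold, seed and output hash.

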