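# Methods

## Model and procedure

`mirmotif` implements a perturbation-based miRNA target-site discovery
procedure. The experimental design it assumes: several cell cultures (default
3) are each treated with a miRNA inhibitor, a non-targeting control
oligonucleotide, and vehicle only ("mock"), in replicate (default 2), and
profiled as log2 expression intensities (microarray-like). Transcripts that
rise when the miRNA is inhibited are candidate direct targets; the sequence
signature of direct targeting is an excess of miRNA-complementary k-mers in
their mRNA regions relative to transcripts that fall or do not move.

### Differential expression and grouping

Per cell line and transcript, the fold change is the geometric form
2^(Δ mean log2) — the standard choice for log-scale intensity data — and
significance comes from a two-sided unpaired Student's (pooled-variance)
*t*-test. Welch's form is available (`welch=True`) but is not the default:
with only two replicates per condition the Welch test is markedly
conservative (its null rejection rate at α = 0.05 is ≈ 2.3%), while the
pooled test is exact under the generator's equal-variance Gaussian noise.

The reference group defaults to the pooled control **and** mock samples
(`reference=("control", "mock")`), giving 4 reference replicates against 2
treated. This matches the design in which inhibitor-treated cells are
compared against non-targeting-control or mock-treated samples, and it is
what makes a 2-replicate design usable at all: at effect 1 log2 unit and
noise SD 0.25, per-line power is ≈ 0.92 against the pooled reference versus
≈ 0.56 against control alone. Either single reference can be selected.

Classification uses strict inequalities — up: FC > 1.2 and p < 0.05; down:
FC < 0.8 and p < 0.05; ties fall to unchanged — and the consensus call
requires the same class in ≥ `min_lines` (default 2) of the cell lines. If a
permissive `min_lines` lets both directions reach the bar, the call falls
back to unchanged. No multiple-testing correction is applied by default
(grouping is on raw p-values); Benjamini–Hochberg is available behind
`bh_correct=True`. A pooled-lines mode (one test over all lines' samples)
replaces the consensus when `pooled_lines=True`.

The ΔΔCt helper (`ddct_fold_change`) implements relative qPCR
quantification, fold change = 2^−ΔΔCt, for cross-checking individual genes.

### Motif catalogue and origin classes

All subsequences of the mature miRNA with k ∈ [k_min, k_max] (default 6–9 nt)
are enumerated — Σₖ (L−k+1) positional windows, 66 for a 23-nt miRNA. Window
origin is classified 1-based: *seed* when the window fully covers nucleotides
2–7; *3′-end* when it lies entirely past ceil(L/2) (position ≥ 13 for
L = 23); otherwise *central*. The 3′-half boundary is not canonical in the
field; it is exposed (`three_prime_start`) and the half-sequence default is
our documented choice. Duplicate subsequences from different positions are
collapsed for counting — a site match cannot distinguish them — and keep the
union of their origin classes for reporting.

Matching is exact Watson–Crick reverse complementation in the DNA alphabet
(U→T at ingestion, uppercase): no G:U wobble, no mismatches, and only the
sense mRNA strand is scanned, since the miRNA binds the mRNA itself.
Overlapping occurrences are counted by default; a presence/absence mode
(each transcript counted at most once per motif) is computed alongside.

### Counting implementation

The scanner pre-aggregates dense k-mer count arrays (4^k bins per k,
occurrence and presence variants) per (region, DE group). Building the
tables is a single pass over the sequences; counting any catalogue —
observed or shuffled — is then pure array lookup. This is what makes the
1000-shuffle null cheap: the tables are fixed and only the 66 looked-up
codes change per shuffle. A direct string scanner (`count_occurrences`)
serves the one-sequence API and as an internal cross-check; windows
containing non-ACGT characters are excluded from the tables.

### Enrichment and the shuffled-miRNA null

Counts are normalized per group: f = occurrences / n_transcripts(group),
with transcripts lacking a region excluded from that region's denominator.
Two ratios are formed per motif and region: f_up/f_down and
f_up/f_unchanged. Zero handling uses a pseudocount (default
1/max(group size), i.e. one pseudo-occurrence spread over the largest
group), recorded in the run manifest.

The null repeats the identical catalogue → count → normalize → ratio code
path for uniform composition-preserving shuffles of the miRNA (default
1000; the identity is testable by feeding the true miRNA through the null
path, which reproduces the observed ratios exactly). Two empirical
probabilities are reported:

- `p_chance` = (1 + #{null ratio > 1.5}) / (1 + n_shuffles) when the
  observed ratio itself exceeds 1.5, else 1 — operationalizing "the
  probability the ratio exceeds the 1.5 criterion by chance";
- `p_rank` = (1 + #{null ratio ≥ observed}) / (1 + n_shuffles), the
  conventional smoothed permutation rank p, co-reported because the gated
  estimator discards information when the observed ratio is large.

Per-motif p-values compare a motif's ratio against the pooled null ratios of
the same region and k across shuffles; the headline region statistic
aggregates motifs by summed occurrences (preserving count additivity, unlike
a mean of ratios) and compares against the per-shuffle aggregate null. A
region is flagged *enriched* when its aggregate up/unchanged ratio exceeds
1.5 with `p_chance` < 0.05. The choice of per-motif versus per-region
probabilities is ambiguous in principle; all are emitted, with the region
aggregate treated as the headline.

The absolute 1.5 criterion presumes realistic scale: with groups of only a
few dozen transcripts and very short regions, null aggregate ratios are
noisy enough to exceed 1.5 frequently, and the criterion loses meaning. At
the scale the pipeline targets (hundreds of transcripts per group, region
lengths of hundreds to thousands of nt) null aggregates concentrate near 1.

### Octamer composition (up vs down)

For k = 8, the relative composition of motif occurrences within the up set
and within the down set is compared per motif (columns are raw count shares
summing to 1). The composition ratio uses add-one smoothing on raw counts —
without it, sparse motifs divide by zero. Note that composition is
scale-free: if the same sites are planted in both groups at proportional
rates, the two compositions are similar even when absolute per-transcript
frequencies differ threefold; composition differences appear when the up
set's sites are specific to it.

### Isoform pairs

A gene contributes every (up, down) combination of its transcripts that pass
the same per-line thresholds and ≥ min_lines consensus — m up-members and n
down-members yield m×n pairs, ordered deterministically. By default the two
members may qualify in different cell lines; `same_lines=True` requires
≥ min_lines shared lines.

## Synthetic data generator

The generator emulates the study design, not the platform: i.i.d. per-base
sequences at a configured GC content (default 0.45, roughly mRNA-like) for
5′UTR/CDS/3′UTR with Gaussian lengths (defaults 200/1200/800 nt; CDS forced
to a multiple of 3, no codon model); log2 intensities as baseline ~
N(8, 1) plus a treatment effect (±effect_log2fc on inhibitor samples of
up/down transcripts) plus N(0, noise_sd) noise. Replicate-level variance of
the original arrays is unknown; noise_sd = 0.25 is a free parameter chosen
so that a 2-replicate design has high but not saturating per-line power
(≈ 0.9), and is documented as such. Mock is generated identically to
control. Planted target sites (default: the target sites of the miRNA's
3′-end octamer windows) overwrite background bases without overlap at
Poisson rates — `plant_rate_target` for the chosen (region, group), default
1.5/transcript, `plant_rate_background` elsewhere, default 0.5, i.e. a 3×
contrast; placement is best-effort on rare short regions, and the recorded
truth is the actual placements. The first `n_switch_genes` genes carry
exactly two isoforms with opposite effects as switch ground truth.

What the generator does **not** model — probe effects, normalization
artifacts, batch effects, correlated noise, codon structure, real UTR
composition biases (GC gradients, repeats), G:U wobble pairing — bounds what
passing tests show: they validate the statistical machinery and its
calibration under the stated noise model, not performance on real arrays.
Real 5′UTRs are, in particular, more GC-rich and repeat-laden than the
i.i.d. null, so real-data enrichment ratios inherit composition biases that
only the shuffled-miRNA null (which preserves miRNA composition) partially
absorbs.

## Numerical and degenerate-input choices

- Zero-variance t-tests: both groups constant and equal → p = 1; constant
  and unequal → p = 0 (infinite-t limit); occurrences are logged.
- Strict inequalities at every threshold; boundary values are unchanged /
  not significant.
- Empty (region, group) combinations drop out with a warning; their
  frequencies are NaN and never reach significance.
- All randomness flows from numpy `SeedSequence` fan-out: the pipeline seed
  deterministically derives per-stage child seeds, so stages are
  individually reproducible and identical config + seed gives byte-identical
  output tables.
- Problem sizes in the test and acceptance suites (≈ 1200–2000 transcripts,
  200 shuffles, 20 repetitions) are chosen as the smallest scale at which
  the 1.5-ratio criterion operates in its intended regime.

## Known limitations

- Exact matching only; thermodynamic duplex stability, wobble pairing and
  conservation are out of scope.
- The moderated-statistics stack used for the original array analysis
  (GCRMA + empirical-Bayes linear models) is intentionally replaced by the
  plain t-test machinery above; input matrices are assumed normalized.
- The per-motif null pools shuffled windows within (region, k), which
  ignores between-motif composition differences; the region aggregate does
  not have this issue and is the recommended statistic.
- The 3′-end boundary (half-sequence rule) and the pseudocount are
  documented conventions, both configurable.
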