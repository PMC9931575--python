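# Methods

This note records the statistical model, parameter defaults, and numerical
choices behind the `cge` package, and the scope and limitations of the
simulator used to validate it.

## 1. Tag model

A locus design specifies a reference amplicon, a variant region (default 6 nt,
`original_seq` vs `mutant_seq`), and a tag scheme over the `2f` flank
positions (default `f = 5` on each side, 10 positions total). During oligo
synthesis each flank position is doped: each of the three non-reference bases
appears with probability 0.08, so the per-position mutation probability is
`p = 0.24` and the number of tag mutations per oligo is Binomial(10, 0.24).

Closed forms used throughout:

- number of tags at exactly `k` substitutions: `C(10, k) · 3^k`
  (1, 30, 405, 3240, … for k = 0, 1, 2, 3);
- `P(K ∈ {2,3}) = 0.5314` — most oligos are usefully tagged;
- `P(K ≤ 5) = 0.9839` — the efficiency-analysis acceptance radius;
- `P(K = 0) = 0.76^10 = 0.0643` — HDR-original templates indistinguishable
  from wild type (reported as `expected_wt_leakage`, not corrected for).

For coding-region targets, tags instead come from synonymous degenerate
codon positions (`CodonTagSpec`); the designer verifies synonymy and refuses
positions without a synonymous alternative.

## 2. Read extraction

1. **Locus assignment.** A read is assigned to a locus iff its first 20 nt
   exactly match that locus's amplicon prefix. Duplicate prefixes across loci
   are a configuration error.
2. **Window extraction.** The matcher locates the first occurrence of either
   variant sequence in the read (reads containing both are rejected as
   `ambiguous_center`) and takes the 16-nt window `5' flank + variant + 3'
   flank`. Windows truncated by the read end are rejected.
3. **Substitution-only matching.** The 10-nt concatenated flank is compared
   to the reference flank by Hamming distance; the window is accepted iff
   the distance is ≤ `max_subs`. No gapped alignment is attempted.

Two stringencies are used:

- `max_subs = 5` for editing-efficiency decomposition: keeps 98.4% of HDR
  tags while bounding spurious acceptance.
- `max_subs = 2` for lineage-pair analysis, combined with the
  exactly-2-mutations tag filter (below).

**Indel behaviour.** A 1-nt indel confined to one flank shifts at most 5 of
the 16 window positions. When the indel is adjacent to the variant (the
common NHEJ geometry) and neighbouring flank bases differ, the shifted window
accumulates ≥3 mismatches and is rejected at `max_subs = 2`. At
`max_subs = 5` rejection of indels is *not* guaranteed — a shifted flank can
legitimately land inside the Hamming ball — which is one reason the pair
analysis uses the tighter radius. The matcher is validated read-for-read
against a brute-force oracle (exact containment in the enumerated Hamming
ball of windows) on randomized corpora including indels.

## 3. Editing-outcome classification

Each accepted window is classified:

- **WT**: original variant, zero flank mutations;
- **HDR_original**: original variant, 1…`max_subs` flank mutations;
- **HDR_mutant**: mutant variant, 0…`max_subs` flank mutations;
- **NHEJ**: everything else assigned to the locus (no acceptable window —
  typically an indel-disrupted junction).

This classifier is deliberately simple and carries known biases that are
reported rather than hidden: unmutated HDR-original templates count as WT
(expected share 6.4%), and HDR tags with more than `max_subs` mutations
(1.6% at radius 5) fall into NHEJ. The efficiency report exposes both the
raw counts and these expected leakages.

## 4. Paired-lineage statistics

For each tag present as both an original and a mutant lineage:

```
log2fc = log2[ (mut_end + 1)/(orig_end + 1) ÷ (mut_base + 1)/(orig_base + 1) ]
```

- **Pseudocount** +1 on every count; a lineage absent at the endpoint
  contributes 0 reads, not a dropped pair.
- **Baseline threshold**: both baseline counts must *strictly exceed*
  `min_baseline_count` (raw counts, before pseudocount). Defaults by assay
  depth: 50 (E-box fitness), 20 (GRB2-class), 5 (CDK1-class), 100 (ChIP
  input, applied to the input sample only).
- **Tag filter**: only tags with exactly 2 flank mutations
  (`tag_mutation_filter = (2,)`) enter the pair analysis — an abundant class
  (2- and 3-mutation tags together cover 53% of oligos) that cannot be
  created from a WT read by a single sequencing error.
- **Test**: two-sided Wilcoxon signed-rank on the per-pair log2fc, exact
  null distribution for n ≤ 25, normal approximation with continuity
  correction above; zero differences dropped (`wilcox` rule); no
  multiple-comparison adjustment by default (each locus is a separate
  experiment; Benjamini–Hochberg is available as `adjust_pvalues_bh`).
- **Confidence interval**: percentile bootstrap of the median (2,000
  resamples, seeded).
- **Internal replicates**: pairs are split into disjoint groups by the
  parity of the 5'-most mutated flank position (or by the base at a
  designated randomized position for codon-tag designs) and each group is
  tested separately.
- **Replicate correlation**: per-tag log2fc matched by exact tag string
  across independent experiments, Pearson r.

ChIP enrichment reuses the same machinery with (input, IP) in place of
(baseline, endpoint).

## 5. Simulator

`cge.simulate` draws a full ground-truth experiment:

1. each transfected cell's outcome is multinomial over (WT, HDR, NHEJ),
   default (0.6, 0.3, 0.1);
2. HDR cells integrate original or mutant templates with equal probability
   and a tag drawn from the binomial flank model; cells sharing (variant,
   tag) found one lineage;
3. NHEJ cells acquire a 1–10-nt deletion centered on the cut site;
4. lineages grow exponentially from the baseline day (2) to the endpoint day
   (8) with rate `base_growth + fitness_effect·[mutant] + N(0, σ)` where
   σ = `lineage_rate_sd` = 0.05/day by default;
5. each sequenced sample is a multinomial read draw from lineage abundances
   at the configured depth (default 10⁶), with iid substitution errors at
   rate 0.001 per base (drawn exactly: a Binomial(L, rate) error count, then
   distinct uniform positions).

The generative identity used in validation:
`median log2fc = (endpoint_day − baseline_day) · fitness_effect / ln 2`,
e.g. −0.231/day × 6 days → −2.

`simulate_count_tables` is a count-level fast path (lineage counts drawn
directly, no read synthesis) used for many-locus calibration runs; it shares
the lineage-founding code with the FASTQ path and is tested against it.
`simulate_chip` reweights IP sampling of HDR-mutant lineages by a configured
binding fold change.

**Scope and limitations.** The simulator models substitution sequencing
error only (no simulated indel errors or quality-dependent error), a single
deletion allele per NHEJ cell, no PCR jackpotting or UMI structure, and
growth noise that is lineage-iid. These are the conditions under which the
pipeline's estimators are validated; real libraries add PCR and
amplification noise that the baseline-count threshold is designed to absorb.

## 6. Numerical and scale choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical seeds reproduce identical FASTQ bytes.
- Exact binomial pmfs via `scipy.stats.binom`; Wilcoxon and Pearson via
  `scipy.stats`; FASTQ via `Bio.SeqIO`.
- Test and example problem sizes (5,000–30,000 cells, 10⁵–10⁶ reads,
  100–200 null loci) are chosen so the whole validation suite runs in
  minutes on one core while keeping ≥100 lineage pairs past the strict >50
  baseline threshold — the regime where the median and signed-rank test are
  well calibrated. They are this package's choices for tractable validation,
  not statements about experimental scale.
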