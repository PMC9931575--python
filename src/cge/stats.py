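"""Paired-lineage statistics for competitive genome editing.

Each sequence tag observed with both the mutant and the original variant
defines a lineage pair: two cell lineages founded in the same well,
differing only by the engineered variant (plus the shared near-silent tag).
The variant's effect is the per-pair log2 fold change

    log2fc = log2[ endpoint (mut/orig) / baseline (mut/orig) ]

computed on +1-pseudocounted read counts — day 8 over day 2 for fitness,
ChIP IP over input for binding. Tags are filtered on raw baseline counts
(strict '>', e.g. >50 for E-box fitness, >100 for ChIP input) and on their
flank-mutation count (the headline analyses use exactly-2-mutation tags;
one-mutation original-variant tags can arise from PCR/sequencing error).
The per-locus median is tested against zero with a two-sided Wilcoxon
signed-rank test; no multiple-comparison adjustment is applied by default.
Internal-replicate binning splits the pairs into disjoint groups by tag
features and repeats the test per group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .extract import TagCountTable, hamming

#: raw-count baseline inclusion thresholds (strict '>') used per experiment type
DEFAULT_THRESHOLDS = {"ebox": 50, "grb2": 20, "cdk1": 5, "chip_input": 100}
PSEUDOCOUNT = 1

#: records kept for the headline analysis: tags with exactly two flank mutations
DEFAULT_TAG_MUTATION_FILTER = (2,)

#: switch from the exact signed-rank null to the normal approximation above this n
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class LineagePairRecord:
    """One tag seen with both variants; the unit of the paired analysis."""

    locus_name: str
    tag: str
    n_flank_mutations: int
    count_orig_baseline: int
    count_mut_baseline: int
    count_orig_endpoint: int
    count_mut_endpoint: int
    log2fc: float
    reference_flank: str = ""


@dataclass(frozen=True)
class FitnessResult:
    """Per-locus (or per-group) summary of the paired log2 fold changes."""

    locus_name: str
    n_pairs: int
    median_log2fc: float
    p_value: float
    filter_settings: dict = field(default_factory=dict)
    group_label: str | None = None
    ci_low: float | None = None
    ci_high: float | None = None


def pair_log2fc(
    orig_baseline: int, mut_baseline: int, orig_endpoint: int, mut_endpoint: int
) -> float:
    """log2[(endpoint mut/orig) / (baseline mut/orig)] with +1 pseudocounts."""
    num = (mut_endpoint + PSEUDOCOUNT) / (orig_endpoint + PSEUDOCOUNT)
    den = (mut_baseline + PSEUDOCOUNT) / (orig_baseline + PSEUDOCOUNT)
    return math.log2(num / den)


def pair_lineages(
    baseline: TagCountTable,
    endpoint: TagCountTable,
    reference_flank: str,
    min_baseline_count: int = DEFAULT_THRESHOLDS["ebox"],
    tag_mutation_filter: Sequence[int] | None = DEFAULT_TAG_MUTATION_FILTER,
) -> list[LineagePairRecord]:
    """Build lineage pairs from baseline and endpoint count tables.

    A tag yields a pair iff (a) its flank-mutation count is in
    ``tag_mutation_filter`` (None disables the filter) and (b) its raw
    baseline count strictly exceeds ``min_baseline_count`` for *both*
    variants. Pseudocounts enter only the ratio; missing endpoint counts
    are raw 0 and stay finite through the pseudocount.
    """
    if baseline is None or endpoint is None:
        raise ValueError("both baseline and endpoint tables are required")
    if baseline.locus_name != endpoint.locus_name:
        raise ValueError(
            f"tables describe different loci: {baseline.locus_name} vs {endpoint.locus_name}"
        )
    allowed = None if tag_mutation_filter is None else set(tag_mutation_filter)
    tags = {tag for (_, tag) in baseline.counts}
    records = []
    for tag in sorted(tags):
        n_mut = hamming(tag, reference_flank)
        if allowed is not None and n_mut not in allowed:
            continue
        ob = baseline.count("original", tag)
        mb = baseline.count("mutant", tag)
        if ob <= min_baseline_count or mb <= min_baseline_count:
            continue
        oe = endpoint.count("original", tag)
        me = endpoint.count("mutant", tag)
        records.append(
            LineagePairRecord(
                locus_name=baseline.locus_name,
                tag=tag,
                n_flank_mutations=n_mut,
                count_orig_baseline=ob,
                count_mut_baseline=mb,
                count_orig_endpoint=oe,
                count_mut_endpoint=me,
                log2fc=pair_log2fc(ob, mb, oe, me),
                reference_flank=reference_flank,
            )
        )
    return records


def wilcoxon_signed_rank(values: Sequence[float]) -> float:
    """Two-sided signed-rank p-value against a zero median.

    Exact null for n <= 25 (after dropping zero differences, the classical
    convention), normal approximation with continuity correction above.
    All-zero input is degenerate: p = 1 with a warning.
    """
    x = np.asarray(values, dtype=float)
    nz = x[x != 0.0]
    if nz.size == 0:
        warnings.warn("all differences are exactly zero; signed-rank p undefined, returning 1.0",
                      stacklevel=2)
        return 1.0
    method = "exact" if nz.size <= WILCOXON_EXACT_MAX_N else "approx"
    res = sps.wilcoxon(
        nz, zero_method="wilcox", alternative="two-sided", correction=True, method=method
    )
    return float(min(res.pvalue, 1.0))


def _bootstrap_median_ci(
    values: np.ndarray, n_boot: int = 2000, alpha: float = 0.05, seed: int = 0
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    meds = np.median(
        rng.choice(values, size=(n_boot, values.size), replace=True), axis=1
    )
    lo, hi = np.quantile(meds, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def fitness_test(
    records: Sequence[LineagePairRecord],
    group_label: str | None = None,
    filter_settings: dict | None = None,
    ci: bool = False,
    ci_seed: int = 0,
) -> FitnessResult:
    """Median log2 fold change and its two-sided signed-rank test."""
    if not records:
        raise ValueError("fitness_test requires at least one lineage pair")
    x = np.array([r.log2fc for r in records])
    p = wilcoxon_signed_rank(x)
    lo = hi = None
    if ci:
        lo, hi = _bootstrap_median_ci(x, seed=ci_seed)
    return FitnessResult(
        locus_name=records[0].locus_name,
        n_pairs=len(records),
        median_log2fc=float(np.median(x)),
        p_value=p,
        filter_settings=dict(filter_settings or {}),
        group_label=group_label,
        ci_low=lo,
        ci_high=hi,
    )


def chip_enrichment(
    ip: TagCountTable,
    input_table: TagCountTable,
    reference_flank: str,
    min_input_count: int = DEFAULT_THRESHOLDS["chip_input"],
    tag_mutation_filter: Sequence[int] | None = DEFAULT_TAG_MUTATION_FILTER,
) -> tuple[list[LineagePairRecord], FitnessResult]:
    """Allele-specific ChIP enrichment: IP over input, per lineage pair.

    Identical mathematics to the fitness analysis with baseline := input and
    endpoint := IP; inclusion filters on the input counts only (strict '>',
    default >100).
    """
    records = pair_lineages(
        baseline=input_table,
        endpoint=ip,
        reference_flank=reference_flank,
        min_baseline_count=min_input_count,
        tag_mutation_filter=tag_mutation_filter,
    )
    settings = {"min_input_count": min_input_count, "tag_mutation_filter": tag_mutation_filter}
    return records, fitness_test(records, filter_settings=settings)


def mutated_positions(tag: str, reference_flank: str) -> list[int]:
    """0-based tag positions where the tag departs from the reference flank."""
    return [i for i, (a, b) in enumerate(zip(tag, reference_flank)) if a != b]


def bin_internal_replicates(
    records: Sequence[LineagePairRecord],
    scheme: str = "first_position_parity",
    designated_position: int = 0,
) -> dict[str, list[LineagePairRecord]]:
    """Split lineage pairs into disjoint internal-replicate groups.

    ``first_position_parity``: two groups, keyed 'odd'/'even' by the 1-based
    position of the 5'-most flank mutation (tags without mutations cannot be
    assigned and are dropped with a warning). ``first_random_base``: four
    groups keyed by the base observed at ``designated_position`` (0-based),
    the scheme used for fully randomized codon-tag designs.
    """
    groups: dict[str, list[LineagePairRecord]] = {}
    n_unassignable = 0
    for r in records:
        if scheme == "first_position_parity":
            pos = mutated_positions(r.tag, r.reference_flank)
            if not pos:
                n_unassignable += 1
                continue
            key = "odd" if (pos[0] + 1) % 2 == 1 else "even"
        elif scheme == "first_random_base":
            key = r.tag[designated_position]
        else:
            raise ValueError(f"unknown binning scheme {scheme!r}")
        groups.setdefault(key, []).append(r)
    if n_unassignable:
        warnings.warn(
            f"{n_unassignable} zero-mutation tags cannot be parity-binned; excluded",
            stacklevel=2,
        )
    return groups


def internal_replicate_fitness(
    records: Sequence[LineagePairRecord],
    scheme: str = "first_position_parity",
    designated_position: int = 0,
) -> dict[str, FitnessResult]:
    """Per-group medians and signed-rank tests for the internal replicates."""
    groups = bin_internal_replicates(records, scheme, designated_position)
    return {
        key: fitness_test(recs, group_label=key)
        for key, recs in sorted(groups.items())
        if recs
    }


def replicate_correlation(
    records_exp1: Sequence[LineagePairRecord],
    records_exp2: Sequence[LineagePairRecord],
) -> tuple[float, float, int]:
    """Pearson correlation of per-tag log2fc across two independent experiments.

    Tags are matched by exact string; each input should already carry the
    per-experiment baseline filter, so the shared set satisfies it in both.
    Returns (r, two-sided p, number of shared tags).
    """
    by_tag1 = {r.tag: r.log2fc for r in records_exp1}
    by_tag2 = {r.tag: r.log2fc for r in records_exp2}
    shared = sorted(set(by_tag1) & set(by_tag2))
    if len(shared) < 2:
        raise ValueError(f"need >= 2 shared tags for a correlation, got {len(shared)}")
    x = np.array([by_tag1[t] for t in shared])
    y = np.array([by_tag2[t] for t in shared])
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), len(shared)


def adjust_pvalues_bh(results: Iterable[FitnessResult]) -> list[float]:
    """Optional Benjamini-Hochberg FDR over a collection of locus results.

    Off by default in the pipelines: each locus is a separate experiment
    and the headline analysis reports unadjusted p-values.
    """
    pvals = np.array([r.p_value for r in results])
    return list(sps.false_discovery_control(pvals, method="bh"))
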