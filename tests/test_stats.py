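"""Paired-lineage log2 fold changes, signed-rank testing, binning, replicates."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cge import (
    LineagePairRecord,
    TagCountTable,
    bin_internal_replicates,
    chip_enrichment,
    enumerate_tags,
    fitness_test,
    internal_replicate_fitness,
    pair_lineages,
    pair_log2fc,
    replicate_correlation,
    wilcoxon_signed_rank,
)

REF = "ACGTACGTAC"


def table(sample, counts, locus="L"):
    t = TagCountTable(sample_id=sample, locus_name=locus)
    for key, c in counts.items():
        t.counts[key] = c
    t.total_reads_assigned = sum(counts.values())
    return t


def record(tag, log2fc, n_mut=2, ref=REF):
    return LineagePairRecord(
        locus_name="L", tag=tag, n_flank_mutations=n_mut,
        count_orig_baseline=100, count_mut_baseline=100,
        count_orig_endpoint=100, count_mut_endpoint=100,
        log2fc=log2fc, reference_flank=ref,
    )


class TestPairLog2fc:
    def test_no_change_identity(self):
        assert pair_log2fc(100, 100, 100, 100) == 0.0

    def test_worked_example_with_pseudocount(self):
        # baseline 100/100, endpoint orig 100 / mut 25
        assert pair_log2fc(100, 100, 100, 25) == pytest.approx(math.log2(26 / 101))

    def test_finite_for_all_zero_counts(self):
        assert math.isfinite(pair_log2fc(0, 0, 0, 0))

    @settings(deadline=None, max_examples=200)
    @given(st.tuples(*[st.integers(min_value=0, max_value=10_000)] * 4))
    def test_pseudocount_keeps_log2fc_finite_and_label_swap_negates(self, counts):
        ob, mb, oe, me = counts
        v = pair_log2fc(ob, mb, oe, me)
        assert math.isfinite(v)
        assert pair_log2fc(mb, ob, me, oe) == pytest.approx(-v, abs=1e-12)


class TestPairLineages:
    def _tables(self, tag_counts):
        base = {}
        end = {}
        for tag, (ob, mb, oe, me) in tag_counts.items():
            base[("original", tag)] = ob
            base[("mutant", tag)] = mb
            end[("original", tag)] = oe
            end[("mutant", tag)] = me
        return table("baseline", base), table("endpoint", end)

    def test_strict_threshold_excludes_exact_boundary(self):
        tag_ok = enumerate_tags(REF, 2)[0]
        tag_edge = enumerate_tags(REF, 2)[1]
        b, e = self._tables({tag_ok: (51, 51, 10, 10), tag_edge: (50, 51, 10, 10)})
        recs = pair_lineages(b, e, REF, min_baseline_count=50, tag_mutation_filter=(2,))
        assert [r.tag for r in recs] == [tag_ok]

    def test_mutation_count_filter(self):
        tags = {
            enumerate_tags(REF, 1)[0]: (100, 100, 50, 50),
            enumerate_tags(REF, 2)[0]: (100, 100, 50, 50),
            enumerate_tags(REF, 3)[0]: (100, 100, 50, 50),
        }
        b, e = self._tables(tags)
        recs = pair_lineages(b, e, REF, min_baseline_count=10, tag_mutation_filter=(2,))
        assert len(recs) == 1 and recs[0].n_flank_mutations == 2
        recs = pair_lineages(b, e, REF, min_baseline_count=10, tag_mutation_filter=(1,))
        assert len(recs) == 1 and recs[0].n_flank_mutations == 1
        recs = pair_lineages(b, e, REF, min_baseline_count=10, tag_mutation_filter=None)
        assert len(recs) == 3

    def test_missing_endpoint_counts_become_zero(self):
        tag = enumerate_tags(REF, 2)[0]
        b = table("baseline", {("original", tag): 100, ("mutant", tag): 100})
        e = table("endpoint", {})
        recs = pair_lineages(b, e, REF, min_baseline_count=50, tag_mutation_filter=(2,))
        assert len(recs) == 1
        assert recs[0].count_orig_endpoint == 0 and math.isfinite(recs[0].log2fc)

    def test_mismatched_loci_rejected(self):
        b = table("baseline", {}, locus="A")
        e = table("endpoint", {}, locus="B")
        with pytest.raises(ValueError):
            pair_lineages(b, e, REF)

    def test_label_swap_negates_every_log2fc(self):
        tags = enumerate_tags(REF, 2)[:20]
        rng = np.random.default_rng(3)
        counts = {
            t: tuple(int(x) for x in rng.integers(60, 400, 4)) for t in tags
        }
        b, e = self._tables(counts)
        fwd = pair_lineages(b, e, REF, min_baseline_count=50, tag_mutation_filter=(2,))
        swapped = {t: (mb, ob, me, oe) for t, (ob, mb, oe, me) in counts.items()}
        b2, e2 = self._tables(swapped)
        rev = pair_lineages(b2, e2, REF, min_baseline_count=50, tag_mutation_filter=(2,))
        assert len(fwd) == len(rev) > 0
        for a, b_ in zip(fwd, rev):
            assert a.log2fc == pytest.approx(-b_.log2fc, abs=1e-12)


class TestWilcoxon:
    def test_six_negative_values_exact_p(self):
        # all-negative n=6: two-sided exact p = 2/2^6
        assert wilcoxon_signed_rank([-0.5, -1.0, -0.2, -2.0, -0.7, -1.5]) == (
            pytest.approx(2 / 2**6)
        )

    def test_symmetric_values_give_high_p_and_zero_median(self):
        vals = [0.3, -0.3, 1.1, -1.1, 0.7, -0.7, 2.0, -2.0]
        recs = [record(t, v) for t, v in zip(enumerate_tags(REF, 2), vals)]
        res = fitness_test(recs)
        assert res.median_log2fc == 0.0
        assert res.p_value > 0.9

    def test_all_zero_differences_return_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_signed_rank([0.0, 0.0, 0.0]) == 1.0

    def test_agrees_with_exact_null_enumeration(self, rng):
        """Against a from-scratch enumeration of all 2^n sign assignments."""
        for n in (5, 8, 10):
            x = rng.normal(0.4, 1.0, n)
            while np.any(x == 0) or len(set(abs(x))) < n:
                x = rng.normal(0.4, 1.0, n)
            ranks = np.argsort(np.argsort(np.abs(x))) + 1
            w_obs = ranks[x > 0].sum()
            mean_w = n * (n + 1) / 4
            stats = [
                np.sum([r for r, s in zip(ranks, signs) if s])
                for signs in itertools.product([False, True], repeat=n)
            ]
            dev = abs(w_obs - mean_w)
            p_exact = np.mean([abs(w - mean_w) >= dev - 1e-9 for w in stats])
            assert wilcoxon_signed_rank(x) == pytest.approx(p_exact, rel=1e-9)

    def test_exact_and_normal_regimes_agree_at_moderate_n(self, rng):
        x = rng.normal(0.3, 1.0, 24)
        exact_p = wilcoxon_signed_rank(x)
        import cge.stats as stats_mod
        old = stats_mod.WILCOXON_EXACT_MAX_N
        try:
            stats_mod.WILCOXON_EXACT_MAX_N = 1
            approx_p = wilcoxon_signed_rank(x)
        finally:
            stats_mod.WILCOXON_EXACT_MAX_N = old
        assert approx_p == pytest.approx(exact_p, rel=0.15)


class TestFitnessTest:
    def test_requires_records(self):
        with pytest.raises(ValueError):
            fitness_test([])

    def test_median_and_ci_cover_point_mass(self):
        recs = [record(t, -1.0) for t in enumerate_tags(REF, 2)[:12]]
        res = fitness_test(recs, ci=True)
        assert res.median_log2fc == -1.0
        assert res.ci_low <= -1.0 <= res.ci_high
        assert res.n_pairs == 12


class TestChipEnrichment:
    def test_equal_ratios_give_zero(self):
        tags = enumerate_tags(REF, 2)[:10]
        inp = table("input", {(v, t): 200 for t in tags for v in ("original", "mutant")})
        ip = table("ip", {(v, t): 150 for t in tags for v in ("original", "mutant")})
        recs, res = chip_enrichment(ip, inp, REF, min_input_count=100)
        assert len(recs) == 10
        assert all(r.log2fc == 0.0 for r in recs)

    def test_input_threshold_is_strict(self):
        tag = enumerate_tags(REF, 2)[0]
        inp = table("input", {("original", tag): 100, ("mutant", tag): 101})
        ip = table("ip", {("original", tag): 500, ("mutant", tag): 500})
        with pytest.raises(ValueError):  # no record passes -> fitness_test refuses
            chip_enrichment(ip, inp, REF, min_input_count=100)

    def test_fourfold_binding_loss(self):
        tags = enumerate_tags(REF, 2)[:15]
        inp = table("input", {(v, t): 400 for t in tags for v in ("original", "mutant")})
        ip = table(
            "ip",
            {("original", t): 400 for t in tags} | {("mutant", t): 100 for t in tags},
        )
        _, res = chip_enrichment(ip, inp, REF, min_input_count=100)
        assert res.median_log2fc == pytest.approx(math.log2(101 / 401), abs=1e-12)
        assert res.p_value < 0.01


class TestBinning:
    def test_parity_binning_by_first_mutated_position(self):
        t_pos3 = list(REF)
        t_pos3[2] = "A" if REF[2] != "A" else "C"  # 1-based position 3 -> odd
        t_pos2_9 = list(REF)
        t_pos2_9[1] = "A" if REF[1] != "A" else "C"  # first mutation at position 2
        t_pos2_9[8] = "A" if REF[8] != "A" else "C"
        recs = [
            record("".join(t_pos3), -1.0, n_mut=1),
            record("".join(t_pos2_9), -0.5, n_mut=2),
        ]
        groups = bin_internal_replicates(recs, "first_position_parity")
        assert [r.log2fc for r in groups["odd"]] == [-1.0]
        assert [r.log2fc for r in groups["even"]] == [-0.5]

    def test_zero_mutation_tags_unassignable_with_warning(self):
        recs = [record(REF, 0.2, n_mut=0), record(enumerate_tags(REF, 1)[0], -0.1, n_mut=1)]
        with pytest.warns(UserWarning, match="parity"):
            groups = bin_internal_replicates(recs, "first_position_parity")
        assert sum(len(v) for v in groups.values()) == 1

    def test_first_random_base_binning(self):
        tags = ["AACGTACGTA", "CACGTACGTA", "GACGTACGTA", "TACGTACGTA"]
        recs = [record(t, 0.1) for t in tags]
        groups = bin_internal_replicates(recs, "first_random_base", designated_position=0)
        assert sorted(groups) == ["A", "C", "G", "T"]

    def test_null_data_group_medians_agree(self, rng):
        tags = enumerate_tags(REF, 2)
        vals = rng.normal(0, 0.5, len(tags))
        recs = [record(t, v) for t, v in zip(tags, vals)]
        res = internal_replicate_fitness(recs, "first_position_parity")
        assert set(res) == {"odd", "even"}
        pooled_sd = np.std(vals)
        for r in res.values():
            assert abs(r.median_log2fc) < 3 * 1.2533 * pooled_sd / np.sqrt(r.n_pairs)


class TestReplicateCorrelation:
    def test_identical_records_correlate_perfectly(self, rng):
        tags = enumerate_tags(REF, 2)[:30]
        recs = [record(t, v) for t, v in zip(tags, rng.normal(0, 1, 30))]
        r, p, n = replicate_correlation(recs, recs)
        assert r == pytest.approx(1.0)
        assert n == 30 and p < 1e-6

    def test_anticorrelated_records(self, rng):
        tags = enumerate_tags(REF, 2)[:30]
        vals = rng.normal(0, 1, 30)
        a = [record(t, v) for t, v in zip(tags, vals)]
        b = [record(t, -v) for t, v in zip(tags, vals)]
        r, _, _ = replicate_correlation(a, b)
        assert r == pytest.approx(-1.0)

    def test_independent_noise_gives_near_zero_r(self, rng):
        tags = enumerate_tags(REF, 2)
        a = [record(t, v) for t, v in zip(tags, rng.normal(0, 1, len(tags)))]
        b = [record(t, v) for t, v in zip(tags, rng.normal(0, 1, len(tags)))]
        r, _, n = replicate_correlation(a, b)
        assert n == len(tags)
        assert abs(r) < 3 / np.sqrt(n - 3)  # Fisher-z null envelope

    def test_only_shared_tags_enter_the_correlation(self):
        tags = enumerate_tags(REF, 2)
        a = [record(t, v) for t, v in zip(tags[:6], [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])]
        b = [record(t, v) for t, v in zip(tags[2:9], [0.3, 0.4, 0.5, 0.6, 9.9, 9.9, 9.9])]
        r, _, n = replicate_correlation(a, b)
        assert n == 4  # tags[2:6] overlap
        assert r == pytest.approx(1.0)

    def test_too_few_shared_tags_rejected(self):
        a = [record(enumerate_tags(REF, 2)[0], 0.5)]
        b = [record(enumerate_tags(REF, 2)[1], 0.5)]
        with pytest.raises(ValueError, match="shared"):
            replicate_correlation(a, b)
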