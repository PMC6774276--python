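import numpy as np
import pytest

from exoeval.compare import (
    ConcordanceResult,
    NotNormalizedError,
    compare,
    fp_reduction,
    genotype_concordance,
    genotypes_from_records,
    metrics,
    refilter_min_af,
)
from exoeval.normalize import ReferenceSequence, VariantRecord, regularize
from exoeval.regions import RegionSet

from .oracles import brute_force_compare

BASES = "ACGT"


def v(pos, ref="A", alt="G", chrom="c", **kw):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


def everywhere(chrom="c", n=10_000):
    return RegionSet.from_tuples([(chrom, 0, n)])


class TestMetrics:
    @pytest.mark.parametrize(
        "tp,fn,fp,sens,ppv",
        [
            (45_946, 3_394, 8_405, 93.12, 84.54),
            (46_320, 2_476, 1_218, 94.93, 97.44),
            (43_929, 3_053, 11_005, 93.50, 79.97),
            (43_840, 1_252, 7_073, 97.22, 86.11),
            (2_106, 2_142, 1_330, 49.58, 61.29),
        ],
    )
    def test_validation_table_arithmetic(self, tp, fn, fp, sens, ppv):
        mp = metrics(tp, fn, fp)
        assert mp.sensitivity_pct == sens
        assert mp.ppv_pct == ppv

    def test_undefined_marked_not_zero(self):
        mp = metrics(0, 5, 0)
        assert mp.sensitivity_pct == 0.00 and mp.ppv is None
        assert metrics(0, 0, 3).sensitivity is None

    def test_half_up_rounding(self):
        # 0.93125 must round to 93.13, not bankers' 93.12
        assert metrics(14_900, 1_100, 0).sensitivity_pct == 93.13


class TestFpReduction:
    @pytest.mark.parametrize(
        "before,after,expected",
        [(8_581, 1_218, 85.8), (11_280, 947, 91.6), (7, 7, 0.0)],
    )
    def test_reduction_values(self, before, after, expected):
        assert fp_reduction(before, after) == expected

    def test_zero_baseline_undefined(self):
        with pytest.raises(ValueError):
            fp_reduction(0, 0)


class TestCompare:
    def test_partition_by_hand(self):
        v1, v2, v3 = v(5), v(9, "C", "T"), v(20, "G", "A")
        res = compare([v1, v2], [v1, v3], everywhere())
        assert (len(res.tp), len(res.fp), len(res.fn)) == (1, 1, 1)
        assert res.truth_size_in_region == 2

    def test_identity(self):
        recs = [v(5), v(9, "C", "T")]
        res = compare(recs, list(recs), everywhere())
        mp = res.metric_pair
        assert (len(res.fp), len(res.fn)) == (0, 0)
        assert (mp.sensitivity, mp.ppv) == (1.0, 1.0)

    def test_empty_region(self):
        res = compare([v(5)], [v(5)], RegionSet())
        assert res.truth_size_in_region == 0
        assert (len(res.tp), len(res.fp), len(res.fn)) == (0, 0, 0)

    def test_unnormalized_input_detected(self):
        with pytest.raises(NotNormalizedError, match="regularize"):
            compare([v(5, "AT", "GC")], [], everywhere())
        # explicit opt-out for raw-stage comparisons
        compare([v(5, "AT", "GC")], [], everywhere(), require_normalized=False)

    def test_n_alleles_never_match(self):
        res = compare([v(5, "A", "N")], [v(5, "A", "N")], everywhere())
        assert len(res.tp) == 0 and len(res.fp) == 1 and len(res.fn) == 1

    def test_genotype_aware_flag(self):
        q = [v(5, genotype=(0, 1))]
        t = [v(5, genotype=(1, 1))]
        assert len(compare(q, t, everywhere()).tp) == 1
        assert len(compare(q, t, everywhere(), genotype_aware=True).tp) == 0

    def test_symmetry_swaps_fp_and_fn(self):
        q = [v(5), v(9, "C", "T"), v(30, "T", "A")]
        t = [v(5), v(21, "G", "C")]
        a = compare(q, t, everywhere())
        b = compare(t, q, everywhere())
        assert [r.key for r in a.fp] == [r.key for r in b.fn]
        assert [r.key for r in a.fn] == [r.key for r in b.fp]

    def test_subset_region_monotonicity(self):
        q = [v(5), v(50, "C", "T"), v(500, "T", "A")]
        t = [v(5), v(500, "T", "A"), v(700, "G", "C")]
        full = compare(q, t, everywhere())
        sub = compare(q, t, RegionSet.from_tuples([("c", 0, 100)]))
        assert len(sub.fp) <= len(full.fp)
        assert sub.truth_size_in_region <= full.truth_size_in_region

    def test_exonic_strata_use_point_test(self):
        coding = RegionSet.from_tuples([("c", 0, 10)])
        q = [v(5), v(50, "C", "T")]
        res = compare(q, q, everywhere(), coding=coding)
        assert res.strata["exonic_snv"].tp == 1
        assert res.strata["snv"].tp == 2


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", range(50))
    def test_matches_haplotype_matcher(self, seed):
        """Comparison equals an independent matcher that groups records by
        the full mutated chromosome string, on regularized random sets."""
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(BASES), size=300))
        ref_obj = ReferenceSequence({"c": seq})

        def random_records(n):
            out = []
            for _ in range(n):
                pos = int(rng.integers(2, 280))
                r = rng.random()
                if r < 0.5:
                    ref_a = seq[pos - 1]
                    alt_a = str(rng.choice([b for b in BASES if b != ref_a]))
                elif r < 0.75:
                    ins = "".join(rng.choice(list(BASES), size=int(rng.integers(1, 3))))
                    ref_a, alt_a = seq[pos - 1], seq[pos - 1] + ins
                else:
                    dlen = int(rng.integers(1, 3))
                    ref_a, alt_a = seq[pos - 1 : pos + dlen], seq[pos - 1]
                out.append(v(pos, ref_a, alt_a))
            return regularize(out, ref_obj)

        query, truth = random_records(15), random_records(15)
        lo = int(rng.integers(0, 150))
        region = RegionSet.from_tuples([("c", lo, lo + int(rng.integers(50, 150)))])
        res = compare(query, truth, region)
        want = brute_force_compare(query, truth, region, {"c": seq})
        assert (len(res.tp), len(res.fn), len(res.fp)) == want
        # conservation invariants on every run
        assert len(res.tp) + len(res.fn) == res.truth_size_in_region
        assert len(res.tp) + len(res.fp) == res.query_size_in_region


class TestGenotypeConcordance:
    def test_identical_and_partial(self):
        seq_g, refs = genotypes_from_records(
            [v(i, "A", "G", genotype=(0, 1)) for i in range(1, 101)]
        )
        assert genotype_concordance(seq_g, dict(seq_g), refs).pct == 100.0
        arr = dict(seq_g)
        for i in range(1, 3):
            arr[("c", i)] = ("G", "G")
        assert genotype_concordance(seq_g, arr, refs).pct == 98.0

    def test_no_shared_sites_is_undefined(self):
        res = genotype_concordance({("c", 1): ("A", "G")}, {("c", 2): ("A", "G")})
        assert res.fraction is None and res.pct is None

    def test_hom_ref_sites_disregarded(self):
        refs = {("c", 1): "A", ("c", 2): "A"}
        seq_g = {("c", 1): ("A", "A"), ("c", 2): ("A", "G")}
        arr_g = {("c", 1): ("A", "A"), ("c", 2): ("A", "G")}
        res = genotype_concordance(seq_g, arr_g, refs)
        assert res.shared_sites == 1 and res.pct == 100.0


class TestRefilterMinAf:
    def test_boundary_inclusive(self):
        kept = refilter_min_af([v(5, af=0.19), v(9, "C", "T", af=0.2)], 0.2)
        assert [r.pos for r in kept] == [9]

    def test_zero_threshold_is_identity(self):
        recs = [v(5, af=0.01), v(9, "C", "T", af=0.9)]
        assert refilter_min_af(recs, 0.0) == recs

    def test_missing_af_kept_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="exoeval.compare"):
            kept = refilter_min_af([v(5)], 0.5)
        assert kept and "lack an AF annotation" in caplog.text

    def test_never_decreases_ppv_on_labeled_synthetic_set(self, sim_bundle):
        """Removing sub-threshold records (all FPs by construction) can
        only raise PPV."""
        _, _, _, truth, lib = sim_bundle
        query = lib.calls.query
        before = compare(query, truth.records, lib.target).metric_pair.ppv
        filtered = refilter_min_af(query, 0.2)
        removed = {r.key for r in query} - {r.key for r in filtered}
        assert removed and all(
            lib.calls.labels[k].startswith("FP") for k in removed
        )
        after = compare(filtered, truth.records, lib.target).metric_pair.ppv
        assert after >= before
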