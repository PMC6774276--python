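import numpy as np
import pytest

from exoeval.classify import classify_fn, classify_fp, homopolymer_length
from exoeval.compare import compare
from exoeval.coverage import threshold_fractions
from exoeval.reads import mark_duplicates
from exoeval.regions import GenomicInterval, RegionSet
from exoeval.simulate import (
    SimulationConfig,
    amplicon_config,
    capture_config,
    make_reference,
    make_truth,
    simulate_library,
    write_outputs,
)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(reference_length=500)
        with pytest.raises(ValueError):
            SimulationConfig(library="nanopore")
        with pytest.raises(ValueError):
            SimulationConfig(fp_counts={"bogus": 1})
        with pytest.raises(ValueError):
            SimulationConfig(fraction_in_hcr=1.2)

    def test_dict_roundtrip(self):
        cfg = amplicon_config(seed=9)
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg


class TestMakeReference:
    def test_no_features(self):
        cfg = SimulationConfig(seed=1, n_homopolymers=0, n_repeats=0)
        _, features = make_reference(cfg)
        assert features == []

    def test_planted_runs_verifiable_by_substring_inspection(self):
        cfg = SimulationConfig(seed=2, n_homopolymers=10,
                               homopolymer_length_range=(6, 6), n_repeats=0)
        reference, features = make_reference(cfg)
        runs = [f for f in features if f.kind == "homopolymer"]
        assert len(runs) == 10
        seq = reference[cfg.chrom]
        for f in runs:
            run = seq[f.start : f.end]
            assert len(run) == 6 and len(set(run)) == 1
            assert seq[f.start - 1] != run[0] and seq[f.end] != run[0]

    def test_determinism(self):
        cfg = SimulationConfig(seed=3)
        r1, f1 = make_reference(cfg)
        r2, f2 = make_reference(cfg)
        assert r1[cfg.chrom] == r2[cfg.chrom] and f1 == f2


class TestMakeTruth:
    def test_counts_by_class(self):
        cfg = SimulationConfig(seed=4, n_snv=80, n_indel=20)
        reference, features = make_reference(cfg)
        truth = make_truth(reference, cfg, features)
        assert len(truth.records) == 100
        assert sum(v.is_indel for v in truth.records) == 20

    def test_all_truth_inside_hcr_when_fraction_one(self):
        cfg = SimulationConfig(seed=5, fraction_in_hcr=1.0, n_snv=60, n_indel=15)
        reference, features = make_reference(cfg)
        truth = make_truth(reference, cfg, features)
        assert all(
            truth.hcr.contains_vcf_pos(v.chrom, v.pos) for v in truth.records
        )

    def test_hcr_excludes_difficult_regions(self, sim_bundle):
        _, _, _, truth, _ = sim_bundle
        assert not truth.hcr.intersect(truth.difficult)

    def test_configured_fraction_outside_hcr(self, sim_bundle):
        cfg, _, _, truth, _ = sim_bundle
        outside = sum(
            not truth.hcr.contains_vcf_pos(v.chrom, v.pos) for v in truth.records
        )
        expected = round((1 - cfg.fraction_in_hcr) * len(truth.records))
        assert abs(outside - expected) <= 2  # indel spans may straddle edges

    def test_targets_overlap(self, sim_bundle):
        _, _, _, truth, _ = sim_bundle
        otr = truth.overlap_target
        assert otr.total_bases > 0
        assert otr.total_bases < truth.target_amplicon.total_bases

    def test_infeasible_density_rejected(self):
        cfg = SimulationConfig(seed=6, reference_length=1000, n_snv=500, n_indel=0,
                               n_homopolymers=0, n_repeats=0)
        reference, features = make_reference(cfg)
        with pytest.raises(ValueError, match="infeasible"):
            make_truth(reference, cfg, features)


class TestSimulateLibrary:
    def test_clean_run_has_no_errors(self):
        cfg = SimulationConfig(seed=7, n_snv=60, n_indel=15, fraction_in_hcr=1.0,
                               fp_counts={}, fn_counts={}, make_reads=False)
        reference, features = make_reference(cfg)
        truth = make_truth(reference, cfg, features)
        lib = simulate_library(reference, truth, cfg)
        everywhere = RegionSet([GenomicInterval(cfg.chrom, 0, cfg.reference_length)])
        res = compare(lib.calls.query, truth.records, everywhere)
        assert (len(res.fp), len(res.fn)) == (0, 0)

    def test_labels_partition_query_and_dropped(self, sim_bundle):
        cfg, _, _, truth, lib = sim_bundle
        assert set(lib.calls.labels) == {v.key for v in lib.calls.query}
        dropped_keys = {v.key for v, _ in lib.calls.dropped}
        assert dropped_keys.isdisjoint(lib.calls.labels)
        assert dropped_keys | {
            v.key for v in lib.calls.query if lib.calls.labels[v.key] == "TP"
        } <= {v.key for v in truth.records}

    def test_configured_error_counts_realized(self, sim_bundle):
        cfg, _, _, _, lib = sim_bundle
        n_fp = sum(1 for l in lib.calls.labels.values() if l.startswith("FP"))
        assert abs(n_fp - sum(cfg.fp_counts.values())) <= 2  # rare key collisions
        assert len(lib.calls.dropped) == sum(cfg.fn_counts.values())

    def test_injected_fp_evidence_fires_intended_rule(self, sim_bundle):
        """Every injected FP classifies back to its injected category."""
        _, _, _, _, lib = sim_bundle
        checked = 0
        for v in lib.calls.query:
            label = lib.calls.labels[v.key]
            if label.startswith("FP:"):
                assert classify_fp(v, lib.calls.evidence[v.key]).value == label[3:]
                checked += 1
        assert checked >= 50

    def test_dropped_fn_evidence_fires_intended_cause(self, sim_bundle):
        _, _, _, _, lib = sim_bundle
        for v, label in lib.calls.dropped:
            cause = classify_fn(v, lib.calls.evidence[v.key])
            want = label[3:]
            flags = set(cause.library_flags) | set(cause.sequencer_flags)
            if want == "both":
                assert cause.top.value == "both"
            elif want == "unknown":
                assert cause.top.value == "unknown"
            else:
                assert flags == {want}

    def test_determinism_of_simulation(self):
        cfg = capture_config(seed=8, mean_depth=30.0)
        reference, features = make_reference(cfg)
        truth = make_truth(reference, cfg, features)
        a = simulate_library(reference, truth, cfg)
        b = simulate_library(reference, truth, cfg)
        assert [r.read_id for r in a.reads] == [r.read_id for r in b.reads]
        assert [v.key for v in a.calls.query] == [v.key for v in b.calls.query]

    def test_byte_identical_outputs(self, tmp_path):
        cfg = amplicon_config(seed=9, mean_depth=30.0, reference_length=40_000,
                              n_snv=120, n_indel=30)
        for d in ("a", "b"):
            reference, features = make_reference(cfg)
            truth = make_truth(reference, cfg, features)
            lib = simulate_library(reference, truth, cfg)
            write_outputs(tmp_path / d, reference, truth, lib, cfg)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name


class TestLibraryContrasts:
    @pytest.mark.parametrize("seed", [21, 22])
    def test_capture_callable_fraction_exceeds_amplicon(self, seed):
        """At equal mean depth the capture profile keeps more bases in the
        callable range and fewer below 10X, despite the amplicon library's
        heavier tail."""
        acfg = amplicon_config(seed=seed, mean_depth=100.0)
        ccfg = capture_config(seed=seed, mean_depth=100.0)
        reference, features = make_reference(acfg)
        truth = make_truth(reference, acfg, features)
        alib = simulate_library(reference, truth, acfg)
        clib = simulate_library(reference, truth, ccfg)
        fa = threshold_fractions(alib.depth_track)
        fc = threshold_fractions(clib.depth_track)
        assert fc.callable_ >= fa.callable_
        assert (clib.depth_track.depths < 10).mean() <= (
            alib.depth_track.depths < 10
        ).mean()

    def test_dedup_contrast(self, sim_bundle):
        """Amplicon reads share 5' primer positions, so start-only keying is
        catastrophic while start+end keying loses roughly the configured
        PCR-duplicate rate (a small trim-space saturation excess allowed)."""
        cfg, reference, features, truth, lib = sim_bundle
        se = mark_duplicates(lib.reads, "start_end")
        so = mark_duplicates(lib.reads, "start_only")
        assert so.loss_fraction > 0.8
        assert abs(se.loss_fraction - cfg.duplicate_rate) <= 0.06

        ccfg = capture_config(seed=cfg.seed, mean_depth=60.0)
        clib = simulate_library(reference, truth, ccfg)
        cse = mark_duplicates(clib.reads, "start_end")
        cso = mark_duplicates(clib.reads, "start_only")
        assert cse.loss_fraction < 0.01
        assert cso.loss_fraction < so.loss_fraction  # capture far less affected
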