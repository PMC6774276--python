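import numpy as np
import pytest

from exoeval.normalize import (
    NormalizeError,
    ReferenceSequence,
    VariantClass,
    VariantRecord,
    apply_variant,
    apply_variants,
    decompose_primitives,
    is_parsimonious,
    left_align,
    regularize,
    split_multiallelic,
)

from .oracles import minimal_representation

BASES = "ACGT"


def v(chrom, pos, ref, alt, **kw):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


class TestVariantRecord:
    def test_classification(self):
        assert v("c", 3, "T", "G").variant_class is VariantClass.SNV
        assert v("c", 3, "A", "AG").variant_class is VariantClass.INSERTION
        assert v("c", 3, "AG", "A").variant_class is VariantClass.DELETION
        assert v("c", 3, "AT", "GC").variant_class is VariantClass.MNV
        assert v("c", 3, "ATG", "GTGC").variant_class is VariantClass.COMPLEX

    @pytest.mark.parametrize(
        "kw",
        [
            dict(pos=0, ref="A", alt="G"),
            dict(pos=3, ref="A", alt="A"),
            dict(pos=3, ref="", alt="G"),
            dict(pos=3, ref="A", alt="Z"),
            dict(pos=3, ref="A", alt="G", af=1.5),
        ],
    )
    def test_invalid_records_rejected(self, kw):
        with pytest.raises(NormalizeError):
            VariantRecord(chrom="c", **kw)


class TestSplitMultiallelic:
    def test_two_alternates_het(self):
        out = split_multiallelic("chr1", 10, "A", ["G", "T"], genotype=(1, 2))
        assert [(r.alt, r.genotype) for r in out] == [("G", (1, 0)), ("T", (0, 1))]
        assert all(r.orig_gt == "1/2" for r in out)

    def test_biallelic_passthrough_and_count(self):
        assert len(split_multiallelic("chr1", 10, "A", ["G"])) == 1
        assert len(split_multiallelic("chr1", 10, "A", ["G", "T", "C"])) == 3

    def test_alt_equal_ref_rejected(self):
        with pytest.raises(NormalizeError):
            split_multiallelic("chr1", 10, "A", ["A"])


class TestDecompose:
    def test_mnv_becomes_snvs(self, toy_reference):
        ref = ReferenceSequence({"c": "ACGATGCA"})
        out = decompose_primitives(v("c", 5, "TG", "GC"), ref)
        assert [(p.pos, p.ref, p.alt) for p in out] == [(5, "T", "G"), (6, "G", "C")]
        assert len({p.phase_set for p in out}) == 1

    def test_snv_and_pure_indels_pass_through(self):
        ref = ReferenceSequence({"c": "ACGTACGT"})
        for rec in (v("c", 3, "G", "T"), v("c", 3, "G", "GAA"), v("c", 3, "GTA", "G")):
            assert decompose_primitives(rec, ref) == [rec]

    def test_complex_allele_split(self):
        ref = ReferenceSequence({"c": "ACGTCGATGAA"})
        out = decompose_primitives(v("c", 7, "ATG", "GTGC"), ref)
        assert [(p.pos, p.ref, p.alt) for p in out] == [(7, "A", "G"), (9, "G", "GC")]

    def test_ref_mismatch_raises(self):
        ref = ReferenceSequence({"c": "AAAA"})
        with pytest.raises(NormalizeError, match="REF mismatch"):
            decompose_primitives(v("c", 2, "CG", "TT"), ref)

    @pytest.mark.parametrize("seed", range(40))
    def test_haplotype_equivalence_on_random_complex_alleles(self, seed):
        """Primitives reconstruct exactly the input's alternate haplotype."""
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(BASES), size=80))
        ref_obj = ReferenceSequence({"c": seq})
        pos = int(rng.integers(2, 60))
        ref_len = int(rng.integers(1, 7))
        ref_a = seq[pos - 1 : pos - 1 + ref_len]
        alt_a = "".join(rng.choice(list(BASES), size=int(rng.integers(1, 7))))
        if ref_a == alt_a:
            return
        rec = v("c", pos, ref_a, alt_a)
        prims = decompose_primitives(rec, ref_obj)
        assert apply_variants(seq, prims) == apply_variant(seq, pos, ref_a, alt_a)


class TestLeftAlign:
    def test_spec_deletion_in_homopolymer(self):
        ref = ReferenceSequence({"chr1": "ATTTTC"})
        out = left_align(v("chr1", 4, "TT", "T"), ref)
        assert (out.pos, out.ref, out.alt) == (1, "AT", "A")

    def test_snv_unchanged(self):
        ref = ReferenceSequence({"chr1": "ATTTTC"})
        rec = v("chr1", 3, "T", "G")
        assert left_align(rec, ref) is rec

    def test_non_parsimonious_deletion(self):
        ref = ReferenceSequence({"chr1": "ATTTTC"})
        out = left_align(v("chr1", 2, "TTT", "TT"), ref)
        assert (out.pos, out.ref, out.alt) == (1, "AT", "A")

    def test_ref_mismatch_raises(self):
        ref = ReferenceSequence({"chr1": "ATTTTC"})
        with pytest.raises(NormalizeError):
            left_align(v("chr1", 2, "GG", "G"), ref)

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_exhaustive_search_oracle(self, seed):
        """Left alignment equals the minimal-leftmost representation found
        by exhaustively enumerating haplotype-equivalent candidates."""
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(BASES), size=200, p=[0.4, 0.1, 0.1, 0.4]))
        ref_obj = ReferenceSequence({"c": seq})
        pos = int(rng.integers(2, 180))
        if rng.random() < 0.5:
            ins = "".join(rng.choice(list(BASES), size=int(rng.integers(1, 4))))
            rec = v("c", pos, seq[pos - 1], seq[pos - 1] + ins)
        else:
            dlen = int(rng.integers(1, 4))
            rec = v("c", pos, seq[pos - 1 : pos + dlen], seq[pos - 1])
        got = left_align(rec, ref_obj)
        want = minimal_representation(seq, rec.pos, rec.ref, rec.alt)
        assert (got.pos, got.ref, got.alt) == want
        # idempotence, monotone position, parsimony
        assert left_align(got, ref_obj) == got
        assert got.pos <= rec.pos
        assert is_parsimonious(got)


class TestRegularize:
    def test_empty_stream(self, toy_reference):
        assert regularize([], toy_reference) == []

    def test_mnv_count_increases(self):
        ref = ReferenceSequence({"c": "ACGATGCA"})
        out = regularize([v("c", 5, "TG", "GC")], ref)
        assert len(out) == 2 and all(p.variant_class is VariantClass.SNV for p in out)

    def test_idempotent_on_normalized_stream(self):
        ref = ReferenceSequence({"c": "ACGTTTTACGT"})
        recs = [v("c", 2, "C", "T"), v("c", 4, "TT", "T"), v("c", 9, "C", "A")]
        once = regularize(recs, ref)
        assert regularize(once, ref) == once

    def test_duplicates_collapsed_keeping_max_qual(self):
        ref = ReferenceSequence({"c": "ACGT"})
        out = regularize([v("c", 2, "C", "T", qual=10.0), v("c", 2, "C", "T", qual=55.0)], ref)
        assert len(out) == 1 and out[0].qual == 55.0

    def test_equivalent_indels_collapse_after_alignment(self):
        ref = ReferenceSequence({"c": "ATTTTC"})
        out = regularize([v("c", 4, "TT", "T"), v("c", 2, "TT", "T")], ref)
        assert len(out) == 1
        assert (out[0].pos, out[0].ref, out[0].alt) == (1, "AT", "A")


class TestBcftoolsOracle:
    def test_left_align_agrees_with_bcftools_norm(self, tmp_path):
        """Independent cross-check of the normalizer against bcftools norm."""
        import subprocess

        from exoeval.vcfio import read_vcf, write_vcf

        rng = np.random.default_rng(123)
        seq = "".join(rng.choice(list(BASES), size=500, p=[0.35, 0.15, 0.15, 0.35]))
        ref_obj = ReferenceSequence({"c": seq})
        records = []
        for _ in range(40):
            pos = int(rng.integers(2, 450))
            if rng.random() < 0.5:
                ins = "".join(rng.choice(list(BASES), size=int(rng.integers(1, 4))))
                rec = v("c", pos, seq[pos - 1], seq[pos - 1] + ins, qual=50.0)
            else:
                dlen = int(rng.integers(1, 4))
                rec = v("c", pos, seq[pos - 1 : pos + dlen], seq[pos - 1], qual=50.0)
            records.append(rec)

        fasta = tmp_path / "ref.fa"
        ref_obj.to_fasta(fasta)
        vcf_in = tmp_path / "in.vcf"
        write_vcf(records, ref_obj.lengths(), vcf_in)
        vcf_out = tmp_path / "out.vcf"
        subprocess.run(["samtools", "faidx", str(fasta)], check=True)
        subprocess.run(
            ["bcftools", "norm", "-f", str(fasta), "-o", str(vcf_out), str(vcf_in)],
            check=True,
            capture_output=True,
        )
        # regularize deduplicates equivalent records; bcftools norm does not
        expected = sorted({r.key for r in read_vcf(vcf_out).records})
        got = sorted({r.key for r in regularize(records, ref_obj)})
        assert got == expected
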