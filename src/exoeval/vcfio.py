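"""VCF reading and writing (pysam-backed).

Reading splits multi-allelic records into biallelic :class:`VariantRecord`s
immediately — every downstream operation works per alternate allele.
Symbolic alleles (``<DEL>``, breakends) and alternates equal to the
reference are not representable and are skipped with a warning count.

Writing emits VCF v4.2 with one sample column (``GT``), an ``AF`` INFO
field, and a ``PS`` INFO field carrying the phase-set identifier that links
primitives decomposed from a single source record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pysam

from .normalize import NormalizeError, VariantRecord, split_multiallelic

logger = logging.getLogger(__name__)

__all__ = ["read_vcf", "write_vcf", "VcfReadResult"]


@dataclass
class VcfReadResult:
    records: List[VariantRecord]
    n_skipped_symbolic: int = 0
    n_skipped_invalid: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _is_symbolic(alt: Optional[str]) -> bool:
    return alt is None or any(c in alt for c in "<>[]*.")


def read_vcf(path) -> VcfReadResult:
    """Read a VCF (plain or bgzip) into biallelic records.

    Multi-allelic records are split; the per-alternate genotype rewrite and
    the retained original genotype follow :func:`split_multiallelic`.
    """
    records: List[VariantRecord] = []
    n_symbolic = 0
    n_invalid = 0
    with pysam.VariantFile(str(path)) as vf:
        has_sample = len(vf.header.samples) > 0
        for rec in vf:
            alts = rec.alts or ()
            keep_alts = []
            for alt in alts:
                if _is_symbolic(alt):
                    n_symbolic += 1
                else:
                    keep_alts.append(alt.upper())
            if not keep_alts:
                continue
            genotype = None
            phased = False
            if has_sample:
                sample = rec.samples[0]
                gt = sample.get("GT")
                if gt is not None and all(a is not None for a in gt):
                    genotype = tuple(gt)
                    phased = bool(getattr(sample, "phased", False))
            af = rec.info.get("AF") if "AF" in rec.info else None
            if af is not None and not isinstance(af, (tuple, list)):
                af = (af,)
            filt = ";".join(rec.filter.keys()) or "PASS"
            try:
                split = split_multiallelic(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref.upper(),
                    alts=keep_alts,
                    genotype=genotype,
                    phased=phased,
                    qual=rec.qual,
                    filter=filt,
                    af=af,
                )
            except NormalizeError as exc:
                logger.warning("skipping invalid record: %s", exc)
                n_invalid += 1
                continue
            records.extend(split)
    if n_symbolic:
        logger.warning("skipped %d symbolic alternate allele(s)", n_symbolic)
    return VcfReadResult(records, n_symbolic, n_invalid)


def _build_header(contig_lengths: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.add_line(
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele fraction">'
    )
    header.add_line(
        '##INFO=<ID=PS,Number=1,Type=Integer,Description='
        '"Phase set linking primitives from one source record">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample("SAMPLE")
    return header


def write_vcf(
    records: Sequence[VariantRecord],
    contig_lengths: Mapping[str, int],
    path,
) -> None:
    """Write biallelic records as a sorted single-sample VCF v4.2 file."""
    header = _build_header(contig_lengths)
    ordered = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in ordered:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                alleles=(v.ref, v.alt),
                qual=v.qual,
            )
            if v.filter and v.filter != "PASS":
                rec.filter.add(v.filter)
            else:
                rec.filter.add("PASS")
            if v.af is not None:
                rec.info["AF"] = (v.af,)
            if v.phase_set is not None:
                rec.info["PS"] = v.phase_set
            gt = v.genotype if v.genotype is not None else (None, None)
            rec.samples["SAMPLE"]["GT"] = gt
            rec.samples["SAMPLE"].phased = v.phased
            out.write(rec)
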