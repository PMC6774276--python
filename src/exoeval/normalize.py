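"""Variant regularization: multi-allelic splitting, primitive decomposition,
and left-align/parsimony normalization.

Variant callers and aligners represent the same alternate haplotype in many
ways (multi-allelic records, multi-nucleotide variants, complex alleles,
right-shifted indels).  Benchmarking a call set against a truth set by exact
(chrom, pos, ref, alt) matching therefore requires both sets to be rewritten
into a canonical minimal form first.  This module provides that rewriting:

* :func:`split_multiallelic` — one record per alternate allele;
* :func:`decompose_primitives` — MNVs/complex alleles become SNV and simple
  indel primitives that jointly reconstruct the same alternate haplotype;
* :func:`left_align` — the leftmost, most parsimonious representation of an
  SNV or pure indel against the reference;
* :func:`regularize` — the full pipeline, sorted and deduplicated.

The haplotype-equivalence contract: substituting the output primitives into
the reference yields exactly the string obtained by substituting the input
allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

logger = logging.getLogger(__name__)

__all__ = [
    "VariantClass",
    "VariantRecord",
    "ReferenceSequence",
    "NormalizeError",
    "split_multiallelic",
    "decompose_primitives",
    "left_align",
    "regularize",
    "apply_variant",
    "is_parsimonious",
]

_VALID_BASES = frozenset("ACGTN")


class NormalizeError(ValueError):
    """A variant is inconsistent with the reference or otherwise invalid."""


class VariantClass(str, Enum):
    SNV = "snv"
    INSERTION = "insertion"
    DELETION = "deletion"
    MNV = "mnv"
    COMPLEX = "complex"


@dataclass(frozen=True)
class VariantRecord:
    """One alternate allele at one site.

    ``pos`` is the 1-based position of the first reference base.  ``genotype``
    is a pair of allele indices (0 = reference, 1 = this alternate) with a
    phase flag; after multi-allelic splitting the original genotype string is
    retained in ``orig_gt``.  ``phase_set`` links primitives decomposed from
    one source record.  ``af`` is the alternate-allele fraction when known.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: Optional[Tuple[int, int]] = None
    phased: bool = False
    qual: Optional[float] = None
    filter: str = "PASS"
    af: Optional[float] = None
    phase_set: Optional[int] = None
    orig_gt: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise NormalizeError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise NormalizeError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise NormalizeError(
                f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}"
            )
        for allele in (self.ref, self.alt):
            if not set(allele) <= _VALID_BASES:
                raise NormalizeError(
                    f"allele {allele!r} at {self.chrom}:{self.pos} contains "
                    "characters outside A,C,G,T,N"
                )
        if self.af is not None and not (0.0 <= self.af <= 1.0):
            raise NormalizeError(f"allele fraction {self.af} outside [0, 1]")
        if self.qual is not None and self.qual < 0:
            raise NormalizeError(f"negative quality {self.qual}")

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference span."""
        return self.pos + len(self.ref) - 1

    @property
    def variant_class(self) -> VariantClass:
        ref, alt = self.ref, self.alt
        if len(ref) == 1 and len(alt) == 1:
            return VariantClass.SNV
        if len(ref) == len(alt):
            return VariantClass.MNV
        if len(ref) < len(alt) and alt.startswith(ref):
            return VariantClass.INSERTION
        if len(alt) < len(ref) and ref.startswith(alt):
            return VariantClass.DELETION
        return VariantClass.COMPLEX

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


class ReferenceSequence:
    """In-memory reference genome: chromosome name -> uppercase sequence."""

    def __init__(self, sequences: Mapping[str, str]) -> None:
        self._seqs: Dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            if not set(seq) <= _VALID_BASES:
                bad = sorted(set(seq) - _VALID_BASES)
                raise ValueError(f"contig {name}: invalid bases {bad}")
            self._seqs[name] = seq

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def chromosomes(self) -> List[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        """Subsequence ``[start0, end0)`` in 0-based coordinates."""
        return self._seqs[chrom][start0:end0]

    @classmethod
    def from_fasta(cls, path) -> "ReferenceSequence":
        from Bio import SeqIO

        seqs = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(seqs)

    def to_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def _check_against_reference(v: VariantRecord, reference: ReferenceSequence) -> None:
    if v.chrom not in reference:
        raise NormalizeError(f"unknown contig {v.chrom}")
    expected = reference.fetch(v.chrom, v.pos - 1, v.pos - 1 + len(v.ref))
    if expected != v.ref:
        raise NormalizeError(
            f"REF mismatch at {v.chrom}:{v.pos}: record has {v.ref!r}, "
            f"reference has {expected!r}"
        )


def apply_variant(sequence: str, pos: int, ref: str, alt: str) -> str:
    """Substitute ``ref``->``alt`` at 1-based ``pos`` into ``sequence``.

    Utility for haplotype-equivalence checks; raises if ``ref`` does not
    match the sequence at ``pos``.
    """
    i = pos - 1
    if sequence[i : i + len(ref)] != ref:
        raise NormalizeError(f"ref {ref!r} does not match sequence at pos {pos}")
    return sequence[:i] + alt + sequence[i + len(ref) :]


def apply_variants(sequence: str, variants: Sequence[VariantRecord]) -> str:
    """Apply span-disjoint variants to a chromosome sequence.

    Applied right to left so earlier coordinates stay valid; when an indel
    and an SNV share their anchor position (as primitives decomposed from
    one complex allele may), the indel is applied first.
    """
    out = sequence
    ordered = sorted(variants, key=lambda r: (-r.pos, 0 if r.is_indel else 1))
    for v in ordered:
        out = apply_variant(out, v.pos, v.ref, v.alt)
    return out


# ---------------------------------------------------------------------------
# multi-allelic splitting


def split_multiallelic(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    genotype: Optional[Tuple[int, ...]] = None,
    phased: bool = False,
    qual: Optional[float] = None,
    filter: str = "PASS",
    af: Optional[Sequence[Optional[float]]] = None,
) -> List[VariantRecord]:
    """Split a raw VCF record with ``k`` alternates into ``k`` biallelic records.

    The genotype is rewritten per alternate: allele indices equal to that
    alternate map to 1, every other index to 0 (reference) for matching
    purposes; the original multi-allelic genotype is kept in ``orig_gt``.
    An alternate equal to the reference allele is rejected.
    """
    if not alts:
        raise NormalizeError(f"record at {chrom}:{pos} has no alternate allele")
    orig_gt = None
    if genotype is not None:
        sep = "|" if phased else "/"
        orig_gt = sep.join(str(a) for a in genotype)
    out: List[VariantRecord] = []
    for j, alt in enumerate(alts, start=1):
        gt: Optional[Tuple[int, int]] = None
        if genotype is not None and len(genotype) == 2:
            gt = tuple(1 if a == j else 0 for a in genotype)  # type: ignore[assignment]
        a = af[j - 1] if af is not None and j - 1 < len(af) else None
        out.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                genotype=gt,
                phased=phased,
                qual=qual,
                filter=filter,
                af=a,
                orig_gt=orig_gt,
            )
        )
    return out


# ---------------------------------------------------------------------------
# primitive decomposition

# Global alignment scoring for complex alleles.  Fixed so that outputs are
# reproducible; ties are broken toward leftmost gap placement.
_MATCH, _MISMATCH, _GAP = 1, -1, -2


def _align(ref: str, alt: str) -> List[Tuple[Optional[int], Optional[int]]]:
    """Needleman-Wunsch alignment of ref vs alt.

    Returns aligned column pairs of (ref index, alt index), None marking a
    gap.  Traceback preference (diagonal, then gap-in-alt, then gap-in-ref)
    combined with forward DP yields a deterministic, leftmost-gap layout.
    """
    n, m = len(ref), len(alt)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * _GAP
    for j in range(1, m + 1):
        score[0][j] = j * _GAP
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = score[i - 1][j - 1] + (_MATCH if ref[i - 1] == alt[j - 1] else _MISMATCH)
            u = score[i - 1][j] + _GAP
            l = score[i][j - 1] + _GAP
            score[i][j] = max(d, u, l)
    cols: List[Tuple[Optional[int], Optional[int]]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i][j] == score[i - 1][j - 1] + (
            _MATCH if ref[i - 1] == alt[j - 1] else _MISMATCH
        ):
            cols.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and score[i][j] == score[i - 1][j] + _GAP:
            cols.append((i - 1, None))
            i -= 1
        else:
            cols.append((None, j - 1))
            j -= 1
    cols.reverse()
    return cols


def decompose_primitives(
    v: VariantRecord, reference: ReferenceSequence
) -> List[VariantRecord]:
    """Decompose an MNV or complex allele into SNV and simple-indel primitives.

    SNVs and pure indels pass through unchanged.  An MNV becomes one SNV per
    mismatching position.  Complex alleles are split by global alignment of
    ref vs alt; indel runs are anchored VCF-style on the preceding reference
    base (or the following base when the variant starts at position 1).
    Output primitives carry a shared ``phase_set`` and jointly reconstruct
    the same alternate haplotype as the input.
    """
    _check_against_reference(v, reference)
    vclass = v.variant_class
    if vclass in (VariantClass.SNV, VariantClass.INSERTION, VariantClass.DELETION):
        return [v]

    ps = v.phase_set if v.phase_set is not None else v.pos
    base = dict(
        chrom=v.chrom,
        genotype=v.genotype,
        phased=v.phased,
        qual=v.qual,
        filter=v.filter,
        af=v.af,
        phase_set=ps,
        orig_gt=v.orig_gt,
    )

    if vclass is VariantClass.MNV:
        prims = [
            VariantRecord(pos=v.pos + i, ref=r, alt=a, **base)
            for i, (r, a) in enumerate(zip(v.ref, v.alt))
            if r != a
        ]
        return prims

    # complex allele: walk the alignment, emitting SNVs at mismatched columns
    # and anchored indels at gap runs
    cols = _align(v.ref, v.alt)
    prims: List[VariantRecord] = []
    k = 0
    while k < len(cols):
        ri, ai = cols[k]
        if ri is not None and ai is not None:
            if v.ref[ri] != v.alt[ai]:
                prims.append(
                    VariantRecord(pos=v.pos + ri, ref=v.ref[ri], alt=v.alt[ai], **base)
                )
            k += 1
            continue
        # gap run: collect consecutive columns gapped on the same side
        run_ref = []
        run_alt = []
        start_ri = ri
        while k < len(cols) and (cols[k][0] is None or cols[k][1] is None):
            cri, cai = cols[k]
            if cri is not None:
                run_ref.append(v.ref[cri])
            if cai is not None:
                run_alt.append(v.alt[cai])
            k += 1
        # anchor: last reference index consumed before this run
        anchor_ref_idx = None
        for back in range(k - len(run_ref) - len(run_alt) - 1, -1, -1):
            if cols[back][0] is not None:
                anchor_ref_idx = cols[back][0]
                break
        ins = "".join(run_alt)
        dele = "".join(run_ref)
        if anchor_ref_idx is not None:
            anchor_pos = v.pos + anchor_ref_idx
            anchor_base = v.ref[anchor_ref_idx]
            prims.append(
                VariantRecord(
                    pos=anchor_pos,
                    ref=anchor_base + dele,
                    alt=anchor_base + ins,
                    **base,
                )
            )
        else:
            # run begins at the first column; anchor left on the genome when
            # possible, otherwise right-anchor on the following reference base
            if v.pos > 1:
                anchor_pos = v.pos - 1
                anchor_base = reference.fetch(v.chrom, anchor_pos - 1, anchor_pos)
                prims.append(
                    VariantRecord(
                        pos=anchor_pos,
                        ref=anchor_base + dele,
                        alt=anchor_base + ins,
                        **base,
                    )
                )
            else:
                run_len_ref = len(dele)
                nxt = reference.fetch(v.chrom, run_len_ref, run_len_ref + 1)
                prims.append(
                    VariantRecord(pos=1, ref=dele + nxt, alt=ins + nxt, **base)
                )
    # drop accidental no-ops (possible when alignment pairs identical runs)
    return [p for p in prims if p.ref != p.alt]


# ---------------------------------------------------------------------------
# left alignment


def left_align(v: VariantRecord, reference: ReferenceSequence) -> VariantRecord:
    """Leftmost, most parsimonious representation of an SNV or pure indel.

    Iteratively (a) truncates equal trailing bases, left-extending with the
    preceding reference base whenever an allele would become empty, and
    (b) trims equal leading bases while both alleles have length >= 2.
    Idempotent; never increases ``pos``.  A variant whose REF disagrees with
    the reference raises :class:`NormalizeError`.
    """
    _check_against_reference(v, reference)
    seq = reference[v.chrom]
    pos, ref, alt = v.pos, v.ref, v.alt
    while True:
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if (len(ref) == 1 or len(alt) == 1) and pos == 1:
                break  # cannot extend past the contig start
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                pos -= 1
                b = seq[pos - 1]
                ref, alt = b + ref, b + alt
        elif len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        else:
            break
    if (pos, ref, alt) == (v.pos, v.ref, v.alt):
        return v
    return replace(v, pos=pos, ref=ref, alt=alt)


def is_parsimonious(v: VariantRecord) -> bool:
    """Parsimony condition satisfied by fully normalized records.

    Either both alleles have length 1 (an SNV), or the first bases agree,
    the last bases differ, and the shorter allele has length 1 (a minimal
    left-anchored indel).  At the contig start (pos 1) an indel cannot be
    left-extended, so equal trailing bases are tolerated there.
    """
    ref, alt = v.ref, v.alt
    if len(ref) == 1 and len(alt) == 1:
        return True
    if ref[0] != alt[0] or min(len(ref), len(alt)) != 1:
        return False
    return ref[-1] != alt[-1] or v.pos == 1


# ---------------------------------------------------------------------------
# full regularization


def regularize(
    records: Iterable[VariantRecord],
    reference: ReferenceSequence,
) -> List[VariantRecord]:
    """Normalize a stream of (already biallelic) records.

    Pipeline: primitive decomposition -> left alignment -> sort by
    (chrom, pos, ref, alt) -> collapse exact duplicates keeping the highest
    quality.  Output length may exceed input length because MNVs and complex
    alleles expand into primitives.  Idempotent.
    """
    normalized: List[VariantRecord] = []
    for rec in records:
        try:
            for prim in decompose_primitives(rec, reference):
                normalized.append(left_align(prim, reference))
        except NormalizeError as exc:
            raise NormalizeError(
                f"while regularizing {rec.chrom}:{rec.pos} {rec.ref}>{rec.alt}: {exc}"
            ) from exc
    normalized.sort(key=lambda r: r.key)
    out: List[VariantRecord] = []
    for rec in normalized:
        if out and out[-1].key == rec.key:
            prev = out[-1]
            pq = prev.qual if prev.qual is not None else float("-inf")
            rq = rec.qual if rec.qual is not None else float("-inf")
            if rq > pq:
                out[-1] = rec
        else:
            out.append(rec)
    return out
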