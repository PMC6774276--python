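"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — per-base bitmaps, exhaustive
enumeration, full-haplotype string comparison — and shares no code with the
implementation paths it checks.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from exoeval.normalize import VariantRecord
from exoeval.regions import GenomicInterval, RegionSet


# ---------------------------------------------------------------------------
# region arithmetic via per-base membership bitmaps


def bitmap(regions: RegionSet, chrom: str, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for iv in regions.intervals():
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask


def regions_from_bitmap(mask: np.ndarray, chrom: str) -> RegionSet:
    out = []
    start = None
    for i, bit in enumerate(mask):
        if bit and start is None:
            start = i
        elif not bit and start is not None:
            out.append(GenomicInterval(chrom, start, i))
            start = None
    if start is not None:
        out.append(GenomicInterval(chrom, start, len(mask)))
    return RegionSet(out)


# ---------------------------------------------------------------------------
# minimal leftmost variant representation by exhaustive search


def minimal_representation(
    sequence: str, pos: int, ref: str, alt: str
) -> Tuple[int, str, str]:
    """Enumerate every (pos, ref, alt) with the same mutated haplotype and
    return the most parsimonious one, leftmost on ties.

    The mutated haplotype fixes a common prefix/suffix with the reference;
    only representations inside the disagreeing window (padded by the
    original allele span) can differ, which bounds the enumeration.
    """
    mutated = sequence[: pos - 1] + alt + sequence[pos - 1 + len(ref) :]
    # longest common prefix / suffix between sequence and mutated haplotype
    lcp = 0
    while (
        lcp < min(len(sequence), len(mutated)) and sequence[lcp] == mutated[lcp]
    ):
        lcp += 1
    lcs = 0
    while (
        lcs < min(len(sequence), len(mutated)) - 0
        and lcs < len(sequence)
        and sequence[len(sequence) - 1 - lcs] == mutated[len(mutated) - 1 - lcs]
    ):
        lcs += 1

    candidates: List[Tuple[int, int, int, str, str]] = []
    max_ref_len = len(ref) + len(alt) + 2
    for p in range(1, lcp + 2):  # representation must start inside the prefix+1
        for ref_len in range(1, max_ref_len + 1):
            if p - 1 + ref_len > len(sequence):
                continue
            cand_ref = sequence[p - 1 : p - 1 + ref_len]
            # alt is forced by requiring the same mutated haplotype
            alt_len = len(mutated) - (len(sequence) - ref_len)
            if alt_len < 1:
                continue
            cand_alt = mutated[p - 1 : p - 1 + alt_len]
            if cand_ref == cand_alt:
                continue
            trial = (
                sequence[: p - 1] + cand_alt + sequence[p - 1 + ref_len :]
            )
            if trial == mutated:
                candidates.append(
                    (len(cand_ref) + len(cand_alt), p, ref_len, cand_ref, cand_alt)
                )
    assert candidates, "no equivalent representation found"
    size, p, _, cand_ref, cand_alt = min(candidates, key=lambda c: (c[0], c[1]))
    return p, cand_ref, cand_alt


# ---------------------------------------------------------------------------
# brute-force truth comparison by single-variant haplotype equality


def brute_force_compare(
    query: Sequence[VariantRecord],
    truth: Sequence[VariantRecord],
    region: RegionSet,
    sequences: Dict[str, str],
) -> Tuple[int, int, int]:
    """(TP, FN, FP) counts by grouping records on their mutated haplotype.

    Two records are equivalent iff substituting them into the reference
    yields the same full chromosome string; each haplotype group
    contributes min(#query, #truth) true positives.
    """

    def hap(v: VariantRecord) -> Optional[Tuple[str, str]]:
        if not region.contains_vcf_pos(v.chrom, v.pos):
            return None
        if "N" in v.ref or "N" in v.alt:
            return ("N-sentinel", f"{id(v)}")  # N alleles never match
        seq = sequences[v.chrom]
        return (v.chrom, seq[: v.pos - 1] + v.alt + seq[v.pos - 1 + len(v.ref) :])

    q_groups = Counter(h for h in (hap(v) for v in query) if h is not None)
    t_groups = Counter(h for h in (hap(v) for v in truth) if h is not None)
    tp = sum(min(n, t_groups.get(h, 0)) for h, n in q_groups.items())
    fp = sum(q_groups.values()) - tp
    fn = sum(t_groups.values()) - tp
    return tp, fn, fp
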