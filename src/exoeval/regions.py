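"""Genomic interval sets and BED arithmetic.

Coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
A :class:`RegionSet` is always *canonical*: per chromosome the intervals are
sorted, non-overlapping and non-adjacent (touching intervals are merged, as
``bedtools merge`` does), so base-set semantics hold exactly:
``|A ∩ B| + |A − B| == |A|`` for any two sets.

VCF positions are 1-based; the only place the two conventions meet is
:meth:`RegionSet.contains_vcf_pos`, which tests ``start < pos <= end``.
Chromosome names are matched by exact string equality — no ``chr`` prefix
harmonization is attempted, so mismatched inputs fail loudly rather than
silently producing empty intersections of renamed contigs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Tuple

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "BedParseError",
    "DesignStats",
    "parse_bed",
    "write_bed",
    "design_stats",
]


class BedParseError(ValueError):
    """Raised for malformed BED input; the message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


_IvalList = List[Tuple[int, int]]


class RegionSet:
    """A canonical set of genomic intervals (sorted, merged per chromosome)."""

    __slots__ = ("_ivals",)

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        by_chrom: Dict[str, _IvalList] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._ivals: Dict[str, _IvalList] = {}
        for chrom in sorted(by_chrom):
            merged: _IvalList = []
            for start, end in sorted(by_chrom[chrom]):
                # merge overlapping *and* adjacent intervals
                if merged and start <= merged[-1][1]:
                    prev = merged[-1]
                    if end > prev[1]:
                        merged[-1] = (prev[0], end)
                else:
                    merged.append((start, end))
            self._ivals[chrom] = merged

    @classmethod
    def from_tuples(cls, tuples: Iterable[Tuple[str, int, int]]) -> "RegionSet":
        return cls(GenomicInterval(c, s, e) for c, s, e in tuples)

    # -- introspection -------------------------------------------------

    def chromosomes(self) -> List[str]:
        return [c for c in self._ivals if self._ivals[c]]

    def intervals(self) -> Iterator[GenomicInterval]:
        for chrom, ivals in self._ivals.items():
            for start, end in ivals:
                yield GenomicInterval(chrom, start, end)

    @property
    def total_bases(self) -> int:
        return sum(e - s for iv in self._ivals.values() for s, e in iv)

    def __bool__(self) -> bool:
        return any(self._ivals.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return {c: v for c, v in self._ivals.items() if v} == {
            c: v for c, v in other._ivals.items() if v
        }

    def __hash__(self) -> int:  # canonical form makes this well-defined
        return hash(tuple((c, tuple(v)) for c, v in sorted(self._ivals.items()) if v))

    def __repr__(self) -> str:
        n = sum(len(v) for v in self._ivals.values())
        return f"RegionSet({n} intervals, {self.total_bases} bases)"

    # -- membership ----------------------------------------------------

    def contains(self, chrom: str, pos0: int) -> bool:
        """True iff the 0-based position ``pos0`` lies inside the set."""
        import bisect

        ivals = self._ivals.get(chrom)
        if not ivals:
            return False
        i = bisect.bisect_right(ivals, (pos0, float("inf")))
        if i == 0:
            return False
        start, end = ivals[i - 1]
        return start <= pos0 < end

    def contains_vcf_pos(self, chrom: str, pos: int) -> bool:
        """Membership test for a 1-based VCF position (start < pos <= end)."""
        return self.contains(chrom, pos - 1)

    # -- set algebra ---------------------------------------------------

    def intersect(self, other: "RegionSet") -> "RegionSet":
        """Bases present in both sets."""
        out: List[GenomicInterval] = []
        for chrom in self._ivals:
            a, b = self._ivals[chrom], other._ivals.get(chrom, [])
            i = j = 0
            while i < len(a) and j < len(b):
                lo = max(a[i][0], b[j][0])
                hi = min(a[i][1], b[j][1])
                if lo < hi:
                    out.append(GenomicInterval(chrom, lo, hi))
                if a[i][1] <= b[j][1]:
                    i += 1
                else:
                    j += 1
        return RegionSet(out)

    def subtract(self, other: "RegionSet") -> "RegionSet":
        """Bases present in this set but not in ``other``."""
        out: List[GenomicInterval] = []
        for chrom, a in self._ivals.items():
            b = other._ivals.get(chrom, [])
            j = 0
            for start, end in a:
                cur = start
                while j < len(b) and b[j][1] <= cur:
                    j += 1
                k = j
                while k < len(b) and b[k][0] < end:
                    bs, be = b[k]
                    if bs > cur:
                        out.append(GenomicInterval(chrom, cur, bs))
                    cur = max(cur, be)
                    if be >= end:
                        break
                    k += 1
                if cur < end:
                    out.append(GenomicInterval(chrom, cur, end))
        return RegionSet(out)

    def union(self, other: "RegionSet") -> "RegionSet":
        return RegionSet(list(self.intervals()) + list(other.intervals()))

    __and__ = intersect
    __sub__ = subtract
    __or__ = union


def parse_bed(text: str) -> RegionSet:
    """Parse BED-format text into a canonical :class:`RegionSet`.

    Only the first three columns are used; extra columns are ignored.
    Blank lines and lines starting with ``#``, ``track`` or ``browser``
    are skipped.  Malformed coordinates raise :class:`BedParseError`
    naming the offending line number.
    """
    intervals: List[GenomicInterval] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise BedParseError(f"line {lineno}: expected >=3 fields, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: non-integer coordinate") from exc
        try:
            intervals.append(GenomicInterval(chrom, start, end))
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: {exc}") from exc
    return RegionSet(intervals)


def read_bed(path) -> RegionSet:
    from pathlib import Path

    return parse_bed(Path(path).read_text())


def write_bed(regions: RegionSet) -> str:
    """Serialize to 3-column BED text (comment lines are not preserved)."""
    lines = [f"{iv.chrom}\t{iv.start}\t{iv.end}" for iv in regions.intervals()]
    return "\n".join(lines) + ("\n" if lines else "")


@dataclass(frozen=True)
class DesignStats:
    """How well a target design covers a coding annotation."""

    covered_bases: int
    covered_fraction: float
    missed_bases: int


def design_stats(target: RegionSet, coding: RegionSet) -> DesignStats:
    """Coverage of the ``coding`` region set by a ``target`` design.

    Raises ``ValueError`` when the coding set is empty (fraction undefined).
    """
    coding_total = coding.total_bases
    if coding_total == 0:
        raise ValueError("coding region set is empty; covered fraction undefined")
    covered = target.intersect(coding).total_bases
    return DesignStats(
        covered_bases=covered,
        covered_fraction=covered / coding_total,
        missed_bases=coding_total - covered,
    )
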