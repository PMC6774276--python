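"""Alignment-record utilities: seeded downsampling and duplicate marking.

Duplicate marking supports two keying criteria whose contrast matters for
amplicon libraries: ``start_end`` (chrom, start, end, strand — coordinate-
identical reads only) and ``start_only`` (chrom, strand and the strand-
appropriate 5' position, as conventional duplicate markers use).  Because
every ``start_end`` group lies inside a ``start_only`` group, the start_end
flagged set is always a subset of the start_only flagged set; on amplicon
data, where all reads of an amplicon share their 5' primer position,
start_only keying is catastrophic while start_end keying removes only true
coordinate copies.

Downsampling is a per-read Bernoulli draw keyed on (seed, read_id) rather
than a stream RNG, so the kept subset is independent of input order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pysam

__all__ = [
    "AlignmentRecord",
    "downsample",
    "mark_duplicates",
    "DedupResult",
    "read_sam",
    "write_sam",
]

DUPLICATE_FLAG = 0x400
REVERSE_FLAG = 0x10


@dataclass(frozen=True)
class AlignmentRecord:
    """A simplified single-end alignment: 0-based half-open [start, end)."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"
    mapq: int = 60
    mean_bq: float = 30.0
    seq: Optional[str] = None
    quals: Optional[Tuple[int, ...]] = None
    duplicate: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read {self.read_id}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id}: strand must be + or -")
        if self.mapq < 0:
            raise ValueError(f"read {self.read_id}: negative MAPQ")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Strand-appropriate 5' coordinate (start on +, end on -)."""
        return self.start if self.strand == "+" else self.end


def _keep_probability(seed: int, read_id: str) -> float:
    h = hashlib.blake2b(
        f"{seed}:{read_id}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(h, "big") / 2**64


def downsample(
    reads: Iterable[AlignmentRecord], fraction: float, seed: int
) -> List[AlignmentRecord]:
    """Keep each read independently with probability ``fraction``.

    Deterministic given (seed, read_id) and independent of input order;
    the same seed and input always yield the identical subset.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    return [r for r in reads if _keep_probability(seed, r.read_id) < fraction]


@dataclass
class DedupResult:
    reads: List[AlignmentRecord]
    n_flagged: int

    @property
    def loss_fraction(self) -> float:
        return self.n_flagged / len(self.reads) if self.reads else 0.0


def mark_duplicates(
    reads: Sequence[AlignmentRecord],
    criterion: str = "start_end",
) -> DedupResult:
    """Flag duplicate reads by coordinate key.

    ``start_end`` groups on (chrom, start, end, strand); ``start_only`` on
    (chrom, strand, 5' position).  Within each group exactly one read — the
    one with the highest mean base quality, ties broken toward the
    lexicographically smallest read id — stays unflagged; the rest get the
    duplicate flag.  Returns the reads (in input order) plus the loss
    fraction flagged/total.
    """
    if criterion not in ("start_end", "start_only"):
        raise ValueError(f"unknown criterion {criterion!r}")

    def key(r: AlignmentRecord):
        if criterion == "start_end":
            return (r.chrom, r.start, r.end, r.strand)
        return (r.chrom, r.strand, r.five_prime)

    groups: Dict[object, List[int]] = {}
    for i, r in enumerate(reads):
        groups.setdefault(key(r), []).append(i)

    flagged = set()
    for members in groups.values():
        # total order: highest mean_bq kept, ties to smallest read_id
        keep = min(members, key=lambda i: (-reads[i].mean_bq, reads[i].read_id))
        for i in members:
            if i != keep:
                flagged.add(i)

    out = [
        replace(r, duplicate=(i in flagged)) if (i in flagged) != r.duplicate else r
        for i, r in enumerate(reads)
    ]
    return DedupResult(reads=out, n_flagged=len(flagged))


# ---------------------------------------------------------------------------
# simplified SAM IO (QNAME, FLAG, RNAME, POS, MAPQ, CIGAR M-only, SEQ, QUAL)


def write_sam(
    reads: Sequence[AlignmentRecord],
    contig_lengths: Dict[str, int],
    path,
) -> None:
    """Write records as plain-text SAM; the 0x400 FLAG bit marks duplicates."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": n} for c, n in contig_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.reference_name = r.chrom
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.flag = (REVERSE_FLAG if r.strand == "-" else 0) | (
                DUPLICATE_FLAG if r.duplicate else 0
            )
            length = len(r)
            a.cigartuples = [(0, length)]  # all-M
            a.query_sequence = r.seq if r.seq is not None else "N" * length
            if r.quals is not None:
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in r.quals)
                )
            else:
                a.query_qualities = [int(round(r.mean_bq))] * length
            out.write(a)


def read_sam(path) -> List[AlignmentRecord]:
    out: List[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for a in sam:
            quals = tuple(a.query_qualities) if a.query_qualities is not None else None
            mean_bq = sum(quals) / len(quals) if quals else 0.0
            out.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    chrom=a.reference_name,
                    start=a.reference_start,
                    end=a.reference_end,
                    strand="-" if a.is_reverse else "+",
                    mapq=a.mapping_quality,
                    mean_bq=mean_bq,
                    seq=a.query_sequence,
                    quals=quals,
                    duplicate=a.is_duplicate,
                )
            )
    return out
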