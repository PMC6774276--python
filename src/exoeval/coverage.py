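"""Per-base depth statistics: callable fractions, evenness, binned histograms
and the normalized between-library Z-score comparison.

Depth is binned into 45 fixed categories chosen for resolution where it
matters: 5X steps below 10X (where calls become impossible), 10X steps
through the callable range up to 400X, and 200X steps above.  The callable
interval itself is [5X, 400X], *endpoint-inclusive* — a deliberate second
convention next to the lower-inclusive/upper-exclusive bin bounds; both are
asserted in tests.

The Z-score compares two libraries' depth distributions bin by bin:
``Diff_i = a_i - b_i`` and ``Z_i = (Diff_i - mean(Diff)) / sd(Diff)`` with
the sample (n-1) standard deviation; positive Z means the first library
covers that depth category more heavily than its average excess.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .regions import GenomicInterval, RegionSet

__all__ = [
    "BIN_EDGES",
    "DepthTrack",
    "BinnedDepth",
    "depth_histogram",
    "z_scores",
    "threshold_fractions",
    "ThresholdFractions",
    "evenness",
    "EvennessResult",
]

# 2 bins [0,5),[5,10); 39 bins [10,20)..[390,400); 4 bins [400,600),[600,800),
# [800,1000),[1000,inf) -> 45 total.  The >400X tail needs exactly four bins
# for the 200X increment to complete the count; asserted below.
BIN_EDGES: np.ndarray = np.array(
    [0.0, 5.0] + [float(x) for x in range(10, 401, 10)] + [600.0, 800.0, 1000.0, np.inf]
)
assert len(BIN_EDGES) - 1 == 45


@dataclass
class DepthTrack:
    """Per-base depth over a region set, in region (chrom, start) order."""

    region: RegionSet
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if len(self.depths) != self.region.total_bases:
            raise ValueError(
                f"depth vector length {len(self.depths)} != region size "
                f"{self.region.total_bases}"
            )
        if len(self.depths) and self.depths.min() < 0:
            raise ValueError("negative depth values")

    @property
    def average_depth(self) -> float:
        if len(self.depths) == 0:
            raise ValueError("empty depth track has no average depth")
        return float(self.depths.mean())

    @classmethod
    def from_reads(cls, reads, region: RegionSet) -> "DepthTrack":
        """Compute per-base depth of alignment records over ``region``."""
        chunks: List[np.ndarray] = []
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for r in reads:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        for iv in region.intervals():
            delta = np.zeros(len(iv) + 1, dtype=np.int64)
            for start, end in by_chrom.get(iv.chrom, ()):
                s = max(start, iv.start)
                e = min(end, iv.end)
                if s < e:
                    delta[s - iv.start] += 1
                    delta[e - iv.start] -= 1
            chunks.append(np.cumsum(delta[:-1]))
        depths = np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.int64)
        return cls(region=region, depths=depths)

    @classmethod
    def from_bedgraph(cls, text: str, region: Optional[RegionSet] = None) -> "DepthTrack":
        """Parse a BedGraph-like TSV (chrom, start, end, depth) of 0-based
        half-open runs; the region defaults to the union of the runs."""
        runs: List[Tuple[str, int, int, int]] = []
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split()
            if len(f) < 4:
                raise ValueError(f"bedgraph line {lineno}: expected 4 fields")
            runs.append((f[0], int(f[1]), int(f[2]), int(float(f[3]))))
        if region is None:
            region = RegionSet(
                GenomicInterval(c, s, e) for c, s, e, _ in runs
            )
        values: Dict[str, Dict[int, int]] = {}
        for c, s, e, d in runs:
            col = values.setdefault(c, {})
            for p in range(s, e):
                col[p] = d
        chunks = []
        for iv in region.intervals():
            col = values.get(iv.chrom, {})
            chunks.append(
                np.array([col.get(p, 0) for p in range(iv.start, iv.end)])
            )
        depths = np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.int64)
        return cls(region=region, depths=depths)

    def to_bedgraph(self) -> str:
        """Serialize as run-length-encoded BedGraph text."""
        lines = []
        offset = 0
        for iv in self.region.intervals():
            vals = self.depths[offset : offset + len(iv)]
            offset += len(iv)
            if len(vals) == 0:
                continue
            run_start = 0
            for i in range(1, len(vals) + 1):
                if i == len(vals) or vals[i] != vals[run_start]:
                    lines.append(
                        f"{iv.chrom}\t{iv.start + run_start}\t{iv.start + i}"
                        f"\t{int(vals[run_start])}"
                    )
                    run_start = i
        return "\n".join(lines) + ("\n" if lines else "")


@dataclass
class BinnedDepth:
    """45-bin depth histogram; bounds are lower-inclusive/upper-exclusive."""

    lower: np.ndarray
    upper: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.lower) == len(self.upper) == len(self.counts) == 45):
            raise ValueError("expected exactly 45 bins")
        if not np.all(np.diff(self.lower) > 0):
            raise ValueError("bin bounds must be strictly increasing")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def fractions(self) -> np.ndarray:
        t = self.total
        return self.counts / t if t else self.counts.astype(float)


def depth_histogram(track: DepthTrack) -> BinnedDepth:
    """Bin a depth track into the 45 fixed depth categories."""
    counts, _ = np.histogram(track.depths, bins=BIN_EDGES)
    return BinnedDepth(
        lower=BIN_EDGES[:-1].copy(), upper=BIN_EDGES[1:].copy(), counts=counts
    )


def z_scores(a: BinnedDepth, b: BinnedDepth, normalize: bool = False) -> np.ndarray:
    """Per-bin Z values of the coverage difference between two libraries.

    ``Diff_i = a_i - b_i`` on base counts (or on per-bin fractions with
    ``normalize=True``, useful when the two tracks span different region
    sizes); Z standardizes Diff with its sample (n-1) SD.  A zero SD —
    identical offsets in every bin — yields all-zero Z by convention.
    Positive Z means the first library covers that bin more heavily.
    """
    if not np.array_equal(a.lower, b.lower) or not np.array_equal(a.upper, b.upper):
        raise ValueError("bin bounds differ between the two histograms")
    av = a.fractions() if normalize else a.counts.astype(float)
    bv = b.fractions() if normalize else b.counts.astype(float)
    diff = av - bv
    sd = diff.std(ddof=1)
    if sd == 0:
        return np.zeros_like(diff)
    return (diff - diff.mean()) / sd


@dataclass(frozen=True)
class ThresholdFractions:
    below: float
    callable_: float
    above: float
    extra: Dict[int, float]

    def __post_init__(self) -> None:
        assert abs(self.below + self.callable_ + self.above - 1.0) < 1e-12


def threshold_fractions(
    track: DepthTrack,
    lo: int = 5,
    hi: int = 400,
    extra: Sequence[int] = (),
) -> ThresholdFractions:
    """Fractions of bases below, within and above the callable range.

    The callable interval ``[lo, hi]`` is endpoint-inclusive.  ``extra``
    thresholds report the fraction of bases covered at or above each.
    """
    if lo >= hi:
        raise ValueError("lo must be < hi")
    n = len(track.depths)
    if n == 0:
        raise ValueError("empty depth track")
    d = track.depths
    below = int((d < lo).sum())
    above = int((d > hi).sum())
    return ThresholdFractions(
        below=below / n,
        callable_=(n - below - above) / n,
        above=above / n,
        extra={int(t): float((d >= t).sum() / n) for t in extra},
    )


@dataclass
class EvennessResult:
    normalized: np.ndarray
    fraction_above_average: float


def evenness(track: DepthTrack) -> EvennessResult:
    """Per-base depth normalized by the track average, plus the fraction of
    bases strictly above the average depth (~0.4 for both real library
    types; a perfectly even track scores 0)."""
    avg = track.average_depth
    if avg == 0:
        raise ValueError("average depth is zero; evenness undefined")
    return EvennessResult(
        normalized=track.depths / avg,
        fraction_above_average=float((track.depths > avg).mean()),
    )
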