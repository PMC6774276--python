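"""Rule-based categorization of false-positive and false-negative calls.

Manual review of miscalled sites in a genome browser follows recognizable
visual signatures: alternate reads all on one strand, support only at read
ends, a low call quality, a homopolymer context, or several competing
alternate alleles.  :class:`PileupEvidence` is the machine-readable stand-in
for that per-site view, and the classifiers below apply the same signatures
as deterministic rules.

False positives get exactly one of six categories, evaluated in a fixed
precedence order (configurable): strand_bias, read_end, low_quality,
homopolymer, mixed_allele, unknown.  False negatives get a cause split into
library-derived sub-flags (coverage, genotype, read_quality) and
sequencer-derived sub-flags (homopolymer, signal_shift); "signal shift" has
no sequence-level definition and is only ever an externally supplied marker,
never inferred.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .normalize import ReferenceSequence, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PileupEvidence",
    "FPCategory",
    "FNTopLevel",
    "FNCause",
    "FNThresholds",
    "EvidenceError",
    "classify_fp",
    "classify_fn",
    "category_table",
    "homopolymer_length",
    "evidence_from_reads",
    "evidence_table_to_tsv",
    "evidence_table_from_tsv",
]


class EvidenceError(ValueError):
    """Pileup evidence is insufficient to classify the call."""


class FPCategory(str, Enum):
    STRAND_BIAS = "strand_bias"
    READ_END = "read_end"
    LOW_QUALITY = "low_quality"
    HOMOPOLYMER = "homopolymer"
    MIXED_ALLELE = "mixed_allele"
    UNKNOWN = "unknown"


DEFAULT_FP_PRECEDENCE: Tuple[FPCategory, ...] = (
    FPCategory.STRAND_BIAS,
    FPCategory.READ_END,
    FPCategory.LOW_QUALITY,
    FPCategory.HOMOPOLYMER,
    FPCategory.MIXED_ALLELE,
)


class FNTopLevel(str, Enum):
    LIBRARY = "library_derived"
    SEQUENCER = "sequencer_derived"
    BOTH = "both"
    UNKNOWN = "unknown"


LIBRARY_FLAGS = ("coverage", "genotype", "read_quality")
SEQUENCER_FLAGS = ("homopolymer", "signal_shift")


@dataclass(frozen=True)
class FNCause:
    top: FNTopLevel
    library_flags: frozenset = frozenset()
    sequencer_flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.top is FNTopLevel.BOTH:
            assert self.library_flags and self.sequencer_flags
        if self.top is FNTopLevel.UNKNOWN:
            assert not self.library_flags and not self.sequencer_flags

    @property
    def label(self) -> str:
        flags = sorted(self.library_flags) + sorted(self.sequencer_flags)
        if not flags:
            return self.top.value
        return f"{self.top.value}:{'+'.join(flags)}"


@dataclass(frozen=True)
class FNThresholds:
    """Thresholds for false-negative cause flags.

    ``min_depth`` is the callable floor (5X); ``min_af`` mirrors the
    minimum-allele-frequency caller parameter (0.2); ``min_bq`` is the
    Phred base-quality floor; ``homopolymer_min`` the run length that
    defines a homopolymer context.
    """

    min_depth: int = 5
    min_af: float = 0.2
    min_bq: float = 20.0
    homopolymer_min: int = 4


@dataclass
class PileupEvidence:
    """Per-site read-support summary consumed by the classifiers.

    ``allele_counts`` maps allele string to (forward, reverse) supporting
    read counts; ``end_distances`` holds, per alt-supporting read, the
    1-based distance from the variant to the nearer read end (1 = terminal
    base).  ``homopolymer_len`` is the longest single-base reference run
    containing or immediately adjacent to the site.  ``signal_shift`` is an
    externally supplied marker (see module docstring).
    """

    depth: int
    allele_counts: Dict[str, Tuple[int, int]]
    end_distances: List[int] = field(default_factory=list)
    mean_base_quality: Optional[float] = None
    qual: Optional[float] = None
    homopolymer_len: int = 1
    n_alt_alleles: int = 1
    signal_shift: bool = False

    def alt_support(self, alt: str) -> Tuple[int, int]:
        return self.allele_counts.get(alt, (0, 0))


def classify_fp(
    v: VariantRecord,
    e: PileupEvidence,
    precedence: Sequence[FPCategory] = DEFAULT_FP_PRECEDENCE,
    strand_bias_max_fraction: float = 0.02,
    read_end_max_distance: int = 5,
    read_end_frac: float = 1.0,
    min_qual: float = 20.0,
    homopolymer_min: int = 4,
) -> FPCategory:
    """Assign one of six categories to a false-positive call.

    Rules, evaluated in ``precedence`` order, first match wins:

    * strand_bias — at most 2% of alt-supporting reads come from one strand
      (min(fwd, rev)/(fwd+rev) <= 0.02; fires at exactly 2%);
    * read_end — every alt-supporting read carries the variant within five
      bases of a read end (fires at exactly 5; ``read_end_frac`` < 1 relaxes
      "every" to a fraction);
    * low_quality — call quality < 20 (exactly 20 does not fire);
    * homopolymer — the site sits in or next to a single-base run of length
      >= 4 (fires at exactly 4);
    * mixed_allele — more than one distinct alternate allele observed;
    * unknown — no rule fired.

    A site with zero alt-supporting reads cannot be classified and raises
    :class:`EvidenceError`.
    """
    fwd, rev = e.alt_support(v.alt)
    total = fwd + rev
    if total <= 0:
        raise EvidenceError(
            f"no alt-supporting reads at {v.chrom}:{v.pos}; cannot classify FP"
        )
    qual = e.qual if e.qual is not None else v.qual

    def fires(cat: FPCategory) -> bool:
        if cat is FPCategory.STRAND_BIAS:
            return min(fwd, rev) / total <= strand_bias_max_fraction
        if cat is FPCategory.READ_END:
            if not e.end_distances:
                return False
            near = sum(1 for d in e.end_distances if d <= read_end_max_distance)
            return near / len(e.end_distances) >= read_end_frac
        if cat is FPCategory.LOW_QUALITY:
            return qual is not None and qual < min_qual
        if cat is FPCategory.HOMOPOLYMER:
            return e.homopolymer_len >= homopolymer_min
        if cat is FPCategory.MIXED_ALLELE:
            return e.n_alt_alleles > 1
        return False

    for cat in precedence:
        if fires(cat):
            return cat
    return FPCategory.UNKNOWN


def classify_fn(
    v: VariantRecord,
    e: PileupEvidence,
    cfg: FNThresholds = FNThresholds(),
) -> FNCause:
    """Assign a cause class to a false negative from its pileup evidence.

    Library sub-flags: coverage (depth below the callable floor), genotype
    (alt allele present but below the caller's minimum fraction),
    read_quality (mean supporting base quality below threshold).  Sequencer
    sub-flags: homopolymer context, and the signal-shift marker.  The top
    level follows from which groups fired; no flag at all means unknown.
    """
    lib = set()
    seq = set()
    if e.depth < cfg.min_depth:
        lib.add("coverage")
    fwd, rev = e.alt_support(v.alt)
    alt_frac = (fwd + rev) / e.depth if e.depth > 0 else 0.0
    if 0.0 < alt_frac < cfg.min_af:
        lib.add("genotype")
    if e.mean_base_quality is not None and e.mean_base_quality < cfg.min_bq:
        lib.add("read_quality")
    if e.homopolymer_len >= cfg.homopolymer_min:
        seq.add("homopolymer")
    if e.signal_shift:
        seq.add("signal_shift")

    if lib and seq:
        top = FNTopLevel.BOTH
    elif lib:
        top = FNTopLevel.LIBRARY
    elif seq:
        top = FNTopLevel.SEQUENCER
    else:
        top = FNTopLevel.UNKNOWN
    return FNCause(top=top, library_flags=frozenset(lib), sequencer_flags=frozenset(seq))


def category_table(
    labels: Sequence[str],
    classes: Optional[Sequence[str]] = None,
    unknown_label: str = "unknown",
) -> pd.DataFrame:
    """Tabulate category labels: counts, percent of all, percent of
    clearly-classified (non-unknown) calls; optionally stratified by a
    parallel variant-class vector.
    """
    if classes is not None and len(classes) != len(labels):
        raise ValueError("labels and classes must have equal length")
    df = pd.DataFrame({"category": list(labels)})
    df["vclass"] = list(classes) if classes is not None else "all"
    rows = []
    for vclass, grp in df.groupby("vclass", sort=True):
        counts = grp["category"].value_counts()
        n_all = int(counts.sum())
        n_classified = int(counts.drop(unknown_label, errors="ignore").sum())
        for cat, n in counts.sort_index().items():
            rows.append(
                {
                    "vclass": vclass,
                    "category": cat,
                    "n": int(n),
                    "pct_of_all": 100.0 * n / n_all if n_all else 0.0,
                    "pct_of_classified": (
                        100.0 * n / n_classified
                        if n_classified and cat != unknown_label
                        else float("nan")
                    ),
                }
            )
    return pd.DataFrame(
        rows, columns=["vclass", "category", "n", "pct_of_all", "pct_of_classified"]
    )


# ---------------------------------------------------------------------------
# evidence construction


def homopolymer_length(
    reference: ReferenceSequence, chrom: str, pos: int, span: int = 1
) -> int:
    """Longest single-base run containing or adjacent to the variant span.

    ``pos`` is 1-based, ``span`` the reference-allele length.  "Adjacent"
    means the run starts or ends within one base of the span.
    """
    seq = reference[chrom]
    lo = max(0, pos - 2)  # one base left of the span, 0-based
    hi = min(len(seq), pos - 1 + span + 1)  # one base right of the span
    best = 1
    for p in range(lo, hi):
        base = seq[p]
        i = p
        while i > 0 and seq[i - 1] == base:
            i -= 1
        j = p
        while j + 1 < len(seq) and seq[j + 1] == base:
            j += 1
        best = max(best, j - i + 1)
    return best


def evidence_from_reads(
    reads,  # Sequence[AlignmentRecord]; untyped to avoid a circular import
    v: VariantRecord,
    reference: Optional[ReferenceSequence] = None,
    signal_shift: bool = False,
) -> PileupEvidence:
    """Summarize SNV evidence from simplified alignment records.

    Assumes ungapped (all-M) alignments: the base observed at the variant
    position is read from the payload sequence by offset.  Indel support is
    not extracted from alignments — supply a precomputed evidence table for
    indels.
    """
    pos0 = v.pos - 1
    depth = 0
    counts: Dict[str, Tuple[int, int]] = {}
    distances: List[int] = []
    alt_quals: List[float] = []
    for r in reads:
        if r.chrom != v.chrom or not (r.start <= pos0 < r.end):
            continue
        depth += 1
        if r.seq is None:
            continue
        base = r.seq[pos0 - r.start]
        f, rv = counts.get(base, (0, 0))
        counts[base] = (f + 1, rv) if r.strand == "+" else (f, rv + 1)
        if base == v.alt:
            distances.append(min(pos0 - r.start + 1, r.end - pos0))
            if r.quals is not None:
                alt_quals.append(r.quals[pos0 - r.start])
            else:
                alt_quals.append(r.mean_bq)
    ref_base = v.ref[0]
    n_alt = sum(1 for b, (f, rv) in counts.items() if b != ref_base and f + rv > 0)
    hp = (
        homopolymer_length(reference, v.chrom, v.pos, len(v.ref))
        if reference is not None
        else 1
    )
    mean_bq = sum(alt_quals) / len(alt_quals) if alt_quals else None
    return PileupEvidence(
        depth=depth,
        allele_counts=counts,
        end_distances=distances,
        mean_base_quality=mean_bq,
        qual=v.qual,
        homopolymer_len=hp,
        n_alt_alleles=max(n_alt, 1) if counts else 0,
        signal_shift=signal_shift,
    )


# ---------------------------------------------------------------------------
# evidence TSV round-trip (the pre-computed-evidence input path)

_EV_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "role",
    "depth",
    "alt_fwd",
    "alt_rev",
    "end_distances",
    "mean_bq",
    "qual",
    "homopolymer_len",
    "n_alt_alleles",
    "signal_shift",
]


def evidence_table_to_tsv(
    entries: Sequence[Tuple[VariantRecord, PileupEvidence, str]],
) -> str:
    """Serialize (record, evidence, role) triplets; role is ``FP`` or ``FN``."""
    rows = []
    for v, e, role in entries:
        fwd, rev = e.alt_support(v.alt)
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "role": role,
                "depth": e.depth,
                "alt_fwd": fwd,
                "alt_rev": rev,
                "end_distances": ",".join(str(d) for d in e.end_distances),
                "mean_bq": "" if e.mean_base_quality is None else e.mean_base_quality,
                "qual": "" if e.qual is None else e.qual,
                "homopolymer_len": e.homopolymer_len,
                "n_alt_alleles": e.n_alt_alleles,
                "signal_shift": int(e.signal_shift),
            }
        )
    df = pd.DataFrame(rows, columns=_EV_COLUMNS)
    return df.to_csv(sep="\t", index=False)


def evidence_table_from_tsv(
    text: str,
) -> List[Tuple[VariantRecord, PileupEvidence, str]]:
    df = pd.read_csv(io.StringIO(text), sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        qual = float(row.qual) if str(row.qual) != "" else None
        v = VariantRecord(
            chrom=str(row.chrom), pos=int(row.pos), ref=str(row.ref),
            alt=str(row.alt), qual=qual,
        )
        dists = (
            [int(d) for d in str(row.end_distances).split(",") if d != ""]
            if str(row.end_distances)
            else []
        )
        e = PileupEvidence(
            depth=int(row.depth),
            allele_counts={str(row.alt): (int(row.alt_fwd), int(row.alt_rev))},
            end_distances=dists,
            mean_base_quality=float(row.mean_bq) if str(row.mean_bq) != "" else None,
            qual=qual,
            homopolymer_len=int(row.homopolymer_len),
            n_alt_alleles=int(row.n_alt_alleles),
            signal_shift=bool(int(row.signal_shift)),
        )
        out.append((v, e, str(row.role)))
    return out
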