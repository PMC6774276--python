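"""Synthetic exome-library generator.

Produces the full fixture universe for end-to-end evaluation without any
external data: a toy reference with planted homopolymer runs and tandem
repeats, a truth variant set with genotypes, a high-confidence region (HCR)
that excludes planted difficult regions, two overlapping target designs
(an amplicon design and a capture design), and — per library profile —
simulated reads, a depth track, and a query call set with per-record
ground-truth labels (TP, FP with its intended category, FN with its
intended cause) plus category-consistent pileup evidence.

Two library profiles are emulated:

* ``amplicon`` — fixed PCR-primer-defined amplicon endpoints, per-amplicon
  lognormal depth (high dispersion), heavy coordinate duplication, and
  false positives biased toward strand-bias artifacts;
* ``capture`` — random fragment endpoints, mildly overdispersed per-base
  depth, negligible duplication, and false positives biased toward
  homopolymer artifacts.

Every draw is governed by ``SimulationConfig.seed``; identical configs give
byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .classify import PileupEvidence, homopolymer_length
from .normalize import ReferenceSequence, VariantRecord, left_align
from .reads import AlignmentRecord
from .regions import GenomicInterval, RegionSet

__all__ = [
    "SimulationConfig",
    "amplicon_config",
    "capture_config",
    "PlantedFeature",
    "TruthSet",
    "LabeledCallSet",
    "SimulatedLibrary",
    "make_reference",
    "make_truth",
    "simulate_library",
    "write_outputs",
]

_BASES = np.array(["A", "C", "G", "T"])

FP_CATEGORIES = (
    "strand_bias",
    "read_end",
    "low_quality",
    "homopolymer",
    "mixed_allele",
    "unknown",
)
FN_CAUSES = (
    "coverage",
    "genotype",
    "read_quality",
    "homopolymer",
    "signal_shift",
    "both",
    "unknown",
)


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions.

    Depth defaults follow the two real library profiles (270X amplicon,
    115X capture, set by the factories below); ``amplicon_sigma`` is the
    lognormal sigma of per-amplicon depth, ``capture_dispersion`` the
    gamma overdispersion of capture depth.  ``duplicate_rate`` is the
    fraction of reads that are PCR copies (0.13 amplicon / 0.001 capture,
    the coordinate-duplicate losses seen with start+end keying).
    ``fp_counts``/``fn_counts`` give per-category injection and per-cause
    dropout counts; ``fraction_in_hcr`` the fraction of truth variants
    placed inside the high-confidence region.
    """

    seed: int = 0
    chrom: str = "chr1"
    reference_length: int = 100_000
    n_homopolymers: int = 40
    homopolymer_length_range: Tuple[int, int] = (5, 9)
    n_repeats: int = 12
    repeat_unit_range: Tuple[int, int] = (2, 4)
    repeat_copies_range: Tuple[int, int] = (4, 8)
    n_snv: int = 400
    n_indel: int = 100
    fraction_in_hcr: float = 0.95
    library: str = "capture"
    mean_depth: float = 115.0
    amplicon_sigma: float = 1.0
    capture_dispersion: float = 0.1
    duplicate_rate: float = 0.001
    amplicon_length: int = 280
    amplicon_step: int = 190
    min_read_length: int = 40
    fragment_length_range: Tuple[int, int] = (120, 240)
    fp_counts: Dict[str, int] = field(default_factory=dict)
    fn_counts: Dict[str, int] = field(default_factory=dict)
    fp_in_hcr_fraction: float = 0.1
    make_reads: bool = True

    def __post_init__(self) -> None:
        if self.library not in ("amplicon", "capture"):
            raise ValueError(f"unknown library kind {self.library!r}")
        if self.reference_length < 1000:
            raise ValueError("reference_length must be >= 1000")
        for name in ("fraction_in_hcr", "duplicate_rate", "fp_in_hcr_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} {val} outside [0, 1]")
        for d in (self.fp_counts, self.fn_counts):
            for k, n in d.items():
                if n < 0:
                    raise ValueError(f"negative count for {k}")
        for k in self.fp_counts:
            if k not in FP_CATEGORIES:
                raise ValueError(f"unknown FP category {k!r}")
        for k in self.fn_counts:
            if k not in FN_CAUSES:
                raise ValueError(f"unknown FN cause {k!r}")
        if min(self.n_snv, self.n_indel) < 0:
            raise ValueError("variant counts must be non-negative")

    def to_dict(self) -> Dict:
        from dataclasses import asdict

        d = asdict(self)
        for k in (
            "homopolymer_length_range",
            "repeat_unit_range",
            "repeat_copies_range",
            "fragment_length_range",
        ):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "SimulationConfig":
        d = dict(d)
        for k in (
            "homopolymer_length_range",
            "repeat_unit_range",
            "repeat_copies_range",
            "fragment_length_range",
        ):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


_DEFAULT_FN = {
    "coverage": 10,
    "genotype": 8,
    "read_quality": 5,
    "homopolymer": 8,
    "signal_shift": 4,
    "both": 3,
    "unknown": 2,
}


def amplicon_config(**overrides) -> SimulationConfig:
    """Amplicon-library study conditions (high depth, high dispersion,
    strand-bias-dominated false positives, heavy duplication)."""
    base = dict(
        library="amplicon",
        mean_depth=270.0,
        duplicate_rate=0.13,
        fp_counts={
            "strand_bias": 30,
            "homopolymer": 10,
            "read_end": 6,
            "low_quality": 6,
            "mixed_allele": 4,
            "unknown": 4,
        },
        fn_counts=dict(_DEFAULT_FN),
    )
    base.update(overrides)
    return SimulationConfig(**base)


def capture_config(**overrides) -> SimulationConfig:
    """Capture-library study conditions (even depth, fragment endpoints,
    homopolymer-dominated false positives, negligible duplication)."""
    base = dict(
        library="capture",
        mean_depth=115.0,
        duplicate_rate=0.001,
        fp_counts={
            "strand_bias": 5,
            "homopolymer": 25,
            "read_end": 6,
            "low_quality": 6,
            "mixed_allele": 4,
            "unknown": 4,
        },
        fn_counts=dict(_DEFAULT_FN),
    )
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass(frozen=True)
class PlantedFeature:
    kind: str  # "homopolymer" | "repeat"
    chrom: str
    start: int  # 0-based half-open
    end: int


# ---------------------------------------------------------------------------
# reference


def make_reference(
    cfg: SimulationConfig,
) -> Tuple[ReferenceSequence, List[PlantedFeature]]:
    """Random reference with planted homopolymer runs and tandem repeats.

    Planted coordinates are returned for self-validation; homopolymer runs
    are flanked by differing bases so the recorded run length is exact.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    L = cfg.reference_length
    seq = rng.choice(_BASES, size=L)

    blocked = np.zeros(L, dtype=bool)
    pad = 15
    edge = 100  # keep features away from contig ends
    features: List[PlantedFeature] = []

    def place(span: int) -> Optional[int]:
        for _ in range(200):
            start = int(rng.integers(edge, L - edge - span))
            if not blocked[start - pad : start + span + pad].any():
                blocked[start - pad : start + span + pad] = True
                return start
        return None

    lo, hi = cfg.homopolymer_length_range
    for _ in range(cfg.n_homopolymers):
        run_len = int(rng.integers(lo, hi + 1))
        start = place(run_len)
        if start is None:
            break
        base = str(rng.choice(_BASES))
        seq[start : start + run_len] = base
        others = [b for b in "ACGT" if b != base]
        seq[start - 1] = str(rng.choice(others))
        seq[start + run_len] = str(rng.choice(others))
        features.append(PlantedFeature("homopolymer", cfg.chrom, start, start + run_len))

    ulo, uhi = cfg.repeat_unit_range
    clo, chi = cfg.repeat_copies_range
    for _ in range(cfg.n_repeats):
        unit_len = int(rng.integers(ulo, uhi + 1))
        copies = int(rng.integers(clo, chi + 1))
        unit = rng.choice(_BASES, size=unit_len)
        if len(set(unit.tolist())) < 2:  # avoid degenerate homopolymer units
            unit[0] = str(rng.choice([b for b in "ACGT" if b != unit[-1]]))
        span = unit_len * copies
        start = place(span)
        if start is None:
            break
        seq[start : start + span] = np.tile(unit, copies)
        features.append(PlantedFeature("repeat", cfg.chrom, start, start + span))

    reference = ReferenceSequence({cfg.chrom: "".join(seq.tolist())})
    return reference, features


# ---------------------------------------------------------------------------
# truth set, HCR and target designs


@dataclass
class TruthSet:
    records: List[VariantRecord]
    hcr: RegionSet
    target_amplicon: RegionSet
    target_capture: RegionSet
    difficult: RegionSet
    hp_adjacent_keys: List[Tuple[str, int, str, str]]
    outside_hcr_keys: List[Tuple[str, int, str, str]]

    @property
    def overlap_target(self) -> RegionSet:
        return self.target_amplicon.intersect(self.target_capture)


def _region_mask(region: RegionSet, chrom: str, L: int) -> np.ndarray:
    mask = np.zeros(L, dtype=bool)
    for iv in region.intervals():
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask


def make_truth(
    reference: ReferenceSequence,
    cfg: SimulationConfig,
    features: Sequence[PlantedFeature],
) -> TruthSet:
    """Truth variants, HCR and the two overlapping target designs.

    The two designs share a large overlap region; the HCR is the chromosome
    minus the difficult regions (planted tandem repeats plus dedicated
    exclusion windows).  A ``1 - fraction_in_hcr`` share of truth variants
    is placed inside exclusion windows so that high-confidence restriction
    measurably trims the truth set.  Variants earmarked for homopolymer-
    related dropout are planted immediately after planted runs.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    chrom = cfg.chrom
    L = cfg.reference_length
    seq = reference[chrom]
    n_total = cfg.n_snv + cfg.n_indel
    if n_total * 30 > L:
        raise ValueError(
            f"infeasible density: {n_total} variants on a {L} bp reference"
        )

    whole = RegionSet([GenomicInterval(chrom, 0, L)])
    t_a = RegionSet([GenomicInterval(chrom, 0, int(L * 0.85))])
    t_b = RegionSet([GenomicInterval(chrom, int(L * 0.15), L)])
    otr = t_a.intersect(t_b)

    n_outside = int(round((1.0 - cfg.fraction_in_hcr) * n_total))
    n_fp_outside = int(
        round(
            sum(n for c, n in cfg.fp_counts.items() if c != "homopolymer")
            * (1.0 - cfg.fp_in_hcr_fraction)
        )
    )
    n_windows = max(1, math.ceil((n_outside + n_fp_outside) / 2) + 1)

    occupied = np.zeros(L, dtype=bool)
    margin = 12
    feature_spans = [(f.start, f.end) for f in features]
    for s, e in feature_spans:
        occupied[max(0, s - 2) : e + 2] = True

    # exclusion windows: difficult-by-fiat regions inside the OTR
    windows: List[Tuple[int, int]] = []
    otr_iv = next(otr.intervals())
    for _ in range(n_windows):
        for _ in range(300):
            ws = int(rng.integers(otr_iv.start + 50, otr_iv.end - 110))
            if not occupied[ws - 10 : ws + 70].any():
                occupied[ws - 10 : ws + 70] = True
                windows.append((ws, ws + 60))
                break
    difficult = RegionSet(
        [GenomicInterval(chrom, s, e) for s, e in windows]
        + [
            GenomicInterval(f.chrom, f.start, f.end)
            for f in features
            if f.kind == "repeat"
        ]
    )
    hcr = whole.subtract(difficult)
    # windows are blocked for ordinary placement; re-open them for the
    # dedicated outside-HCR variants below
    window_positions = [p for s, e in windows for p in range(s + 5, e - 5)]

    records: List[VariantRecord] = []
    used_keys = set()
    hp_adjacent_keys: List[Tuple[str, int, str, str]] = []
    outside_keys: List[Tuple[str, int, str, str]] = []

    def genotype_and_af():
        if rng.random() < 0.65:
            return (0, 1), 0.5
        return (1, 1), 1.0

    def add(record: VariantRecord, span_lo: int, span_hi: int) -> None:
        records.append(record)
        used_keys.add(record.key)
        occupied[max(0, span_lo - margin) : span_hi + margin] = True

    def random_snv_at(pos0: int) -> VariantRecord:
        ref_b = seq[pos0]
        alt_b = str(rng.choice([b for b in "ACGT" if b != ref_b]))
        gt, af = genotype_and_af()
        return VariantRecord(
            chrom=chrom, pos=pos0 + 1, ref=ref_b, alt=alt_b,
            genotype=gt, qual=50.0, af=af,
        )

    # 1) homopolymer-adjacent truth SNVs (reserved for hp-related dropout)
    n_hp_needed = cfg.fn_counts.get("homopolymer", 0) + cfg.fn_counts.get("both", 0)
    hp_feats = [f for f in features if f.kind == "homopolymer"]
    hp_in_otr = [
        f for f in hp_feats if otr.contains(chrom, f.end) and hcr.contains(chrom, f.end)
    ]
    if n_hp_needed > len(hp_in_otr):
        raise ValueError(
            f"need {n_hp_needed} homopolymer-adjacent truth sites but only "
            f"{len(hp_in_otr)} planted runs are available in the overlap region"
        )
    for f in hp_in_otr[:n_hp_needed]:
        pos0 = f.end  # base immediately after the run (adjacent)
        v = random_snv_at(pos0)
        add(v, pos0, pos0 + 1)
        hp_adjacent_keys.append(v.key)

    # 2) outside-HCR truth variants, placed inside exclusion windows
    n_out_indel = int(round(n_outside * cfg.n_indel / n_total)) if n_total else 0
    n_out_snv = n_outside - n_out_indel
    free_window_positions = [p for p in window_positions]
    rng.shuffle(free_window_positions)

    def take_window_pos(span: int) -> Optional[int]:
        while free_window_positions:
            p = free_window_positions.pop()
            near = [q for q in free_window_positions if abs(q - p) > span + 6]
            if len(near) != len(free_window_positions):
                free_window_positions[:] = near
            return p
        return None

    def random_indel_at(pos0: int) -> Optional[VariantRecord]:
        if rng.random() < 0.5 and pos0 + 4 < L:  # deletion
            dlen = int(rng.integers(1, 4))
            ref_a = seq[pos0 : pos0 + 1 + dlen]
            alt_a = ref_a[0]
        else:  # insertion
            ilen = int(rng.integers(1, 4))
            ref_a = seq[pos0]
            alt_a = ref_a + "".join(rng.choice(_BASES, size=ilen).tolist())
        gt, af = genotype_and_af()
        try:
            v = VariantRecord(
                chrom=chrom, pos=pos0 + 1, ref=ref_a, alt=alt_a,
                genotype=gt, qual=50.0, af=af,
            )
            return left_align(v, reference)
        except ValueError:
            return None

    for kind, n_k in (("snv", n_out_snv), ("indel", n_out_indel)):
        placed = 0
        while placed < n_k:
            pos0 = take_window_pos(6)
            if pos0 is None:
                raise ValueError("exclusion windows exhausted; lower n_outside")
            v = random_snv_at(pos0) if kind == "snv" else random_indel_at(pos0)
            if v is None or v.key in used_keys:
                continue
            add(v, min(v.pos - 1, pos0), pos0 + 6)
            outside_keys.append(v.key)
            placed += 1

    # 3) ordinary truth variants at clean positions in OTR ∩ HCR
    clean_mask = (
        _region_mask(otr, chrom, L)
        & _region_mask(hcr, chrom, L)
    )
    n_snv_left = cfg.n_snv - len(hp_adjacent_keys) - n_out_snv
    n_indel_left = cfg.n_indel - n_out_indel

    def place_clean(kind: str) -> None:
        for _ in range(500):
            pos0 = int(rng.integers(50, L - 50))
            if occupied[pos0 - 2 : pos0 + 8].any() or not clean_mask[pos0]:
                continue
            if homopolymer_length(reference, chrom, pos0 + 1, 4) >= 4:
                continue
            v = random_snv_at(pos0) if kind == "snv" else random_indel_at(pos0)
            if v is None or v.key in used_keys:
                continue
            add(v, min(v.pos - 1, pos0), pos0 + (1 if kind == "snv" else 6))
            return
        raise ValueError("could not place truth variant; reference too crowded")

    for _ in range(n_snv_left):
        place_clean("snv")
    for _ in range(n_indel_left):
        place_clean("indel")

    records.sort(key=lambda r: r.key)
    return TruthSet(
        records=records,
        hcr=hcr,
        target_amplicon=t_a,
        target_capture=t_b,
        difficult=difficult,
        hp_adjacent_keys=hp_adjacent_keys,
        outside_hcr_keys=outside_keys,
    )


# ---------------------------------------------------------------------------
# library simulation


@dataclass
class LabeledCallSet:
    """Query calls plus ground-truth labels and per-site evidence.

    ``labels`` maps each query record key to ``"TP"`` or ``"FP:<category>"``;
    ``dropped`` lists (truth record, ``"FN:<cause>"``) pairs for calls the
    simulated caller missed.  ``evidence`` covers both query and dropped
    keys with category/cause-consistent pileup summaries.
    """

    query: List[VariantRecord]
    labels: Dict[Tuple[str, int, str, str], str]
    dropped: List[Tuple[VariantRecord, str]]
    evidence: Dict[Tuple[str, int, str, str], PileupEvidence]


@dataclass
class SimulatedLibrary:
    kind: str
    target: RegionSet
    reads: List[AlignmentRecord]
    depth_track: Optional["DepthTrack"]
    calls: LabeledCallSet


def _balanced_counts(rng, total: int) -> Tuple[int, int]:
    fwd = int(rng.binomial(total, 0.5))
    fwd = min(max(fwd, int(0.3 * total)), total - int(0.3 * total))
    return fwd, total - fwd


def _clean_evidence(
    rng, v: VariantRecord, reference: ReferenceSequence, mean_depth: float,
    af: float,
) -> PileupEvidence:
    depth = max(10, int(rng.poisson(mean_depth)))
    alt_n = max(1, int(round(depth * af)))
    fwd, rev = _balanced_counts(rng, alt_n)
    return PileupEvidence(
        depth=depth,
        allele_counts={v.alt: (fwd, rev)},
        end_distances=[int(d) for d in rng.integers(20, 81, size=min(alt_n, 30))],
        mean_base_quality=float(np.round(rng.uniform(30, 38), 1)),
        qual=v.qual,
        homopolymer_len=homopolymer_length(reference, v.chrom, v.pos, len(v.ref)),
        n_alt_alleles=1,
    )


def _fp_evidence(
    rng, v: VariantRecord, reference: ReferenceSequence, category: str,
    mean_depth: float,
) -> PileupEvidence:
    """Evidence constructed to fire exactly the intended FP rule (and, by
    construction, no higher-precedence rule)."""
    depth = max(20, int(rng.poisson(mean_depth)))
    alt_n = max(10, int(round(depth * (v.af or 0.2))))
    fwd, rev = _balanced_counts(rng, alt_n)
    distances = [int(d) for d in rng.integers(20, 81, size=min(alt_n, 30))]
    hp = homopolymer_length(reference, v.chrom, v.pos, len(v.ref))
    n_alt = 1
    if category == "strand_bias":
        minority = 1 if alt_n >= 50 else 0
        if rng.random() < 0.5:
            fwd, rev = alt_n - minority, minority
        else:
            fwd, rev = minority, alt_n - minority
    elif category == "read_end":
        distances = [int(d) for d in rng.integers(1, 6, size=max(5, min(alt_n, 30)))]
    elif category == "mixed_allele":
        n_alt = 2
    # low_quality and homopolymer need no evidence adjustment: the former is
    # carried by the record quality, the latter by the planted run context
    return PileupEvidence(
        depth=depth,
        allele_counts={v.alt: (fwd, rev)},
        end_distances=distances,
        mean_base_quality=float(np.round(rng.uniform(28, 36), 1)),
        qual=v.qual,
        homopolymer_len=hp,
        n_alt_alleles=n_alt,
    )


def _fn_evidence(
    rng, v: VariantRecord, reference: ReferenceSequence, cause: str,
    mean_depth: float,
) -> PileupEvidence:
    depth = max(20, int(rng.poisson(mean_depth)))
    af = 0.5
    bq = float(np.round(rng.uniform(28, 36), 1))
    signal = False
    if cause == "coverage":
        depth = int(rng.integers(1, 5))
    elif cause == "genotype":
        af = float(np.round(rng.uniform(0.05, 0.15), 3))
    elif cause == "read_quality":
        bq = float(np.round(rng.uniform(8, 16), 1))
    elif cause == "signal_shift":
        signal = True
    elif cause == "both":
        af = float(np.round(rng.uniform(0.05, 0.15), 3))  # + homopolymer site
    alt_n = max(1, int(round(depth * af))) if af > 0 else 0
    fwd, rev = _balanced_counts(rng, alt_n) if alt_n else (0, 0)
    return PileupEvidence(
        depth=depth,
        allele_counts={v.alt: (fwd, rev)},
        end_distances=[int(d) for d in rng.integers(20, 81, size=min(alt_n, 30))],
        mean_base_quality=bq,
        qual=None,
        homopolymer_len=homopolymer_length(reference, v.chrom, v.pos, len(v.ref)),
        n_alt_alleles=1,
        signal_shift=signal,
    )


def _amplicon_reads(rng, cfg: SimulationConfig, target: RegionSet) -> List[AlignmentRecord]:
    reads: List[AlignmentRecord] = []
    mean_len = (cfg.min_read_length + cfg.amplicon_length) / 2.0
    per_amp = cfg.mean_depth * cfg.amplicon_step / mean_len
    mu = math.log(per_amp) - cfg.amplicon_sigma**2 / 2.0
    amp_i = 0
    for iv in target.intervals():
        starts = range(iv.start, max(iv.start + 1, iv.end - cfg.min_read_length),
                       cfg.amplicon_step)
        for amp_start in starts:
            amp_end = min(iv.end, amp_start + cfg.amplicon_length)
            span = amp_end - amp_start
            if span < cfg.min_read_length:
                continue
            amp_i += 1
            n_total = int(round(rng.lognormal(mu, cfg.amplicon_sigma)))
            if n_total <= 0:
                continue
            n_copies = int(rng.binomial(n_total, cfg.duplicate_rate))
            n_unique = n_total - n_copies
            amp_lo = len(reads)
            for strand, n_s in zip("+-", _split(rng, n_unique)):
                m = span - cfg.min_read_length + 1
                k = min(n_s, m)
                trims = rng.choice(m, size=k, replace=False)
                extra = n_s - k  # trim space saturated: surplus are copies
                group: List[AlignmentRecord] = []
                for t in trims:
                    length = cfg.min_read_length + int(t)
                    if strand == "+":
                        s, e = amp_start, amp_start + length
                    else:
                        s, e = amp_end - length, amp_end
                    group.append(
                        AlignmentRecord(
                            read_id=f"amp{amp_i}_{strand}{len(reads) + len(group)}",
                            chrom=iv.chrom, start=s, end=e, strand=strand,
                            mean_bq=float(np.round(rng.normal(32, 3), 1)),
                        )
                    )
                for j in range(extra):
                    src = group[int(rng.integers(0, len(group)))]
                    group.append(replace(src, read_id=f"{src.read_id}_s{j}"))
                reads.extend(group)
            # PCR copies of already-emitted molecules of this amplicon
            if len(reads) > amp_lo:
                for j in range(n_copies):
                    src = reads[int(rng.integers(amp_lo, len(reads)))]
                    reads.append(replace(src, read_id=f"{src.read_id}_d{j}"))
    return reads


def _split(rng, n: int) -> Tuple[int, int]:
    a = int(rng.binomial(n, 0.5))
    return a, n - a


def _capture_reads(rng, cfg: SimulationConfig, target: RegionSet) -> List[AlignmentRecord]:
    reads: List[AlignmentRecord] = []
    flo, fhi = cfg.fragment_length_range
    mean_len = (flo + fhi) / 2.0
    shape = 1.0 / max(cfg.capture_dispersion, 1e-6)
    rid = 0
    for iv in target.intervals():
        for w_start in range(iv.start, iv.end, 1000):
            w_end = min(iv.end, w_start + 1000)
            weight = rng.gamma(shape, 1.0 / shape)
            lam = weight * (w_end - w_start) * cfg.mean_depth / mean_len
            n = int(rng.poisson(lam))
            if n == 0:
                continue
            starts = rng.integers(w_start, w_end, size=n)
            lengths = rng.integers(flo, fhi + 1, size=n)
            strands = rng.random(n) < 0.5
            for s, ln, fwd in zip(starts, lengths, strands):
                e = min(int(s) + int(ln), iv.end)
                s = int(s)
                if e - s < cfg.min_read_length:
                    continue
                rid += 1
                reads.append(
                    AlignmentRecord(
                        read_id=f"cap{rid}",
                        chrom=iv.chrom, start=s, end=e,
                        strand="+" if fwd else "-",
                        mean_bq=float(np.round(rng.normal(32, 3), 1)),
                    )
                )
    n_copies = int(rng.binomial(len(reads), cfg.duplicate_rate))
    for j in range(n_copies):
        src = reads[int(rng.integers(0, len(reads)))]
        reads.append(replace(src, read_id=f"{src.read_id}_d{j}"))
    return reads


def simulate_library(
    reference: ReferenceSequence,
    truth: TruthSet,
    cfg: SimulationConfig,
) -> SimulatedLibrary:
    """Simulate one library: reads, depth track, query calls and labels.

    The query call set is the truth set restricted to this library's target,
    minus the configured per-cause FN dropouts, plus the configured
    per-category FP injections; every record keeps its ground-truth label
    and a pileup-evidence summary consistent with it.
    """
    from .coverage import DepthTrack

    rng = np.random.default_rng([cfg.seed, 2 if cfg.library == "amplicon" else 3])
    chrom = cfg.chrom
    L = cfg.reference_length
    seq = reference[chrom]
    target = (
        truth.target_amplicon if cfg.library == "amplicon" else truth.target_capture
    )

    truth_in_target = [
        v for v in truth.records if target.contains_vcf_pos(v.chrom, v.pos)
    ]

    # --- FN dropouts ---------------------------------------------------
    hp_pool = [
        v for v in truth_in_target
        if v.key in set(truth.hp_adjacent_keys)
    ]
    outside = set(truth.outside_hcr_keys)
    plain_pool = [
        v for v in truth_in_target
        if v.key not in set(truth.hp_adjacent_keys) and v.key not in outside
    ]
    rng.shuffle(plain_pool)
    plain_pool = list(plain_pool)

    dropped: List[Tuple[VariantRecord, str]] = []
    evidence: Dict[Tuple[str, int, str, str], PileupEvidence] = {}
    dropped_keys = set()
    hp_idx = 0
    for cause in FN_CAUSES:
        n = cfg.fn_counts.get(cause, 0)
        for _ in range(n):
            if cause in ("homopolymer", "both"):
                if hp_idx >= len(hp_pool):
                    raise ValueError("not enough homopolymer-adjacent truth sites")
                v = hp_pool[hp_idx]
                hp_idx += 1
            else:
                if not plain_pool:
                    raise ValueError("not enough truth variants for FN dropouts")
                v = plain_pool.pop()
            dropped.append((v, f"FN:{cause}"))
            dropped_keys.add(v.key)
            evidence[v.key] = _fn_evidence(rng, v, reference, cause, cfg.mean_depth)

    # --- TP calls ------------------------------------------------------
    query: List[VariantRecord] = []
    labels: Dict[Tuple[str, int, str, str], str] = {}
    for v in truth_in_target:
        if v.key in dropped_keys:
            continue
        call = replace(v, qual=float(np.round(rng.uniform(50, 100), 1)),
                       af=_jitter_af(rng, v.af))
        query.append(call)
        labels[call.key] = "TP"
        evidence[call.key] = _clean_evidence(
            rng, call, reference, cfg.mean_depth, call.af or 0.5
        )

    # --- FP injections -------------------------------------------------
    used_keys = {v.key for v in truth.records} | {q.key for q in query}
    in_target = _region_mask(target, chrom, L)
    in_hcr = _region_mask(truth.hcr, chrom, L)
    window_mask = in_target & ~in_hcr

    def fp_site_clean(inside_hcr: bool) -> int:
        for _ in range(1000):
            pos0 = int(rng.integers(50, L - 50))
            if not in_target[pos0]:
                continue
            if inside_hcr != bool(in_hcr[pos0]):
                continue
            if homopolymer_length(reference, chrom, pos0 + 1, 1) >= 4:
                continue
            return pos0
        raise ValueError("could not place FP site")

    hp_runs = _homopolymer_runs(seq)
    used_hp = set()

    def fp_site_homopolymer() -> Tuple[int, int]:
        for _ in range(2000):
            i = int(rng.integers(0, len(hp_runs)))
            if i in used_hp:
                continue
            s, e = hp_runs[i]
            if not (in_target[e] and in_hcr[e]):
                continue
            used_hp.add(i)
            return s, e
        raise ValueError("no homopolymer runs left for FP injection")

    for category in FP_CATEGORIES:
        n = cfg.fp_counts.get(category, 0)
        for j in range(n):
            qual = (
                float(np.round(rng.uniform(5, 19), 1))
                if category == "low_quality"
                else float(np.round(rng.uniform(25, 60), 1))
            )
            af = float(np.round(rng.uniform(0.05, 0.40), 3))
            if category == "homopolymer":
                s, e = fp_site_homopolymer()
                run_base = seq[s]
                if j % 2 == 0:  # insertion extending the run
                    v = VariantRecord(
                        chrom=chrom, pos=e, ref=seq[e - 1], alt=seq[e - 1] + run_base,
                        genotype=(0, 1), qual=qual, af=af,
                    )
                    v = left_align(v, reference)
                else:  # SNV on the base after the run
                    alt_b = str(rng.choice([b for b in "ACGT" if b != seq[e]]))
                    v = VariantRecord(
                        chrom=chrom, pos=e + 1, ref=seq[e], alt=alt_b,
                        genotype=(0, 1), qual=qual, af=af,
                    )
            else:
                inside = rng.random() < cfg.fp_in_hcr_fraction
                if not window_mask.any():
                    inside = True
                pos0 = fp_site_clean(inside)
                ref_b = seq[pos0]
                alt_b = str(rng.choice([b for b in "ACGT" if b != ref_b]))
                v = VariantRecord(
                    chrom=chrom, pos=pos0 + 1, ref=ref_b, alt=alt_b,
                    genotype=(0, 1), qual=qual, af=af,
                )
            if v.key in used_keys:
                continue  # rare collision; injected count drops by one
            used_keys.add(v.key)
            query.append(v)
            labels[v.key] = f"FP:{category}"
            evidence[v.key] = _fp_evidence(rng, v, reference, category, cfg.mean_depth)

    query.sort(key=lambda r: r.key)
    calls = LabeledCallSet(query=query, labels=labels, dropped=dropped,
                           evidence=evidence)

    # --- reads and depth ------------------------------------------------
    reads: List[AlignmentRecord] = []
    depth_track = None
    if cfg.make_reads:
        if cfg.library == "amplicon":
            reads = _amplicon_reads(rng, cfg, target)
        else:
            reads = _capture_reads(rng, cfg, target)
        depth_track = DepthTrack.from_reads(reads, target)

    return SimulatedLibrary(
        kind=cfg.library, target=target, reads=reads,
        depth_track=depth_track, calls=calls,
    )


def _jitter_af(rng, af: Optional[float]) -> float:
    base = af if af is not None else 0.5
    if base >= 0.99:
        return float(np.round(rng.uniform(0.95, 1.0), 3))
    return float(np.round(np.clip(rng.normal(base, 0.02), 0.45, 0.6), 3))


def _homopolymer_runs(seq: str, min_len: int = 4) -> List[Tuple[int, int]]:
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j + 1 < n and seq[j + 1] == seq[i]:
            j += 1
        if j - i + 1 >= min_len and i > 2 and j < n - 3:
            runs.append((i, j + 1))
        i = j + 1
    return runs


# ---------------------------------------------------------------------------
# file emission


def write_outputs(
    out_dir,
    reference: ReferenceSequence,
    truth: TruthSet,
    library: SimulatedLibrary,
    cfg: SimulationConfig,
) -> Dict[str, Path]:
    """Write the complete fixture set as plain-text files.

    Emits FASTA, 3-column BEDs (HCR, both targets, difficult regions),
    truth and query VCFs, simplified SAM, BedGraph depth and a labels TSV.
    Byte-identical across runs with the same config.
    """
    from .classify import evidence_table_to_tsv
    from .reads import write_sam
    from .regions import write_bed
    from .vcfio import write_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    paths["reference"] = out / "reference.fa"
    reference.to_fasta(paths["reference"])
    for name, region in (
        ("hcr", truth.hcr),
        ("target_amplicon", truth.target_amplicon),
        ("target_capture", truth.target_capture),
        ("difficult", truth.difficult),
    ):
        paths[name] = out / f"{name}.bed"
        paths[name].write_text(write_bed(region))
    lengths = reference.lengths()
    paths["truth_vcf"] = out / "truth.vcf"
    write_vcf(truth.records, lengths, paths["truth_vcf"])
    paths["query_vcf"] = out / "query.vcf"
    write_vcf(library.calls.query, lengths, paths["query_vcf"])
    if library.reads:
        paths["sam"] = out / "reads.sam"
        write_sam(library.reads, lengths, paths["sam"])
    if library.depth_track is not None:
        paths["depth"] = out / "depth.bedgraph"
        paths["depth"].write_text(library.depth_track.to_bedgraph())

    label_lines = ["chrom\tpos\tref\talt\tlabel"]
    for v in library.calls.query:
        label_lines.append(
            f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{library.calls.labels[v.key]}"
        )
    for v, lab in library.calls.dropped:
        label_lines.append(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{lab}")
    paths["labels"] = out / "labels.tsv"
    paths["labels"].write_text("\n".join(label_lines) + "\n")

    entries = []
    for v in library.calls.query:
        lab = library.calls.labels[v.key]
        if lab.startswith("FP"):
            entries.append((v, library.calls.evidence[v.key], "FP"))
    for v, lab in library.calls.dropped:
        entries.append((v, library.calls.evidence[v.key], "FN"))
    paths["evidence"] = out / "evidence.tsv"
    paths["evidence"].write_text(evidence_table_to_tsv(entries))

    import json

    paths["config"] = out / "config.json"
    paths["config"].write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True))
    return paths
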