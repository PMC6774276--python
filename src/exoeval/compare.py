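"""Truth-set comparison: TP/FN/FP partitions, sensitivity/PPV, concordance.

A query call set is benchmarked against a truth set inside an evaluation
region.  Matching is exact and allele-level — a query record is a true
positive iff a truth record with identical (chrom, pos, ref, alt) exists in
the region — which is why both sets must be regularized first (see
:mod:`exoeval.normalize`); representation differences, not genotypes, are
the dominant source of spurious mismatches.  A genotype-aware mode is
available behind a flag.

Sensitivity = TP/(TP+FN), PPV = TP/(TP+FP); percentages are rendered with
half-up rounding at two decimals (one decimal for FP reductions) to match
conventional report tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .normalize import VariantClass, VariantRecord, is_parsimonious
from .regions import RegionSet

logger = logging.getLogger(__name__)

__all__ = [
    "MetricPair",
    "StratumCounts",
    "ComparisonResult",
    "NotNormalizedError",
    "compare",
    "metrics",
    "fp_reduction",
    "genotype_concordance",
    "ConcordanceResult",
    "genotypes_from_records",
    "refilter_min_af",
]


class NotNormalizedError(ValueError):
    """Input records violate the parsimony condition; regularize first."""


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricPair:
    """Sensitivity and PPV as fractions; ``None`` marks an undefined value
    (zero denominator), which is deliberately distinct from 0."""

    sensitivity: Optional[float]
    ppv: Optional[float]

    @property
    def sensitivity_pct(self) -> Optional[float]:
        if self.sensitivity is None:
            return None
        return _round_half_up(100.0 * self.sensitivity, 2)

    @property
    def ppv_pct(self) -> Optional[float]:
        if self.ppv is None:
            return None
        return _round_half_up(100.0 * self.ppv, 2)


def metrics(tp: int, fn: int, fp: int) -> MetricPair:
    """Sensitivity and PPV from TP/FN/FP counts."""
    if min(tp, fn, fp) < 0:
        raise ValueError("counts must be non-negative")
    sens = tp / (tp + fn) if tp + fn > 0 else None
    ppv = tp / (tp + fp) if tp + fp > 0 else None
    return MetricPair(sensitivity=sens, ppv=ppv)


def fp_reduction(fp_before: int, fp_after: int) -> float:
    """Percent reduction in FP count, rounded half-up to one decimal."""
    if fp_before <= 0:
        raise ValueError("fp_before must be positive for a defined reduction")
    return _round_half_up(100.0 * (1.0 - fp_after / fp_before), 1)


@dataclass
class StratumCounts:
    total: int = 0  # query records in region (tp + fp)
    truth: int = 0  # truth records in region (tp + fn)
    tp: int = 0
    fn: int = 0
    fp: int = 0

    @property
    def metric_pair(self) -> MetricPair:
        return metrics(self.tp, self.fn, self.fp)


@dataclass
class ComparisonResult:
    """TP/FN/FP partitions plus stratified counts.

    Strata: ``total``, ``snv``, ``indel`` and (should regularization have
    been skipped) ``other`` for residual equal-length multi-base records;
    when a coding region set is supplied, ``exonic_snv``/``exonic_indel``
    strata are added using a point test on the variant position.
    """

    tp: List[VariantRecord]
    fn: List[VariantRecord]
    fp: List[VariantRecord]
    region: RegionSet
    strata: Dict[str, StratumCounts]

    @property
    def truth_size_in_region(self) -> int:
        return len(self.tp) + len(self.fn)

    @property
    def query_size_in_region(self) -> int:
        return len(self.tp) + len(self.fp)

    @property
    def metric_pair(self) -> MetricPair:
        return metrics(len(self.tp), len(self.fn), len(self.fp))

    def _check_invariants(self) -> None:
        t = self.strata["total"]
        assert t.tp == len(self.tp) and t.fn == len(self.fn) and t.fp == len(self.fp)
        assert t.truth == t.tp + t.fn
        assert t.total == t.tp + t.fp
        for name in ("tp", "fn", "fp"):
            parts = sum(
                getattr(self.strata[s], name)
                for s in ("snv", "indel", "other")
                if s in self.strata
            )
            assert parts == getattr(t, name), f"stratum {name} counts do not sum"


def _class_stratum(v: VariantRecord) -> str:
    if len(v.ref) == 1 and len(v.alt) == 1:
        return "snv"
    if v.is_indel:
        return "indel"
    return "other"  # equal-length >1: should be empty after regularization


def _restrict(
    records: Sequence[VariantRecord], region: RegionSet
) -> List[VariantRecord]:
    return [v for v in records if region.contains_vcf_pos(v.chrom, v.pos)]


def compare(
    query: Sequence[VariantRecord],
    truth: Sequence[VariantRecord],
    region: RegionSet,
    coding: Optional[RegionSet] = None,
    require_normalized: bool = True,
    genotype_aware: bool = False,
) -> ComparisonResult:
    """Compare a query call set against a truth set within ``region``.

    Both sets are restricted to the region first (point test on the 1-based
    position).  Matching is one-to-one on (chrom, pos, ref, alt); with
    ``genotype_aware`` the unordered genotype must agree as well.  Alleles
    containing N never match.  With ``require_normalized`` (the default),
    records violating the parsimony condition raise
    :class:`NotNormalizedError` — exact matching is only meaningful on
    regularized input.
    """
    if require_normalized:
        for name, recs in (("query", query), ("truth", truth)):
            for v in recs:
                if not is_parsimonious(v):
                    raise NotNormalizedError(
                        f"{name} record {v.chrom}:{v.pos} {v.ref}>{v.alt} is not "
                        "normalized; run regularize() on both input sets first"
                    )

    q_in = _restrict(query, region)
    t_in = _restrict(truth, region)

    def match_key(v: VariantRecord):
        if "N" in v.ref or "N" in v.alt:
            return None  # N alleles never match anything
        if genotype_aware:
            gt = tuple(sorted(v.genotype)) if v.genotype is not None else None
            return (*v.key, gt)
        return v.key

    unmatched: Dict[object, List[int]] = {}
    for i, t in enumerate(t_in):
        k = match_key(t)
        if k is not None:
            unmatched.setdefault(k, []).append(i)

    tp: List[VariantRecord] = []
    fp: List[VariantRecord] = []
    matched_truth = set()
    for qv in q_in:
        k = match_key(qv)
        stack = unmatched.get(k)
        if stack:
            matched_truth.add(stack.pop())
            tp.append(qv)
        else:
            fp.append(qv)
    fn = [t for i, t in enumerate(t_in) if i not in matched_truth]

    strata: Dict[str, StratumCounts] = {"total": StratumCounts()}

    def bump(name: str, kind: str) -> None:
        sc = strata.setdefault(name, StratumCounts())
        setattr(sc, kind, getattr(sc, kind) + 1)
        if kind in ("tp", "fp"):
            sc.total += 1
        if kind in ("tp", "fn"):
            sc.truth += 1

    for kind, recs in (("tp", tp), ("fn", fn), ("fp", fp)):
        for v in recs:
            bump("total", kind)
            cls = _class_stratum(v)
            bump(cls, kind)
            if coding is not None and coding.contains_vcf_pos(v.chrom, v.pos):
                bump(f"exonic_{cls}", kind)

    for cls in ("snv", "indel"):
        strata.setdefault(cls, StratumCounts())
    if strata.get("other") and strata["other"].total + strata["other"].truth > 0:
        logger.warning(
            "comparison saw %d equal-length multi-base records; "
            "input may not be fully decomposed",
            strata["other"].tp + strata["other"].fn + strata["other"].fp,
        )

    result = ComparisonResult(tp=tp, fn=fn, fp=fp, region=region, strata=strata)
    result._check_invariants()
    return result


# ---------------------------------------------------------------------------
# microarray genotype concordance

Site = Tuple[str, int]
Genotype = Tuple[str, str]


@dataclass(frozen=True)
class ConcordanceResult:
    shared_sites: int
    matching_sites: int

    @property
    def fraction(self) -> Optional[float]:
        if self.shared_sites == 0:
            return None  # undefined, not zero
        return self.matching_sites / self.shared_sites

    @property
    def pct(self) -> Optional[float]:
        f = self.fraction
        return None if f is None else _round_half_up(100.0 * f, 2)


def genotypes_from_records(
    records: Iterable[VariantRecord],
) -> Tuple[Dict[Site, Genotype], Dict[Site, str]]:
    """Build (site -> allele-pair genotype, site -> ref allele) maps.

    Records without genotypes are treated as heterozygous ref/alt.
    """
    genos: Dict[Site, Genotype] = {}
    refs: Dict[Site, str] = {}
    for v in records:
        gt = v.genotype if v.genotype is not None else (0, 1)
        alleles = tuple(sorted(v.alt if a else v.ref for a in gt))
        genos[(v.chrom, v.pos)] = alleles  # type: ignore[assignment]
        refs[(v.chrom, v.pos)] = v.ref
    return genos, refs


def genotype_concordance(
    seq_genotypes: Mapping[Site, Genotype],
    array_genotypes: Mapping[Site, Genotype],
    ref_alleles: Optional[Mapping[Site, str]] = None,
) -> ConcordanceResult:
    """Genotype concordance over shared non-reference sites.

    Genotypes are unordered diploid allele pairs keyed by (chrom, pos).
    Sites where both calls are homozygous reference are disregarded (when
    ``ref_alleles`` provides the reference allele); zero shared sites yields
    an explicit undefined result.
    """
    shared = 0
    matching = 0
    for site, sg in seq_genotypes.items():
        if site not in array_genotypes:
            continue
        ag = array_genotypes[site]
        sg_s, ag_s = tuple(sorted(sg)), tuple(sorted(ag))
        if ref_alleles is not None and site in ref_alleles:
            r = ref_alleles[site]
            if sg_s == (r, r) and ag_s == (r, r):
                continue  # both homozygous reference: disregarded
        shared += 1
        if sg_s == ag_s:
            matching += 1
    return ConcordanceResult(shared_sites=shared, matching_sites=matching)


# ---------------------------------------------------------------------------
# post-hoc allele-fraction refilter


def refilter_min_af(
    records: Sequence[VariantRecord], min_af: float
) -> List[VariantRecord]:
    """Keep records with allele fraction >= ``min_af`` (boundary inclusive).

    A post-hoc stand-in for re-running the caller with a raised
    minimum-allele-frequency parameter.  Records lacking an AF annotation
    are kept and counted in a warning.
    """
    if not 0.0 <= min_af <= 1.0:
        raise ValueError(f"min_af {min_af} outside [0, 1]")
    missing = sum(1 for v in records if v.af is None)
    if missing:
        logger.warning(
            "refilter_min_af: %d record(s) lack an AF annotation and were kept",
            missing,
        )
    return [v for v in records if v.af is None or v.af >= min_af]
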