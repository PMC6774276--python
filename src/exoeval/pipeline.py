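"""End-to-end evaluation pipeline and report rendering.

The pipeline reproduces the canonical optimization progression for a call
set benchmarked against a truth set:

* **VCF1** — raw calls restricted to the target region;
* **VCF2** — both sets regularized (decomposition + left alignment), which
  can only reveal additional matches on a normalized truth set;
* **VCF3** — comparison restricted to target ∩ high-confidence region,
  which removes difficult genome regions and with them most false
  positives at minimal true-positive cost;
* optional **VCF3+AF** — a post-hoc minimum-allele-fraction refilter.

The report carries per-stage TP/FN/FP partitions with stratified counts,
both FP-reduction baselines (VCF1→VCF3 and VCF2→VCF3), and a provenance
block (inputs, config hash, tool version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from . import __version__
from .compare import ComparisonResult, MetricPair, compare, fp_reduction, refilter_min_af
from .normalize import ReferenceSequence, VariantRecord, regularize
from .regions import RegionSet

logger = logging.getLogger(__name__)

__all__ = ["StageSnapshot", "PipelineReport", "run_pipeline", "render_report"]

STRATUM_ORDER = [
    ("total", "Total Variants"),
    ("snv", "Total SNVs"),
    ("exonic_snv", "Exonic SNVs"),
    ("indel", "Total Indels"),
    ("exonic_indel", "Exonic Indels"),
    ("other", "Other"),
]


@dataclass
class StageSnapshot:
    name: str
    comparison: ComparisonResult
    truth_total_raw: int  # truth records in region before truth normalization
    truth_total_normalized: int

    def to_dict(self) -> Dict:
        strata = {}
        for key, sc in self.comparison.strata.items():
            mp = sc.metric_pair
            strata[key] = {
                "total": sc.total,
                "truth": sc.truth,
                "tp": sc.tp,
                "fn": sc.fn,
                "fp": sc.fp,
                "sensitivity_pct": mp.sensitivity_pct,
                "ppv_pct": mp.ppv_pct,
            }
        return {
            "name": self.name,
            "truth_total_raw": self.truth_total_raw,
            "truth_total_normalized": self.truth_total_normalized,
            "strata": strata,
        }


@dataclass
class PipelineReport:
    stages: List[StageSnapshot]
    provenance: Dict
    fp_reductions: Dict[str, float] = field(default_factory=dict)
    classification: Optional[Dict] = None
    coverage: Optional[Dict] = None

    def stage(self, name: str) -> StageSnapshot:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_dict(self) -> Dict:
        d = {
            "provenance": self.provenance,
            "stages": [s.to_dict() for s in self.stages],
            "fp_reductions": self.fp_reductions,
        }
        if self.classification is not None:
            d["classification"] = self.classification
        if self.coverage is not None:
            d["coverage"] = self.coverage
        return d


def _config_hash(config: Dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    query: Sequence[VariantRecord],
    truth: Sequence[VariantRecord],
    reference: ReferenceSequence,
    target: RegionSet,
    hcr: RegionSet,
    coding: Optional[RegionSet] = None,
    min_af: Optional[float] = None,
    genotype_aware: bool = False,
    config: Optional[Dict] = None,
    inputs: Optional[Dict[str, str]] = None,
) -> PipelineReport:
    """Run the VCF1 → VCF2 → VCF3 (→ VCF3+AF) evaluation progression.

    The truth set is regularized with the same routine as the query;
    normalization is idempotent, so an already-normal truth set is
    unchanged.  Stage comparisons:

    1. ``VCF1`` — raw query vs raw truth, inside ``target``;
    2. ``VCF2`` — regularized query vs regularized truth, inside ``target``;
    3. ``VCF3`` — same call sets inside ``target ∩ hcr``;
    4. ``VCF3+AF`` (when ``min_af`` is given) — stage 3 after dropping
       query records with allele fraction below ``min_af``.
    """
    config = dict(config or {})
    config.setdefault("min_af", min_af)
    provenance = {
        "tool": "exoeval",
        "version": __version__,
        "inputs": dict(inputs or {}),
        "config": config,
        "config_hash": _config_hash(config),
    }

    stages: List[StageSnapshot] = []

    def snap(name: str, result: ComparisonResult, region: RegionSet,
             truth_norm: Sequence[VariantRecord]) -> None:
        raw_n = sum(1 for v in truth if region.contains_vcf_pos(v.chrom, v.pos))
        norm_n = sum(
            1 for v in truth_norm if region.contains_vcf_pos(v.chrom, v.pos)
        )
        stages.append(
            StageSnapshot(
                name=name,
                comparison=result,
                truth_total_raw=raw_n,
                truth_total_normalized=norm_n,
            )
        )
        mp = result.metric_pair
        logger.info(
            "stage %-8s region=%dbp truth=%d TP=%d FN=%d FP=%d sens=%s ppv=%s",
            name, region.total_bases, result.truth_size_in_region,
            len(result.tp), len(result.fn), len(result.fp),
            mp.sensitivity_pct, mp.ppv_pct,
        )

    # stage 1: raw comparison in the target region
    r1 = compare(query, truth, target, coding=coding,
                 require_normalized=False, genotype_aware=genotype_aware)
    snap("VCF1", r1, target, truth)

    # stage 2: regularized comparison in the target region
    query_n = regularize(query, reference)
    truth_n = regularize(truth, reference)
    r2 = compare(query_n, truth_n, target, coding=coding,
                 genotype_aware=genotype_aware)
    snap("VCF2", r2, target, truth_n)

    # stage 3: restriction to the high-confidence region
    region3 = target.intersect(hcr)
    r3 = compare(query_n, truth_n, region3, coding=coding,
                 genotype_aware=genotype_aware)
    snap("VCF3", r3, region3, truth_n)

    fp_reductions: Dict[str, float] = {}
    if len(r1.fp) > 0:
        fp_reductions["vcf1_to_vcf3"] = fp_reduction(len(r1.fp), len(r3.fp))
    if len(r2.fp) > 0:
        fp_reductions["vcf2_to_vcf3"] = fp_reduction(len(r2.fp), len(r3.fp))

    # stage 4 (optional): allele-fraction refilter
    if min_af is not None:
        query_f = refilter_min_af(query_n, min_af)
        r4 = compare(query_f, truth_n, region3, coding=coding,
                     genotype_aware=genotype_aware)
        snap("VCF3+AF", r4, region3, truth_n)
        if len(r3.fp) > 0:
            fp_reductions["vcf3_to_af"] = fp_reduction(len(r3.fp), len(r4.fp))

    return PipelineReport(
        stages=stages, provenance=provenance, fp_reductions=fp_reductions
    )


# ---------------------------------------------------------------------------
# rendering


def _fmt_pct(x: Optional[float]) -> str:
    return "NA" if x is None else f"{x:.2f}%"


def _table_rows(report: PipelineReport) -> List[List[str]]:
    rows = [
        [
            "Stage", "Stratum", "Total Variants", "Truth set",
            "TPs", "FNs", "FPs", "Sensitivity", "PPV",
        ]
    ]
    for stage in report.stages:
        for key, label in STRATUM_ORDER:
            sc = stage.comparison.strata.get(key)
            if sc is None or (key == "other" and sc.total + sc.truth == 0):
                continue
            mp = sc.metric_pair
            rows.append(
                [
                    stage.name, label, str(sc.total), str(sc.truth),
                    str(sc.tp), str(sc.fn), str(sc.fp),
                    _fmt_pct(mp.sensitivity_pct), _fmt_pct(mp.ppv_pct),
                ]
            )
    return rows


def render_report(report: PipelineReport, format: str = "tsv") -> str:
    """Serialize a report as ``tsv``, ``json`` or ``markdown``.

    The JSON form round-trips: loading it recovers every count.  Table
    forms mirror the conventional validation-table layout (stratum, total,
    truth, TP, FN, FP, sensitivity, PPV).
    """
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True)
    rows = _table_rows(report)
    if format == "tsv":
        return "\n".join("\t".join(r) for r in rows) + "\n"
    if format == "markdown":
        out = ["| " + " | ".join(rows[0]) + " |",
               "|" + "---|" * len(rows[0])]
        out += ["| " + " | ".join(r) + " |" for r in rows[1:]]
        if report.fp_reductions:
            out.append("")
            for k, v in sorted(report.fp_reductions.items()):
                out.append(f"- FP reduction {k.replace('_', ' ')}: {v}%")
        return "\n".join(out) + "\n"
    raise ValueError(f"unknown report format {format!r}")
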