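"""Quality / genotype-frequency / curation filter cascade.

Stage order and bookkeeping follow the usual SV-callset workflow: raw calls
are first screened on depth fold-change (DHFFC) and heterozygosity-score
(MSHQ) thresholds, then on a minimum number of carriers of each of the
three genotypes, and finally against an external manual-curation decision
file. Thresholds are strict/inclusive exactly as printed in the defaults:
DEL pass at dhffc < 0.7, DUP at dhffc > 1.3, and every type needs
mshq >= 3. Non-autosomal and multi-allelic records are removed in the
quality stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import SVRecord, SV_TYPES

logger = logging.getLogger("svload")

__all__ = [
    "FilterThresholds",
    "FilterReport",
    "apply_quality_filters",
    "apply_genotype_frequency_filter",
    "apply_curation",
    "filter_cascade",
]

STAGES = ("raw", "quality", "genotype_frequency", "curation")


@dataclass(frozen=True)
class FilterThresholds:
    dhffc_del_max: float = 0.7  # DEL passes strictly below
    dhffc_dup_min: float = 1.3  # DUP passes strictly above
    mshq_min: float = 3.0  # inclusive, all types
    min_per_genotype: int = 2

    def __post_init__(self) -> None:
        if min(self.dhffc_del_max, self.dhffc_dup_min, self.mshq_min) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.min_per_genotype < 0:
            raise ValueError("min_per_genotype must be non-negative")


@dataclass
class FilterReport:
    """Per-stage, per-SV-type locus counts plus a per-locus fate label."""

    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    fates: dict[str, str] = field(default_factory=dict)

    def record_stage(self, stage: str, records: list[SVRecord]) -> None:
        counts = {t: 0 for t in SV_TYPES}
        for r in records:
            counts[r.svtype] += 1
        counts["Total"] = len(records)
        self.stage_counts[stage] = counts

    def set_fates(self, records: list[SVRecord], fate: str) -> None:
        for r in records:
            self.fates[r.variant_id] = fate

    def removal_fractions(self) -> dict[str, float]:
        """Fraction of raw calls removed by the full cascade, per type."""
        raw = self.stage_counts["raw"]
        final_stage = [s for s in STAGES if s in self.stage_counts][-1]
        final = self.stage_counts[final_stage]
        return {
            t: (1.0 - final[t] / raw[t]) if raw[t] else 0.0
            for t in (*SV_TYPES, "Total")
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": s, **c} for s, c in self.stage_counts.items()
        ]
        return pd.DataFrame(rows)


def apply_quality_filters(
    records: list[SVRecord],
    thresholds: FilterThresholds = FilterThresholds(),
    missing_dhffc: str = "drop",
    report: FilterReport | None = None,
) -> tuple[list[SVRecord], FilterReport]:
    """Depth/heterozygosity quality screen plus autosomal/biallelic gate.

    DEL passes iff dhffc < dhffc_del_max and mshq >= mshq_min; DUP passes
    iff dhffc > dhffc_dup_min and mshq >= mshq_min; INV needs only the mshq
    criterion (depth fold-change carries no signal for balanced events, so
    a missing dhffc on an INV is permitted).

    ``missing_dhffc`` chooses what to do with a DEL/DUP lacking dhffc:
    ``"drop"`` (default, logged) or ``"error"``.
    """
    if missing_dhffc not in ("drop", "error"):
        raise ValueError("missing_dhffc must be 'drop' or 'error'")
    report = report or FilterReport()
    if "raw" not in report.stage_counts:
        report.record_stage("raw", records)
    passing: list[SVRecord] = []
    n_nodhffc = 0
    for r in records:
        if not (r.is_autosomal and r.is_biallelic):
            report.fates[r.variant_id] = "FAIL_NOT_AUTOSOMAL_BIALLELIC"
            continue
        if r.svtype in ("DEL", "DUP") and np.isnan(r.dhffc):
            if missing_dhffc == "error":
                raise ValueError(f"{r.variant_id}: {r.svtype} lacks DHFFC")
            n_nodhffc += 1
            report.fates[r.variant_id] = "FAIL_MISSING_DHFFC"
            continue
        mshq_ok = not np.isnan(r.mshq) and r.mshq >= thresholds.mshq_min
        if r.svtype == "DEL":
            ok = mshq_ok and r.dhffc < thresholds.dhffc_del_max
        elif r.svtype == "DUP":
            ok = mshq_ok and r.dhffc > thresholds.dhffc_dup_min
        else:
            ok = mshq_ok
        if ok:
            passing.append(r)
        else:
            report.fates[r.variant_id] = "FAIL_QUALITY"
    if n_nodhffc:
        logger.warning("quality filter: dropped %d DEL/DUP records lacking DHFFC", n_nodhffc)
    report.record_stage("quality", passing)
    return passing, report


def apply_genotype_frequency_filter(
    records: list[SVRecord],
    min_per_genotype: int = 2,
    report: FilterReport | None = None,
) -> tuple[list[SVRecord], FilterReport]:
    """Require at least ``min_per_genotype`` individuals of each genotype.

    Counts are taken over non-missing calls only, so a locus with enough
    called carriers passes regardless of additional missing genotypes.
    """
    report = report or FilterReport()
    if "raw" not in report.stage_counts:
        report.record_stage("raw", records)
    passing: list[SVRecord] = []
    for r in records:
        g = r.genotypes
        counts = [(g == k).sum() for k in (0, 1, 2)]
        if min(counts) >= min_per_genotype:
            passing.append(r)
        else:
            report.fates[r.variant_id] = "FAIL_GENOTYPE_FREQUENCY"
    report.record_stage("genotype_frequency", passing)
    return passing, report


def apply_curation(
    records: list[SVRecord],
    decisions: dict[str, str],
    absent_policy: str = "reject",
    report: FilterReport | None = None,
) -> tuple[list[SVRecord], FilterReport]:
    """Apply an external curation decision file (variant_id -> ACCEPT/REJECT).

    ``absent_policy`` handles ids with no decision: ``"reject"`` (default),
    ``"accept"`` or ``"error"``.
    """
    if absent_policy not in ("reject", "accept", "error"):
        raise ValueError("absent_policy must be reject/accept/error")
    bad = {v for v in decisions.values()} - {"ACCEPT", "REJECT"}
    if bad:
        raise ValueError(f"unknown curation decisions {sorted(bad)}")
    report = report or FilterReport()
    if "raw" not in report.stage_counts:
        report.record_stage("raw", records)
    passing: list[SVRecord] = []
    for r in records:
        d = decisions.get(r.variant_id)
        if d is None:
            if absent_policy == "error":
                raise ValueError(f"{r.variant_id}: no curation decision")
            d = "ACCEPT" if absent_policy == "accept" else "REJECT"
        if d == "ACCEPT":
            passing.append(r)
        else:
            report.fates[r.variant_id] = "FAIL_CURATION"
    report.record_stage("curation", passing)
    return passing, report


def filter_cascade(
    records: list[SVRecord],
    thresholds: FilterThresholds = FilterThresholds(),
    decisions: dict[str, str] | None = None,
    absent_policy: str = "reject",
    second_decisions: dict[str, str] | None = None,
) -> tuple[list[SVRecord], FilterReport]:
    """Run quality -> genotype-frequency -> curation in order.

    The genotype-frequency stage counts genotypes on the post-quality set,
    and curation applies to the post-genotype-frequency set, so stage counts
    are non-increasing per SV type. If ``decisions`` is None the curation
    stage is skipped (all genotype-frequency survivors accepted).

    ``second_decisions``, when given, is a second curator's decision file:
    the report gains the size of the ACCEPT-intersection as a concordance
    summary (the accepted set itself always follows ``decisions``).
    """
    report = FilterReport()
    report.record_stage("raw", records)
    passing, report = apply_quality_filters(records, thresholds, report=report)
    passing, report = apply_genotype_frequency_filter(
        passing, thresholds.min_per_genotype, report=report
    )
    if decisions is not None:
        passing, report = apply_curation(passing, decisions, absent_policy, report=report)
        if second_decisions is not None:
            a = {v for v, d in decisions.items() if d == "ACCEPT"}
            b = {v for v, d in second_decisions.items() if d == "ACCEPT"}
            report.stage_counts["curation"]["second_curator_accept_intersection"] = len(a & b)
    report.set_fates(passing, "PASS")
    return passing, report
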