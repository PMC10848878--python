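"""Filter cascade semantics: thresholds, genotype counts, curation, bookkeeping."""

import pytest

from svload.filtering import (
    FilterThresholds,
    apply_curation,
    apply_genotype_frequency_filter,
    apply_quality_filters,
    filter_cascade,
)
from svload.simulate import decisions_from_truth
from svload.types import SV_TYPES


@pytest.mark.parametrize(
    "svtype,dhffc,mshq,passes",
    [
        ("DEL", 0.5, 4.0, True),
        ("DEL", 0.7, 4.0, False),  # strict <0.7
        ("DEL", 0.69, 2.9, False),
        ("DUP", 1.3, 4.0, False),  # strict >1.3
        ("DUP", 1.31, 4.0, True),
        ("INV", float("nan"), 3.0, True),  # inclusive >=3; dhffc not needed
        ("INV", float("nan"), 2.9, False),
    ],
)
def test_quality_threshold_boundaries(mk_record, svtype, dhffc, mshq, passes):
    rec = mk_record([0, 1, 2], svtype=svtype, dhffc=dhffc, mshq=mshq)
    out, _ = apply_quality_filters([rec])
    assert (len(out) == 1) is passes


def test_quality_removes_non_autosomal_and_multiallelic(mk_record):
    recs = [
        mk_record([0, 1, 2], variant_id="x", chrom="chrX", is_autosomal=False),
        mk_record([0, 1, 2], variant_id="m", is_biallelic=False),
        mk_record([0, 1, 2], variant_id="ok"),
    ]
    out, rep = apply_quality_filters(recs)
    assert [r.variant_id for r in out] == ["ok"]
    assert rep.fates["x"] == rep.fates["m"] == "FAIL_NOT_AUTOSOMAL_BIALLELIC"


def test_missing_dhffc_policy(mk_record):
    rec = mk_record([0, 1, 2], svtype="DEL", dhffc=float("nan"))
    out, _ = apply_quality_filters([rec])
    assert out == []
    with pytest.raises(ValueError, match="lacks DHFFC"):
        apply_quality_filters([rec], missing_dhffc="error")


@pytest.mark.parametrize(
    "counts,passes",
    [
        ((2, 2, 2, 0), True),  # boundary
        ((200, 10, 1, 0), False),
        ((2, 2, 2, 50), True),  # missing excluded from counts
        ((1, 5, 5, 0), False),
    ],
)
def test_genotype_frequency_counts(mk_record, counts, passes):
    n_rr, n_het, n_aa, n_miss = counts
    g = [0] * n_rr + [1] * n_het + [2] * n_aa + [-1] * n_miss
    out, _ = apply_genotype_frequency_filter([mk_record(g)], min_per_genotype=2)
    assert (len(out) == 1) is passes


def test_curation_policies(mk_record):
    recs = [mk_record([0, 1, 2], variant_id=v) for v in "abc"]
    out, _ = apply_curation(recs, {"a": "ACCEPT", "b": "REJECT"}, absent_policy="reject")
    assert [r.variant_id for r in out] == ["a"]
    out, _ = apply_curation(recs, {}, absent_policy="accept")
    assert len(out) == 3
    with pytest.raises(ValueError, match="no curation decision"):
        apply_curation(recs, {"a": "ACCEPT"}, absent_policy="error")


def test_cascade_counts_are_non_increasing_and_consistent(small_cohort):
    decisions = decisions_from_truth(small_cohort.truth)
    final, report = filter_cascade(small_cohort.records, FilterThresholds(), decisions)
    stages = list(report.stage_counts)
    assert stages == ["raw", "quality", "genotype_frequency", "curation"]
    for t in (*SV_TYPES, "Total"):
        col = [report.stage_counts[s][t] for s in stages]
        assert col == sorted(col, reverse=True)
    for s in stages:
        c = report.stage_counts[s]
        assert c["Total"] == sum(c[t] for t in SV_TYPES)
    # fates partition the input
    assert len(report.fates) == len(small_cohort.records)
    assert sum(f == "PASS" for f in report.fates.values()) == len(final)


def test_filters_are_idempotent(small_cohort):
    decisions = decisions_from_truth(small_cohort.truth)
    once, _ = filter_cascade(small_cohort.records, FilterThresholds(), decisions)
    twice, rep2 = filter_cascade(once, FilterThresholds(), decisions)
    assert [r.variant_id for r in twice] == [r.variant_id for r in once]
    assert all(
        rep2.stage_counts[s]["Total"] == len(once) for s in rep2.stage_counts
    )


def test_truth_decisions_recover_exactly_the_true_loci(small_cohort):
    """Curation with truth labels accepts exactly the non-artifact loci."""
    t = small_cohort.truth
    decisions = decisions_from_truth(t)
    accepted, _ = apply_curation(small_cohort.records, decisions)
    expected = {v for v, a in zip(t.variant_ids, t.injected_artifact) if not a}
    assert {r.variant_id for r in accepted} == expected


def test_threshold_validation():
    with pytest.raises(ValueError):
        FilterThresholds(dhffc_del_max=-1)
    with pytest.raises(ValueError):
        FilterThresholds(min_per_genotype=-2)
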