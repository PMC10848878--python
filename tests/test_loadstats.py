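"""SFS construction, goodness-of-fit, load summaries, rank test, rescue."""

import itertools

import numpy as np
import pytest

from svload.annotate import polarize
from svload.loadstats import (
    build_sfs,
    compare_groups,
    derived_allele_frequency,
    fixation_and_rescue,
    individual_load,
    load_by_group,
    sfs_gof_test,
)
from svload.types import OverlapCategory, SampleInfo


def _call(mk_record, ancestral, svtype="DEL"):
    og = (0, 0) if ancestral == "REF" else (2, 2)
    return polarize(mk_record([0], svtype=svtype), og)


# ---------------------------------------------------------------------------
# Derived allele frequency
# ---------------------------------------------------------------------------


def test_derived_frequency_arithmetic(mk_record):
    call = _call(mk_record, "REF")
    # 40 individuals, 4 derived alleles
    g = [1] * 4 + [0] * 36
    rec = mk_record(g)
    assert derived_allele_frequency(rec, call, np.arange(40)) == pytest.approx(0.05)
    rec = mk_record([1] * 40)
    assert derived_allele_frequency(rec, call, np.arange(40)) == pytest.approx(0.5)
    # polarity flip: ancestral=ALT, everyone HOM_REF -> derived freq 1
    flip = _call(mk_record, "ALT")
    rec = mk_record([0] * 40)
    assert derived_allele_frequency(rec, flip, np.arange(40)) == pytest.approx(1.0)


def test_derived_frequency_errors(mk_record):
    unpol = polarize(mk_record([0]), (0, 2))
    with pytest.raises(ValueError, match="unpolarized"):
        derived_allele_frequency(mk_record([0, 1]), unpol, np.arange(2))
    call = _call(mk_record, "REF")
    with pytest.raises(ValueError, match="no non-missing"):
        derived_allele_frequency(mk_record([-1, -1]), call, np.arange(2))


# ---------------------------------------------------------------------------
# SFS
# ---------------------------------------------------------------------------


def test_sfs_binning_and_monomorphic_exclusion(mk_record):
    # 50 samples: frequencies 0.04, 0.05, 0.93 and one fixed locus
    recs = [
        mk_record([1] * 4 + [0] * 46, variant_id="f04"),
        mk_record([1] * 5 + [0] * 45, variant_id="f05"),
        mk_record([2] * 43 + [1] * 7, variant_id="f93"),
        mk_record([2] * 50, variant_id="fixed"),
    ]
    calls = {r.variant_id: _call(mk_record, "REF") for r in recs}
    for vid, c in calls.items():
        c.variant_id = vid
    cats = {r.variant_id: OverlapCategory.PARTIAL_CDS for r in recs}
    sfs = build_sfs(recs, calls, np.arange(50), cats, "DELETERIOUS")
    assert sfs.counts.sum() == 3  # fixed locus excluded
    assert sfs.counts[0] == 1  # 0.04 in [0, 0.05)
    assert sfs.counts[1] == 1  # 0.05 in [0.05, 0.10)
    assert sfs.counts[18] == 1  # 0.93 in [0.90, 0.95)


def test_sfs_gof_worked_example_and_degenerate_cases():
    # proportional spectra: statistic 0, p 1
    stat, df, p = sfs_gof_test(np.array([50, 30, 20]), np.array([500, 300, 200]))
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    # hand computation: obs (10,0), equal expected proportions -> 10.0 on 1 df
    stat, df, p = sfs_gof_test(np.array([10, 0]), np.array([5, 5]))
    assert stat == pytest.approx(10.0)
    assert df == 1
    assert p == pytest.approx(0.001565, rel=1e-3)
    with pytest.raises(ValueError, match="degenerate"):
        sfs_gof_test(np.array([2, 1]), np.array([3, 1]))


def test_sfs_gof_statistic_scales_with_total_count():
    obs = np.array([30, 10, 10])
    neu = np.array([200, 200, 100])
    s1, _, _ = sfs_gof_test(obs, neu)
    s2, _, _ = sfs_gof_test(obs * 3, neu)
    assert s2 == pytest.approx(3 * s1)


# ---------------------------------------------------------------------------
# Individual load
# ---------------------------------------------------------------------------


def test_individual_load_fractions(mk_record):
    sample_ids = ["s"]
    recs = []
    for i, g in enumerate([1] * 4 + [2] * 3 + [0] * 3):
        recs.append(mk_record([g], variant_id=f"v{i}"))
    ra = {r.variant_id for r in recs}
    ls = individual_load(recs, ra, "s", sample_ids)
    assert (ls.masked_load, ls.realized_load) == (0.4, 0.3)
    assert ls.n_het + ls.n_hom_derived + ls.n_hom_ancestral == ls.n_loci_called

    all_ref = [mk_record([0], variant_id=f"r{i}") for i in range(5)]
    ls = individual_load(all_ref, {r.variant_id for r in all_ref}, "s", sample_ids)
    assert ls.masked_load == 0.0 and ls.realized_load == 0.0

    ls = individual_load([], set(), "s", sample_ids)
    assert ls.masked_load is None and ls.realized_load is None


def test_load_by_group_equal_genotypes_give_equal_means(mk_record):
    infos = [
        SampleInfo("a", "SCAND_ORIGINAL", generation_class="F1"),
        SampleInfo("b", "SCAND_ORIGINAL", generation_class="F2"),
        SampleInfo("c", "FINLAND"),
    ]
    ids = ["a", "b", "c"]
    recs = [mk_record([1, 1, 1], variant_id=f"v{i}") for i in range(10)]
    ra = {r.variant_id for r in recs}
    summaries = [individual_load(recs, ra, s, ids) for s in ids]
    df = load_by_group(summaries, infos).set_index("group")
    assert df.loc["F1", "masked_mean"] == df.loc["F2", "masked_mean"] == df.loc["FINLAND", "masked_mean"] == 1.0
    assert list(df.index) == ["F1", "F2", "FINLAND"]


# ---------------------------------------------------------------------------
# Rank-sum test
# ---------------------------------------------------------------------------


def brute_force_ranksum_p(a, b):
    """Oracle: enumerate every assignment of pooled values to group a."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w_obs = ranks[: len(a)].sum()
    ws = [
        sum(ranks[list(c)])
        for c in itertools.combinations(range(len(pooled)), len(a))
    ]
    n = len(ws)
    p_le = sum(w <= w_obs + 1e-9 for w in ws) / n
    p_ge = sum(w >= w_obs - 1e-9 for w in ws) / n
    return min(1.0, 2 * min(p_le, p_ge))


def test_ranksum_examples():
    _, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == pytest.approx(1.0)
    _, p = compare_groups([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1)  # 2/20 most extreme assignments
    _, p = compare_groups([5, 5], [5, 5, 5])
    assert p == 1.0
    with pytest.raises(ValueError):
        compare_groups([], [1])


def test_ranksum_matches_enumeration_with_ties():
    rng = np.random.default_rng(5)
    for _ in range(30):
        n = rng.integers(2, 9)
        na = rng.integers(1, n)
        vals = rng.integers(0, 4, size=n).astype(float)  # heavy ties
        a, b = vals[:na], vals[na:]
        _, p = compare_groups(a, b)
        assert p == pytest.approx(brute_force_ranksum_p(a, b), abs=1e-12)


def test_ranksum_large_samples_use_normal_approximation():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 1, 30)
    b = rng.normal(1, 1, 30)
    _, p = compare_groups(a, b)
    from scipy.stats import mannwhitneyu

    assert p == pytest.approx(mannwhitneyu(a, b, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# Fixation / rescue
# ---------------------------------------------------------------------------


def test_fixation_and_rescue_rules(mk_record):
    pre = np.arange(6)
    post = np.arange(6, 9)
    calls = {}
    recs = []
    # fixed pre (all hom-derived), regained post via one HET
    recs.append(mk_record([2] * 6 + [2, 1, 2], variant_id="fx"))
    calls["fx"] = polarize(mk_record([0], variant_id="fx"), (0, 0))
    # a single HET pre -> not fixed
    recs.append(mk_record([2] * 5 + [1] + [2] * 3, variant_id="nf"))
    calls["nf"] = polarize(mk_record([0], variant_id="nf"), (0, 0))
    # ancestral=ALT flavour: hom-derived is HOM_REF
    recs.append(mk_record([0] * 6 + [0, 0, 1], variant_id="flip"))
    calls["flip"] = polarize(mk_record([0], variant_id="flip"), (2, 2))
    # fixed pre but never regained
    recs.append(mk_record([2] * 9, variant_id="stuck"))
    calls["stuck"] = polarize(mk_record([0], variant_id="stuck"), (0, 0))
    for vid, c in calls.items():
        c.variant_id = vid

    rep = fixation_and_rescue(recs, calls, pre, post, min_called=5)
    assert set(rep.fixed_pre_ids) == {"fx", "flip", "stuck"}
    assert rep.n_regained == 2
    assert set(rep.founder_fixed_ids) == {"fx", "flip", "stuck"}

    # too few called individuals -> not fixed
    sparse = [mk_record([2, 2, -1, -1, -1, -1] + [1, 2, 2], variant_id="sp")]
    calls_sp = {"sp": polarize(mk_record([0], variant_id="sp"), (0, 0))}
    calls_sp["sp"].variant_id = "sp"
    rep = fixation_and_rescue(sparse, calls_sp, pre, post, min_called=5)
    assert rep.n_fixed_pre == 0

    with pytest.raises(ValueError, match="non-empty"):
        fixation_and_rescue(recs, calls, np.array([]), post)
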