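"""Gene-overlap categories, repeat attribution, length spectra, polarization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from svload.annotate import (
    classify_gene_overlap,
    length_spectrum,
    peak_composition,
    polarize,
    polarize_all,
    reference_ancestral_subset,
    repeat_composition,
)
from svload.types import (
    Ancestral,
    GeneModel,
    MutationClass,
    OverlapCategory,
    RepeatFeature,
)


@pytest.fixture
def genes():
    return [
        GeneModel("enclosed", "chr1", (200, 800), [(300, 400)]),
        GeneModel("partial", "chr1", (2000, 4000), [(2500, 2600), (3500, 3600)]),
        GeneModel("intronic_host", "chr1", (10_000, 20_000), [(10_000, 10_100), (19_900, 20_000)]),
    ]


@pytest.mark.parametrize(
    "pos,end,expected,hits",
    [
        (100, 1000, OverlapCategory.ENCLOSING, ["enclosed"]),
        (2450, 2550, OverlapCategory.PARTIAL_CDS, ["partial"]),
        (12_000, 13_000, OverlapCategory.NONCODING, ["intronic_host"]),
        (50_000, 50_100, OverlapCategory.INTERGENIC, []),
    ],
)
def test_gene_overlap_categories(mk_record, genes, pos, end, expected, hits):
    rec = mk_record([0, 1, 2], pos=pos, end=end)
    cat, gene_ids = classify_gene_overlap(rec, genes)
    assert cat is expected
    assert gene_ids == hits


def test_gene_overlap_priority_and_order_invariance(mk_record, genes):
    """A variant enclosing one gene and hitting another's CDS is ENCLOSING,
    whatever the input order of the gene list."""
    rec = mk_record([0, 1, 2], pos=150, end=2550)
    for perm in itertools.permutations(genes):
        cat, gene_ids = classify_gene_overlap(rec, list(perm))
        assert cat is OverlapCategory.ENCLOSING
        assert gene_ids == ["enclosed"]


def _oracle_composition(rec, feats):
    """Per-base brute force with the smaller-start / lexicographic tie rule."""
    counts: dict[str, int] = {}
    for base in range(rec.pos, rec.end + 1):
        covering = sorted(
            (f for f in feats if f.chrom == rec.chrom and f.start <= base <= f.end),
            key=lambda f: (f.start, f.repeat_class),
        )
        if covering:
            cls = covering[0].repeat_class
            counts[cls] = counts.get(cls, 0) + 1
    return counts


def test_repeat_composition_examples(mk_record):
    rec = mk_record([0], pos=1, end=100)
    comp = repeat_composition(rec, [RepeatFeature("chr1", 20, 79, "SINE")])
    assert comp.bases_per_class == {"SINE": 60}
    assert comp.unannotated_bases == 40

    # variant-local SINE [10,60] and LINE [50,80]: overlap goes to SINE
    feats = [RepeatFeature("chr1", 10, 60, "SINE"), RepeatFeature("chr1", 50, 80, "LINE")]
    comp = repeat_composition(rec, feats)
    assert comp.bases_per_class == {"SINE": 51, "LINE": 20}
    assert comp.bases_per_class == _oracle_composition(rec, feats)

    assert repeat_composition(rec, []).unannotated_bases == 100


@settings(derandomize=True, max_examples=60)
@given(
    st.lists(
        st.tuples(
            st.integers(1, 120),
            st.integers(0, 60),
            st.sampled_from(["SINE", "LINE", "LTR", "DNA"]),
        ),
        max_size=8,
    )
)
def test_repeat_attribution_matches_per_base_oracle(layout):
    from svload.types import SVRecord

    rec = SVRecord("v1", "chr1", 20, 119, "DEL", 100, np.zeros(1, np.int8))
    feats = [RepeatFeature("chr1", s, s + w, cls) for s, w, cls in layout]
    comp = repeat_composition(rec, feats)
    assert comp.bases_per_class == _oracle_composition(rec, feats)
    assert comp.total() == rec.length


def test_length_spectrum_binning(mk_record):
    recs = [
        mk_record([0], variant_id="a", length=190),
        mk_record([0], variant_id="b", length=190),
        mk_record([0], variant_id="c", length=500),
    ]
    edges, counts = length_spectrum(recs, bin_width=10)["DEL"]
    assert counts[np.searchsorted(edges, 190)] == 2
    with pytest.raises(ValueError):
        length_spectrum(recs, bin_width=0)


def test_peak_composition_empty_window(mk_record):
    recs = [mk_record([0], length=500)]
    assert peak_composition(recs, [], (180, 200)) == {"unannotated": 0.0}


def test_del_peak_is_sine_dominated(small_cohort):
    """Peak-length deletions carry the simulator's SINE coupling."""
    comp = peak_composition(
        small_cohort.records, small_cohort.repeats, (180, 200), svtype="DEL"
    )
    assert comp.get("SINE", 0) > 0.8


@pytest.mark.parametrize(
    "og,svtype,ancestral,mclass",
    [
        ((0, 0), "DEL", Ancestral.REF, MutationClass.TRUE_DELETION),
        ((2, 2), "DEL", Ancestral.ALT, MutationClass.INSERTION),
        ((0, 0), "DUP", Ancestral.REF, MutationClass.COPY_GAIN),
        ((2, 2), "DUP", Ancestral.ALT, MutationClass.COPY_LOSS_IN_REFERENCE),
        ((0, 0), "INV", Ancestral.REF, MutationClass.INVERSION_DERIVED),
        ((2, 2), "INV", Ancestral.ALT, MutationClass.INVERSION_ANCESTRAL_REF),
        ((0, 2), "DEL", Ancestral.UNPOLARIZED, MutationClass.UNPOLARIZED),
        ((1, 0), "DEL", Ancestral.UNPOLARIZED, MutationClass.UNPOLARIZED),
        ((-1, 0), "DEL", Ancestral.UNPOLARIZED, MutationClass.UNPOLARIZED),
    ],
)
def test_polarization_rules(mk_record, og, svtype, ancestral, mclass):
    rec = mk_record([0, 1, 2], svtype=svtype, dhffc=0.5 if svtype == "DEL" else 1.5)
    call = polarize(rec, og)
    assert call.ancestral is ancestral
    assert call.mutation_class is mclass


def test_polarization_symmetric_in_outgroups(mk_record):
    rec = mk_record([0, 1, 2])
    for g1, g2 in itertools.product((-1, 0, 1, 2), repeat=2):
        assert polarize(rec, (g1, g2)).ancestral is polarize(rec, (g2, g1)).ancestral


def test_polarize_requires_two_outgroups(mk_record):
    with pytest.raises(ValueError, match="two outgroup"):
        polarize(mk_record([0]), (0, 0, 0))


def test_reference_ancestral_subset(mk_record):
    calls = {
        "a": polarize(mk_record([0], variant_id="a"), (0, 0)),
        "b": polarize(mk_record([0], variant_id="b"), (2, 2)),
        "c": polarize(mk_record([0], variant_id="c"), (0, 2)),
    }
    assert reference_ancestral_subset(calls) == {"a"}
    assert reference_ancestral_subset({}) == set()


def test_polarization_recovers_simulated_truth(small_cohort):
    """Wherever both outgroups are concordant-homozygous, the assigned
    ancestral allele equals the simulator's truth."""
    t = small_cohort.truth
    calls = polarize_all(small_cohort.records, small_cohort.outgroup_genotypes, t.variant_ids)
    n_checked = 0
    for i, vid in enumerate(t.variant_ids):
        og = small_cohort.outgroup_genotypes[:, i]
        call = calls[vid]
        if og[0] == og[1] and og[0] in (0, 2):
            assert call.ancestral.value == t.ancestral_allele[i]
            n_checked += 1
        else:
            assert call.ancestral is Ancestral.UNPOLARIZED
    assert n_checked > 100
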