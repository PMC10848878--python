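"""Gene-overlap classes, repeat composition, length spectra, polarization.

Gene overlap uses a fixed priority so every variant lands in exactly one
category: ENCLOSING (the variant contains at least one whole gene span),
then PARTIAL_CDS (>= 1 coding base overlapped), then NONCODING (overlaps a
gene but only intron/UTR), else INTERGENIC.

Repeat composition attributes each variant base to at most one repeat
class; where annotations overlap, the feature with the smaller start wins
(ties broken by lexicographic class name), so the per-class counts plus the
unannotated remainder always sum exactly to the variant length.

Polarization uses two outgroup genotype calls per locus: the ancestral
allele is assigned only when both outgroups are homozygous for the same
allele; any disagreement, heterozygosity or missingness leaves the locus
unpolarized. The call also resolves what the caller's label really was:
a "deletion" whose ALT allele is ancestral is an insertion in the
reference lineage, and so on for duplications and inversions.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
from intervaltree import IntervalTree

from .types import (
    Ancestral,
    GeneModel,
    Genotype,
    MutationClass,
    OverlapCategory,
    PolarizedCall,
    RepeatComposition,
    RepeatFeature,
    SVRecord,
)

__all__ = [
    "GeneIndex",
    "classify_gene_overlap",
    "repeat_composition",
    "length_spectrum",
    "peak_composition",
    "polarize",
    "polarize_all",
    "reference_ancestral_subset",
]


class GeneIndex:
    """Per-chromosome interval index over gene spans and CDS intervals."""

    def __init__(self, genes: list[GeneModel]):
        self.span_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.cds_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g in genes:
            lo, hi = g.gene_span
            self.span_trees[g.chrom][lo : hi + 1] = g
            for s, e in g.cds_intervals:
                self.cds_trees[g.chrom][s : e + 1] = g


def classify_gene_overlap(
    record: SVRecord, genes: list[GeneModel] | GeneIndex
) -> tuple[OverlapCategory, list[str]]:
    """Assign the variant to exactly one gene-overlap category.

    Returns the category and the ids of the genes that triggered it
    (enclosed genes for ENCLOSING, CDS-overlapped genes for PARTIAL_CDS,
    overlapped genes for NONCODING, empty for INTERGENIC).
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    lo, hi = record.pos, record.end
    spans = index.span_trees.get(record.chrom, IntervalTree()).overlap(lo, hi + 1)
    enclosed = sorted(
        {iv.data.gene_id for iv in spans if lo <= iv.data.gene_span[0] and iv.data.gene_span[1] <= hi}
    )
    if enclosed:
        return OverlapCategory.ENCLOSING, enclosed
    cds_hits = index.cds_trees.get(record.chrom, IntervalTree()).overlap(lo, hi + 1)
    if cds_hits:
        return OverlapCategory.PARTIAL_CDS, sorted({iv.data.gene_id for iv in cds_hits})
    if spans:
        return OverlapCategory.NONCODING, sorted({iv.data.gene_id for iv in spans})
    return OverlapCategory.INTERGENIC, []


def repeat_composition(
    record: SVRecord, repeats: list[RepeatFeature]
) -> RepeatComposition:
    """Attribute every base of the variant to one repeat class (or none).

    Overlapping annotations are resolved deterministically: features are
    applied in (start, class-name) order and a base keeps its first
    assignment, i.e. the smaller-start feature wins, ties by lexicographic
    class name.
    """
    length = record.length
    span_len = record.end - record.pos + 1
    assigned = np.zeros(span_len, dtype=bool)
    counts: dict[str, int] = defaultdict(int)
    feats = sorted(
        (f for f in repeats if f.chrom == record.chrom and f.start <= record.end and f.end >= record.pos),
        key=lambda f: (f.start, f.repeat_class),
    )
    for f in feats:
        lo = max(f.start, record.pos) - record.pos
        hi = min(f.end, record.end) - record.pos  # inclusive, variant-local
        window = assigned[lo : hi + 1]
        n_new = int((~window).sum())
        if n_new:
            counts[f.repeat_class] += n_new
            window[:] = True
    annotated = int(assigned.sum())
    # when SVLEN and coordinates disagree, scale bookkeeping to the span
    unannotated = span_len - annotated + (length - span_len)
    return RepeatComposition(
        variant_id=record.variant_id,
        bases_per_class=dict(counts),
        unannotated_bases=unannotated,
    )


def length_spectrum(
    records: list[SVRecord], bin_width: int = 10
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Histogram of SV lengths per type.

    Returns ``{svtype: (bin_edges, counts)}`` with bins ``[k*w, (k+1)*w)``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for svtype in sorted({r.svtype for r in records}):
        lens = np.array([r.length for r in records if r.svtype == svtype])
        top = (int(lens.max()) // bin_width + 1) * bin_width
        edges = np.arange(0, top + bin_width, bin_width)
        counts, _ = np.histogram(lens, bins=edges)
        out[svtype] = (edges, counts)
    return out


def peak_composition(
    records: list[SVRecord],
    repeats: list[RepeatFeature],
    window: tuple[int, int],
    svtype: str | None = None,
) -> dict[str, float]:
    """Aggregate repeat composition of variants in a closed length window.

    Returns base-count proportions per repeat class (plus ``unannotated``);
    an empty selection gives an all-zero composition.
    """
    lo, hi = window
    sel = [
        r
        for r in records
        if lo <= r.length <= hi and (svtype is None or r.svtype == svtype)
    ]
    totals: dict[str, int] = defaultdict(int)
    grand = 0
    for r in sel:
        comp = repeat_composition(r, repeats)
        for cls, n in comp.bases_per_class.items():
            totals[cls] += n
        totals["unannotated"] += comp.unannotated_bases
        grand += comp.total()
    if grand == 0:
        return {"unannotated": 0.0}
    return {cls: n / grand for cls, n in sorted(totals.items())}


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------

_CLASS_BY_TYPE = {
    ("DEL", Ancestral.REF): MutationClass.TRUE_DELETION,
    ("DEL", Ancestral.ALT): MutationClass.INSERTION,
    ("DUP", Ancestral.REF): MutationClass.COPY_GAIN,
    ("DUP", Ancestral.ALT): MutationClass.COPY_LOSS_IN_REFERENCE,
    ("INV", Ancestral.REF): MutationClass.INVERSION_DERIVED,
    ("INV", Ancestral.ALT): MutationClass.INVERSION_ANCESTRAL_REF,
}


def polarize(record: SVRecord, outgroup_genotypes: tuple[int, int]) -> PolarizedCall:
    """Assign ancestral/derived state from two outgroup genotype calls.

    The ancestral allele is REF iff both outgroups are homozygous
    reference, ALT iff both are homozygous alternative; everything else
    (disagreement, heterozygosity, missingness) is UNPOLARIZED. The result
    is symmetric in the two outgroups.
    """
    if len(outgroup_genotypes) != 2:
        raise ValueError(f"exactly two outgroup genotypes required, got {len(outgroup_genotypes)}")
    g1, g2 = (int(g) for g in outgroup_genotypes)
    if g1 == g2 == Genotype.HOM_REF:
        ancestral = Ancestral.REF
    elif g1 == g2 == Genotype.HOM_ALT:
        ancestral = Ancestral.ALT
    else:
        ancestral = Ancestral.UNPOLARIZED
    if ancestral is Ancestral.UNPOLARIZED:
        mclass = MutationClass.UNPOLARIZED
    else:
        mclass = _CLASS_BY_TYPE[(record.svtype, ancestral)]
    return PolarizedCall(variant_id=record.variant_id, ancestral=ancestral, mutation_class=mclass)


def polarize_all(
    records: list[SVRecord], outgroup_genotypes: np.ndarray, variant_ids: list[str]
) -> dict[str, PolarizedCall]:
    """Polarize a record list against a (2, n_loci) outgroup genotype matrix.

    ``variant_ids`` gives the locus order of the matrix columns; records
    without a matching column raise KeyError.
    """
    col = {vid: i for i, vid in enumerate(variant_ids)}
    out: dict[str, PolarizedCall] = {}
    for r in records:
        i = col[r.variant_id]
        out[r.variant_id] = polarize(
            r, (int(outgroup_genotypes[0, i]), int(outgroup_genotypes[1, i]))
        )
    return out


def reference_ancestral_subset(polarized_calls: dict[str, PolarizedCall]) -> set[str]:
    """Variant ids whose reference allele is the ancestral state."""
    return {vid for vid, c in polarized_calls.items() if c.ancestral is Ancestral.REF}
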