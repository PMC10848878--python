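"""Genotype validation: trio Mendelian concordance and PCA diagnostics.

The Mendelian check asks whether a child's diploid genotype can be formed
by drawing one allele from each parent; over the 27 ordered (father,
mother, child) genotype triples exactly 15 are consistent. Concordance per
trio is the fraction of loci (with all three calls present) that pass.

The PCA codes genotypes as ALT-allele dosage 0/1/2, imputes missing calls
with the locus mean, centers per locus and eigendecomposes the sample
covariance (via SVD). It is used both for population structure and for
spotting sequencing-batch artifacts in rejected call sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .types import Genotype, SVRecord, Trio, genotype_matrix

__all__ = [
    "TrioConcordance",
    "PCAResult",
    "is_mendelian_consistent",
    "trio_concordance",
    "pca_genotypes",
]

# transmissible allele sets per genotype dosage
_ALLELES = {0: (0,), 1: (0, 1), 2: (1,)}


def is_mendelian_consistent(g_father: int, g_mother: int, g_child: int) -> bool:
    """True iff the child genotype is reachable by one allele from each parent."""
    for g in (g_father, g_mother, g_child):
        if g == Genotype.MISSING:
            raise ValueError("is_mendelian_consistent requires non-missing genotypes")
        if g not in (0, 1, 2):
            raise ValueError(f"invalid genotype code {g}")
    return any(
        fa + ma == g_child for fa in _ALLELES[g_father] for ma in _ALLELES[g_mother]
    )


@dataclass
class TrioConcordance:
    trio: Trio
    n_tested: int
    n_consistent: int
    by_svtype: dict[str, tuple[int, int]]  # svtype -> (tested, consistent)

    @property
    def concordance(self) -> float | None:
        """Fraction of tested loci consistent with Mendelian transmission.

        None when no locus had all three genotypes called.
        """
        if self.n_tested == 0:
            return None
        return self.n_consistent / self.n_tested


def trio_concordance(
    trio: Trio, records: list[SVRecord], sample_ids: list[str]
) -> TrioConcordance:
    """Mendelian concordance for one trio over a record set.

    Loci where any of the three individuals is missing are excluded from
    the denominator.
    """
    try:
        fi, mi, ci = (sample_ids.index(s) for s in (trio.father, trio.mother, trio.child))
    except ValueError as exc:
        raise ValueError(f"trio {trio} not in sample list") from exc
    n_tested = n_consistent = 0
    by_type: dict[str, list[int]] = {}
    for r in records:
        gf, gm, gc = int(r.genotypes[fi]), int(r.genotypes[mi]), int(r.genotypes[ci])
        if Genotype.MISSING in (gf, gm, gc):
            continue
        ok = is_mendelian_consistent(gf, gm, gc)
        n_tested += 1
        n_consistent += ok
        t = by_type.setdefault(r.svtype, [0, 0])
        t[0] += 1
        t[1] += ok
    return TrioConcordance(
        trio=trio,
        n_tested=n_tested,
        n_consistent=n_consistent,
        by_svtype={k: (v[0], v[1]) for k, v in by_type.items()},
    )


@dataclass
class PCAResult:
    sample_ids: list[str]
    scores: np.ndarray  # (n_samples, n_components)
    explained_variance: np.ndarray  # per component, decreasing

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_genotypes(
    records: list[SVRecord],
    sample_ids: list[str],
    n_components: int = 20,
) -> PCAResult:
    """PCA of the samples-by-loci ALT-dosage matrix.

    Missing genotypes are imputed by the locus mean before per-locus
    centering; loci with no called genotype at all are dropped. Components
    are capped at min(n_samples, n_usable_loci).
    """
    if len(records) < 2 or len(sample_ids) < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 loci")
    g = genotype_matrix(records).astype(float)  # (loci, samples)
    g[g < 0] = np.nan
    called = ~np.all(np.isnan(g), axis=1)
    g = g[called]
    locus_mean = np.nanmean(g, axis=1, keepdims=True)
    g = np.where(np.isnan(g), locus_mean, g) - locus_mean
    x = g.T  # samples x loci, already locus-centered
    if not np.any(np.abs(x) > 1e-12):
        raise ValueError("no variance: genotype matrix is constant")
    k = min(n_components, min(x.shape) - 1) or 1
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    return PCAResult(
        sample_ids=list(sample_ids),
        scores=scores,
        explained_variance=pca.explained_variance_,
    )
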