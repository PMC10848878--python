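"""Population statistics: unfolded SFS, genetic load, rescue accounting.

The unfolded site-frequency spectrum bins per-locus derived-allele
frequencies into 0.05-wide intervals; loci monomorphic within the chosen
sample subset are excluded. The deleterious class is the set of variants
overlapping coding sequence (fully enclosing a gene or partially
overlapping CDS); intron-only variants serve as the putatively neutral
comparison. A Pearson goodness-of-fit test compares the deleterious
spectrum against expectations derived from the neutral spectrum's bin
proportions.

Genetic load is summarised per individual over the deleterious-class loci
at which the reference allele is ancestral (so homozygous-ALT means
homozygous for the derived allele): the masked load is the fraction of
called loci heterozygous, the realized load the fraction homozygous
derived.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .types import Ancestral, Genotype, OverlapCategory, PolarizedCall, SampleInfo, SVRecord

logger = logging.getLogger("svload")

__all__ = [
    "SFS",
    "LoadSummary",
    "RescueReport",
    "CLASS_CATEGORIES",
    "select_class_records",
    "derived_allele_frequency",
    "build_sfs",
    "sfs_gof_test",
    "individual_load",
    "load_by_group",
    "compare_groups",
    "fixation_and_rescue",
]

CLASS_CATEGORIES = {
    "DELETERIOUS": {OverlapCategory.ENCLOSING, OverlapCategory.PARTIAL_CDS},
    "NEUTRAL": {OverlapCategory.NONCODING},
}

GROUP_ORDER = [f"F{i}" for i in range(1, 7)] + [f"L{i}" for i in range(1, 4)] + [
    "IMMIGRANT_R",
    "IMMIGRANT_NR",
    "FOUNDER",
    "SCAND_ORIGINAL",
    "SCAND_IMMIGRANT_DESC",
    "FINLAND",
    "RUSSIA",
]


def select_class_records(
    records: list[SVRecord],
    categories: dict[str, OverlapCategory],
    class_label: str,
) -> list[SVRecord]:
    """Subset records to one variant class (DELETERIOUS or NEUTRAL)."""
    wanted = CLASS_CATEGORIES[class_label]
    return [r for r in records if categories.get(r.variant_id) in wanted]


def derived_allele_frequency(
    record: SVRecord,
    polarized_call: PolarizedCall,
    sample_idx: np.ndarray,
) -> float:
    """Derived-allele frequency in a sample subset.

    The derived allele is ALT when the reference is ancestral, and REF when
    the ALT allele is ancestral; the denominator is two chromosomes per
    non-missing individual in the subset.
    """
    if polarized_call.ancestral is Ancestral.UNPOLARIZED:
        raise ValueError(f"{record.variant_id}: cannot compute frequency, unpolarized")
    g = record.genotypes[np.asarray(sample_idx)]
    called = g[g != Genotype.MISSING]
    if called.size == 0:
        raise ValueError(f"{record.variant_id}: no non-missing genotype in subset")
    alt_count = int(called.sum())
    if polarized_call.ancestral is Ancestral.REF:
        derived = alt_count
    else:
        derived = 2 * called.size - alt_count
    return derived / (2 * called.size)


@dataclass
class SFS:
    """Unfolded SFS over 0.05-wide derived-frequency bins.

    Bins are half-open [lo, hi) with the last bin closed at 1.0; only
    polymorphic loci (0 < freq < 1 in the subset) are counted, so the bin
    totals equal the number of included loci.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_samples: int
    class_label: str

    @property
    def proportions(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total else self.counts.astype(float)


def build_sfs(
    records: list[SVRecord],
    polarized_calls: dict[str, PolarizedCall],
    sample_idx: np.ndarray,
    categories: dict[str, OverlapCategory],
    class_label: str,
    length_window: tuple[int, int] | None = None,
    svtype: str | None = None,
    bin_width: float = 0.05,
) -> SFS:
    """Bin derived-allele frequencies of one variant class into a spectrum.

    Unpolarized loci, loci outside the length window/type selection, and
    loci monomorphic within the subset are excluded. The record set to pass
    is the caller's choice — to retain rare alleles this is typically the
    callset *before* the genotype-frequency filter.
    """
    sample_idx = np.asarray(sample_idx)
    if sample_idx.size == 0:
        raise ValueError("empty sample subset")
    edges = np.round(np.arange(0.0, 1.0 + bin_width / 2, bin_width), 10)
    counts = np.zeros(len(edges) - 1, dtype=int)
    n_included = 0
    for r in select_class_records(records, categories, class_label):
        call = polarized_calls.get(r.variant_id)
        if call is None or call.ancestral is Ancestral.UNPOLARIZED:
            continue
        if length_window is not None and not (length_window[0] <= r.length <= length_window[1]):
            continue
        if svtype is not None and r.svtype != svtype:
            continue
        g = r.genotypes[sample_idx]
        if not np.any(g != Genotype.MISSING):
            continue
        f = derived_allele_frequency(r, call, sample_idx)
        if f <= 0.0 or f >= 1.0:
            continue  # monomorphic in the subset
        k = min(int(f / bin_width), len(counts) - 1)
        counts[k] += 1
        n_included += 1
    if n_included == 0:
        warnings.warn(f"empty {class_label} spectrum", stacklevel=2)
    assert counts.sum() == n_included
    return SFS(bin_edges=edges, counts=counts, n_samples=int(sample_idx.size), class_label=class_label)


def sfs_gof_test(sfs_deleterious, sfs_neutral) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of the deleterious SFS against neutral proportions.

    Expected counts are the neutral spectrum's bin proportions scaled to the
    deleterious total. Bins are pooled from the right until every expected
    count is >= 5 (standard Pearson practice); fewer than two bins after
    pooling is degenerate. Returns (statistic, df, upper-tail p). The
    statistic scales linearly with the deleterious total count.
    """
    obs = np.asarray(getattr(sfs_deleterious, "counts", sfs_deleterious), dtype=float)
    neu = np.asarray(getattr(sfs_neutral, "counts", sfs_neutral), dtype=float)
    if obs.shape != neu.shape:
        raise ValueError("spectra must share identical bins")
    if neu.sum() <= 0 or obs.sum() <= 0:
        raise ValueError("empty spectrum")
    exp = neu / neu.sum() * obs.sum()
    obs, exp = obs.tolist(), exp.tolist()
    while len(exp) > 1 and min(exp) < 5:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        del exp[-1], obs[-1]
    if len(exp) < 2 or min(exp) < 5:
        raise ValueError("degenerate spectrum: fewer than two bins with expected >= 5")
    obs_a, exp_a = np.array(obs), np.array(exp)
    statistic = float(((obs_a - exp_a) ** 2 / exp_a).sum())
    df = len(exp_a) - 1
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


# ---------------------------------------------------------------------------
# Genetic load
# ---------------------------------------------------------------------------


@dataclass
class LoadSummary:
    """Per-individual masked/realized load over deleterious-class loci.

    Only loci where the reference allele is ancestral enter the counts, so
    HET carries one derived copy and HOM_ALT two; the three genotype counts
    partition ``n_loci_called``.
    """

    sample_id: str
    n_loci_called: int
    n_het: int
    n_hom_derived: int
    n_hom_ancestral: int

    @property
    def masked_load(self) -> float | None:
        return self.n_het / self.n_loci_called if self.n_loci_called else None

    @property
    def realized_load(self) -> float | None:
        return self.n_hom_derived / self.n_loci_called if self.n_loci_called else None


def individual_load(
    records: list[SVRecord],
    reference_ancestral_ids: set[str],
    sample_id: str,
    sample_ids: list[str],
    categories: dict[str, OverlapCategory] | None = None,
    class_label: str = "DELETERIOUS",
) -> LoadSummary:
    """Load summary for one individual.

    ``records`` is restricted to the reference-ancestral polarized subset
    and (when ``categories`` is given) to one overlap class; missing
    genotypes are excluded from the denominator.
    """
    j = sample_ids.index(sample_id)
    use = records if categories is None else select_class_records(records, categories, class_label)
    n_het = n_hom_d = n_hom_a = 0
    for r in use:
        if r.variant_id not in reference_ancestral_ids:
            continue
        g = int(r.genotypes[j])
        if g == Genotype.MISSING:
            continue
        if g == Genotype.HET:
            n_het += 1
        elif g == Genotype.HOM_ALT:
            n_hom_d += 1
        else:
            n_hom_a += 1
    return LoadSummary(
        sample_id=sample_id,
        n_loci_called=n_het + n_hom_d + n_hom_a,
        n_het=n_het,
        n_hom_derived=n_hom_d,
        n_hom_ancestral=n_hom_a,
    )


def _group_key(info: SampleInfo) -> str:
    return info.generation_class or info.population


def load_by_group(
    load_summaries: list[LoadSummary], sample_infos: list[SampleInfo]
) -> pd.DataFrame:
    """Group means/dispersions of masked and realized load.

    Scandinavian-born samples group by generation class (F1..F6, L1..L3),
    everyone else by population; groups are ordered F1..F6, L1..L3, then
    immigrants and the remaining populations. Individuals with no called
    locus are excluded from the means; empty groups are reported with n=0.
    """
    info_by_id = {s.sample_id: s for s in sample_infos}
    rows: dict[str, dict[str, list[float]]] = {}
    for ls in load_summaries:
        info = info_by_id.get(ls.sample_id)
        if info is None:
            raise ValueError(f"no SampleInfo for {ls.sample_id}")
        key = _group_key(info)
        d = rows.setdefault(key, {"masked": [], "realized": []})
        if ls.n_loci_called:
            d["masked"].append(ls.masked_load)
            d["realized"].append(ls.realized_load)
    present = {_group_key(s) for s in sample_infos}
    order = [g for g in GROUP_ORDER if g in present or g in rows]
    order += sorted(set(rows) - set(order))
    out = []
    for g in order:
        d = rows.get(g, {"masked": [], "realized": []})
        n = len(d["masked"])
        out.append(
            {
                "group": g,
                "n": n,
                "masked_mean": float(np.mean(d["masked"])) if n else np.nan,
                "masked_sd": float(np.std(d["masked"], ddof=1)) if n > 1 else np.nan,
                "realized_mean": float(np.mean(d["realized"])) if n else np.nan,
                "realized_sd": float(np.std(d["realized"], ddof=1)) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Two-sample rank test
# ---------------------------------------------------------------------------


def compare_groups(
    values_a, values_b, exact_max_n: int = 25
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test, two-sided.

    Returns (rank-sum statistic of group a, two-sided p). For pooled sample
    sizes up to ``exact_max_n`` the null distribution is enumerated exactly
    over all rank assignments (midranks for ties; p = 2 * min(tail
    probabilities), capped at 1). Larger samples use the tie-corrected
    normal approximation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_a = float(ranks[: a.size].sum())
    if np.all(pooled == pooled[0]):
        return w_a, 1.0
    n = a.size + b.size
    if n <= exact_max_n:
        p = _exact_ranksum_p(ranks, a.size, w_a)
    else:
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    return w_a, p


def _exact_ranksum_p(ranks: np.ndarray, n_a: int, w_a: float) -> float:
    """Exact two-sided p by dynamic programming over doubled midranks."""
    r2 = np.round(ranks * 2).astype(int)  # midranks double to integers
    total = int(r2.sum())
    n = len(r2)
    # ways[k, s]: subsets of size k with doubled-rank sum s
    ways = np.zeros((n_a + 1, total + 1))
    ways[0, 0] = 1.0
    for r in r2:
        for k in range(min(n_a, n) - 1, -1, -1):
            row = ways[k]
            nz = np.nonzero(row)[0]
            ways[k + 1, nz + r] += row[nz]
    dist = ways[n_a]
    n_subsets = comb(n, n_a)
    w2 = int(round(w_a * 2))
    p_le = dist[: w2 + 1].sum() / n_subsets
    p_ge = dist[w2:].sum() / n_subsets
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


# ---------------------------------------------------------------------------
# Fixation and genetic rescue
# ---------------------------------------------------------------------------


@dataclass
class RescueReport:
    """Counts of derived-allele fixation and post-immigration regain."""

    n_fixed_pre: int
    n_regained: int
    n_founder_fixed: int
    n_founder_regained: int
    fixed_pre_ids: list[str]
    founder_fixed_ids: list[str]

    def __post_init__(self) -> None:
        assert self.n_regained <= self.n_fixed_pre
        assert self.n_founder_regained <= self.n_founder_fixed


def fixation_and_rescue(
    records: list[SVRecord],
    polarized_calls: dict[str, PolarizedCall],
    pre_idx: np.ndarray,
    post_idx: np.ndarray,
    original_idx: np.ndarray | None = None,
    min_called: int = 5,
) -> RescueReport:
    """Account for loci fixed for the derived allele and rescued by immigration.

    A locus is *fixed pre-immigration* when every non-missing genotype in
    the pre subset is homozygous derived and at least ``min_called``
    individuals are called (guarding against spurious fixation from
    missingness). It is *regained* when at least one post-subset individual
    carries an ancestral allele (heterozygote or homozygous ancestral).
    *Founder-fixed* loci show neither a heterozygote nor a homozygous-
    ancestral genotype anywhere in the original population (default: the
    pre subset), i.e. all three founders likely carried only the derived
    allele. Unpolarized loci are skipped.
    """
    pre_idx = np.asarray(pre_idx)
    post_idx = np.asarray(post_idx)
    if pre_idx.size == 0 or post_idx.size == 0:
        raise ValueError("pre and post subsets must be non-empty")
    if np.intersect1d(pre_idx, post_idx).size:
        logger.warning("fixation_and_rescue: pre and post subsets overlap")
    orig_idx = pre_idx if original_idx is None else np.asarray(original_idx)

    fixed_ids: list[str] = []
    regained_ids: list[str] = []
    founder_ids: list[str] = []
    founder_regained_ids: list[str] = []
    for r in records:
        call = polarized_calls.get(r.variant_id)
        if call is None or call.ancestral is Ancestral.UNPOLARIZED:
            continue
        hom_derived = Genotype.HOM_ALT if call.ancestral is Ancestral.REF else Genotype.HOM_REF
        g_pre = r.genotypes[pre_idx]
        called = g_pre[g_pre != Genotype.MISSING]
        is_fixed = called.size >= min_called and np.all(called == hom_derived)
        g_post = r.genotypes[post_idx]
        post_called = g_post[g_post != Genotype.MISSING]
        regained = bool(np.any(post_called != hom_derived))
        if is_fixed:
            fixed_ids.append(r.variant_id)
            if regained:
                regained_ids.append(r.variant_id)
        g_orig = r.genotypes[orig_idx]
        orig_called = g_orig[g_orig != Genotype.MISSING]
        if orig_called.size >= min_called and np.all(orig_called == hom_derived):
            founder_ids.append(r.variant_id)
            if regained:
                founder_regained_ids.append(r.variant_id)
    return RescueReport(
        n_fixed_pre=len(fixed_ids),
        n_regained=len(regained_ids),
        n_founder_fixed=len(founder_ids),
        n_founder_regained=len(founder_regained_ids),
        fixed_pre_ids=fixed_ids,
        founder_fixed_ids=founder_ids,
    )
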