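"""Pedigree-structured synthetic SV cohort generator.

Emulates the study system every downstream stage expects: a small inbred
population descending from three founders by gene-dropping, a large outbred
source population, immigrants that breed into the inbred population some
generations later, two outgroup pseudo-samples for allele polarization, and
a spiked-in set of false calls ("artifacts") whose quality annotations fall
outside the filter thresholds and whose genotypes are correlated within a
sequencing-batch subset of samples.

Deleterious loci are placed so that they overlap coding sequence of
generated gene models; neutral loci fall entirely within introns. The
frequency difference between the classes is encoded purely in the founder
(source-population) derived-allele frequencies — transmission itself is
neutral, so the load dynamics that emerge downstream are driven by drift
and inbreeding alone.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import (
    GeneModel,
    RepeatFeature,
    SampleInfo,
    SVRecord,
    Trio,
)

__all__ = [
    "SimulationConfig",
    "LengthModel",
    "CohortTruth",
    "SimulatedCohort",
    "ConfigError",
    "simulate_cohort",
    "gene_drop",
    "inject_artifacts",
    "decisions_from_truth",
]


class ConfigError(ValueError):
    """Invalid simulation configuration (impossible pedigree, bad mixture)."""


@dataclass(frozen=True)
class LengthModel:
    """SV length mixture: a narrow peak per type plus a log-uniform tail.

    The deletion peak near 190 bp and the duplication peak near 160 bp mimic
    presence/absence polymorphisms of SINE and LINE fragments; loci drawn
    from a peak are coupled to a matching repeat feature in the emitted
    annotation.
    """

    del_peak_bp: int = 190
    del_peak_sd: float = 4.0
    del_peak_weight: float = 0.5
    dup_peak_bp: int = 160
    dup_peak_sd: float = 6.0
    dup_peak_weight: float = 0.4
    tail_min_bp: int = 50
    tail_max_bp: int = 50_000


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults mirror a founder-limited wolf-like population: 3 founders, six
    inbred generations of six breeding pairs with four offspring each, a
    source population of 60, two reproducing immigrants arriving at
    generation 5 whose pairings produce 14 first-generation (L1) offspring,
    ~2% genotyping error and missingness, 60% of loci polarizable by the
    outgroups, and 30% extra injected false calls.
    """

    n_loci_neutral: int = 6000
    n_loci_deleterious: int = 2000
    sv_type_mix: tuple[float, float, float] = (0.79, 0.09, 0.12)  # DEL, DUP, INV
    founder_freq_params_neutral: tuple[float, float] = (1.0, 3.0)  # Beta, mean 0.25
    founder_freq_params_deleterious: tuple[float, float] = (0.5, 9.5)  # Beta, mean 0.05
    n_source: int = 60
    n_generations: int = 6
    n_pairs_per_generation: int = 3
    offspring_per_pair: int = 24
    mating_scheme: str = "mainline"  # or "circular" / "random"
    immigrant_generation: int = 5
    n_immigrants_reproducing: int = 2
    n_immigrants_nonreproducing: int = 3
    immigrant_offspring_per_pair: int = 7
    n_trios: int = 7
    genotyping_error_rate: float = 0.02
    missing_rate: float = 0.02
    artifact_fraction: float = 0.3
    batch_fraction: float = 0.3
    polarizable_fraction: float = 0.6
    prob_derived_is_reference: float = 0.3
    length_model: LengthModel = field(default_factory=LengthModel)
    n_chromosomes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci_neutral <= 0 or self.n_loci_deleterious <= 0:
            raise ConfigError("locus counts must be positive")
        if not math.isclose(sum(self.sv_type_mix), 1.0, abs_tol=1e-9):
            raise ConfigError("sv_type_mix must sum to 1")
        for p in (
            *self.sv_type_mix,
            self.genotyping_error_rate,
            self.missing_rate,
            self.batch_fraction,
            self.polarizable_fraction,
            self.prob_derived_is_reference,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"proportion {p} outside [0,1]")
        if self.artifact_fraction < 0:
            raise ConfigError("artifact_fraction must be >= 0")
        has_immigrants = self.n_immigrants_reproducing > 0 or self.n_immigrants_nonreproducing > 0
        if has_immigrants and not 1 <= self.immigrant_generation <= self.n_generations:
            raise ConfigError(
                "impossible pedigree: immigrants must breed at a generation in "
                f"[1, {self.n_generations}], got {self.immigrant_generation}"
            )
        if self.mating_scheme not in ("mainline", "circular", "random"):
            raise ConfigError("mating_scheme must be 'mainline', 'circular' or 'random'")
        if self.mating_scheme in ("mainline", "circular") and self.offspring_per_pair < 2:
            raise ConfigError(f"{self.mating_scheme} mating needs >= 2 offspring per pair")


@dataclass
class CohortTruth:
    """Simulator ground truth, keyed by locus order of the emitted records."""

    variant_ids: list[str]
    sample_ids: list[str]
    true_genotypes: np.ndarray  # (n_loci, n_samples) int8, pre-error/missing
    deleterious_label: np.ndarray  # bool per locus
    ancestral_allele: np.ndarray  # "REF" / "ALT" / "NA" (artifacts) per locus
    injected_artifact: np.ndarray  # bool per locus
    derived_freq: np.ndarray  # configured source derived-allele frequency
    pedigree: dict[str, tuple[str, str]]  # child -> (father, mother)
    batch_samples: list[str]

    def index_of(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError as exc:
            raise KeyError(variant_id) from exc


@dataclass
class SimulatedCohort:
    records: list[SVRecord]
    sample_ids: list[str]
    samples: list[SampleInfo]
    trios: list[Trio]
    genes: list[GeneModel]
    repeats: list[RepeatFeature]
    outgroup_ids: list[str]
    outgroup_genotypes: np.ndarray  # (2, n_loci) int8
    truth: CohortTruth


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------


def gene_drop(
    pedigree: dict[str, tuple[str, str]],
    founder_genotypes: dict[str, np.ndarray],
    seed: int,
) -> dict[str, np.ndarray]:
    """Drop founder genotypes down a pedigree by random allele transmission.

    Each offspring receives, independently per locus, one uniformly chosen
    allele from each parent. Founder heterozygotes are phased arbitrarily
    (phase never matters under free transmission).

    Parameters
    ----------
    pedigree
        child id -> (father id, mother id); parents must be founders or
        other children. Cycles are rejected.
    founder_genotypes
        founder id -> int8 genotype vector (0/1/2 alt-allele dosage).

    Returns
    -------
    dict of child id -> genotype vector, in the same dosage coding.
    """
    rng = np.random.default_rng(seed)
    haplo: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for fid, g in founder_genotypes.items():
        g = np.asarray(g)
        a = (g >= 1).astype(np.int8)  # carries the alt on hap A if dosage >= 1
        b = (g == 2).astype(np.int8)
        haplo[fid] = (a, b)

    remaining = dict(pedigree)
    out: dict[str, np.ndarray] = {}
    while remaining:
        ready = [c for c, (f, m) in remaining.items() if f in haplo and m in haplo]
        if not ready:
            raise ValueError(f"cyclic or unresolvable pedigree near {sorted(remaining)[:3]}")
        for child in ready:
            f, m = remaining.pop(child)
            haplo[child] = (
                _transmit(haplo[f], rng),
                _transmit(haplo[m], rng),
            )
            out[child] = (haplo[child][0] + haplo[child][1]).astype(np.int8)
    return out


def _transmit(parent_haps: tuple[np.ndarray, np.ndarray], rng: np.random.Generator) -> np.ndarray:
    a, b = parent_haps
    pick_a = rng.integers(0, 2, size=a.shape[0]).astype(bool)
    return np.where(pick_a, a, b).astype(np.int8)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort with ground truth.

    Deterministic given ``config.seed``: same config and seed give
    byte-identical downstream files.
    """
    rng = np.random.default_rng(config.seed)
    n_del_loci = config.n_loci_deleterious
    n_neu_loci = config.n_loci_neutral
    n_real = n_del_loci + n_neu_loci

    # -- per-locus class, type, frequency, polarity ---------------------------
    deleterious = np.zeros(n_real, dtype=bool)
    deleterious[:n_del_loci] = True
    order = rng.permutation(n_real)
    deleterious = deleterious[order]

    svtype_idx = rng.choice(3, size=n_real, p=list(config.sv_type_mix))
    svtypes = np.array(["DEL", "DUP", "INV"])[svtype_idx]

    a_n, b_n = config.founder_freq_params_neutral
    a_d, b_d = config.founder_freq_params_deleterious
    derived_freq = np.where(
        deleterious,
        rng.beta(a_d, b_d, size=n_real),
        rng.beta(a_n, b_n, size=n_real),
    )
    derived_freq = np.clip(derived_freq, 1e-4, 1 - 1e-4)
    ancestral_is_alt = rng.random(n_real) < config.prob_derived_is_reference
    alt_freq = np.where(ancestral_is_alt, 1.0 - derived_freq, derived_freq)

    lengths = _draw_lengths(svtypes, config.length_model, rng)

    # -- pedigree and sample book-keeping ------------------------------------
    founder_ids = [f"FND{i+1}" for i in range(3)]
    samples: list[SampleInfo] = [SampleInfo(f, "FOUNDER") for f in founder_ids]
    pedigree: dict[str, tuple[str, str]] = {}
    generation_members: dict[int, list[str]] = {0: list(founder_ids)}

    prev_pair_offspring: list[list[str]] | None = None  # per-pair sib lists
    for g in range(1, config.n_generations + 1):
        pool = generation_members[g - 1]
        members: list[str] = []
        pair_offspring: list[list[str]] = []
        for p, (father, mother) in enumerate(
            _generation_pairs(g, pool, prev_pair_offspring, config, rng)
        ):
            kids = []
            for k in range(config.offspring_per_pair):
                cid = f"SCAND_F{g}_{p+1}_{k+1}"
                pedigree[cid] = (father, mother)
                members.append(cid)
                kids.append(cid)
                samples.append(SampleInfo(cid, "SCAND_ORIGINAL", generation_class=f"F{g}"))
            pair_offspring.append(kids)
        generation_members[g] = members
        prev_pair_offspring = pair_offspring

    imm_r_ids = [f"IMM_R{i+1}" for i in range(config.n_immigrants_reproducing)]
    imm_nr_ids = [f"IMM_NR{i+1}" for i in range(config.n_immigrants_nonreproducing)]
    samples += [SampleInfo(s, "IMMIGRANT_R") for s in imm_r_ids]
    samples += [SampleInfo(s, "IMMIGRANT_NR") for s in imm_nr_ids]

    l1_ids: list[str] = []
    if imm_r_ids:
        mates = rng.choice(
            generation_members[config.immigrant_generation],
            size=len(imm_r_ids),
            replace=False,
        )
        for imm, mate in zip(imm_r_ids, mates):
            for k in range(config.immigrant_offspring_per_pair):
                cid = f"{imm}_L1_{k+1}"
                pedigree[cid] = (imm, str(mate))
                l1_ids.append(cid)
                samples.append(SampleInfo(cid, "SCAND_IMMIGRANT_DESC", generation_class="L1"))

    n_fin = (2 * config.n_source) // 3
    source_ids = [f"FIN{i+1}" for i in range(n_fin)] + [
        f"RUS{i+1}" for i in range(config.n_source - n_fin)
    ]
    samples += [
        SampleInfo(s, "FINLAND" if s.startswith("FIN") else "RUSSIA") for s in source_ids
    ]

    sample_ids = [s.sample_id for s in samples]
    n_samples = len(sample_ids)

    # -- haplotypes: founders/immigrants/source are HW draws; descendants drop
    haplo: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sid in founder_ids + imm_r_ids + imm_nr_ids + source_ids:
        haplo[sid] = (
            (rng.random(n_real) < alt_freq).astype(np.int8),
            (rng.random(n_real) < alt_freq).astype(np.int8),
        )
    for g in range(1, config.n_generations + 1):
        for cid in generation_members[g]:
            f, m = pedigree[cid]
            haplo[cid] = (_transmit(haplo[f], rng), _transmit(haplo[m], rng))
    for cid in l1_ids:
        f, m = pedigree[cid]
        haplo[cid] = (_transmit(haplo[f], rng), _transmit(haplo[m], rng))

    true_gt = np.empty((n_real, n_samples), dtype=np.int8)
    for j, sid in enumerate(sample_ids):
        a, b = haplo[sid]
        true_gt[:, j] = a + b

    # -- observation layer: genotyping error then missingness -----------------
    obs_gt = true_gt.copy()
    if config.genotyping_error_rate > 0:
        err = rng.random(obs_gt.shape) < config.genotyping_error_rate
        shift = rng.integers(1, 3, size=obs_gt.shape)
        obs_gt = np.where(err, (obs_gt + shift) % 3, obs_gt).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(obs_gt.shape) < config.missing_rate
        obs_gt[miss] = -1

    # -- genomic placement, gene models, repeats ------------------------------
    placements, genes, repeats = _place_loci(svtypes, lengths, deleterious, config, rng)

    dhffc = np.where(
        svtypes == "DEL",
        rng.uniform(0.2, 0.65, n_real),
        rng.uniform(1.35, 2.5, n_real),
    )
    dhffc = np.where(svtypes == "INV", np.nan, dhffc)
    mshq = rng.uniform(3.0, 25.0, n_real)

    records: list[SVRecord] = []
    for i in range(n_real):
        chrom, pos = placements[i]
        records.append(
            SVRecord(
                variant_id=f"SV{i:05d}",
                chrom=chrom,
                pos=pos,
                end=pos + int(lengths[i]) - 1,
                svtype=str(svtypes[i]),
                length=int(lengths[i]),
                genotypes=obs_gt[i],
                dhffc=float(dhffc[i]),
                mshq=float(mshq[i]),
            )
        )

    # -- outgroups -------------------------------------------------------------
    out_gt = np.empty((2, n_real), dtype=np.int8)
    polarizable = rng.random(n_real) < config.polarizable_fraction
    anc_hom = np.where(ancestral_is_alt, 2, 0).astype(np.int8)
    for i in range(n_real):
        if polarizable[i]:
            out_gt[:, i] = anc_hom[i]
        else:
            mode = rng.integers(0, 3)
            if mode == 0:  # disagree, both homozygous
                out_gt[0, i], out_gt[1, i] = 0, 2
            elif mode == 1:  # one heterozygous
                out_gt[0, i], out_gt[1, i] = 1, anc_hom[i]
            else:  # one missing
                out_gt[0, i], out_gt[1, i] = -1, anc_hom[i]

    truth = CohortTruth(
        variant_ids=[r.variant_id for r in records],
        sample_ids=sample_ids,
        true_genotypes=true_gt,
        deleterious_label=deleterious,
        ancestral_allele=np.where(ancestral_is_alt, "ALT", "REF"),
        injected_artifact=np.zeros(n_real, dtype=bool),
        derived_freq=derived_freq,
        pedigree=pedigree,
        batch_samples=[],
    )

    cohort = SimulatedCohort(
        records=records,
        sample_ids=sample_ids,
        samples=samples,
        trios=_pick_trios(pedigree, config.n_trios, rng),
        genes=genes,
        repeats=repeats,
        outgroup_ids=["OUT1", "OUT2"],
        outgroup_genotypes=out_gt,
        truth=truth,
    )
    return inject_artifacts(cohort, config, rng)


def _generation_pairs(
    g: int,
    pool: list[str],
    prev_pair_offspring: list[list[str]] | None,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Breeding pairs for generation ``g`` under the configured scheme.

    ``mainline`` tracks the founding history of a severely bottlenecked
    population: generation 1 stems from founder pairs (f1,f2) and (f2,f3)
    so all three founders transmit, generation 2 from a half-sib pair
    across those two families, and each later generation from a single
    full-sib pair of the previous one. ``circular`` is a ring of
    ``n_pairs_per_generation`` lineages with cousin-type mating; ``random``
    draws each pair uniformly from the previous generation.
    """
    scheme = config.mating_scheme
    if scheme == "mainline":
        if prev_pair_offspring is None:
            return [(pool[i], pool[(i + 1) % len(pool)]) for i in range(min(2, len(pool)))]
        if len(prev_pair_offspring) >= 2:  # half-sib bridge between founder families
            return [(prev_pair_offspring[0][0], prev_pair_offspring[1][1])]
        sibs = prev_pair_offspring[0]
        return [(sibs[0], sibs[1])]
    if scheme == "circular":
        pairs = []
        for p in range(config.n_pairs_per_generation):
            if prev_pair_offspring is None:
                pairs.append((pool[p % len(pool)], pool[(p + 1) % len(pool)]))
            else:
                pairs.append(
                    (
                        prev_pair_offspring[p % len(prev_pair_offspring)][0],
                        prev_pair_offspring[(p + 1) % len(prev_pair_offspring)][1],
                    )
                )
        return pairs
    return [_draw_pair(pool, rng) for _ in range(config.n_pairs_per_generation)]


def _draw_pair(pool: list[str], rng: np.random.Generator) -> tuple[str, str]:
    i, j = rng.choice(len(pool), size=2, replace=False)
    return pool[int(i)], pool[int(j)]


def _pick_trios(
    pedigree: dict[str, tuple[str, str]], n_trios: int, rng: np.random.Generator
) -> list[Trio]:
    children = sorted(pedigree)
    idx = rng.choice(len(children), size=min(n_trios, len(children)), replace=False)
    trios = []
    for i in sorted(int(k) for k in idx):
        c = children[i]
        f, m = pedigree[c]
        trios.append(Trio(child=c, father=f, mother=m))
    return trios


def _draw_lengths(
    svtypes: np.ndarray, lm: LengthModel, rng: np.random.Generator
) -> np.ndarray:
    n = len(svtypes)
    tail = np.round(
        10 ** rng.uniform(math.log10(lm.tail_min_bp), math.log10(lm.tail_max_bp), n)
    ).astype(int)
    lengths = tail.copy()
    at_peak = rng.random(n)
    del_peak = (svtypes == "DEL") & (at_peak < lm.del_peak_weight)
    dup_peak = (svtypes == "DUP") & (at_peak < lm.dup_peak_weight)
    lengths[del_peak] = np.round(
        rng.normal(lm.del_peak_bp, lm.del_peak_sd, del_peak.sum())
    ).astype(int)
    lengths[dup_peak] = np.round(
        rng.normal(lm.dup_peak_bp, lm.dup_peak_sd, dup_peak.sum())
    ).astype(int)
    return np.maximum(lengths, lm.tail_min_bp)


def _place_loci(
    svtypes: np.ndarray,
    lengths: np.ndarray,
    deleterious: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, int]], list[GeneModel], list[RepeatFeature]]:
    """Lay loci along chromosomes with gene models built around each locus.

    Deleterious loci get a gene whose CDS they disrupt (a fraction fully
    enclosing the gene); neutral loci sit wholly inside an intron of a gene
    whose CDS exons flank the variant. Peak-length DEL/DUP loci get a
    covering SINE/LINE repeat feature.
    """
    lm = config.length_model
    cursors = {f"chr{c+1}": 10_000 for c in range(config.n_chromosomes)}
    placements: list[tuple[str, int]] = []
    genes: list[GeneModel] = []
    repeats: list[RepeatFeature] = []
    for i in range(len(svtypes)):
        chrom = f"chr{(i % config.n_chromosomes) + 1}"
        pos = cursors[chrom] + 5000
        end = pos + int(lengths[i]) - 1
        cursors[chrom] = end + 9000
        placements.append((chrom, pos))
        if deleterious[i]:
            if lengths[i] >= 150 and rng.random() < 0.3:
                # variant fully encloses a small gene
                g_lo = pos + 10
                g_hi = min(end - 10, g_lo + 2000)
                cds = [(g_lo + 20, min(g_lo + 120, g_hi - 1))]
                genes.append(GeneModel(f"geneE{i}", chrom, (g_lo, g_hi), cds))
            else:
                # variant partially overlaps one CDS exon of a larger gene
                g_lo, g_hi = pos - 2000, end + 2000
                cds_lo = max(g_lo, end - min(int(lengths[i]) - 1, 50))
                cds_hi = min(g_hi, end + 150)
                genes.append(GeneModel(f"geneP{i}", chrom, (g_lo, g_hi), [(cds_lo, cds_hi)]))
        else:
            # intronic: CDS exons flank the variant at the gene edges
            g_lo, g_hi = pos - 2000, end + 2000
            cds = [(g_lo, g_lo + 100), (g_hi - 100, g_hi)]
            genes.append(GeneModel(f"geneN{i}", chrom, (g_lo, g_hi), cds))
        if svtypes[i] == "DEL" and abs(int(lengths[i]) - lm.del_peak_bp) <= 15:
            repeats.append(RepeatFeature(chrom, pos, end, "SINE"))
        elif svtypes[i] == "DUP" and abs(int(lengths[i]) - lm.dup_peak_bp) <= 20:
            repeats.append(RepeatFeature(chrom, pos, end, "LINE"))
        elif rng.random() < 0.15:
            rep_cls = str(rng.choice(["LINE", "LTR", "DNA", "Simple", "Unknown"]))
            span = int(lengths[i])
            cover = max(1, int(span * rng.uniform(0.1, 0.6)))
            r_start = pos + int(rng.integers(0, max(span - cover, 1)))
            repeats.append(RepeatFeature(chrom, r_start, r_start + cover - 1, rep_cls))
    return placements, genes, repeats


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------


def inject_artifacts(
    cohort: SimulatedCohort,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedCohort:
    """Spike false-positive loci into a cohort (in place, returned for chaining).

    Injected loci carry DHFFC/MSHQ outside the standard filter thresholds
    (DEL dhffc >= 0.7, DUP dhffc <= 1.3, all mshq < 3) and alt genotypes
    concentrated in a random "sequencing batch" subset of samples, so that
    they are removable by quality filtering and detectable as batch
    structure in a PCA of rejected loci.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 104729)
    n_art = int(round(config.artifact_fraction * len(cohort.records)))
    truth = cohort.truth
    n_samples = len(cohort.sample_ids)
    n_batch = max(2, int(round(config.batch_fraction * n_samples)))
    batch_idx = np.sort(rng.choice(n_samples, size=n_batch, replace=False))
    truth.batch_samples = [cohort.sample_ids[int(j)] for j in batch_idx]
    if n_art == 0:
        return cohort

    svtype_idx = rng.choice(3, size=n_art, p=list(config.sv_type_mix))
    svtypes = np.array(["DEL", "DUP", "INV"])[svtype_idx]
    lengths = _draw_lengths(svtypes, config.length_model, rng)
    dhffc = np.where(
        svtypes == "DEL",
        rng.uniform(0.72, 1.2, n_art),
        rng.uniform(0.7, 1.28, n_art),
    )
    dhffc = np.where(svtypes == "INV", np.nan, dhffc)
    mshq = rng.uniform(0.3, 2.9, n_art)

    batch_mask = np.zeros(n_samples, dtype=bool)
    batch_mask[batch_idx] = True
    gt = np.zeros((n_art, n_samples), dtype=np.int8)
    u = rng.random((n_art, n_samples))
    gt[:, batch_mask] = np.select(
        [u[:, batch_mask] < 0.5, u[:, batch_mask] < 0.8], [1, 2], default=0
    )
    gt[:, ~batch_mask] = np.where(u[:, ~batch_mask] < 0.03, 1, 0)

    lm = config.length_model
    chroms = sorted({r.chrom for r in cohort.records})
    cursors = {c: max(r.end for r in cohort.records if r.chrom == c) + 20_000 for c in chroms}
    n0 = len(cohort.records)
    art_gt_rows = []
    for k in range(n_art):
        chrom = chroms[k % len(chroms)]
        pos = cursors[chrom] + 5000
        end = pos + int(lengths[k]) - 1
        cursors[chrom] = end + 9000
        # false calls are triggered by the same reference repeats as true ones
        if svtypes[k] == "DEL" and abs(int(lengths[k]) - lm.del_peak_bp) <= 15:
            cohort.repeats.append(RepeatFeature(chrom, pos, end, "SINE"))
        elif svtypes[k] == "DUP" and abs(int(lengths[k]) - lm.dup_peak_bp) <= 20:
            cohort.repeats.append(RepeatFeature(chrom, pos, end, "LINE"))
        cohort.records.append(
            SVRecord(
                variant_id=f"SV{n0 + k:05d}",
                chrom=chrom,
                pos=pos,
                end=end,
                svtype=str(svtypes[k]),
                length=int(lengths[k]),
                genotypes=gt[k],
                dhffc=float(dhffc[k]),
                mshq=float(mshq[k]),
            )
        )
        art_gt_rows.append(gt[k])

    truth.variant_ids += [r.variant_id for r in cohort.records[n0:]]
    truth.true_genotypes = np.vstack([truth.true_genotypes, np.vstack(art_gt_rows)])
    truth.deleterious_label = np.concatenate([truth.deleterious_label, np.zeros(n_art, bool)])
    truth.ancestral_allele = np.concatenate([truth.ancestral_allele, np.full(n_art, "NA")])
    truth.injected_artifact = np.concatenate([truth.injected_artifact, np.ones(n_art, bool)])
    truth.derived_freq = np.concatenate([truth.derived_freq, np.full(n_art, np.nan)])

    # outgroups are uninformative at false loci: both heterozygous
    cohort.outgroup_genotypes = np.hstack(
        [cohort.outgroup_genotypes, np.ones((2, n_art), dtype=np.int8)]
    )
    return cohort


def decisions_from_truth(truth: CohortTruth) -> dict[str, str]:
    """Curation decision map that accepts exactly the non-artifact loci."""
    return {
        vid: ("REJECT" if art else "ACCEPT")
        for vid, art in zip(truth.variant_ids, truth.injected_artifact)
    }
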