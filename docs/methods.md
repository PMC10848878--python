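# Methods

## Scope and model

`svload` analyses biallelic, autosomal structural variants (DEL/DUP/INV)
genotyped across a cohort that contains a small founder-derived inbred
population, a large outbred source population, and immigrants from that
source. The scientific quantities it computes are:

**Masked and realized genetic load.** For individual *i* over a set of
putatively deleterious loci — variants that fully enclose a gene or overlap
coding sequence, restricted to loci where the *reference* allele is
ancestral so that genotype dosage counts derived alleles directly —

- masked load = n_het(i) / n_called(i)
- realized load = n_hom_derived(i) / n_called(i)

where n_called excludes missing genotypes and the three genotype counts
partition it. Masked load is diversity hidden from selection if the
deleterious alleles are recessive; realized load is expressed. Under
inbreeding, genotype frequencies shift from heterozygous to homozygous, so
masked load is expected to fall and realized load to rise with the number
of generations from the founders, and immigration is expected to reverse
both — the central contrasts the pipeline reports.

**Unfolded site-frequency spectrum.** Per locus, the derived-allele
frequency in a chosen sample subset is the derived-allele count over
2 × (non-missing individuals); the derived allele is ALT when the reference
is ancestral and REF otherwise. Frequencies are binned into 0.05-wide
intervals `[0, 0.05) … [0.95, 1.0]`; loci monomorphic in the subset are
excluded, so counts total the polymorphic locus count. Because the
genotype-frequency filter removes rare alleles by construction, spectra are
built from the callset *before* that filter (quality-filtered only), by
default restricted to deletions of 50–10,000 bp, the best-behaved class.

**Goodness of fit.** The deleterious (coding-overlap) spectrum is tested
against the neutral (intron-only) spectrum by Pearson's statistic with
expected counts equal to the neutral bin proportions scaled to the
deleterious total. Bins are pooled from the right until every expected
count is ≥ 5; the degrees of freedom are (pooled bins − 1). The statistic
therefore scales linearly with the deleterious total; this is documented
behaviour, not an invariance. Treating the neutral proportions as fixed is
justified by the large neutral-to-deleterious count imbalance typical of
these data (intronic variants outnumber coding ones by orders of
magnitude); the type-I error of the test is verified by simulation at that
imbalance.

**Polarization.** A locus is polarized only when two outgroup genotypes
agree and are homozygous; disagreement, heterozygosity or missingness in
either outgroup leaves it unpolarized (strict both-required rule — a single
informative outgroup is not accepted). Polarization also resolves the
caller's label against the reference lineage: DEL with ancestral
REF → true deletion, with ancestral ALT → insertion; DUP → copy gain vs
copy loss in the reference; INV → derived vs reference-derived orientation.

**Mendelian concordance.** A (father, mother, child) genotype triple is
consistent when the child's dosage can be formed by one allele from each
parent; of the 27 ordered triples, 15 are consistent. Per-trio concordance
is computed over loci where all three genotypes are called.

**Rank-sum contrast.** Group comparisons (e.g. immigrant offspring vs
inbred contemporaries) use the two-sample Wilcoxon rank-sum test,
two-sided. For pooled n ≤ 25 the null distribution is enumerated exactly by
dynamic programming over doubled midranks (ties handled exactly;
p = 2·min(tail probabilities), capped at 1); larger samples use the
tie-corrected normal approximation.

**Fixation and rescue.** A polarized locus is fixed pre-immigration when
every non-missing genotype in the pre-immigration subset is homozygous
derived and at least `min_called` (default 5) individuals are called — the
floor guards against spurious fixation driven by missingness. It is
regained when any post-immigration individual carries an ancestral allele.
"Founder-fixed" loci show no heterozygote and no homozygous-ancestral
genotype anywhere in the original population, i.e. the founders most likely
carried only the derived allele.

## Filtering conventions

Thresholds follow the published duphold/smoove practice and are applied
with their printed strictness: DEL pass at DHFFC < 0.7 (strict), DUP at
DHFFC > 1.3 (strict), all types at MSHQ ≥ 3 (inclusive). Inversions are
exempt from the depth criterion (a balanced event has no depth signal); a
missing DHFFC on a DEL/DUP drops the record with a warning by default.
The genotype-frequency filter requires ≥ 2 individuals of each of the three
genotypes, counting non-missing calls only, and runs on the post-quality
set; curation decisions apply last, with undecided variants rejected by
default. Each filter is idempotent and stage counts are non-increasing.
Manual curation itself (image review) is out of scope; the decision-file
interface lets real curation results plug in, and the simulator's truth
labels stand in for them in tests.

## The cohort simulator

The generator produces the full input bundle (VCF, outgroup VCF, sample and
trio tables, GFF3 gene models, repeat BED, curation decisions) plus ground
truth. Its defaults are the package's study conditions and are not tuned
per analysis:

| parameter | default | rationale |
|---|---|---|
| n_loci_deleterious / n_loci_neutral | 2000 / 6000 | a desk-scale callset; the deleterious class is deliberately enriched relative to genome-wide CDS density so per-individual load fractions are stable |
| sv_type_mix (DEL/DUP/INV) | 0.79 / 0.09 / 0.12 | raw-call proportions typical of short-read SV callers |
| founder freq, neutral | Beta(1, 3), mean 0.25 | common polymorphism in the source population |
| founder freq, deleterious | Beta(0.5, 9.5), mean 0.05 | left-shifted spectrum under purifying selection |
| prob. derived allele is reference | 0.3 | a sizeable minority of called deletions are reference-lineage insertions (TE presence/absence) |
| pedigree | 3 founders, 6 generations, `mainline` mating | see below |
| offspring per pair | 24 | a breeding pair's pooled litters over its lifetime |
| n_source | 60 | source population (two subpopulations, 2:1) |
| immigrants | 2 reproducing (gen 5) + 3 non-reproducing | late immigration event; 2 × 7 = 14 first-generation (L1) offspring |
| genotyping_error_rate | 0.02 | short-read SV genotyping error consistent with ~95% trio concordance |
| missing_rate | 0.02 | typical callset missingness |
| artifact_fraction | 0.3 | false calls spiked beyond the filter thresholds |
| polarizable_fraction | 0.6 | fraction of loci with concordant homozygous outgroups |
| DEL / DUP length peaks | 190 bp / 160 bp | SINE / LINE presence-absence polymorphisms; peak loci are coupled to matching repeat features |

**Pedigree.** The default `mainline` scheme mirrors a severely bottlenecked
founding: generation 1 descends from founder pairs (f1,f2) and (f2,f3) — so
all three founders transmit — generation 2 from a half-sib pair bridging
the two families, and each later generation from a single full-sib pair.
Inbreeding then accumulates rapidly (F ≈ 0.125, 0.31, 0.42, 0.52, 0.60 over
generations 2–6), the regime in which masked load visibly halves within a
few generations. `circular` (a ring of lineages with cousin-type mating)
and `random` (uniform pair draws, full-sib mating allowed) schemes are
available for gentler regimes. Transmission is strictly neutral
gene-dropping — one uniformly chosen allele per parent per locus,
independent across loci — so all load dynamics downstream arise from drift
and inbreeding alone; the deleterious/neutral difference is encoded only in
founder frequencies.

**Placement and annotation.** Deleterious loci are placed overlapping the
CDS of a generated gene (a fraction fully enclosing a small gene), neutral
loci wholly inside introns of genes whose CDS exons flank them, artifacts
anywhere. Peak-length DELs/DUPs (true and false alike — false calls are
triggered by the same reference repeats) receive a covering SINE/LINE
feature, plus sparse random background repeats.

**Observation layer.** True genotypes pass through a symmetric error
channel (with probability `genotyping_error_rate` a call is replaced by one
of the other two genotypes uniformly) and then missingness. Artifacts carry
DHFFC/MSHQ sampled beyond the filter thresholds and alt genotypes
concentrated in a random "sequencing batch" subset (30% of samples), which
makes them removable by quality filtering and visible as batch structure in
a PCA of rejected loci.

**What the simulator does not emulate.** No linkage or recombination map
(loci are independent — real SVs share haplotype background); no selection
during transmission (no purging); no sequence-level breakpoints or
genotype-likelihood error structure; stylized chromosome geometry; a
noise-free pedigree record. Passing tests therefore demonstrate the
*accounting and statistics* are correct under a faithful population-genetic
null, not that the filters' thresholds are optimal for any particular real
callset.

## Numerical and interface conventions

- Coordinates are 1-based inclusive internally (VCF convention); BED is
  converted at the I/O boundary, GFF3 is native. SV length prefers |SVLEN|
  when a file carries it, else END − POS + 1. The writer emits END but not
  SVLEN: modern htslib rederives END from SVLEN with padding-base
  semantics that would shift inclusive ends by one.
- DHFFC/MSHQ may be read per-record (INFO) or per-sample (FORMAT, reduced
  by the mean over called samples).
- Repeat attribution is per-base with a deterministic tie-break: features
  apply in (start, class-name) order and a base keeps its first assignment;
  class counts plus the unannotated remainder always equal the variant
  length.
- Gene-overlap categories are assigned by fixed priority (ENCLOSING first),
  so every variant gets exactly one; INTERGENIC is an explicit fourth
  category so totals are complete. "Enclosing" means the gene span is
  contained in the variant interval, inclusive at both ends. UTRs and
  introns are not distinguished inside NONCODING.
- PCA codes genotypes as ALT dosage (polarization is irrelevant for
  structure), imputes missing calls with the locus mean, centers per locus
  and takes a full SVD; components are capped at min(samples, loci) − 1.
  No LD pruning is applied.
- Degenerate inputs are reported, not silently dropped: a trio with no
  fully-called locus has undefined concordance; an individual with no
  called deleterious locus has undefined load; an all-constant genotype
  matrix is a PCA error; spectra too sparse to pool to two bins with
  expected ≥ 5 are a goodness-of-fit error (the pipeline records the
  comparison as unavailable rather than aborting).

## Problem sizes used by the test suite

The acceptance-style tests run the default 8,000-locus cohort (plus 30%
artifacts) for the load-trajectory and rescue checks (10 seeds), a
5,000-locus cohort for artifact-removal/batch-PCA checks (10 seeds),
800-locus cohorts for trio-concordance calibration (10 seeds), and 1,000
multinomial replicates at a 10,000:300 neutral:deleterious imbalance for
the goodness-of-fit calibration. These sizes are the package's choices for
stable, seedable statistical checks at desk scale.

## Known limitations

- Translocations/breakends and multi-allelic records are out of scope
  (multi-allelic records are flagged and removed at the quality stage).
- The load definitions weight every deleterious-class locus equally; no
  distribution of fitness effects is inferred.
- The exact rank-sum branch is O(n²·Σranks) in time; beyond pooled n = 25
  the tie-corrected normal approximation is used.
- Curation concordance between two curators is reported only as the size of
  the ACCEPT-intersection when a second decision file is supplied.
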