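"""Cohort simulator: determinism, gene-dropping, frequency and SFS structure."""

import numpy as np
import pytest

from svload import io
from svload.simulate import (
    ConfigError,
    SimulationConfig,
    gene_drop,
    simulate_cohort,
)
from svload.validation import trio_concordance


def test_same_seed_gives_byte_identical_vcf(tmp_path, small_config):
    a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
    for p in (a, b):
        c = simulate_cohort(small_config)
        io.write_sv_vcf(c.records, c.sample_ids, p)
    assert a.read_bytes() == b.read_bytes()


def test_error_free_cohort_is_fully_mendelian(clean_cohort):
    """Gene-dropping guarantees consistency when no noise is injected."""
    for trio in clean_cohort.trios:
        tc = trio_concordance(trio, clean_cohort.records, clean_cohort.sample_ids)
        assert tc.n_tested == len(clean_cohort.records)
        assert tc.concordance == 1.0


def test_gene_drop_degenerate_and_binomial_cases():
    ped = {"kid": ("dad", "mom")}
    hom_ref = np.zeros(10, dtype=np.int8)
    hom_alt = np.full(10, 2, dtype=np.int8)
    out = gene_drop(ped, {"dad": hom_ref, "mom": hom_ref}, seed=0)
    assert np.all(out["kid"] == 0)
    out = gene_drop(ped, {"dad": hom_alt, "mom": hom_ref}, seed=0)
    assert np.all(out["kid"] == 1)

    het = np.ones(10_000, dtype=np.int8)
    out = gene_drop(ped, {"dad": het, "mom": het}, seed=1)
    props = [(out["kid"] == k).mean() for k in (0, 1, 2)]
    assert props[0] == pytest.approx(0.25, abs=0.02)
    assert props[1] == pytest.approx(0.50, abs=0.02)
    assert props[2] == pytest.approx(0.25, abs=0.02)


def test_gene_drop_rejects_cycles():
    with pytest.raises(ValueError, match="cyclic"):
        gene_drop({"a": ("b", "f"), "b": ("a", "f")}, {"f": np.zeros(2, np.int8)}, 0)


def test_source_population_frequencies_match_config():
    """Law of large numbers: simulated source DAF tracks the Beta means."""
    cfg = SimulationConfig(
        n_loci_neutral=2000,
        n_loci_deleterious=2000,
        artifact_fraction=0.0,
        genotyping_error_rate=0.0,
        missing_rate=0.0,
        seed=3,
    )
    c = simulate_cohort(cfg)
    t = c.truth
    src = np.array([i for i, s in enumerate(c.samples) if s.population in ("FINLAND", "RUSSIA")])
    g = t.true_genotypes[:, src].astype(float)
    alt_freq = g.sum(axis=1) / (2 * src.size)
    daf = np.where(t.ancestral_allele == "ALT", 1 - alt_freq, alt_freq)
    assert daf[t.deleterious_label].mean() == pytest.approx(0.05, abs=0.02)
    assert daf[~t.deleterious_label].mean() == pytest.approx(0.25, abs=0.02)


def test_inbred_heterozygosity_declines_with_generation():
    """Expected heterozygosity is non-increasing across F1..F6 (10 seeds)."""
    per_gen = np.zeros(6)
    for seed in range(10):
        cfg = SimulationConfig(
            n_loci_neutral=400, n_loci_deleterious=100, artifact_fraction=0.0, seed=seed
        )
        c = simulate_cohort(cfg)
        info = {s.sample_id: s for s in c.samples}
        for g in range(1, 7):
            idx = [
                j
                for j, s in enumerate(c.truth.sample_ids)
                if info[s].generation_class == f"F{g}"
            ]
            per_gen[g - 1] += (c.truth.true_genotypes[:, idx] == 1).mean() / 10
    assert np.all(np.diff(per_gen) <= 0)


def test_deleterious_sfs_dominates_neutral_cumulatively(clean_cohort):
    """Deleterious derived-frequency spectrum is left-shifted vs neutral."""
    t = clean_cohort.truth
    src = np.array(
        [i for i, s in enumerate(clean_cohort.samples) if s.population in ("FINLAND", "RUSSIA")]
    )
    g = t.true_genotypes[:, src].astype(float)
    alt_freq = g.sum(axis=1) / (2 * src.size)
    daf = np.where(t.ancestral_allele == "ALT", 1 - alt_freq, alt_freq)
    poly = (daf > 0) & (daf < 1)
    edges = np.arange(0, 1.0001, 0.05)
    cum_del = np.cumsum(np.histogram(daf[poly & t.deleterious_label], bins=edges)[0])
    cum_neu = np.cumsum(np.histogram(daf[poly & ~t.deleterious_label], bins=edges)[0])
    cum_del = cum_del / cum_del[-1]
    cum_neu = cum_neu / cum_neu[-1]
    assert np.all(cum_del >= cum_neu - 0.02)
    assert cum_del[0] > cum_neu[0] + 0.1


def test_artifacts_obey_construction_contract(small_cohort, clean_cohort):
    t = small_cohort.truth
    art = t.injected_artifact
    assert art.sum() == round(0.3 * 400)
    recs = {r.variant_id: r for r in small_cohort.records}
    for vid, is_art in zip(t.variant_ids, art):
        r = recs[vid]
        if is_art:
            assert r.mshq < 3
            if r.svtype == "DEL":
                assert r.dhffc >= 0.7
            elif r.svtype == "DUP":
                assert r.dhffc <= 1.3
        else:
            assert r.mshq >= 3
    # artifact_fraction=0 leaves the record set untouched
    assert not clean_cohort.truth.injected_artifact.any()
    assert len(clean_cohort.records) == 400


def test_config_validation():
    with pytest.raises(ConfigError, match="impossible pedigree"):
        SimulationConfig(immigrant_generation=0)
    with pytest.raises(ConfigError, match="sum to 1"):
        SimulationConfig(sv_type_mix=(0.5, 0.2, 0.2))
    with pytest.raises(ConfigError, match="mating_scheme"):
        SimulationConfig(mating_scheme="polka")
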