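"""Shared fixtures: small simulated cohorts and record factories."""

from __future__ import annotations

import numpy as np
import pytest

from svload.simulate import SimulationConfig, simulate_cohort
from svload.types import SVRecord


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast cohort: 400 loci, default pedigree, artifacts included."""
    return SimulationConfig(n_loci_neutral=300, n_loci_deleterious=100, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def clean_cohort():
    """Error-free, artifact-free cohort: genotypes are exactly the truth."""
    cfg = SimulationConfig(
        n_loci_neutral=300,
        n_loci_deleterious=100,
        genotyping_error_rate=0.0,
        missing_rate=0.0,
        artifact_fraction=0.0,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def mk_record():
    """Factory for hand-built SV records with sensible defaults."""

    def _mk(
        genotypes,
        svtype="DEL",
        pos=1000,
        length=None,
        end=None,
        variant_id="v1",
        chrom="chr1",
        dhffc=0.5,
        mshq=5.0,
        **kw,
    ) -> SVRecord:
        g = np.asarray(genotypes, dtype=np.int8)
        if end is None:
            end = pos + (length or 100) - 1
        return SVRecord(
            variant_id=variant_id,
            chrom=chrom,
            pos=pos,
            end=end,
            svtype=svtype,
            length=length or (end - pos + 1),
            genotypes=g,
            dhffc=dhffc,
            mshq=mshq,
            **kw,
        )

    return _mk
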