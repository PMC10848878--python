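"""End-to-end orchestration: simulate -> filter -> validate -> annotate -> load.

Each stage reads and writes the standard exchange formats, so any stage can
be re-run from the serialized outputs of the previous one. Every emitted
TSV starts with a comment line naming the package version, a hash of the
effective configuration and the seed; a machine-readable run summary (JSON)
collects the per-stage counts and headline statistics. Everything is
deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .annotate import (
    GeneIndex,
    classify_gene_overlap,
    peak_composition,
    polarize_all,
    reference_ancestral_subset,
    repeat_composition,
)
from .filtering import FilterThresholds, apply_quality_filters, filter_cascade
from .loadstats import (
    build_sfs,
    compare_groups,
    fixation_and_rescue,
    individual_load,
    load_by_group,
    sfs_gof_test,
)
from .simulate import SimulationConfig, decisions_from_truth, simulate_cohort
from .types import OverlapCategory
from .validation import pca_genotypes, trio_concordance

logger = logging.getLogger("svload")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "write_cohort_inputs"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Declarative configuration for a full run.

    In self-test mode (``simulate=True``) all inputs are generated by the
    cohort simulator and the file paths are filled in automatically.
    """

    out_dir: str = "svload_run"
    vcf: str | None = None
    samples: str | None = None
    pedigree: str | None = None
    genes: str | None = None
    repeats: str | None = None
    outgroups: str | None = None
    decisions: str | None = None
    simulate: bool = False
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    pca_components: int = 20
    sfs_length_window: tuple[int, int] = (50, 10_000)
    sfs_svtype: str | None = "DEL"
    rescue_min_called: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        thr = FilterThresholds(**raw.pop("thresholds", {}))
        sim_raw = raw.pop("sim", {})
        seed = raw.get("seed", 0)
        sim = SimulationConfig(**{"seed": seed, **sim_raw})
        return cls(thresholds=thr, sim=sim, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _tsv_header(config: PipelineConfig) -> str:
    return f"# svload {__version__} config={config.config_hash()} seed={config.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_tsv_header(config))
        df.to_csv(fh, sep="\t", index=False)


def write_cohort_inputs(cohort, out_dir: Path) -> dict[str, Path]:
    """Serialize a simulated cohort into the exchange formats the pipeline reads."""
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / "cohort.vcf",
        "outgroups": out_dir / "outgroups.vcf",
        "samples": out_dir / "samples.tsv",
        "pedigree": out_dir / "trios.tsv",
        "genes": out_dir / "genes.gff3",
        "repeats": out_dir / "repeats.bed",
        "decisions": out_dir / "decisions.tsv",
        "truth": out_dir / "truth.tsv",
    }
    io.write_sv_vcf(cohort.records, cohort.sample_ids, paths["vcf"])
    out_records = []
    for i, r in enumerate(cohort.records):
        o = dataclasses.replace(r, genotypes=cohort.outgroup_genotypes[:, i].copy())
        out_records.append(o)
    io.write_sv_vcf(out_records, cohort.outgroup_ids, paths["outgroups"])
    io.write_samples(cohort.samples, paths["samples"])
    io.write_pedigree(cohort.trios, paths["pedigree"])
    io.write_gene_models_gff3(cohort.genes, paths["genes"])
    io.write_repeats_bed(cohort.repeats, paths["repeats"])
    io.write_decisions(decisions_from_truth(cohort.truth), paths["decisions"])
    t = cohort.truth
    pd.DataFrame(
        {
            "variant_id": t.variant_ids,
            "deleterious": t.deleterious_label.astype(int),
            "ancestral": t.ancestral_allele,
            "artifact": t.injected_artifact.astype(int),
            "derived_freq": t.derived_freq,
        }
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order; returns the machine-readable run summary.

    Raises :class:`PipelineError` naming the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }

    # -- stage: simulate / load inputs ---------------------------------------
    stage = "simulate" if config.simulate else "load_inputs"
    try:
        if config.simulate:
            cohort = simulate_cohort(
                dataclasses.replace(config.sim, seed=config.seed)
            )
            paths = write_cohort_inputs(cohort, out / "inputs")
            for key, p in paths.items():
                if getattr(config, key, None) is None and key != "truth":
                    setattr(config, key, str(p))
        for key in ("vcf", "samples", "pedigree", "genes", "repeats", "outgroups"):
            p = getattr(config, key)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"missing input '{key}': {p}")
        records, sample_ids = io.read_sv_vcf(config.vcf)
        samples = io.read_samples(config.samples)
        trios = io.read_pedigree(config.pedigree)
        io.check_cohort_integrity(samples, trios, sample_ids)
        genes, repeats = io.read_annotations(config.genes, config.repeats)
        out_records, out_ids = io.read_sv_vcf(config.outgroups)
        if len(out_ids) != 2:
            raise ValueError(f"outgroup VCF must carry exactly 2 samples, has {len(out_ids)}")
        outgroup_gts = np.vstack([r.genotypes for r in out_records]).T
        outgroup_vids = [r.variant_id for r in out_records]
        decisions = io.read_decisions(config.decisions) if config.decisions else None
        summary[stage] = {"n_records": len(records), "n_samples": len(sample_ids)}
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    # -- stage: filter ---------------------------------------------------------
    try:
        filtered, report = filter_cascade(records, config.thresholds, decisions)
        _write_tsv(report.to_frame(), out / "filter_report.tsv", config)
        io.write_sv_vcf(filtered, sample_ids, out / "filtered.vcf")
        summary["filter"] = {
            "stage_counts": report.stage_counts,
            "removal_fractions": report.removal_fractions(),
        }
    except Exception as exc:
        raise PipelineError(f"stage 'filter' failed: {exc}") from exc

    # -- stage: validate -------------------------------------------------------
    try:
        concs = [trio_concordance(t, filtered, sample_ids) for t in trios]
        conc_df = pd.DataFrame(
            {
                "child": [c.trio.child for c in concs],
                "n_tested": [c.n_tested for c in concs],
                "n_consistent": [c.n_consistent for c in concs],
                "concordance": [c.concordance for c in concs],
            }
        )
        _write_tsv(conc_df, out / "trio_concordance.tsv", config)
        pca = pca_genotypes(filtered, sample_ids, config.pca_components)
        scores = pd.DataFrame(
            pca.scores,
            columns=[f"PC{i+1}" for i in range(pca.n_components)],
        )
        scores.insert(0, "sample_id", pca.sample_ids)
        _write_tsv(scores, out / "pca_scores.tsv", config)
        defined = [c.concordance for c in concs if c.concordance is not None]
        summary["validate"] = {
            "n_trios": len(concs),
            "mean_concordance": float(np.mean(defined)) if defined else None,
            "pca_explained_variance_top2": [float(v) for v in pca.explained_variance[:2]],
        }
    except Exception as exc:
        raise PipelineError(f"stage 'validate' failed: {exc}") from exc

    # -- stage: annotate -------------------------------------------------------
    try:
        index = GeneIndex(genes)
        # quality-only set retains rare alleles for the SFS
        quality_set, _ = apply_quality_filters(records, config.thresholds)
        annotate_set = list({x.variant_id: x for x in quality_set + filtered}.values())
        categories: dict[str, OverlapCategory] = {}
        gene_hits: dict[str, list[str]] = {}
        for r in annotate_set:
            cat, hits = classify_gene_overlap(r, index)
            categories[r.variant_id] = cat
            gene_hits[r.variant_id] = hits
        calls = polarize_all(annotate_set, outgroup_gts, outgroup_vids)
        ref_anc = reference_ancestral_subset(calls)
        ann_rows = []
        for r in filtered:
            comp = repeat_composition(r, repeats)
            top_class = max(comp.bases_per_class, key=comp.bases_per_class.get) if comp.bases_per_class else ""
            ann_rows.append(
                {
                    "variant_id": r.variant_id,
                    "svtype": r.svtype,
                    "length": r.length,
                    "category": categories[r.variant_id].value,
                    "genes": ",".join(gene_hits[r.variant_id]),
                    "ancestral": calls[r.variant_id].ancestral.value,
                    "mutation_class": calls[r.variant_id].mutation_class.value,
                    "top_repeat_class": top_class,
                    "repeat_bases": sum(comp.bases_per_class.values()),
                }
            )
        _write_tsv(pd.DataFrame(ann_rows), out / "annotated.tsv", config)
        pol_filtered = [calls[r.variant_id] for r in filtered]
        cat_counts = pd.Series([categories[r.variant_id].value for r in filtered]).value_counts()
        del_peak = peak_composition(filtered, repeats, (180, 200), svtype="DEL")
        summary["annotate"] = {
            "category_counts": cat_counts.to_dict(),
            "polarized_fraction": float(
                np.mean([c.ancestral.value != "UNPOLARIZED" for c in pol_filtered])
            )
            if pol_filtered
            else 0.0,
            "mutation_class_counts": pd.Series(
                [c.mutation_class.value for c in pol_filtered]
            )
            .value_counts()
            .to_dict(),
            "del_peak_composition": del_peak,
        }
    except Exception as exc:
        raise PipelineError(f"stage 'annotate' failed: {exc}") from exc

    # -- stage: load -----------------------------------------------------------
    try:
        info_by_id = {s.sample_id: s for s in samples}
        unrelated_pops = {"FINLAND", "RUSSIA", "IMMIGRANT_R", "IMMIGRANT_NR", "FOUNDER"}
        sfs_idx = np.array(
            [i for i, s in enumerate(sample_ids) if info_by_id[s].population in unrelated_pops]
        )
        sfs_del = build_sfs(
            quality_set, calls, sfs_idx, categories, "DELETERIOUS",
            length_window=config.sfs_length_window, svtype=config.sfs_svtype,
        )
        sfs_neu = build_sfs(
            quality_set, calls, sfs_idx, categories, "NEUTRAL",
            length_window=config.sfs_length_window, svtype=config.sfs_svtype,
        )
        sfs_df = pd.DataFrame(
            {
                "bin_low": sfs_del.bin_edges[:-1],
                "bin_high": sfs_del.bin_edges[1:],
                "deleterious": sfs_del.counts,
                "neutral": sfs_neu.counts,
            }
        )
        _write_tsv(sfs_df, out / "sfs.tsv", config)
        try:
            gof = dict(zip(("statistic", "df", "p"), sfs_gof_test(sfs_del, sfs_neu)))
        except ValueError as exc:  # too few counts to compare spectra
            logger.warning("SFS comparison skipped: %s", exc)
            gof = None

        load_summaries = [
            individual_load(filtered, ref_anc, s.sample_id, sample_ids, categories)
            for s in samples
        ]
        load_df = pd.DataFrame(
            {
                "sample_id": [ls.sample_id for ls in load_summaries],
                "n_loci_called": [ls.n_loci_called for ls in load_summaries],
                "n_het": [ls.n_het for ls in load_summaries],
                "n_hom_derived": [ls.n_hom_derived for ls in load_summaries],
                "masked_load": [ls.masked_load for ls in load_summaries],
                "realized_load": [ls.realized_load for ls in load_summaries],
            }
        )
        _write_tsv(load_df, out / "individual_load.tsv", config)
        groups = load_by_group(load_summaries, samples)
        _write_tsv(groups, out / "load_by_group.tsv", config)

        def _class_idx(cls: str) -> list[int]:
            return [
                i
                for i, s in enumerate(sample_ids)
                if info_by_id[s].generation_class == cls
            ]

        l1 = [ls for ls in load_summaries if info_by_id[ls.sample_id].generation_class == "L1"]
        f_last = [
            ls
            for ls in load_summaries
            if info_by_id[ls.sample_id].generation_class == f"F{config.sim.n_generations}"
        ]
        comparison = {}
        if l1 and f_last:
            w_m, p_m = compare_groups(
                [x.masked_load for x in l1 if x.n_loci_called],
                [x.masked_load for x in f_last if x.n_loci_called],
            )
            w_r, p_r = compare_groups(
                [x.realized_load for x in l1 if x.n_loci_called],
                [x.realized_load for x in f_last if x.n_loci_called],
            )
            comparison = {
                "masked_ranksum_p": p_m,
                "realized_ranksum_p": p_r,
                "n_immigrant_offspring": len(l1),
                "n_inbred_contemporaries": len(f_last),
            }
            _write_tsv(
                pd.DataFrame([comparison]), out / "group_comparison.tsv", config
            )

        pre_classes = {f"F{g}" for g in (config.sim.immigrant_generation, config.sim.n_generations)}
        pre_idx = np.array(
            [i for i, s in enumerate(sample_ids) if info_by_id[s].generation_class in pre_classes]
        )
        post_idx = np.array(
            [i for i, s in enumerate(sample_ids) if info_by_id[s].generation_class == "L1"]
        )
        original_idx = np.array(
            [i for i, s in enumerate(sample_ids) if info_by_id[s].population == "SCAND_ORIGINAL"]
        )
        rescue = None
        if pre_idx.size and post_idx.size:
            rescue = fixation_and_rescue(
                filtered, calls, pre_idx, post_idx, original_idx, config.rescue_min_called
            )
            _write_tsv(
                pd.DataFrame(
                    [
                        {
                            "n_fixed_pre": rescue.n_fixed_pre,
                            "n_regained": rescue.n_regained,
                            "n_founder_fixed": rescue.n_founder_fixed,
                            "n_founder_regained": rescue.n_founder_regained,
                        }
                    ]
                ),
                out / "rescue.tsv",
                config,
            )
        summary["load"] = {
            "sfs_gof": gof,
            "sfs_totals": {
                "deleterious": int(sfs_del.counts.sum()),
                "neutral": int(sfs_neu.counts.sum()),
            },
            "group_means": groups.to_dict(orient="records"),
            "rescue": dataclasses.asdict(rescue) if rescue else None,
            "immigrant_comparison": comparison or None,
        }
    except Exception as exc:
        raise PipelineError(f"stage 'load' failed: {exc}") from exc

    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
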