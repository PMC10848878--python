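"""Readers and writers for the formats the pipeline touches.

VCF is the primary carrier: coordinates are kept 1-based inclusive
internally, exactly as read. BED input (0-based half-open) is converted at
this boundary and nowhere else. DHFFC/MSHQ may live either in INFO
(one value per record, the smoove default emulated here) or in FORMAT
(per sample, reduced by the mean) — pick with ``dhffc_source``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pysam

from .types import (
    GeneModel,
    Genotype,
    RepeatFeature,
    SampleInfo,
    SVRecord,
    SV_TYPES,
    Trio,
)

logger = logging.getLogger("svload")

__all__ = [
    "FormatError",
    "ValidationError",
    "read_sv_vcf",
    "write_sv_vcf",
    "read_annotations",
    "read_gene_models",
    "read_repeat_bed",
    "read_pedigree",
    "read_samples",
    "read_decisions",
    "write_samples",
    "write_pedigree",
    "write_decisions",
    "write_gene_models_gff3",
    "write_repeats_bed",
    "check_cohort_integrity",
]


class FormatError(ValueError):
    """Malformed input file (bad coordinates, unknown ploidy, missing header)."""


class ValidationError(ValueError):
    """Referentially inconsistent inputs (unknown or duplicated sample ids)."""


_SEX_CHROMS = {"X", "Y", "chrX", "chrY", "chrZ", "chrW", "Z", "W", "MT", "chrM"}


def _parse_gt(gt: tuple, variant_id: str) -> int:
    """Translate a pysam GT tuple into a Genotype code."""
    if len(gt) != 2:
        raise FormatError(
            f"{variant_id}: genotype ploidy {len(gt)} is not diploid ({gt!r})"
        )
    if gt[0] is None or gt[1] is None:
        return int(Genotype.MISSING)
    n_alt = sum(1 for a in gt if a > 0)
    return n_alt  # 0 HOM_REF, 1 HET, 2 HOM_ALT


def read_sv_vcf(
    path: str | Path,
    dhffc_source: str = "info",
    autosome_names: set[str] | None = None,
) -> tuple[list[SVRecord], list[str]]:
    """Read a multi-sample SV VCF into records plus the sample order.

    Records whose SVTYPE is not DEL/DUP/INV are skipped (the skip count is
    logged). Multi-allelic records are kept but flagged ``is_biallelic=False``
    so the quality filter can drop them. Length prefers |SVLEN| when present,
    falling back to END − POS + 1.

    Parameters
    ----------
    dhffc_source
        ``"info"`` (per-record values) or ``"format"`` (per-sample values,
        reduced by the mean over non-missing samples).
    autosome_names
        Chromosome names regarded as autosomal; default: everything except
        common sex/mitochondrial names.
    """
    if dhffc_source not in ("info", "format"):
        raise ValueError("dhffc_source must be 'info' or 'format'")
    try:
        vcf = pysam.VariantFile(str(path))
    except ValueError as exc:
        raise FormatError(f"{path}: not a valid VCF ({exc})") from exc
    samples = list(vcf.header.samples)
    records: list[SVRecord] = []
    n_skipped = 0
    for rec in vcf:
        svtype = _info_get(rec, "SVTYPE")
        if svtype not in SV_TYPES:
            n_skipped += 1
            continue
        variant_id = rec.id or f"{rec.chrom}_{rec.pos}_{svtype}"
        end = rec.stop  # pysam: 0-based exclusive == 1-based inclusive END
        svlen = _info_get(rec, "SVLEN")
        if isinstance(svlen, tuple):
            svlen = svlen[0]
        length = abs(int(svlen)) if svlen is not None else end - rec.pos + 1
        gts = np.empty(len(samples), dtype=np.int8)
        for i, s in enumerate(samples):
            gts[i] = _parse_gt(rec.samples[s].get("GT", (None, None)), variant_id)
        if dhffc_source == "info":
            dhffc = _scalar(_info_get(rec, "DHFFC"))
            mshq = _scalar(_info_get(rec, "MSHQ"))
        else:
            dhffc = _format_mean(rec, samples, "DHFFC")
            mshq = _format_mean(rec, samples, "SHQ")
        is_auto = (
            rec.chrom in autosome_names
            if autosome_names is not None
            else rec.chrom not in _SEX_CHROMS
        )
        records.append(
            SVRecord(
                variant_id=variant_id,
                chrom=rec.chrom,
                pos=rec.pos,
                end=end,
                svtype=svtype,
                length=max(length, 1),
                genotypes=gts,
                dhffc=dhffc,
                mshq=mshq,
                is_autosomal=is_auto,
                is_biallelic=len(rec.alts or ()) == 1,
            )
        )
    if n_skipped:
        logger.info("read_sv_vcf: skipped %d records with SVTYPE outside %s", n_skipped, SV_TYPES)
    return records, samples


def _info_get(rec, key):
    """INFO accessor tolerant of keys absent from the header."""
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _scalar(v) -> float:
    if v is None:
        return float("nan")
    if isinstance(v, tuple):
        v = v[0]
    return float(v)


def _format_mean(rec, samples: list[str], key: str) -> float:
    vals = []
    for s in samples:
        v = rec.samples[s].get(key)
        if v is not None and not (isinstance(v, float) and np.isnan(v)):
            vals.append(float(v))
    return float(np.mean(vals)) if vals else float("nan")


def write_sv_vcf(
    records: list[SVRecord],
    sample_ids: list[str],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write records as a VCF 4.2 file with symbolic ALT alleles.

    DHFFC/MSHQ go into INFO; a NaN DHFFC (inversions) is omitted rather
    than written. SVLEN is not emitted: END fully determines the length
    under the 1-based inclusive convention, and modern htslib rederives
    END from SVLEN with padding-base semantics that would shift it.
    """
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="1-based inclusive end">')
    header.add_line(
        '##INFO=<ID=DHFFC,Number=1,Type=Float,Description="Duphold depth fold-change vs flanks">'
    )
    header.add_line(
        '##INFO=<ID=MSHQ,Number=1,Type=Float,Description="Mean smoove heterozygosity score">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##ALT=<ID=DEL,Description="Deletion">')
    header.add_line('##ALT=<ID=DUP,Description="Duplication">')
    header.add_line('##ALT=<ID=INV,Description="Inversion">')
    chroms: dict[str, int] = {}
    for r in records:
        chroms[r.chrom] = max(chroms.get(r.chrom, 0), r.end + 1000)
    if contig_lengths:
        chroms.update(contig_lengths)
    for chrom, ln in chroms.items():
        header.add_line(f"##contig=<ID={chrom},length={ln}>")
    for s in sample_ids:
        header.add_sample(s)

    gt_tuples = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.variant_id)):
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                stop=r.end,
                alleles=("N", f"<{r.svtype}>"),
                id=r.variant_id,
            )
            rec.info["SVTYPE"] = r.svtype
            if not np.isnan(r.dhffc):
                rec.info["DHFFC"] = r.dhffc
            if not np.isnan(r.mshq):
                rec.info["MSHQ"] = r.mshq
            for i, s in enumerate(sample_ids):
                rec.samples[s]["GT"] = gt_tuples[int(r.genotypes[i])]
            out.write(rec)


# ---------------------------------------------------------------------------
# Gene models and repeats
# ---------------------------------------------------------------------------


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (``.gff``/``.gff3``) or BED12 (``.bed``)."""
    p = Path(path)
    if p.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3_genes(p)
    if p.suffix.lower() == ".bed":
        return _read_bed12_genes(p)
    raise FormatError(f"{path}: unknown gene-model format (expect .gff3 or .bed)")


def _read_gff3_genes(path: Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        cds = [(c.start, c.end) for c in db.children(g, featuretype="CDS")]
        gene_id = g.attributes.get("ID", [g.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=g.seqid,
                gene_span=(g.start, g.end),  # gffutils keeps GFF3 1-based inclusive
                cds_intervals=cds,
                strand=g.strand if g.strand in "+-" else "+",
            )
        )
    return genes


def _read_bed12_genes(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 12:
        raise FormatError(f"{path}: BED12 requires 12 columns, found {df.shape[1]}")
    for row in df.itertuples(index=False):
        chrom, start, end, name = row[0], int(row[1]), int(row[2]), row[3]
        strand = row[5]
        thick_s, thick_e = int(row[6]), int(row[7])
        sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row[11]).rstrip(",").split(",")]
        _check_bed_coords(chrom, start, end, path)
        cds = []
        for size, off in zip(sizes, offsets):
            bs, be = start + off, start + off + size  # 0-based half-open block
            cs, ce = max(bs, thick_s), min(be, thick_e)
            if cs < ce:
                cds.append((cs + 1, ce))  # to 1-based inclusive
        genes.append(
            GeneModel(
                gene_id=name,
                chrom=chrom,
                gene_span=(start + 1, end),
                cds_intervals=cds,
                strand=strand if strand in "+-" else "+",
            )
        )
    return genes


def read_repeat_bed(path: str | Path) -> list[RepeatFeature]:
    """Read repeat annotation from BED4+ (name column = repeat class)."""
    feats: list[RepeatFeature] = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise FormatError(f"{path}: repeat BED requires >= 4 columns")
    for row in df.itertuples(index=False):
        chrom, start, end, cls = row[0], int(row[1]), int(row[2]), row[3]
        _check_bed_coords(chrom, start, end, path)
        feats.append(RepeatFeature(chrom=chrom, start=start + 1, end=end, repeat_class=cls))
    return feats


def _check_bed_coords(chrom: str, start: int, end: int, path) -> None:
    if start < 0 or end < 0:
        raise FormatError(f"{path}: negative coordinate on {chrom}:{start}-{end}")
    if end <= start:
        raise FormatError(f"{path}: out-of-order interval {chrom}:{start}-{end}")


def read_annotations(
    gene_path: str | Path, repeat_path: str | Path
) -> tuple[list[GeneModel], list[RepeatFeature]]:
    """Read gene models and repeat features, normalized to 1-based inclusive."""
    return read_gene_models(gene_path), read_repeat_bed(repeat_path)


# ---------------------------------------------------------------------------
# Samples, pedigree, curation decisions
# ---------------------------------------------------------------------------


def read_samples(path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"sample_id", "population"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: sample table needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dups = sorted(df["sample_id"][df["sample_id"].duplicated()].unique())
        raise ValidationError(f"{path}: duplicated sample ids {dups}")
    out = []
    for row in df.itertuples(index=False):
        gen = getattr(row, "generation_class", None)
        cov = getattr(row, "coverage", None)
        out.append(
            SampleInfo(
                sample_id=row.sample_id,
                population=row.population,
                generation_class=None if gen in (None, "", "NA") or pd.isna(gen) else gen,
                coverage=None if cov in (None, "", "NA") or pd.isna(cov) else float(cov),
            )
        )
    return out


def read_pedigree(path: str | Path) -> list[Trio]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"child", "father", "mother"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: pedigree needs columns {sorted(required)}")
    return [Trio(child=r.child, father=r.father, mother=r.mother) for r in df.itertuples(index=False)]


def read_decisions(path: str | Path) -> dict[str, str]:
    """Read a curation decision file: variant_id TAB ACCEPT|REJECT."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"variant_id", "decision"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: decision file needs columns {sorted(required)}")
    if df["variant_id"].duplicated().any():
        dups = sorted(df["variant_id"][df["variant_id"].duplicated()].unique())
        raise ValidationError(f"{path}: duplicate decisions for {dups[:5]}")
    bad = set(df["decision"]) - {"ACCEPT", "REJECT"}
    if bad:
        raise FormatError(f"{path}: unknown decisions {sorted(bad)}")
    return dict(zip(df["variant_id"], df["decision"]))


def write_samples(samples: list[SampleInfo], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "population": [s.population for s in samples],
            "generation_class": [s.generation_class or "" for s in samples],
            "coverage": [s.coverage if s.coverage is not None else "" for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def write_pedigree(trios: list[Trio], path: str | Path) -> None:
    pd.DataFrame(
        {
            "child": [t.child for t in trios],
            "father": [t.father for t in trios],
            "mother": [t.mother for t in trios],
        }
    ).to_csv(path, sep="\t", index=False)


def write_gene_models_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene + CDS features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.gene_span[0], g.gene_id)):
            lo, hi = g.gene_span
            fh.write(
                f"{g.chrom}\tsvload\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for k, (s, e) in enumerate(g.cds_intervals):
                fh.write(
                    f"{g.chrom}\tsvload\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{k};Parent={g.gene_id}\n"
                )


def write_repeats_bed(repeats: list[RepeatFeature], path: str | Path) -> None:
    """Write repeat features as BED4 (0-based half-open)."""
    with open(path, "w") as fh:
        for r in sorted(repeats, key=lambda r: (r.chrom, r.start, r.repeat_class)):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.repeat_class}\n")


def write_decisions(decisions: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"variant_id": list(decisions), "decision": list(decisions.values())}
    ).to_csv(path, sep="\t", index=False)


def check_cohort_integrity(
    samples: list[SampleInfo], trios: list[Trio], vcf_sample_ids: list[str]
) -> None:
    """Referential-integrity check between sample table, pedigree and VCF."""
    ids = {s.sample_id for s in samples}
    if len(ids) != len(samples):
        raise ValidationError("duplicated sample_id in sample table")
    missing = ids - set(vcf_sample_ids)
    if missing:
        raise ValidationError(f"samples absent from VCF: {sorted(missing)}")
    for t in trios:
        unknown = {t.child, t.father, t.mother} - ids
        if unknown:
            raise ValidationError(f"trio {t} references unknown samples {sorted(unknown)}")
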