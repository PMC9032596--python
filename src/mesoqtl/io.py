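"""Readers and writers for the pipeline's tabular and variant formats.

All tabular interchange is TSV; regions export both a 1-based inclusive
report table and 0-based half-open BED; variants travel as VCF v4.2 with one
sample column per parent/pool and an AD (ref,alt depth) FORMAT field.
Every writer/reader pair round-trips losslessly on simulated data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .bsaseq import PoolVariantSite
from .genmap import F2GenotypeMatrix, GeneticMap
from .regions import GenomicRegion

DEFAULT_SAMPLES = ("W64A", "K12", "LM", "SM")
ROLES = ("parent1", "parent2", "LM", "SM")


class FormatError(ValueError):
    """A file does not satisfy the declared format contract."""


# --------------------------------------------------------------------- tables


def write_map_tsv(gmap: GeneticMap, path) -> None:
    t = gmap.table.copy()
    t["cm"] = t["cm"].map(lambda v: f"{v:.4f}")
    t.to_csv(path, sep="\t", index=False)


def read_map_tsv(path) -> GeneticMap:
    t = pd.read_csv(path, sep="\t", dtype={"marker": str})
    try:
        return GeneticMap(t)
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e


def write_genotypes_tsv(genos: F2GenotypeMatrix, path) -> None:
    genos.to_frame().rename_axis("individual").to_csv(path, sep="\t")


def read_genotypes_tsv(path, gmap: GeneticMap | None = None) -> F2GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        genos = F2GenotypeMatrix.from_frame(df)
        if gmap is not None:
            genos.check_against_map(gmap)
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e
    return genos


def write_phenotypes_tsv(table: pd.DataFrame, path) -> None:
    t = table.copy()
    t["value"] = t["value"].map(lambda v: f"{v:.6f}")
    t.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    required = {"family", "environment", "replicate", "value"}
    missing = required - set(t.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    t["family"] = t["family"].astype(str)
    t["value"] = t["value"].astype(float)
    return t


def read_deg_tsv(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    required = {"gene_id", "comparison", "log2fc", "fdr"}
    missing = required - set(t.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return t


def read_annotation_tsv(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "start", "end"}
    missing = required - set(t.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return t


def read_external_qtl_tsv(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    required = {"study", "trait", "chrom", "start", "end"}
    missing = required - set(t.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return t


# -------------------------------------------------------------------- regions


def write_regions(regions: list[GenomicRegion], tsv_path, bed_path=None) -> None:
    """1-based inclusive report TSV plus optional 0-based half-open BED."""
    rows = [
        {
            "region": r.label or f"{r.chrom}:{r.start}-{r.end}",
            "chrom": r.chrom,
            "start_bp": r.start,
            "end_bp": r.end,
            "length_mb": f"{r.length_mb:.2f}",
        }
        for r in regions
    ]
    pd.DataFrame(
        rows, columns=["region", "chrom", "start_bp", "end_bp", "length_mb"]
    ).to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for r in regions:
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.label}\n")


def read_regions_tsv(path) -> list[GenomicRegion]:
    t = pd.read_csv(path, sep="\t")
    required = {"chrom", "start_bp", "end_bp"}
    missing = required - set(t.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        GenomicRegion(
            str(r.chrom), int(r.start_bp), int(r.end_bp),
            str(getattr(r, "region", "")) if "region" in t.columns else "",
        )
        for r in t.itertuples(index=False)
    ]


# ------------------------------------------------------------------------ VCF


def write_pool_vcf(
    sites: list[PoolVariantSite],
    path,
    samples: tuple = DEFAULT_SAMPLES,
    contigs: dict | None = None,
) -> None:
    """VCF v4.2 with GT and AD per sample; samples order parent1, parent2, LM, SM."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=mesoqtl",
        '##INFO=<ID=VC,Number=1,Type=String,Description="Variant class (SNP or InDel)">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depths per allele">',
    ]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    ordered = sorted(sites, key=lambda s: (str(s.chrom), s.pos))
    for s in ordered:
        fields = [
            str(s.chrom), str(s.pos), ".", s.ref, s.alt, ".", "PASS",
            f"VC={s.variant_class}", "GT:AD",
            f"{s.parent1_gt}:{s.p1_ref},{s.p1_alt}",
            f"{s.parent2_gt}:{s.p2_ref},{s.p2_alt}",
            f"./.:{s.lm_ref},{s.lm_alt}",
            f"./.:{s.sm_ref},{s.sm_alt}",
        ]
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_pools(path, sample_roles: dict | None = None):
    """Parse a 4-sample pool VCF into PoolVariantSites.

    sample_roles maps sample name -> role in {parent1, parent2, LM, SM}.
    Multiallelic records are skipped (count returned). Returns
    (sites, n_multiallelic_skipped).
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if sample_roles is None:
        if len(samples) != 4:
            raise FormatError(
                f"{path}: expected 4 samples for default role mapping, got {samples}"
            )
        sample_roles = dict(zip(samples, ROLES))
    missing_roles = set(ROLES) - set(sample_roles.values())
    if missing_roles:
        raise FormatError(f"{path}: no sample assigned to roles {sorted(missing_roles)}")
    unknown = set(sample_roles) - set(samples)
    if unknown:
        raise FormatError(f"{path}: role mapping names absent samples {sorted(unknown)}")
    by_role = {role: name for name, role in sample_roles.items()}

    sites: list[PoolVariantSite] = []
    n_skipped = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_skipped += 1
            continue
        depths = {}
        gts = {}
        for role in ROLES:
            sample = rec.samples[by_role[role]]
            ad = sample.get("AD")
            if ad is None or all(v is None for v in ad):
                raise FormatError(
                    f"{path}: sample {by_role[role]!r} lacks AD at {rec.chrom}:{rec.pos}"
                )
            depths[role] = (int(ad[0] or 0), int(ad[1] or 0))
            gt = sample.get("GT")
            if gt is None or all(v is None for v in gt):
                gts[role] = "./."
            else:
                gts[role] = "/".join("." if v is None else str(v) for v in gt)
        ref, alt = rec.ref, rec.alts[0]
        vclass = "SNP" if len(ref) == 1 and len(alt) == 1 else "InDel"
        sites.append(
            PoolVariantSite(
                chrom=str(rec.chrom),
                pos=int(rec.pos),
                ref=ref,
                alt=alt,
                variant_class=vclass,
                parent1_gt=gts["parent1"],
                parent2_gt=gts["parent2"],
                lm_ref=depths["LM"][0], lm_alt=depths["LM"][1],
                sm_ref=depths["SM"][0], sm_alt=depths["SM"][1],
                p1_ref=depths["parent1"][0], p1_alt=depths["parent1"][1],
                p2_ref=depths["parent2"][0], p2_alt=depths["parent2"][1],
            )
        )
    vf.close()
    return sites, n_skipped


# ----------------------------------------------------------------------- misc


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, Path):
        return str(v)
    raise TypeError(f"not JSON-serializable: {type(v)}")
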