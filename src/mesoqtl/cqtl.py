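"""Constitutive-QTL (cQTL) integration and candidate-gene nomination.

A cQTL is a cluster of overlapping (or near-adjacent) physical evidence
intervals for the same trait complex: CIM QTL support intervals projected to
physical coordinates, BSA-linked regions, and externally reported QTL. The
default clustering gap is 2 Mb — the smallest round value that unifies the
six chromosome-4 BSA regions of the study design into one envelope — and is
exposed because no published rule exists.

Candidate genes are the genes inside a cQTL envelope that are differentially
expressed in at least one parental comparison after the strict thresholds
FDR < 0.001 and |log2FC| > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genmap import GeneticMap
from .qtlscan import QTLPeak
from .regions import GenomicRegion


@dataclass(frozen=True)
class EvidenceInterval:
    """A physical interval with its provenance (QTL scan, BSA, or external)."""

    region: GenomicRegion
    source: str                  # e.g. "qMES4-1/20cm", "BSA-SNP4-1", "study:Han2020"
    kind: str                    # "QTL" | "BSA" | "external"
    pve: float | None = None
    lod: float | None = None
    delta: float | None = None

    def __post_init__(self):
        if not self.source:
            raise ValueError("evidence source must be non-empty")
        if self.kind not in ("QTL", "BSA", "external"):
            raise ValueError(f"unknown evidence kind {self.kind!r}")


@dataclass
class CQTLReport:
    name: str
    envelope: GenomicRegion
    members: list[EvidenceInterval]
    summed_pve: float

    def __post_init__(self):
        for m in self.members:
            if m.region.chrom != self.envelope.chrom:
                raise ValueError("member on a different chromosome than the envelope")
            if m.region.start < self.envelope.start or m.region.end > self.envelope.end:
                raise ValueError("envelope does not cover member " + m.source)


def qtl_physical_interval(peak: QTLPeak, gmap: GeneticMap) -> GenomicRegion:
    """Physical support interval of a QTL peak: bp span of its flanking markers."""
    left, right = peak.marker_interval
    t = gmap.table
    rows = {name: t[t["marker"] == name] for name in (left, right)}
    for name, row in rows.items():
        if row.empty:
            raise ValueError(f"flanking marker {name!r} not on map")
        if pd.isna(row["bp"].iloc[0]):
            raise ValueError(f"flanking marker {name!r} lacks a physical position")
    start = int(rows[left]["bp"].iloc[0])
    end = int(rows[right]["bp"].iloc[0])
    if start == end:
        raise ValueError(f"zero-length physical interval for {peak.name}")
    if start > end:
        start, end = end, start
    return GenomicRegion(str(peak.chrom), start, end, label=peak.name)


def merge_evidence(
    intervals: list[EvidenceInterval], max_gap_bp: int = 2_000_000
) -> list[list[EvidenceInterval]]:
    """Single-linkage clusters of same-chromosome intervals with gap <= max_gap_bp.

    Deterministic and order-independent: intervals are sorted by
    (chrom, start, end, source) before the sweep.
    """
    by_chrom: dict[str, list[EvidenceInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.region.chrom, []).append(iv)
    clusters: list[list[EvidenceInterval]] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.region.start, v.region.end, v.source))
        cur = [ivs[0]]
        cur_end = ivs[0].region.end
        for iv in ivs[1:]:
            if iv.region.start - cur_end - 1 <= max_gap_bp:
                cur.append(iv)
                cur_end = max(cur_end, iv.region.end)
            else:
                clusters.append(cur)
                cur = [iv]
                cur_end = iv.region.end
        clusters.append(cur)
    return clusters


def define_cqtl(
    cluster: list[EvidenceInterval],
    name: str,
    require_qtl: bool = True,
    require_bsa: bool = True,
) -> CQTLReport | None:
    """Envelope of a cluster, or None when the membership rule fails.

    By default a cQTL must combine at least one QTL-derived and one
    BSA-derived interval (external evidence counts as QTL support).
    """
    kinds = {iv.kind for iv in cluster}
    if require_qtl and not kinds & {"QTL", "external"}:
        return None
    if require_bsa and "BSA" not in kinds:
        return None
    start = min(iv.region.start for iv in cluster)
    end = max(iv.region.end for iv in cluster)
    chrom = cluster[0].region.chrom
    summed = sum(iv.pve for iv in cluster if iv.pve is not None)
    return CQTLReport(
        name=name,
        envelope=GenomicRegion(chrom, start, end, label=name),
        members=list(cluster),
        summed_pve=float(summed),
    )


def deg_filter(
    records: pd.DataFrame, fdr_max: float = 0.001, lfc_min: float = 1.0
) -> pd.DataFrame:
    """Differential-expression filter with strict inequalities:
    FDR < fdr_max and |log2FC| > lfc_min."""
    required = {"gene_id", "comparison", "log2fc", "fdr"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    keep = (records["fdr"] < fdr_max) & (records["log2fc"].abs() > lfc_min)
    return records[keep].reset_index(drop=True)


def genes_in_region(annotation: pd.DataFrame, region: GenomicRegion) -> pd.DataFrame:
    """Genes whose 1-based inclusive interval overlaps the region."""
    required = {"gene_id", "chrom", "start", "end"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    chroms = set(annotation["chrom"].astype(str))
    if region.chrom not in chroms:
        raise ValueError(
            f"region chromosome {region.chrom!r} not present in annotation "
            f"chromosomes {sorted(chroms)}"
        )
    sub = annotation[annotation["chrom"].astype(str) == region.chrom]
    hit = (sub["start"] <= region.end) & (sub["end"] >= region.start)
    return sub[hit].reset_index(drop=True)


def candidate_genes(
    report: CQTLReport,
    annotation: pd.DataFrame,
    degs: pd.DataFrame,
    fdr_max: float = 0.001,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Genes inside the cQTL envelope that pass the DEG filter in any comparison.

    One row per (gene, comparison); direction is the sign of log2FC.
    """
    inside = genes_in_region(annotation, report.envelope)
    if degs.empty:
        return pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "comparison", "log2fc",
                     "fdr", "direction"]
        )
    passed = deg_filter(degs, fdr_max, lfc_min)
    merged = inside.merge(passed, on="gene_id", how="inner")
    merged["direction"] = merged["log2fc"].map(lambda v: "up" if v > 0 else "down")
    return merged.sort_values(["gene_id", "comparison"]).reset_index(drop=True)
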