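"""Bulked-segregant delta-index mapping (QTL-seq style).

Two pools of extreme-phenotype F2 plants (LM = longest mesocotyls,
SM = shortest) plus the two parents are sequenced; at every informative site
(parents homozygous for different alleles) the index is the fraction of
reads carrying a designated parent's allele. Near a selected locus the two
bulks diverge: delta = index_LM - index_SM departs from 0.

Significance comes from a null simulation faithful to the design: draw
bulk-size F2 genotypes (1:2:1), form the pool allele frequency, draw binomial
read counts at a given depth for two independent bulks, and take the central
``level`` interval of the simulated delta distribution, tabulated over a
depth grid and interpolated per site/window. Windows averaging the per-site
delta whose mean lies outside the band mark linked regions; adjacent
significant windows merge into regions.

Orientation convention: the index counts the tolerant (first) parent's
allele, so LM-bulk enrichment for the tolerant allele appears as delta > 0.
Zero-depth sites are masked (NaN), never imputed; masking propagates to
delta and windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import GenomicRegion, merge_regions

POOLS = ("LM", "SM")


@dataclass(frozen=True)
class PoolVariantSite:
    """Per-site allele depths for the two parents and the two bulks.

    Genotypes are VCF-style strings; depths are (ref, alt) read counts.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str        # "SNP" or "InDel"
    parent1_gt: str
    parent2_gt: str
    lm_ref: int
    lm_alt: int
    sm_ref: int
    sm_alt: int
    p1_ref: int = 0
    p1_alt: int = 0
    p2_ref: int = 0
    p2_alt: int = 0

    def __post_init__(self):
        for d in (self.lm_ref, self.lm_alt, self.sm_ref, self.sm_alt,
                  self.p1_ref, self.p1_alt, self.p2_ref, self.p2_alt):
            if d < 0:
                raise ValueError("negative read depth")

    def depths(self, pool: str) -> tuple[int, int]:
        if pool == "LM":
            return self.lm_ref, self.lm_alt
        if pool == "SM":
            return self.sm_ref, self.sm_alt
        if pool == "parent1":
            return self.p1_ref, self.p1_alt
        if pool == "parent2":
            return self.p2_ref, self.p2_alt
        raise KeyError(f"unknown pool {pool!r}")


def select_extreme_bulks(family_means: pd.Series, k: int):
    """Top-k and bottom-k family ids by mean trait value (ties by family id)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(family_means)
    if 2 * k > n:
        raise ValueError(f"2k = {2 * k} exceeds the {n} available families")
    if family_means.nunique() == 1:
        warnings.warn("all family means equal: extreme bulks are id-ordered", stacklevel=2)
    df = family_means.rename("value").rename_axis("family").reset_index()
    high = df.sort_values(["value", "family"], ascending=[False, True], kind="mergesort")
    low = df.sort_values(["value", "family"], ascending=[True, True], kind="mergesort")
    high_ids = high["family"].head(k).tolist()
    low_ids = low["family"].head(k).tolist()
    return high_ids, low_ids


def _parent_allele(site: PoolVariantSite, parent: str) -> str | None:
    gt = site.parent1_gt if parent == "parent1" else site.parent2_gt
    alleles = set(gt.replace("|", "/").split("/"))
    if alleles == {"0"}:
        return "ref"
    if alleles == {"1"}:
        return "alt"
    return None  # heterozygous or missing


def filter_informative_sites(
    sites: list[PoolVariantSite], min_depth: int = 10
) -> list[PoolVariantSite]:
    """Keep sites with opposite homozygous parents and adequate pool depth."""
    kept = []
    for s in sites:
        a1, a2 = _parent_allele(s, "parent1"), _parent_allele(s, "parent2")
        if a1 is None or a2 is None or a1 == a2:
            continue
        if s.lm_ref + s.lm_alt < min_depth or s.sm_ref + s.sm_alt < min_depth:
            continue
        kept.append(s)
    return kept


def compute_index(
    site: PoolVariantSite, pool: str, index_parent: str = "parent1"
) -> float | None:
    """Fraction of reads carrying the index parent's allele; None if no reads."""
    allele = _parent_allele(site, index_parent)
    if allele is None:
        raise ValueError(f"{index_parent} is not homozygous at {site.chrom}:{site.pos}")
    ref, alt = site.depths(pool)
    total = ref + alt
    if total == 0:
        return None
    return (ref if allele == "ref" else alt) / total


def build_index_track(
    sites: list[PoolVariantSite], index_parent: str = "parent1"
) -> pd.DataFrame:
    """Per-site index per pool and delta = index_LM - index_SM (NaN = masked)."""
    rows = []
    for s in sites:
        idx_lm = compute_index(s, "LM", index_parent)
        idx_sm = compute_index(s, "SM", index_parent)
        rows.append(
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "variant_class": s.variant_class,
                "depth_lm": s.lm_ref + s.lm_alt,
                "depth_sm": s.sm_ref + s.sm_alt,
                "index_lm": np.nan if idx_lm is None else idx_lm,
                "index_sm": np.nan if idx_sm is None else idx_sm,
            }
        )
    track = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "variant_class", "depth_lm", "depth_sm",
                 "index_lm", "index_sm"],
    )
    track["delta"] = track["index_lm"] - track["index_sm"]
    return track


def delta_index(track: pd.DataFrame) -> np.ndarray:
    """Per-site delta values; masked (NaN) wherever either pool index is masked."""
    return (track["index_lm"] - track["index_sm"]).to_numpy(float)


def sliding_window(
    track: pd.DataFrame,
    window_bp: int = 1_000_000,
    step_bp: int = 200_000,
    min_sites: int = 10,
) -> pd.DataFrame:
    """Unweighted window means of the per-site values.

    Windows start at 1 and tile each chromosome at ``step_bp``; a site
    belongs to [start, start + window_bp). Windows with fewer than
    ``min_sites`` unmasked sites are masked (NaN means).
    """
    if not (window_bp >= step_bp > 0):
        raise ValueError("need window_bp >= step_bp > 0")
    out = []
    for chrom, sub in track.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        max_pos = int(pos.max()) if len(pos) else 0
        starts = np.arange(1, max_pos + 1, step_bp, dtype=np.int64)
        for start in starts:
            end = start + window_bp - 1
            inwin = sub[(sub["pos"] >= start) & (sub["pos"] < start + window_bp)]
            ok = inwin.dropna(subset=["delta"])
            n_sites = len(ok)
            masked = n_sites < min_sites
            out.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "n_sites": n_sites,
                    "index_lm_mean": np.nan if masked else ok["index_lm"].mean(),
                    "index_sm_mean": np.nan if masked else ok["index_sm"].mean(),
                    "delta_mean": np.nan if masked else ok["delta"].mean(),
                    "mean_depth": np.nan
                    if masked
                    else (ok["depth_lm"].mean() + ok["depth_sm"].mean()) / 2.0,
                }
            )
    return pd.DataFrame(
        out,
        columns=["chrom", "start", "end", "n_sites", "index_lm_mean",
                 "index_sm_mean", "delta_mean", "mean_depth"],
    )


@dataclass
class ConfidenceBand:
    """Simulated null delta quantiles tabulated over a read-depth grid."""

    depths: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    level: float
    bulk_size: int
    population: str

    def bounds(self, depth) -> tuple[np.ndarray, np.ndarray]:
        d = np.clip(np.asarray(depth, float), self.depths[0], self.depths[-1])
        return (
            np.interp(d, self.depths, self.lo),
            np.interp(d, self.depths, self.hi),
        )


def simulate_null_ci(
    bulk_size: int = 30,
    population: str = "F2",
    depth_grid=tuple(range(5, 205, 5)),
    n_sim: int = 10_000,
    level: float = 0.99,
    rng: np.random.Generator | int | None = None,
    sequencing_error: float = 0.0,
) -> ConfidenceBand:
    """Null distribution of delta for two independent bulks at each depth.

    Per replicate and bulk: draw ``bulk_size`` F2 genotypes (1:2:1 at an
    unlinked locus), form the pool allele frequency, then binomial read
    counts at the given depth; delta is the difference of the two bulk
    indices. The band is the central ``level`` interval (type-7 quantiles).
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    if not 0.5 < level < 1.0:
        raise ValueError("confidence level must be in (0.5, 1)")
    if population not in ("F2", "RIL"):
        raise ValueError(f"unsupported population type {population!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    depths = np.asarray(sorted(depth_grid), float)
    lo = np.empty(len(depths))
    hi = np.empty(len(depths))
    qlo, qhi = (1.0 - level) / 2.0, (1.0 + level) / 2.0
    for i, d in enumerate(depths):
        if population == "F2":
            counts = rng.multinomial(bulk_size, [0.25, 0.5, 0.25], size=(n_sim, 2))
            freq = (counts[..., 1] + 2 * counts[..., 2]) / (2.0 * bulk_size)
        else:  # RIL: homozygous lines, 1:1
            freq = rng.binomial(bulk_size, 0.5, size=(n_sim, 2)) / bulk_size
        if sequencing_error > 0:
            freq = freq * (1 - sequencing_error) + (1 - freq) * sequencing_error
        reads = rng.binomial(int(d), freq)
        idx = reads / d
        delta = idx[:, 0] - idx[:, 1]
        lo[i] = np.quantile(delta, qlo)
        hi[i] = np.quantile(delta, qhi)
    return ConfidenceBand(depths, lo, hi, level, bulk_size, population)


def call_linked_regions(
    windows: pd.DataFrame,
    band: ConfidenceBand,
    merge_gap_bp: int = 0,
    two_sided: bool = True,
    sites: pd.DataFrame | None = None,
    label_prefix: str = "BSA",
) -> list[GenomicRegion]:
    """Regions where the windowed delta lies outside the confidence band.

    Overlapping or near-adjacent (gap <= merge_gap_bp) significant windows
    merge; when a site track is supplied, each region is clipped to the
    outermost supporting sites it contains.
    """
    ok = windows.dropna(subset=["delta_mean", "mean_depth"])
    if ok.empty:
        return []
    lo, hi = band.bounds(ok["mean_depth"].to_numpy())
    delta = ok["delta_mean"].to_numpy()
    sig = (delta > hi) | (delta < lo) if two_sided else delta > hi
    sig_rows = ok[sig]
    if sig_rows.empty:
        return []
    raw = [
        GenomicRegion(str(r.chrom), int(r.start), int(r.end))
        for r in sig_rows.itertuples(index=False)
    ]
    merged = merge_regions(raw, max_gap_bp=merge_gap_bp, label_prefix=label_prefix)
    if sites is None:
        return merged
    clipped = []
    for reg in merged:
        inside = sites[
            (sites["chrom"].astype(str) == reg.chrom)
            & (sites["pos"] >= reg.start)
            & (sites["pos"] <= reg.end)
        ]
        if inside.empty:
            clipped.append(reg)
        else:
            lo_pos, hi_pos = int(inside["pos"].min()), int(inside["pos"].max())
            if lo_pos < hi_pos:
                clipped.append(GenomicRegion(reg.chrom, lo_pos, hi_pos, reg.label))
            else:
                clipped.append(reg)
    return clipped
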