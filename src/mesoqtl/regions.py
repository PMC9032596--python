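"""Physical genomic intervals (1-based, inclusive endpoints) and interval arithmetic.

Coordinates follow the convention of maize QTL/BSA reporting: 1-based
inclusive base-pair endpoints; lengths in Mb are (end - start)/1e6 rounded
half-up to two decimals. BED export (0-based, half-open) is handled in
:mod:`mesoqtl.io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as tabulated reports do (not banker's)."""
    if abs(x) >= 1e15:  # beyond float decimal resolution; quantizing is a no-op
        return float(x)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GenomicRegion:
    """A physical interval on a chromosome, 1-based with inclusive endpoints."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", str(self.chrom))
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"degenerate region {self.label or self.chrom}: "
                f"start {self.start} >= end {self.end}"
            )

    @property
    def length_mb(self) -> float:
        """Span in megabases, (end - start)/1e6, half-up to 2 decimals."""
        return float(
            (Decimal(self.end - self.start) / Decimal(10**6)).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_UP
            )
        )

    def overlaps(self, other: "GenomicRegion") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end

    def gap_to(self, other: "GenomicRegion") -> int:
        """Gap in bp between two intervals on the same chromosome (0 if overlapping)."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        if self.overlaps(other):
            return 0
        if self.end < other.start:
            return other.start - self.end - 1
        return self.start - other.end - 1


def region_length_mb(region: GenomicRegion) -> float:
    """Length of a region in Mb to two decimals (half-up)."""
    return region.length_mb


def merge_regions(
    regions: list[GenomicRegion], max_gap_bp: int = 0, label_prefix: str = "merged"
) -> list[GenomicRegion]:
    """Single-linkage merge of same-chromosome regions whose gap is <= max_gap_bp.

    Order-independent: input is sorted by (chrom, start, end) before sweeping.
    """
    out: list[GenomicRegion] = []
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_start, cur_end = rs[0].start, rs[0].end
        for r in rs[1:]:
            if r.start - cur_end - 1 <= max_gap_bp:
                cur_end = max(cur_end, r.end)
            else:
                out.append(
                    GenomicRegion(chrom, cur_start, cur_end, f"{label_prefix}{chrom}:{len(out) + 1}")
                )
                cur_start, cur_end = r.start, r.end
        out.append(
            GenomicRegion(chrom, cur_start, cur_end, f"{label_prefix}{chrom}:{len(out) + 1}")
        )
    return out
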