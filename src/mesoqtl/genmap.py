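"""Genetic map and F2 genotype containers.

The map is the marker scaffold every stage works against: per chromosome an
ordered list of markers with genetic (cM) and physical (bp) positions.
Genotypes of a biparental F2 are coded by the count of second-parent (K12)
alleles: 0 = AA (first-parent homozygote, W64A), 1 = AB, 2 = BB, -1 = missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GENOTYPE_CODES = {"AA": 0, "AB": 1, "BB": 2, "NA": -1, "-": -1, "": -1}
CODE_STRINGS = {0: "AA", 1: "AB", 2: "BB", -1: "NA"}


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker scaffold: columns marker, chrom, cm, bp."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["marker", "chrom", "cm", "bp"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"map table missing columns: {missing}")
        t = self.table.reset_index(drop=True)
        if t["marker"].duplicated().any():
            dups = t.loc[t["marker"].duplicated(), "marker"].tolist()
            raise ValueError(f"duplicate marker names: {dups}")
        for chrom, sub in t.groupby("chrom", sort=False):
            cm = sub["cm"].to_numpy(float)
            bp = sub["bp"].to_numpy()
            if not np.all(np.diff(cm) > 0):
                raise ValueError(f"cM positions not strictly increasing on chrom {chrom}")
            if not np.all(np.diff(bp) > 0):
                raise ValueError(f"bp positions not increasing on chrom {chrom}")
        object.__setattr__(self, "table", t)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def chrom_table(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    @property
    def total_length_cm(self) -> float:
        """Summed per-chromosome spans (last minus first marker)."""
        return float(
            sum(
                sub["cm"].iloc[-1] - sub["cm"].iloc[0]
                for _, sub in self.table.groupby("chrom", sort=False)
            )
        )

    @property
    def n_intervals(self) -> int:
        return sum(len(sub) - 1 for _, sub in self.table.groupby("chrom", sort=False))

    @property
    def mean_interval_cm(self) -> float:
        return self.total_length_cm / self.n_intervals

    def marker_index(self, name: str) -> int:
        idx = self.table.index[self.table["marker"] == name]
        if len(idx) == 0:
            raise KeyError(f"marker {name!r} not on map")
        return int(idx[0])


@dataclass(frozen=True)
class F2GenotypeMatrix:
    """Individuals x markers genotype codes aligned to a GeneticMap.

    codes: int8 array, 0/1/2 = AA/AB/BB (count of second-parent alleles),
    -1 = missing.
    """

    codes: np.ndarray
    individuals: list
    markers: list

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int8)
        if codes.ndim != 2:
            raise ValueError("codes must be 2-D (individuals x markers)")
        if codes.shape != (len(self.individuals), len(self.markers)):
            raise ValueError(
                f"codes shape {codes.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        bad = ~np.isin(codes, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError(f"invalid genotype codes at {int(bad.sum())} cells")
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "individuals", list(self.individuals))
        object.__setattr__(self, "markers", list(self.markers))

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def missing_rate(self) -> float:
        return float((self.codes < 0).mean())

    def check_against_map(self, gmap: GeneticMap) -> None:
        if self.markers != list(gmap.table["marker"]):
            extra = set(self.markers) - set(gmap.table["marker"])
            absent = set(gmap.table["marker"]) - set(self.markers)
            raise ValueError(
                f"genotype markers do not match map (not on map: {sorted(extra)}; "
                f"missing from genotypes: {sorted(absent)})"
            )

    def to_frame(self) -> pd.DataFrame:
        data = np.vectorize(CODE_STRINGS.get)(self.codes)
        return pd.DataFrame(data, index=self.individuals, columns=self.markers)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "F2GenotypeMatrix":
        vals = df.to_numpy(dtype=object)
        codes = np.empty(vals.shape, dtype=np.int8)
        for (i, j), v in np.ndenumerate(vals):
            key = str(v).strip().upper() if not pd.isna(v) else "NA"
            if key not in GENOTYPE_CODES:
                raise ValueError(
                    f"unknown genotype code {v!r} for individual "
                    f"{df.index[i]!r} at marker {df.columns[j]!r}"
                )
            codes[i, j] = GENOTYPE_CODES[key]
        return cls(codes, list(df.index), list(df.columns))
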