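"""Forward simulation of a biparental maize cross and its pooled sequencing.

Emulates the study design the downstream stages assume: a W64A x K12 F2
population (default 346 plants) genotyped at 260 markers on 10 chromosomes
(~1410.6 cM), F2:3 family phenotypes in three sowing-depth environments with
10 replicates, extreme 30+30 bulks, and pooled read depths at ~45x coverage.

Model summary
-------------
* Each F2 individual is two independent gametes; recombination between
  adjacent loci follows the Haldane map function by default (no
  interference), r = (1 - exp(-2d/100))/2. Kosambi is available.
* Genotypes are coded by the count of second-parent (K12) alleles.
* A QTL's additive effect ``a`` multiplies (K12 allele count - 1), so a
  negative ``a`` means the first parent (W64A) carries the allele that
  increases the trait, matching the field's reporting convention.
* F2:3 family means given the F2 parent genotype: AA -> -a, BB -> +a,
  AB -> d/2 (one generation of selfing halves the heterozygote dominance
  deviation).
* Pooled sequencing: per site, total depth ~ Poisson(coverage); the
  alternate-allele depth ~ Binomial(depth, p') where p is the bulk allele
  frequency and p' folds in a symmetric sequencing error.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genmap import F2GenotypeMatrix, GeneticMap

# Per-chromosome cM lengths: realistic maize-linkage proportions, summing to 1410.6.
DEFAULT_CHROM_LENGTHS = (196.2, 158.4, 162.0, 143.4, 150.0, 131.4, 127.2, 124.8, 114.0, 103.2)
DEFAULT_ENVIRONMENTS = ("3cm", "15cm", "20cm")
# Mean F2:3 family mesocotyl length (cm) per sowing depth, as reported for
# the study population: 3.74 / 10.95 / 13.09 at 3 / 15 / 20 cm.
DEFAULT_ENV_MEANS = (3.74, 10.95, 13.09)
# Per-replicate residual sd per environment; deeper sowing is noisier.
DEFAULT_RESIDUAL_SD = (1.0, 2.2, 2.8)


def haldane_r(d_cm) -> np.ndarray:
    """Recombination fraction from map distance (cM), no interference."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, float) / 100.0))


def kosambi_r(d_cm) -> np.ndarray:
    return 0.5 * np.tanh(2.0 * np.asarray(d_cm, float) / 100.0)


MAP_FUNCTIONS = {"haldane": haldane_r, "kosambi": kosambi_r}


@dataclass(frozen=True)
class TrueQTL:
    """A simulated causal locus with per-environment additive/dominance effects.

    ``additive[env] < 0`` means the first parent's (W64A) allele increases the
    trait in that environment.
    """

    name: str
    chromosome: int
    position_cm: float
    additive: dict
    dominance: dict

    def effect(self, env: str) -> tuple[float, float]:
        return float(self.additive.get(env, 0.0)), float(self.dominance.get(env, 0.0))

    def family_values(self, env: str) -> np.ndarray:
        """F2:3 family expectation indexed by F2 parent code (AA, AB, BB)."""
        a, d = self.effect(env)
        return np.array([-a, d / 2.0, a])


def default_qtl_architecture() -> list[TrueQTL]:
    """The seven mesocotyl-length QTL used as the default simulated truth.

    Effects (trait cm) per sowing-depth environment follow the reported
    single-environment CIM estimates for the W64A x K12 population.
    """
    return [
        TrueQTL("qMES1-1", 1, 110.8,
                {"3cm": 0.25, "15cm": -0.75, "20cm": -0.91},
                {"3cm": 0.03, "15cm": -0.11, "20cm": -0.15}),
        TrueQTL("qMES1-2", 1, 145.2, {"15cm": -1.17}, {"15cm": 0.10}),
        TrueQTL("qMES3-1", 3, 55.7,
                {"15cm": -1.88, "20cm": -1.03}, {"15cm": -0.21, "20cm": -1.20}),
        TrueQTL("qMES4-1", 4, 88.1,
                {"3cm": -0.34, "15cm": -0.83, "20cm": -1.25},
                {"3cm": -0.02, "15cm": -0.09, "20cm": -0.18}),
        TrueQTL("qMES4-2", 4, 119.2, {"15cm": -1.10, "20cm": 0.17},
                {"15cm": 0.08, "20cm": 0.10}),
        TrueQTL("qMES6-1", 6, 14.3,
                {"3cm": -1.01, "15cm": -0.61, "20cm": -1.14},
                {"3cm": -1.51, "15cm": 0.97, "20cm": -1.43}),
        TrueQTL("qMES7-1", 7, 67.0, {"3cm": -0.80, "15cm": -0.61},
                {"3cm": -0.03, "15cm": 0.08}),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic cross.

    Defaults are the study conditions: 346 F2 plants, 260 markers on 10
    chromosomes spanning 1410.6 cM, three sowing depths x 10 replicates,
    30+30 extreme bulks, ~45x pooled coverage.
    """

    seed: int = 0
    n_f2: int = 346
    n_chromosomes: int = 10
    markers_per_chromosome: tuple = (26,) * 10
    chromosome_lengths: tuple = DEFAULT_CHROM_LENGTHS
    environments: tuple = DEFAULT_ENVIRONMENTS
    replicates: int = 10
    env_means: tuple = DEFAULT_ENV_MEANS
    residual_sd: tuple = DEFAULT_RESIDUAL_SD
    gxe_sd: float = 0.3
    qtl_architecture: tuple = field(default_factory=lambda: tuple(default_qtl_architecture()))
    bulk_size: int = 30
    bulk_environment: str = "20cm"
    coverage_mean: float = 45.0
    sequencing_error: float = 0.001
    map_function: str = "haldane"
    bp_per_cm: float = 1.0e6
    missing_rate: float = 0.0
    variant_sites_per_chromosome: int = 300
    indel_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.n_f2 < 1 or self.replicates < 1:
            raise ValueError("all counts must be >= 1")
        if len(self.markers_per_chromosome) != self.n_chromosomes:
            raise ValueError("markers_per_chromosome length != n_chromosomes")
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ValueError("chromosome_lengths length != n_chromosomes")
        if any(m < 2 for m in self.markers_per_chromosome):
            raise ValueError("need >= 2 markers per chromosome")
        if any(length <= 0 for length in self.chromosome_lengths):
            raise ValueError("zero-length chromosome")
        if len(self.env_means) != len(self.environments):
            raise ValueError("env_means length != number of environments")
        if len(self.residual_sd) != len(self.environments):
            raise ValueError("residual_sd length != number of environments")
        for p in (self.sequencing_error, self.missing_rate, self.indel_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.map_function not in MAP_FUNCTIONS:
            raise ValueError(f"unknown map function {self.map_function!r}")
        for q in self.qtl_architecture:
            if not 1 <= q.chromosome <= self.n_chromosomes:
                raise ValueError(f"QTL {q.name} on unknown chromosome {q.chromosome}")
            if not 0.0 <= q.position_cm <= self.chromosome_lengths[q.chromosome - 1]:
                raise ValueError(f"QTL {q.name} position {q.position_cm} cM off the map")

    @property
    def rfun(self):
        return MAP_FUNCTIONS[self.map_function]

    def env_index(self, env: str) -> int:
        return self.environments.index(env)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthRecord:
    """Everything needed to verify downstream parameter recovery."""

    config: SimConfig
    qtl_codes: np.ndarray          # n_f2 x n_qtl F2 genotype codes at the true QTL
    genetic_values: pd.DataFrame   # family x environment genetic values
    bulk_high: list                # family ids in the high (LM) bulk
    bulk_low: list


def make_map(config: SimConfig) -> GeneticMap:
    """Evenly spaced marker scaffold with deterministic cM -> bp scaling."""
    rows = []
    for c in range(config.n_chromosomes):
        m = config.markers_per_chromosome[c]
        length = config.chromosome_lengths[c]
        cm = np.linspace(0.0, length, m)
        for j, pos in enumerate(cm):
            rows.append(
                {
                    "marker": f"M{c + 1:02d}_{j + 1:02d}",
                    "chrom": c + 1,
                    "cm": round(float(pos), 4),
                    "bp": int(round(pos * config.bp_per_cm)) + 1,
                }
            )
    return GeneticMap(pd.DataFrame(rows))


def _simulate_codes(
    loci_cm_per_chrom: dict[int, np.ndarray],
    n: int,
    rng: np.random.Generator,
    rfun,
) -> dict[int, np.ndarray]:
    """F2 genotype codes (count of second-parent alleles) at arbitrary loci.

    Two independent gamete chains per individual; each chain flips parental
    origin between adjacent loci with the map-function recombination fraction.
    """
    out = {}
    for chrom in sorted(loci_cm_per_chrom):
        loci = np.asarray(loci_cm_per_chrom[chrom], float)
        if np.any(np.diff(loci) < 0):
            raise ValueError("loci must be sorted within chromosome")
        r = rfun(np.diff(loci))
        codes = np.zeros((n, len(loci)), dtype=np.int8)
        for _gamete in range(2):
            start = rng.integers(0, 2, size=n, dtype=np.int8)
            if len(r):
                switches = (rng.random((n, len(r))) < r).astype(np.int8)
                parity = np.cumsum(switches, axis=1) & 1
                origins = np.concatenate(
                    [start[:, None], start[:, None] ^ parity], axis=1
                )
            else:
                origins = start[:, None]
            codes += origins
        out[chrom] = codes
    return out


def simulate_f2_genotypes(
    gmap: GeneticMap, config: SimConfig, rng: np.random.Generator | None = None
) -> F2GenotypeMatrix:
    """Simulate the F2 marker matrix for a map (missing data applied per config)."""
    rng = config.rng() if rng is None else rng
    loci = {
        chrom: gmap.chrom_table(chrom)["cm"].to_numpy(float) for chrom in gmap.chromosomes
    }
    per_chrom = _simulate_codes(loci, config.n_f2, rng, config.rfun)
    codes = np.concatenate([per_chrom[c] for c in gmap.chromosomes], axis=1)
    if config.missing_rate > 0:
        mask = rng.random(codes.shape) < config.missing_rate
        codes = np.where(mask, np.int8(-1), codes)
    individuals = [f"F{i + 1:04d}" for i in range(config.n_f2)]
    return F2GenotypeMatrix(codes, individuals, list(gmap.table["marker"]))


def _qtl_codes_from_markers(
    genotypes: F2GenotypeMatrix, gmap: GeneticMap, truth: list[TrueQTL]
) -> np.ndarray:
    """Fallback: use the genotype at the marker nearest each QTL (documented
    approximation when exact QTL genotypes were not simulated jointly)."""
    if not truth:
        return np.empty((genotypes.n_individuals, 0), dtype=np.int8)
    cols = []
    for q in truth:
        sub = gmap.chrom_table(q.chromosome)
        if len(sub) == 0:
            raise ValueError(f"QTL {q.name}: chromosome {q.chromosome} not on map")
        cm = sub["cm"].to_numpy(float)
        if not (cm[0] - 1e-9 <= q.position_cm <= cm[-1] + 1e-9):
            raise ValueError(f"QTL {q.name} at {q.position_cm} cM is off the map")
        nearest = sub.index[np.argmin(np.abs(cm - q.position_cm))]
        cols.append(genotypes.codes[:, nearest])
    return np.stack(cols, axis=1)


def simulate_f23_phenotypes(
    genotypes: F2GenotypeMatrix,
    truth: list[TrueQTL],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    gmap: GeneticMap | None = None,
    qtl_codes: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """F2:3 family phenotypes: genetic value + environment + GxE + residual.

    Returns (phenotype table, per-family genetic values by environment).
    The phenotype table has columns family, environment, replicate, value.
    """
    rng = config.rng() if rng is None else rng
    if qtl_codes is None:
        if gmap is None:
            raise ValueError("either qtl_codes or gmap must be supplied")
        qtl_codes = _qtl_codes_from_markers(genotypes, gmap, truth)
    n = genotypes.n_individuals
    if qtl_codes.shape != (n, len(truth)):
        raise ValueError("qtl_codes shape mismatch")

    fam = genotypes.individuals
    gvals = np.zeros((n, len(config.environments)))
    for e, env in enumerate(config.environments):
        for k, q in enumerate(truth):
            vals = q.family_values(env)
            codes = qtl_codes[:, k]
            contrib = np.where(codes >= 0, vals[np.clip(codes, 0, 2)], 0.0)
            gvals[:, e] += contrib
    genetic = pd.DataFrame(gvals, index=fam, columns=list(config.environments))

    records = []
    for e, env in enumerate(config.environments):
        ge = rng.normal(0.0, config.gxe_sd, size=n) if config.gxe_sd > 0 else np.zeros(n)
        eps = rng.normal(0.0, config.residual_sd[e], size=(n, config.replicates))
        base = config.env_means[e] + gvals[:, e] + ge
        values = base[:, None] + eps
        for i, f in enumerate(fam):
            for r in range(config.replicates):
                records.append((f, env, r + 1, values[i, r]))
    table = pd.DataFrame(records, columns=["family", "environment", "replicate", "value"])
    return table, genetic


_BASES = np.array(list("ACGT"))


def make_variant_sites(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Random variant positions along each chromosome, with alleles and class.

    The reference allele is assigned to the first parent (W64A), the
    alternate to K12; both parents are homozygous (informative sites).
    """
    rows = []
    for c in range(config.n_chromosomes):
        max_bp = int(config.chromosome_lengths[c] * config.bp_per_cm)
        n_sites = config.variant_sites_per_chromosome
        pos = np.sort(rng.choice(np.arange(1, max_bp + 1), size=n_sites, replace=False))
        is_indel = rng.random(n_sites) < config.indel_fraction
        ref_idx = rng.integers(0, 4, size=n_sites)
        alt_shift = rng.integers(1, 4, size=n_sites)
        for j in range(n_sites):
            ref = _BASES[ref_idx[j]]
            if is_indel[j]:
                ref, alt = ref + "AC", ref
                vclass = "InDel"
            else:
                alt = _BASES[(ref_idx[j] + alt_shift[j]) % 4]
                vclass = "SNP"
            rows.append(
                {
                    "chrom": c + 1,
                    "pos": int(pos[j]),
                    "cm": (int(pos[j]) - 1) / config.bp_per_cm,
                    "ref": ref,
                    "alt": alt,
                    "variant_class": vclass,
                }
            )
    return pd.DataFrame(rows)


def simulate_pool_reads(
    site_codes: np.ndarray,
    members_high: np.ndarray,
    members_low: np.ndarray,
    sites: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> list:
    """Sequencing depths for the two bulks and two parents at variant sites.

    site_codes: n_f2 x n_sites F2 genotype codes at the site positions.
    Returns a list of :class:`mesoqtl.bsaseq.PoolVariantSite`.
    """
    from .bsaseq import PoolVariantSite

    for name, members in (("high", members_high), ("low", members_low)):
        if len(members) == 0:
            raise ValueError(f"empty {name}-bulk member set")
    n_sites = len(sites)
    if site_codes.shape[1] != n_sites:
        raise ValueError("site_codes does not match sites table")
    e = config.sequencing_error
    out = []

    def pool_depths(p_alt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        depth = rng.poisson(config.coverage_mean, size=n_sites)
        p_eff = p_alt * (1 - e) + (1 - p_alt) * e
        alt = rng.binomial(depth, p_eff)
        return depth - alt, alt

    k_hi, k_lo = len(members_high), len(members_low)
    p_hi = site_codes[members_high].sum(axis=0) / (2.0 * k_hi)
    p_lo = site_codes[members_low].sum(axis=0) / (2.0 * k_lo)
    lm_ref, lm_alt = pool_depths(p_hi)
    sm_ref, sm_alt = pool_depths(p_lo)
    p1_ref, p1_alt = pool_depths(np.zeros(n_sites))   # W64A carries the ref allele
    p2_ref, p2_alt = pool_depths(np.ones(n_sites))

    for j, row in enumerate(sites.itertuples(index=False)):
        out.append(
            PoolVariantSite(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                variant_class=str(row.variant_class),
                parent1_gt="0/0",
                parent2_gt="1/1",
                lm_ref=int(lm_ref[j]), lm_alt=int(lm_alt[j]),
                sm_ref=int(sm_ref[j]), sm_alt=int(sm_alt[j]),
                p1_ref=int(p1_ref[j]), p1_alt=int(p1_alt[j]),
                p2_ref=int(p2_ref[j]), p2_alt=int(p2_alt[j]),
            )
        )
    return out


def residual_sd_for_pve(
    architecture: list[TrueQTL],
    env: str,
    focal: str,
    target_pve: float,
    n_rep: int,
    gxe_sd: float = 0.0,
) -> float:
    """Per-replicate residual sd giving the focal QTL a target PVE among family means.

    Under unlinked loci, a QTL's family-mean variance is a^2/2 + 3 d^2/16;
    the focal PVE is V_focal / (V_genetic_total + gxe^2 + sd^2/r).
    """
    def qvar(q: TrueQTL) -> float:
        a, d = q.effect(env)
        return a * a / 2.0 + 3.0 * d * d / 16.0

    v_total = sum(qvar(q) for q in architecture)
    v_focal = next(qvar(q) for q in architecture if q.name == focal)
    resid_fam = v_focal / target_pve - v_total - gxe_sd**2
    if resid_fam <= 0:
        raise ValueError(f"target PVE {target_pve} not attainable for {focal} in {env}")
    return float(np.sqrt(n_rep * resid_fam))


@dataclass
class ScenarioResult:
    gmap: GeneticMap
    genotypes: F2GenotypeMatrix
    phenotypes: pd.DataFrame
    sites: list
    truth: TruthRecord
    paths: dict


def _config_to_jsonable(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["qtl_architecture"] = [dataclasses.asdict(q) for q in config.qtl_architecture]
    return d


def scenario_study(config: SimConfig, outdir: str | Path) -> ScenarioResult:
    """Generate and write the full study bundle: map, genotypes, phenotypes,
    pool VCF, and truth JSON. Deterministic under config.seed."""
    from . import io as mio
    from .bsaseq import select_extreme_bulks
    from .phenostats import family_means

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    gmap = make_map(config)
    sites = make_variant_sites(config, rng)

    # Simulate markers, QTL loci and variant sites jointly on one gamete
    # realization so QTL/site genotypes are exact, then split the views.
    loci: dict[int, list[tuple[float, str, int]]] = {}
    for c in range(1, config.n_chromosomes + 1):
        entries = []
        sub = gmap.chrom_table(c)
        for k, cm in enumerate(sub["cm"].to_numpy(float)):
            entries.append((cm, "marker", int(sub.index[k])))
        for k, q in enumerate(config.qtl_architecture):
            if q.chromosome == c:
                entries.append((q.position_cm, "qtl", k))
        ssub = sites[sites["chrom"] == c]
        for k, cm in zip(ssub.index, ssub["cm"].to_numpy(float)):
            entries.append((cm, "site", int(k)))
        entries.sort(key=lambda t: (t[0], t[1], t[2]))
        loci[c] = entries

    per_chrom = _simulate_codes(
        {c: np.array([t[0] for t in loci[c]]) for c in loci}, config.n_f2, rng, config.rfun
    )
    marker_codes = np.empty((config.n_f2, gmap.n_markers), dtype=np.int8)
    qtl_codes = np.empty((config.n_f2, len(config.qtl_architecture)), dtype=np.int8)
    site_codes = np.empty((config.n_f2, len(sites)), dtype=np.int8)
    for c, entries in loci.items():
        for j, (_, kind, idx) in enumerate(entries):
            col = per_chrom[c][:, j]
            if kind == "marker":
                marker_codes[:, idx] = col
            elif kind == "qtl":
                qtl_codes[:, idx] = col
            else:
                site_codes[:, idx] = col

    if config.missing_rate > 0:
        mask = rng.random(marker_codes.shape) < config.missing_rate
        marker_codes = np.where(mask, np.int8(-1), marker_codes)
    individuals = [f"F{i + 1:04d}" for i in range(config.n_f2)]
    genotypes = F2GenotypeMatrix(marker_codes, individuals, list(gmap.table["marker"]))

    phenotypes, genetic = simulate_f23_phenotypes(
        genotypes, list(config.qtl_architecture), config, rng, qtl_codes=qtl_codes
    )

    means = family_means(phenotypes, config.bulk_environment)
    high, low = select_extreme_bulks(means, config.bulk_size)
    fam_index = {f: i for i, f in enumerate(individuals)}
    members_high = np.array([fam_index[f] for f in high])
    members_low = np.array([fam_index[f] for f in low])

    pool_sites = simulate_pool_reads(site_codes, members_high, members_low, sites, config, rng)

    truth = TruthRecord(config, qtl_codes, genetic, list(high), list(low))
    paths = {
        "map": outdir / "map.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "vcf": outdir / "pools.vcf",
        "truth": outdir / "truth.json",
    }
    mio.write_map_tsv(gmap, paths["map"])
    mio.write_genotypes_tsv(genotypes, paths["genotypes"])
    mio.write_phenotypes_tsv(phenotypes, paths["phenotypes"])
    contigs = {
        str(c + 1): int(config.chromosome_lengths[c] * config.bp_per_cm) + 1
        for c in range(config.n_chromosomes)
    }
    mio.write_pool_vcf(pool_sites, paths["vcf"], contigs=contigs)
    truth_json = {
        "config": _config_to_jsonable(config),
        "qtl_codes": {q.name: qtl_codes[:, k].tolist()
                      for k, q in enumerate(config.qtl_architecture)},
        "genetic_values": {env: genetic[env].round(6).tolist()
                           for env in config.environments},
        "families": individuals,
        "bulk_high": list(high),
        "bulk_low": list(low),
    }
    paths["truth"].write_text(json.dumps(truth_json, indent=1, sort_keys=True) + "\n")
    return ScenarioResult(gmap, genotypes, phenotypes, pool_sites, truth,
                          {k: str(v) for k, v in paths.items()})
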