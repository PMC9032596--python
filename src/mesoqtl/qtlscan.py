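"""Composite interval mapping (CIM) for F2 / F2:3 designs.

The scan follows the Haley-Knott regression formulation: at each evaluated
position the trait (F2:3 family means by default) is regressed on the
expected additive dosage and heterozygote probability computed from flanking
marker genotypes, plus background marker cofactors outside a +/- window
around the test position. LOD = (n/2) log10(RSS_null / RSS_full), where the
null model keeps the cofactors but drops the position terms.

Genotype probabilities between markers come from an exact 4-state hidden
Markov chain over ordered gamete pairs (two independent gamete chains per
individual, Haldane transitions by default), so arbitrary missing-data
patterns are conditioned on all typed markers of the chromosome.

Additive effects are reported with the maize-convention sign: the additive
dosage counts second-parent (K12) alleles, so a negative estimate means the
first parent (W64A) carries the trait-increasing allele. When the phenotype
is an F2:3 family mean, the fitted heterozygote coefficient estimates d/2
(one selfing generation), so the dominance effect is reported with a
``dominance_scale`` of 2.

Gene action is classified from |d/a| (Stuber intervals): additive (A) up to
0.20, partial dominance (PD) up to 0.80, dominance (D) up to 1.20,
over-dominance (OD) beyond.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genmap import F2GenotypeMatrix, GeneticMap
from .regions import round_half_up
from .simdata import MAP_FUNCTIONS

GENE_ACTION_BOUNDS = ((0.20, "A"), (0.80, "PD"), (1.20, "D"))


def classify_gene_action(a: float, d: float) -> tuple[float, str]:
    """(|d/a| rounded to 2 decimals, gene-action class).

    Classification uses the unrounded ratio; intervals are closed on the
    right ([0, 0.20] -> A, (0.20, 0.80] -> PD, (0.80, 1.20] -> D, else OD).
    By convention a = 0 with d != 0 is over-dominant, a = d = 0 is additive.
    """
    if not (math.isfinite(a) and math.isfinite(d)):
        raise ValueError("effects must be finite")
    if a == 0.0:
        return (0.0, "A") if d == 0.0 else (math.inf, "OD")
    ratio = abs(d / a)
    for bound, label in GENE_ACTION_BOUNDS:
        if ratio <= bound:
            return round_half_up(ratio, 2), label
    return round_half_up(ratio, 2), "OD"


# ---------------------------------------------------------------------------
# Genotype probability grid
# ---------------------------------------------------------------------------

# Ordered gamete-pair states (g1, g2); g = 1 means K12 origin.
_STATE_EMISSION = {
    0: np.array([1.0, 0.0, 0.0, 0.0]),   # AA consistent with (0,0)
    1: np.array([0.0, 1.0, 1.0, 0.0]),   # AB consistent with (0,1), (1,0)
    2: np.array([0.0, 0.0, 0.0, 1.0]),   # BB consistent with (1,1)
    -1: np.ones(4),
}


def _pair_transition(r: float) -> np.ndarray:
    m = np.array([[1 - r, r], [r, 1 - r]])
    return np.kron(m, m)


@dataclass
class ProbGrid:
    """Per-position F2 genotype probabilities on a cM grid.

    positions: DataFrame with chrom, cm, left_marker, right_marker.
    probs: (n_individuals, n_positions, 3) array of P(AA), P(AB), P(BB).
    """

    positions: pd.DataFrame
    probs: np.ndarray
    step_cm: float
    gmap: GeneticMap

    @property
    def n_positions(self) -> int:
        return len(self.positions)


def genotype_probabilities(
    gmap: GeneticMap,
    genos: F2GenotypeMatrix,
    step_cm: float = 1.0,
    map_function: str = "haldane",
) -> ProbGrid:
    """Conditional genotype probabilities at a step grid plus all marker positions."""
    if step_cm <= 0:
        raise ValueError("step_cm must be > 0")
    genos.check_against_map(gmap)
    rfun = MAP_FUNCTIONS[map_function]
    n = genos.n_individuals
    pos_rows = []
    prob_blocks = []

    for chrom in gmap.chromosomes:
        sub = gmap.chrom_table(chrom)
        cm = sub["cm"].to_numpy(float)
        names = sub["marker"].tolist()
        cols = [gmap.marker_index(nm) for nm in names]
        codes = genos.codes[:, cols]
        m = len(cm)

        # Emission lookup indexed by code+1: missing, AA, AB, BB.
        lut = np.stack(
            [_STATE_EMISSION[-1], _STATE_EMISSION[0], _STATE_EMISSION[1], _STATE_EMISSION[2]]
        )
        emis = lut[codes.T.astype(int) + 1]  # (m, n, 4)

        trans = [
            _pair_transition(float(rfun(cm[i + 1] - cm[i]))) for i in range(m - 1)
        ]

        fwd = np.empty((m, n, 4))
        f = 0.25 * emis[0]
        fwd[0] = f / np.maximum(f.sum(1, keepdims=True), 1e-300)
        for i in range(m - 1):
            f = (fwd[i] @ trans[i]) * emis[i + 1]
            fwd[i + 1] = f / np.maximum(f.sum(1, keepdims=True), 1e-300)

        bwd = np.empty((m, n, 4))
        bwd[m - 1] = 1.0
        for i in range(m - 2, -1, -1):
            b = (emis[i + 1] * bwd[i + 1]) @ trans[i].T
            bwd[i] = b / np.maximum(b.sum(1, keepdims=True), 1e-300)

        # Grid: union of the step grid and the marker positions.
        grid = np.unique(
            np.round(
                np.concatenate([np.arange(cm[0], cm[-1] + step_cm / 2, step_cm), cm]), 6
            )
        )
        grid = grid[(grid >= cm[0] - 1e-9) & (grid <= cm[-1] + 1e-9)]

        block = np.empty((n, len(grid), 3))
        marker_idx = np.searchsorted(cm, grid, side="right") - 1
        marker_idx = np.clip(marker_idx, 0, m - 1)
        for j, x in enumerate(grid):
            i = int(marker_idx[j])
            if abs(x - cm[i]) < 1e-8 or i == m - 1:
                i = i if abs(x - cm[i]) < 1e-8 else m - 1
                p4 = fwd[i] * bwd[i]
                left = right = names[min(i, m - 1)]
                if abs(x - cm[i]) >= 1e-8:  # beyond last marker (should not occur)
                    left = right = names[m - 1]
            else:
                dl, dr = x - cm[i], cm[i + 1] - x
                tl = _pair_transition(float(rfun(dl)))
                tr = _pair_transition(float(rfun(dr)))
                p4 = (fwd[i] @ tl) * ((emis[i + 1] * bwd[i + 1]) @ tr.T)
                left, right = names[i], names[i + 1]
            p4 = p4 / np.maximum(p4.sum(1, keepdims=True), 1e-300)
            block[:, j, 0] = p4[:, 0]
            block[:, j, 1] = p4[:, 1] + p4[:, 2]
            block[:, j, 2] = p4[:, 3]
            pos_rows.append(
                {"chrom": chrom, "cm": float(x), "left_marker": left, "right_marker": right}
            )
        prob_blocks.append(block)

    positions = pd.DataFrame(pos_rows)
    probs = np.concatenate(prob_blocks, axis=1)
    return ProbGrid(positions, probs, step_cm, gmap)


# ---------------------------------------------------------------------------
# Cofactor selection (stepwise forward/backward on marker main effects)
# ---------------------------------------------------------------------------


def _marker_designs(genos: F2GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Additive (-1/0/+1) and dominance (0/1) columns, missing -> marker mean."""
    codes = genos.codes.astype(float)
    miss = codes < 0
    xa = codes - 1.0
    xd = (codes == 1).astype(float)
    xa[miss] = np.nan
    xd[miss] = np.nan
    col_a = np.nanmean(np.where(miss, np.nan, xa), axis=0)
    col_d = np.nanmean(np.where(miss, np.nan, xd), axis=0)
    col_a = np.where(np.isnan(col_a), 0.0, col_a)
    col_d = np.where(np.isnan(col_d), 0.0, col_d)
    xa = np.where(miss, col_a[None, :], xa)
    xd = np.where(miss, col_d[None, :], xd)
    return xa, xd


def _fit_rss(X: np.ndarray, y: np.ndarray) -> float:
    q, _ = np.linalg.qr(X)
    u = q.T @ y
    return float(y @ y - u @ u)


def _marker_block(xa, xd, selected):
    cols = [np.ones((xa.shape[0], 1))]
    for j in selected:
        cols.append(xa[:, [j]])
        cols.append(xd[:, [j]])
    return np.concatenate(cols, axis=1)


def select_cofactors(
    genos: F2GenotypeMatrix,
    y: np.ndarray,
    alpha_in: float = 0.05,
    alpha_out: float = 0.05,
    max_steps: int = 100,
    max_cofactors: int | None = None,
) -> list[int]:
    """Stepwise forward/backward marker selection (2-df additive+dominance tests).

    Deterministic: ties break on smallest p-value then lowest marker index.
    Returns marker column indices into the genotype matrix.
    """
    y = np.asarray(y, float)
    n, m = genos.codes.shape
    if len(y) != n:
        raise ValueError("phenotype length does not match genotypes")
    if m == 0 or float(np.var(y)) == 0.0:
        return []
    xa, xd = _marker_designs(genos)
    selected: list[int] = []

    for _step in range(max_steps):
        if max_cofactors is not None and len(selected) >= max_cofactors:
            break
        X = _marker_block(xa, xd, selected)
        q, _ = np.linalg.qr(X)
        resid = y - q @ (q.T @ y)
        rss_cur = float(resid @ resid)
        if rss_cur <= 1e-12:
            break
        za = xa - q @ (q.T @ xa)
        zd = xd - q @ (q.T @ xd)
        gaa = np.einsum("ij,ij->j", za, za)
        gdd = np.einsum("ij,ij->j", zd, zd)
        gad = np.einsum("ij,ij->j", za, zd)
        ba = za.T @ resid
        bd = zd.T @ resid
        det = gaa * gdd - gad**2
        with np.errstate(divide="ignore", invalid="ignore"):
            drss = np.where(
                det > 1e-10 * np.maximum(gaa * gdd, 1e-300),
                (gdd * ba**2 - 2 * gad * ba * bd + gaa * bd**2) / det,
                np.where(gaa > 1e-12, ba**2 / np.maximum(gaa, 1e-300), 0.0),
            )
        drss = np.clip(np.nan_to_num(drss), 0.0, rss_cur)
        dfe = n - X.shape[1] - 2
        if dfe <= 0:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            fstat = (drss / 2.0) / np.maximum((rss_cur - drss) / dfe, 1e-300)
        pvals = stats.f.sf(fstat, 2, dfe)
        pvals[selected] = np.inf
        best = int(np.argmin(pvals))
        if not pvals[best] < alpha_in:
            break
        selected.append(best)

        # Backward sweep: drop any selected marker whose 2-df test exceeds alpha_out.
        while len(selected) > 1:
            X_all = _marker_block(xa, xd, selected)
            rss_full = _fit_rss(X_all, y)
            dfe_b = n - X_all.shape[1]
            worst_p, worst_j = -1.0, None
            for j in selected:
                others = [k for k in selected if k != j]
                rss_red = _fit_rss(_marker_block(xa, xd, others), y)
                fst = ((rss_red - rss_full) / 2.0) / max(rss_full / dfe_b, 1e-300)
                p = float(stats.f.sf(fst, 2, dfe_b))
                if p > worst_p or (p == worst_p and (worst_j is None or j < worst_j)):
                    worst_p, worst_j = p, j
            if worst_p > alpha_out:
                selected.remove(worst_j)
            else:
                break
    return sorted(selected)


# ---------------------------------------------------------------------------
# CIM scan engine
# ---------------------------------------------------------------------------


@dataclass
class LODCurve:
    positions: pd.DataFrame     # chrom, cm, left_marker, right_marker
    lod: np.ndarray
    additive: np.ndarray
    dominance: np.ndarray
    rss_null: np.ndarray
    rss_full: np.ndarray
    tss: float
    n: int
    threshold: float | None = None
    environment: str | None = None


def _cofactor_metadata(gmap: GeneticMap, cofactors) -> tuple[np.ndarray, np.ndarray]:
    chroms = gmap.table["chrom"].to_numpy()
    cms = gmap.table["cm"].to_numpy(float)
    idx = np.asarray(list(cofactors), dtype=int)
    if idx.size == 0:
        return np.empty(0), np.empty(0)
    return chroms[idx], cms[idx]


def _scan_engine(
    grid: ProbGrid,
    Y: np.ndarray,
    cof_design: np.ndarray,
    cof_chrom: np.ndarray,
    cof_cm: np.ndarray,
    window_cm: float,
    effects: bool,
):
    """Vectorized Haley-Knott scan over all positions for B phenotype columns.

    Returns (lod [npos x B], a, d, rss_null, rss_full) with effect arrays for
    the first column only (or None when effects=False).
    Null-model projections are cached per distinct cofactor-exclusion set.
    """
    n, B = Y.shape
    npos = grid.n_positions
    pos_chrom = grid.positions["chrom"].to_numpy()
    pos_cm = grid.positions["cm"].to_numpy(float)
    ssY = np.einsum("ij,ij->j", Y, Y)
    n_cof = len(cof_chrom)

    cache: dict[tuple, tuple] = {}
    lod = np.empty((npos, B))
    rss_null_out = np.empty(npos)
    rss_full_out = np.empty(npos)
    a_out = np.full(npos, np.nan) if effects else None
    d_out = np.full(npos, np.nan) if effects else None

    xa_all = grid.probs[:, :, 2] - grid.probs[:, :, 0]
    xd_all = grid.probs[:, :, 1]
    ones = np.ones((n, 1))

    for p in range(npos):
        if n_cof:
            keep = ~(
                (cof_chrom == pos_chrom[p]) & (np.abs(cof_cm - pos_cm[p]) <= window_cm)
            )
            key = tuple(np.nonzero(keep)[0])
        else:
            key = ()
        if key not in cache:
            if key:
                cols = np.concatenate([[2 * k for k in key], [2 * k + 1 for k in key]])
                cols.sort()
                Xn = np.concatenate([ones, cof_design[:, cols]], axis=1)
            else:
                Xn = ones
            qn, rn = np.linalg.qr(Xn)
            # Guard collinear cofactor columns: drop directions with ~zero R diagonal.
            good = np.abs(np.diag(rn)) > 1e-8 * max(1.0, np.abs(rn[0, 0]))
            if not good.all():
                qn = qn[:, good]
            un = qn.T @ Y
            rssn = ssY - np.einsum("ij,ij->j", un, un)
            cache[key] = (qn, rssn)
        qn, rssn = cache[key]

        Z = np.column_stack([xa_all[:, p], xd_all[:, p]])
        Zr = Z - qn @ (qn.T @ Z)
        qz, rz = np.linalg.qr(Zr)
        diag = np.abs(np.diag(rz))
        good = diag > 1e-8 * max(diag.max(), 1e-300)
        qz = qz[:, good]
        uz = qz.T @ Y
        rssf = rssn - np.einsum("ij,ij->j", uz, uz)
        rssf = np.maximum(rssf, 1e-12)
        lod[p] = (n / 2.0) * (np.log10(rssn) - np.log10(rssf))
        rss_null_out[p] = rssn[0]
        rss_full_out[p] = rssf[0]
        if effects and good.all() and Zr.shape[1] == 2:
            beta = np.linalg.solve(rz, qz.T @ Y[:, 0])
            a_out[p] = beta[0]
            d_out[p] = beta[1]
    return lod, a_out, d_out, rss_null_out, rss_full_out


def _build_cofactor_design(genos: F2GenotypeMatrix, cofactors) -> np.ndarray:
    xa, xd = _marker_designs(genos)
    idx = list(cofactors)
    cols = []
    for j in idx:
        cols.append(xa[:, [j]])
        cols.append(xd[:, [j]])
    if not cols:
        return np.empty((genos.codes.shape[0], 0))
    return np.concatenate(cols, axis=1)


def cim_scan(
    grid: ProbGrid,
    phenos: np.ndarray,
    genos: F2GenotypeMatrix | None = None,
    cofactors=(),
    window_cm: float = 10.0,
    dominance_scale: float = 2.0,
    environment: str | None = None,
) -> LODCurve:
    """Composite interval mapping scan; with no cofactors this is plain
    interval mapping. ``dominance_scale=2`` converts the fitted heterozygote
    coefficient of F2:3 family means to the underlying dominance effect."""
    y = np.asarray(phenos, float)
    if y.ndim != 1 or len(y) != grid.probs.shape[0]:
        raise ValueError("phenotype vector does not match the probability grid")
    cofactors = list(cofactors)
    if cofactors and genos is None:
        raise ValueError("genotypes are required when cofactors are supplied")
    cof_design = (
        _build_cofactor_design(genos, cofactors) if cofactors else np.empty((len(y), 0))
    )
    cof_chrom, cof_cm = (
        _cofactor_metadata(grid.gmap, cofactors) if cofactors else (np.empty(0), np.empty(0))
    )
    lod, a, d, rssn, rssf = _scan_engine(
        grid, y[:, None], cof_design, cof_chrom, cof_cm, window_cm, effects=True
    )
    tss = float(((y - y.mean()) ** 2).sum())
    return LODCurve(
        positions=grid.positions.copy(),
        lod=lod[:, 0],
        additive=a,
        dominance=d * dominance_scale,
        rss_null=rssn,
        rss_full=rssf,
        tss=tss,
        n=len(y),
        environment=environment,
    )


def interval_mapping(grid: ProbGrid, phenos, dominance_scale: float = 2.0) -> LODCurve:
    """Plain interval mapping: the cofactor-free reduction of the CIM scan."""
    return cim_scan(grid, phenos, cofactors=(), dominance_scale=dominance_scale)


def permutation_threshold(
    grid: ProbGrid,
    phenos: np.ndarray,
    genos: F2GenotypeMatrix | None = None,
    cofactors=(),
    n_perm: int = 1000,
    alpha: float = 0.05,
    window_cm: float = 10.0,
    rng: np.random.Generator | int | None = None,
    cofactor_procedure=None,
) -> float:
    """Genome-wide LOD threshold: (1-alpha) quantile of permuted max LOD.

    Family means are permuted; by default the supplied cofactors are held
    fixed across permutations. Pass ``cofactor_procedure`` (a callable
    y -> cofactor indices) to re-select cofactors per permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    y = np.asarray(phenos, float)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    perms = np.column_stack([rng.permutation(y) for _ in range(n_perm)])

    if cofactor_procedure is not None:
        max_lods = np.empty(n_perm)
        for b in range(n_perm):
            cof = cofactor_procedure(perms[:, b])
            curve = cim_scan(grid, perms[:, b], genos, cof, window_cm)
            max_lods[b] = curve.lod.max()
    else:
        cofactors = list(cofactors)
        cof_design = (
            _build_cofactor_design(genos, cofactors)
            if cofactors
            else np.empty((len(y), 0))
        )
        cof_chrom, cof_cm = (
            _cofactor_metadata(grid.gmap, cofactors)
            if cofactors
            else (np.empty(0), np.empty(0))
        )
        lod, *_ = _scan_engine(
            grid, perms, cof_design, cof_chrom, cof_cm, window_cm, effects=False
        )
        max_lods = lod.max(axis=0)
    return float(np.quantile(max_lods, 1.0 - alpha))  # numpy default: type-7


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QTLPeak:
    name: str
    environment: str | None
    chrom: object
    position_cm: float
    marker_interval: tuple[str, str]
    lod: float
    additive: float
    dominance: float
    da_ratio: float
    gene_action: str
    pve: float

    def __post_init__(self):
        if not 0.0 <= self.pve <= 100.0:
            raise ValueError(f"PVE {self.pve} outside [0, 100]")


def _refine_peak_cm(curve: LODCurve, p: int, chrom_mask: np.ndarray) -> float:
    """Sub-grid peak position by a parabola through the argmax and its two
    grid neighbors on the same chromosome (positions are reported to 0.1 cM,
    finer than the scan step). Falls back to the grid position at chromosome
    boundaries or degenerate curvature."""
    cms = curve.positions["cm"].to_numpy(float)
    grid_cm = float(cms[p])
    if p - 1 < 0 or p + 1 >= len(cms) or not (chrom_mask[p - 1] and chrom_mask[p + 1]):
        return grid_cm
    x = cms[p - 1 : p + 2]
    y = curve.lod[p - 1 : p + 2]
    if not (y[1] >= y[0] and y[1] >= y[2]):
        return grid_cm
    denom = (x[1] - x[0]) * (y[1] - y[2]) - (x[1] - x[2]) * (y[1] - y[0])
    if abs(denom) < 1e-12:
        return grid_cm
    vertex = x[1] - 0.5 * (
        (x[1] - x[0]) ** 2 * (y[1] - y[2]) - (x[1] - x[2]) ** 2 * (y[1] - y[0])
    ) / denom
    if not np.isfinite(vertex):
        return grid_cm
    return float(np.clip(vertex, x[0], x[2]))


def call_qtl_peaks(
    curve: LODCurve, threshold: float, gmap: GeneticMap | None = None
) -> list[QTLPeak]:
    """One peak per contiguous supra-threshold segment per chromosome.

    The highest-LOD position wins (ties -> leftmost); flanking markers are the
    nearest typed markers bracketing the peak; PVE is the incremental variance
    explained by the position terms at the peak, relative to the total sum of
    squares.
    """
    peaks: list[QTLPeak] = []
    pos = curve.positions
    above = curve.lod >= threshold
    per_chrom_counter: dict = {}
    for chrom in dict.fromkeys(pos["chrom"]):
        sel = (pos["chrom"] == chrom).to_numpy()
        idx = np.nonzero(sel & above)[0]
        if idx.size == 0:
            continue
        # Split into contiguous runs of grid indices.
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        for run in np.split(idx, breaks + 1):
            lods = curve.lod[run]
            p = int(run[np.argmax(lods)])  # argmax returns first (leftmost) max
            cm = _refine_peak_cm(curve, p, sel)
            if gmap is not None:
                sub = gmap.chrom_table(chrom)
                mcm = sub["cm"].to_numpy(float)
                names = sub["marker"].tolist()
                li = int(np.searchsorted(mcm, cm + 1e-9) - 1)
                li = max(0, min(li, len(names) - 2))
                interval = (names[li], names[li + 1])
            else:
                interval = (pos["left_marker"].iloc[p], pos["right_marker"].iloc[p])
            a = float(curve.additive[p])
            d = float(curve.dominance[p])
            ratio, action = classify_gene_action(a, d)
            pve = 100.0 * (curve.rss_null[p] - curve.rss_full[p]) / curve.tss
            k = per_chrom_counter.get(chrom, 0) + 1
            per_chrom_counter[chrom] = k
            peaks.append(
                QTLPeak(
                    name=f"q{chrom}-{k}",
                    environment=curve.environment,
                    chrom=chrom,
                    position_cm=round(cm, 1),
                    marker_interval=interval,
                    lod=float(curve.lod[p]),
                    additive=a,
                    dominance=d,
                    da_ratio=ratio,
                    gene_action=action,
                    pve=float(np.clip(pve, 0.0, 100.0)),
                )
            )
    return peaks


def peaks_to_frame(peaks: list[QTLPeak]) -> pd.DataFrame:
    rows = [
        {
            "qtl": p.name,
            "environment": p.environment,
            "chrom": p.chrom,
            "position_cm": p.position_cm,
            "marker_interval": f"{p.marker_interval[0]}-{p.marker_interval[1]}",
            "lod": round(p.lod, 2),
            "additive": round(p.additive, 2),
            "dominance": round(p.dominance, 2),
            "da_ratio": p.da_ratio,
            "gene_action": p.gene_action,
            "pve_percent": round(p.pve, 2),
        }
        for p in peaks
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "qtl", "environment", "chrom", "position_cm", "marker_interval",
            "lod", "additive", "dominance", "da_ratio", "gene_action", "pve_percent",
        ],
    )


def scan_environment(
    gmap: GeneticMap,
    genos: F2GenotypeMatrix,
    table: pd.DataFrame,
    environment: str,
    step_cm: float = 1.0,
    window_cm: float = 10.0,
    alpha_in: float = 0.05,
    alpha_out: float = 0.05,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    grid: ProbGrid | None = None,
) -> tuple[LODCurve, list[QTLPeak], float]:
    """Full single-environment CIM analysis on F2:3 family means."""
    from .phenostats import family_means

    means = family_means(table, environment)
    means = means.reindex(genos.individuals)
    if means.isna().any():
        missing = means.index[means.isna()].tolist()[:5]
        raise ValueError(f"families without phenotypes: {missing} ...")
    y = means.to_numpy(float)
    if grid is None:
        grid = genotype_probabilities(gmap, genos, step_cm)
    cof = select_cofactors(genos, y, alpha_in, alpha_out)
    curve = cim_scan(grid, y, genos, cof, window_cm, environment=environment)
    thr = permutation_threshold(
        grid, y, genos, cof, n_perm=n_perm, alpha=alpha, window_cm=window_cm, rng=rng
    )
    curve.threshold = thr
    peaks = call_qtl_peaks(curve, thr, gmap)
    return curve, peaks, thr
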