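"""CIM scan: genotype probabilities, cofactor selection, LOD oracles,
permutation thresholds, peak calling, and gene-action classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mesoqtl import phenostats, qtlscan, simdata
from mesoqtl.qtlscan import (
    LODCurve,
    call_qtl_peaks,
    cim_scan,
    classify_gene_action,
    genotype_probabilities,
    interval_mapping,
    permutation_threshold,
    select_cofactors,
)


@pytest.fixture(scope="module")
def scan_data(small_config):
    cfg = small_config
    gmap = simdata.make_map(cfg)
    rng = np.random.default_rng(101)
    genos = simdata.simulate_f2_genotypes(gmap, cfg, rng)
    table, _ = simdata.simulate_f23_phenotypes(
        genos, list(cfg.qtl_architecture), cfg, rng, gmap=gmap
    )
    y = (
        phenostats.family_means(table, "20cm")
        .reindex(genos.individuals)
        .to_numpy(float)
    )
    grid = genotype_probabilities(gmap, genos, step_cm=2.0)
    return gmap, genos, y, grid


class TestClassifyGeneAction:
    @pytest.mark.parametrize(
        "a,d,ratio,action",
        [
            (-1.03, -1.20, 1.17, "D"),
            (-0.61, 0.97, 1.59, "OD"),
            (0.17, 0.10, 0.59, "PD"),
            (1.0, 0.0, 0.00, "A"),
            (-1.01, -1.51, 1.50, "OD"),
            (0.25, 0.03, 0.12, "A"),
        ],
    )
    def test_reference_pairs(self, a, d, ratio, action):
        got_ratio, got_action = classify_gene_action(a, d)
        assert got_ratio == pytest.approx(ratio, abs=1e-9)
        assert got_action == action

    def test_boundaries_closed_on_right(self):
        assert classify_gene_action(1.0, 0.20)[1] == "A"
        assert classify_gene_action(1.0, 0.2000001)[1] == "PD"
        assert classify_gene_action(1.0, 0.80)[1] == "PD"
        assert classify_gene_action(1.0, 1.20)[1] == "D"
        assert classify_gene_action(1.0, 1.2000001)[1] == "OD"

    def test_zero_additive_conventions(self):
        assert classify_gene_action(0.0, 0.0) == (0.0, "A")
        ratio, action = classify_gene_action(0.0, 0.5)
        assert math.isinf(ratio) and action == "OD"

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_gene_action(float("nan"), 1.0)

    @given(
        a=st.floats(-10, 10, allow_nan=False),
        d=st.floats(-10, 10, allow_nan=False),
    )
    def test_exhaustive_partition(self, a, d):
        _, action = classify_gene_action(a, d)
        assert action in {"A", "PD", "D", "OD"}


class TestGenotypeProbabilities:
    def test_probabilities_sum_to_one(self, scan_data):
        *_, grid = scan_data
        assert np.allclose(grid.probs.sum(axis=2), 1.0, atol=1e-10)

    def test_degenerate_at_typed_marker(self, scan_data):
        gmap, genos, _, grid = scan_data
        name = gmap.table["marker"].iloc[3]
        cm = float(gmap.table["cm"].iloc[3])
        j = grid.positions.index[
            (grid.positions["chrom"] == 1) & (np.abs(grid.positions["cm"] - cm) < 1e-9)
        ][0]
        codes = genos.codes[:, 3]
        for code, channel in ((0, 0), (1, 1), (2, 2)):
            sel = codes == code
            assert np.allclose(grid.probs[sel, j, channel], 1.0)

    def test_midpoint_between_homozygous_markers_matches_enumeration(self):
        # Two markers 10 cM apart, individual typed AA at both ends. Exact
        # per-gamete conditional: P(non-recombinant path) over both flanks.
        gmap = simdata.GeneticMap(
            pd.DataFrame(
                {"marker": ["a", "b"], "chrom": [1, 1], "cm": [0.0, 10.0],
                 "bp": [1, 10_000_001]}
            )
        )
        genos = simdata.F2GenotypeMatrix(
            np.array([[0, 0]], dtype=np.int8), ["i1"], ["a", "b"]
        )
        grid = genotype_probabilities(gmap, genos, step_cm=5.0)
        mid = grid.positions.index[np.abs(grid.positions["cm"] - 5.0) < 1e-9][0]
        r = float(simdata.haldane_r(5.0))
        p_gamete = (1 - r) ** 2 / ((1 - r) ** 2 + r**2)
        expected = p_gamete**2
        assert grid.probs[0, mid, 0] == pytest.approx(expected, abs=1e-12)
        assert grid.probs[0, mid, 0] > 0.9

    def test_missing_chromosome_falls_back_to_prior(self):
        gmap = simdata.GeneticMap(
            pd.DataFrame(
                {"marker": ["a", "b"], "chrom": [1, 1], "cm": [0.0, 20.0],
                 "bp": [1, 2]}
            )
        )
        genos = simdata.F2GenotypeMatrix(
            np.array([[-1, -1]], dtype=np.int8), ["i1"], ["a", "b"]
        )
        grid = genotype_probabilities(gmap, genos, step_cm=20.0)
        assert np.allclose(grid.probs[0, :, :], [0.25, 0.5, 0.25], atol=1e-12)

    def test_invalid_step_rejected(self, scan_data):
        gmap, genos, *_ = scan_data
        with pytest.raises(ValueError):
            genotype_probabilities(gmap, genos, step_cm=0.0)


class TestSelectCofactors:
    def test_no_phenotype_variation_empty(self, scan_data):
        _, genos, *_ = scan_data
        assert select_cofactors(genos, np.ones(genos.n_individuals)) == []

    def test_strong_qtl_marker_selected(self, scan_data):
        gmap, genos, y, _ = scan_data
        selected = select_cofactors(genos, y)
        # truth at 45.0 cM on chrom 1: markers M01_05 (44.4) / M01_06 (55.6)
        cms = gmap.table.iloc[selected]
        near = cms[(cms["chrom"] == 1) & ((cms["cm"] - 45.0).abs() < 12)]
        assert len(near) >= 1

    def test_null_selection_rate_modest(self, rng):
        """Markers unlinked to a pure-noise trait enter roughly at alpha-rate."""
        cfg = simdata.SimConfig(
            seed=1, n_f2=150, n_chromosomes=2, markers_per_chromosome=(8, 8),
            chromosome_lengths=(70.0, 70.0), environments=("e",), env_means=(0.0,),
            residual_sd=(1.0,), qtl_architecture=(),
        )
        gmap = simdata.make_map(cfg)
        rates = []
        for _ in range(30):
            genos = simdata.simulate_f2_genotypes(gmap, cfg, rng)
            y = rng.normal(size=cfg.n_f2)
            rates.append(len(select_cofactors(genos, y)) / 16)
        assert np.mean(rates) < 0.15

    def test_power_at_pve14(self, rng):
        """A 14%-PVE locus (n=346) is captured by itself or a neighbor.

        Scaled-down version of the full 200-replicate experiment."""
        arch = (simdata.TrueQTL("q", 1, 45.0, {"e": -1.25}, {"e": -0.18}),)
        rsd = simdata.residual_sd_for_pve(list(arch), "e", "q", 0.14, 10)
        cfg = simdata.SimConfig(
            seed=1, n_f2=346, n_chromosomes=1, markers_per_chromosome=(14,),
            chromosome_lengths=(72.0,), environments=("e",), env_means=(10.0,),
            residual_sd=(rsd,), gxe_sd=0.0, qtl_architecture=arch,
        )
        gmap = simdata.make_map(cfg)
        hits = 0
        n_sim = 40
        for _ in range(n_sim):
            genos = simdata.simulate_f2_genotypes(gmap, cfg, rng)
            table, _ = simdata.simulate_f23_phenotypes(
                genos, list(arch), cfg, rng, gmap=gmap
            )
            y = (
                phenostats.family_means(table, "e")
                .reindex(genos.individuals)
                .to_numpy(float)
            )
            sel = select_cofactors(genos, y)
            cms = gmap.table.iloc[sel]
            if ((cms["chrom"] == 1) & ((cms["cm"] - 45.0).abs() <= 6)).any():
                hits += 1
        assert hits / n_sim >= 0.88


class TestCIMScan:
    def test_zero_cofactors_equals_independent_interval_mapping(self, scan_data):
        """CIM with no cofactors must reproduce a brute-force per-position
        Haley-Knott regression computed with an unrelated least-squares path."""
        *_, y, grid = scan_data
        curve = interval_mapping(grid, y)
        n = len(y)
        for j in range(0, grid.n_positions, 7):
            xa = grid.probs[:, j, 2] - grid.probs[:, j, 0]
            xd = grid.probs[:, j, 1]
            X = np.column_stack([np.ones(n), xa, xd])
            rss_full = float(
                np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
            )
            rss_null = float(np.sum((y - y.mean()) ** 2))
            lod = n / 2 * math.log10(rss_null / rss_full)
            assert curve.lod[j] == pytest.approx(lod, abs=1e-8)

    def test_lod_at_typed_marker_matches_marker_regression(self, scan_data):
        gmap, genos, y, grid = scan_data
        curve = interval_mapping(grid, y)
        n = len(y)
        for mi in (2, 7, 13):
            cm = float(gmap.table["cm"].iloc[mi])
            chrom = gmap.table["chrom"].iloc[mi]
            j = grid.positions.index[
                (grid.positions["chrom"] == chrom)
                & (np.abs(grid.positions["cm"] - cm) < 1e-9)
            ][0]
            codes = genos.codes[:, mi].astype(float)
            X = np.column_stack([np.ones(n), codes - 1, (codes == 1).astype(float)])
            rss_full = float(
                np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
            )
            rss_null = float(np.sum((y - y.mean()) ** 2))
            lod = n / 2 * math.log10(rss_null / rss_full)
            assert curve.lod[j] == pytest.approx(lod, abs=1e-8)

    def test_effect_signs_and_magnitudes_near_truth(self, scan_data):
        *_, y, grid = scan_data
        curve = interval_mapping(grid, y)
        p = int(np.argmax(curve.lod))
        assert curve.positions["chrom"].iloc[p] == 1
        assert abs(curve.positions["cm"].iloc[p] - 45.0) <= 8
        assert curve.additive[p] == pytest.approx(-1.25, abs=0.35)

    def test_cofactors_within_window_do_not_blank_peak(self, scan_data):
        gmap, genos, y, grid = scan_data
        cof = select_cofactors(genos, y)
        curve = cim_scan(grid, y, genos, cof, window_cm=10.0)
        p = int(np.argmax(curve.lod))
        assert curve.positions["chrom"].iloc[p] == 1
        assert abs(curve.positions["cm"].iloc[p] - 45.0) <= 8


class TestPermutationThreshold:
    def test_alpha_one_gives_minimum(self, scan_data):
        *_, y, grid = scan_data
        thr = permutation_threshold(grid, y, n_perm=50, alpha=1.0, rng=5)
        thr_05 = permutation_threshold(grid, y, n_perm=50, alpha=0.05, rng=5)
        assert thr <= thr_05

    def test_monotone_nonincreasing_in_alpha(self, scan_data):
        *_, y, grid = scan_data
        thrs = [
            permutation_threshold(grid, y, n_perm=100, alpha=a, rng=5)
            for a in (0.01, 0.05, 0.2, 0.63, 1.0)
        ]
        assert all(a >= b for a, b in zip(thrs, thrs[1:]))

    def test_deterministic_under_seed(self, scan_data):
        *_, y, grid = scan_data
        t1 = permutation_threshold(grid, y, n_perm=60, rng=9)
        t2 = permutation_threshold(grid, y, n_perm=60, rng=9)
        assert t1 == t2

    def test_null_genomewide_error_rate_calibrated(self, rng):
        """Reduced nested simulation: reject-rate near alpha on null traits."""
        cfg = simdata.SimConfig(
            seed=1, n_f2=150, n_chromosomes=2, markers_per_chromosome=(8, 8),
            chromosome_lengths=(70.0, 70.0), environments=("e",), env_means=(0.0,),
            residual_sd=(1.0,), qtl_architecture=(),
        )
        gmap = simdata.make_map(cfg)
        genos = simdata.simulate_f2_genotypes(gmap, cfg, rng)
        grid = genotype_probabilities(gmap, genos, step_cm=2.0)
        rejections = 0
        n_outer = 60
        for _ in range(n_outer):
            y = rng.normal(size=cfg.n_f2)
            curve = interval_mapping(grid, y)
            thr = permutation_threshold(grid, y, n_perm=100, alpha=0.05, rng=rng)
            rejections += curve.lod.max() >= thr
        # alpha = 0.05; binomial(60, 0.05) stays below 11 with prob > 0.999
        assert rejections <= 10


class TestPeakCalling:
    def _curve(self, lods, cms=None):
        n = len(lods)
        cms = cms if cms is not None else np.arange(n, dtype=float)
        pos = pd.DataFrame(
            {"chrom": 1, "cm": cms, "left_marker": "L", "right_marker": "R"}
        )
        return LODCurve(
            positions=pos, lod=np.asarray(lods, float),
            additive=np.full(n, -1.0), dominance=np.full(n, -0.1),
            rss_null=np.full(n, 100.0), rss_full=np.full(n, 80.0),
            tss=200.0, n=100,
        )

    def test_no_supra_threshold_positions(self):
        assert call_qtl_peaks(self._curve([1.0, 2.0, 1.5]), threshold=3.0) == []

    def test_two_separated_peaks_with_valley(self):
        lods = [0.5, 4.0, 5.0, 4.0, 0.5, 0.6, 0.4, 4.5, 6.0, 4.2, 0.3]
        peaks = call_qtl_peaks(self._curve(lods), threshold=3.0)
        assert len(peaks) == 2
        assert [p.position_cm for p in peaks] == [2.0, 8.0]
        assert all(p.pve == pytest.approx(10.0) for p in peaks)

    def test_tied_maximum_selects_leftmost_then_refines_to_plateau(self):
        peaks = call_qtl_peaks(self._curve([0.0, 4.0, 4.0, 0.0]), threshold=3.0)
        assert len(peaks) == 1
        # grid argmax is the leftmost tied point; the parabola through the
        # plateau puts the reported position midway between the tied points
        assert peaks[0].position_cm == 1.5

    def test_boundary_peak_keeps_grid_position(self):
        peaks = call_qtl_peaks(self._curve([5.0, 4.0, 0.0]), threshold=3.0)
        assert peaks[0].position_cm == 0.0

    def test_end_to_end_peak_recovers_truth(self, scan_data):
        gmap, genos, y, grid = scan_data
        cof = select_cofactors(genos, y)
        curve = cim_scan(grid, y, genos, cof)
        thr = permutation_threshold(grid, y, genos, cof, n_perm=100, rng=11)
        peaks = call_qtl_peaks(curve, thr, gmap)
        best = max(peaks, key=lambda p: p.lod)
        assert best.chrom == 1
        assert abs(best.position_cm - 45.0) <= 8
        left, right = best.marker_interval
        cms = gmap.table.set_index("marker")["cm"]
        # position is reported to 0.1 cM; allow that rounding at the interval edges
        assert cms[left] - 0.05 <= best.position_cm <= cms[right] + 0.05
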