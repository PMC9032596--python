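# Methods

This note documents the models, the parameter choices that matter, and the
limits of what the synthetic data can show. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Cross and phenotype simulator (`simdata`)

**Meiosis model.** Each F2 individual is the union of two independent
gametes. Along a chromosome, a gamete's parental origin flips between
adjacent loci with probability given by the map function — Haldane by
default, `r = (1 − e^(−2d/100))/2`, i.e. no crossover interference
(Kosambi is available). Genotypes are coded as the count of second-parent
(K12) alleles: 0 = AA (W64A homozygote), 1 = AB, 2 = BB.

**Map.** Default: 10 chromosomes, 26 evenly spaced markers each
(260 markers, 250 intra-chromosome intervals, 1410.6 cM total, mean spacing
5.64 cM). Per-chromosome lengths (196.2 … 103.2 cM) were fixed once to give
maize-like proportions summing to 1410.6; the longest chromosome accommodates
the most distal default QTL (145.2 cM). Physical positions use a linear
1 cM = 1 Mb scaling (configurable), needed because linkage results are in cM
while BSA regions are in bp.

**QTL effects and sign convention.** A locus contributes `a·(g − 1) +
d·[g = 1]` with `g` the K12-allele count, so a *negative* `a` means the
tolerant parent W64A carries the trait-increasing allele — the convention in
which the field reports these effects. F2:3 family means given the F2 parent
genotype are AA → −a, AB → d/2, BB → +a: one generation of selfing halves
the heterozygote dominance deviation. The default architecture is the seven
reported MES QTL with their per-environment (3/15/20 cm) effect estimates.

**Noise model.** Observed value = environment mean + Σ QTL contributions +
a per-family×environment normal G×E deviation (sd 0.3 by default) + a
per-replicate normal residual. Default environment means (3.74, 10.95,
13.09 cm) are the reported F2:3 means per sowing depth; default residual sds
(1.0, 2.2, 2.8 cm) encode that deeper sowing is noisier and give strong but
not saturated heritability. A closed-form helper
(`residual_sd_for_pve`) converts a target PVE for a focal QTL into the
per-replicate residual sd via `Var_QTL = a²/2 + 3d²/16` for F2:3 family
means under unlinked loci; the QTL-recovery experiments use it to pin the
focal PVE at 14% *before* any scan is run.

Known tension: the reported per-environment effect heterogeneity (the same
QTL changing sign or magnitude across depths) intrinsically generates more
G×E variance than the reported heritability partition (H²_B ≈ 0.91,
H²_GE ≈ 0.09) implies. The generator is faithful to the per-environment
effects; its realized H²_B on default settings is therefore lower (~0.6–0.7)
and H²_GE higher. Both cannot be matched simultaneously.

**Pooled sequencing.** Bulks are F2 plants (selected through their F2:3
family means, as in the study design), so the null model for the index draws
F2 genotypes. Per site, pool allele frequency `p = (2·n_BB + n_AB)/(2k)`;
total depth ~ Poisson(coverage, default 45); alternate depth ~
Binomial(depth, p′) with `p′ = p(1−e) + (1−p)e` folding in a symmetric
sequencing error (default 0.001). The reference allele is assigned to W64A,
the alternate to K12; parents emit homozygous depths. Variant positions are
uniform per chromosome (default 300/chromosome, ~20% InDels) — real variant
density, LD decay from ancestral haplotypes, and mapping artifacts are *not*
modeled, so passing tests demonstrate correctness of the algorithms under
the design's sampling model, not robustness to real sequencing pathologies.

**Determinism.** All randomness flows through one `numpy` Generator seeded
from `SimConfig.seed`; `scenario_study` output is byte-identical under a
fixed seed.

## Phenotype genetics (`phenostats`)

Balanced family × environment ANOVA by expected mean squares:
`σ²_ε = MS_error`, `σ²_ge = (MS_GE − MS_err)/r`, `σ²_g = (MS_G − MS_GE)/(nr)`
with negative estimates truncated at zero (raw values retained). Unbalanced
tables are rejected rather than silently plugged.

Heritabilities share one denominator `σ²_g + σ²_ge/n + σ²_ε/(nr)`:
`H²_B` has `σ²_g` in the numerator; `H²_GE` has `σ²_ge/n`. The published
formula for the interaction heritability puts `σ²_g/n` in the numerator,
which is algebraically forced to `H²_B/n` and contradicts the reported
estimates; the corrected numerator is the default and the literal form is
available with `as_printed=True`.

Rate of change under deep sowing defaults to
`RC = (T_deep/T_normal − 1)·100` — the orientation that reproduces all
reported parental and F1/F2:3 percentages; the literal printed form
`(1 − T_normal/T_deep)·100` sits behind the same `as_printed` flag.

Kurtosis is reported as *excess* kurtosis (normal = 0) and the normality
flag is `|skew| < 1 ∧ |kurtosis| < 1`; the convention is stated because the
source of the rule does not specify one. A constant sample is treated as a
degenerate pass.

## CIM scan (`qtlscan`)

**Genotype probabilities.** An exact 4-state hidden Markov chain over
ordered gamete pairs (two independent two-state chains; emissions are
consistency indicators of the observed unordered genotype, with missing
codes emitting 1). Forward–backward messages give P(AA/AB/BB) at every grid
position conditional on *all* typed markers of the chromosome, so arbitrary
missing-data patterns are handled; an entirely untyped chromosome simply
yields the 1:2:1 prior, which is why such individuals are retained rather
than dropped. The evaluation grid is the union of a fixed step (default
1 cM) and the marker positions.

**Regression scan.** Haley–Knott: trait ~ intercept + E[additive dosage] +
P(heterozygote) + cofactors, with `LOD = (n/2)·log10(RSS_null/RSS_full)`
where the null keeps the cofactors. When the phenotype is an F2:3 family
mean the heterozygote coefficient estimates d/2, so reported dominance
effects apply a scale factor of 2 (configurable for per-plant F2 scans).
This is a deliberate divergence from the reference software's EM mixture
likelihood: at ~5.6 cM marker density the LOD difference is negligible,
the regression is deterministic, and permutations become matrix products.
The engine caches the null-model QR per distinct cofactor-exclusion set and
evaluates all permutation columns in one pass.

**Cofactors.** Stepwise forward/backward selection on marker main effects
(2-df additive + dominance F-tests, in/out at p < 0.05, ties by smallest p
then lowest index; missing genotypes mean-imputed for the cofactor design).
Cofactors within ±10 cM (the window) of the test position are excluded from
that position's model. Permutation thresholds (default 1000 permutations,
type-7 quantile at 1 − α) hold the observed-data cofactors fixed across
permutations; re-selection per permutation is available via
`cofactor_procedure` but is not the default — fixed cofactors keep
1000-permutation scans desk-scale, and the null-calibration test verifies
the genome-wide type-I error is near α under this scheme.

**Peaks.** One peak per contiguous supra-threshold segment per chromosome;
grid ties break leftmost. The reported position refines the grid argmax with
a parabola through its two grid neighbors (positions are reported to
0.1 cM, finer than the scan step); at chromosome boundaries or degenerate
curvature the grid position is kept. Flanking markers are the nearest typed
markers bracketing the peak; PVE = 100·(RSS_null − RSS_full)/TSS at the
peak. Gene action classifies the *unrounded* |d/a| into right-closed
intervals ([0, 0.20] → A, (0.20, 0.80] → PD, (0.80, 1.20] → D, else OD),
resolving the gap between 0.20 and 0.21 in the published class definitions;
a = 0 maps to OD when d ≠ 0 and to A when both are zero.

## BSA index mapping (`bsaseq`)

Informative sites require opposite homozygous parents and ≥ 10 reads in
both pools (default). The index is the fraction of reads carrying the
designated index parent's allele (default: the tolerant parent, so
enrichment in the long-mesocotyl bulk appears as Δ > 0); zero-depth sites
are masked, never imputed, and masking propagates to Δ and windows.

Sliding windows (defaults: 1 Mb window, 200 kb step, ≥ 10 sites, all
configurable) take unweighted means of per-site values; these defaults are
*choices*, not reconstructions — the source analysis does not state its
window parameters — picked to resolve regions of the 2–9 Mb scale actually
reported. The confidence band simulates the null exactly as the design
implies: per replicate, 30 F2 genotypes per bulk (1:2:1), binomial reads at
a given depth, Δ of two independent bulks; central `level` interval
(default 99%) tabulated on a depth grid (5…200 in steps of 5) with linear
interpolation, because per-site simulation would be wastefully slow.
Windows whose mean Δ lies outside the band (two-sided by default; one-sided
available) are significant; near-adjacent significant windows merge and
regions are optionally clipped to their outermost supporting sites.

## cQTL integration (`cqtl`)

QTL peaks project to physical intervals via their flanking markers'
bp positions. Evidence intervals (QTL, BSA, external) cluster by
single-linkage with a maximum gap, default 2 Mb — the smallest round value
that unifies the six chromosome-4 BSA regions (inter-region gaps ≈ 1.03 and
1.45 Mb) into the single reported envelope; it is exposed as a parameter
since no published rule exists. A cluster qualifies as a cQTL when it
combines QTL-type and BSA-type evidence (both requirements toggleable); the
envelope is the min-start/max-end of members and member PVEs are summed.
Coordinates are 1-based inclusive internally; BED export converts to
0-based half-open. Lengths in Mb are (end − start)/10⁶ rounded half-up to
two decimals. DEG thresholds are strict inequalities (FDR < 0.001,
|log2FC| > 1); candidate genes are envelope-overlapping genes passing the
filter in any comparison.

## Problem sizes used in the checks

The calibration and recovery checks run at the study's own scale: 30+30
bulks at 45× with a 10,000-replicate band and 20,000 null sites; 200 CIM
replicates of n = 346 families on the full 260-marker map with
200-permutation thresholds (the permutation count the threshold quantile
needs at α = 0.05, keeping 200 replicates tractable); 20 heritability
replicates of the 200-family × 3-environment × 10-replicate design.
Module-level simulation examples use smaller replicate counts with
correspondingly wider binomial bounds, stated per test.

## Known limitations

- No crossover interference, segregation distortion, or genotyping-error
  model beyond the symmetric allele flip in sequencing.
- The ANOVA is strictly balanced; REML/mixed models are out of scope.
- CIM fits single-QTL models per position (no multiple-QTL or epistasis
  modeling); closely linked QTL can shadow each other, and a cofactor
  outside the window but linked to the tested region can still displace
  peaks — an inherent property of the method, visible in the recovery
  experiments.
- The BSA null assumes free recombination between the site and the trait
  loci; sites linked to a real QTL are not "null", so band exceedance is a
  per-site significance statement, not a genome-wide error rate.
- Exit codes follow click's convention (2 for usage/validation errors).
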