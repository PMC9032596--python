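# mesoqtl

Genetic dissection of **maize mesocotyl elongation under deep sowing**, as a
tested, desk-scale Python pipeline. The mesocotyl is the stem segment that
pushes a grass seedling to the soil surface; when maize is sown at 15–20 cm
instead of the usual 3–5 cm, mesocotyl length (MES) determines whether the
seedling emerges at all. The package re-implements the computational chain
used to map this trait in a biparental W64A × K12 cross:

1. **simdata** — forward simulation of the study design: an F2 population
   (default 346 plants) on a 10-chromosome, 260-marker, ~1410.6 cM map
   (Haldane map function), F2:3 family phenotypes in three sowing-depth
   environments × 10 replicates under a configurable QTL architecture,
   30+30 extreme bulks, and pooled sequencing depths at ~45× coverage
   (VCF with per-pool AD fields).
2. **phenostats** — balanced two-way ANOVA variance components
   (σ²_g, σ²_ge, σ²_ε); broad-sense and G×E heritability
   `H²_B = σ²_g / (σ²_g + σ²_ge/n + σ²_ε/nr)`; heterosis indices
   (HI, RH, MH, OH, ARR); deep-sowing rate of change; distribution
   moments with the |skew| < 1 ∧ |kurtosis| < 1 normality flag; 2^−ΔΔCt
   relative expression.
3. **qtlscan** — composite interval mapping (CIM) by Haley–Knott regression
   on HMM genotype probabilities, stepwise cofactor selection (in/out at
   p < 0.05), a 10 cM exclusion window, genome-wide thresholds from
   permutations, and Stuber gene-action classes from |d/a|
   (A ≤ 0.20 < PD ≤ 0.80 < D ≤ 1.20 < OD).
4. **bsaseq** — bulked-segregant ΔSNP/ΔInDel-index mapping: per-site pool
   indices, sliding-window averages, a ≥10,000-replicate simulated 99%
   confidence band tabulated over read depth, and linked-region calling.
5. **cqtl** — physical-interval integration: QTL support intervals + BSA
   regions merge (single linkage, default gap 2 Mb) into constitutive QTLs
   (cQTLs), whose gene content is intersected with differential-expression
   tables (FDR < 0.001, |log2FC| > 1) to nominate candidate genes.
6. **io / cli** — TSV/VCF/BED readers and writers plus a `mesoqtl` command
   with subcommands `simulate`, `phenostats`, `qtlscan`, `bsa`, `cqtl`,
   and `all`.

It is aimed at quantitative geneticists who want a transparent, fully
testable reference for this analysis style — every stage runs in seconds to
minutes on simulated data with known truth.

## Worked example

```python
import numpy as np
from mesoqtl import simdata, phenostats, qtlscan

cfg = simdata.SimConfig(seed=42, variant_sites_per_chromosome=50)
scenario = simdata.scenario_study(cfg, "demo")          # writes TSV/VCF/JSON

report = phenostats.environment_report(scenario.phenotypes)
h = report["heritability"]
print(f"H_B2 = {h['H_B2']:.4f}, H_GE2 = {h['H_GE2']:.4f}")

curve, peaks, thr = qtlscan.scan_environment(
    scenario.gmap, scenario.genotypes, scenario.phenotypes, "20cm",
    n_perm=200, rng=42,
)
print(f"genome-wide LOD threshold (alpha=0.05): {thr:.2f}")
for p in sorted(peaks, key=lambda p: -p.lod)[:4]:
    print(f"{p.name}  chr{p.chrom}  {p.position_cm:6.1f} cM  LOD {p.lod:5.1f}  "
          f"a {p.additive:+.2f}  d {p.dominance:+.2f}  |d/a| {p.da_ratio}  "
          f"{p.gene_action}  PVE {p.pve:.1f}%")
```

prints

```
H_B2 = 0.6312, H_GE2 = 0.2871
genome-wide LOD threshold (alpha=0.05): 4.28
q4-1  chr4    86.5 cM  LOD  48.4  a -1.20  d -0.03  |d/a| 0.03  A  PVE 18.5%
q6-1  chr6    15.8 cM  LOD  46.5  a -1.40  d -1.59  |d/a| 1.14  D  PVE 17.5%
q3-1  chr3    57.3 cM  LOD  40.8  a -0.95  d -1.04  |d/a| 1.09  D  PVE 14.7%
q1-1  chr1   110.7 cM  LOD  39.7  a -1.09  d -0.58  |d/a| 0.53  PD  PVE 14.2%
```

The default simulated architecture places seven MES QTL with per-environment
effects; the 20 cm scan recovers the four major ones near their true
positions (chr 4 at 88.1 cM, chr 6 at 14.3 cM, chr 3 at 55.7 cM, chr 1 at
110.8 cM). Negative additive effects mean the deep-sowing-tolerant parent
(W64A) carries the allele that lengthens the mesocotyl. The same dataset
feeds the BSA and cQTL stages; `mesoqtl all --seed 42 --outdir run/` chains
everything from the shell.

## Layout

```
src/mesoqtl/    genmap, regions, simdata, phenostats, qtlscan, bsaseq,
                cqtl, io, cli
tests/          unit + property + acceptance tests (pytest, hypothesis)
docs/methods.md model assumptions, parameter choices, limitations
```
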