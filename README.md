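# pondiv

Taxonomic and functional diversity analysis of **two-region pond
metacommunities**, built for benthic diatom surveys in which each pond
contributes a standardized count of identified valves (e.g. 400 per sample)
and each species is coded against a binary catalogue of functional traits
(ecological guilds, life-forms, attachment modes, biovolume size classes).
The motivating design is a Mediterranean-coastal versus Alpine comparison of
temporary ponds (12 per region), but any pond × species count table with a
two-region mapping and a species × trait table will do.

It is aimed at community ecologists who want the complete inference chain —
from raw count tables to calibrated permutation p-values — in one tested,
seeded, reproducible package rather than a patchwork of scripts.

## What it computes

**α / γ diversity.** Per-pond species richness, regional γ (pooled
richness), Wilcoxon rank-sum comparison with Cliff's δ
(δ = P(X>Y) − P(X<Y)), exact (hypergeometric) species accumulation curves
E[S_m] = Σ_s [1 − C(n−f_s, m)/C(n, m)], and a permutation test on the
accumulation-curve AUC (AUC = Σ_m E[S_m]) that reshuffles pond labels
between regions.

**Functional diversity.** Gower distances on binary traits, PCA trait
spaces, and abundance-weighted FRic (convex-hull volume), FDis (weighted
mean distance to the weighted centroid) and FDiv (Villéger divergence about
the hull-vertex gravity centre), per pond and under functional rarefaction
with the same AUC permutation machinery.

**β structure.** Bray–Curtis distances, non-metric MDS (k = 2), one-factor
PERMANOVA (McArdle–Anderson), multivariate dispersion homogeneity
(betadisper-style, with Anderson's negative-eigenvalue correction), the
Baselga partition β_SOR = β_SIM + β_SNE (pairwise and multiple-site), and
Raup–Crick β_RC from a richness-preserving, frequency-weighted null
(β_RC ≈ 0.5 → stochastic assembly, → 1 → deterministic turnover).

**Functional assembly.** Abundance-weighted SES.MPD against a taxa-label
randomization null, and the convex-hull **functional overlap index**

    overlap = (V_A + V_B − V_combined) / V_combined

computed from the two regional hulls in a pooled 3-axis PCA trait space,
with a membership-permutation test.

**Indicators and networks.** Group-equalized IndVal (stat = √(A·B)) with
permutation p-values, per-region trait-frequency comparisons, and bipartite
species–trait networks (degrees, density, Louvain modularity) tested
against Patefield fixed-margin null matrices.

A seeded synthetic metacommunity generator reproduces the study design (two
regions × 12 ponds × 400 valves, regional pools with controllable overlap
and richness contrast, region-biased trait frequencies) so the whole
pipeline is testable without field data.

## Worked example

```python
import pondiv as pv

cm, tm, _ = pv.generate_metacommunity(pv.GeneratorConfig(seed=42))

rich = pv.species_richness(cm)
cp, gs = rich[cm.ponds_in("CP")], rich[cm.ponds_in("GS")]
test = pv.wilcoxon_rank_sum(cp.to_numpy(), gs.to_numpy())
auc = pv.auc_permutation_test(cm.restrict("CP"), cm.restrict("GS"),
                              n_perm=10_000, seed=1)
pa = pv.to_presence_absence(cm)
multi = pv.baselga_multisite(pa)
rc = pv.raup_crick(pa, n_rand=999, seed=2)
```

prints (via the obvious f-strings):

```
mean alpha:  CP 18.08  GS 29.92
gamma:       CP 60  GS 98
rank-sum:    W = 0.0, p = 3.52e-05, delta = -1.00
AUC diff:    -377.58 (p = 0.0001)
beta:        SOR 0.923 = SIM 0.904 + SNE 0.019
Raup-Crick:  0.55 (SD 0.37)
```

Read: the Alpine-like region (GS) is richer per pond (29.9 vs 18.1 species;
complete separation, δ = −1) and accumulates species faster (AUC difference
−377.6, permutation p = 1e-4); almost all β diversity is species turnover
(β_SIM 0.904 of β_SOR 0.923), and β_RC ≈ 0.55 puts pairwise turnover near
the stochastic-assembly expectation. The full pipeline, including the
functional-overlap test and network null models, runs with

```sh
pondiv run --outdir results/          # or: pondiv run --fast for a smoke run
pondiv synth --preset paperlike --seed 0 --outdir data/
```

and writes per-stage CSV/JSON plus a deterministic `manifest.json` (same
config + seed ⇒ byte-identical outputs).

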