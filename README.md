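# epimsap

Analysis of **Methylation-Sensitive Amplified Polymorphism (MSAP)**
fingerprints for non-model organisms — built around a field study of
the Caribbean sea urchin *Diadema antillarum*, but usable for any
two-digest (HpaII/MspI) MSAP survey.

MSAP digests genomic DNA in parallel with two isoschizomers that cut
the same CCGG motif but are blocked by different CpG methylation
configurations. The joint fragment presence pattern across digests
encodes a methylation state per locus — (1/1) non-methylated NMT,
(1/0) hemimethylated HMM, (0/1) internal-cytosine-methylated ICM,
(0/0) conservatively hypermethylated HPM — without needing a reference
genome. `epimsap` takes capillary-electrophoresis peak tables (or
pre-binarized fragment matrices) through to:

- filtered binary fragment matrices (50–1500 bp, > 40 RFU, ≥ 15 %
  prevalence) and methylation-state matrices with
  methylation-susceptible-locus (MSL) partitioning;
- per-locus Shannon diversity H = −Σ pₛ ln pₛ and grouped
  state-frequency profiles;
- distance-based statistics implemented from first principles on the
  Gower-centered matrix G = −½ J D² J: PERMANOVA (sequential pseudo-F
  with permutation p), PERMDISP, PCoA, dbRDA and RDA variance
  partitioning;
- DAPC (PCA to k−1 components, then discriminant axes) with
  loading-percentile selection of influential loci;
- the **plasticity-coupling statistic**: Spearman rank correlation
  between per-group-pair epigenetic centroid distances (PCoA space)
  and phenotypic centroid distances (log righting time), with exact
  small-n permutation p;
- ecological field metrics (sediment-trap deposition, N:P limitation
  status, seasons, size classes, transect density, chained monthly
  survival);
- a seeded synthetic-data generator with ground truth for every stage.

## Worked example

Simulate a monitoring-style survey (4 sites × 2 seasons, 20 urchins
per group, 300 loci), score it, and test for seasonal methylation
structure:

```sh
$ epimsap simulate --seed 2 --out simdir
$ epimsap score --fragments simdir/fragments.csv --out states.csv
{"n_loci": 238, "n_msl": 238, "n_polymorphic_msl": 238, "pct_polymorphic_msl": 100.0}

$ epimsap diversity --states states.csv --meta simdir/metadata.csv --group-by season
{"mean_H": 0.6824878535099578, "sd_H": 0.21426775669179496, "n_loci": 238}

$ epimsap permanova --states states.csv --meta simdir/metadata.csv --n-perm 99 --seed 1
term      SS        df  F        R2        p
site      57.150    3   0.9954   0.01771   0.48
season    202.675   1   10.5902  0.06282   0.01
Residual  2966.375  155           0.91946
```

Reading the output: of the 300 simulated loci, 238 survive the
prevalence filter and all are methylation-susceptible and polymorphic;
mean per-locus Shannon diversity is 0.68 (bounded by ln 4 ≈ 1.386 for
four states). The sequential PERMANOVA attributes 6.3 % of the
methylation sum of squares to season (p = 0.01 at 99 permutations)
and 1.8 % to site (p = 0.48) — the generator's seasonal effect is an
order of magnitude stronger than its site effect, and the analysis
recovers that ordering.

The same stages are available as library calls
(`epimsap.msap_scoring`, `epimsap.multivariate`, `epimsap.plasticity`,
…), and `epimsap run --config run.yaml` chains
score → diversity → PERMANOVA/PERMDISP → PCoA → dbRDA → DAPC →
plasticity with a reproducibility manifest.

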