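# soilnet

Co-occurrence network, diversity and guild analysis for soil-microbiome
count tables, plus a synthetic community generator that emulates a
3 (microbial-biomass level) × 3 (fertilizer type) × 2 (soil habitat)
factorial design with native-soil controls (57 samples).

## What it does

- **`soilnet.io_tables`** — TSV readers/writers for count tables, ranked
  taxonomy lineages (with `unclassified_`/`norank_` markers), sample
  designs with physicochemical/yield covariates; lossless GraphML network
  export/import.
- **`soilnet.synthetic_community`** — latent-factor log-normal →
  Dirichlet-multinomial count generator with planted taxon–taxon
  association blocks, per-treatment-cell composition targets (bias-corrected
  by a deterministic fixed-point calibration), covariates, and full ground
  truth for recovery benchmarking.
- **`soilnet.diversity`** — rarefaction (without replacement), Chao1
  (bias-corrected), Shannon (natural log), Bray–Curtis distances, classical
  PCoA (negative eigenvalues dropped and reported), PERMANOVA and ANOSIM
  with label-permutation p-values. All implemented from first principles;
  tests cross-check against scikit-bio.
- **`soilnet.conet`** — the ensemble co-occurrence pipeline: abundance
  filtering; five association measures per taxon pair (Spearman, Pearson,
  symmetrized Kullback–Leibler, Bray–Curtis, mutual information with
  equal-frequency binning); sample-permutation p-values; empirical Brown
  combination (covariance-corrected Fisher; reduces exactly to Fisher under
  independence); edge calling at |Spearman| > 0.6 and combined p < 0.05;
  topology indices (density, clustering, path length, sign percentages) and
  normalized-degree hub detection at cutoff 0.2.
- **`soilnet.guild_pathogen`** — genus-over-family trophic-guild lookup
  against a bundled TSV mini-database; per-sample potential plant/animal
  pathogen relative abundance.
- **`soilnet.factorial_stats`** — balanced full-factorial ANOVA (rejects
  unbalanced designs), Pearson/Spearman correlation screens, agronomic
  nitrogen-use efficiency.
- **`soilnet.cli`** — `generate → diversity → network → guilds → stats`
  pipeline with seeds, YAML config and a checksummed manifest.

## CLI

```sh
soilnet run-all --out-dir out --seed 20170001          # full pipeline
soilnet generate --out-dir out --seed 1                # synthetic data only
soilnet network --out-dir out -b 1000 --factor ismb    # one network per level
soilnet diversity --out-dir out --permutations 999
soilnet guilds --out-dir out --min-confidence Probable
soilnet stats --out-dir out
```

Outputs are plain TSV (counts, taxonomy, design, alpha/beta diversity,
topology shaped like a per-network index table, guild assignments,
pathogen scores, ANOVA tables) plus GraphML networks and a
`manifest.json` recording config, seeds and per-file SHA-256 checksums;
reruns with identical config are byte-identical.

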