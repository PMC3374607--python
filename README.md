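# permcomp

Permutation-based compositional analysis of mucosal 16S rRNA count tables,
built for cross-sectional IBD cohort studies that ask whether disease
phenotype, host genotype (NOD2, ATG16L1), *C. difficile* carriage and
clinical covariates are associated with shifts in gut microbial
composition. The package ships a synthetic-cohort generator with the same
statistical structure (170 subjects: 52 ileal Crohn's disease, 58 colitis,
60 non-IBD controls; three sequencing platforms; qPCR tracks), so the whole
pipeline runs and is testable without any sequence data.

## The model

Reads are binned into seven phyla/subphyla categories (Actinobacteria,
Bacteroidetes, *Firmicutes* Clostridium Group IV, Clostridium Group XIVa,
Bacillus, Proteobacteria, Other); samples with fewer than 100 reads are
excluded. The six predominant categories form the compositional response:
counts x are adjusted with a 0.5 pseudocount and centered-log-ratio
transformed,

```
clr_i = ln(x_i) − (1/6) Σ_j ln(x_j),
```

so Euclidean distances between samples are Aitchison distances. Inference
is distance-based: with G = −½·C·d²·C the Gower-centered inner-product
matrix and H_k the projector of the cumulative design through term k, the
sequential sum of squares of term k is tr((H_k − H_{k−1})G), its effect
size is R² = SS/SS_total, and its pseudo-F

```
F = (SS_term / df_term) / (SS_res / df_res)
```

gets a p-value by permuting subject labels against the fixed distance
matrix (p = (1 + #{F_b ≥ F_obs}) / (1 + B)). For a scalar response this
reproduces classical sequential ANOVA/ANCOVA exactly, which is how the
per-category and qPCR analyses run (qPCR relative frequencies enter through
the empirical logit ln((p+ε)/(1−p+ε))).

On top of the engine sit: forward stepwise selection of main effects and
all first-order interactions by permutation p-value (entry at α = 0.05);
Benjamini–Hochberg FDR over each reported table; a repeated-measures
permutation ANCOVA that treats the three sequencing platforms as
within-subject measurements (subject blocks are permuted whole for
between-subject terms, platform labels are shuffled within subjects for the
Measurements effect); and a chi-square / Kruskal–Wallis cohort-description
table.

## Worked example

```python
from permcomp import (
    CandidatePool, SimulationConfig, clr_transform, euclidean_distances,
    ileal_cd_effect_preset, simulate_cohort, stepwise_select,
)

cohort = simulate_cohort(
    SimulationConfig(seed=7, effect_map=ileal_cd_effect_preset())
)
clr = clr_transform(cohort.counts["sanger"])          # 170 x 6, rows sum to 0
d = euclidean_distances(clr)                          # Aitchison distances
pool = CandidatePool.full(list(cohort.metadata.columns))
trace = stepwise_select(d, pool, cohort.metadata, n_permutations=999, seed=1)
print(trace.steps.head(3))
print(trace.final.table.round(4).head(3)[["term", "df", "r2", "p", "fdr"]])
```

prints

```
   step                        term         kind  df  entry_r2  entry_p
0     1                   phenotype         main   2  0.144371    0.001
1     2  phenotype*immunomodulators  interaction   1  0.029061    0.003
2     3               race*steroids  interaction   1  0.024402    0.004

                         term  df      r2      p     fdr
0                   phenotype   2  0.1444  0.001  0.0045
1  phenotype*immunomodulators   1  0.0291  0.001  0.0045
2               race*steroids   1  0.0211  0.002  0.0060
```

The injected disease-phenotype effect enters first with a composition
R² ≈ 0.14 (14% of the total Aitchison variance) at the permutation floor
p = 1/1000; the FDR column is the BH adjustment across the final table.
Later entries are a mix of the weaker injected colitis shift leaking into
interactions and forward-selection false entries — stepwise selection over
91 candidates is greedy, which is why the package also reports null
calibration rates (below).

The same analysis runs end-to-end from the shell:

```sh
permcomp run --dump-defaults > config.yaml   # edit, then
permcomp run --config config.yaml --seed 7 --out results/
```

writing the cohort table, per-platform MANCOVA tables, per-category ANCOVA
tables, the repeated-measures table with its Measurements row, and the two
qPCR ANCOVA tables, plus a manifest; identical configs give byte-identical
tables.

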