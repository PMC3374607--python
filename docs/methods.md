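# Methods

## Scope and data model

The package analyzes subject-level seven-category taxon count tables (one
per sequencing platform), a 13-covariate clinical/genotype metadata table,
and qPCR relative-frequency tables, and asks which covariates are
associated with shifts in mucosal microbial composition. The seven
categories — Actinobacteria, Bacteroidetes, *Firmicutes* Clostridium Group
IV, Clostridium Group XIVa, Bacillus, Proteobacteria, Other — are the
analysis's taxonomic resolution; the Firmicutes subdivision is driven by an
editable concordance table (`src/permcomp/data/firmicutes_concordance.tsv`)
mapping lower-rank classifier names to the three groups, because no single
authoritative mapping exists between classifier output and the
Clostridium-cluster schema. Names are matched case- and
punctuation-insensitively; anything unmatched lands in Other, so binning is
total. Samples with fewer than 100 reads are dropped (strict inequality:
exactly 100 is kept).

## Compositional response

The six named categories (Other excluded) form the response. A 0.5
pseudocount is added to the raw counts *before* closure, then the centered
log-ratio is taken in natural log. CLR maps each sample to a zero-sum
vector in which Euclidean distance is the Aitchison distance; the transform
is closure-invariant, so counts and proportions give identical results, and
the log base only rescales distances without affecting permutation
inference. qPCR relative frequencies p ∈ [0,1] enter a univariate analysis
through the empirical logit ln((p+ε)/(1−p+ε)), finite at 0 and 1. Because
qPCR yields copy-number ratios rather than counts, there is no natural
count-based ε; the default is half the smallest nonzero observed frequency
(data-adaptive, scales with assay resolution) and a fixed ε can be set in
configuration when exact cross-dataset reproducibility matters. Relative
frequencies above 1 — possible with independently calibrated standard
curves — are clamped to 1 with a logged count.

## Distance-matrix permutation inference

All inference runs through one engine: G = −½·C·d²·C (Gower centering),
sequential projections H_k of the cumulative design, SS_k = tr((H_k −
H_{k−1})G), pseudo-F = (SS/df)/(SS_res/df_res). Design columns are
treatment dummies (lexicographically first level as reference) for
categorical covariates, linear untransformed columns for numeric ones, and
elementwise products of the parent encodings for interactions. The
cumulative design is orthonormalized incrementally with an SVD-based rank
cut (relative tolerance 1e-8); a term adding no rank raises an error naming
it (or is skipped with a log entry during stepwise selection). Term df is
the rank increment, which matters when sparse factor cells make an
interaction collinear with its parents.

Sums of squares are sequential (Type I) in the supplied order — for
stepwise models, the selection order — and the order-dependence is
deliberate and surfaced in the output. Significance comes from freely
permuting whole metadata rows against the fixed distance matrix; all terms
share one permutation stream. Monte-Carlo p-values use the +1/+1
correction, p = (1 + #{F_b ≥ F_obs})/(1 + B), so p = 0 is impossible and
the floor is 1/(B+1); B defaults to 999 and is configurable. For n ≤ 7 an
exhaustive mode enumerates all n! relabelings and reports the exact tail
proportion without the correction (the identity relabeling is part of the
enumerated null set). Exceedance is counted with a 1e-10 relative
tolerance: relabelings equivalent to the observed one reproduce F only up
to reordering round-off (~1e-15), and an exact float comparison
systematically undercounts these true ties — the tolerance restores exact
agreement with brute-force enumeration and cannot flip genuinely distinct
F values. On a scalar response (distance = |y_i − y_j|) the pseudo-F equals
the classical sequential ANOVA/ANCOVA F to machine precision, which is the
package's per-category and qPCR ANCOVA.

## Stepwise selection and FDR

Forward-only selection: at each step every not-yet-selected candidate (13
main effects plus all 78 first-order interactions by default) is tested as
the last sequential term on a shared per-step permutation stream, and the
smallest-p candidate enters if p ≤ α (default 0.05). Interaction hierarchy
is not enforced — interactions compete regardless of whether their parents
entered. Exact p ties are broken by pool order, with main effects listed
before interactions. This tie-break is deliberate: tied p-values almost
always sit at the 1/(B+1) floor, where the permutation test has exhausted
its resolution; ranking such candidates by incremental R² or pseudo-F just
amplifies noise and mechanically favors higher-df interaction blocks that
are nearly collinear with a main effect already at the floor. Preferring
the earlier pool entry is the same determinism rule vegan's `ordistep`
uses and acts as a weak marginality preference. Selection stops when no
candidate passes, the pool empties, or residual df would run out; a
`max_terms` cap is available for screening designs. The final model is
re-partitioned once in selection order with a fresh seeded permutation run,
and BH-FDR is applied across that one table's p-values (the FDR family is
the rows of one reported table). The BH step-up is the standard one:
adjusted_(i) = min_{j≥i} p_(j)·m/j, capped at 1.

Missing covariate values: subjects missing any pooled covariate are dropped
once per analysis (with a logged count) rather than per candidate model,
because candidate p-values must be comparable on one permutation stream and
one n within a step.

## Repeated measures across platforms

Each subject's per-platform CLR values (complete cases only) are stacked
long and partitioned sequentially: between-subject terms first (the union
of the per-platform selections: mains, then interactions), then the
within-subject Measurements (platform) factor last; R² uses the stacked
total SS as denominator since no within/between split of R² is canonical
here. Exchangeability differs by term kind, so two restricted schemes give
the p-values: subjects are permuted as whole blocks for between-subject
terms (preserving within-subject structure), and responses are shuffled
within each subject's block for Measurements. The within-block scheme fixes
every block mean — the same conditioning as subtracting subject means — and
leaves every between-subject term's SS exactly invariant (asserted in
tests). With a single platform the engine collapses to the plain univariate
permutation ANCOVA to 1e-10.

## Cohort description table

Categorical covariates are compared across phenotypes by Pearson chi-square
on the level × phenotype contingency table (no continuity correction,
asymptotic p; exact tests are out of scope at these margins); age and BMI
by Kruskal–Wallis with tie correction. The three-level anti-TNF variable is
one test. BH-FDR runs across the table. The degenerate all-values-equal
Kruskal case returns H = 0, p = 1 explicitly.

## Synthetic cohort generator

The generator emulates the cross-sectional surgical-cohort design the
pipeline assumes; its defaults are the study conditions, not tuning knobs.

* **Design**: 52/58/60 subjects (ileal CD / colitis / control).
* **Covariates** are drawn marginally per phenotype — the observable a
  published cohort table reports — at those tables' frequencies (e.g. NOD2
  risk-carrier 38/15/12%, current smoker 33/3/25%, *C. difficile* toxin
  6/28/0%, all IBD-only medications 0% in controls). Age and BMI are
  truncated normals matching the per-phenotype median and range (sd =
  range/4). ATG16L1 pins only the NR/NR marginal; the R/NR vs R/R split
  follows Hardy–Weinberg proportions of the implied NR allele frequency.
  Joint covariate structure beyond these marginals is not modelled.
* **Composition**: one latent Dirichlet draw per subject with parameters
  base_composition × concentration; the baseline seven-category composition
  (2/25/12/30/8/15/8%) is a realistic ileal-mucosa profile with ~92% of
  reads in the six named categories, and concentration 50 gives the
  overdispersion typical of mucosal 16S counts (a single tunable scalar;
  plain multinomial sampling would be far too regular). Effects are
  injected on the log scale of the Dirichlet parameters:
  (covariate, level, category, log-fold) entries multiply matching
  subjects' parameters by exp(log-fold); continuous entries scale with the
  standardized covariate. With an empty effect map the generator is an
  exact null for every covariate, which the calibration tests exploit.
* **Platforms**: Sanger-like (mean 500 reads/sample), 454 V1–V3-like
  (7260) and V3–V5-like (5400); depth per sample is negative-binomial
  (dispersion 10) around the platform mean, so low draws can fall below the
  100-read filter as in real runs. All platforms share the subject's latent
  composition (the true inter-platform coupling is unknown; a shared draw
  is the simplest choice and the only one the complete-case analysis
  needs). Counts are multinomial at the drawn depth, so categories sum to
  depth exactly.
* **qPCR**: target relative frequency = summed latent proportions of the
  tracked categories (the *C. coccoides–E. rectales* group tracks
  Clostridium XIVa + IV; *F. prausnitzii* tracks Clostridium IV) times
  multiplicative lognormal noise (sd 0.35 — copy-number ratios are positive
  and right-skewed), clamped to (0, 1].
* **Seeding**: one master seed; covariates, compositions, each platform and
  each qPCR target draw from named substreams with fixed spawn keys, so
  adding a platform never perturbs earlier draws and identical configs give
  byte-identical outputs.
* **Calibrated preset**: `ileal_cd_effect_preset()` injects an ileal-CD
  dysbiosis (Clostridium-group depletion, Proteobacteria/Bacillus
  expansion, milder colitis shift) whose log-folds were calibrated once so
  the realized single-term phenotype R² of the CLR composition on a
  Sanger-depth cohort averages ≈ 0.134 (the 0.12–0.15 range reported for
  disease phenotype in comparable mucosal cohorts), then frozen.

What passing tests on this generator do **not** show about real data: real
mucosal counts have subject-level covariance between taxa beyond a shared
Dirichlet draw, platform-specific primer bias (here platforms differ only
in depth), joint covariate dependence, and informative missingness. The
generator validates the inference machinery — calibration, recovery,
determinism — not the biology.

## Numerical and problem-size choices

Rank tolerance 1e-8 (relative, SVD-based); tie tolerance 1e-10 (relative)
on F exceedance; SS additivity asserted at 1e-8 relative on every result; a
degenerate response (total SS = 0) and saturated designs raise immediately.
The stochastic validation suites use B = 199 with 500 null cohorts
(type-I error of a pre-specified term, expected in [0.03, 0.07] at α =
0.05) and 100 effect-recovery replicates scored on the first selected term
— sizes chosen to put Monte-Carlo standard errors well inside the asserted
bands. Default B for reported analyses is 999, giving the conventional
0.001 p floor.

## Known limitations

Free raw-data permutation only (no residual-permutation schemes); forward
selection is greedy and its per-step minimum over ~91 candidates inflates
entry of weak terms — selection traces should be read with the null
calibration in mind; no backward elimination; no mixed-effects or Bayesian
alternatives; ordination and plotting are out of scope.
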