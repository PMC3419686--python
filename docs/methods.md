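# Methods

## Scope and data model

The package analyses genus-level community structure in a cohort of
subjects with 16S rRNA read counts, clinical metadata and (optionally)
labelled relative pairs. The count table is the entry point: rows are taxa
with semicolon-delimited lineage strings, columns are samples, entries are
non-negative integer read counts. Rank aggregation sums rows sharing the
requested rank-level name; reads unassigned at that rank are pooled into a
single `unassigned` sentinel that stays in the normalisation denominator
(profiles remain on the simplex) but is excluded from dominance calls and
the core-microbiota report — dominance and core membership are statements
about named taxa, while relative abundances must still sum to one over all
reads.

## Community typing

Pairwise Jensen–Shannon divergences between genus frequency profiles are
computed in nats; the square root (a metric, bounded by √ln 2 ≈ 0.833) is
the working distance. Clustering is agglomerative complete linkage,
implemented directly so the merge history and its tie behaviour are part of
the contract: at each step the minimal complete-link distance pair merges,
exact ties breaking on the lexicographically smallest cluster-id pair.
Merge heights are non-decreasing (complete linkage is monotone). "Top-level
clades" means the k-cluster cut that removes the k−1 highest merges
(equivalent to a cutree at k); groups are renumbered by their smallest
sample index so the labelling is deterministic.

Two assignment rules coexist: the clade cut, and dominant-genus typing
(Prevotella / Bacteroides / everything else as the diverse-Firmicutes
type, exact ties broken lexicographically). Both are emitted with an
agreement score because real cohorts sit on a gradient where the two rules
nearly — but not exactly — coincide. Silhouette widths use the same
sqrt-JSD matrix as the clustering; singleton clusters score 0, and the
degenerate all-identical case (a = b = 0) scores 0 by convention. PCoA is
delegated to scikit-bio (Gower double-centering of −½D², eigh); only axes
with positive eigenvalues are returned, with a warning if fewer than
requested.

Repeat-sample stability compares first- and second-visit labels through an
explicit second→first sample map and reports the unchanged fraction plus a
transition table.

## Correlation networks

Taxa entering a network are pre-filtered to ≥10% prevalence (≥1 read), which
removes the constant-vector hazards of rank correlation; the flag is
exposed. Spearman rho is the Pearson correlation of mid-ranks; p-values use
the two-sided t approximation t = ρ√((n−2)/(1−ρ²)) on n−2 df, which is
accurate at the cohort sizes targeted here (hundreds of samples); a
permutation option exists for small n, and |ρ| = 1 maps to p = 0.
Taxon–taxon edges are kept at strict p < 0.001 and taxon–trait edges at
p ≤ 0.005 — both thresholds configurable, since the two conventions are
used inconsistently in the literature this pipeline serves. No
multiple-testing correction is applied by default (raw thresholds are the
field convention for these networks); Benjamini–Hochberg is available
behind a flag. Missing trait values are handled pairwise-complete with the
per-edge n recorded; pairs with fewer than 4 complete cases are skipped
with a warning.

Modularity is Newman–Girvan on the unweighted simple graph:
Q = Σ_c [e_c/m − (d_c/2m)²]. Signed correlation weights stay on the edges
as attributes but do not enter Q — modularity with negative weights is
ill-defined without a signed extension, and the edge sign is a rendering /
reporting concern. The Louvain optimizer is written here: local moving in a
seed-shuffled node order, then aggregation into super-nodes (aggregated
graphs carry induced weights and self-loops), repeated until no gain. A
single greedy sweep is prone to shallow local optima on small graphs, so
the optimizer restarts 10 times with sub-seeded visit orders and keeps the
best-Q partition; the whole procedure is deterministic given the seed.
Edgeless graphs return singleton modules with Q = 0. The anchored
sub-network of a genus is the induced subgraph on the anchor and its direct
neighbours (anchor edges plus neighbour–neighbour edges).

## Family concordance and heritability

A pair is concordant iff both members carry the same community-type label
(clade-cut by default, dominant-taxon switchable). The first-degree rate
pools sibling and parent-offspring pairs weighted by pair counts (total
concordant over total pairs), and

    h² = 2 × (first-degree rate − spouse rate),

the logic being that spouses share household but not genes while
first-degree relatives share half their genes. Estimates outside [0, 1] are
flagged, never clamped: at the reference design (54/76/42 pairs) the
estimator's sampling SE is ≈ 0.16, so single-cohort estimates are expected
to swing widely and occasionally go negative. The spouse vs first-degree
contrast is tested by permuting relationship-class labels across the pooled
pair list (two-sided on the rate difference, add-one p estimator); a
permutation test is preferred to a two-proportion z-test because pairs
within a family are not independent (the z-test is available behind a flag
for comparison).

## Clinical statistics

Metabolic syndrome trait flags follow NHLBI-style criteria: TG > 150 mg/dl;
HDL ≤ 50 (women) or < 40 (men) mg/dl; SBP > 130 **or** DBP > 85 mmHg;
fasting glucose ≥ 100 mg/dl; each alternatively satisfied by the matching
medication flag, and waist circumference deliberately excluded (it is
nearly collinear with BMI). The male HDL cut-off is configurable between
`<40` and `<=40` because both conventions circulate. A missing measurement
with no medication flag leaves that criterion undetermined (excluded from
the count, with a warning) rather than silently false. Friedewald LDL is
TC − HDL − TG/5, undefined at TG ≥ 400 mg/dl.

Adjusted correlations residualize both variables on [1, covariates] by
least squares and test the residual correlation on n − 2 − k df (exact
under normality; Spearman-on-residuals available). The community-type
association test regresses each trait on intercept + age + sex + two group
indicators and compares against the covariates-only model with a 2-df
F-test ((2, n−5) df); per-group adjusted means are least-squares means at
the covariate means. Binary traits use logistic regression with a 2-df
likelihood-ratio test, since a linear model on a 0/1 response has no exact
F-theory. Pairwise contrasts (each group vs the rest) are computed only
when the overall 2-df test passes 0.05, mirroring the sequential protocol
such analyses follow. Wilcoxon rank-sum uses exact enumeration for
m + n ≤ 20 without ties and the tie-corrected normal approximation
otherwise. Occupation cross-tabs report counts with within-network column
percentages per sex. Subgroup abundance scans compare each taxon's relative
abundance between a subject subset and its complement (Wilcoxon, BH
q-values); note that compositional closure makes the complement of an
enriched taxon shift downward — sign matters when reading the output.

## The synthetic cohort generator

The generator is the package's study-conditions module: its defaults encode
the cohort regime the pipeline targets, and tests run against it.

* **Compositions.** Three archetype mean vectors over a 203-genus panel:
  Prevotella-dominated, Bacteroides-dominated (each suppressing the other's
  flagship genus — near-mutual exclusion on the simplex), and a
  diverse-Firmicutes type in which Firmicutes genera are jointly boosted
  with Oscillospira first among them (the highest-entropy type). Mixing
  prevalences default to 47/14/39%. A subject's composition is
  0.95 · Dirichlet(θ·m) + 0.05 · m: the Dirichlet supplies realistic
  overdispersion while the small deterministic admixture guarantees the
  17-genus core never fully drops out of a sample. θ (default 55) controls
  archetype overlap; it was calibrated once so that the k = 3 clade-cut
  silhouette on sqrt-JSD sits mid-way in the gradient regime (≈ 0.24,
  stable across seeds), and `SimConfig.separated()` (θ = 2000) gives tight,
  trivially recoverable clusters for recovery tests.
* **Bimodal prevalence.** The 17 core genera are always present; the
  remaining genera are gated by per-subject presence Bernoullis with
  per-taxon probabilities ≤ 0.85, producing the familiar two-peaked
  prevalence histogram and exactly 17 core calls at the 95% cutoff.
* **Depth.** Reads per sample ~ round(N(10 357, 3 764²)) floored at 3 000;
  counts are multinomial draws, so column sums equal the drawn depths
  exactly.
* **Traits.** Sex (~64% female), age (truncated normals by sex), and
  sex-specific baselines with mild age slopes for BMI, waist, blood
  pressure, lipids and glucose; TG and CRP are lognormal. Planted
  taxon–trait effects enter on the standardized log relative abundance
  (a clr-like scale — planting on raw fractions would let compositional
  closure dominate the planted signal), with the coefficient calibrated by
  a short iteration against the generated cohort so the realized marginal
  Spearman correlation lands within a few hundredths of its target. LDL is
  then computed by Friedewald, keeping the lipid panel internally
  consistent.
* **Families.** Pairs are the edges of family trees (couples at the root,
  children chained below); each edge's "new" member copies the anchor's
  archetype with the planted concordance probability and otherwise draws
  from the mixing distribution restricted to the other archetypes, so the
  per-pair concordance probability is exact (c_s = 0.389 for spouse edges,
  c_f = 0.483 for first-degree edges by default, at 54/76/42 pairs).
* **Repeats.** 19 second-visit samples by default; with probability equal
  to the switch rate (0.21) the archetype changes — to the Prevotella type
  when the origin differs, otherwise to a non-Prevotella type — so the
  change probability equals the switch rate exactly and changes
  predominantly land on Prevotella. Occupation is archetype-linked for men
  (farmers over-represented in the Prevotella type) and near-uniform for
  women.
* **Determinism.** The master seed spawns one child stream per stage
  (archetypes, families, compositions+counts, traits, repeats, planted
  effects); the same (config, seed) reproduces every table byte-exactly.

### What the generator does not emulate

Sequence-level artefacts (chimeras, barcode errors, OTU clustering noise),
taxonomic misassignment, diet and seasonality beyond the repeat-switch
rule, within-family shared-household effects on traits, and longitudinal
drift. Passing tests on this generator demonstrate that the estimators
recover the structure they assume; they do not validate those assumptions
on real cohorts.

## Problem sizes and numerical choices

Tests and the acceptance script run cohorts of 60–310 subjects with 30–203
genera, 1,000-replicate estimator-recovery loops at the 54/76/42 pair
design, 500–600-replicate type-I calibrations, and 100,000-permutation
Spearman references — sizes chosen so the whole suite completes in well
under a minute per module while keeping Monte-Carlo error small relative to
the tolerances tested. Numerical conventions: JSD clipped to [0, ln 2]
before the square root; distance matrices validated symmetric with zero
diagonal to 1e-12; silhouette and linkage ties broken deterministically as
described; silhouette comparisons against the brute-force oracle at 1e-9;
the permutation p uses the add-one estimator; seeds are spawned via
`numpy.random.SeedSequence` so streams are independent and reproducible.

## Known limitations

* The t approximation for Spearman p is inaccurate below n ≈ 25; use the
  permutation option there (the network stages target hundreds of samples).
* Modularity ignores edge signs and weights; strongly negative-correlation
  structure is represented in edge attributes but not in the partition
  objective.
* The heritability contrast conflates shared household with shared genes
  whenever spouse and first-degree environments differ systematically; it
  is a descriptive contrast, not a variance-component estimate, and is
  reported with its out-of-range flag rather than truncated.
* Louvain with restarts is a heuristic; optimality is verified
  exhaustively only on small graphs in the test suite.
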