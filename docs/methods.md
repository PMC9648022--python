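# Methods

This note documents the statistical procedures implemented in `cervtrans`,
the assumptions behind them, the tunable parameters, what the synthetic-data
generators do and do not emulate, and the numerical conventions chosen where
the procedures are genuinely underdetermined.

## Stage model and data conventions

Disease stage is the ordinal code 0 = Normal, 1 = LSIL, 2 = HSIL, 3 = SCC,
following the two-tier squamous-lesion terminology; CIN sub-grades map onto
it (CIN1 → LSIL, CIN2/3 → HSIL) but the raw label is retained so IHC results
can be stratified by CIN grade. Expression values are assumed normalized and
log2-scaled on input; the package performs no normalization. Genes measured
by several probes are represented by the probe with the highest row mean;
ties keep the probe first in file order (deterministic and stable under
re-serialization). Interaction networks are undirected simple graphs:
reversed duplicate edges merge, self-loops are dropped with a warning, and
an optional score threshold (STRING-style third column) can be applied — no
default threshold is claimed.

## Heterogeneity

PCA operates on gene-wise centered, unscaled log2 values (standard for
microarray intensities, where variance structure is informative); variance
fractions come from the singular values. Within-stage heterogeneity is the
distribution of all unordered within-stage sample-pair Pearson correlations.
By default r is computed across **all** genes; restricting to a top-variable
subset is a function argument. Stage distributions are compared by
Kruskal–Wallis, followed by all pairwise two-sided Wilcoxon rank-sum tests
with Bonferroni correction (p × number of pairs, capped at 1). The rank-sum
p is exact when both groups have ≤ 50 tie-free observations, otherwise the
tie-corrected normal approximation.

## Differential expression and the two set constructions

Each lesion stage is tested against normal gene-wise with Welch's unpooled
two-sample *t* (Welch–Satterthwaite df). This replaces an empirical-Bayes
moderated *t*: the pipeline's substance is the set logic downstream of the
test, and moderation shifts only borderline calls; the test statistic is a
natural extension point. Degenerate rows are defined explicitly: both groups
constant and equal → p = 1; both constant but different → p = 0. log2FC is
the difference of log2 group means; the DEG rule is BH-adjusted p < 0.05 and
|log2FC| > 1 (fold change > 2). BH adjustment is the step-up formula
adj₍ᵢ₎ = min₍ⱼ≥ᵢ₎(m·p₍ⱼ₎/j), capped at 1.

**Sets1 (cross-study)**: per comparison (LSIL/HSIL/SCC vs normal), the union
of up calls and the union of down calls over datasets; a gene called up in
one dataset and down in another is removed from both. Direction consistency
is enforced **per comparison** by default — the alternative global reading
(any disagreement anywhere removes the gene everywhere) is a flag — because
a gene can plausibly move oppositely at different stages without being an
artifact.

**Stepwise genes**: Spearman ρ of expression against the stage code with
average ranks for ties. The two-sided p uses the *t* approximation, switching
to an exact multiset-permutation null when total n ≤ 10, where the
approximation is unreliable. Constant genes get ρ = 0, p = 1.

**Sets2 (cross-stage)**: per dataset, genes DEG-up in at least one
comparison and stepwise-up (symmetrically down). Membership is not
restricted to the carcinoma comparison by default; a flag restricts it.

## Over-representation

ORA uses the hypergeometric upper tail P(X ≥ k) with the universe equal to
the genes measured on the platform (per dataset) — the defensible universe
for array data — overridable by argument. GO/KEGG hierarchies are treated as
flat sets; DAG-aware simplification is out of scope. q-values are BH across
the collection; the conventional thresholds are q < 0.05 for positional
sets and q < 0.1 for functional collections.

## Centrality and consensus hubs

The nine ranking methods are implemented from their definitions (see the
`hub_network` docstring for the formulas). Choices where the methods are
underdetermined:

- **Closeness** uses the harmonic (sum of reciprocal distances) form so
  disconnected graphs are well-defined.
- **Bottleneck** depends on a BFS shortest-path tree, which is ambiguous;
  the canonical rule here is that a newly discovered node's parent is its
  lexicographically smallest neighbor in the previous BFS layer. Scores are
  then reproducible and invariant under order-preserving relabeling. A node
  is a bottleneck of a tree when its subtree (itself included; the root's
  subtree is the whole tree) holds ≥ 25% of the tree's nodes.
- **EPC** draws, per realization, a global threshold t ~ U(0,1) and
  per-edge uniforms, keeps edges with u < t, and credits each node its
  percolated cluster size; the score is the mean cluster size over R
  realizations divided by n. Default R = 5000 with an explicit seed; Monte
  Carlo error is bounded by cluster/n ∈ (0,1].
- **DMNC** exponent ε = 1.7 (the method's original constant). When several
  neighborhood components tie in size, the one with more edges, then the
  lexicographically smallest member, is taken.

Top-k selection (k = 10) keeps every node tied with the k-th score, so a
method's candidate set can exceed k — with integer-valued scores
(Bottleneck, Degree, Stress, MNC) this matters often. Hubs are nodes in the
candidate sets of ≥ 2 datasets by default; the stricter all-datasets reading
is a parameter, since both appear in practice.

## IHC scoring and diagnostic evaluation

HSCORE = 1·(%1+) + 2·(%2+) + 3·(%3+), range 0–300, with the percentage sum
constrained to ≤ 100. Layer scores: parabasal-only 0, lower third 1+, lower
two thirds 2+, beyond 3+; TOP2A's 3+ collapses into 2+. Noninvasive
positivity thresholds are explicit reconstructions (the original scoring
table is not public): Ki-67/TOP2A layer ≥ 2; AURKA/CEP55 intensity ≥ 2;
RFC4 intensity ≥ 2 plus a beyond-basal distribution flag; p16 a supplied
diffuse-block-positivity flag (that criterion is visual, not computable from
the modeled fields). All are configurable. Carcinoma sections are positive
at strictly > 10% positive cells, for all markers.

Proportion CIs are exact Clopper–Pearson — chosen because the printed
reference intervals are reproduced exactly by CP under integer-count
inversion, which also makes the inversion unique (margins ≤ 300). The
binary-test AUC is (sens + spec)/2 with a Hanley–McNeil interval (the
reference does not name its AUC CI method; this is an assumption and is
labelled as such). Percentages round half-up to 1 decimal, AUC to 2.
Exact McNemar uses the two-sided binomial tail at min(b, c); κ is Cohen's
(p₀ − pₑ)/(1 − pₑ) with pₑ = 1 only in the constant-and-equal degenerate
case, where κ := 1. Serial combination is positive iff both markers are,
parallel iff either is; missing calls propagate and are excluded pairwise.

## Survival

Follow-up is administratively censored at 60 months (times beyond the
horizon truncate to 60 with event = 0; the boundary itself is untouched).
The optimal cutpoint maximizes the absolute standardized log-rank statistic
over all observed marker values leaving ≥ minprop = 0.1 of the cohort on
each side (the conventional default of the maximally-selected-rank
approach); ties take the smallest cutoff. The naive p at the selected
cutoff is anti-conservative by construction and the result object carries a
`selection_inflated` flag; an unbiased permutation p over the maximal
statistic is available. Cox models are fitted by partial-likelihood
Newton–Raphson with Efron tie handling (convergence threshold 1e-9 on the
update norm); non-convergence and quasi-separation (|β| > 15) raise.

The time-dependent AUC is the IPCW cumulative/dynamic estimator: cases are
subjects with an observed event by t, weighted 1/G(T⁻); controls are
subjects event-free through t (including those censored exactly at the
administrative horizon, whose common weight cancels in the ratio); G is the
Kaplan–Meier censoring survival, with censoring ordered after events at
tied times. Under zero censoring this reduces identically to the empirical
case/control AUC, and it matches scikit-survival's estimator under
censoring. Nested models are compared per evaluation time (12, 24, 36, 48,
60 months) by paired bootstrap (normal approximation on the bootstrap SE of
the AUC difference) with Holm adjustment across the five times; the
reference only says "adjusted" without naming a method, so Holm is a
documented choice.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structure* the analysis assumes, at the study
scale: three discovery datasets sharing gene identifiers (500 genes, 8
samples per stage); 40 stepwise genes at ±1 log2 per stage step on gene
baselines N(7, 2²); 10 direction-inconsistent genes whose effect sign flips
between datasets; residual noise sd 0.5 with the carcinoma stage inflated
×1.5 (enough to reproduce the depressed within-carcinoma correlations
without tuning); networks of 60 nodes with ER(p = 0.05) background and 4
hubs each wired to 40% of nodes, with non-hub symbols drawn from a
genome-scale 20,000-symbol pool so independently generated networks share
hubs but only incidentally share background genes — the situation the
consensus step actually faces across per-dataset candidate gene sets; an
IHC cohort of 68 high-grade and 101 normal/low-grade sections with the
published marker operating points and a single-parameter Gaussian-copula
dependence between markers; and a survival cohort of n = 252 with
exponential event times, hazard h₀·exp(Xβ) (marker log-HR −0.7,
protective), uniform dropout calibrated by bisection to a 30% pre-horizon
censoring fraction, and the 5-year horizon applied.

Not emulated: probe-level artifacts, batch effects, platform-specific gene
panels beyond the network node pools, HPV genotypes, copy-number segments,
and non-proportional hazards. Passing tests therefore demonstrate that the
pipeline recovers planted truth under its own model assumptions — not that
the assumptions hold for any particular real dataset.

## Simulation sizes used by the test suite

Property tests run at sizes chosen for a single CPU: 100 replicates for the
pipeline-recovery and consensus-hub properties (EPC at R = 500 in the
latter; the closed-form EPC checks use the full R = 5000), 2000 replicates
for log-rank type-I calibration, 500 Cox null fits at n = 120, and 1000
replicates of the IHC operating-point coverage check (whose population
coverage, 95.6–97.8%, is also verified exactly from the binomial pmf).

## Known limitations

- The Welch test substitutes for variance-moderated tests; at very small
  group sizes its calls are noisier than moderated ones.
- The binary-test AUC CI (Hanley–McNeil) is asymptotic and can touch the
  [0,1] boundary at extreme accuracies.
- The bootstrap AUC comparison assumes approximate normality of the AUC
  difference; at very low event counts the permutation/bootstrap machinery
  degrades gracefully (failed resamples are dropped) but the p-values
  coarsen.
- The Cox sampling variance at realistic cohort sizes bounds how tightly a
  planted hazard ratio can be recovered: with ~850 events and a balanced
  binary marker, sd(β̂) ≈ 0.07, so point estimates within ±10% of HR = 2
  occur in ~85% of replicates, not more — a property of the design, not the
  estimator (which is unbiased and calibrated in the null tests).
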