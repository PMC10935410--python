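# Methods

## Measurement model and scale

All analyses operate on median fluorescence ratios (MFR).  MFR is a ratio to
a fluorescence-minus-one control, so MFR = 1 means "no signal" and values are
≥ 1 by construction; readers enforce the floor strictly.  The analyses use
raw MFR, not a log transform, because the fold-change and correlation
definitions are stated on the raw scale; a `log_transform` switch exists on
the correlation stage for sensitivity analysis (see *Known limitations*).

Fold change per analyte is `log2(mean MFR responders / mean MFR
non-responders)` with arithmetic means of raw MFR.  A geometric-mean variant
is available but off by default.  Fold change is exactly antisymmetric under
group relabeling and invariant under rescaling all MFR by a positive
constant.

## Tests and significance classes

* Baseline group comparisons use a two-sided unpaired t-test.  Welch
  (unequal variances) is the default because nothing in the design guarantees
  equal group variances; a pooled-variance option is config-gated.
* Pre/post comparisons use a two-sided paired t-test on post − baseline
  differences over subjects with both timepoints; incomplete subjects are
  excluded with a logged count.
* Zero-variance strata never abort a panel sweep: equal means give t = 0,
  p = 1 by convention; unequal means with zero variance give a flagged
  degenerate result with the p → 0 limit and a warning.
* No multiple-comparison adjustment is applied anywhere by default; the
  Benjamini–Hochberg step-up is available as an opt-in flag on enrichment
  output.

Correlation between two analytes is the ordinary-least-squares (simple
linear regression) fit summarized as R².  The two-sided p uses the exact
algebraic equivalence with the Pearson test: `t = r·sqrt((n−2)/(1−r²))`,
df = n − 2.  The signed r is kept internally for diagnostics even though
grids report R².  Classes follow the grid-legend convention — `strong`:
p < 0.01; `moderate`: 0.01 ≤ p ≤ 0.05; `ns`: p > 0.05; `self` on the
diagonal.  The p = 0.01 boundary falls in `moderate` because the strong
threshold is a strict inequality; counting at the 0.05 level is inclusive
(p ≤ 0.05) and at the 0.01 level strict (p < 0.01), consistent with the
classes.  Constant analytes yield undefined r, are flagged with a warning,
and are classed `ns` rather than aborting the grid.

Anchor profiles (defaults: GSK3β, PDEB4, NLRP3) restrict **both** timepoints
to the paired-subject subset, so a before/after change in significant-pair
counts reflects a change in correlation, not a change of sample.

## Network stage

* **Mapping.**  The shipped mapping collapses the 28 analytes to 23 unique
  network genes: the three GSK3 forms merge to GSK3B, the two FYN forms to
  FYN, and PDE4B and XBP1 are flagged out of the network gene set.  The
  default symbol convention follows the study's network figure verbatim
  (NFKB1 for the p65 subunit, NOS1 for iNOS, PRKCA for PKA C-α); an
  "hgnc" alternative ships with the conventional assignments (RELA, NOS2,
  PRKACA).  Symbol normalization is mechanical (uppercase, Greek
  transliteration, whitespace/hyphen stripping); no alias-database
  resolution is attempted, so inputs must use consistent symbols.
* **Induction.**  The induced network is the seed set plus every host-graph
  node lying on *any* shortest path between a seed pair; all tied geodesics
  are retained, both for determinism and because connector multiplicity is
  informative.  Seeds absent from the host graph are dropped with a warning
  (never fatal); unreachable seed pairs are skipped with a logged count.
  Induction is idempotent on its own output.
* **Propagation.**  Random walk with restart, `s ← α·e + (1−α)·W·s`, W the
  column-normalized adjacency (symmetric normalization `D^-1/2 A D^-1/2`
  available by config), e uniform over the seeds (one multi-seed walk; a
  per-seed union is not implemented because the multi-seed fixed point is the
  standard propagation operator and is what the module rule consumes).
  α defaults to 0.15, standard propagation practice and stable on small
  graphs; α is exposed in the config.  Convergence: L1 residual < 1e−10 or
  10,000 iterations, both reported in the result.  Columns of degree-0 nodes
  return their mass to the restart distribution so scores always sum to 1.
* **Module.**  Top-k scores (ties broken lexicographically by symbol), then
  the largest connected component in the host graph, preferring more seeds
  then the lexicographically smallest node set on ties.  k defaults to
  2×|seeds| and is clamped to the graph size with a warning.  This is one
  concrete instantiation of "highly connected module"; k is a config key.
* **Annotation.**  Measured nodes carry the fold change of their source
  analytes; collapse groups take the arithmetic mean of their analytes'
  fold changes.  Unmeasured connector nodes carry an explicit null, never 0,
  since FC = 0 is a meaningful value (equal group means); GraphML output
  omits the attribute for null and readers restore `None`.
* **Pathway subnetworks.**  A pathway's subnetwork keeps the pathway genes
  present in the induced network plus the network's connectors lying on
  shortest paths (within the network) between retained pathway genes,
  with annotations preserved.  An empty intersection is a warning, not an
  error.

## Enrichment

Upper-tail hypergeometric only: `p = P(X ≥ k)`, X ~ Hypergeometric(N, K, n),
computed via the log-gamma based survival function, exact against
enumeration to 1e−12 on small universes.  The default universe is the
intersection of host-graph nodes with the union of all gene-set members:
genes the analysis could never have selected are not counted.  Graph-only
and explicit-list universes are config options, and enrichment can target
the full induced network instead of the module.  Rows are sorted by
ascending p then pathway name, so output is invariant to input order.
Combined/adjusted ranking scores of enrichment web services are deliberately
not reimplemented.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
the instrument: no optics, compensation, gating or clinical covariates.

Signal model per (subject, cell type, analyte), on the log scale:

    z = μ_eff + L_group · f_subject · w_analyte + ε,     MFR = 1 + exp(z)

* `f_subject ~ N(0,1)` is one latent factor per subject, shared across cell
  types; `w_analyte` are cell-type-specific weights.  This single shared
  factor is the simplest mechanism producing dense within-group correlation
  blocks with cell-type-specific patterns.
* Weights are drawn with magnitude uniform in [0.5, 1] and random sign
  ("unit-scale" weights).  Normalizing the whole weight vector to unit L2
  norm would shrink each analyte's factor signal to ~1/√28 and make the
  design's correlation structure undetectable at n = 9–12; the unit-scale
  choice keeps every analyte's share of the factor comparable while leaving
  pairwise correlation strength varied.
* `μ_eff = μ_analyte + offset_group − σ_z²/2` is variance-calibrated so that
  `E[MFR − 1] = exp(μ_analyte + offset_group)` whatever the loadings.  The
  non-responder elevation `baseline_mean_offset_nonresp` therefore controls
  the fold-change sign pattern independently of the correlation knobs.
* Treatment adds post records for the first `n_post_*` subjects of each
  group: responders shift by `treatment_shift_resp` (+0.5 by default, levels
  rise) with the factor loading multiplied by `post_decorrelation_resp`
  (correlations weaken); non-responders shift by `treatment_shift_nonresp`
  (−0.5, levels fall) with loading unchanged.
* The `1 + exp(·)` transform enforces the MFR = 1 floor without clipping,
  preserving continuity for correlation analysis.

Defaults reproduce the design scale: 12 responders / 11 non-responders at
baseline, 28 analytes, two cell types, 9 paired responders and 4 paired
non-responders.  Factor loadings default to 1.0 (responders) versus 0.3
(non-responders) — responders more correlated — with `noise_sd = 0.4`.  The
noise level is calibrated so the baseline anchor profile yields roughly half
of its 27 possible significant correlations at n = 9 (median 12/27 across
seeds), the density the analysis is designed around, rather than a saturated
or empty grid.  `baseline_mean_offset_nonresp = 0.5` (log-e units) makes the
large majority of fold changes negative at the design sample sizes.
Absolute analyte means `μ_analyte ~ N(1.0, 0.4)` are free parameters, not
calibrated to any instrument.

The interactome generator uses preferential attachment (heavy-tailed degree
like real protein-interaction networks, connected by construction) with
required gene symbols assigned to random nodes.  The gene-set generator
draws uniform node samples with sizes in `[size_min, size_max]` and plants
one pathway sharing exactly `planted_overlap` genes (default 12) with the
designated seed module; the planted set is kept at the minimum configured
size so the forced overlap stays the dominant fraction of its membership and
the set is recoverable by enrichment against a module of ~2×|seeds| nodes.

All randomness flows from one integer seed through a fixed `SeedSequence`
split (means, weights, factors, baseline noise, post noise), so identical
configs give byte-identical tables; the pipeline derives its three
sub-seeds as seed, seed+1, seed+2.

What passing tests on these cohorts show — and do not show: they validate
the pipeline's statistical machinery and its qualitative contracts
(differential correlation, post-treatment decorrelation, fold-change sign
pattern, planted-pathway recovery) under a known generating process.  They
do not certify behavior on real flow-cytometry data, whose marginals,
missingness and batch structure the generator does not model.

## Pipeline conventions

* Exactly one input mode per run: real files or synthetic configs; a seed is
  mandatory in synthetic mode.
* Post-treatment correlation is computed only for groups configured for it
  (default: responders).  Groups with fewer than 3 paired subjects are
  refused with the refusal recorded in the manifest — with the default 4
  paired non-responders, their post-treatment correlations are skipped by
  configuration and the paired count is logged, mirroring the design's
  limitation.
* Every run, success or failure, writes `manifest.json` with the config
  snapshot, per-stage counts and all warnings (dropped seeds, skipped
  strata, degenerate tests), so the manifest alone reconstructs the
  summary-level results.
* Tabular outputs are written with a fixed float format and fixed orderings;
  identical config + seed gives byte-identical TSVs.

## Numerical choices

* |r| within machine epsilon of 1 reports p = 0 (below any representable
  threshold).
* Hypergeometric p is clipped to (0, 1] after the stable sf evaluation.
* RWR tolerance 1e−10 (L1), max 10,000 iterations; α = 1 short-circuits to
  the restart distribution after one iteration.
* Module and enrichment tie-breaks are lexicographic, making every output
  deterministic.

## Test-suite problem sizes

The suite verifies the oracles at sizes chosen for exhaustiveness and speed:
hypergeometric enumeration over all universes N ≤ 10; RWR against direct
linear solves on 100 random graphs of ≤ 50 nodes at α ∈ {0.1, 0.5, 0.9};
induction against full geodesic enumeration on 200 random graphs of ≤ 15
nodes; cohort-pattern properties over 100 generator seeds at the design
scale; enrichment null calibration over 1,000 replicate modules.

## Known limitations

* The analytic t-based correlation p assumes the regression model's
  normality.  Raw MFR is skewed (the generator's marginals are
  softplus-lognormal), and at n = 9–12 the analytic p can differ from an
  exact permutation null by more than Monte-Carlo error — a property of the
  scale, not of the implementation (the same gap, order 1/n, exists for
  exactly normal data between the conditional permutation null and the
  unconditional t null).  The `log_transform` switch reduces but does not
  remove the skew; for small-n confirmatory work a permutation test is the
  safer instrument.
* Gene-symbol handling is purely mechanical; no alias resolution means two
  files using different symbols for one gene yield two nodes.
* The module rule (top-k + largest component) is one reasonable reading of
  "highly connected module"; alternatives (e.g. conductance-based cuts) are
  out of scope.
* Enrichment p-values depend on the interactome and gene-set snapshots
  supplied; they are not comparable across database versions.
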