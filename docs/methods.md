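# Methods

This note documents the statistical machinery in `stabnet`, the
assumptions behind it, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
edge cases.

## 1. The estimand: a stability-graded structural network

The object produced by `run_pipeline` is not a single graph estimate but
a *stability selection* over graphs: B bootstrap replicates of the data
are each pushed through the identical preparation-plus-PC chain, and a
pair of variables enters the final network only if it is adjacent in at
least a threshold fraction of the replicate CPDAGs (default 0.5 — a
majority decision). Retained links are graded by their frequency:

| adjacency frequency | grade |
|---|---|
| < threshold | excluded |
| threshold … 0.80 | low |
| 0.81 … 0.97 | moderate |
| > 0.97 | high |

The upper boundary of the "low" band is taken as 80% inclusive / 81%
exclusive; published descriptions of this banding disagree between "50–80"
and "51–80" at the lower boundary, and the threshold-inclusive reading
(a link in exactly half the models is retained) is used here.

Orientation is a second, separate pass over the same replicates: the
fraction of replicates in which a→b appears *directed* is the
orientation frequency, and a direction at or above the same threshold on
a retained pair is reported as a causal link. Because the two
frequencies are counted from the same CPDAGs,
`orientation_freq(a→b) + orientation_freq(b→a) ≤ adjacency_freq(a,b)`
always holds. On equivalence classes with no orientable edges (e.g. a
chain) orientation mass splits between the two directions and no causal
link is expected — reporting zero causal links is a legitimate outcome,
not a failure mode.

## 2. Per-replicate preparation

**Bootstrap.** n rows drawn with replacement; imputation runs *inside*
the loop so that imputation uncertainty is propagated by the resampling
itself. One completed dataset per replicate (m = 1); classical
multiple-imputation pooling (Rubin's rules) is deliberately absent —
the B replicates play that role.

**Chained-equation imputation.** Incomplete variables are visited in
ascending-missingness order; each is regressed (OLS, intercept) on all
other columns of the current completed matrix; `iterations` (default 10)
full sweeps. Predictive mean matching (default) imputes by copying the
value of one of the `donors` = 5 observed rows whose predictions are
nearest, so bounded and integer-coded variables never receive
out-of-range values. The initial fill is a seeded draw from each
variable's observed values. A `normal` method (linear predictor plus
Gaussian residual noise, clipped into roster bounds) is provided for
continuous-only tables. Parameter uncertainty is not redrawn per
imputation (type-1 PMM); at m = 1 inside a bootstrap this is
inconsequential. Observed cells are never altered — this is asserted
bitwise in the tests.

**Factor combination.** Each subscale family declared in the roster
(default: the five coping subscales, group `CERQ`) is collapsed to one
variable. A 1-factor maximum-likelihood model is fitted on the
standardized members (scikit-learn's `FactorAnalysis`, EM), requiring at
least three members for identifiability. Loadings are sign-normalized so
their sum is non-negative; a uniqueness collapsing to zero (Heywood
case) is logged and clamped at 1e-6. Scores use the regression
(Thomson) method, `f = Λᵀ(ΛΛᵀ+Ψ)⁻¹ z`; they have mean zero and variance
at most one by construction (shrinkage), and are deliberately *not*
rescaled. Caveat established while testing: on members with no common
variance the 1-factor ML problem is weakly identified and both this
implementation and R's `factanal` may park a large loading on a single
variable; the identifiable quantity is the loading *product* (implied
member correlation), which stays near zero.

**Covariate adjustment.** Every outcome/putative column is replaced by
its least-squares residual on an intercept plus the baseline covariates;
categorical covariates expand to indicator contrasts with the first
level as reference; residuals are standardized to unit variance
(Fisher-z inference is scale-invariant; standardization stabilizes the
numerics). Covariate columns are dropped from the output and roster
bounds are cleared. A rank-deficient design raises an error naming the
dependent columns.

## 3. Constraint-based discovery

The conditional-independence test is the Fisher-z test of a vanishing
partial correlation — exact for multivariate Gaussian data, and applied
to *all* variables, including binary and ordinal ones, as plain numeric
columns (one test family, mirroring the common `gaussCItest` practice).
Partial correlations come from precision-matrix inversion on the
submatrix over {x, y} ∪ S, with closed forms for |S| ≤ 1.

The skeleton phase is PC-stable: adjacency sets are frozen at the start
of each depth, so the result cannot depend on the order edges are
visited. Conditioning subsets are enumerated in lexicographic order of
node *name*, which makes the recorded separating sets — and therefore
the orientations — invariant under column permutations of the input.
The conditioning depth is capped at n − 4 so the test's degrees of
freedom stay positive (logged when the cap binds). α defaults to 0.05
and is a required, logged configuration value: the level used in the
published analysis this pipeline emulates is unreported, and the network
one obtains depends on it.

Orientation: unshielded triples x–z–y with z outside the recorded
separating set become v-structures; Meek rules R1–R4 run to a fixed
point. Two conflict policies keep the output a valid CPDAG on
finite-sample input: (i) an edge demanded in both directions stays
undirected (bidirected edges are not representable); (ii) a demanded
arrow that would close a directed *cycle* — which on real bootstrap
replicates happens regularly across three or more edges — is likewise
refused, in deterministic name order, and the edge stays undirected.
Both events are logged. R4 cannot fire without background knowledge and
is included for completeness.

Exact graph oracles back the implementation: `d_separated` (reachability
on the moralized ancestral subgraph) and `cpdag_of` (skeleton +
v-structures + Meek closure of a known DAG). PC driven by the
d-separation oracle reproduces `cpdag_of` exactly on all 543 labeled
4-node DAGs, with `cpdag_of` itself validated against brute-force
enumeration of each Markov-equivalence class, and `d_separated`
cross-checked against networkx's independent implementation.

## 4. The synthetic cohort generator

The generator exists because the motivating cohort's participant-level
records are available only on request; it emulates the *statistical
shape* of such data, not any published numbers beyond the cohort
accounting (303 enrolled, 235 with complete outcomes).

A cohort is a linear-Gaussian SEM sampled ancestrally on a latent
standardized scale (noise variances chosen so each latent has unit
variance, floored at 0.1 when a node's parents already explain more than
90%), followed by per-node observation mapping:

* **skewed markers** — `exp` of the latent (log-normal), matching
  cytokine panels summarized by median (IQR); dependence is defined on
  the latent scale;
* **questionnaire totals** — affine map of the latent onto the
  instrument's published range (±3 sd spans the range), rounded and
  clamped (e.g. fatigue 8–56, loneliness 0–6);
* **binary/categorical** — latent cut at Gaussian quantiles
  (equiprobable by default; severity, smoking, education, migration and
  comorbidity use mildly skewed cutpoints typical of community cohorts).

The fixed-topology study-like SEM (`paper_like_sem`) encodes the
qualitative structure such analyses report: the four outcomes cluster
around fatigue; marker paths CRP→sCD14 and IL-1β→IL-6→TNF-α inside an
interconnected marker cluster; loneliness→depressive symptoms; illness
perceptions→concentration; fear avoidance→physical functioning;
resilience→loneliness; the five coping subscales share the resilience
signal (so the combined factor links to resilience); covariates feed
several network variables; sex and initial severity are present but
isolated. Topology never varies with the seed; edge-weight magnitudes
are drawn uniformly from |w| ∈ [0.3, 0.6] — a simulation choice, not an
estimate, since no effect sizes are reported for these data. Default
n = 235. Attrition is missing-at-random at 5% driven by the
depressive-symptoms latent through a logistic link (slope 1), a
plausible follow-up-attrition mechanism that exercises the imputation
stage nontrivially; covariates and the driver stay complete, keeping the
mechanism MAR given observed data.

What a green test on this generator establishes: the pipeline recovers
linear-Gaussian dependence structure under bounded discretization, skew
and MAR missingness at realistic cohort size. What it does not
establish: behavior under non-linear effects, informative (MNAR)
attrition, measurement error correlated across instruments, or assay
floor/ceiling truncation — none of which are modelled.

## 5. Known limitations established by measurement

Two properties of the stated validation world were measured carefully
and are documented rather than hidden (details and numbers in the
project's decision ledger, outside the package):

* **Bootstrap duplicates inflate the CI test.** The Fisher-z test sees
  n rows but a bootstrap replicate contains only ≈ 63% distinct rows, so
  within-replicate tests are anti-conservative. A pair that is truly
  independent but has an ordinary ~2σ correlation in the *original*
  sample (|r| ≈ 0.13 at n = 235) becomes "dependent" in roughly half of
  the replicates. At n = 235 the retained network therefore contains a
  tail of low-stability spurious links; this is intrinsic to bootstrap
  stability selection at this sample size, and the published analyses
  this mirrors acknowledge the same small-sample caution.
* **Dense graphs with strong same-sign weights are partially
  unidentifiable for PC.** Conditioning on common children induces
  negative dependence that can almost exactly cancel a direct effect:
  on random 10-node DAGs (edge probability 0.3, |w| ∈ [0.4, 0.8]) the
  population partial correlation of a true edge at some PC-visited
  conditioning set is frequently ≈ 0.02, below any test's power at
  n = 2000. Exact skeleton recovery on such graphs plateaus well below
  100% for reasons independent of the test implementation.

Other deliberate scope limits: no FCI/latent-confounder machinery, no
score-based search, no conservative/majority-rule PC beyond the conflict
policy above; no long-format longitudinal tables (each analysis variable
is one column; measurement month is metadata); no graphical layout of
the network beyond GraphML/TSV export.

## 6. Determinism and provenance

Every stochastic step is seeded: replicate b derives independent
resample and imputation seeds from `SeedSequence([master_seed, b])`, and
the sign matrix uses the master seed directly on the full table. Two
runs with the same inputs and master seed produce byte-identical
`network_edges.tsv`. Run directories contain `summary.json`,
`provenance.json` (full config echo, versions, per-replicate edge
counts), `replicates.log`, `network.graphml` and `manifest.json`
(written even on failure). Replicates that fail (e.g. an unimputable
column after resampling) are logged and excluded from numerator and
denominator; the run aborts if more than 5% of B fail.
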