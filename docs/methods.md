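# Methods

## Model

A biomolecular system at steady state is modelled as a structural causal
model over an acyclic graph: each variable (transcript, protein or
metabolite abundance) is a function of its direct causes plus independent
noise. Unmeasured common causes are represented either explicitly, as
latent-marked nodes in a DAG, or implicitly, as bidirected edges in an
acyclic directed mixed graph (ADMG). The two representations are exchanged
by **latent projection**: a directed edge `u → v` survives projection when
a directed path from `u` to `v` runs entirely through latent intermediates,
and a bidirected edge `u ↔ v` appears when a latent source reaches both
ends through latent non-colliders. The projection is exact for the
independence structure: every m-separation among observables is preserved
(this is verified exhaustively in the test suite on graphs up to 7 nodes).

Working on the ADMG rather than an explicit latent DAG means the number and
wiring of latent variables need not be known — only the confounding pattern
among observables matters.

`exogenize_latents` normalises an explicit latent DAG before projection:
childless latents are dropped, single-child latents are contracted into the
child, and latents with parents have those parents rerouted directly to
their children. At the fixpoint every latent is exogenous with at least two
children — the canonical form in which each latent is exactly one source of
confounding. Each rewrite preserves the observable margin, and equality of
all observable m-separations with direct projection is tested.

## Separation and implied independencies

m-separation is decided by reduction to d-separation: each bidirected edge
is replaced by a synthetic hidden common cause, and d-separation is
evaluated on the augmented DAG (networkx). An independent oracle used
only in tests enumerates every simple path and applies the blocking rule
literally; the two agree on a census of >10⁴ queries.

The consistency step enumerates, for every non-adjacent pair of observable
nodes, all separating sets up to `max_cond` variables. Candidate
conditioning sets are drawn from the pair's observable ancestors by default
— sufficient for minimal separators and tractable on networks of realistic
size (tens of nodes); a policy switch widens the pool to all observables.
Output order is deterministic (lexicographic by pair, then by set size and
contents) so reports are reproducible.

## Consistency testing and repair

Continuous data use the Fisher-z test: the partial correlation `r` of the
pair given the conditioning set (computed from regression residuals) is
mapped to `z = atanh(r)·√(n − |Z| − 3)`, standard normal under the null.
Discrete data use a stratified Pearson χ²: per-stratum statistics and
degrees of freedom are summed across configurations of the conditioning
variables; degenerate strata are skipped and counted. Defaults are
α = 0.01 and `max_cond = 3`, values suited to transcriptomic panels with a
few dozen genes and a few hundred replicates; both are configurable.

No multiplicity correction is applied by default — the raw failure
percentage is itself the diagnostic of graph–data mismatch — but a
Benjamini–Hochberg switch is available. Repair adds one bidirected edge per
failed pair (multiple failures of the same pair under different
conditioning sets collapse to one edge), the graphical signature of an
unmeasured common cause. Repair can destroy identifiability, so the
workflow re-checks the query on both the original and repaired graphs and
reports both.

## Identification

The recursive ID procedure decides whether `P[Y|do(X)]` is a functional of
the observational joint. The recursion marginalises non-ancestors, extends
the intervention with variables that cannot transmit effect, factorises
over districts (bidirected-connected components), and either reaches a
chain-rule factorisation or exhibits a hedge (the witness reported on
failure). Conditionals created inside the recursion are taken with respect
to a fixed topological order of the projected graph restricted to the
current scope. When the recursion leaves auxiliary intervened variables
free in the output, they are averaged against their observational marginal
— value-preserving for every distribution consistent with the graph, and
well-defined on empirical joints.

Correctness is defined by evaluation, not by symbolic form: an estimand is
correct when its value on any positive observational joint consistent with
the graph equals the true interventional distribution. The test suite
checks this to 1e-9 against exact truncated-factorisation enumeration on
hundreds of random discrete models with hidden confounders; simplification
of the printed expression is best-effort (marginals of joint terms are
collapsed so that standard adjustment and front-door formulas print in
their familiar form).

## Nuisance variables and simplification

For a query (X, Y), the nuisance variables are the observable descendants
of the causal pathway (nodes on proper directed X→Y paths) that are not
ancestors of Y. Conditioning on them cannot help — they carry no
information about the effect beyond what the pathway provides — and can
hurt, through collider bias and added variance. They are marked latent and
projected out. Retained latents with a single observable child vanish
silently, as they constrain nothing on the margin. The simplification is
validated two ways: retained-variable m-separations are unchanged, and the
downstream ATE estimate moves by less than two Monte-Carlo standard errors
on simulated linear systems.

## Estimation

**Adjustment sets.** The default is the efficiency-oriented set
O = pa(causal-pathway nodes) ∖ (pathway ∪ {X}), which minimises asymptotic
variance among valid adjustment sets in linear systems. Validity is checked
graphically: O must avoid the forbidden set (descendants of the pathway)
and m-separate X from Y in the proper back-door graph (the graph with the
first edge of every proper causal path removed). If O fails — possible in
ADMGs when confounding arcs touch the pathway's parents — the canonical
ancestral set An(X,Y) ∖ forbidden is tried, since it is valid whenever any
valid set exists; only then is "no adjustment set" declared. A brute-force
subset search in the tests confirms both directions on small graphs.

**Linear estimator.** OLS of Y on (X, O). The X coefficient is the total
effect per unit of X, so `ATE = β_X (x1 − x0)` and
`E[Y|do(x)] = β_0 + β_X x + Σ β_O mean(O)` (the g-formula under
linearity, evaluated at covariate means). The distribution form reports
the implied Gaussian with the residual standard deviation.

**Nonparametric ATE (binary X).** Outcome regression fits per-arm linear
models and standardises over the covariate distribution; IPW uses
Hájek-normalised inverse propensity weights from a logistic model on the
adjustment set, truncated to [ε, 1−ε] with ε = 0.01 (truncation counts are
reported); AIPW combines both and is consistent when either model is
correct. The double-robustness property is exercised in the tests with a
deliberately misspecified outcome model.

**Discrete plug-in.** When no adjustment set exists but the query is
identifiable (front-door-like structures), the identified estimand is
evaluated on the empirical joint of the discrete data. Zero cells hit by a
denominator raise an error naming the offending term.

**Intervals.** Percentile bootstrap over replicate resampling: default
1000 resamples at level 95%, seeded and bit-for-bit reproducible. The
interval is widened to include the point estimate in the rare resampling
configurations where the percentiles exclude it.

**Selection policy.** Estimator choice is a deterministic table:
continuous outcome with a valid adjustment set → linear (AIPW instead when
X is binary and the linearity assumption is released); identifiable but
adjustment-free queries → plug-in, requiring discrete data; anything else
is an explicit unsupported-case error. "Most efficient" is operationalised
by this table, not by a formal efficiency bound.

## Synthetic generators

`random_scm` emulates the target data regime: steady-state replicates from
linear-Gaussian mechanisms. Edge weights are uniform on ±[0.3, 1.0] — the
magnitude floor keeps generators away from near-unfaithful cancellations
that would make CI-calibration studies meaningless — noise variances on
[0.5, 1.5], intercepts zero, and each latent confounder is an exogenous
hidden parent of exactly two observables (the canonical confounding form;
richer latent structure projects onto it). Sampling is ancestral, and
`do` severs incoming edges before fixing values. `true_effect` computes
ground truth by path tracing (dynamic programming over the sum of
path-weight products), checked in tests against explicit path enumeration
and against interventional finite differences.

`random_discrete_scm` produces strictly positive Dirichlet CPTs (floored
at 0.02) so that every conditional needed by an estimand exists; exact
observational and interventional laws are computed by enumeration for
state spaces up to 10⁶.

What the generators do *not* emulate: nonlinear regulation, feedback,
measurement error with structure, batch effects, and the condition
heterogeneity of real compendia. Passing tests therefore certify the
inferential machinery under its stated assumptions, not robustness to
their violation — on real data the consistency step is exactly the tool
that flags such mismatch.

## Numerical choices and problem sizes

- Fisher-z caps |r| at 1 − 1e-15 and the z statistic at 38 (the normal
  tail underflows beyond that); perfect dependence reports p = 0.
- Estimand evaluation tolerates 1e-6 deviation of total mass from one
  before normalising (exact joints hit machine precision; empirical joints
  can drift slightly).
- Districts, node pools and conditioning sets are sorted everywhere a tie
  could occur, so all outputs are deterministic under a fixed seed.
- Test-suite and acceptance problem sizes (censuses of 10⁴ separation
  queries, 200 discrete models, 500 calibration replicates at n = 2000,
  50–100 linear SCMs at n = 5000 with a few hundred bootstrap resamples)
  were chosen to make binomial and Monte-Carlo error bars decisively
  smaller than the tolerances being checked while keeping the whole suite
  in the tens of seconds on one CPU.

## Known limitations

- Acyclic, steady-state models only; no feedback or time resolution.
- Single exposure, single outcome; no conditional or counterfactual
  queries.
- Mixed continuous/discrete statements are skipped in consistency testing
  rather than tested with a hybrid statistic.
- Repair is additive only (bidirected edges); it never deletes or
  reorients directed edges, and false-positive CI failures can make an
  identifiable query unidentifiable — the report surfaces both analyses so
  this is visible.
- The plug-in estimator requires every estimand cell to be observed;
  high-cardinality discrete data at small n will fail with a named cell
  rather than silently extrapolate.
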