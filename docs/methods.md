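# Methods

This note documents the model assumptions, algorithmic choices, defaults and
known limitations of `copulacd`.

## Model and assumptions

The data are n subjects by d variables, each variable flagged discrete or
continuous, with an explicit missingness mask. Two assumptions carry the
whole pipeline:

1. **Nonparanormal observations.** There exist strictly monotone functions
   f_1, …, f_d and a positive-definite correlation matrix Σ⁰ such that
   (f_1(X_1), …, f_d(X_d)) is multivariate Gaussian. Discrete variables are
   deliberately pushed through the same copula: their category codes are
   rank-transformed exactly like continuous values. This is an approximation
   (it slightly underestimates some correlations, since a discrete variable's
   ties compress its rank distribution) adopted because modelling discrete
   variables exactly buys little accuracy at a large cost in machinery. The
   inferred graph is therefore a statement about the latent surrogate
   variables; conditional independencies involving discrete variables are
   read through their surrogates.

2. **Missing at random (MAR).** Missingness may depend on observed values
   but not on the missing ones. EM needs only MAR; the deletion and
   imputation comparators implicitly need the stronger MCAR.

## Step 1 — normal scores

Each column's rescaled empirical CDF uses **mid-ranks over (n + 1)**:
`F̂(x) = midrank(x) / (n + 1)` with n the column's non-missing count. A
strict-inequality variant of the empirical CDF (counting only x_j < x) would
assign the column minimum probability 0 and an infinite normal score; the
mid-rank form keeps all scores finite, is symmetric under negation, and
coincides with the strict form up to a half-step shift for distinct values.
The strict variant remains available (`method="strict"`), clamped to
[1/(n+1), n/(n+1)]. Ties — inevitable for discrete variables — share their
average rank and map to equal scores. Constant columns are an error naming
the offending variables, since their normal scores are undefined.

Because ranks are invariant under strictly increasing maps, the transform of
g(X) equals the transform of X **exactly** for any strictly monotone g. The
test suite asserts bitwise equality of the transform with and without the
benchmark's cube distortion.

## Step 2 — correlation under missing data

`em_correlation` computes the Gaussian MLE of (μ, Σ) under MAR by EM,
grouping rows by missing pattern. Defaults: initialisation from the
mean-imputed covariance (always well defined), convergence when the relative
observed-data log-likelihood change falls below **1e-6**, at most **500**
iterations (non-convergence is flagged on the result, not raised). The mean
is estimated jointly and discarded; only the unit-diagonal normalisation of
Σ feeds Step 3. The observed-data log-likelihood is recorded per iteration
and checked to be non-decreasing on every run — a violation raises, because
it can only be a bug. Rows with every cell missing are dropped (logged).

Comparison estimators: pairwise-complete Spearman (entries with fewer than 3
joint observations are zeroed with a warning), the adjusted variant
S = 2 sin(π ρ / 6) that makes Spearman consistent for the Pearson correlation
under Gaussianity, listwise-deletion Spearman (error below 3 complete rows)
and mean-imputation Spearman. None of these guarantees positive
definiteness; matrices with minimum eigenvalue below **δ = 1e-8** are
projected to the nearest correlation matrix (Higham-style alternating
projections via statsmodels' `corr_nearest`, followed by an explicit
eigenvalue floor at δ and re-normalisation). The same floor is a numerical
safety net on EM output.

**Effective sample size.** The BIC needs a sample size M. Pairwise deletion
gives every entry its own n; to keep scores comparable across estimators, M
is always the number of rows that are not entirely missing, recorded on the
`CorrelationMatrix`.

## Step 3 — Bayesian scoring and search

All DAGs on each window of at most five variables are enumerated once per
process (1, 3, 25, 543, 29,281 DAGs for one to five variables) and cached as
parent bitmasks together with per-DAG d-separation and ancestor indicators,
so scoring a window is a handful of vectorised operations. Mutual
information comes from log-determinants of correlation submatrices; the BIC
penalty counts **edges only** as Dim[𝒢]: Gaussian-DAG parameter counts also
include node variances, but those are identical for every DAG on a fixed
node set and cancel when posteriors are normalised. Posterior weights use a
uniform prior and log-sum-exp.

*Adjacency search*: starting from the complete graph, each still-adjacent
pair (X, Y) is tested against conditioning sets Z of increasing size
0–3 drawn from the variables currently adjacent to X or Y (stable within a
level); the window {X, Y} ∪ Z is scored and the edge deleted as soon as the
reliability of X ⫫ Y | Z exceeds the **deletion threshold, default 0.6**
(any value in (0.5, 1] is sensible; 0.5 would delete on even odds).

*Orientation*: for every remaining edge, ancestral statements ("X causes Y",
meaning a directed path exists) are scored in every window recorded during
the search that contains the pair, plus one canonical window per edge (the
pair with up to three lexicographically first skeleton neighbours); a
statement's reliability is the **maximum over windows** (each window is a
different marginal model; the most informative one is used). Statements are
ranked by decreasing reliability, ties broken lexicographically for
determinism. An accepted "X causes Y" orients the full edge X → Y — tail at
X *and* arrowhead at Y, since an ancestor cannot itself be caused by its
descendant — while the complement only fixes the arrowhead at X. Statements
at or below the **orientation threshold 0.5** are ignored (an edge reported
at 50%+ matches the usual convention for displaying such graphs); endpoints
never touched stay circles, and statements conflicting with already-fixed
marks are skipped, which implements "on conflict, keep the more reliable
relation".

*Background knowledge* (`forbid X -> Y`, `forbid * -> Y`) acts twice: the
forbidden "cause" statements are vetoed before ranking, and every DAG in
which a forbidden ancestral relation holds is removed from the hypothesis
space before normalisation. The second part matters: with only a veto, a
two-variable window gives both directions reliability ~0.5 and prior
knowledge could never orient anything; restricting the model space instead
turns "nothing causes G" into posterior support for G → X on G's edges.

*Edge reliabilities* reported on the output PAG are 1 minus the best
independence reliability seen for the pair — the posterior confidence that
the dependence is real.

Note on semantics: the hypothesis space within a window is the set of DAGs
on that window, and "cause" means ancestor within the window. The full
logical calculus that propagates ancestral statements across windows and
expresses latent confounders is out of scope; consequently bi-directed
edges cannot arise from the data path (the edge grammar still supports
them), and orientations claim more than the FCI-style ground-truth PAG marks
do (a v-structure is reported with tails at the parents, where the
ground-truth PAG keeps circles to allow latent-confounder members of the
equivalence class). This costs endpoint accuracy by construction and is the
main reason PC scores higher on mark-level accuracy in the benchmark — PC's
assumptions (no latents) happen to be true there.

## PC comparison

PC runs from the same correlation matrices: partial correlations by
precision-submatrix inversion, Fisher-z two-sided tests with √(n − |Z| − 3)
scaling, stable (order-independent) skeleton phase testing subsets of both
endpoints' neighbourhoods, collider orientation from separating sets, Meek
rules 1–4. Default **α = 0.05**. The CPDAG is embedded into PAG marks
(compelled edges tail/arrowhead, reversible edges circle/circle) so one
metric serves both algorithms.

## Ground-truth PAGs and metrics

Ground truth is computed by oracle FCI: skeleton via exhaustive d-separation
queries, unshielded-collider orientation, then Zhang's rules R1–R4 and
R8–R10. R5–R7 concern selection bias, which the simulator never generates,
so they are omitted. The implementation is validated against an independent
oracle that enumerates every maximal ancestral graph on ≤4 nodes, matches
m-separation fingerprints and extracts invariant marks.

**PAG accuracy** is defined at endpoint-mark granularity: the fraction of
correctly reproduced marks over both endpoints of the union of the two edge
sets, an edge present in only one graph contributing two incorrect
endpoints. This rewards partially correct orientation; it is symmetric and
equals 1 exactly on identity. Skeleton **precision** is 1 when no edges are
inferred (vacuous truth), **recall** 1 when the true graph is empty. These
conventions are isolated in two functions so alternatives can be swapped.

## Benchmark simulator

The benchmark network has nine variables and ten arcs: binary roots B, F, W
(P(B=1)=0.85, P(F=1)=0.95, P(W=1)=2/7, the classic values for this network)
and six continuous descendants, each linear-Gaussian in its parents with
binary parents entering as 0/1 indicators. The joint is therefore linear in
the exogenous variables, the implied correlation matrix is available in
closed form (`analytic_correlation`), and d-separations of the generating
DAG correspond to exactly-zero partial correlations — which is what makes
the oracle-recovery tests exact.

Two presets are shipped as JSON data files and were calibrated once with
`scripts/calibrate_network.py`:

| regime  | noise sd (D, ME, L) | continuous-part condition number | min eigenvalue |
|---------|--------------------:|---------------------------------:|---------------:|
| medium  | 1.0                 | 25                               | 0.12           |
| high    | 0.12                | 1332                             | 0.0034         |

The *high* regime's correlation matrix is close to singular, which is the
stress case for determinant-based scoring: the Spearman adjustment inflates
correlations further and can destroy positive definiteness, and pairwise
deletion under heavy missingness produces indefinite matrices whose
projection loses conditional-independence structure. Oracle-recovery checks
use the medium regime; in the high regime near-singularity makes some
partial correlations numerically indistinguishable from zero, a faithfulness
failure that no search can overcome (and the very phenomenon the benchmark
is designed to exhibit).

Missingness injection is MCAR (i.i.d. Bernoulli per cell) or MAR (drivers =
the always-observed discrete roots B and W, alternating over target columns;
the masking probability is a logistic function of the standardised driver
with slope 1.5 and an intercept calibrated by root finding so the marginal
rate is met; with 2 of 9 columns always observed the per-target rate is
9/7 of the nominal one). Neither mechanism ever leaves a row or column
entirely missing. The benchmark grid defaults to MCAR so the deletion-based
comparators are evaluated under their own assumption; MAR is available and
tested. What the simulator does **not** emulate: selection bias, latent
confounders, MNAR missingness, non-monotone marginal distortions, and
discrete variables with more than two levels — passing benchmarks therefore
says nothing about those features of real data.

The experiment harness runs cells of (regime × missing rate × sample size ×
estimator × algorithm) with 50 seeded replicates by default; replicate seeds
derive from (base seed, cell key, replicate index) so any cell is
independently re-runnable. At 0% missingness the mean-imputation, listwise
and pairwise estimators coincide, so the harness compares only EM and
un/adjusted pairwise Spearman there; the adjusted variant is dropped from
the missing-data arms, where the four remaining estimators are compared.
Failures of individual replicates (e.g. fewer than three complete rows for
listwise deletion at n = 100 with 30% missingness) are counted, not fatal.

`scripts/acceptance.py` reruns the verification suite at reduced size — 20
replicates per benchmark cell and the n ∈ {100, 1000} endpoints — which
keeps the full script within a few minutes on one CPU while using exactly
the study conditions otherwise; the pytest fixtures use the full 50
replicates and the complete n ladder.

## Known limitations

- Reliabilities are window-local; no cross-window logical propagation.
- The copula treatment of discrete variables biases some correlations
  toward zero; with many-valued discrete variables this is mild, with
  near-constant binary variables it can hide weak edges.
- BIC with a single effective sample size M is an approximation when
  different entries of a pairwise-deleted correlation matrix rest on very
  different numbers of observations.
- The d-separation ↔ zero-partial-correlation equivalence used by both
  algorithms holds for the latent Gaussian; at small n, rank discretisation
  makes weak conditional independencies hard to detect, and at large n real
  but tiny dependencies surface as extra edges (precision decreases while
  recall and accuracy grow).
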