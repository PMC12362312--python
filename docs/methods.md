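# Methods

## Problem and model

Cognitive diagnosis assessments classify examinees by mastery or
non-mastery of K discrete skills (attributes) from dichotomous item
responses. This package targets the situation where the response matrix
has missing cells — by design (targeted testing, balanced incomplete
blocks) or by examinee behaviour — and the analysis model is the DINA
model:

- A binary Q-matrix (J items x K attributes) declares which attributes
  each item requires.
- The ideal response is conjunctive: `eta_ij = prod_k alpha_ik^{q_jk}`,
  so an examinee produces a correct ideal response only when mastering
  *every* required attribute.
- Observed responses perturb the ideal response by slipping `s_j`
  (P(wrong | eta=1)) and guessing `g_j` (P(right | eta=0)):
  `P(X_ij=1 | alpha_i) = (1 - s_j)^{eta_ij} g_j^{1 - eta_ij}`.

Estimation is marginal-maximum-likelihood EM over all 2^K latent classes
with an unstructured class prior. Missing cells are skipped in the
per-person likelihood: the row term is a product over observed items only.
Examinee classification is maximum a posteriori (MAP); exact posterior
ties resolve to the lexicographically smallest profile so runs are
reproducible. Parameters and prior components are clamped to
[1e-4, 1 - 1e-4] each M-step, which protects the person-fit logarithms
downstream; monotonicity `1 - s_j > g_j` is guaranteed for generated data
but only logged, not enforced, during estimation.

## RFTI and RFDTI

Both methods adapt iterative (missForest-style) random-forest imputation
to the diagnostic setting. Per item with missing cells (visited in
ascending order of missingness), a classification forest is trained on the
originally-observed rows — response: that item's observed values;
predictors: the other J-1 columns of the current working matrix — and
predicts a class-1 probability `p_ij` for each originally-missing cell.
Rather than rounding every probability, only confident cells are imputed:

    Y_ij = 1   if p_ij >= tau_u
    Y_ij = NA  if tau_l < p_ij < tau_u     (left missing on purpose)
    Y_ij = 0   if p_ij <= tau_l

RFTI fixes `tau_l = 0.5` and searches `tau_u` in [0.5, 1); RFDTI searches
both thresholds (`tau_l` in (0, 0.5), `tau_u` in [0.5, 1)) on an evenly
spaced grid with increment `stepV` (default 0.05).

Iteration stops the first time the change statistic
`Delta = #(masked-cell states changed) / #NA` increases, returning the
previous pass's output; a pass with `Delta = 0` returns immediately, and a
hard cap (default 10 passes) guards against non-termination. State changes
are counted over {0, 1, NA}, so a cell flipping between "imputed" and
"left missing" counts as churn.

Threshold selection: for each candidate pair the thresholded matrix is
refit with the DINA EM (remaining NA ignored), MAP profiles are estimated,
and the adapted response-conformity person-fit index is computed over each
person's nonmissing cells:

    RCI_C_i = (1/m_i) * sum_j |contribution_ij|

where a response matching the MAP profile's ideal response contributes 0
and either mismatch contributes `|ln(P_j / (1 - P_j))|` with `P_j` the
fitted response probability (clamped to [1e-6, 1 - 1e-6]). The grid pair
minimising the mean index RCI_C-bar wins. This trades off coverage against
accuracy: correctly imputed cells match the ideal response and shrink the
index through a larger m_i, wrongly imputed cells add positive terms.
Ties prefer the smaller remaining missing rate, then the larger `tau_l`,
then the smaller `tau_u` (the most complete imputation with the narrowest
NA band).

### Shared probability trace

The working matrix must stay complete so later forests have full
predictors. We update every originally-missing cell with its 0.5-rounded
probability (`1` iff `p_ij >= 0.5`) immediately after its item is
predicted, within the pass (chained updates). With this rule the working
matrix — and therefore the whole sequence of forest probabilities — is
identical for every threshold pair except in how the *output* is
thresholded. `select_thresholds` exploits this: the forest trace is
computed once, lazily up to the first pass at which every grid pair has
stopped, and each pair replays the Delta stopping rule against the shared
trace. This makes the grid search linear in passes rather than in grid
cells, and `iterate_impute` for a single pair is implemented on the same
primitive, so grid results are bit-identical to single-pair runs. The one
place the threshold-free rule is a genuine choice rather than an identity
is a probability of exactly 0.5: the working cell is set to 1 even when an
RFTI-style output maps it to 0. With forests of 50-100 trees this affects
a vanishing fraction of cells and only the internal predictors, never the
reported output.

Forest configuration: 100 trees (the test suite drops to 25-50 for
speed), `mtry = floor(sqrt(J - 1))` features per split, unlimited depth,
class-1 probability = fraction of trees voting 1; an item whose observed
responses are constant skips training and predicts that constant. Each
(pass, item) pair gets its own seed spawned from the caller's seed, so
results are reproducible and independent of which grid is evaluated.

## Missingness generators

All mechanisms act on a random 80% subsample of examinees; the rest stay
complete. The target rate `mr` is defined over the subsample's cells, so
the overall rate is about 0.8 x mr (configurable via
`subsample_fraction`).

- **MCAR**: delete each cell with probability `mr` (a fresh uniform draw
  below `mr` deletes).
- **MAR**: for each target item, the ability proxy is the rest score
  (number correct over the other J-1 items). Proxies are z-normalised —
  an order-preserving step kept for procedural fidelity — and the
  subsample is split into seven fractiles at the 5/15/30/70/85/95th
  percentiles (boundary values go to the higher fractile). Fractile
  deletion rates are `mr x (1.50, 1.35, 1.15, 1.00, 0.85, 0.65, 0.50)`
  from lowest to highest scorers; the fractile widths
  (.05, .10, .15, .40, .15, .10, .05) dot the multipliers to exactly 1,
  so the average rate is `mr`.
- **MNAR**: each subsampled examinee omits exactly `round(mr x J)` items.
  A per-person offset `epsilon` starts at 0; each round draws fresh
  uniforms and deletes where `u > p + epsilon` (`p` = the generating
  model's correct-response probability, supplied as an input so another
  convention can be substituted); too many deletions raise `epsilon` by
  0.01, too few lower it, and the row is regenerated until the count is
  exact. Low-probability (hard) items are deleted preferentially.
- **MIXED**: per-examinee omission *counts* come from the MAR fractile
  rates (proxy = total score): `round(mr x multiplier x J)`, rounded
  half-away-from-zero; *which* items are omitted follows the MNAR
  epsilon procedure.

## Baselines

- **PM** – person-mean; **TW** – `PM_i + IM_j - GM` clipped to [0, 1];
  both rounded half-up (an expectation of exactly 0.5 becomes 1, the
  "at least as likely correct" convention, since the methods are defined
  without a dichotomisation rule).
- **EM** – single imputation under a multivariate-normal working model on
  the item columns: pattern-grouped E-step conditional expectations, ridge
  (1e-4) on the covariance each M-step, conditional means clipped and
  rounded at convergence. The working model is deliberately the standard
  normal-EM for test data, not a latent-trait model.
- **MI** – chained logistic regressions, m = 20 completed datasets,
  10 burn-in cycles visiting items in ascending missingness,
  Bayesian-bootstrap (Dirichlet-weighted) coefficient draws, Bernoulli
  cell draws. The L2 penalty of the regression handles perfect
  separation. Downstream accuracy metrics are pooled by averaging across
  the m datasets (profiles are binary, so metric pooling replaces
  estimate pooling).

## Evaluation

PCA = fraction of examinees with a fully correct estimated pattern;
ACA = fraction of correct person-attribute cells; ACA >= PCA by
construction. The remaining missing rate is reported relative to *all*
N x J cells (so 10% imposed on an 80% subsample is an 8% overall input
rate, and a post-imputation value of ~2% means about a quarter of the
missing cells were left NA on purpose). Replications whose DINA fit did
not converge are excluded from pooled means.

## Synthetic data

The generator mirrors a standard diagnostic-assessment simulation:
J = 30 items; attribute profiles from a K-variate standard normal with
exchangeable correlation 0.5 dichotomised at 0 (marginal mastery 0.5,
pairwise phi = 1/3 at rho = 0.5); Q entries i.i.d. Bernoulli(0.5) with
all-zero rows redrawn and matrices with unmeasured attributes rejected;
s, g ~ U(0.05, 0.25). It does not emulate real-data features such as
attribute hierarchies, item-position effects, rapid-guessing or
speededness, or misspecified Q entries, so passing tests demonstrate
correctness of the pipeline under the DINA generating process, not
robustness to model misfit.

## Problem sizes and numerical choices

- The bundled acceptance study (`scripts/acceptance.py`) uses N = 400,
  J = 30, K = 3, 5 replications per condition, 100-tree forests, and
  threshold step 0.1; the test suite uses N = 150-300 and 10
  replications for the method-ordering checks. These are deliberate
  desk-scale choices: the remaining missing rate is driven mainly by the
  mechanism and proportion, so reduced N and replications estimate it
  adequately, while classification-accuracy comparisons are kept
  qualitative (orderings, monotonicity) at these scales.
- DINA EM: tol 1e-4 on the max parameter change, cap 1000 iterations
  (300 inside the grid search, where dozens of refits occur and the RCI
  comparison needs only stable, not ultra-converged, fits).
- Degenerate inputs: items or persons with no observed cells raise; an
  item with constant observed responses imputes that constant; a
  degenerate MAR proxy (zero variance) collapses everyone into the middle
  fractile with a warning.
- Seed hierarchy: `numpy` `SeedSequence` spawning per condition,
  replication, and pipeline component, so adding a method or mechanism
  leaves all other random streams untouched.

## Known limitations

- Item-parameter recovery under imputation is not an evaluation target
  (the threshold methods optimise profile classification, not item
  calibration).
- Only the plain DINA model is implemented; the person-fit index is
  defined for any CDM with an explicit response function, but other CDMs
  (DINO, fusion, hierarchical variants) are out of scope.
- The MNAR generator needs the true correct-response probabilities and is
  therefore simulation-only machinery.
- The full 360-condition, 100-replication factorial is supported by the
  driver but is a multi-day single-core computation; the bundled configs
  run sub-grids.
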