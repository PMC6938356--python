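# Methods

## The decision problem

Dofetilide, a class III antiarrhythmic (I_Kr blocker), is started in
hospital over a mandated 3-day course of 5–6 oral doses because of its
QT-prolongation risk.  After each dose the clinician either *continues*
the current dose or *lowers* it (500 → 250 → 125 mcg; increases are
off-label), and the episode ends with the patient discharged on the drug
(successful loading) or with the drug stopped.  `doserl` treats each
administered dose as one step of an episodic Markov decision process and
asks two questions: can supervised classifiers mimic the clinician's
dose-adjustment decision, and what does an offline, on-policy
temporal-difference method (SARSA) learn about the value of the two
actions from the logged decisions alone?

## Synthetic cohorts

Real per-dose loading logs are not publicly available, so the package
ships a generator (`doserl.synth`) whose defaults emulate the published
cohort margins: 354 patients, start-dose mix 72/26/2% across
500/250/125 mcg, a 7.1% per-opportunity probability of lowering, 5–6
doses per patient, ~4.2% missingness, and an ~87% marginal success rate.
Patient covariates (demographics, history flags, labs, baseline ECG) are
drawn independently from configured normal/Bernoulli marginals; the QTc
trajectory follows a random walk with a dose-proportional drift (+8 ms
per 500 mcg dose, innovation SD 10 ms) — a deliberately simple stand-in,
since no within-admission kinetics are published — and the probability of
lowering rises with the running QTc above 500 ms on the log-odds scale.

Loading success is drawn from a logistic model over configured covariates
(starting at 500 mcg, sinus rhythm, any dose adjustment, coronary artery
disease by default; a *late* adjustment at position ≥ 4 is also
recognised).  The configured effect sizes are **marginal** odds ratios
(OR 5.0, 2.8, 0.19, 0.33 by default).  Because the odds ratio is not
collapsible, using those values directly as conditional coefficients
would attenuate the marginal associations a univariate refit estimates;
the generator therefore solves (scipy `root` on the realised design
matrix) for conditional coefficients and an intercept such that the
induced marginal ORs and the marginal success rate equal the configured
targets exactly.  A univariate logistic refit on a generated cohort is
then an unbiased estimator of each configured OR, which is what the
parameter-recovery test asserts (coverage of the Wald 95% CI in ≥ 90% of
20 seeds at n = 2000).

An optional `stop_after_adjustment` flag truncates a failed patient's
trajectory at the dose produced by their final adjustment, emulating a
load abandoned right after the decisive decrease.  It is off by default
(default trajectories always span 5–6 doses) and on in the
"late-failure" study condition used by the reinforcement-learning
property tests.

What the generator does **not** emulate: pharmacokinetics and renal
dosing rules, covariate correlation structure (covariates are
independent), informative missingness, and site effects.  Passing tests
therefore demonstrate correctness of the pipeline's computations under
known ground truth, not clinical validity on real loading data.

## Preprocessing

Per-dose quality control blanks QTc values strictly above 600 ms and PR
intervals recorded on a non-sinus rhythm (discordant).  QT is
heart-rate-corrected by Fridericia's formula, QTc = QT / RR^(1/3) with
RR = 60/HR seconds.  Patients with any dose increase are excluded
entirely.  The dose-adjustment label at position t ≥ 2 is "this dose is
strictly below the previous one"; position 1 counts as an opportunity
with no adjustment, so opportunities equal total doses and the naive
always-"no adjustment" classifier has accuracy 1 − adjustments/doses
exactly.

The train/test split (default 80/20) is at the patient level.  Numeric
missing values are imputed with the training median, categorical with the
training mode; categorical fields are one-hot encoded and numeric fields
min-max rescaled to [0, 1] using training statistics only.  Out-of-range
test values are clipped to [0, 1] and a constant training column maps
to 0.  Computing statistics on training rows only is a deliberate
leakage-avoidance choice; clipping makes out-of-range test values
well-defined.

## Baselines

Group comparisons between outcome groups use Pearson chi-square without
continuity correction for categorical variables and a pooled-variance
(Student) t-test for continuous ones, with a Bonferroni-adjusted level
alpha/m reported for the m rows compared.  Associations with loading
success are univariate logistic fits at the dose level, reported as odds
ratios with Wald 95% CIs; the "stepwise" screen simply retains predictors
with p ≤ 0.05, matching a univariate-screening reading of the reported
table (no multivariable elimination is claimed).  Perfect separation and
constant predictors yield flagged results, not exceptions.

The dose-adjustment classifiers are L1-regularised logistic regression,
random forest, gradient-boosted trees, an RBF-kernel SVM and k-nearest
neighbours at k = 1 and k = 10 (scikit-learn, library defaults beyond the
stated hyperparameters, fixed seeds).  Metrics follow the standard
confusion-matrix definitions with precision/recall/F1 defined as 0 when
their denominators vanish, and AUC from predicted scores (0.5 when truth
or scores are single-class).  Under ~7% positive prevalence the naive
comparator's 0.93 accuracy is the bar to beat.

## State construction

Each dose row carries ~25 features: dose position and amount plus the
dose-level ECG/creatinine values and the patient covariates replicated
onto the row.  Features enter PCA and K-means on the [0, 1] min-max scale
(the pipeline's stated rescaling), not as z-scores — the encoding stage
fully determines the cluster geometry.  PCA explained-variance and
within-cluster sum-of-squares (elbow) curves are diagnostics for k;
K-means uses k-means++ seeding with 10 restarts, keeping the best fit by
WSS, and is fitted on training rows only.  State labels are arbitrary
indices; assignment is exact nearest-centroid under Euclidean distance.

## Reinforcement learning

Each dose becomes a transition (S_t, A_t, R_t, S_{t+1}, A_{t+1}): the
state is the dose's K-means cluster, the action is the clinician's
decision after it (`lower` iff the next dose is strictly smaller), and
the reward is 0 except on the final dose of a failed patient, which
receives −10.  The final position's action is `keep` by convention,
except that a failed patient whose last recorded dose was itself a
decrease logs `lower` — the stop is the culmination of that lowering
decision.  Terminal bootstrap values are 0.

Training is a batch of repeated in-order sweeps (patients by id, doses by
position) applying

    Q(S_t, A_t) ← Q(S_t, A_t) + α [R_t + γ Q(S_{t+1}, A_{t+1}) − Q(S_t, A_t)]

from a zero-initialised table, stopping after 50 sweeps or when the
largest per-sweep change falls below 1e-8.  With rewards in {0, −10} and
zero initialisation every value stays ≤ 0.  The linear variant applies
the same semi-gradient update to per-action weight vectors over state
features; with one-hot state features it is algebraically identical to
the tabular sweep (asserted to 1e-9), and a weight magnitude beyond 1e6
sets a divergence flag instead of raising.  The on-policy (logged next
action) target is the default; an off-policy max target is available
behind a flag since the published description is ambiguous between the
two.

The greedy policy (argmax per state, exact ties to `keep`, the 93%
majority action) is compared with the logged clinician actions on
held-out patients; an all-zero table therefore disagrees exactly at the
test set's adjustment rate, a useful identity check.

### What the sensitivity analysis does and does not show

On cohorts whose failures concentrate sharply after dose adjustments —
worst after late, low-dose ones, with failed loads stopping at the
decisive decrease — the learned table ranks `lower` strictly below
`keep` in late-position states, the most negative entry sits at a
late-state `lower`, and the greedy policy is identical across
α ∈ {0.05, 0.1, 0.3} × γ ∈ {0.1, 0.2, 1.0} while the absolute values
change.  That invariance is a property of a strong decision signal, not
of the algorithm: at α = 0.3 the converged sweep is a recency-weighted
average over roughly 1/α visits, so in states where the two actions'
values are close the argmax can flip between grid cells, and on the
default generator (no failure truncation, terminal penalties landing on
`keep` actions) it often does.  The hyperparameter sweep artifact reports
the per-cell policies so this is visible rather than hidden.

## Problem sizes and determinism

Tests run on generated cohorts of 150–400 patients (2 000 for parameter
recovery, 20 seeds) and complete in well under a minute each; the
end-to-end pipeline on the default 354-patient cohort takes a few
seconds.  Every stage is deterministic given the run seed, which fans out
to per-stage derived seeds (seed + stage index); rerunning a
configuration reproduces `summary.json` and all data artifacts
byte-for-byte (`run.log` carries wall times and is excluded).

## Known limitations

* The synthetic QTc process and independent covariates are conveniences;
  effect estimates on real data would face confounding the generator
  does not create.
* Offline evaluation against logged decisions measures imitation of
  clinicians, not policy quality; without exploration the learned values
  are estimates for the behaviour policy only.
* K-means on min-max-scaled mixed features weights variables by their
  encoded range, which is a modelling choice rather than a statistical
  optimum.
* The calibration solver requires each configured success covariate to be
  non-constant in the realised cohort; tiny cohorts fall back to
  target coefficients with a rate-only intercept.
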