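# Methods

This note documents the statistical model behind `hccnma`, the choices made
where the design was genuinely open, and what the synthetic-data experiments
do and do not demonstrate.

## The evidence network

The unit of analysis is a network of randomized trials over 13 minimally
invasive HCC therapies.  Each trial compares 2–3 therapies and reports the
number of patients alive at yearly horizons (OS-1..OS-4); each horizon
defines a subnetwork of the trials reporting it.  The bundled network
(42 articles, 5,666 patients, 16 designs) is a verbatim transcription of a
published trial-characteristics table, with two structural readings encoded
as data rather than heuristics:

- The printed sub-rows (`-a/-b/-c`) of the four three-arm articles describe
  one three-arm trial each; every physical arm is stored once in
  `hcc_arms.csv` and referenced by the sub-rows it serves.  This is the only
  reading that reproduces the published patient totals (5,666 overall,
  2,392 TACE, 891 RFA) — naive row-summing double-counts shared arms.
- The two 2004 Lin sub-rows are one *article* but two independent two-arm
  randomizations with disjoint patients; the loader reconstructs trials as
  connected components of the sub-row/arm sharing graph within an article,
  which separates them automatically.

The loader cross-validates every printed comparison row against the
canonical arms table (same treatments, same sizes) and rejects any mismatch.
Descriptive statistics count articles, not sub-rows, wherever the published
totals demand it.  One three-arm article prints slightly inconsistent arm
sizes across its sub-rows (TACE 16/16 vs companion sizes 17/17 and 9/9);
the transcription follows the printed numbers verbatim.

## Hazard ratios from survival proportions

Source trials publish survival proportions, not hazard ratios.  Under
proportional hazards the cumulative hazard at horizon t is H(t) = −ln S(t)
and the cumulative-hazard ratio equals the hazard ratio, so the package uses
the complementary log-log reconstruction per horizon:

    log HR(a vs b) = ln(−ln S_a(t)) − ln(−ln S_b(t)),
    var_arm = (1 − S) / (n · S · (ln S)²)        (delta method),

with variances added across arms.  HR < 1 means the first-listed therapy has
the lower hazard (better survival).  Boundary proportions (0 or 1) receive a
continuity correction of +0.5 survivors (or deaths) and +1 at risk, flagged
in the output.  Three-arm trials yield a contrast vector against the
lexicographically first arm; its covariance has the baseline arm's variance
term off the diagonal (the shared-arm construction).  The delta-method
covariance is verified against binomial Monte-Carlo resampling in the test
suite (agreement within 5% for n ≥ 100 and moderate S).

This reconstruction deliberately uses only the published horizon-specific
quantities; no censoring information exists at the aggregate level, so no
Kaplan–Meier or IPD modelling is attempted.

## Pairwise meta-analysis

Per design, trial-level log HRs are pooled by inverse variance: a
fixed-effect model, and the DerSimonian–Laird random-effects model with
`τ² = max(0, (Q − (k−1))/C)`, `C = Σw − Σw²/Σw`.  Random effects is the
reporting default (the evidence base is clinically heterogeneous); fixed
effect is available everywhere.  95% CIs use the normal 1.96 quantile with
no small-sample adjustment.

## Bayesian network meta-analysis

A contrast-based random-effects consistency model.  Basic parameters
d_k are log HRs versus the reference (TACE; d_ref = 0), and every contrast
is a difference of basic parameters.  Trial i contributes

    y_i ~ Normal(X_i d, S_i + τ² R_i)

with S_i the within-trial sampling covariance and R_i = I for two-arm
trials, off-diagonal ½ for contrasts sharing a baseline arm.  A contrast
(rather than arm-binomial) likelihood was chosen because the evidence base
*is* horizon-specific log HRs, and it keeps the d-update exactly conjugate.

Priors: d_k ~ Normal(0, 10²) on the log-HR scale (e^10 dwarfs any plausible
hazard ratio) and τ ~ Uniform(0, 5); both configurable.  One τ is shared by
all contrasts within a horizon (homogeneous-heterogeneity assumption).

**Sampler.**  Metropolis-within-Gibbs: given τ the model is linear-Gaussian,
so the full d vector is drawn exactly from its multivariate-normal
conditional (one Cholesky per sweep); τ takes a random-walk Metropolis step
whose scale adapts toward 44% acceptance during burn-in only, keeping the
retained chain time-homogeneous.  Defaults: 4 chains × 20,000 draws after
5,000 burn-in; a fixed seed gives bit-identical draws (per-chain generators
spawned from one `SeedSequence`).  Convergence is summarized by rank-
normalized split R-hat (ArviZ) with a warning above 1.05.

**Degenerate networks.**  When the contrast network has no residual degrees
of freedom (number of contrasts ≤ number of basic parameters) nothing in the
data informs τ: a uniform prior would pass straight through to the posterior
and inflate every credible interval by prior artefact.  The sampler
therefore fixes τ = 0 in that case (logged), which makes a one-design
network reproduce its direct pooled estimate and an A–B–C chain reproduce
the closed-form indirect estimator with additive variances — both checked in
the tests.  `tau_fixed` can also be set explicitly.

**League tables.**  Cell (row, col) is the posterior median HR of row versus
col with 2.5/97.5 percentiles; quantiles are taken on the log scale and
exponentiated, so reciprocal symmetry (cell(a,b)·cell(b,a) = 1, low(a,b) =
1/high(b,a)) holds exactly.

## Ranking

Per posterior draw, therapies are ranked by d (lower hazard = better; the
direction flag can be flipped for harm outcomes), with exact ties broken by
seeded jitter of magnitude 1e−12.  SUCRA_t = Σ_{r<T} P(rank_t ≤ r)/(T−1).
The rank matrix is doubly stochastic, mean SUCRA is exactly ½, and SUCRA
reduces to the win probability for T = 2 — all asserted as invariants.

## Inconsistency (net heat)

Direct evidence is first condensed to one fixed-effect estimate per design;
a weighted least-squares fit of those estimates on the consistency design
matrix (reference column dropped; pseudo-inverse tolerance 1e−10) gives
network estimates, an exactly additive Q decomposition, and the hat matrix
H = X(XᵀWX)⁺XᵀW.  The contribution matrix reported for display is the
row-normalized absolute hat matrix.  "Detaching" a design removes its row
and refits; the change matrix holds the resulting per-design changes in Q
contributions (total change on the diagonal), negative values implicating
the detached design in the disagreement.  Design-level fixed-effect
aggregation is the standard construction behind net heat displays and keeps
the decomposition exact; within-design heterogeneity is reported separately
through the pairwise τ², not folded into these weights.

## Synthetic data and calibration

The generator draws trial-specific contrasts δ ~ Normal(d, τ²) (with the
shared-baseline covariance in three-arm trials), ties survival curves
together on the cumulative-hazard scale, S_arm(t) = S_ref(t)^exp(·), and
samples survivor counts by chained binomial thinning so counts decline
monotonically while keeping Binomial(n, S(t)) margins.  The default
fixture-shaped scenario reuses the bundled 42-trial roster — identical
designs, arm sizes and outcome-reporting pattern, including the year-4
disconnection of PAI — with true effects spanning the magnitude range of the
published network estimates versus TACE (HR 0.24–1.33) and a TACE survival
curve of (0.60, 0.40, 0.28, 0.20) over years 1–4, typical of unresectable
HCC.

What it emulates: the exact network topology, binomial sampling noise,
between-trial heterogeneity, proportional hazards across horizons.  What it
does not: non-proportional hazards, censoring and loss to follow-up,
region/era covariate effects, correlated reporting across horizons beyond
the survival-curve coupling, and publication bias.  Passing calibration
therefore demonstrates that the pipeline is a correct and well-calibrated
implementation of its assumed model — not that the model captures every
feature of the real trials.

Calibration experiments run the full extraction → NMA pipeline per
replicate.  Problem sizes used by the tests and the acceptance script:
100 replicates at 100 patients/arm for credible-interval coverage (observed
0.94–0.98 per parameter, nominal 0.95) and 100 replicates at 1,600
patients/arm for bias (observed max |bias| ≈ 0.02 on the log-HR scale);
replicate fits use 2 chains × 2,500 draws after 1,000 burn-in, enough for
these summaries at this scale.

## Design-level reanalysis of the published tables

The package bundles the published per-design direct HRs (point + 95% CI,
standard errors recovered from the CI width on the log scale) for all four
horizons and can run the NMA directly on them.  This design-level fit is an
approximation to the original study-level analysis — per-trial effects and
the original model settings are unpublished — and is used for qualitative
checks only: PEI ranks last by SUCRA at OS-1 and OS-2, and TACE+HIFU sits at
or next to the top.  At OS-1 TACE+RT can contest the top rank because the
precise but strongly inconsistent RT-involved comparisons (the same designs
the net-heat analysis flags) drag its design-level estimate down.  One
published OS-2 entry (PAI design) prints a CI that does not bracket its
point estimate; both are kept as printed and a warning is logged.

## Known limitations

- Aggregate-data reconstruction cannot recover censoring; the extracted log
  HRs are cumulative-hazard ratios at each horizon, exact under
  proportional hazards and exchangeable follow-up only.
- Consistency is imposed by construction in the Bayesian model;
  inconsistency is assessed separately at the design level rather than by
  node splitting.
- Horizons are analyzed independently; no borrowing of strength across
  years.
- The τ random walk can mix slowly when the likelihood pins τ against the
  zero boundary (near-exact data); fix τ in such edge cases.
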