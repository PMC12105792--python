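# Methods

## Data model

A visit log has one row per RFID detection (timestamp at 1 s resolution,
individual ID, feeder ID).  The study design alternates week-long *full*
periods with two-week *empty* gaps.  The full week preceding an empty gap is
an association period (AP); the full week after refilling is a diffusion
period (DP).  The same calendar week therefore serves as DP *k* and AP
*k*+1.  All windows are half-open `[start, end)` in timezone-naive local
time.

Repeated antenna reads can be collapsed with a configurable debounce gap
(consecutive reads of the same bird at the same feeder within the gap
collapse to the first read).  The default gap is 0 — every read kept —
because the definition of a "visit" is a genuine analysis choice and both
the association index and the feeder-use covariate depend on it; surfacing
it as configuration makes the sensitivity testable.

## Association index (modSRI)

For a dyad (A, B) at one feeder in one AP:

```
modSRI = #{visits by A with a B-detection within ±tau}
         + #{visits by B with an A-detection within ±tau}
         ---------------------------------------------------
                        n_A + n_B
```

Each visit contributes at most once to the numerator, so the index lies in
[0, 1]; a dyad with no visits at all scores 0.  The numerator definition —
*paired visits of either member* rather than paired visit-pairs or chained
co-detection events — is an interpretation (the published derivation of the
index is in supplementary material not available here); it is isolated in
`association.compute_modsri` so alternative operationalizations can be
swapped in one place.  Defaults: τ = 20 s, with τ = 30 s as the
conventional sensitivity setting.  Dyads with no temporally proximate
detections get edge weight 0, not missing: a zero edge means "no
transmission pathway" in the diffusion model.

The implementation pairs sorted detection vectors with binary search; the
test suite checks it against a brute-force all-pairs oracle, plus exact
symmetry, monotonicity in τ, and invariance to duplicating all reads.

## OADA

For naive individual *i* with informed set `z`, the additive acquisition
rate is `R_i = exp(β x_i) + s Σ_j a_ij z_j`.  The order-of-acquisition
likelihood is the product over events of `R_event / Σ_naive R`; censored
individuals (at risk, never acquired) stay in every denominator.  The
baseline rate is deliberately not parameterized — it cancels from the
order-conditional likelihood, which is why the order-based variant is used
rather than time-based alternatives that require a baseline learning-rate
function.

*Risk set.* Individuals with a row in the preceding AP network.  Birds
detected in a DP but absent from the AP have no association entries and are
excluded with a logged warning; AP members never detected in the DP are
censored.  This mirrors the imperfect AP/DP membership overlap of real
deployments.

*Ties.* First visits at the same logger second are ordered by a seeded
random permutation and recorded in the diffusion record's tie log.

*ILV.* Individual feeder use (visit count in the AP), mean-centred and
scaled (sample SD) within feeder × period; a degenerate SD yields zeros.  A
`ratio` mode (counts over the mean count) is available.  The ILV moderates
only the asocial rate.

*Fitting.* Social (s, β) and asocial (β) models are fitted by bounded
L-BFGS-B with multistart (5 starts over a log-spread of s origins, seeded);
s ∈ [0, 1e6], β ∈ [−20, 20].  A fit is flagged non-converged when the
optimizer fails, the projected gradient is large, or the interior Hessian
has a meaningfully *negative* eigenvalue (a saddle).  A singular (ridge)
Hessian with s running to its asymptote is **not** flagged: when a
diffusion follows the network almost perfectly the likelihood increases
monotonically in s toward a finite asymptote, the MLE is effectively
unbounded, and the correct downstream behaviour is an unbounded profile CI
and a saturated pST upper limit, not replacement of the fit.

*Model comparison.* AICc with n = number of acquisition events
(`AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)`; k = 2 social, k = 1 asocial; fits
with n ≤ k+1 raise an error instructing pooling).  Lower AICc wins; exact
ties go to the asocial model (parsimony); a non-converged social winner is
replaced by the asocial model and the replacement logged.  No ΔAICc
threshold beyond plain comparison is applied.

*Profile CI.* Bounds solve `2(ℓ_max − profile(s)) = 3.841` with β profiled
out at each s by bounded 1-D optimization and the crossing located by
bisection (relative tolerance 1e-4).  No crossing below the cap (default
1e6) flags the upper limit unbounded.

*pST.* Deterministic per-event attribution
`q_k = s·exposure / (exp(β x) + s·exposure)`, averaged over events (the
first acquirer has q = 0).  Reference implementations estimate this
quantity by forward simulation; the deterministic estimator is reproducible
and exactly testable, and `oada.simulate_pst` provides the simulation-based
variant as a cross-check (the two can differ slightly because the simulated
version averages over resimulated orders).  CI endpoints are pST evaluated
at the profile bounds with their profiled β; because the profiled β moves
with s, an endpoint can cross the point estimate, in which case the
interval is clamped to bracket it.  An unbounded upper s maps to
pST = 0.99999.

## Temperature meta-regression

Daytime average temperature for each DP is the mean of hourly temperatures
over the clock hours spanned by feeder activity (first to last visit hour,
inclusive, across all feeders) on the first day of the DP; "active hours"
are not externally defined, so a fixed-hours mode is available as
configuration.

Each feeder-period contributes logit-pST (0/1 adjusted by 1e-5, applied
equally to CI endpoints), with SE = (logit upper − logit lower)/3.92.
Feeder-periods where the asocial model won carry pST = 0 and receive the
mean SE across social-model estimates.  The model is

```
logit(pST) ~ temperature + DP + (1 | feeder),   weights 1/SE²
```

i.e. marginally `y ~ N(Xb, σ²_f ZZᵀ + σ² diag(1/w))`.  Standard
mixed-model routines do not accept per-observation residual-variance
weights, so the two-component criterion is implemented directly: variance
components optimized on the log scale (floor 1e-12, reported as 0 below
1e-8) by REML (default) or ML via Nelder-Mead with multiple starts; with
the feeder variance at zero the solution reduces exactly to closed-form
weighted least squares, which is the test oracle.  Wald t statistics use
residual degrees of freedom (n − p); the fit records which df method
produced the p-values.  DP enters as a numeric covariate.

Fisher's exact test on the 2 × K table of best-model frequencies per DP is
computed by exact enumeration of all tables with the observed margins
(multivariate hypergeometric; p sums probabilities ≤ observed with 1e-12
slack) when the grand total is ≤ 200, else by seeded Monte-Carlo.  The
pipeline reports the test both before and after convergence replacement,
since either classification is defensible.

## Synthetic data generator

The generator defines the conditions under which the pipeline is verified:

- 8 feeders with disjoint memberships (strong site fidelity), group sizes
  drawn uniformly from 8–42, four full/empty cycles of 7 + 14 days.
- Visits arise from latent flocks of ~6 birds: each flock emits Poisson
  arrival epochs during active daylight (08:00–17:00, matching short
  mid-winter days at high latitude); each member joins an epoch with
  probability 0.5 and is detected at the epoch ± Gaussian jitter (SD 5 s);
  each bird also makes solo visits at 0.25/h.  With the default flock
  arrival rate of 1.5/h this yields ~1 visit/bird/hour and a sharply
  bimodal association structure (within-flock modSRI ≈ 0.3–0.4,
  between-flock ≈ 0.01–0.03) — the regime in which a co-detection index
  carries signal.  Real streams include antenna re-reads and much more
  between-individual heterogeneity; recovery results refer to this latent
  structure, not to any field dataset.
- Each full week, 20% of members are absent ("dropout"), producing censored
  individuals and risk-set newcomers exactly as imperfect AP/DP overlap
  does.
- Diffusion orders are drawn from the additive OADA rate model on the
  modSRI network realized in the preceding week, using the same
  standardized feeder-use ILV the analysis computes, then embedded into the
  week's visit stream as each participant's first visit (spaced ≥ 30 s on
  the first DP morning; later candidate visits are kept so flock clustering
  survives into the next AP).  The generator is order-only — no acquisition
  latencies are modeled, matching the order-conditional analysis.
- Per-period temperatures default to (−8, −11, 5, −2) °C — spanning the
  plausible mid-winter range and deliberately *non-monotone* across the
  season so the temperature effect is identifiable separately from the DP
  covariate (mid-winter cold snaps, not a trend, are the realistic
  pattern).  The weather series is piecewise constant per cycle, so the
  daytime average on the first DP day equals the period temperature
  exactly.
- The optional temperature link sets `log s = log s₀ + slope·T`: s is a
  nonnegative rate, so the natural monotone link is logarithmic; a negative
  slope makes both s and the induced pST decrease with temperature.
- Ground truth records per-period s, β, the realized per-event attribution
  pST, memberships, flocks and the seed; identical seeds reproduce the
  dataset byte-for-byte.

## Problem sizes used in verification

The test suite and the acceptance script use: pooled fits over 100
diffusions of 15 individuals for s recovery; 100 single-diffusion null
replicates for model-selection behaviour; 200 (tests) / 100 (script)
replicates of 5-diffusion pools for profile-CI coverage at true s = 3; 200
replicates of n = 29 weighted regressions for slope recovery; and 50
(tests) / 25 (script) full 8-feeder × 4-period end-to-end studies for sign
recovery of the temperature effect.  These sizes give Monte-Carlo error
comfortably below the margins asserted.

## Known limitations

- The modSRI numerator definition is an interpretation (see above).
- pST is the deterministic per-event attribution, not a simulation average;
  values can differ slightly from simulation-based estimators.
- The meta-regression's p-values use residual df, not Satterthwaite; with
  n ≈ 29 and 3 fixed effects the difference is small but real.
- The generator's flock process is a stand-in: it makes the association
  index informative but does not emulate dominance structure, diurnal
  routines, or weather-dependent visit rates.
- Temperature enters linearly; threshold or interactive effects are out of
  scope.
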