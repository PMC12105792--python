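# feederdiff

Social-transmission analysis of RFID feeder-visit streams.

`feederdiff` quantifies how strongly wild foraging groups rely on social
information when rediscovering an intermittently available food source, and
how that reliance varies with ambient temperature.  It is aimed at
behavioural ecologists working with PIT-tag/RFID feeder deployments in which
feeders alternate between full and empty periods: the full week before an
empty gap defines a social network, and the order in which birds first
return after refilling is the behavioural diffusion.

## The inference chain

1. **Association networks (modSRI).**  For every feeder × association
   period, each dyad gets a modified Simple Ratio Index: the number of
   visits (by either member) with at least one detection of the partner
   within ±τ s (default τ = 20, sensitivity τ = 30), divided by the dyad's
   total visits.  The index lies in [0, 1] and tolerates visit streams too
   dense for classic grouping-event detection.

2. **Order-of-acquisition diffusion analysis (OADA).**  Under the additive
   network-based diffusion model, a naive individual *i* acquires at rate

   ```
   R_i = exp(β x_i) + s Σ_j a_ij z_j
   ```

   where `a_ij` is the modSRI edge, `z_j = 1` once *j* is informed, `x_i`
   is standardized individual feeder use (an ILV moderating only the
   asocial rate), and `s` is the social-transmission strength relative to
   the baseline asocial rate.  OADA conditions on the acquisition order, so
   the shared baseline rate cancels.  Social (s, β) and asocial (β only)
   models are compared by AICc; a winning social model with convergence
   problems is replaced by the asocial model.

3. **pST with profile-likelihood CIs.**  The proportion of acquisition
   events attributable to social transmission,
   `pST = mean_k [ s·exposure_k / (exp(β x_k) + s·exposure_k) ]`,
   standardizes `s` across networks.  95% CIs for `s` come from the profile
   likelihood (χ²₁ cutoff 3.84); when a diffusion follows the network so
   closely that no upper limit exists below the cap, the pST upper limit is
   fixed at 0.99999.

4. **Temperature meta-regression.**  Per feeder-period logit-pST values
   (0/1 adjusted by 1e-5; SE = logit CI range / 3.92; asocial winners get
   pST = 0 with the mean social SE) are regressed on daytime average
   temperature and diffusion-period number with weights 1/SE² and a feeder
   random intercept, via a two-variance-component (RE)ML fit.

A synthetic-data module generates visit streams (latent flock arrivals +
solo visits), diffusion orders from the same additive model, and hourly
temperatures with known ground truth, so every stage is testable by
parameter recovery.

## Worked example

Simulate a small four-feeder study in which the generative social
transmission strength increases as temperature drops
(`log s = log 2 − 0.4·T`), then run the full pipeline:

```
$ cat demo.yaml
simulate:
  n_feeders: 4
  group_size_range: [10, 16]
  temp_slope_log_s: -0.4
  s_baseline: 2.0

$ feederdiff simulate --out demo_data --seed 7 --config demo.yaml
$ feederdiff run --visits demo_data/visits.csv --schedule demo_data/schedule.csv \
      --weather demo_data/weather.csv --out demo_out --seed 7
analysed 16/16 feeder-period combinations (tau=20 s)
temperature slope on logit-pST: -0.847 +/- 0.301
Fisher exact p (best-model frequencies): 0.3327
```

The fitted temperature slope on logit-pST is −0.85 ± 0.30: colder diffusion
periods show a higher proportion of socially attributable acquisitions,
recovering the sign of the generative link.  The ground truth for this seed
has per-period `s` of 163, 49, 4.5 and 0.27 at −11, −8, −2 and +5 °C, with
realized pST falling from 0.86 (coldest) to 0.14 (warmest).  `demo_out/`
contains the per-model fit table (`fits.csv`), the pST table (`pst.csv`),
per-period temperatures, tidy meta-regression coefficients and a run log
with the config hash and seeds.  `feederdiff run --tau 30 ...` repeats the
analysis at the ±30 s co-detection threshold.

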