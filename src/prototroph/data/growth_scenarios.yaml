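# Packaged long-term culture scenarios.  Rates and schedules mirror the
# study conditions they emulate: the ilvD-boosted prototroph doubling
# every 3.2 days across 39 days of unconditioned valine-free culture,
# the first-generation prototroph doubling every 4.3 days across 19
# days, and a pathway-free control collapsing in valine-free medium
# (-88% over 6 days, i.e. a ~1.96-day half-life).  Counts carry 10%
# multiplicative noise; three replicates, as the growth panels report.
pMTIV_ilvD_plus:
  doubling_days: 3.2
  n_passages: 10
  passage_interval_days: 3.9
  seed_count: 100000
  noise_cv: 0.10
  n_replicates: 3
  seed: 42
pMTIV_valfree:
  doubling_days: 4.3
  n_passages: 5
  passage_interval_days: 3.8
  seed_count: 100000
  noise_cv: 0.10
  n_replicates: 3
  seed: 42
pCtrl_valfree:
  decline_halflife: 1.96
  n_passages: 3
  passage_interval_days: 2.0
  seed_count: 100000
  noise_cv: 0.10
  n_replicates: 3
  seed: 42
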