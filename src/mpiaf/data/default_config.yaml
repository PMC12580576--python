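# Default end-to-end run: a 60-observer cohort with independent traits,
# single behavioural session, five 60-s eyes-closed EEG trials per observer.
master_seed: 20250101

cohort:
  n_observers: 60
  planted_correlations: {}

behaviour:
  n_sessions: 1
  illusions: [fle, lum_fle, fe, fd, fg, mips, tg, fj]

recording:
  fs: 256
  n_channels: 19
  n_epochs: 5
  epoch_seconds: 60

iaf:
  electrode_set: all_19
  min_channels: 9

stats:
  family: full
  B: 1000
  alpha: 0.05
  partial_age: false
  reliabilities:
    paf: 0.87
    cog: 0.87
    f_paf: 0.87

io:
  out_dir: mpiaf_run
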