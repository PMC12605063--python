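# chordaffect

Analysis pipeline for affective responses to consonant and dissonant piano
chords, exercised end-to-end on a built-in synthetic EEG + behaviour
generator:

- **chord_stimuli** — equal-temperament pitch math (A4 = 440 Hz, 12-TET),
  the full stimulus inventory (7 root-position major triads, 7 six-four
  inversions, 2 × 7 dissonant four-note structures, neutral click tones),
  RMS-normalised additive-synthesis audio, and randomised schedules with
  200–300 ms ISI jitter.
- **synth_eeg** — seeded 64-channel, 500 Hz recordings composing 1/f
  background, narrowband alpha/beta/gamma oscillations whose envelopes carry
  controllable DFA exponents (spectral fGn synthesis), condition-locked ERP
  kernels near 100/200/300 ms, optional blink artifacts; plus behavioural
  trial tables from a mixed-effects logistic accuracy model with published
  per-condition reaction-time means.
- **preprocess** — downsample → 45–55 Hz notch → 1–45 Hz band-pass (both
  zero-phase Butterworth) → common average reference → bad-channel
  exclusion (100 µV rule) → FastICA ocular removal → (−100, 800) ms epochs
  with (−100, 0) ms baseline correction.
- **erp_stats** — global field power, prominence-ranked peak/window
  selection, and channel-space cluster-based permutation contrasts
  (Wilcoxon signed-rank z, cluster mass, max-statistic FWER, 800
  permutations).
- **band_dynamics** — Hilbert-envelope band amplitude and detrended
  fluctuation analysis over 5–50 s log-spaced windows.
- **behav_stats** — Fisher's exact test (exact 2×2, Monte-Carlo r×c with
  fixed margins), Kruskal–Wallis, pairwise rank-sum post-hocs with
  Bonferroni correction.
- **glmm** — mixed-effects logistic regression of trial accuracy on
  stimulus type × standardised neural predictor with crossed random effects
  (subject intercept + uncorrelated type slopes, item intercept), estimated
  by a Laplace approximation written for this package; likelihood-ratio
  tests and odds-ratio tables.
- **brainvision / pipeline / cli** — BrainVision (.vhdr/.vmrk/.eeg) reader
  and writer (multiplexed float32/int16 subset), JSON run configuration,
  and an end-to-end runner.

## CLI

```bash
chordaffect stimuli   --out stim/ --seed 1 --neutral-count 14 --sample-rate 44100
chordaffect simulate  --subjects 4 --seed 1 --out data/
chordaffect preprocess --in data/ --out epochs/
chordaffect erp       --epochs epochs/ --nperm 800 --seed 1 --out clusters.tsv
chordaffect bands     --in data/ --out bands.tsv --dfa-range 5 50
chordaffect behav     --trials data/trials.tsv --out behav.json
chordaffect glmm      --trials data/trials.tsv --neural bands.tsv --band gamma \
                      --predictor amplitude --out glmm.tsv
chordaffect run       --config cfg.json --out report/
```

A minimal run configuration:

```json
{"seed": 1, "n_subjects": 30}
```

(All other fields default to the protocol parameters: 500 Hz acquisition,
250 Hz analysis rate, 5 repetitions per stimulus, 800 permutations,
5–50 s DFA windows.)

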