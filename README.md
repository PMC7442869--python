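# crowdkit

Simulation and analysis pipeline for training-induced changes in the
radial–tangential anisotropy of visual crowding. The package generates a
fully synthetic study — 4AFC constant-stimuli training data and
block-design ROI BOLD time series — and analyzes it end to end:

1. **synthetic_data** — seeded generative model: 17 observers, 4 training
   days, radial/tangential flanker conditions, 1348 trials per condition
   per observer (5 spacing levels, 0.75°–2.75° in 0.5° steps), and per
   scanning session 8 BOLD runs of alternating 16-s fixation/stimulation
   blocks (8 stimulation + 9 fixation, TR = 2 s, 4 stimulus conditions)
   with gamma-HRF responses, linear drift and AR(1) noise. An optional
   latent coupling ties each observer's behavioral anisotropy change to
   their radial BOLD amplitude change.
2. **psychophysics** — maximum-likelihood cumulative-normal psychometric
   fits (guess fixed at 0.25, lapse bounded in [0, 0.06]), critical
   spacing at the 68% criterion by analytic inversion, crowding-zone
   geometry (radial/tangential ratio) and the behavioral anisotropy index
   `A_psy = (C_r − C_t)/(C_r + C_t)`.
3. **bold_pipeline** — block-design GLM with a shifted gamma-variate HRF
   (δ = 2.25 s, τ = 1.25 s, α = 2; unit-peak regressors), OLS estimation,
   percent signal change (`100·β/β_intercept`), the per-axis crowding
   index `C = PSC(present) − PSC(absent)` and the BOLD anisotropy index
   `A = (C_rad − C_tan)/(PSC_abs,rad + PSC_abs,tan)`.
4. **group_stats** — paired t-tests, fully within-subject
   repeated-measures ANOVA (1–3 factors, classical sums of squares, no
   sphericity correction by default; Greenhouse–Geisser behind a flag)
   and Spearman rank correlation with midranks (exact permutation p for
   small n).
5. **cli** — orchestration with YAML configs, a single fan-out seed and a
   hash-bearing run manifest.

## CLI

```bash
# full chain: simulate -> psychometric fits -> GLM/PSC -> stats -> report.md
crowdkit replicate --seed 1 --outdir out/

# stages, individually
crowdkit simulate --config config.yaml --seed 1 --outdir out/
crowdkit fit-psy  --trials out/trials.csv      --outdir out/
crowdkit fit-bold --bold-dir out/bold          --outdir out/
crowdkit stats    --zones out/zones.csv --bold out/bold_indices.csv --outdir out/
crowdkit report   --stats out/stats.json       --outdir out/
```

All outputs are plain text: trial tables and fit tables as CSV, BOLD runs
as CSV plus a JSON schedule sidecar, statistics as JSON, the report as
Markdown. Identical seeds give byte-identical outputs (hashes recorded in
`manifest.json`).

A config file may override any generator/analysis setting, e.g.:

```yaml
study:      {n_subjects: 17, n_days: 4, trials_per_condition_per_day: 337}
population: {c_rad_pre: [2.16, 0.20], c_tan_pre: [1.61, 0.15], coupling: true}
bold:       {runs_per_session: 8, noise_sd: 5.0, ar1_coef: 0.3}
```

## Notes

- The HRF parameter triple is interpreted as a *shifted gamma-variate
  impulse response* (the convention of the analysis toolkits those
  parameters come from); a literal cumulative gamma would saturate and is
  not a plausible impulse response.
- GLMs are fitted per run and condition betas averaged across runs;
  a concatenated single-GLM variant is available via `--concatenate`.
- PSC convention: condition regressors are normalized to unit peak, so
  `PSC = 100·β/β_intercept` is the block-plateau response in percent of
  baseline.
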