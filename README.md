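# snarcpipe

Analysis pipeline for spatial-numerical association (SNARC/MARC) experiments
with binary-response reaction-time tasks, plus a synthetic-data generator so
the whole pipeline is testable without any experimental data.

Stages:

1. **simulate** — trial-level RT data for a 2-task × 2-block × 8-digit × 20-rep
   design (ex-Gaussian within-trial noise, configurable per-group slope
   distributions, error and lapse rates) and 7-item directional-preference
   questionnaire responses.
2. **preprocess** — the sequential trial filter (incorrect responses →
   200–1500 ms window → iterative ±3 SD trimming until the retained set is
   stable) and participant exclusion (retention < 75% in either task, or any
   empty digit × side cell).
3. **slopes** — per-digit dRT profiles (mean right-hand RT − mean left-hand RT)
   and per-participant slopes: linear magnitude + parity contrast for parity
   judgment (SNARC and MARC), categorical and continuous magnitude models for
   magnitude classification; Fisher-z standardized weights alongside.
4. **inference** — one-sample / Welch / paired t-tests with JZS Bayes factors
   (Cauchy prior, r-scale 0.707, optional one-sided truncation), Pearson
   correlations with default stretched-beta Bayes factors, a permutation
   Jonckheere–Terpstra monotone-trend test, and Holm correction.
5. **bootstrap** — H0 bootstrapping of individual slopes (two sets of 20 RTs
   resampled per digit, 5000 iterations) classifying each participant as
   reliable / reliable-reverse / unreliable against the mid-90% null interval,
   with group × label χ² / Fisher-exact contingency tests.
6. **cdpq** — questionnaire scoring (LR = −1, none/mixed = 0, RL = +1, sum in
   [−7, 7]), per-item group contingency tests with Bonferroni post-hocs, trend
   tests, and slope–score correlations.

## CLI

The `snarcpipe` command reads a JSON or YAML run config:

```yaml
master_seed: 1
out_dir: out
n_boot: 5000
n_perm: 2000
groups:
  - {group_label: German,  n_participants: 130, slope_mean: -6.03, slope_sd: 6.68, marc_sd: 70}
  - {group_label: Turkish, n_participants: 112, slope_mean: -3.43, slope_sd: 8.63, marc_sd: 80}
  - {group_label: Iranian, n_participants: 75,  slope_mean: -1.69, slope_sd: 6.72, marc_sd: 70}
```

```sh
snarcpipe all --config config.yaml --seed 1 --out out/
snarcpipe simulate --config config.yaml        # trials.csv + cdpq.csv only
snarcpipe preprocess --config config.yaml      # needs trials_path in config
snarcpipe slopes --config config.yaml
```

`all` writes a report bundle: filter audit, exclusion list, slopes table,
group t-test / Welch / paired-test / correlation tables, trend tests,
bootstrap classifications with prevalence tables and contingency tests,
questionnaire scores and item tests, and a machine-readable `summary.json`.
Everything is deterministic under a fixed `master_seed`; individual
participants are reproducible in isolation because their seeds derive from
the master seed and their id.

Existing data can be analyzed by setting `trials_path` (and optionally
`cdpq_path`) instead of `groups`; the trial CSV columns are
`participant_id, group, task, block, trial_index, digit, response_side,
correct, rt_ms`.

## Python API

```python
from snarcpipe import (
    GroupConfig, simulate_study, filter_trials, compute_drt, fit_pj_model,
    one_sample_t, jzs_bf, jonckheere_terpstra, h0_bootstrap, score_record,
)
```

All statistical operations are usable standalone; see the module docstrings
for conventions (e.g. more negative magnitude slopes = stronger regular
SNARC effect).
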