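# synergykit

Muscle-synergy analysis of standing up and sitting down under rollator
support, for movement scientists studying how walking-aid support reorganizes
muscle coordination. The package implements the full chain from raw
multi-channel surface EMG to statistics: preprocessing and movement-event
detection, extraction of **temporal** and **spatial muscle synergies** by
non-negative matrix factorization, cross-validated selection of the number of
synergies, matching of activation profiles across movement strategies,
activation-timing analysis, and linear mixed models on the muscle weightings.
Because no public recordings exist for this study design, a first-class
synthetic-cohort generator with known ground truth drives all validation.

## The model

EMG envelopes of all trials of one movement strategy (101 time-normalized
samples x 30 muscles per trial) are concatenated into
`M ∈ R^{101 x 30·tr}` and factorized as

```
M^s(t) ≈ Σ_n C_n(t) · W^s_n            (temporal synergies)
```

with trial-independent activation profiles `C_n` and trial-dependent muscle
weightings `W^s_n`; the transposed arrangement gives spatial synergies
(trial-independent weighting vectors, trial-dependent profiles). The number
of synergies is chosen on the fivefold cross-validated `R² = 1 − SSE/SST`
curve, either at the *R²-knee* (first left endpoint whose linear fit to the
remaining curve has MSE < 1e-4) or as *N\** (smallest n with `R² ≥ 0.9` and
increment < 0.05). Profiles are matched across strategies by constrained
k-means++ (centroid correlation ≥ 0.9, one profile per strategy per
cluster), timed by full-width at half-maximum, and the weightings are tested
for support effects (unassisted / light touch / full support) with a
two-stage participant-random-intercept mixed model under Bonferroni control.
See `docs/methods.md` for the full account.

## Worked example

The numbered scripts under `analysis/` run a desk-scale study on a synthetic
cohort (four participants, non-challenging sit-to-stand, two movement
strategies with three planted synergies each, full raw-signal simulation):

```
cd analysis
python 01_simulate_cohort.py
python 02_preprocess.py
python 03_extract_synergies.py
python 04_match_profiles.py
python 05_timing_fwhm.py
python 06_support_stats.py
```

which prints, among other lines:

```
median |event error| (s): start 0.030, seat transition 0.020, end 0.020
sit_to_stand|non_challenging|forward_leaning: temporal knee 4 (R² 0.905), spatial knee 4 (R² 0.783); parameter sums 524 vs 524
sit_to_stand|non_challenging: 6 clusters (2 shared across strategies, 4 strategy-specific); assignment agreement over 10 repeats: 100%
forward_leaning synergy 2: peak 44 %, width 12.3 % (none)
forward_leaning synergy 1: peak 6 %, width 16.0 % (start)
forward_leaning: 1/4 synergies support-sensitive (stage-1 alpha 0.0063)
  synergy 3: FS-vs-UA coefficient -0.098 (p = 3.69e-03)
```

Reading this: detected movement events sit within tens of milliseconds of
the generator's truth; the R²-knee selects 4 synergies against 3 planted
(the raw-signal path adds a residual baseline component — the envelope-level
generator recovers the planted order, see the tests); the matcher finds the
shared early and seat-off synergies and separates the strategy-specific late
profiles; mid-movement synergies are briefer (12 % of the cycle) than
boundary synergies, which are measured one-sided; and one synergy's
weightings shift significantly under full support — with only two
participants per strategy in this demo, power for the rest is limited. The
same operations are exposed as a CLI
(`synergykit simulate|preprocess|extract|match|fwhm|stats|run-all`).

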