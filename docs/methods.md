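# Methods

## Data model

A participant is a complete 3-phase × 5-trial × 2-stimulus grid of
non-negative SCR amplitudes (μS): acquisition (ACQ), early extinction
(EXT_EARLY) and late extinction (EXT_LATE), each with trials 1–5 and a CS+
(CSP) / CS- (CSM) response per trial. Strategies that reason about
"extinction trials 1–10" concatenate the two extinction blocks in order.
Missing cells are rejected at I/O time rather than modelled; responses are
analysed as raw scores with no transformation. The interchange format is a
long CSV (`participant, group, phase, trial, stimulus, response`); floats
are written with `%.17g` and parsed with round-trip precision so
read∘write is cell-exact.

## Synthetic source population

No public trial-level dataset with this exact protocol is available, so the
source population is synthetic:

    response(i, p, t, s) = max(0, a_i + μ(p, t, s) + ε_{i,p,t,s})

with `a_i ~ N(0, σ_subject²)` a participant random intercept and `ε ~ N(0,
σ_noise²)` i.i.d. cell noise. The rectification at zero reproduces the
zero-inflation of scored SCRs while keeping SD-unit effect injection
interpretable; a lognormal model was the considered alternative, rejected
because additive offsets in SD units would then act multiplicatively.

Defaults (chosen once as a plausible differential-conditioning profile, and
documented as defaults rather than as claims about any real sample):

| parameter | default | meaning |
|---|---|---|
| n_participants | 379 | source-population size the sweeps resample from |
| μ(·,·,CSM) | 0.30 μS | flat CS- orienting level |
| μ(ACQ,·,CSP) | 0.55 → 0.80 μS | differential acquisition, CS+ > CS- on every trial |
| μ(EXT,·,CSP) | 0.80 → 0.30 μS | monotone decay to the CS- level across the 10 extinction trials |
| σ_subject | 0.20 μS | between-participant intercept SD |
| σ_noise | 0.25 μS | within-cell noise SD |

Each participant draws from an independent substream keyed by
`(seed, participant index)`, so enlarging the population extends it without
reshuffling earlier rows. The generator produces *null* data only; group
structure enters downstream. What the generator does **not** emulate:
between-study heterogeneity of the pooled sample, non-normal response
shapes beyond the zero floor, trial-order autocorrelation beyond the shared
intercept, and any clinical-subgroup structure. Passing tests therefore
demonstrate properties of the method under a clean, known data-generating
process — not claims about any particular empirical dataset.

## Resampling and group allocation

`phase_wise` bootstrap (the default) draws each of the six phase × stimulus
blocks independently across source rows, matching a design in which all CS+
or CS- responses from one phase are resampled together; `phase_only` keeps
the two stimuli of a phase together; `full_row` resamples whole
participants (used as the sanity check for the effect-size-inflation
analysis, capped at the source size so no participant repeats more than
chance allows). Groups 1–3 are allocated equally at random; when N is not
divisible by 3 the remainder goes to uniformly chosen distinct groups, so
sizes differ by at most 1 (e.g. N = 2000 → 667/667/666).

## Effect injection

Three built-in schedules add trial-wise offsets, in SD units, to group 3's
CS+ only: BASE (strong differential acquisition, rapid extinction), A
(moderate acquisition, rapid extinction), B (no early-extinction decline).
The SD reference is the per-(phase, trial) SD of CS+ scores over the whole
bootstrapped sample, computed before injection — the only reference that
makes the injected magnitude independent of the random group allocation; a
group-restricted reference is available as a parameter. The schedules are
standalone profiles applied to raw bootstrapped values; a `stacked` switch
reads A and B as increments over BASE instead, since the verbal description
of the phenotypes admits both readings. Injection is purely additive
(means shift by exactly `offset × sd`), never re-floored, and leaves CS-,
other groups, row order and ids untouched.

## ANOVA engine

The engine implements the classical univariate mixed-design decomposition
directly, because no installed package handles multiple within factors with
per-term partial eta squared. Each subject's cell vector is projected onto
orthonormal (normalized Helmert) contrast bases — one subspace per subset
of within factors, plus the scaled subject mean — and every stratum then
reduces to a one-way Group decomposition of the projected scores:

* between stratum: SS_Group vs subjects-within-groups;
* stratum S: SS_S (grand-mean part), SS_{S×Group}, vs S ×
  subjects-within-groups.

Because the bases are orthonormal, the strata sum exactly to the total
corrected SS (a tested invariant, 1e-9 relative). ηp² = SS/(SS + SS_error)
uses raw sums of squares, so sphericity corrections are irrelevant. With
the ±1 group-size imbalance the strata use the standard weighted one-way
decomposition — the behaviour of classical `aov`-style sequential SS, and
identical to the balanced formulas when groups are equal; at the design
sizes used the difference is negligible.

Degeneracy: a stratum carrying no variance at all (all responses identical,
or a differential analysis of CS+ ≡ CS- data) raises an explicit error that
evaluation loops convert to a flagged-and-counted missing value. Zero
*error* SS with a non-zero effect is legitimate and yields ηp² = 1 (F
reported as infinity).

Two strategies do not fit the shared mixed-model path: the single-trial
differential strategy is a plain one-way Group ANOVA, and the
paired-contrast strategy is mapped to a one-way Group ANOVA on per-subject
phase-difference scores — the unique reduction that makes its output a
group-level interaction effect size comparable with the rest.

## Strategy catalogue

Fifteen strategies in three families (4 acquisition→extinction, 7 static
extinction, 4 extinction-change), each a declarative spec: trial windows,
aggregation (mean, trial-by-trial, running average, single trial, max),
stimulus handling (differential, both stimuli, CS+ only) and the model term
reported. Source designs used 8–32 trials; windows stated as fractions are
resolved on this 5 + 10 layout with half-up rounding (last three-quarters
of 10 → 8 trials; quarters → 3; halves → 5; last half of 5 acquisition
trials → trials 3–5). These resolutions are module-level constants, not
buried literals. The running average maps extinction trials (1,2), (2,3),
(3,4), (4,5) to four pseudo-trials. The maximum-response rule takes each
subject's largest acquisition differential. Strategy ids (`ACQ_EXT.2`,
`EXT.6`, …) are stable strings used across all outputs.

## Robustness statistics

For one sample size, the 100 resampled datasets give a 100 × 15 matrix of
ηp². Robustness of a within-family pair is Kendall τ_b between the two
columns (scipy's tie-corrected implementation; an all-pairs enumeration
oracle guards it in the tests). The 95% CI resamples the 100 paired
observations 1,000 times (percentile interval, linear interpolation);
re-running entire pipelines 1,000 × 100 times per size would measure the
same quantity at ~1,000× the cost, and is available simply by sweeping with
different seeds. Degenerate ηp² values are pairwise-deleted and counted.
Per-strategy summaries average that strategy's pairwise mean τ_b values
within its family.

Trend tests: Pearson r (two-sided) of mean τ_b against sample size per
pair, BH-FDR at Q = 0.1 within each family; pairs with constant τ_b are
reported as missing and excluded from the family. The effect-size trend
correlates the *per-resample* family-average ηp² against sample size — each
bootstrapped dataset contributes one point per family, which is what the
per-size spreads summarise; a `size_mean` aggregation (one point per size)
is provided for comparison, but with few sizes a hyperbolic ~1/N decline
cannot reach conventional significance from 6 points regardless of how
clear it is.

## Determinism

Every resample uses an independent substream keyed by `(seed, size index,
resample index)`; CI bootstraps key on `(seed, 10000 + size)`. Sweeps are
therefore bit-reproducible from (source CSV, config, seed), which the
manifest written next to every report directory records in full.

## Problem sizes

The shipped drivers and checks sweep N ∈ {30, 60, 120, 240, 480, 960} with
100 resamples per size — the published grid extends to N = 2000, but
results stabilise near N = 960, and the default grid keeps a full sweep in
tens of seconds. The full 16-size grid is the `ResampleConfig` default for
users who want it.

## Known limitations

* The generator's moments are stylised; absolute τ_b levels depend on the
  source population's shape, so only relative/structural claims (orderings,
  trends, null calibration) transfer.
* Only three injected-effect shapes, all CS+-only and non-negative; effects
  that alter CS- or reverse the differential are expressible via custom
  schedules but untested territory.
* The ANOVA engine targets balanced-to-±1 designs; it is not a general
  unbalanced GLM.
* No raw SCR trace processing: scored, non-negative amplitudes are the
  package's ground floor.
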