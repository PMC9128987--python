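# scrrobust

Robustness of fear-conditioning analysis strategies under bootstrap
resampling.

Human fear-conditioning studies index the same learning process — the
acquisition and extinction of conditioned skin-conductance responses (SCRs)
to a reinforced CS+ versus a safety-signal CS- — with a remarkable variety
of statistical recipes: different trial windows, trial-by-trial versus
averaged analysis, differential (CS+ − CS-) versus separate-stimulus models.
This package implements a simulation framework for asking whether those
recipes agree with each other, and whether bigger samples make them agree
more.

## What it computes

The unit of data is one participant's complete trial grid: 5 acquisition
trials plus 10 extinction trials (early/late blocks of 5), CS+ and CS- per
trial, responses in μS. The pipeline:

1. **Bootstrap** a dataset of N rows from a source population, by default
   *phase-wise*: each phase × stimulus block is resampled independently
   across participants, creating chimeric rows (a full-row mode is also
   provided).
2. **Allocate** three equal-but-random groups, so no group effect exists by
   construction — or **inject** one of three simulated group-level effects,
   adding trial-wise offsets (in per-trial SD units) to group 3's CS+ to
   mimic distinct conditioning/extinction trajectories.
3. **Evaluate** 15 published analytic strategies, each reduced to the
   partial eta squared ηp² = SS_effect / (SS_effect + SS_error) of its
   highest-order Group interaction from a balanced mixed-design ANOVA
   (between: Group; within: subsets of Phase, Trial, Stimulus).
4. **Quantify robustness**: for each pair of strategies within a family
   (acquisition→extinction, static extinction, extinction change), the
   Kendall τ_b rank correlation of their ηp² values across 100 bootstrap
   datasets, with 95% percentile CIs from 1,000 bootstrap draws; Pearson
   trend tests of τ_b against sample size (N = 30 … 2000) with
   Benjamini–Hochberg FDR control at Q = 0.1.

Because the pooled empirical sample the design calls for is not publicly
deposited, a synthetic generator stands in for it: differential acquisition,
CS+ decay across extinction, subject-level random intercepts, and
zero-floored normal noise (`max(0, a_i + μ(p,t,s) + ε)`).

## Worked example

```python
import numpy as np
from scrrobust import (GeneratorConfig, generate_null_population,
                       bootstrap_dataset, allocate_groups, evaluate_all)

source = generate_null_population(GeneratorConfig(seed=3))   # 379 rows
rng = np.random.default_rng(1)
boot = bootstrap_dataset(source, 30, "phase_wise", rng)
boot = boot.with_groups(allocate_groups(30, 3, rng))
for r in evaluate_all(boot)[:4]:
    print(r.strategy, round(r.eta_p2, 3))
```

```
ACQ_EXT.1 0.132
ACQ_EXT.2 0.078
ACQ_EXT.3 0.128
ACQ_EXT.4 0.115
```

Thirty participants and no group effect whatsoever — yet every
acquisition→extinction strategy reports what convention would call a
medium-to-large group "effect" (ηp² 0.08–0.13, all pure noise), and they
disagree with each other about its size. How consistently strategies rank
the same datasets, measured at scale via τ_b, is the package's object of
study.

The full analysis lives in `analysis/` as numbered drivers
(`01_generate_population.py` → `04_trends.py`); each prints what it found
and writes its tables under `results/`. Run them in order; on this build
they show mean within-family τ_b staying flat (~0.22–0.28) from N = 30 to
N = 960 on null data, family-dependent gains under injected effects (e.g.
extinction-change strategies rising to τ_b ≈ 0.61), and category-average
null ηp² falling from ~0.07–0.09 at N = 30 to ~0.002 at N = 960.

A `scrrobust` command-line interface wraps the same library
(`generate`, `inject`, `evaluate`, `sweep`, `trends`); every run writes a
manifest sufficient to reproduce its outputs byte-for-byte.

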