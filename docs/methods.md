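# Methods

This note documents the statistical procedures, the synthetic-data model, the
numerical conventions, and the design choices made where the design was
genuinely open.

## Data model and conventions

One bottle bioassay is a cumulative down/dead count on the fixed observation
schedule {0, 5, 10, 15, 30, …, 180} minutes; "down" pools knockdown and death
(a mosquito unable to right itself or fly), so a single monotone count per
bottle is the primitive observation. Escaped mosquitoes are represented as a
lower `n_introduced` at assay start — no imputation, no mid-assay correction.
One sentinel cage is a cumulative dead count at 0 h (pre-deployment), 0.5 h
(pick-up) and 12 h. All percentages live on the 0–100 scale; times are integer
minutes; transect distances integer feet. Per-record invariants (monotone
counts, counts within [0, n]) are enforced at construction; study-level
structure (matching solvent controls per strain, shared schedule, non-empty
units) is checked by `validate_dataset`, which reports rather than raises.
The standard protocol's 25-females-per-bottle cap is an optional
`max_introduced` protocol check there, not a hard type constraint, because
calibration analyses deliberately simulate much larger bottles.

## Mortality aggregation and Abbott's correction

Replicate aggregation is the **unweighted mean of per-bottle (per-cage)
percentages**, not pooled counts; the two differ only when escapes leave
slightly unequal n, and mean ± SE across replicates is what this assay's
displays report. SE uses the n−1 sample SD over replicates divided by √R, and
is reported as 0 for a single replicate. Abbott's correction
`100·(T − C)/(100 − C)` is applied per strain only when mean control mortality
is **strictly** above 3% (acetone bottles read at 180 min; control cages at
12 h), is clamped below at 0 (negative corrected mortality is not
interpretable), and returns T exactly when C = 0. Field summaries always carry
both raw and corrected means plus the trigger decision, because a reader
should be able to see whether correction was applied and what it changed.

## Diagnostic time and classification

The diagnostic time is computed from the **mean reference curve**: the
earliest scheduled time at which it equals 100%, which (since every per-bottle
percentage is ≤ 100) happens exactly when every reference mosquito is down.
No tolerance is applied: 100·k/n and means of such values are exact in
floating point when all bottles are complete, and any incomplete bottle keeps
the mean strictly below 100. If the reference never completes within 180 min
the assay is declared uninterpretable rather than classified. The CDC bands
leave (96, 97) unassigned for continuous percentages; "developing resistance"
here extends to all mortality < 97, preserving 97 as the susceptibility lower
bound and leaving no gap. Formal resistance inference is restricted to
technical-grade assays; formulated-product results are classified but flagged.

## Concordance statistic and bootstrap

RMSE is computed over all 15 schedule times including t = 0 (the protocol
compares "from 0 to 180 min"); excluding t = 0 is available as a sensitivity
option since mortality there is structurally 0. The bootstrap resampling unit
is the **independent experimental unit**: replicate bottles within each arm
and sentinel cages, drawn with replacement jointly each iteration, with the
field mean recomputed from the resampled cages because it is itself an
estimate. Arms are resampled independently — with identically distributed
arms the difference distribution is symmetric about zero, not degenerate. An
alternative unit resampling the 15 schedule time points (same draw applied to
both arms) is provided for sensitivity analysis. The default interval is the
2.5/97.5 percentile interval, the minimal non-parametric choice; a BCa
interval (bias correction from the bootstrap distribution, acceleration from
a grouped leave-one-unit-out jackknife across both arms and the cages) is
available. Significance is zero-exclusion of the 95% interval; no
multiple-testing correction is applied across panels. Every result records
its seed, resample count, CI method and resampling unit.

**Known limitation — small replicate counts.** With only 4 bottles per arm
and 9 cages (the study design), the percentile interval undercovers: measured
coverage of a true zero difference is ≈ 0.90 at 4 bottles/arm versus 0.950 at
10 bottles/arm and 0.956 at 20 (500 simulated datasets each, 1000 resamples).
This is the familiar small-cluster deficiency of percentile bootstrap
intervals, not an implementation artifact — the calibration test asserts
nominal coverage at 10 bottles/arm, where the interval's nominal claim is
meaningful. Significance calls from 4-replicate studies should be read with
this slight anti-conservatism in mind (BCa helps little at n = 4).

## Synthetic-data model

Per-mosquito knockdown times are log-logistic — CDF
`F(t) = 1/(1 + (t/kt50)^(−shape))` — sampled by inverse transform on the
closed-form quantile; the law has a heavy right tail that mimics the delayed
knockdown of formulated products, and a Weibull option (parameterized by the
same median) is provided. A refractory `immune_fraction` never goes down
within the assay, producing the flat sub-100% plateaus of resistant
populations; modelling plateaus with a very large KT50 instead was rejected
because observed plateaus are flat, not slowly rising. Spontaneous control
knockdown is an independent per-mosquito event (rate ≤ 3%) at a uniform time,
so the Abbott trigger is exercised on both sides of its threshold. Times are
censored onto the schedule as cumulative counts. Cage mortality is
`Binomial(n, efficacy)` at 12 h with the 0.5 h count a binomial thinning
(default early-death fraction 0.5 — roughly half of eventual deaths visible at
pick-up, a typical ULV pattern). Mosquitoes are independent within bottles; no
over-dispersion is modelled.

Design counts follow the study protocol: 4 replicate bottles of 25 females
(with a 15% per-bottle chance of one escapee, matching "on several occasions a
mosquito escaped") plus 4 acetone controls per strain × chemical, and 3 cages
of 20 females at each of 100/200/300 ft plus 3 controls per strain. The four
preset scenarios fix KT50/shape/immune parameters so the expected curves match
the published panels' anchors — susceptible references complete by their
diagnostic times (15–30 min pyrethroid, 30–90 min organophosphate), formulated
deltamethrin completes by 120 min while technical deltamethrin plateaus in the
80s, and the resistant malathion-chemistry arms plateau near 55% at 180 min —
with field efficacies 0.977/0.994/1.0/0.474 per panel. These presets are study
conditions, fixed once.

What the generator does **not** emulate: within-bottle correlation
(over-dispersion), weather- and distance-dependent spray deposition (cage
efficacy is one probability per strain × product, not per distance),
dose–response structure, or time-varying control mortality. Passing tests
therefore demonstrate correctness of the estimators and calibration of the
bootstrap under the stated model, not robustness to field heterogeneity.

## Problem sizes used in checks

Formula-level checks are exact or oracle-based (1000 random curves).
Expectation-level generator checks use 10⁵ draws (KS distance < 0.01 against
the closed-form CDF) and 1000-mosquito bottles (plateau recovery within
binomial error). Bootstrap calibration uses 500 independent datasets × 1000
resamples. Pipeline-level checks run the presets at the study design sizes.

## Reproduction of the published statistics

Recomputing the published per-bottle summary statistics (field means, RMSEs
43.35/62.67/…, bootstrap mean differences 19.31/2.51) requires the study's
supplementary raw tables, which are not redistributed with the package; the
reproduction test runs whenever those tables are placed under
`data/appendix_a/` in the package's CSV schemas. Two published values are
deliberately not treated as reproduction targets: the "adjusted" 57.6% field
mean (inconsistent with the stated no-trigger Abbott rule; both raw and
corrected values are surfaced instead) and the two CIs whose bounds are
inconsistent with their adjacent RMSE point differences (likely reported on a
squared-error scale); intervals here are always on the RMSE scale.
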