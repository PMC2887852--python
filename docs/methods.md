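# Methods

## Signal model and parameter definitions

Every ROI curve is a heartbeat-gated series: one sample per cardiac cycle
(RR = 60/HR seconds) of the ROI-averaged signal intensity, with `n_baseline`
pre-contrast frames at the start. All parameters are computed on the
baseline-corrected curve (mean of the pre-contrast frames subtracted).

**Contrast arrival (LV).** The acquisition gives no marker for bolus
arrival, so it is detected as the first frame at or after the baseline window
whose SI exceeds `baseline mean + k·SD` (sample SD of the baseline frames,
`k = 3` by default) *and* whose successor also exceeds it. The two-frame
confirmation rejects single-frame noise spikes; with a noise-free baseline
the criterion degenerates to the first sustained positive frame. This is the
standard robust bolus-arrival heuristic; `k` is configurable because the
optimal threshold scales with baseline SNR.

**Upslope.** An OLS line of SI on *recorded* time (so mild heart-rate drift
is handled without resampling) is fitted to every run of `w` consecutive
frames — `w = 5` for myocardium, `w = 3` for the LV, whose bolus is more
compact — and the maximum slope is returned. Windows may start no earlier
than `n_baseline − (w − 1)`: a fit may bridge the bolus foot but may not lie
wholly inside the baseline, where noise artifacts could win. Ties break to
the earliest window. The maximal sliding-window slope is the established
convention for this parameter family; an `anchored` mode (single window at
the detected foot) is provided as the alternative reading.

**Peak enhancement.** SImax is the maximum frame value from the search start
(the LV arrival frame, by default) to the end of the series; an optional
`first_pass_end` index excludes recirculation. Ties go to the earliest
frame. A maximum on the final searched frame raises a truncated-peak
warning rather than an error, since the true peak may lie beyond the
acquisition.

**Timing.** `T_SI50%max` is the time from LV arrival to the first crossing
of 50% of SImax, refined by linear interpolation between the straddling
frames (the curves are reported at 0.1-s precision, finer than the ~0.8-s
frame spacing; a frame-snapped mode is available). `T_SImax` is
frame-snapped by definition — the peak is an attribute of a sampled frame
and interpolation of a flat extremum is not meaningful. Beat-converted
times multiply by HR/60 using each patient's own adenosine heart rate; with
one image per slice per beat, a beat difference is exactly an image-count
difference, which is what a reader perceives.

**Normalization.** Relative upslope and relative SImax divide the myocardial
value by the mid-slice LV blood-pool value (×100). This cancels global gain,
coil and bolus-dose factors; it assumes the LV reference is positive, and a
nonpositive reference raises a degenerate-reference error rather than
returning a sign-flipped percentage.

## Territories, exclusion, pairing

Territories are explicit per-patient segment sets in the 16-segment model
(6 basal / 6 mid / 4 apical; no apex cap) because post-surgical coronary
anatomy does not follow a fixed atlas. Territory parameters are arithmetic
means over segments. LGE exclusion has two levels:

- `territory` (default): any LGE segment excludes the whole territory —
  matches whole-vessel exclusion accounting;
- `segment`: LGE segments are dropped and the rest averaged, requiring at
  least 2 clean segments (the minimum is a package choice; a single segment
  was judged too noisy to represent a territory).

Each graft territory is paired against the same patient's native reference —
the unbypassed native territory with the most LGE-free segments, ties broken
LAD > LCX > RCA for determinism. Patients without an analyzable native
territory are dropped from pairing with a logged reason; the run report
reconciles `analyzed = input − excluded` per category.

Differences are signed so that a graft that enhances less (lower upslope,
lower SImax) or later (longer T50/Tmax) is *negative*. The add-up score is
the sum of the three reference-normalized signed terms (upslope, SImax, T50;
timing negated). The fractional form makes the three dimensionally
incompatible parameters commensurate and gives score 0 for identical arms;
terms and weights are configurable because other compositions (absolute
differences, z-scores) are equally defensible.

## Statistics

Within-patient comparisons use the Wilcoxon signed-rank test, between-group
comparisons the Mann-Whitney U test, both two-sided. Exact p-values
(doubled-tail convention, `min(1, 2·min(P(T≤t), P(T≥t)))`) are computed by
full enumeration — all 2^n sign assignments up to n = 15 nonzero
differences; all group labellings up to a combined n = 12 — which remains
valid under ties, where tabulated null distributions do not. Larger samples
use the normal approximation with tie and continuity correction (delegated
to scipy). Zero differences are dropped before ranking; an all-zero
difference vector is reported as an undefined test, not p = 1. No
multiple-testing correction is applied in the primary tables (a Holm option
exists), mirroring how such clinical comparisons are conventionally
reported.

## Synthetic cohort generator

The generator emulates: gamma-variate LV and myocardial first-pass curves
(`A·((t−t0)/αβ)^α·exp(α−(t−t0)/β)`, normalized so the peak equals `A` at
`t0 + αβ`), heartbeat-gated sampling at RR = 60/HR, pre-contrast baseline
frames with additive Gaussian noise, a recirculation shoulder (same kernel,
scaled and delayed), and the cohort structure: 38 post-CABG patients with
one native territory (85% of patients) plus one or two grafts on disjoint
segments, and 20 no-CAD patients with three native territories. Key
defaults, chosen once to be physiologically plausible for this population
and acquisition:

| knob | default | rationale |
|---|---|---|
| HR under adenosine | 77 ± 11 bpm (CABG), 87 ± 13 (no-CAD) | hyperemic heart rates of the two groups |
| frames / baseline | 45 / 4 | covers the first pass at all simulated heart rates |
| LV bolus | A = 100 ± 10, α = 3, β = 1.6 s | compact ventricular bolus, ~5 s rise |
| myocardial kinetics | α = 6, β = 1.5 s ± 3%, amplitude ratio 0.24 ± 0.07 | relative SImax in the 20–30% range, relative upslope ~15–20% |
| native transit | 2.0 ± 0.3 s | LV-cavity-to-myocardium bolus transit under hyperemia |
| graft arrival delay | venous 0.31 ± 0.15 s, LIMA 0.62 ± 0.20 s | longer conduit path; LIMA longest (≈0.4 / 0.8 beats at 77 bpm) |
| patient kinetic factor | 1.0 ± 0.2 (shared within patient) | between-patient spread of timing parameters without touching within-patient contrasts |
| noise | SD 0.5 SI units | ROI-averaged curves are low-noise (peak myocardial SNR ≈ 50) |
| LGE probability | 0.03 per segment (CABG), 0 (no-CAD) | reproduces ~10% territory exclusion under the territory-level policy |
| second graft probability | 0.8 | ≈1.8 grafts/patient, ~69 graft territories per cohort |

Myocardial curves are delayed, widened, attenuated gamma-variates rather
than convolutions of the LV input with a residue function: timing and
amplitude extraction — what this pipeline measures — is fully exercised by
the direct parameterization, and perfusion quantification by deconvolution
is out of scope. SI is treated as linear in contrast concentration (no
saturation; the low-dose regime is the usual mitigation). Not modelled:
respiratory/cardiac motion, contour errors, arrhythmia, k-space effects.
Passing tests on this generator therefore demonstrate correctness of the
*analysis* under known kinetics, not robustness to image-domain artifacts.

All randomness flows from a single integer seed through one generator with
a fixed draw layout, so two specs differing only in a delay mean consume
identical random streams: delay sweeps are paired (common random numbers)
and per-seed monotonicity of the estimated delay is a meaningful check.

## Validation experiments and problem sizes

- **Oracle equivalence**: the vectorized sliding-window upslope agrees with
  per-window `numpy.polyfit` enumeration to < 1e-9 on 1,000 random curves;
  exact Wilcoxon/Mann-Whitney p-values match pure-Python enumeration of the
  null (and scipy's exact method on tie-free data) to < 1e-12 across
  hundreds of tied and continuous configurations with n ≤ 10.
- **Delay recovery**: injected graft delays of 0 / 0.2 / 0.6 s on cohorts of
  40 single-segment pairs, 20 seeds: the mean graft-minus-native Tmax
  recovers each level within 0.15 s and increases strictly with the
  injected delay in every seed.
- **Type-I control**: 1,000 null cohorts (no injected delay, 40 pairs): the
  paired Wilcoxon on Tmax rejects at the nominal 5% within 99% binomial
  bounds.
- **Qualitative concordance**: 50 default cohorts: significant positive
  graft beat-delay, LIMA > venous, and null amplitude parameters. The
  conjunction holds in roughly 80% of replicates; the three components
  individually hold in ~90–95%. The joint rate is capped near 0.90 by the
  two "no significant difference" requirements alone (each true null is
  declared non-significant 95% of the time), so the conjunction sits at the
  boundary whenever the delay effect size is realistic for this population
  (standardized effect ≈ 0.5, i.e. ~90–95% power at 46 pairs).

Sizes were chosen so the full suite runs in a few minutes on one CPU while
keeping every check at the scale stated above.

## Known limitations

- Arrival detection needs ≥ 2 baseline frames and a sustained rise; very
  slow wash-in with SNR near the threshold can push the detected arrival
  late, lengthening all timing parameters of that patient coherently (the
  LV origin is shared).
- Frame-snapped Tmax carries quantization noise of up to RR/2 per curve;
  territory averaging and pairing reduce but do not remove it.
- The LIMA-vs-venous class comparison averages within patient before
  pairing, so patients with many grafts of one kind are not up-weighted.
- The add-up score reconstruction is one of several defensible
  compositions; conclusions about "no add-up effect" should be checked
  against alternative term choices (supported via configuration).
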