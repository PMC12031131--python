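# Methods

This note records the models, conventions and design decisions behind
`kardia`, in the spirit of a statistical-software methods appendix: what
is computed, under which assumptions, with which defaults, and what the
synthetic validation does and does not establish.

## Input model and preprocessing

An RR series is a positive sequence of beat-to-beat intervals in
milliseconds; beat times are derived with the first beat at `t = 0` and
interval *k* spanning `(t_{k-1}, t_k]`.  Milliseconds are the canonical
unit throughout because the short-term HRV normative literature is
tabulated in ms/ms².  Unit auto-detection calls a file "seconds" when the
median raw value is below 10 — physiological RR is 0.3–2 s or
300–2000 ms, so the rule has no ambiguous zone.

**Segment selection.**  From a longer recording the analysis takes the
contiguous ~5-min stretch (default `duration_s = 300`) with the best
stability score, defined as the coefficient of variation of 30-s-block
mean RR within the candidate window; candidates start at every beat and
ties resolve to the earliest start.  Any monotone variance-style score
would serve; this one is fixed so runs are reproducible.

**Artifacts.**  A beat is flagged when it deviates from the local median
(11-beat centred window, shrunk at edges) by more than 20% — the common
automatic-editing heuristic, standing in for the visual inspection a
pipeline cannot do.  Flagged beats are replaced by cubic-spline
interpolation over beat index; a segment with ≥ 5% flagged beats is
refused rather than repaired, since heavy editing manufactures
variability.  No detrending is applied by default (smoothness-priors
style detrending is deliberately out of scope; the spectral step removes
per-segment means).

**Tachogram.**  Spectral analysis needs uniform sampling, so RR-vs-time
is cubic-spline interpolated onto a 4 Hz grid (comfortably above twice
the 0.4 Hz upper HF edge), spanning `[first beat, last beat]` with
exactly `floor(span·fs)` samples.

## Linear indices

Sample (N−1) denominators for SDNN; RMSSD is the root mean square over
the N−1 successive differences; NN50 counts strict exceedances of 50 ms.
The triangular index divides the beat count by the modal bin height of
the RR histogram with bins anchored at multiples of 1/128 s (7.8125 ms).
Welch band powers use 150-s Hann segments with 50% overlap, per-segment
mean removal and density scaling, integrated by the trapezoidal rule over
VLF [0.0033, 0.04), LF [0.04, 0.15) and HF [0.15, 0.4) Hz; total power is
their sum, and LF/HF is reported as NaN (not infinity, not an exception)
when HF is zero, so degenerate synthetic inputs flow through the
pipeline.  Whether VLF starts at 0 or 0.0033 Hz differs between
software packages; the lower edge here is explicit and configurable.
Poincaré axes come from the lag-1 return map: `SD1² = var(ΔRR)/2`,
`SD2² = 2·SDNN² − SD1²` floored at zero; under these definitions
`SD1² + SD2² = 2·SDNN²` identically whenever the floor is inactive.

## Correlation dimension

Delay embedding with `m = 10`, `τ = 1` beat (the short-term HRV
convention), Euclidean norm, Theiler window `w = m·τ` to exclude
temporally adjacent pairs.  The correlation integral is

    C(r) = (2/P) · #{(j,k) : k−j > w, ‖u_j − u_k‖ < r},
    P = (N_v − w)(N_v − w − 1),

evaluated on 30 log-spaced radii spanning `[0.05σ, 2.5σ]` where σ is the
SD of embedded-vector components — σ-scaling makes the estimate invariant
under affine rescaling of the series.  The implementation is verified
*exactly* (integer pair counts) against a literal O(N²) double loop.

**Slope fit.**  Local slopes of log C vs log r come from centred finite
differences over the usable curve: points with C > 0, below the
saturation level C = 0.9 (where log C flattens toward 0), and with at
least 10 counted pairs.  The scaling region is a contiguous run of ≥ 5
points chosen by the *relative* dispersion of its local slopes
(`var/mean²`; runs with non-positive mean slope are excluded), and among
runs scoring within a factor 2 of the best, the one ending at the largest
radius wins.  Two failure modes motivated these choices over a plain
minimum-variance rule: (i) periodic attractors produce lacunarity steps —
flat stretches of C(r) whose slopes are ≈ 0 with near-zero variance but
carry no scaling information; (ii) with measurement noise the small-r
end of the curve follows the noise, not the attractor, so among
equivalent candidates the region above the noise floor is the right one.
D2 is the least-squares slope over the selected run, clipped to
`[0, m]` — values above the embedding dimension are estimation artifacts.
If no usable run exists the flag `no_plateau` is set and a mid-half
global fit is reported (the correct diagnosis for broadband noise); a
(near-)constant series is a single-point attractor and reports D2 = 0
with the `degenerate` flag — a value the pipeline must tolerate, since
real patient cohorts contain such recordings.

Exact numerical agreement with any particular commercial implementation
is not claimed; the contract is internal-oracle equivalence plus correct
dimensions for attractors of known dimension (limit cycle ≈ 1, 2-torus
≈ 2, noise ≫ 3 in an m = 10 embedding).

## HRV grade

The grade counts abnormal values among SDNN, RMSSD and total power
against a normative table: 0 = none, 3 = all three.  The default
direction is `low_only` (reduced variability is the screening target); a
`two_sided` mode checks the full range and requires upper limits.  Values
exactly equal to a limit count as normal — a deterministic tie rule.  The
packaged table carries the published short-term 95% ranges for SDNN
(32–93 ms) and RMSSD (19–75 ms); no pooled short-term norm of comparable
standing exists for total power, so its packaged lower limit (500 ms²)
is an explicitly labelled package approximation and the table is designed
to be overridden per site (`load_normative_table` merges named limits
only).  Hard-coding an invented cutoff as canonical would fabricate data;
shipping a sourced, editable config is the honest alternative.

## Cohort statistics

Descriptives use sample SD/variance, `se = sd/√n`, and adjusted
Fisher–Pearson skewness (constant samples report skewness 0 with a
degenerate flag).  Normality is gated by Shapiro–Wilk (delegated to
scipy; the contract is the standard statistic).  The group contrast is
Mann–Whitney U, reported as `min(U_x, U_y)` with a two-tailed p — exact
by full enumeration of labelings when `n ≤ 20` without ties, otherwise
the tie-corrected normal approximation with continuity correction.  The
exact path is tested exhaustively against an independent enumeration for
all splits with `n ≤ 12`.

Correlation matrices are Spearman (Pearson on midranks) and Pearson,
with covariates (age by default) partialed out by least-squares
residualization of both variables — and, for Spearman, of the ranked
covariates — with p from the t transform at `n − 2 − k` df.  Variables
fully explained by the covariates report a partial coefficient of 0.
Correlations are computed in the patient group only by default (the
between-group contrast would otherwise masquerade as correlation), with
an all-subjects switch.  The significance filter is strict `p < α` at
`α = 0.001` with no further multiple-testing correction; an FDR switch
exists but defaults off to mirror the strict-α convention of the
clinical protocol this pipeline follows.

Post-hoc power: Cohen's d from the pooled SD, noncentrality
`d·√(n₁n₂/(n₁+n₂))`, two-tailed power under the noncentral t with
`n₁+n₂−2` df (method `t_noncentral`; a `mw_are` variant scales the
effective n by the rank test's 0.955 asymptotic relative efficiency).
The unequal group sizes are taken from the data as given.  With the
published per-group D2 statistics (2.54 ± 1.23, n = 39 vs 1.71 ± 1.33,
n = 85) this reproduces the ≈ 91% achieved-power figure.

## Synthetic cohort

The generator emulates what the pipeline consumes — beat times, not
tachograms — via IPFM: a beat fires each time the integrated modulated
rate `(1 + m(t))/T` crosses an integer (trapezoidal integration at 5 ms
steps, linear interpolation of crossings).  `m(t)` combines an LF
oscillator (0.1 Hz), an HF oscillator (0.25 Hz) and broadband noise
(white by default, 1/f optional) on a 2 Hz grid; the invariant
`a_lf + a_hf + 3·noise_sd < 1` keeps the rate positive.  Recordings are
330 s so segment selection has headroom over the 300-s analysis window.

Per-subject parameters are drawn from group profiles through a single
latent "autonomic richness" `u ~ U(0,1)` that co-scales the oscillator
amplitudes and the noise level (±15% independent jitter on top).  This
coupling is what produces the observed within-patient pattern of D2
rising and falling together with the linear indices.  The default
profiles encode the study contrast: HC with rich two-oscillator
modulation plus noise (higher SDNN/RMSSD/powers, D2 mostly 2–5), FM
dominated by a weak, near-periodic single component (reduced indices, D2
near 1, occasionally degenerate).  The noise-to-modulation ratio is the
main D2 dial; the ranges were fixed once so the standardized group
difference in D2 is ≈ 0.65 on the scale of the published group means and
SDs, and then frozen.  Ages are drawn normal (HC 47.7 ± 12.3, FM
50.8 ± 11.8 years, clipped to 20–80).

Clinical covariates are attached afterwards by a Gaussian copula
calibrated against the *realized* HRV indices: anchor variables (d2,
grade) are converted to normal scores via midranks; each generated
variable's latent is a linear combination of its parents' scores plus
independent noise, with coefficients solving the target correlations
(Spearman targets converted to latent Pearson via `2·sin(πρ/6)`) and an
infeasibility error naming the offending pair when the residual variance
would go negative.  Monotone scale mappings (FIQ → [0,100], NRS →
integers 0–10, SF-36 PHI → [0,100], …) preserve the rank correlations.
Default targets: FIQ vs D2 −0.4567, FIQ vs grade +0.5058, FIQ vs NRS
+0.6976, FIQ vs SF-36 PHI −0.5720, plus moderate links to the remaining
scales.  Integer rounding (NRS, WPI, SS) introduces ties that attenuate
realized coefficients by a few hundredths; at n = 85 sampling noise of
±0.1 on a rho is expected.

Determinism: per-subject seeds derive from `SeedSequence(master,
spawn_key=(index,))`, so cohorts are bit-reproducible and independent of
generation order; the clinical copula uses `master + 1`.

**What passing tests show — and don't.**  The synthetic cohort
demonstrates that the pipeline recovers a designed group contrast,
rank-correlation structure and power relationship end-to-end.  It does
not validate clinical cutoffs, capture respiratory sinus arrhythmia
dynamics beyond a fixed-frequency oscillator, ectopy, circadian
nonstationarity, or the true joint distribution of clinical scales; FM
profile parameters are a synthetic stand-in tuned only to the direction
and approximate effect size of the published group contrast, not to its
absolute levels.

## Problem sizes and numerical choices

Default runs analyze 124 subjects (39 HC / 85 FM) of ~380 beats each;
the replicate study uses 20 cohorts.  These sizes were chosen to match
the study design while keeping a full replicate battery in the
minutes range on a single core.  Degenerate inputs are handled by
explicit flags rather than exceptions wherever a real cohort could
produce them (constant series, zero HF power, all-tied samples).  The
exact Mann–Whitney path refuses ties instead of silently switching
conventions; `auto` mode falls back to the corrected normal
approximation.  All report tables serialize with fixed float formats and
sorted keys so identical runs are byte-identical.

## Known limitations

* D2 on ~380-beat series is a coarse estimate; a 2-torus needs ≳ 1000
  beats to read as 2.  Short-segment estimates are best interpreted
  comparatively (between groups under identical settings), which is how
  the pipeline uses them.
* The grade's total-power limit is a documented approximation pending
  site norms.
* Partial Spearman via rank residualization is a convention, not the
  only one; it is stated in the report metadata.
* The IPFM model has no baroreflex closed loop; LF/HF structure is
  imposed, not emergent.
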