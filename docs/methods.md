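# Methods

This note documents the models, estimators, numerical choices, and known
limits of `hemitrace`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Signal model

A whole-cell sweep is modelled as

    i(t) = sum_k (delta_k / 2) * (1 + erf((t - t_k) / B_k))  +  d(t)  +  e(t)

where each gating transition *k* is an erf-shaped edge with signed step
`delta_k` (pA), center `t_k`, and time constant `B_k` (bounded by the 300 ms
maximum transition time); `d(t)` is slow baseline drift from one of four
families (linear, single exponential, double exponential, logarithmic); and
`e(t)` is i.i.d. Gaussian noise. Unitary conductance is γ = Δi / V_m
(pA/mV → nS, reported in pS). Noise is specified as a conductance-equivalent
SD (default 30 pS) so one configuration serves all step potentials.

The analysis makes no assumption about channel kinetics or conductance
levels beyond this edge model: it is segmentation-based, not a hidden-Markov
idealization.

## The simulator

`SimulationConfig` defaults describe a control-condition sweep: 30 s at
4 kHz, +70 mV, one channel, states 217 ± 66 pS (fully open) and 80 ± 28 pS
(substate, 5.3% of events), edge time constants exponential with mean
5.2 ms truncated at 300 ms, 30 pS noise. Preset constructors describe the
two contrast conditions: `gap19()` (sparser gating at ~5.8 transitions per
30 s, 34.7% substate) and `egfp()` (≈91% of control activity, 13.9 ms mean
edge time constant). Control rates are tuned once to ≈14.5 transitions per
30 s trace.

Gating schedule: opening attempts are a Poisson process per channel
(default 0.36 /s), accepted only while the channel is closed and at least
`min_dwell` after the previous transition; the open sojourn is
`min_dwell + Exp(dwell_mean − min_dwell)` (defaults 0.35 s + Exp(0.65 s)).
The minimum sojourn is a consistency requirement of the signal model, not a
biological claim: edges may take up to 300 ms, so shorter sojourns would
not be completed, resolvable transitions (and the 0.3 s median window would
erase them regardless of detector settings). No dwell-time model is implied
beyond this; the simulator's sojourn law is an explicit stand-in, and the
package deliberately computes no dwell-time statistics.

Events are kept 0.5 s clear of the sweep ends. Per-trace seeds derive from
one master seed via `numpy` `SeedSequence` spawning, so cohorts are
bit-reproducible.

What the simulator does **not** emulate: amplifier/Bessel frequency
response, capacitive transients, seal-leak physics, 1/f or correlated
noise, open-channel excess noise, and flicker/sub-edge gating. Passing
tests therefore demonstrate correctness of the analysis under its own
signal model, not robustness to every artifact of real recordings.

## Filtering

**Median filter** — centered running window (default `T_MF` = 0.3 s, the
slowest observed transition). Edge policy: windows shrink at the trace ends
(no fabricated samples); even-length windows use the midpoint of the two
central order statistics. Implementation: pandas rolling median (skiplist,
O(n log w)).

**TVD** — minimizes ½Σ(yᵢ−xᵢ)² + λΣ|xᵢ₊₁−xᵢ|. The production solver is a
majorization–minimization iteration (banded tridiagonal solve per step,
default 30 iterations, optional tolerance-based early exit); an exact,
non-iterative direct solver (Condat's algorithm, equivalent to the
taut-string construction) is included and is the reference the MM path is
validated against (which is itself cross-checked against the dual
box-constrained least-squares formulation on small inputs). A small floor
(1e−10 × signal range) on |Δx| keeps the reweighting nonsingular.

λ is in pA·sample units and is scale dependent. The default is
noise-adaptive: λ = 25 × the robust per-sample noise SD (median absolute
first difference / (0.6745·√2)), ≈ 50 pA·sample at 30 pS noise and +70 mV.
An absolute λ tuned to a particular digitizer scaling does not transfer
across acquisition setups, which is why the package does not hard-code one;
both λ and the iteration count are exposed (`--lambda`, `--tvd-iters`).

## Detection

The "derivative" of the median-filtered trace is operationalized as a
lagged difference `D[i] = m[i+L] − m[i−L]` with span 2L = `T_MF`: it reads
out the full level change of a step while slow drift contributes only
slope × `T_MF`, far below threshold — drifting baselines cannot fire the
detector. A candidate is raised per contiguous super-threshold
constant-sign region, placed at the steepest point (plateau midpoint for
clean steps); same-direction candidates within `min_separation`
(default `T_MF`/2) merge, keeping the larger. The default threshold is
60 pS = 2 × the 30 pS background-noise SD. Openings are positive-going at
positive V_m; the sign convention flips with V_m and direction is always
stored explicitly.

Refinement searches ±300 ms around each candidate for the
maximum-magnitude, sign-consistent first difference of the TVD trace; an
unrefinable candidate keeps its approximate time, with a warning.

**Two-tier thresholding.** The 60 pS threshold serves the initial passes
whose purpose is isolating the baseline. Once the drift is removed, the
detector's false-positive rate is governed by the noise of the lagged
median difference (≈1.6 pS at default settings), so smaller transitions
are reliably resolvable; a final detection pass on the corrected trace
runs at `final_threshold_ps` (default 30 pS, the background-noise SD) so
sub-60 pS events appear in the finalized analysis. Set it to `None` to
disable the extra pass.

## Transition fitting

Each transition is fitted with A·erf((t−t_c)/B) + C over ±150 ms by
bounded nonlinear least squares. Initial values: A = half the level
difference across the window, B = 1 ms (with 10 and 50 ms restarts),
C = the pre-edge mean; bounds 0 < B ≤ 0.3 s. The center t_c is fitted,
bounded ±50 ms around the refined time: freezing it at the sample grid
would bias B for edges faster than a sample period. a_trans = 2|A|;
tc_trans = B; direction is carried by the sign of A, B is constrained
positive. Windows shrink to the midpoint toward any neighboring
transition; events closer than 20 samples are fitted jointly as a sum of
two erf terms to prevent amplitude cross-contamination. Non-convergence
after the restarts flags the fit: amplitude falls back to the level
difference, tc is reported missing (NaN). C is fitted rather than frozen
at the local baseline mean; that mean is its initial guess.

Edges with tc below the sample period (250 µs at 4 kHz) are not
identifiable in B; they are reported at the scale of the sample period,
which matters only below the first bin of the tc histograms.

## Baseline correction

The idealized trace is the cumulative sum of signed fitted steps rendered
as erf edges (using each event's fitted B, so the residual near edges is
unbiased). Raw − idealized is fitted with all four drift families by
nonlinear least squares (long records decimated to ≤8000 points; drift is
smooth on the seconds scale, so decimation does not move the
coefficients); the winner is the lowest AIC, with every converged family
retained for inspection and a user override available. Initialization:
exponential amplitudes from the residual range, time constants at span/3
(span/6 and span/2 for the double exponential); the log family's `c`
starts at one sample period to keep its argument positive, bounded
positive. If every family fails, a constant (mean) baseline is used, with
a warning.

The corrected trace is re-detected and re-fitted; the loop repeats until
the event set is unchanged between cycles (same count, directions, times
within 2 samples) or 5 cycles, then the final low-threshold pass runs. The
last step of `analyze_trace` recomputes baseline, corrected trace, and
summary as a pure function of (raw trace, event list, config); the manual
edit operations use the same mapping, which is what makes
add-then-remove an exact identity and audit-log replay exact.

## Gating metrics

NPo uses the half-way discriminator: threshold = 0.5 × the fully open
level (default open level: the main-component mean, 217 pS, times |V_m|;
user-overridable). Time above the threshold counts ≥1 open channel; each
further open-level of current adds one (nominal stacked-channel
semantics). Excursions shorter than 1 ms are discarded as noise, so a flat
noisy trace scores exactly 0. An open level within 3× the noise SD flags
NPo unreliable. Levels lying close to the discriminator exchange time
across it with the noise; that is a property of the threshold rule itself.

Transition counts are tallied per state class by the 1-SD interval rule
(an event belongs to the component whose mean ± SD contains its
conductance; ambiguity resolved by nearest mean in SD units; no interval →
unclassified) and normalized to the nominal 30 s window for comparability.

## Distribution statistics

Conductance histograms (10 pS bins, max-normalized, mirroring how such
distributions are displayed) are fitted with 1 or 2 Gaussians by least
squares; a maximum-likelihood mixture mode (scikit-learn) is the
cross-check. Degenerate samples flag the component with SD floored at the
bin width. The substate share is AUC_sub/(AUC_full + AUC_sub); when a
reference condition shows no separate substate peak, the test condition's
substate Gaussian is rescaled (amplitude only, mean and SD fixed) onto the
reference histogram within its ±1 SD range to estimate the buried
contribution, flagged as a template estimate.

tc distributions: mono vs biexponential is decided by a likelihood-ratio
test on the raw samples (mono fitted by the sample mean, the two-component
mixture by EM; χ², 2 df, 5% level). AIC was rejected for this decision
because it overselects the biexponential on mono-generated data; the LRT
keeps the mono-selection error at its nominal level while retaining power
for genuinely biexponential samples. Parameters are then reported from the
requested estimator: histogram least squares (2 ms bins) by default, or
raw-sample maximum likelihood (`mle=True`), which has markedly lower
sampling variance at cohort-scale event counts and is what the
reproduction script uses for the kinetics quantities.

A practical limit worth knowing: decomposing two overlapping Gaussians
(80 ± 28 vs 217 ± 66 pS) from a few hundred events leaves the substate SD
with large sampling spread whichever estimator is used — component means
are robust, component SDs from small two-component fits should be read
with that spread in mind.

## Problem sizes

The validation suite simulates desk-scale cohorts: 15 control traces and
100 substate-enriched traces of 30 s at 4 kHz for conductance recovery,
12 traces for detection sensitivity/precision, and event-count-scale
samples (515–1656) for kinetics recovery; the reproduction script uses the
same sizes. These sizes were chosen so that estimator sampling spread sits
inside the validation tolerances (checked on generative draws alone) while
keeping the full run to minutes on one CPU.

## Known limitations

- Events with below-threshold amplitudes at the final pass (< 30 pS by
  default) never enter the automated result; they remain reachable through
  the manual-edit API.
- Overlapping events closer than the joint-fit window can still bias each
  other's amplitudes; the simulator's minimum sojourn keeps this rare in
  validation, real flickery channels would hit it more often.
- NPo near-threshold behavior (levels within ~2 noise SD of the
  discriminator) trades time across the threshold; no correction is
  attempted.
- The reanalysis loop has no proof of convergence; it stops at 5 cycles
  and flags non-convergence.
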