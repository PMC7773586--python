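# Methods

## The observable and the clock

The quantity analyzed throughout is the background-subtracted fluorescence
intensity of a tagged protein in a fixed box at the bud neck, sampled at
1-min intervals, together with (for ring components) the diameter of the
contractile ring seen edge-on as two diffraction-limited puncta. Cells are
asynchronous, so every cell is re-timed to its own clock: the frame at which
the anaphase spindle (tubulin channel) breaks, defined as t = 0. All times
below are minutes relative to spindle breakage; intensities are arbitrary
units; lengths are μm.

## Synthetic data model

**Template curves.** Each protein's noise-free accumulation curve is a
baseline plus a sum of asymmetric Gaussian bumps, each with a peak time μ,
amplitude A, and separate rise/fall widths σ_L, σ_R. This form is smooth,
has few parameters, makes the peak time an explicit parameter, and
reproduces asymmetries such as Cyk3's attenuated rise and slow fall. The
packaged panel (`data/panel.yaml`) holds 25 proteins in six modules
(actomyosin ring, vesicle transport, primary septum, secondary septum,
septum maturation, temporal coordination). Peak, arrival and departure times
are the published values where published (e.g., Hof1 at −5/−1/+6, Chs2 at
+2, Chs3/Chs4 at +4, Cts1 arriving +5 and peaking +25); where unpublished,
values are fixed once and flagged `decision` in the per-field provenance
block (e.g., Kre6 at +10, between secondary-septum formation and
primary-septum degradation; Crh1 at +12, slightly later; Myo2/Exo84/Abp1
arrivals at −7/−6/−6 following Bni1 at −8). Amplitudes and widths are always
shape decisions; widths were chosen so that each mean curve has a peak
defined to ±1 min at the default noise (a perfectly flat plateau has no
meaningful argmax). The septin (Cdc3) template is the one calibrated entry:
its double-ring bump amplitude was solved once so that the expected mean
curve (template convolved with the default timing jitter) drops exactly
22.6% between −6 and −1 min, the published hourglass-to-double-ring loss.

**Per-cell traces.** A cell's trace is the template evaluated at t + δ with
δ ~ N(0, jitter_sd), times (1 + ε_t) with ε_t ~ N(0, noise_cv) per frame.
Defaults: jitter_sd = 0.75 min (cell-to-cell timing spread below the 1-min
frame interval, consistent with the tight cross-strain alignment of the
ring-marker curves), noise_cv = 0.05 (a realistic ROI-sum measurement error
for a GFP signal of this brightness).

**Constriction.** Ring diameter is d₀ until onset (−6 min), then declines
linearly at the slow rate until the slow-phase drop is spent, then at the
fast rate until the ring is gone, then 0. Per-cell slow/fast rates and
per-phase drops are sampled independently from positive-truncated normals
around the published statistics (0.02 ± 0.02 and 0.18 ± 0.05 μm/min;
0.10 ± 0.07 and 0.92 ± 0.11 μm); phase durations are drop/rate and
d₀ = slow_drop + fast_drop. Sampling both rates and drops preserves the
published rate statistics *and* contribution statistics; the published mean
phase window is then derived, not imposed (zero-variance defaults give a
breakpoint at −1 min). The truncated normals are *moment-matched*: the
location of the underlying normal is solved so the truncated mean equals the
target mean. Plain rejection sampling would inflate the slow-rate ensemble
mean by ~29%; the price of matching the mean is a realized slow-rate SD of
≈0.014 instead of the nominal 0.02 (the other three parameters sit far from
the bound and match both moments). Measured diameters carry additive
Gaussian noise, default 0.01 μm — the localization precision of sub-pixel
Gaussian fitting on a bright ring marker. Ring-marker proteins (Myo1, Mlc2)
couple intensity to ring length: after onset the intensity is the onset
value scaled by d(t)/d₀, reproducing the tight intensity–diameter
correlation that justifies using ring-marker intensity as a constriction
readout.

**Conditions.** Perturbation parameters are the published *measured* ratios,
so `apply_condition` inverts the measurement model: the amplitude factor is
enforced on the raw peak value, and the rate factor on the maximal 5-min
rising slope by numerically solving for a rise-width stretch (a naive 1/r
width scaling does not reproduce windowed slope ratios). Peak shifts are
additive. Latrunculin-A cells do not constrict and disassemble linearly from
the peak; cyk3Δ scales the fast constriction rate by 0.6.

**Movies.** A cell is rendered as two 2-D Gaussian puncta (PSF σ = 0.15 μm)
separated by d(t) along the neck axis, total flux equal to the driving
trace; the spindle is a line along the mother–bud axis that elongates from
1.2 to 4.6 μm through anaphase and splits into two shrinking halves at the
true breakage frame. Default scene: 64×64 px at 0.1 μm/px, 91 frames at
1-min intervals spanning −45…+45 min, constant background 100 counts/px,
gain 50 photons per intensity unit, Poisson photon noise plus Gaussian read
noise (σ = 2). One top-level seed determines everything; per-cell streams
derive from (seed, protein index, cell index). Every simulated cell writes a
ground-truth row (jitter, sampled rates/drops, breakpoint, condition
factors) for recovery scoring.

**What the generator does not emulate.** No photobleaching, no cell
segmentation or tracking errors, no z-dimension or focus drift, no
autofluorescence structure, no correlated biological noise between proteins
of one cell (each trace is an independent cell). Passing recovery tests
therefore demonstrates the correctness and calibration of the analysis
chain, not robustness to every artifact of real microscopy.

## Quantification

ROI intensity is the sum over an axis-aligned neck box of pixel values minus
the median of a 2-px concentric margin ring, clipped at zero per pixel —
invariant to adding a constant to the image and equivariant to scaling. Ring
diameter comes from the intensity profile along the neck axis through the
ROI center: a two-Gaussian (shared width) plus constant model is accepted
over the one-Gaussian model only if it lowers the residual SSE by ≥ 20%;
otherwise the puncta are unresolved and the diameter is 0, with the single
punctum position retained as the midpoint. Three noise gates precede model
selection — profile amplitude ≥ 6 estimated noise SDs (successive-difference
estimator on integer-pixel samples), one-peak SSE improvement ≥ 25 σ², and
each fitted punctum amplitude ≥ 3 σ — because without them pure-background
and dim frames yield hallucinated two-punctum fits. Spindle breakage is
detected on frames smoothed with a 1-px Gaussian and thresholded at
background + half the above-background maximum: once a component ≥ 1.5 μm
has persisted for 3 frames, breakage is the first frame where the largest
component falls below 50% of its running maximum, or two components ≥ 25%
of it appear, or none remains. Constriction symmetry is the maximal
displacement of the puncta midpoint from its initial position, normalized by
the initial radius (threshold 0.25 for the asymmetric call).

## Alignment and aggregation

Traces are shifted by −t₀ and linearly interpolated onto the −45…+45 min
grid; points outside the observed interval are missing, never extrapolated.
Aggregation is the per-gridpoint mean and sample SD (ddof = 1) over
non-missing cells, masked where fewer than n_min = 10 cells contribute.
Normalization (peak-to-1, optional baseline subtraction) is an explicit
post-step; Pearson correlations are affine-invariant, so it does not affect
the similarity analysis.

## Signature extraction and comparisons

Mean curves are smoothed with a centered window-3 moving average; peaks are
local maxima with prominence ≥ 10% of the curve range and separation ≥ 3
min, each refined to the local argmax of the unsmoothed curve (so a
noiseless unimodal curve peaks exactly at its argmax). Arrival/departure are
the first/last crossings of baseline + 15% of (peak − baseline), baseline
being the mean of the first five unmasked points. Condition comparisons
report, relative to control: raw peak-value ratio, primary-peak shift,
maximal 5-min rising-slope ratio, and above-baseline area ratio — all on
mean curves (whether the original measurements were per-cell is not
recoverable; mean curves are the documented choice).

## Biphasic constriction fit

The constriction window starts at the last gridpoint before the smoothed
diameter stays below the plateau by more than a noise margin
(2.5 estimated SDs of the smoothed trace, at least 1% of the plateau) for
two consecutive frames, where the plateau is the median diameter over frames
at ≥ 95% of the maximum; it ends where the diameter first reaches the
resolution floor (0.05 μm). Traces that never reach the floor are flagged
incomplete and excluded from ensemble summaries (a cell that has not
finished constriction has no measurable phase contributions); zero-slow-rate
fits are excluded from the fold ratio, with logged counts. Within the
window, for every interior gridpoint candidate t_b the continuous
two-segment line with non-positive slopes is fitted by exact least squares
(active-set enumeration over the two slope constraints — direct, not
iterative); the candidate with minimal SSE wins and ties resolve to the
earliest t_b, which favors detecting the slow phase. Slopes are constrained
non-positive because a constricting ring cannot grow; the breakpoint is
restricted to grid candidates because 1-min sampling does not support
sub-frame refinement. The slow-phase drop is plateau − fit(t_b) — the slow
segment extrapolated back to the pre-constriction diameter — and the
fast-phase drop is the fitted decline to the window end, so the two drops
sum exactly to the fitted total and the reported onset is where the slow
line meets the plateau (on noiseless data this recovers the true onset
exactly; a fixed 95%-of-d₀ window start would systematically swallow half
of a 0.10 μm slow phase and bias the fast-phase contribution upward).

## Similarity analysis

Pairwise Pearson correlation of mean curves over −20…+30 min (covering all
panel events except the earliest arrivals; configurable), pairwise-complete
with a minimum overlap of 15 gridpoints; zero-variance curves are masked
with a warning. Ranking is by descending r with ties broken by peak-time
distance, then protein id. Module assignment maximizes the mean r against
each module's reference curves and reports the nearest-peak-time module
alongside, flagging disagreement.

## Numerical and testing notes

Problem sizes follow the study design: 30 cells per protein and condition
(the per-strain n is not published; 30 is typical for this kind of
time-lapse panel), 91-frame movies, 25-protein panels. The test suite checks
exact identities (noiseless recovery, conservation, invariances at 1e-9 to
1e-12), oracle equivalence of the changepoint fit against an independent
NNLS enumeration (1e-9), and stochastic recovery at the defaults (rates
within 20%, fast-phase contribution within 3 points of 90.4%, averaged over
ten independent 30-cell ensembles so the check reflects estimator accuracy
rather than single-draw Monte-Carlo scatter; peak times within 1 min;
Kre6–Crh1 rank-1 in ≥ 18/20 panels). Seed-to-seed scatter of the 30-cell
septin-drop estimate is ≈ 1.2 percentage points around 22.2; occasional
draws fall outside ±2 points of the calibrated 22.6.

## Known limitations

Sub-minute breakpoints are quantized to the grid, which biases the fast
rate downward by ~4–6% at default noise. Slow phases with drops below the
diameter noise floor are unresolvable per cell. The below-resolution
diameter convention (0 μm) is a downstream convenience, not an estimate.
The renderer draws the division site only — no whole-cell context — so
segmentation-dependent errors are out of scope.
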