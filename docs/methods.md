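# Methods

This note documents the signal model, the statistic, the parameter choices
that matter, and what the synthetic scenes do and do not establish.

## Signal model and radar geometry

The radar is a bistatic impulse UWB system: 2048 fast-time samples span a
60 ns record, so each fast-time row maps to range via r = c·τ/2 (two-way
propagation, 9 m unambiguous range, native row spacing ~4.4 mm).  Slow
time is sampled at 64 Hz.  The probe pulse has a 500 MHz −3 dB bandwidth;
modelling its power spectrum as Gaussian and taking the conjugate
time-domain envelope gives a range-domain blur of σ_r ≈ 0.08 m, which is
how the simulator smears every reflector.

A breathing person is modelled as a band of reflectivity of extent
`body_thickness_m` (default 0.45 m — the effective reflecting extent of a
torso with clothing and limb scatter; entropy-pit extents measured on real
profiles run 0.40–0.54 m) whose echo amplitude is modulated sinusoidally
at the breathing rate along slow time, scaled by 1/r² propagation loss.
Chest-displacement phase modulation is deliberately simplified to
amplitude modulation: the entropy statistic only consumes the slow-time
spectrum's order, not its modulation mechanics.

Shadowing is a hard cone: a target strictly behind another whose bearing
differs by at most `shadow_half_angle_deg` (default 20°, boundary
inclusive) has its amplitude multiplied by `shadow_atten` ∈ (0, 1].  The
attenuation is a free scene parameter — no physical value is asserted —
and the canned experiment scenes set it per geometry (below).

Multipath "trailing" is a ground-bounce replica of the target's breathing
modulation occupying `trail_length_m` (1.0 m) behind the torso, displaced
by a path-length excess `trail_gap_m` (0.4 m), at `trail_amp_frac` (0.18)
of the target amplitude.  Static wall clutter is a slow-time-constant
random profile over 0–1 m.  Receiver noise is white Gaussian.

## Pre-processing

1. **Distance accumulation**: the 2048 rows are summed (not averaged) into
   200 contiguous blocks — 152 of 10 rows and 48 of 11, evenly interleaved
   — conserving the total sample sum and the absolute energy of weak
   targets.  Bin width 45 mm.
2. **Clutter removal**: each row minus its centered sliding mean (window
   100 samples ≈ 1.56 s; 2·50+1 = 101 points in the interior, truncated
   symmetrically at the edges so no data is fabricated).  A slow-time
   constant row maps to zero exactly.  Note the side effect: the window is
   short relative to a 4 s breathing period, so the subtraction passes a
   substantial fraction of the respiration line into the removed mean —
   a 0.25 Hz tone keeps only |1 − H_MA(0.25)|² ≈ 5 % of its energy (the
   moving-average frequency response H_MA ≈ 0.77 there).  The statistic
   tolerates this because it is amplitude-invariant.  The same high-pass
   action depletes the lowest octave of the *noise* too, which caps
   noise-bin entropy slightly below the ideal ceiling (see bounds below).
3. **FIR low-pass** along slow time: Hamming-window design, order 64
   (65 taps, linear phase, integer group delay compensated by edge-padded
   forward filtering).  Default cutoff 16 Hz.  A much lower cutoff would
   concentrate the surviving noise into very few dyadic subbands and make
   the noise-entropy distribution both low and volatile; 16 Hz leaves the
   noise spread over ~6 of the 7 subbands, so empty bins sit near the
   entropy ceiling (≈1.7–1.75 nats) with a tight spread, which is what the
   median − k·MAD pit threshold needs.

## Autocorrelation

R(Δ) for Δ = 0..N−1 with the biased estimator (divide by N): it
guarantees |R(Δ)| ≤ R(0) and a nonnegative spectrum.  The expectation is
realised as a time average of the single realization.  Lag 0 is retained:
the wavelet stage sees it as one broadband sample among thousands.  The
essential scaling: the periodic component contributes coherently at every
lag, so its share of the autocorrelation's energy grows linearly with the
record length, while the noise contribution collapses onto small lags and
estimator fluctuations.  This is why the canned experiment scenes use a
128 s dwell (N = 8192): band-integrated *power* ratios — what an energy
detector sees — are dwell-independent, but the post-autocorrelation
order/disorder contrast keeps improving, which is precisely the regime
where a shadowed target becomes recoverable without becoming visible to
the baseline.  (The `SceneConfig` default remains a 32 s record, N = 2048.)

## Wavelet entropy

Each autocorrelated vector is decomposed with a J = 6 level DWT (db4,
4 vanishing moments; both configurable) into D_1..D_6 plus A_6 — 7
subbands, entropy ceiling ln 7 ≈ 1.946 nats.  Periodization boundary
handling keeps the transform orthonormal, so subband energies obey
Parseval exactly and the energy "probability" vector is well defined; a
symmetric extension would leak ~0.1–1 % of energy into duplicated
boundary coefficients.

Two energy conventions: `mean_per_coeff` (default) divides each subband
energy by its coefficient count, which equalises white-noise subbands
(equal per-coefficient variance under an orthonormal transform) and
maximises the noise-vs-breathing contrast; `raw_sum` keeps plain sums,
under which white-noise band shares halve per level and H → 2 ln 2 as J
grows — retained as an option and as a closed-form cross-check.  The
approximation band A_J is included as a (J+1)-th band deliberately: the
respiration line lives in the lowest octave (0–0.5 Hz at these rates) and
excluding A_J would discard exactly the ordered component.

Optional non-overlapping temporal windows of length L (L must divide N;
coefficients are assigned to the window containing their time support,
energies normalised by the per-window count N_j(i)) follow the temporal
evolution of the statistic; per-window entropies are combined by mean
(default) or max.  The default is a single window spanning the record.
A zero-energy bin is reported at the maximum ln(J+1) and flagged: no
structure is maximal disorder.

Numerical conventions: 0·ln 0 = 0; probability vectors are validated to
sum to 1 within 1e−8; entropy is clipped only by arithmetic, never
post-hoc, and 0 ≤ H ≤ ln(J+1) holds to floating point.

## Detection

The entropy-vs-range profile (wall region 0–1 m excluded) is thresholded
at median(H) − k·MAD(H), k = 3 — relative, so detection is invariant to
profile-wide offsets.  Candidate pits are maximal below-threshold runs.
Each pit's reported extent is its **width at half depth**: the crossings
of (median + H_min)/2 walking outward from the minimum, linearly
interpolated between bins.  Measured this way the width tracks the
physical extent of the dip rather than its depth — a weak (shadowed)
target's pit measures its torso, not its SNR; measured at the threshold
instead, the same pit would shrink quartically with SNR because subband
dominance goes as the fourth power of amplitude ratios.  The reported
range is the centre of that interval (stable for deep flat-bottomed pits,
whose raw argmin wanders across the bottom); the argmin itself is kept as
a field, reporting the nearer bin on exact ties.

A pit is accepted iff its width lies in [0.2, 0.8] m, bracketing measured
human pit extents.  A width-failing pit starting within 1.0 m behind an
already-accepted pit is labelled `rejected_ghost` (multipath trailing —
ordered energy, wrong extent); otherwise `rejected_width`.

The baseline energy detector integrates each bin's periodogram over the
respiration band 0.1–1.0 Hz and calls peaks above
max(median + 8·MAD, 2.5·median) spanning at least two bins.  The second
term matters on long dwells, where the band-power floor becomes so smooth
that floor-level bumps are many MADs significant; an energy reader does
not call a peak that sits at the floor.

## Canned experiment scenes

* `shadowed_pair_scene(b)` — blocker at 3 m (0.30 Hz), target at b ∈
  {5, 6, 7} m directly behind (0.25 Hz), shadow attenuation {0.5, 0.75,
  1.0} respectively: chosen so the shadowed target's band power stays
  below the baseline's floor while its periodicity remains recoverable by
  autocorrelation, shallower with distance behind the blocker (diffraction
  refills the cone; at 7 m the 1/r⁴ round-trip loss alone suffices).
* `angle_sweep_scene(θ)` — blocker at 2.5 m, target at 4 m at bearing θ ∈
  {10°, 15°, 20°, 25°, 30°}; attenuation 0.35 inside the cone; trailing
  disabled to isolate the angle variable.
* `single_target_scene` / `noise_only_scene` — one breather at 3 m with
  its multipath trail; empty room.

## What the simulations do and do not show

The simulator reproduces the *statistical structure* the method exploits:
static clutter, narrow-band breathing spread over neighbouring range
cells, range attenuation, a shadow cone, ordered multipath trailing,
broadband noise.  It does not model wall dielectrics, antenna patterns,
target micro-motion beyond a sinusoid, breathing harmonics (available but
off by default), non-Gaussian interference, or inter-person variability.
Passing the seeded-recovery suites therefore demonstrates that the
implementation realises the method's mechanism — order detection
surviving energy attenuation — not a field-performance claim.  Entropy
values from hardware data depend on the radar's noise shaping and are not
reproduction targets; only the qualitative profile structure (noise bins
near the ceiling, torso-width pits at targets, a distinct shallower dip
~0.8 m behind a strong target) carries over.

## Problem sizes

Full-scale runs use 2048×8192 matrices (200×8192 after accumulation);
the 20-seed recovery experiment and the angle sweep each run the complete
pipeline per seed/angle.  Monte-Carlo checks use 200 replicates of
N = 2048 (entropy ceiling) and 60 replicates of N = 4096 at J = 10
(raw-sum closed form).

## Known limitations

* The shadow cone is binary with a single attenuation factor; real
  shadowing is range- and frequency-dependent.
* Width gating assumes a roughly upright torso; a prone person's radial
  extent may fall outside [0.2, 0.8] m.
* The per-window entropy combiner (mean/max) is a design choice; nothing
  in the statistic prescribes one.
* With very low FIR cutoffs the noise-entropy floor drops and spreads,
  degrading the robust threshold; the default keeps the passband wide
  deliberately.
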