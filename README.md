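# bioradar

Wavelet-entropy detection of multiple stationary breathing humans in
ultra-wideband (UWB) bio-radar echo matrices — including targets hidden in
the **shadowing region** behind a nearer person, where conventional
energy-based detection fails.

## The problem

A bistatic impulse UWB radar staring through a wall records an echo matrix
R(τ, t): fast time τ maps to range (r = c·τ/2), slow time t carries the
sub-centimetre chest motion of breathing.  The nearest person is easy to
find — their respiration line towers over the noise floor of the
range–power profile.  A second person standing behind them is illuminated
only by the energy the first body lets through: their echo is attenuated
below the noise floor and an energy detector returns a false negative.

What survives shadowing is not energy but *order*.  The shadowed person's
slow-time signal is still quasi-periodic, while empty range bins contain
broadband noise.  This package detects that difference in order:

1. **Pre-processing** — distance accumulation (2048 → 200 range bins),
   sliding-window mean subtraction (window 100 samples) to cancel static
   wall clutter, and a linear-phase FIR low-pass along slow time.
2. **Autocorrelation** per range bin, R_x(Δ) = E[x(t)x(t−Δ)]: noise energy
   collapses onto Δ = 0 while the periodic respiration component survives
   at all lags.
3. **Wavelet entropy** — a J-level dyadic DWT splits each autocorrelated
   vector into subbands D_1..D_J, A_J with energies E_j = Σ_k |C_j(k)|²;
   the relative energies P_j = E_j / Σ_j E_j form a probability
   distribution whose Shannon entropy

       H = − Σ_j P_j ln P_j,   0 ≤ H ≤ ln(J+1)

   is low for an ordered narrow-band signal (breathing concentrates into
   one octave band) and near the ceiling for noise.
4. **Detection** — breathing targets appear as *entropy pits*: contiguous
   dips below a robust threshold median(H) − k·MAD(H).  Pits are gated on
   physical width (a human torso is a few decimetres thick); wide dips
   caused by ground-bounce multipath trailing behind a target are rejected
   as ghosts.  A respiration-band power-spectrum baseline is computed
   alongside for comparison.

A synthetic scene simulator (wall clutter, per-target breathing
signatures, 1/r² propagation loss, a shadow cone, multipath trailing,
receiver noise) makes every stage testable without radar hardware.

## Worked example

Blocker at 3 m, second person at 6 m inside the shadow cone, 128 s dwell:

```python
from bioradar import RunConfig, run_pipeline, shadowed_pair_scene

cfg = RunConfig(scene=shadowed_pair_scene(6.0, seed=1))
res = run_pipeline(cfg, out_dir="run1")
for p in res.report.detections:
    print(f"{p.range_m:5.2f} m  width {p.width_m:.2f} m  "
          f"H_min {p.h_min:.2f}  {p.status}")
print("baseline peaks:", res.power_peaks_m)
```

prints (trimmed to the structurally relevant pits):

```
 3.00 m  width 0.61 m  H_min 0.17  accepted
 4.13 m  width 0.89 m  H_min 0.56  rejected_ghost
 6.00 m  width 0.24 m  H_min 1.03  accepted
baseline peaks: [2.98828125]
```

Read: the entropy profile (noise bins ≈ 1.6–1.75 nats, threshold 1.65)
shows a deep 0.61 m-wide pit at 3 m (the blocker), a 0.89 m-wide dip just
behind it — too wide for a torso, classified as the blocker's multipath
ghost — and a genuine torso-width pit at 6 m: the shadowed person.  The
energy baseline reports only the 3 m target; the 6 m respiration-band
power sits at its noise floor.

The same chain is scriptable from the shell:

```sh
bioradar pipeline --config examples/shadowed_pair.yaml --out run1
bioradar simulate --config cfg.yaml --out raw.csv
bioradar preprocess raw.csv pre.csv
bioradar autocorr pre.csv ac.csv
bioradar entropy ac.csv entropy.csv
bioradar detect entropy.csv
```

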