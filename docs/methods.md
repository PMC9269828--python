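# Methods

## Acquisition model

The accessory carries two coplanar rings of `N_a = 8` antennas on a 10 mm
radius (20 mm accessory diameter); antenna *i* sits at angle `2πi/N_a`,
antenna 0 at angle 0. Each transmitter pairs with its three closest
receivers — `(i−1) mod N_a`, `i`, `(i+1) mod N_a` — giving 24 transmission
S-parameters per frame at a single frequency of 7.6 GHz (the antennas are
narrowband; additional in-band frequencies carry no independent information).
Frames are taken every 4 mm along the trajectory axis; frame *n* covers
`[z_n, z_n + step)` with `z_n = n·step`. The physical axial offset between
the transmitting and receiving rings is unspecified for the hardware;
treating the rings as coplanar is an explicit modelling assumption, kept as
a geometry field (`tx_rx_ring_offset_z_mm`) defaulting to zero. Lengths are
millimetres throughout; distances entering wave phases are converted to
metres.

## Calibration

Automatic temporal subtraction: frame *n*'s reference is the minimiser of
the frame distance over all previous frames (`pool_window` can cap the pool
for very long trajectories; default unlimited), ties broken towards the most
recent frame. The default distance is the modified Hausdorff distance
`max(d(A,B), d(B,A))`, `d(A,B) = mean_a min_b |a−b|`, over the frames' 24
coefficients as (Re, Im) points. How S-parameter sets are turned into point
sets is not uniquely determined by the method's published description;
complex-plane points per channel were chosen because they preserve magnitude
and phase per pair. A Chebyshev alternative (max per-pair magnitude
difference, the literal max-norm reading of the selection rule) is available
via `metric="chebyshev"`. The MHD is a pseudometric here: symmetry and
identity hold, the triangle inequality does not in general and is never
relied on.

Frame 0 has no predecessor: it is emitted as a zero-field sentinel, never
scored, and detection output for it is "no alarm" by definition. Frames
flagged by the detector are *not* excluded from later reference pools
(the selection rule is applied literally); exclusion would be a
straightforward extension.

One consequence worth knowing: on a perfectly noiseless scene whose lesion
footprint is symmetric about a grid-aligned centre, axially mirrored frames
are *identical*, so the reference search finds an exact duplicate and the
residual is exactly zero. Any noise or off-grid lesion centre (i.e. any
realistic input) removes the degeneracy.

## Focuser

The image over a square XY grid (half-width 45 mm covering the 90 mm
maximal colon diameter, 1 mm pitch, odd pixel count so the origin is a pixel
centre) is

```
I(r) = Σ_{i=0..N_a−1} Σ_{j∈{i−1,i,i+1}} Es²(T_i, R_j)
       · J₁(2k·|r_Rj − r|) · exp(j(2k·|r_Rj − r| + φ_ij))
```

with `k = 2πf/c` (`c` the vacuum speed of light — the insufflated lumen
behaves like free space), `φ_ij = 2π((j−i) mod N_a)/N_a`, and `Es²` the
complex square of the calibrated scattered field (the monofocusing
convention; plain delay-and-sum on `Es` is available via `field_power=1`).
Only the receiver-to-pixel distance appears in the kernel, exactly as the
method prescribes; no transmitter-distance term is invented. `J₁(0) = 0`
naturally suppresses pixels at receiver positions, so no guard radius is
needed. The stored image is `|I|`; the complex field is retained on the
image object because reconstruction is exactly linear in `Es²`
(`I(a·Es) = a²·I(Es)`), which the tests exploit.

`per_pair_max` reports, for each pair, the maximum of its single-pair partial
image restricted to the angular sector of half-width `π/N_a` about the pair's
mid-bearing, normalised to the maximum across pairs; the complex partial
images sum pixel-wise to the full reconstruction.

### Localization behaviour and its limits

The single-frequency kernel weights pixels by `|J₁(2k·d_R)|`, which peaks
about 5.8 mm from each receiver and has its first null near `d_R ≈ 12 mm`.
The consequence, measured on noiseless single-scatterer scenes: the
scatterer *bearing* is recovered at any radius, but the radial coordinate of
the image argmax is biased towards the J₁ peak ring once the scatterer is
more than ~6 mm from the array. For scattering centres 1–5 mm off the
encapsulated array surface (radius 11–15 mm — the tip of a protruding lesion
the accessory passes, and the regime of the worked localization example at
12 mm) the median argmax error over 20 fixed-seed scenes is ≈8.8 mm, below a
quarter wavelength (λ/4 ≈ 9.9 mm at 7.6 GHz). At 12–22 mm radius the median
error grows to ≈14 mm, dominated by the radial bias. Detection is
unaffected: the alarm uses only the image *maximum*, which rises sharply
whenever a lesion is in the slice, wherever the argmax lands.

## Detector

Simple exponential smoothing with a deviation band:

```
s_{n+1} = α·y_n + (1−α)·s_n
w_{n+1} = α·|y_n − s_{n+1}| + (1−α)·w_n
band    = s_{n+1} ± δ·w_{n+1}
```

`y_n` is the raw image maximum (normalising by a trajectory-wide maximum
would be non-causal; the trigger is already scale-invariant per trajectory).
Frame *n* alarms iff `y_n` lies strictly above the band forecast from the
previous state (one-sided by default, since a lesion only raises the
amplitude; a two-sided option exists). The printed form of the band
recursion is ambiguous about grouping; the adopted reading — an
exponentially smoothed absolute one-step deviation scaled by δ — is the
standard forecasting-band construction, guarantees non-negative width, and
collapses to a point band on constant input. Measuring the deviation against
`s_n` instead of `s_{n+1}` is exposed as `deviation_reference="level"`.

Initialisation is not prescribed by the method: the level starts at the
first scored frame's maximum with zero deviation, and alarms are suppressed
for `warmup_frames = 3` scored frames while the band adapts. Defaults
`α = 0.3, δ = 3` were fixed once from the behaviour of the smoothing
recursion on the synthetic ensemble's noise floor (α small enough to keep a
multi-frame memory, δ large enough that single-frame noise extremes of the
8281-pixel image maximum stay inside the band); both are mandatory flags in
the CLI `detect` command so reports always carry them. Raising δ can only
shrink the alarm set (asserted as a set-inclusion property), trading
sensitivity against specificity.

## Synthetic scenes

The simulator reproduces the statistical structure the pipeline exploits,
not antenna electromagnetics:

* **Clutter** per pair: amplitude `A_c/√d` with round-trip phase `2k·d_wall`
  at the pair's mid-bearing; `d_wall` follows the lumen radius (default
  25 mm; the colon is 40–90 mm in diameter), sinusoidal folds
  (default 1.5 mm amplitude, 40 mm period in the benchmark) and a half-sine
  lateral centre-line drift (`curvature_mm`, 6 mm peak in the benchmark's
  curved trajectories). Clutter varies smoothly with z — the premise that
  makes temporal subtraction work.
* **Lesions**: Born single scattering, `τ·(size/10mm)³·g(d_T)·g(d_R)` with
  the 2D cylindrical kernel `g(d) = exp(−jkd)/√d`, volume scaling of the
  scattering strength, and a raised-cosine axial footprint confined to
  `[z_c − size/2, z_c + size/2]` (a lesion contributes nothing outside its
  own extent). The contrast `τ = (ε*_lesion − ε*_bg)/ε*_bg` with
  `ε* = ε_r − jσ/(2πfε₀)` uses ε_r = 46, σ = 8 S/m for healthy mucosa
  (literature-range values at 7.6 GHz; only the ratio matters to the
  scale-free detector) and +30%/+90% for neoplasm, giving |τ| ≈ 0.44.
* **Debris**: weak scatterers (amplitude 0.05) with broad 40 mm footprints —
  clutter-like, slowly varying, so calibration and the adaptive band absorb
  them.
* **Noise**: i.i.d. circular complex Gaussian, total σ = 0.02 per pair —
  chosen so the polyp-free frame-to-frame image-maximum variation sits far
  below (≪10% of) a 30 mm lesion's peak response, keeping the detector's
  premise testable while leaving a realistic noise floor.

Simulation is a pure function of (scene spec, seed). What the simulator does
**not** model: full-wave propagation, antenna patterns and coupling, tissue
heterogeneity beyond the two-tissue contrast, mucosa thickness variation, or
quantitatively calibrated clutter/noise levels (none are published for the
ex vivo setup — the defaults are labelled stand-ins). Passing the synthetic
benchmark therefore demonstrates the algorithm's correctness and its
robustness to the modelled effects (drift, folds, curvature, debris, noise),
not clinical performance on real tissue.

## Benchmark ensemble and evaluation

The 15-trajectory benchmark (`colowave.ensemble`) uses the ex vivo study's
per-sample lesion sizes (10–65 mm), sample lengths (80–330 mm) and histology
labels as inputs; trajectories 11, 13 and 14 are curved and trajectory 12
carries debris. (The source is internally inconsistent about whether sample
12 or 14 was curved; the majority reading — 11/13/14 curved, 12 debris — is
used.) Lesion axial position and bearing are drawn per trajectory from a
`SeedSequence([base_seed, sample_index])`, with the placement and noise
streams split so they are independent; lesion centres keep
`size/2 + 20 mm` clearance from the trajectory start so the dilated extent
lies past the warm-up. The lesion scattering centre sits at 19 mm radius
(6 mm inside the nominal wall, the protruding tip).

Counting follows the hybrid unit that reproduces per-sample reports with
sensitivity exactly 100 and fractional specificities (e.g. 16/17 = 94.12%):
each ground-truth lesion is one positive unit, detected iff ≥1 alarm frame
overlaps its extent dilated by ±1 frame (`tolerance_frames`, configurable,
absorbing the manual registration of lesion positions); every scored healthy
frame is one negative unit. Both pooled (micro-averaged) and
macro-averaged percentages are computed; zero denominators yield an explicit
"undefined". The frame-level positive unit is available via
`positive_unit="frame"`.

Problem sizes used throughout (tests and the acceptance script): 15
trajectories of 21–83 frames (about 800 frames total), 91×91-pixel images at
1 mm pitch — the full pipeline over the ensemble completes in a few seconds.

## Numerical choices and degenerate inputs

* Trajectory CSV round-trips bit-exactly (floats serialised with `repr`,
  complex values as separate re/im columns); repeated writes are
  byte-identical.
* Reference-selection ties break to the most recent frame; equality is exact
  float equality (ties occur in practice only for exactly duplicated
  frames).
* Per-pair focuser kernels depend only on (geometry, grid, frequency) and
  are LRU-cached.
* Empty point sets, empty reference pools, non-consecutive or off-grid
  frames, mismatched plans/frequencies, z outside the scene, and zero
  denominators in the metrics all raise typed errors naming the offending
  frame/pair rather than degrading silently.
* Trajectories shorter than `warmup_frames + 2` are rejected with the
  required minimum stated.
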