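# Methods

This note documents the models implemented in `thermotrack`, the defaults
and why they were chosen, the numerical decisions that affect
reproducibility, and what the synthetic validation does and does not show.

## Temperature physics

Water viscosity follows the three-parameter Vogel correlation
η(T) = A·base^(B/(T−C)) with A = 2.414×10⁻⁵ Pa·s, B = 247.8 K, C = 140 K and
**base 10**. These constants are the standard base-10 parameter set: they
reproduce the accepted 1.002 mPa·s at 20 °C only with a base-10 exponent
(an e-base evaluation with the same constants is off by an order of
magnitude). The base is exposed on `ViscosityModel` for users with e-base
parameter sets. The correlation is good to ~1% in the middle of the liquid
range and undershoots slightly near boiling (≈0.311 vs. the tabulated
0.315 mPa·s at 90 °C, a 1.2% error), which is why the validation tolerance
at 90 °C is 2%.

Stokes–Einstein diffusion D = k_B·T/(6πηr) takes the hydrodynamic radius
explicitly. The library's worked example of a cell diffusing at 0.30 µm²/s
at 33 °C (0.86 µm²/s at 91 °C) corresponds to r = 1 µm. `ParticlePhysics`
restricts temperatures to the liquid-water window (273–373 K) because the
viscosity model has no meaning outside it. The speed × viscosity product is
offered as a radius-free proxy for flagellar force: at terminal velocity
F = 6πηr·v, so for one population observed across temperatures the product
v̄·η tracks F up to the constant geometric factor.

Temperatures are kelvin throughout the library; the configuration layer
converts °C → K by adding 273.15.

## Reconstruction

Raw holograms are lifted to complex fields before propagation: non-negative
intensity frames as √I with zero phase, signed (background-subtracted)
frames as sign(x)·√|x|; complex inputs pass through. Off-axis carrier
demodulation is out of scope — the package consumes amplitude-encoded
stacks, as produced by upstream reconstruction front-ends.

Angular-spectrum propagation multiplies the 2D spectrum by
exp(i·2π·z·√((n/λ)² − f_x² − f_y²)) and **hard-zeros evanescent components**
(negative radicand), the standard band-limited choice, so results are
bit-reproducible. At z = 0 the operator returns the input exactly rather
than band-limiting it. Consequences tested: |H| = 1 on the propagating band,
+z/−z round trips restore band-limited fields to < 10⁻⁶ relative error, and
band power is conserved for any z.

Two background modes are provided. Median subtraction removes everything
stationary but leaves a "ghost": a slow particle's vacated median position
still differs from the current frame. Frame-to-frame differencing removes
even objects present in every frame (needed when surface-adherent cells
dominate), at the cost of one frame and a dipole signature per mover; its
output video's time origin advances by one frame interval, and all
downstream timestamps refer to the differenced video. The temporal median
is not a linear operator; what holds (and is tested) is that both modes
are exactly invariant to adding any time-constant image, and differencing
is additionally linear.

Defaults: pixel size 0.178 µm/px, 15 frames/s, wavelength 0.520 µm, medium
index 1.33, Z sweep −200..+200 µm in 10 µm steps. The 0.178 µm value is the
calibration convention of the analysis settings this pipeline mirrors, not
the optically derived 3.45/20 ≈ 0.1725 µm.

## Detection and linking

Changed pixels are |frame − background| > threshold, with the automatic
threshold at 3 robust sigmas (median absolute deviation × 1.4826) of the
subtracted video. Detection operates on the absolute change so both
subtraction modes feed one detector. DBSCAN (Euclidean, in pixels,
eps = 3 px, min_samples = 4) groups changed pixels; each non-noise cluster
becomes a detection with an intensity-weighted centroid. Coordinates are
0-based with pixel-center origin; x = column·pixel_size, y = row·pixel_size.

Linking is Jaqaman-style: per consecutive frame pair, a square assignment
matrix with squared centroid distances in the link block (capped at
max_link_distance, default 10 µm/frame — comfortably above per-frame
displacements at observed instantaneous speeds of ~100 µm/s and 15 fps),
birth/death alternatives on the diagonal at the squared cap, and zeros in
the complementary block. With that construction the optimal assignment
minimizes Σd² + cap²·(#unlinked), which the test suite verifies against
exhaustive enumeration on small scenes. scipy's Hungarian solver provides
deterministic tie-breaking. A second assignment pass closes gaps of up to
max_gap_frames (default 2) missed frames when end and start lie within
max_link_distance × frame-span; closed gaps are filled by linear
interpolation and flagged, and flagged points do not count toward the
15-observed-frame minimum track length.

## Track features

Mean speed divides the summed step lengths by (N−1)Δt — i.e. by the number
of steps, not points — so a constant-velocity track returns exactly its
speed. With that convention mean_speed × duration equals the path length
exactly, making the displacement ratio (chord/path) and sinuosity
(path/chord) exact reciprocals; this identity is asserted numerically.
Sinuosity is deliberately oriented as path/chord so that straight = 1 and
circling ≫ 1 (values > 20 classify circular tracks); a closed track with
zero chord returns a capped value (10⁶) with a flag. "Displacement" is
reported both as the raw chord (µm) and as a rate (µm/s, chord/duration).

Autocorrelations are computed at 1 s and 2 s lags (converted to frames by
rounding): Pearson correlation for scalar series (speed, turn angle) and
⟨v⃗_t·v⃗_{t+lag}⟩/⟨‖v⃗‖²⟩ for velocity. Tracks too short for a lag yield
NaN missing-value markers, not errors; the classifier imputes them with
training-set medians. Zero-length steps contribute zero speed and are
skipped in angle statistics.

The covariance diffusion estimator, per axis,
D̂ = ⟨Δx²⟩/(2Δt) + ⟨Δx_n·Δx_{n+1}⟩/Δt, uses the negative adjacent-step
covariance that static localization noise induces to cancel the bias that
same noise puts on the squared-step term; tests confirm the estimate stays
within 5% of truth with 0.05 µm noise. Tracks need ≥ 5 steps (the
conventional minimum); sample-level summaries flag recordings with fewer
than 10 accepted tracks rather than rejecting them.

## Classification

A 200-tree random forest (fixed seed, deterministic) consumes the 17-entry
feature vector. Because no manually labelled real recordings ship with the
package, the default model trains on the synthetic generator's ground truth:
swimmers in all four modes at 10–30 µm/s versus Brownian tracks at
0.2–1.0 µm²/s, immobile particles, both under bulk drift of 2–8 µm/s, and
median-subtraction ghost tracks (the linker alternating between a particle
and its vacated median position — a detection artifact that otherwise mimics
fast zigzag swimming). **All reported accuracies are accuracies on synthetic
data**; a real deployment with substantially different flow or noise
profiles should retrain on its own labelled tracks
(`classify.train_classifier`).

Swim types are rule-based with precedence circular → helical → long run →
run-and-tumble:

- **circular**: sinuosity > 20.
- **helical**: dominant transverse oscillation. The track is projected on
  its principal axis and the transverse coordinate is differenced twice:
  second-differencing whitens both localization noise trends and the 1/f²
  spectrum of rotational-diffusion wander (a diffusing heading is itself a
  random walk, so a single difference is not enough), while a genuine
  sinusoid stays narrowband. The call requires a 3-bin spectral window at
  ≥ 2 cycles per track holding ≥ 40% of the total second-increment power,
  and at most one tumble-like turn. Helical is deliberately tested *before*
  long run: a projected helix with realistic drift/transverse speeds clears
  the long-run displacement-ratio threshold while never turning sharply
  enough to register a tumble, so the opposite order would absorb every
  helix into "long run".
- **long run**: displacement ratio ≥ 0.55 and no tumble.
- **run-and-tumble**: fall-through; a tumble is a step-to-step turn > 60°
  (or > 45° with a simultaneous > 30% speed drop). The thresholds are
  package conventions — "tumble" has no universal numeric definition — and
  are configurable.

On a balanced 4 × 50-track synthetic set with moderate noise the rules
recover 82% of ground-truth modes; the dominant confusion is circular
tracks read as helical when noise keeps sinuosity under 20.

## Motion History Image and motile fraction

The MHI maps each pixel to the frame index of its largest absolute change
(|frame − median| by default, |frame_{t+1} − frame_t| in difference mode),
with ties broken toward the earliest frame and pixels below threshold
masked; it is exactly invariant to constant offsets. Rendering uses a
perceptually uniform colormap with the colorbar in frame numbers.

Motile fraction = (mean motile count per frame / imaging volume in mL) /
cell concentration. The imaging volume for a 365 µm × 365 µm × 1 mm field
is 0.133 µL. Two counting routes are provided: connected-component counts
on frame-differenced video (8-connectivity, area within [4 px, ∞) by
default), and counts of classifier-labelled motile tracks covering each
frame — the latter is robust to track fragmentation and is what the
pipeline reports. Concentration may be supplied directly or as OD ×
dilution with a user calibration factor; no default OD calibration is
shipped.

## Synthetic scenes

Simulation is 2D throughout (the tracking surface is 2D projections; a
helix is generated directly as its projected spiral). Brownian steps are
i.i.d. Gaussian with per-axis σ = √(2DΔt); run-and-tumble uses exponential
run durations with uniform new headings; circular uses a constant angular
rate; all swim modes accept rotational diffusion. Drift adds a uniform
(optionally y-sheared, emulating stacked convection planes) displacement
per frame to every non-adherent particle. Rendering draws Gaussian blobs
(σ = 1.5 px, peak amplitude 10) on Gaussian noise (σ = 1), SNR 10 by
default. One global seed is split into stable per-particle sub-seeds, so
adding a particle never perturbs the others, and scenes are bit-exactly
reproducible.

Particles reflect at the field boundary. This keeps the number of cells in
view constant — emulating the steady-state exchange of swimmers through a
real field of view — at the cost of un-physical wall bounces; bounce kinks
are rare within any single 15-frame track window and do not measurably
affect classification.

The reference catalog spans the qualitative temperature regimes of a
slow-heating experiment on a mesophile: motile fraction 20% at 28 °C, 25%
at 34 °C, 60% at 44 °C, collapsing at 61/66 °C with growing drift, and 0%
at 84 °C where all motion is bulk drift. Brownian populations in every
scene use the temperature-correct Stokes–Einstein D for r = 1 µm. Scenes
are 150 frames (10 s) of 256 × 256 px at 0.5 µm/px — sizes chosen so the
full suite, including two end-to-end scene runs, completes in a few minutes
on one CPU while leaving every per-track statistic well-sampled.

What the synthetic validation shows: the pipeline's detection, linking,
feature, classification and summary stages are internally correct, recover
constructed ground truth, and match independent brute-force oracles. What
it does not show: performance on real holographic recordings, whose noise
is structured (fringes, speckle), whose cells vary in brightness and shape,
and whose drift fields are not uniform. The Gaussian-blob PSF carries no
holographic fringe structure; the angular-spectrum module is instead tested
on point-source fields it propagates itself.

## Degenerate inputs and numerical conventions

- Median subtraction requires ≥ 3 frames; differencing ≥ 2; MHI ≥ 2.
- Tracks require ≥ 2 points and strictly increasing times; features needing
  more points yield NaN markers inside `feature_vector` (and raise when
  called directly).
- Assignment "infeasible" entries use a large finite cost (10¹⁵), keeping
  the Hungarian solver's optimality intact while forbidding the links.
- The frame-rate constancy check aborts when any interval deviates from the
  median by > 0.1%.
- Config hashes are SHA-256 over canonical sorted JSON of the resolved
  configuration; every output artifact embeds the hash.

## Known limitations

- 2D only: out-of-plane motion foreshortens speeds and angles; helix pitch
  and radius are not extracted.
- No off-axis fringe demodulation, phase reconstruction, or autofocus.
- The default classifier is synthetic-trained; field data with unfamiliar
  artifact modes will need retraining.
- Gap closing assumes near-linear motion across the gap; interpolated
  points are flagged so downstream users can drop them.
- Surface interactions are emulated only as immobile clutter; hydrodynamic
  slowing near walls is not modelled.
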