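# Methods

This note documents the models behind `cellphantom`, the defaults and their
rationale, the numerical choices, and what the synthetic data does and does
not capture.

## Growth model

Cells are spherocylinders described by length `l` (pole to pole), width
`2r`, axial position `x` in a trench with its origin at the closed end, age,
birth length and a per-cell division threshold. Units are micrometres and
minutes throughout.

**Elongation.** Single cells elongate exponentially, `l(t+dt) =
l(t)·e^{λ·dt}`, the standard law for steadily growing bacteria; it produces
the exponential rising edges of the mother-cell sawtooth. The default rate
λ = ln2/23 min⁻¹ corresponds to a 23-minute doubling time, typical of
*E. coli* in rich medium. Width is constant within a cell's lifetime.

**Division.** Three size-regulation strategies are implemented, selected by
`regulation_mode`:

- *adder*: divide when `l − l_birth ≥ Δ`, with Δ drawn per cell at birth
  from a truncated normal. The default Δ mean is half the configured
  division length, so steady-state cells divide at the configured mean.
- *sizer*: divide when `l ≥ L_div`, `L_div` truncated-normal with the
  configured mean (4 μm) and SD (0.3 μm), truncated at the cap diameter 2r.
- *timer*: divide when `age ≥ τ`, τ truncated-normal (SD 1 min), τ > 0.

Daughters split `l − septum_gap` (default gap 0.1 μm) by the configured
asymmetry ratio (default symmetric), get fresh ids, widths, thresholds and
bend amplitudes, and keep the mother's axial span. Two timer-specific
choices deserve note, because timer regulation has no size feedback to
absorb systematic biases:

- the discrete event loop fires division at the first *frame* past τ, which
  would inflate every cycle by up to `dt`; daughters therefore inherit the
  overshoot `age − τ` as their starting age, making cycle times unbiased in
  the renewal-theory sense;
- the default τ mean is `ln(2 + septum_gap/ℓ̄_birth)/λ` rather than the bare
  doubling time `ln2/λ`: each division discards the septum gap, and without
  this correction mean size shrinks by `gap/2` every generation until
  lineages pile up at the minimum viable size. With it, log-size is a
  driftless random walk.

Cells shorter than 0.4 μm + septum gap defer division until they have grown
(a minimum-viable-size floor). Lysis removes a cell with probability
`p_lyse` per timepoint, logged.

**Collisions and washout.** Cells in a mother-machine trench are quasi
one-dimensional, so contacts are resolved by a single sweep along the axis
from the closed end: each cell is displaced outward just far enough to
clear the wall and its inner neighbour. The sweep preserves ordering, is
exact (no iteration, no convergence failure mode) and leaves residual
overlaps of exactly zero, well within the 0.01 μm tolerance asserted by the
invariant checks. A cell whose centroid crosses the open end is removed and
logged as washed out.

**Mass audit.** The run accumulates total elongation, septum losses, lysed
and washed-out lengths; `founder + growth − septa = in-trench + lysed +
washed` closes to floating-point precision and is checked on every run.

## Rendering

Each cell's image contribution is the analytic chord-length projection of
its hull: a pixel at perpendicular distance `d < r` from the medial axis
holds `2√(r² − d²)`. This is mathematically the same object as voxelising
the revolved hull and summing along the optical axis, but exact: the patch
integrates to the spherocylinder volume `πr²(l − 2r/3)` (equivalently
cylinder + two hemispherical caps), and the agreement is better than 1% at
the default 3× super-sampling. Bent cells are produced by displacing each
axial slice laterally along a parabolic bow with sub-pixel linear
interpolation, which conserves each slice's integral; bend amplitudes are
drawn per cell from a half-normal with scale 0 by default (straight rods).

Scenes are composed in order: media level `I_m` everywhere, device walls
`I_t` (rectangular slabs; corner rounding is not modelled), then cell OPL
added on top multiplied by `I_c`. Labels are painted from the same analytic
footprints and never pass through the optics, so ground truth is bit-
identical across all optical and camera parameter changes. Physics leaves
hulls disjoint, but placement rounding at exact cell–cell contacts can
produce a one-pixel footprint tie; ties are resolved by chord depth, and
any overlap wider than the physics tolerance plus one pixel raises an
internal error.

`perlin_background` provides classic gradient-lattice noise for agar-pad
style textures (zero mean; autocorrelation length monotone in the lattice
scale); it is additive and optional, and defaults to off for mother-machine
scenes.

## Optics

Kernels are rendered at the super-sampled object-plane pitch
`camera_pixel/magnification/supersample` (default 6.5 μm/100×/3 ≈ 21.7 nm).

- **Fluorescence**: Airy intensity `[2J₁(v)/v]²`, `v = 2π·NA·ρ/λ_em`,
  normalised to unit sum. First zero at 0.61 λ/NA, verified against a
  root-finder on J₁.
- **Phase contrast**: the annular aperture's amplitude
  `A(v) = [2/(1−ε²)]·[J₁(v)/v − ε²·J₁(εv)/(εv)]`, with ε the inner/outer
  annulus radius ratio (both radii configurable; only the ratio enters).
  `obscured_airy_psf` exposes the intensity `|A|²` (+ optional uniform
  offset, renormalised), which degenerates elementwise to the Airy kernel
  as ε→0.
- **Phase-contrast imaging** uses the weak-object approximation:
  `I = I_bg·(1 − γ·(A ⊛ φ))` with the *signed* amplitude kernel and φ the
  excess OPL. A non-negative unit-sum kernel mathematically cannot produce
  a halo (for such k, `I = I_m − k⊛deficit ≤ I_m` everywhere), whereas the
  annulus's near-zero DC response makes the signed kernel produce exactly
  the observed artefacts: dark body, bright halo ring, interior shade-off.
  The small constant `halo_offset` restores part of the DC response and so
  modulates both artefacts.
- **Apodisation** multiplies by a centred Gaussian (σ in pixels, ∞ = off)
  and renormalises. **Defocus** convolves the in-focus kernel with a
  Gaussian of width `defocus_rate·|z|` (default 0.3 μm of lateral blur per
  μm of defocus) — a deliberately simple axial model whose only promised
  property is monotone FWHM growth in |z|. The **3-D fluorescence** option
  stacks defocused 2-D kernels; a full vectorial high-NA model is out of
  scope.

Convolution runs in the Fourier domain on the reflectively padded scene and
must (and does) match a double-loop spatial oracle to 1e−8; the result is
block-averaged down to camera resolution. Kernel pitch is validated against
the scene pitch.

## Camera

`out = clip(round(gain·(Poisson(scale·I) + N(0, σ_r)) + baseline), 0,
2^bits − 1)` — Poisson, then Gaussian, then quantisation. The photon
transfer curve (variance vs mean over flat fields) has slope = gain, and
dark frames recover σ_r after removing the 1/12 DN² quantisation variance;
both are used as self-checks. Histogram matching is the exact rank mapping
(ties averaged), hence idempotent and rank-preserving; Fourier matching
rescales each coefficient by the ratio of reference to synthetic mean
amplitude in its integer radial bin, keeping synthetic phases. The region
error report (cells/device/media relative mean and variance errors) is
advisory: the original tuning loop it supports is a human-in-the-loop
process without a closed-form objective, and no black-box optimiser is
bundled by design.

## Dataset export

Image-formation parameters (intensities, apodisation, defocus, halo offset,
photon scale, read noise) are jittered ±5% uniformly (or as a relative SD,
gaussian) around their tuned values — mechanistic variation of the imaging
process, applied before the camera, so the object-to-image mapping stays
physical and the ground truth is pixel-identical across jitters of one
frame. Dialects: `binary_weightmap` writes binary non-touching masks
(labels eroded until no two components are 8-connected) plus the U-net
border weightmap `w_class + w0·exp(−(d₁+d₂)²/2σ²)` (defaults w0=10, σ=5 px,
class balancing optional — the exact class weighting is exposed as a flag
since conventions differ); `instances_tiled` writes labelled touching
instances, optionally tiled side-by-side with globally unique ids. Frame
sampling can be weighted inversely to cell count so the expected number of
exported cells per image stays flat across cell-size regimes. Formats:
16-bit TIFF images, 8-bit PNG binary masks, 16-bit PNG instance labels,
32-bit float TIFF weightmaps, CSV manifest with every parameter draw.

## Evaluation

- **Identification error**: scan the sawtooth's first derivative for
  one-frame reversals (dip-then-rise or spike-then-fall) whose relative
  size exceeds 5%; a drop is division-compatible, and excused, when the
  post/pre ratio lies in [0.4, 0.6]. The rate is flagged timepoints over
  all timepoints. The 5% floor and the halving band are configurable; the
  defaults are calibrated so the simulator's own clean traces (growth
  ≈ 3%/frame at the default λ and dt) score exactly zero.
- **Threshold optimisation**: grid search (default 0.50–0.995, step 0.005,
  lowest-argmax tie-break) maximising the mean Jaccard index against truth;
  the alternative statistic — cumulative intersection of per-cell length
  and width histograms (50 bins over the pooled range) — is also available
  and peaks at a consistent threshold on blurred-truth fixtures.
- **Seeded watershed**: seeds are components above `t_seed` (default 0.999
  for sigmoid-saturated network outputs; optical test scenes use a lower
  seed level since their plateaus are not saturated), flooded over the
  inverted map restricted to the `t_opt` foreground, which the output
  labels partition exactly.
- **Precision**: SD of pooled residuals around per-segment quadratic fits
  to stationary-phase lengths; segments shorter than 4 points are skipped.
- **Mask geometry**: per-label principal-axis analysis; length is the major
  axis extent (+1 px pixel-centre convention), width the mean lateral
  extent over the middle half of the axis (excluding the tapering poles).
  Rotation-invariant to about a pixel.

## Problem sizes and determinism

Everything is seeded: one pipeline seed is spawned into per-stage
`SeedSequence` streams, so runs are bit-reproducible (identical event logs
and manifests). Test and acceptance runs use desk-scale sizes chosen to
make the statistics sharp: 500-step invariant sweeps, ~2600 divisions for
the adder regression (slope SE ≈ 0.03), ~10⁵ pixels per photon-transfer
level, 10⁴ jitter draws, 10³-point precision segments.

## What the synthetic data does not capture

The rendering has no sub-cellular structure (nucleoid, membrane), no
refractive-index gradients within a cell, and absorbs the physical
OPL-to-phase scaling into the empirical intensities `I_c/I_t/I_m`, so
absolute units are not reconstructed. The optics is scalar and aberration-
free apart from the parametric defocus; polarisation and coverslip
mismatch are not modelled. The physics is one-dimensional: 2-D monolayer
colony mechanics, nutrient-coupled growth modulation and fluorescence
expression dynamics are out of scope (a hook field exists on the cell
agent). Passing tests therefore demonstrate internal consistency of the
generative model and its statistics, not that any particular real
microscope is matched; matching a real instrument is exactly what the
histogram/Fourier/region tools and the jitter mechanism are for, and it
remains a per-experiment calibration step.
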