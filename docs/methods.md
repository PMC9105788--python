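# Methods

This note documents the models, algorithms and parameter choices behind
`pulmophase`, what the synthetic phantom does and does not emulate, and the
numerical decisions a maintainer should know about.

## Signal model and flip-angle optimization

The acquisition is a perfectly spoiled gradient-echo (UTE) sequence, so the
longitudinal magnetization settles into the Ernst steady state. We use the
closed-form fixed point

    S = M0 sinα (1 − E1)/(1 − E1 cosα) e^(−TE/T2*),   E1 = e^(−TR/T1),

rather than a time-stepped isochromat simulation: under ideal spoiling the
recursion `M⁺ = M cosα`, `M(t+TR) = M0 + (M⁺ − M0)E1` converges to exactly
this value, and the test suite guards the closed form against the iterated
recursion to 1e−10 relative error. The tissue pairs used throughout
(T1/T2* = 1391.9/83.68 ms for air-like, 1292.3/74.84 ms for oxygen-like
tissue; 7.2% and 10.6% reductions) are the phantom calibration values that
mimic the air → 100% O2 change in lung. At TR = 5 ms both pairs share the
integer-degree signal optimum of 5° (Ernst angle 4.85°/5.04°), while PSE
grows monotonically with flip angle to 7.67% at 90°; the protocol's 8° is
a signal-vs-enhancement tradeoff.

## Trajectory

Center-out radial spokes rotate in-plane by the golden angle between
*view-groups*; all Nz Cartesian kz partitions are collected at one azimuth
before rotating, which sets the self-gating time unit to Nz×TR (40 ms at
desk scale, 150 ms in vivo). The implementation uses the 3-decimal rounded
increment 111.246° (what a scanner would be programmed with); with it no
azimuth repeats within any realistic protocol length. Spokes are spread
over the full 360° since each covers only a k-space half-line. Gradient
ramp-up is modeled as a quadratic-then-linear |k| profile (first 60 samples
of the in-vivo spoke); pre-samples are excluded from reconstruction.

## Synthetic phantom

The generator emulates the continuous air → wash-in → oxygen free-breathing
study on a procedural thorax: body ellipse, two lung ellipsoids clipped
below by a paraboloid diaphragm dome, heart, aorta, liver, and three
intrapulmonary vessels per lung, all with anti-aliased (soft) boundaries.
Choices that define the default study conditions:

- **Protocol (desk scale).** Matrix 64, nz 8, 64-sample spokes, TR/TE/FA =
  5 ms/0.14 ms/8°, 1800 view-groups split 600/600/600 — a 1:1 structural
  scale-down of the 4800-view, 256×256×30 in-vivo protocol that keeps every
  ratio the pipeline cares about (views per segment ≫ Nyquist, ~6 breathing
  cycles per segment).
- **Breathing.** Raised cosine at 0.25 Hz with 30 mm diaphragm excursion
  (deep free breathing; ~1.5 slices at the 20 mm desk slice spacing so that
  motion is resolvable along z). Optional cycle-period jitter and a
  separate oxygen-segment amplitude scale exercise the binning/matching
  paths. Cardiac modulation: 5% intensity on heart and vessels at 1.2 Hz
  (its depth is not documented anywhere we know of; it only needs to sit in
  the 0.6–3 Hz band).
- **Wash-in.** Single exponential; τ defaults to a quarter of the wash-in
  segment (60 s in vivo, where 3–5 min reaches plateau; 6 s at desk scale)
  so the oxygen segment is ≥ 98% equilibrated in either geometry.
- **Tissues.** Lung parenchyma uses the calibration T1/T2* pairs at proton
  density 0.3, making lungs dark relative to soft tissue as on real UTE
  images (this matters: it is what makes threshold segmentation meaningful
  and what makes ratio maps streak-sensitive, see Limitations). Blood,
  liver and muscle do not enhance.
- **Forward model.** Each view-group's spokes are sampled from the frame
  rendered at the group's center time: 8 ring-arranged Gaussian coil
  sensitivities, Cartesian FFT along z, exact in-plane Fourier summation at
  the spoke sample locations, then complex Gaussian noise scaled to the
  peak k-center magnitude (default 0.2%). All randomness flows from one
  seed; identical configs are bit-reproducible.

What the phantom does **not** emulate: anatomical texture (XCAT-style
atlases), B0 off-resonance and T2* blur along the readout, flow, bulk
motion, coil coupling, and hysteresis between inhale and exhale (breathing
is a single-valued function of phase). Passing tests therefore demonstrate
the correctness of the *processing chain* under controlled conditions, not
clinical performance.

## Self-gating

The k = 0 sample of every center-out spoke is the coil-weighted projection
integral of the instantaneous object; an FFT across the Nz k-centers of a
view-group gives a superior–inferior projection profile every Nz×TR.
Per coil, profiles are normalized by their temporal-mean energy (removing
coil gain and the slow enhancement drift), band-passed to 0.1–0.5 Hz
(zero-phase 4th-order Butterworth; cardiac occupies 0.6–3 Hz), and PCA over
z positions extracts the leading motion component. A coil is *good* when
the unfiltered projection of its PC weights has its spectral peak inside
the respiratory band with ≥ 50% in-band energy — judged before band
limiting, because band-passed noise would trivially qualify. The reported
amplitude is the PC-weight projection of the slow-detrended raw profile,
low-passed at 0.55 Hz (midway between the respiratory and cardiac bands):
keeping the respiratory harmonics preserves the monotone mapping between
amplitude and diaphragm position that pure fundamental-band filtering
distorts, which measurably tightens the amplitude-sorted bins. The
representative signal is the medoid (highest mean |Pearson r| to the other
good-coil components), with its sign set so amplitude correlates positively
with a diaphragm-edge surrogate. If no coil qualifies, the pipeline falls
back to the single best coil with a warning (this is also the degenerate
path for motionless data).

## Binning and state matching

Within each of the air and oxygen segments, view-groups are resorted by
amplitude (stable sort; ties broken by acquisition order) and cut into
overlapping rank windows: window 450 / step 50 on a 1600-view segment gives
the canonical 24 phases; the generic rule `step = n//32`,
`window = n − 23·step` reproduces those numbers and scales to any segment.
Four representative states from end-expiration to end-inspiration default
to phases {1, 9, 16, 24} (rounded linspace — the selection is configurable
since any near-even spacing is defensible). Because breathing depth can
differ between segments, each air state is matched to the oxygen phase with
the closest diaphragm position — per phase, the z of maximum gradient of
the bin-averaged projection profile, parabolic-refined to sub-slice
precision — under a monotonicity constraint solved by dynamic programming,
with an ordered-assignment fallback (warning) if the constraint cannot be
met.

## Reconstruction

kz is Cartesian (inverse FFT), the in-plane non-Cartesian step is
convolution gridding with a Kaiser–Bessel kernel (width 4, oversampling
1.5, Beatty β) and analytic deapodization; forward and adjoint are exact
transposes (unitary FFTs, shared interpolation weights), verified by the
adjoint identity to < 1e−6. Density compensation starts from the analytic
annular ramp (per-sample annulus area, flat-capped at the angular Nyquist
radius, shared k-center divided among spokes) scaled by each spoke's
angular Voronoi share, then is refined by 12 Pipe–Menon iterations with the
gridding kernel. The refinement matters: amplitude-sorted view subsets are
angularly irregular, and with ramp-only weights two subsets of the same
static object disagree at the ~1% level in dark lung — comparable to the
oxygen effect itself; after refinement, bin-to-bin MPSE scatter drops an
order of magnitude. Coils are combined by root-sum-of-squares (no
sensitivity model is assumed), magnitudes are taken, and the slice
direction can be Fourier-resampled to a coarser spacing (the in-vivo
protocol reconstructs 1 cm kz resolution for SNR). No iterative or
compressed-sensing reconstruction is used anywhere.

## Registration

Thirion demons with the classic force
`δu = (m∘(Id+u) − f)∇f / (‖∇f‖² + (m∘(Id+u) − f)²)`, per-iteration update
smoothing (σ_fluid = 1 voxel), field smoothing (σ_diffusion = 1 voxel),
step cap 1 voxel, over a 3-level coarse-to-fine pyramid (50
iterations/level; the slice axis is only downsampled while > 4 slices
remain). Intensities are min–max normalized internally; histogram matching
is deliberately **off** — the oxygen-induced intensity difference is the
signal being measured. Each level returns the field with the lowest
observed mean-squared difference rather than the last iterate: a pure
intensity difference (enhancement without motion) admits no MSE-reducing
displacement, and keeping the best field prevents the slow drift that
would otherwise warp lung edges to "explain away" enhancement. MSE is
consequently non-increasing across levels by construction.

## PSE analysis

Before division, both volumes are low-passed in-plane by a k-space Gaussian
parameterized by target resolution (default 10 mm); the filter applies only
the blur needed *beyond* the native voxel size (resolutions add in
quadrature), so the native target is an exact identity and DC — hence every
mean — is preserved exactly. PSE = 100·(S_O2 − S_air)/S_air on the mask;
voxels whose air signal falls below 1e−6 of the volume maximum are dropped
with a count. The mask at desk scale is phantom ground truth eroded by one
voxel (standing in for manual segmentation that excludes aorta and
diaphragm blur); an Otsu + two-largest-dark-components + erosion fallback
serves data without ground truth. Summary operations: slice-wise MPSE along
the anterior→posterior axis with the posterior/anterior percent increase
(last 4 vs first 3 slices by default; the anterior slice count is an
explicit parameter) and a Spearman rank trend; histogram + Gaussian-KDE
distribution with peak location; test–retest coefficient of variation using
the population (n) standard deviation — with two repeats the n vs n−1
convention is a pure scale factor, and n is the conservative documented
choice.

## Coordinates

Image arrays are (x, y, z) with x = left–right, y = anterior→posterior,
z = superior–inferior — z is the Cartesian kz axis. This puts the
diaphragm edge in the kz projection profile, which is what self-gating and
state matching measure; the gravity-dependence analysis (`ap_trend`)
accordingly slices along y. Internal indexing is 0-based; human-readable
reports are 1-based.

## Problem sizes

The default test suite simulates the full desk-scale study once (matrix
64, nz 8, 8 coils, 1800 view-groups, ~35 s) and runs the complete pipeline
on it (~1 min including ten volume reconstructions, five registrations and
all analysis); smaller static phantoms (600–900 views) isolate individual
stages. These sizes were chosen so every property is measured at the same
view-to-Nyquist and cycles-per-segment ratios as the in-vivo protocol while
the whole suite stays interactive (~2.5 min).

## Known limitations

- Ratio (PSE) maps formed from *different* view subsets inherit each
  subset's residual streaks; with realistically dark lungs this limits
  voxelwise PSE accuracy (~±2 pp at 95th percentile at desk scale) even
  though masked means are accurate to ~0.1 pp. The in-plane low-pass and
  MPSE reporting are the method's own answer to this.
- Demons is intensity-driven: it cannot distinguish enhancement from
  motion along intensity gradients. The best-MSE stopping rule bounds but
  does not eliminate enhancement flattening (~0.5 pp at desk scale).
- Self-gating amplitude is a surrogate, monotone in diaphragm position
  only to ~2% rank error at desk scale (8 kz partitions); middle-phase
  bins are correspondingly broader in true position than end-phase bins.
- The wash-in segment is discarded for imaging (air and oxygen volumes
  come from the protocol ends); fitting wash-in kinetics is out of scope,
  though the sliding-window machinery would support it.
- No cardiac binning, no B0/off-resonance correction, no trajectory-error
  calibration.
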