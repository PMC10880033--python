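# Methods

This note documents the models, numerical choices and known limitations of
the package, in the order of the processing chain.

## Acquisition model

`AcquisitionDescriptor` carries every physical constant of the emulated
protocol: 50 Hz excitation, 2.5 mm isotropic voxels, an 8-slice slab,
four wave phases per vibration period, one acquisition per MEG direction
(x, y, z) plus one without MEG, and a fractional bipolar motion-encoding
gradient of 35 mT/m and 6.1 ms (two rectangular lobes of 3.05 ms). The
default in-plane matrix, 64×54, is half the acquired 128×108 so that the
full pipeline runs in tens of seconds; the full matrix is available via
configuration. Density is fixed at ρ = 1000 kg/m³, the universal
soft-tissue convention in elastography.

For a displacement component u(t) = Re[U e^(−iωt)] the accrued phase over
one MEG is φ = Re[ξ·U] with the complex fractional-encoding efficiency

    ξ = γ G ∫₀^τ s(t) e^(−iωt) dt

(γ gyromagnetic ratio, G gradient amplitude, s(t) the normalized bipolar
waveform). For the rectangular bipolar shape the integral has the closed
form −(i/ω)(1 − e^(−iωτ/2))²; the encoder evaluates it by midpoint
quadrature (≥200 steps) so that any waveform shape can be configured, and
the decoder uses the closed form — the two agree to <0.1%. At the default
parameters |ξ| ≈ 0.0253 rad/µm: a 163 µm displacement produces ≈4 rad of
encoded phase, i.e. the data genuinely wrap.

Time convention: e^(−iωt), with the square root branch of
k = ω√(ρ/G\*) fixed to Re(k) > 0, hence Im(k) ≤ 0 for lossy media. One
non-obvious consequence: |e^(iks)| then *grows* along +s, so a wave of
bounded amplitude inside the kidney must be anchored (unit amplitude) at
the *max*-projection face of its propagation axis.

## Digital kidney phantom

Geometry is a caricature of a kidney imaged as a thin axial slab: nested
ellipsoids for whole kidney, central sinus and an intrasinusoidal vessel,
plus four medullary blobs on an elliptical ring; the cortex is the
remainder. Through-slab semi-axes are much longer than the 8-slice slab
(a kidney is ~11 cm long), so compartment boundaries are dominantly
in-plane and the cortex shell stays connected. Default compartment moduli
(G_d, G_l in kPa): cortex (0.68, 0.48), medulla (0.68, 0.47), sinus
(0.48, 0.24), vessel (0.50, 0.22) — the healthy-kidney range at 50 Hz,
with the vessel made slightly distinct so all four compartments are
separable in recovery tests. On the default grid the compartment voxel
counts are ordered cortex > medulla > sinus > vessel, as in real renal
anatomy.

### Wave synthesis

Within each compartment the displacement is a superposition of locally
exact plane waves u = p·A·exp(i k_ℓ (n̂·r) + iφ₀) using that compartment's
complex wavenumber, so the homogeneous Helmholtz equation holds exactly on
compartment interiors (verified to <2% finite-difference residual on
2-voxel-eroded interiors); boundary voxels are acknowledged as
non-physical and excluded from accuracy statements.

The drive composition is dictated by attenuation physics. At these moduli
α ≈ 0.1 /mm, so an in-plane traveling wave decays by ~5 nepers across the
kidney — a 60× amplitude range across the field of view, which no phase
reconstruction can survive at a 163 µm mean. Real fields avoid this by
reverberation; the phantom avoids it structurally:

* **x/y displacement** — counter-propagating through-slab (±z) shear
  pairs with equal amplitudes and a π relative phase, the flattest
  standing profile over the slab (max/mean ≈ 1.24–1.43 in every
  compartment, with a mid-slab amplitude valley that later seeds the wrap
  correction);
* **z displacement** — eight z-polarized in-plane waves entering at the
  rim from equally spaced azimuths (rim-anchored, decaying inward);
* **compressional contamination** — one longitudinal wave with a real
  wavenumber 6× smaller than the smallest shear |k| (the long-wavelength
  regime the curl operator is meant to remove). Its weight is kept small
  (≈15% of the drive) so the kidney-mean displacement stays at its nominal
  value; consequently the phantom's curl/divergence ratio is higher than
  a reverberant in vivo field's, and is reported as computed.

Each component is normalized to unit peak amplitude inside the kidney and
the total field is rescaled so the kidney-mean total displacement equals
the quadrature sum of the source amplitudes (163 µm by default). The
rescaling is homogeneous of degree one in the amplitudes, so encoding
stays exactly linear in them.

The second harmonic U2 is the fundamental field remodulated to the 2f
wavenumber with the fundamental's amplitude envelope, so |U2| is a fixed
local fraction (default 23%) of |U1| — matching how harmonic contamination
of a drive is defined and measured. A separately launched 2f wave would
decay twice as fast and make the mean contamination depend on position
rather than on the drive.

Noise is additive Gaussian on every phase volume (default 0.05 rad),
including the no-MEG reference; a smooth deterministic background phase
(mimicking static field inhomogeneity) is added to all acquisitions and
must cancel in the reference subtraction. Fixed seeds give bit-identical
phase stacks; everything is written as NIfTI-1 plus a YAML sidecar and
round-trips through the reader.

## Reconstruction

Chain: reference subtraction (wrapped difference), wrap correction,
temporal DFT over the four wave phases, scaling by ξ.

With N = 4 samples the second harmonic sits in the Nyquist bin: its
coefficient uses the 1/N convention, is real, and captures only the cosine
quadrature component — an intrinsic limitation of four-phase acquisitions,
shared by the emulated protocol. Reconstruction of the fundamental is
unaffected (the bins are orthogonal).

### Wrap correction beyond the spatial sampling limit

At 4 rad of encoded phase and 6–8 voxels per wavelength, neighbor steps of
the true phase reach |Δφ| ≈ 4 rad > π: classical spatial unwrapping is
mathematically under-sampled, and empirically leaves ~20% of voxels wrong
here. `model_guided_unwrap` instead uses the temporal model
φₙ = A0 + Re[A1 e^(−2πin/N)] + Re[A2 e^(−4πin/N)]:

1. **Direct harmonic recovery.** For N = 4 the sums φ₀+φ₂ = 2(A0+A2) and
   φ₁+φ₃ = 2(A0−A2) cancel the fundamental exactly and are small enough to
   recover from wrapped data directly — no unwrapping needed for A0, A2.
2. **Recurrence-guided growth.** Any superposition of two exponentials
   along an axis satisfies A1(s+h) = 2C·A1(s) − A1(s−h) with
   C ≈ cos(kh). Starting from a wrap-free low-amplitude seed, a
   priority-driven growth predicts each voxel's four samples from a solved
   neighbor (recurrence where two upstream voxels exist, complex ratio or
   persistence otherwise) and snaps the wrapped samples to the nearest
   2π-congruent values. The prediction error scales with the local
   *change* of the wavenumber, not the wavenumber itself.
3. **Confidence ordering.** The frontier is ordered by (prediction
   confidence, predictor amplitude), so every recurrence-backed step runs
   before any blind one, and the few unavoidable blind steps happen at
   amplitude valleys. Low-confidence steps additionally test the
   2π-congruent candidates around the nominal prediction against the
   wrapped samples one and two voxels ahead.
4. **Regions.** Unwrapping runs per mechanically similar region —
   parenchyma (cortex+medulla) and sinus complex (sinus+vessels) — whose
   internal wavenumber contrasts are negligible while the
   parenchyma/sinus interface carries a ~2.4 rad true phase jump. Each
   region's arbitrary 2π offset is anchored by zeroing its rounded mean
   (valid because every region spans ≳1 wavelength). Errors cannot
   propagate across the interface.
5. **Redundancy and polish.** The growth runs from three well-separated
   seeds and the per-sample median is kept; a final sweep re-snaps each
   voxel against the recurrence predictions of its neighbors with the
   region-median dispersion, eroding any residual mis-solved patch.

On the default phantom this reconstructs the displacement field exactly
(no wrap errors) in the noise-free case and with a fraction of a percent
of affected voxels at 0.05 rad noise. The spec-level spatial unwrapper
(`unwrap_phase`, reliability-sorted, region-aware) remains available and
is exact whenever the data respect the π-per-voxel limit.

## Inversion

* Smoothing: discretely sampled Gaussian, σ = 0.75 voxel, truncated to
  3³ support and renormalized (per-axis center weight
  1/(1+2e^(−8/9))), applied identically to real and imaginary parts.
* Curl/divergence: second-order central differences (one-sided at volume
  edges, which are excluded from validity).
* Laplacian: central stencil of order 2, 4 or 6. The default is 6: at
  6–8 voxels per wavelength the 2nd-order stencil biases |G\*| by +5…+9%
  (dispersion), and because the error is complex for a lossy wave it also
  rotates G\*, leaking storage-modulus-scale error into the much smaller
  loss modulus. Order 6 keeps both effects below ~1%, and the quadratic
  convergence of the order-2 scheme is verified separately.
* Slab padding: the smoothing+gradient+Laplacian chain reaches 5 voxels,
  which would consume the whole 8-slice slab from the z-faces inward.
  Before the chain, the field is extrapolated beyond the slab faces with
  the per-column three-term recurrence (exact for two counter-propagating
  waves; linear fallback at near-zero amplitude). Without it the innermost
  slices inherit edge-padding artefacts worth −4…−7% in G_l.
* Least squares: G\* = −ρω²·Σ(∇²qⱼ)\*qⱼ / (Σ|∇²qⱼ|² + ε) with
  ε = 10⁻⁶ × median |∇²q|² as a division-blow-up floor; voxels below the
  floor, outside the mask, in the stencil halo, or with G_d ≤ 0 are
  flagged invalid, never silently clamped.
* Derived maps use the complex wavenumber (c_s = ω/Re k, α = |Im k|)
  rather than the |G\*| closed form; this choice reproduces the ~0.1 /mm
  attenuation scale of kidney tissue at these moduli and keeps c_s and α
  mutually consistent.

## ROI statistics

Statistics (mean, median, sample SD with n−1, RMS) are computed over valid
voxels only; invalid voxels are excluded, not zero-filled. The composite
ROIs "vessel_sinus" (sinus ∪ vessels) and "kidneys" (all compartments) are
built from the label map. Reporting can be restricted to the two innermost
slices (the slices with the most reliable inversion in an 8-slice slab);
the restriction is applied before the median. Pairwise ROI differences are
first-minus-second of the medians. Boundary voxels are kept in the default
summaries (as any real segmentation-based analysis would), which pulls
compartment medians slightly toward their neighbors; recovery accuracy
statements use 2-voxel-eroded interiors instead.

## Cohort statistics

The study design: each subject measured fasting and after a drinking
challenge, left and right kidney separately; one sample = the median of a
parameter over an ROI. QA metrics are compared with two-sided paired
t-tests (zero-variance differences return p = 1 with a warning);
biomechanical medians with Wilcoxon tests — signed-rank for paired
contrasts (hydration within subject), rank-sum for unpaired ones (ROI vs
ROI on the pooled sample). Ties are excluded (zero differences; values
occurring in both groups) rather than mid-ranked. Exact null distributions
are used for n ≤ 25 without ties, the normal approximation otherwise; the
exact p-values are verified against full enumeration for n ≤ 8.
Significance is α = 0.05 with star annotations (≤0.05/≤0.01/≤0.001); no
multiple-testing correction is applied by default (a Holm option exists).
Left and right kidneys are pooled as paired units with the subject id
retained.

The synthetic cohort generator draws per-(subject, side, state, ROI)
medians as baseline (from the compartment moduli and derived quantities)
plus a subject random effect, a smaller side effect, and measurement
noise; hydration effects are additive shifts on the hydrated state. SDs
are set to the dispersion scale of healthy-kidney medians (e.g. 0.09 kPa
between subjects and 0.025 kPa within for the storage modulus). Under the
null the two states are exchangeable by construction, and the empirical
false-positive rate of the hydration contrast at α = 0.05 is ~0.05
(calibration is checked over 1000 simulated cohorts).

## Problem sizes

Default analyses use the 64×54×8 grid (half the acquired in-plane matrix)
and the two-compartment 24×24×8 phantom for unit tests; the full 128×108×8
matrix is supported via configuration. A full demo-grid
encode→reconstruct→invert chain takes ~40 s on one CPU, dominated by the
wrap solver's three growth passes.

## What the phantom does and does not establish

Passing the recovery tests shows the processing chain is internally
consistent: encoding, wrap correction, scaling, differentiation and the
algebraic inversion are mutually inverse at the study's amplitudes, noise
level and sampling density, including across compartment contrasts.
It does not establish accuracy on real kidneys: the phantom has
piecewise-constant isotropic moduli, locally plane (not reverberant or
scattered) waves, no dispersion between f and 2f, no flow, breathing or
misalignment, idealized magnitude contrast, and sharp (single-voxel)
compartment boundaries. Absolute in vivo MRE values are additionally
method-dependent (smoothing, inversion variant, frequency), so comparisons
across pipelines should rely on contrasts rather than absolute moduli.

## Known limitations

* The wrap solver assumes the temporal model (fundamental + second
  harmonic) and locally two-exponential spatial structure; strongly
  scattered fields would degrade its extrapolation (gracefully — errors
  stay 2π-quantized and region-contained).
* With N = 4 wave phases the second-harmonic amplitude is phase-blind
  (Nyquist bin); reconstructed contamination is a lower bound. QA on the
  synthesized field itself is exact.
* The two-compartment tiny phantom leaves no medulla/vessel, so pipeline
  summaries adapt to the compartments present.
* At amplitudes far above ~250 µm per direction even the model-guided
  solver's valley steps would exceed π and reconstruction would fail; the
  emulated protocol sits safely below this.
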