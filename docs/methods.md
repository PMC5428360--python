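# Methods

## The measurement model

A quadriwave lateral shearing interferometer (QWLSI) replaces the reference
beam of a conventional interferometric microscope with four laterally
displaced replicas of the wavefront under test, produced by a quadriwave
grating of pitch *d*. On a sensor a distance *l* behind the grating, the +1/−1
order pair of each axis is separated by the lateral shear

    s = 2·√2·l·λ/d ,

and their interference encodes the *shearing wavefronts*

    W_x(x, y) = W(x − s/2, y) − W(x + s/2, y)
    W_y(x, y) = W(x, y − s/2) − W(x, y + s/2)

on fringe carriers at spatial frequency 2√2/d along the two sensor axes. In
the Fourier domain the shearing operation is a multiplication:

    F_x(u, v) = −2i·sin(π·s·u)·F(u, v),   F_y(u, v) = −2i·sin(π·s·v)·F(u, v).

The amplitude factor 2·|sin(π·s·u)| is the *spectral sensitivity* of the
measurement relative to an externally referenced interferometer: it reaches 2
at u = 1/(2s) (signal doubled, noise unchanged) and vanishes on the lattice
u = m/s, v = n/s, where the wavefront is unobservable and inversion amplifies
noise without bound (*spectral leaking*). A second interferometer with shear
s′ fills in those blind frequencies; the dual-shear sensitivity

    σ′(u, v) = √2·√( sin²(πsu) + sin²(πsv) + sin²(πs′u) + sin²(πs′v) )

carries a √2 penalty because the beam splitter halves each arm's photons.
The package evaluates σ and σ′ on the centred discrete grid (odd sizes, a
single DC bin), computes the standard deviation of σ′ over all bins for every
shear-ratio pair (β, β′) = (s/L, s′/L), and picks the off-diagonal pair with
the flattest σ′ — the same criterion that singles out pairs near
(1.88%, 1.57%) on a 501² grid over a 7.066 mm field, where σ′ vanishes at DC
only and averages ≈ 2.

## Retrieval pipeline

1. **Demodulation** (`qwlsi.demodulate`). FFT of the interferogram; crop an
   n_out × n_out window centred on each axis sideband; inverse FFT; take the
   argument. The crop width *is* the retrieval resolution (501 on a 2048
   sensor — no zero padding), and the window translation removes the integer
   part of the carrier. The four-replica intensity also contains diagonal
   intermodulation sidebands of equal strength at (±f_c, ±f_c); the carrier
   search therefore looks only inside 22.5° wedges around the positive u and
   v axes. A radial raised-cosine taper (flat to 80% of the window radius,
   default radius = min(n_out/2, 40% of the carrier distance)) suppresses
   cross-talk between sidebands.

2. **Unwrapping** (`qwlsi.dlpu`): differential leveling phase unwrapping, a
   fully vectorized, path-independent algorithm. Periodic forward differences
   of the wrapped phase are re-wrapped ("leveled") into (−π, π], which
   restores the true differential wherever the true gradient is below
   π/pixel. The leveled differentials are integrated in the Fourier domain
   (per-bin least squares with transfer H = e^{2πik/N} − 1, DC fixed to 0)
   into a continuous *reference* phase. The wrap count at each pixel is then
   the rounded difference (reference − wrapped)/2π; adding 2π times that
   count to the wrapped input guarantees congruence — output minus input is
   an integer multiple of 2π everywhere, whatever the input.

   Because a constant differential (a tilt) lives entirely in the zeroed DC
   bin of the integration, the mean slope is estimated separately from the
   differentials — excluding the wrap-around column/row, whose entries hold
   the boundary jump of a non-periodic field rather than a gradient sample —
   removed before integration, and restored as a plane afterwards. This is
   the detilt-then-restore step of the algorithm made concrete: a direct
   plane fit on the wrapped sawtooth would estimate a near-zero slope and
   defeat the rounding. Piston is aligned on the circle (argument of the mean
   phasor of the difference) before rounding; rounding ties break half away
   from zero.

   Correctness domain: exact recovery up to a global 2π constant whenever
   the true gradient magnitude is < π/pixel and the field is compatible with
   the periodic boundary — compact features on a flat background, a plain
   tilt, or any combination. Fields with genuine residues (deep shot noise)
   are handled best-effort; congruence still holds but no accuracy is
   guaranteed. The test suite cross-checks against the sequential
   quality-guided unwrapper in scikit-image.

3. **Fusion** (`qwlsi.reconstruct`). Unwrapped shearing phases are converted
   to optical path difference (W_x = λ·φ_x/2π — the OPD is the wavelength-
   independent quantity) and the wavefront spectrum is the per-bin
   least-squares solution of the four observations:

       F = i·Σ_k sin_k·F_k / (2·Σ_k sin_k²),

   sin_k ∈ {sin(πsu), sin(πsv), sin(πs′u), sin(πs′v)}. With one shear the
   same formula runs over two observations and bins whose denominator falls
   below ε = 10⁻⁶ of its maximum are zeroed and counted (the spectral-leak
   lattice); with two well-chosen shears only the DC bin is blind and no
   regularization is applied. Equal weights assume equal arm noise; weights
   are exposed for unequal exposures. DC (piston) is fixed to zero; tilt is
   reconstructed and preserved. Etch depth follows as z = OPD/(n − 1).

## Synthetic data

The forward model (`qwlsi.simulate`) renders
I = |Σ_k exp(i2π f_k·r)·exp(iφ(r − δ_k))|² for the four orders, with
carriers ±√2/d on each axis and displacements δ_k = l·λ·f_k, so the order
pair separation reproduces s = 2√2·l·λ/d exactly. It is scalar and
monochromatic at the dominant wavelength (623 nm): the grating's carrier
frequency is set by the pitch alone and the shear's λ-dependence cancels in
the shearing phase to first order, so broadband effects enter only at second
order in shear × spatial frequency (see *Limitations*). The camera model maps
the noiseless intensity maximum to a mean photon count, draws Poisson shot
noise, requantizes to a target gray level and clips at the bit-depth
saturation. The default per-frame count of 1400 with an 8-bit mapping target
of 132 gray reproduces a photon-starved acquisition whose frame-to-frame
intensity deviation reaches ≈ 27 gray at a frame maximum of 132 — shot-noise
SD of 3.5 gray at the brightest fringe. Read noise is not modelled.
Inter-camera registration offsets and vibration are emulated by sub-pixel
Fourier translation of the rendered frame.

Phantoms: a 1D sinusoid (the sensitivity probe), an etched circular target
(OPD = −depth·(n−1) inside the disc: etching removes glass, so the disc is
optically thinner; retrieval compares magnitudes), and a reproducible
cell-like field of Gaussian domes and torus shells with configurable blob
widths. All generators take explicit seeds; there is no hidden global state.

What the generator does *not* emulate: partial coherence and speckle,
grating fabrication errors and parasitic orders, camera read noise and fixed
pattern noise, mechanical drift beyond a rigid per-frame translation. Tests
passing on these phantoms therefore demonstrate the correctness of the
*algorithms* under shot noise and quantization, not the full error budget of
a physical instrument.

## Study conditions and problem sizes

- Full-scale geometry (sensitivity maps, noise experiment): 7.066 mm field,
  grating pitch 30 µm, 2048² sensor, 501² retrieval grid, β = 1.88%,
  β′ = 1.57%, λ = 623 nm, 8-bit camera.
- The noise-halving experiment (`qwlsi.benchmarks.noise_halving_ratio`)
  renders 50 shot-noise realizations. The comparison is photon-budget
  normalized, which is what the √2 factor in σ′ presumes: the reference
  (external-reference-equivalent) measurement receives the full mean count
  (2800 at the brightest fringe) and each dual arm half of it (1400). The
  pixel-mean temporal SD of the fused phase divided by that of the reference
  shearing phases comes out ≈ 0.55 at this grid, against ≈ 0.5 expected from
  the mean sensitivity σ′ ≈ 2 alone; the exact per-bin propagation
  √(mean(1/σ′²)) predicts the measured value to within 1%. Runtime is
  ≈ 2 minutes on one CPU; unit tests use a scaled replica of the same
  spectral layout (512² sensor, carrier bin 160, 129² retrieval grid) that
  runs in milliseconds per frame.
- Grids are odd-sized wherever half-pixel Fourier shifts are inverted
  exactly: odd DFTs have no Nyquist bin, whose sub-pixel translation is
  ill-defined.

## Numerical choices

- ε-regularization (single shear): bins with denominator < 10⁻⁶ × maximum are
  zeroed and reported, never interpolated.
- Rounding ties in the unwrap count: half away from zero, fixed for
  reproducibility.
- Carrier localization demands a peak ≥ 5× the median spectral magnitude
  (outside the DC exclusion disc); a pure-DC or noise-only frame raises a
  demodulation error instead of returning garbage.
- The offset estimator binarizes at a fraction (default 0.5) of each map's
  absolute maximum and requires the largest connected component to hold at
  least half the foreground — scattered (noise-only) foregrounds are
  rejected.
- SD maps include the DC bin by default (exclusion is a flag); the SD is the
  population standard deviation over all bins.
- Shear-pair optimizer ties break lexicographically toward smaller ratios;
  the pair is returned as (larger, smaller).

## Limitations

- Achromaticity is first-order: the residual between two wavelengths obeys
  |sinc(πs₁u) − sinc(πs₂u)| ≈ (πsu)²·(Δλ²/λ²)/6 and exceeds 0.5% RMS above
  roughly 12 cycles/field at β = 1.88% for the 614–632 nm span. The 0.5%
  agreement figure applies to specimens band-limited below that — the
  small-shear regime in which the derivative approximation of the shearing
  wavefront holds.
- A hardware grating pitch generally puts the carrier on a fractional DFT
  bin; the residual (sub-bin) carrier appears as a static tilt in the
  shearing phases. It cancels in background subtraction (the systematic-
  error calibration the pipeline supports) and is irrelevant to temporal-SD
  measurements; simulation configs built with `design_config` place the
  carrier on an integer bin instead.
- The DLPU has no residue handling; heavily undersampled or very noisy
  phases unwrap best-effort (congruently, but possibly with local 2π
  errors).
- No GPU path: parallelism is a performance property, not part of the
  contract; the step inventory of the pipeline (2 interferogram FFTs, 4
  crop+IFFTs, 4 unwraps, 4 shearing-wavefront FFTs, 1 fusion, 1 inverse) is
  asserted, timings are only reported.
- At most two shears; no iterative/zonal (Southwell-type) reconstruction.
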