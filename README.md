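# qwlsi — dual-shear quadriwave lateral shearing interferometry

A toolkit for quantitative phase imaging with quadriwave lateral shearing
interferometers (QWLSI): simulation of quadriwave interferograms of phase
objects, Fourier sideband demodulation, path-independent phase unwrapping,
dual-shear least-squares wavefront reconstruction, and the spectral
sensitivity analysis that selects the optimal pair of lateral shears. It is
aimed at people building or modelling self-referenced phase microscopes —
label-free imaging of transparent specimens (cells, etched targets) where the
measured quantity is optical path difference (OPD).

## The method in brief

A quadriwave grating of pitch *d* splits the probe into four replicas; at
distance *l* behind it the replica pair of each axis is sheared by
*s* = 2√2·*l*·λ/*d*, and their interference records the shearing wavefronts
*W*(x∓s/2) − *W*(x±s/2) on fringe carriers. In the Fourier domain shearing is
multiplication by −2i·sin(π·s·u), so the measurement's amplitude sensitivity
relative to an externally referenced interferometer is

σ(u,v) = 2·√(sin²(πsu) + sin²(πsv)),

which doubles the signal at u = 1/(2s) but vanishes on the lattice u = m/s,
v = n/s — the *spectral leaking* problem. A second interferometer with a
different shear s′ complements those blind frequencies; the dual-shear
sensitivity σ′ includes the √2 shot-noise cost of splitting the beam, and the
flattest σ′ over the sampled band (minimum standard deviation over the
frequency grid) defines the optimal shear-ratio pair. The retrieval chain is
sideband crop → inverse FFT → differential-leveling phase unwrapping (a
fully vectorized, path-independent unwrapper) → per-frequency least-squares
fusion of the four shearing-wavefront spectra. See `docs/methods.md` for the
full model, assumptions, and limitations.

## Worked example

Simulate a dual-shear acquisition of a cell-like phantom, retrieve the
wavefront, and check the recovery:

```python
import numpy as np
import qwlsi as q

# a scaled instrument: 512-px sensor, fringe carrier on bin 160, 129-px
# retrieval grid, shear ratios 1.88% / 1.57% of the 7.066 mm field
cfg = q.design_config(sensor_pixels=512, carrier_bins=160, n_pixels=129)
la, lb = cfg.distance_for_beta(0.0188), cfg.distance_for_beta(0.0157)

cells = q.make_cell_phantom(4, (0, 300), seed=7, n_pixels=512,
                            extent_mm=cfg.beam_size_mm)
frame_a = q.render_interferogram(cells, cfg, la, noise="none")
frame_b = q.render_interferogram(cells, cfg, lb, noise="none")

run = q.RunConfig(acquisition=cfg, distance_a_mm=la, distance_b_mm=lb)
result = q.run_pipeline(run, frame_a, frame_b)
print(result.qc["steps"])
print(f"shear residual A: {result.qc['shear_residual_nm']['frame_a']:.3f} nm")
```

prints

```
{'fft_interferogram': 2, 'crop_ifft': 4, 'unwrap': 4,
 'fft_shearing_wavefront': 4, 'least_squares_fusion': 1,
 'ifft_wavefront_spectrum': 1}
shear residual A: 0.162 nm
```

— the step inventory of the retrieval algorithm and the RMS mismatch between
the re-sheared output and the measured shearing wavefront (a fraction of a
nanometre for a noiseless render; the recovered map matches the phantom to
about 0.1% of its 182 nm peak-to-valley). The same pipeline is available from
the shell:

```sh
qwlsi simulate --phantom cells --l1 9.42 --l2 7.86 --noise shot --seed 1 --out sim/
qwlsi retrieve --frame-a sim/frameA.tiff --frame-b sim/frameB.tiff --out out/
qwlsi optimize-shear --beta-min 0.01 --beta-max 0.03 --steps 101
```

Selecting the shear pair for the full-size instrument (501² grid, 7.066 mm
field):

```python
smap = q.sigma_dual(0.0188, 0.0157, extent_mm=7.066, n_pixels=501)
print(q.count_zero_bins(smap), round(float(smap.values.mean()), 2))
```

prints `1 2.0`: one blind bin (DC only) and a mean relative sensitivity of
about 2 — against a whole lattice of blind bins for any single shear.

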