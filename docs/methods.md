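# Methods

## Physical model

X-ray-induced acoustic computed tomography (XACT) images the X-ray
energy deposition (XED) map `H(r)`: a short X-ray pulse heats the
sample, thermoelastic expansion launches an ultrasound wave, and a ring
of transducers records the pressure. Under instantaneous heating in a
homogeneous medium with sound speed `v`, and normalising the Grüneisen
prefactor to unity, the pressure at a detector located at `r_d` is the
time derivative of the integral of `H` over the circular arc of radius
`v t` centred on the detector:

    p(r_d, t) = d/dt ∫_{|r − r_d| = v t} H(r) dθ .

The integral is taken in the angle subtended at the detector (dθ
measure), which absorbs the `1/(vt)` geometric factor of the 2D
spherical mean. Discretising `H` on a pixel grid yields the linear
measurement model `p = M h` with `h` the flattened image.

Assumptions: 2D geometry (sources confined to the detection plane),
ideal point detectors, constant sound speed, no attenuation or
dispersion, no finite-aperture effects.

## Discrete operator

* **Quadrature.** For each detector and time sample the arc is sampled
  at `Nq` angular midpoint nodes restricted to the sector in which the
  arc can intersect the grid bounding box (no effort is spent on empty
  arc segments); the entry is the node mean times the subtended angle.
* **Interpolation.** The image is evaluated at quadrature nodes by
  bilinear interpolation; nodes outside the grid contribute zero.
* **Time derivative.** Second-order central differences in the
  interior, first-order one-sided stencils at the ends, folded into the
  operator.
* **Adjoint.** The adjoint scatters the bilinear weights and applies
  the exact transpose of the derivative stencil, so `⟨Mu, w⟩ = ⟨u, Mᵀw⟩`
  holds to round-off (verified at 1e−10 in the suite). Both directions
  are applied matrix-free; `assemble_dense` materialises the matrix
  only for small test instances (≤ 1e7 entries).

Default quadrature: `Nq = 1000` for data generation, `600` for
reconstruction. Forward data are always generated on a finer grid and
quadrature than the reconstruction uses, so inversion tests do not
commit the inverse crime of inverting their own discretisation.

## Corruption model

Multichannel acquisition electronics interfere so that at each time
step `q` all detectors share one offset:

    p(q) = M(q) h + z(q) 1 + e,   e ~ N(0, σ²I),   z(q) ~ N(0, β²),

giving the per-time-step covariance `Σ(q) = β² 1 1ᵀ + σ² I`. The offset
paints vertical stripes on the sinogram; back-projected through a
circular geometry the stripes become concentric rings. `σ` is set from
a target SNR measured as the mean power of the input sinogram over all
entries (the "measured" AWGN convention — stated because SNR
conventions differ). `β` is hardware-dependent and therefore a free
parameter; the default `β = 3σ` puts the simulation in the
stripe-dominant regime `σ ≤ β` where the artifact is prominent. Noise
and offsets are drawn from separately seeded generators so each
corruption is independently reproducible.

## Weighted reconstruction

By the Sherman–Morrison formula the whitening weight per time step is
`S(q) = σ⁻²(I − 1 1ᵀ/(σ²/β² + Nd))`; in the stripe-dominant limit with
many detectors this reduces to the centering projector

    S = I − (1/Nd) 1 1ᵀ,

symmetric and idempotent with `S1 = 0`: any per-time-step constant
offset is annihilated *exactly*, not merely attenuated (contrast with
Butterworth smoothing, which leaves the column means nonzero). The
constant `σ⁻²` is dropped in this limit — it rescales the objective
without moving the minimiser. For partial views `Nd` is the number of
active detectors.

Three inversions share this weighting:

* **BP** — delay-and-sum back-projection of `b(t) = p(t) − t·dp/dt`
  (the standard circular-geometry term; plain `p(t)` available), a
  non-model baseline.
* **MBP** — model back-projection `ĥ = Mᵀ(S P)`; uncorrected: `Mᵀ P`.
* **MF-LSQR** — matrix-free LSQR (SciPy's `lsqr` on a `LinearOperator`)
  for `min ‖S(Mh − p)‖² + α‖Lh‖²` on the stacked operator
  `[S M; √α·L]`, with `L` the 5-point Laplacian with zero (Dirichlet)
  padding, kept symmetric so the stacked operator has a true adjoint.

### Regularization scale

`α` is dimensionless: the Laplacian block is internally multiplied by
`‖S M‖ / ‖L‖`, with `‖S M‖` estimated once per geometry by ten power
iterations (deterministic, cached) and `‖L‖ = 8`. Without this the
derivative's `1/Δt` factor (~10⁶ s⁻¹ at 20 MHz) makes any fixed penalty
weight meaningless across discretisations. `α = 1` therefore means
"regulariser comparable to the data term"; useful values in the studies
fall in `[0.01, 10]`.

For the correlation (ordering) study `α` is chosen per view by a small
logarithmic sweep `{0.01, 0.1, 1, 10}` maximising Pearson ρ against the
truth on a held-out corruption seed; the sweep table is recorded in the
run manifest. For the resolution study the Gaussian band filter removes
DC, the background level is unrecoverable, and ρ is tiny and flat in
`α`, so ρ-maximisation is not a usable selection rule there; the study
fixes `α = 1.0`, having measured that the reported FWHM moves by only a
few percent over `α ∈ [0.1, 10]`.

### Solver budget and logging

Defaults: 50 iterations, relative tolerance 1e−6 (studies use 25–30
iterations, which the ρ plateaus justify). LSQR is deterministic for
fixed inputs; the optional convergence history re-runs the solve at
increasing iteration limits (SciPy's `lsqr` has no callback), which is
intended for small diagnostic instances only.

## Filters

* **Butterworth low-pass** (order 2, default cutoff 1 MHz): the
  conventional smoothing baseline. "Centered at 1 MHz" is read as a
  1 MHz cutoff since the operation is described as smoothing away
  high-frequency interference; a band-pass variant sits behind the same
  interface. Applied zero-phase (forward–backward), squaring the
  magnitude response, to avoid arrival-time shifts that would bias the
  delay-based reconstructions.
* **Gaussian detection band**: multiplies each row's spectrum by a
  Gaussian amplitude response centred at `Fc` whose full width at half
  maximum is `bw·Fc` (bandwidth defined at amplitude half-maximum,
  −6 dB, the common transducer convention; this choice makes the
  highest band frequency `Fc(1 + bw/2)` and hence reproduces the
  tabulated theoretical resolutions exactly). Applied via the real FFT,
  so negative frequencies are handled symmetrically and the output is
  exactly real.

## Metrics

* **Pearson ρ** over all pixels (scale- and offset-invariant).
* **CNR** `|mean(target) − mean(background)| / std(background)`.
* **FWHM** of a line cross-profile: baseline is the profile minimum
  (reconstructions ride on a background and band-passed profiles have
  negative side lobes — the tabulated widths are sensitive to this
  choice); half-maximum crossings located by linear interpolation.
  Per-line profiles are averaged over the central half of the line
  length to suppress noise; all four lines and their mean are reported.
* **Theoretical resolution** `d = λmax/2 = v / (2 Fc (1 + bw/2))`.

## Phantoms and synthetic data

* **Line phantom** (resolution study): four vertical lines of width
  100 µm, contrasts 1.2/1.43/1.67/1.9 (evenly spanning 1.2–1.9; exact
  per-line values are a documented choice), centre-to-centre pitch
  2 mm, on a unit background, rasterized with area-weighted sub-pixel
  coverage so the 100 µm width is represented exactly in integral even
  on coarser pixels.
* **Shape phantom** (ordering study): a parameterized letter-like
  arrangement — a bar (amplitude 1.0), a disc (0.8) and an open
  U-shaped ring at distinctly lower contrast (0.3) that ring artifacts
  can plausibly eclipse. No canonical multi-target bitmap exists for
  this kind of benchmark, so all correlation-based checks compare
  algorithms against each other (orderings), never against fixed
  reference values.
* **Scenarios**: truth rasterized on the fine grid, forward-projected,
  AWGN added to a target SNR, then per-time-step offsets at
  `β = offset_ratio·σ`. A manifest records every parameter and derived
  seed; rebuilding from the manifest reproduces the data bit-for-bit.

What the generator does *not* emulate: piecewise (cable-bundle)
offsets that are constant only over detector groups, correlated or
non-white electronics noise, finite transducer apertures, acoustic
attenuation/heterogeneity, and out-of-plane signal. Passing tests
therefore demonstrate the mechanism — exact annihilation of
common-mode offsets and its benefit to model-based inversion — not
performance on any specific hardware.

## Study problem sizes

The packaged studies are reduced relative to the full-scale
protocol (2 cm ROI, 30/60 µm grids, Nq 1000/600, 128 detectors,
20 MHz) so each completes in minutes on one CPU; the reductions are the
package's own defaults and are recorded in every run manifest.

* **Resolution study**: 1 cm ROI (the four lines occupy the central
  6 mm × 8 mm), forward 1/32 mm grid with Nq = 700, reconstruction
  1/16 mm with Nq = 450, 128 detectors on a 5 cm ring, 20 MHz sampling,
  5 dB SNR, α = 1.0, 30 iterations. The manifest documents a 25%
  tolerance on measured FWHM: a single 5 dB noise realization moves the
  per-line widths by tens of µm, and the lowest-contrast line at
  Fc = 1 MHz is the least stable measurement.
* **Ordering study**: 2 cm ROI, forward 0.125 mm / Nq = 260,
  reconstruction 0.25 mm / Nq = 160, 64 detectors, 5 MHz sampling
  (the shape phantom's spectrum is essentially below 2 MHz), 5 dB SNR,
  β = 3σ, 10 corruption seeds per view, views 360°/180°/120° as
  contiguous subsets of the full ring (preserving detector pitch,
  matching how a limited-view acquisition uses a physical ring), 25
  iterations, α per view by the sweep above.

## Numerical notes and edge cases

* Quadrature-convergence testing against the analytic disc formula
  excludes arcs within 5 pixels of the tangency radii `|R ± a|/v`:
  grazing arcs probe the discrete edge profile of the rasterized disc
  (an O(pixel) floor independent of Nq), while transversal arcs show
  clean monotone convergence; the disc is rasterized with supersampled
  coverage for the same reason.
* The centering weight removes one dimension per time step; with few
  detectors the lost signal component is material (a 16-detector toy
  loses 1/16 of the data space), which is why correlation comparisons
  are made at 64+ detectors and as medians over seeds.
* `t = 0` (radius-zero arcs) contributes zero; time windows are sized
  to cover every arc intersecting the grid with a two-sample margin.
* Degenerate inputs error loudly: all-zero sinograms with finite SNR
  targets, constant images in ρ, profiles without half-maximum
  crossings, full-mode weights without σ, β.

## Known limitations

* Unregularized LSQR on tiny, ill-conditioned instances can amplify
  last-ulp differences between mathematically identical weighted
  systems; the exactness demonstrations therefore run with a small
  Laplacian weight, which bounds the condition number without changing
  the offset algebra.
* Evaluated FWHM at Fc = 4 MHz (~170 µm) is only ~2.7 reconstruction
  pixels wide; linear-interpolated crossings keep the estimate usable
  but pixel-scale quantisation is part of the reported number.
* The CNR metric and zero-padding utility are exercised synthetically;
  no experimental acquisitions ship with the package.
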