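# Methods

`propct` simulates and analyzes propagation-based phase-contrast micro-CT in
the single-distance, direct-contrast regime: the imaging mode in which a
partially coherent X-ray beam traverses a weakly absorbing specimen, free
propagation over an effective distance converts phase gradients into
edge-enhanced intensity, and a non-iterative Fourier-filter correction
restores a sharp effective exit-plane image before tomographic
reconstruction. This note records the models, conventions, parameter choices
and known limits of the implementation.

## Effective cone-beam geometry

A point-source cone beam with source-to-object distance `z01` and
source-to-detector distance `z02` is treated throughout as an equivalent
parallel-beam system (Fresnel scaling theorem):

    M      = z02 / z01                    geometric magnification
    z_eff  = z01 * z12 / z02              effective propagation distance
    p_eff  = p / M                        effective (object-plane) pixel
    F_eff  = p_eff^2 / (z_eff * lambda)   effective Fresnel number

with `z12 = z02 - z01` and `lambda = hc/E`, `hc = 1.23984193 eV um` (a fixed
package constant, so every derived number is bit-reproducible). Units are
fixed package-wide — distances mm, pixels um, energies keV, wavelengths um —
and config keys carry unit suffixes (`z01_mm`, `pixel_um`) to keep them from
drifting.

`F_eff` locates the contrast regime: `F >> 1` is near-contact absorption
imaging, `F ~< 1` the direct-contrast regime with pronounced edge fringes.
Fresnel numbers are always computed from full-precision intermediates, never
from rounded printed `p_eff`/`z_eff`; sub-percent discrepancies against
rounded literature values for comparable instruments are expected (the
largest we see is ~0.13%, attributable to rounded instrument distances) and
the package makes no attempt to force agreement beyond 1%. One
documented inconsistency in the reference instrument parameters (a stated
object-to-detector distance of 1077.5 mm versus the 1087.5 mm implied by the
stated z01/z02 pair) is resolved in favour of z01/z02, which is the only
choice consistent with the stated 844.0 mm effective distance.

## Synthetic specimen

Real cochlea projection data are not publicly deposited, so all studies run
on a constructed stand-in (synthetic by design, not a substitute drawn from
any measured dataset): a conical-spiral duct of configurable turns whose wall
is "bone", whose lumen is "soft tissue", with a thin membrane sheet spanning
the duct mid-plane (basilar-membrane analog, optionally "ruptured" with
seeded gaps to mimic dried-specimen tears) and an optional near-opaque wire
along the basal turn (cochlear-implant electrode analog). All structure stays
within 45% of the grid half-width so in-plane rotation never clips material.

Materials are `(delta, beta)` pairs, order-of-magnitude realistic at 25 keV:
air (0, 0); soft tissue (4e-7, 2e-10); membrane (5e-7, 3e-10); bone
(9e-7, 2e-9); metal (1e-6, 1e-6). Only the contrast *structure* (three-peak
histogram, near-opaque implant with transmission < 1% across a few tens of
um) matters for the analyses; no claim of quantitative material constants is
made. The attenuation coefficient is `mu = 4 pi beta / lambda`.

Projection uses rotate-then-sum with linear interpolation: the volume is
rotated in-plane about the vertical grid axis (counterclockwise seen from
+axis; theta = 0 projects along +x) and summed along the beam, giving

    phi = -(2 pi / lambda) * integral(delta dL)
    I_0 = exp(-integral(mu dL))

Beer–Lambert attenuation of the path integral is used (not a path integral
of pointwise attenuations, which appears as a typographical variant in parts
of the literature). Projected mass is rotation-invariant to < 0.5% and the
projector is linear in `delta` and `mu` — both asserted by tests.

## Contrast formation

Two forward models produce detector-plane intensities from an exit wave:

* **TIE (linearized)**: `I_z = I_0 (1 - (z/k) lap(phi))`, `k = 2 pi/lambda`,
  with a spectral transverse Laplacian. Valid for slowly varying absorption
  and large Fresnel numbers.
* **Fresnel (full)**: `|IFFT[FFT[sqrt(I_0) e^{i phi}] H]|^2` with
  `H = exp(-i pi lambda z |nu|^2)`, `nu` in cycles/um. Exact free-space
  propagation within the paraxial approximation; a warning fires when the
  kernel's quadratic phase is under-sampled (`lambda z > p^2 N`).

The two agree to < 1% contrast-relative RMS for `F >= 10` and diverge
monotonically as `F` drops — an oracle pair the tests exploit, alongside the
analytic `sin(pi lambda z nu^2)` transfer factor of a weak phase grating.

**Mirror padding.** Every FFT-based operator (propagator, Laplacian, MBA
filter) reflects the frame to the next power of two strictly above its size
before transforming, and crops after. Without this the DFT's implicit
periodization puts a hard jump at the frame border whose spectral ringing
contaminates the whole field (the effect is worst exactly when a frame is
already a power of two and "needs no padding"). The reflection kink still
produces artifacts in a border band a few tens of pixels wide, which is why
edge metrics trim 10% margins and analytic comparisons in tests evaluate
interior regions.

**Detection chain.** Propagation -> penumbral source blur -> flat-field
(detector gain) multiplication -> Poisson counting noise -> dark offset.
The blur is Gaussian with object-plane FWHM `s (M-1)/M` for source FWHM `s`;
the flat pattern combines per-column gain offsets (the stripe/ring driver)
with a smooth ripple; Poisson draws use `numpy`'s Generator seeded per frame
as `(seed, stream_offset + index)`, so one integer seed makes the entire
stack reproducible while frames stay independent. Flat/dark correction is
`(raw - mean(darks)) / (mean(flats) - mean(darks))`; whether dark subtraction
conceptually precedes or follows empty-beam normalization at a real
instrument is declared here, not inferred.

## Phase retrieval: MBA and BAC

The modified Bronnikov algorithm (MBA) estimates a phase map from a single
flat-corrected frame via the regularized filter

    phi_tilde = -IFFT[ FFT[1 - I] / (xi^2 + eta^2 + alpha) ]

with `xi, eta` in **cycles/pixel** (so `alpha` is per-pixel^2 and values of
order 0.005–0.05 suit real detectors) and the leading minus sign carrying
the sign of the inverse Laplacian. Sign conventions in this family of
methods are usually left implicit; this package fixes them so that
`phi_tilde` is a **positive** multiple of the true phase for weak pure-phase
objects — which in turn makes the Bronnikov Aided Correction (BAC) strength
gamma positive:

    I_0_estimate = I_z / (1 - gamma * lap(phi_tilde))

`gamma = 0` is a bit-exact identity. The DC component of the contrast is
retained (the filter is finite at DC); no physical prefactor `z/k` is
applied to `phi_tilde` — the estimate is defined up to scale and `gamma`
absorbs it, so parameter-recovery tests compare shapes (correlation), not
amplitudes. For noiseless pure-phase TIE data and `alpha -> 0` the matched
strength is exactly `gamma = 1/(4 pi^2) ~= 0.0253`, independent of distance
(the phase estimate already scales with z); this closed form anchors the
round-trip identity test at 1e-3 RMS.

The BAC denominator is clamped at 1e-3 with the affected pixel fraction
logged; above 1% clamped pixels the call fails with advice to reduce gamma.
In practice `alpha` and `gamma` are chosen by visual inspection; as a
convenience extension `tune_bac` grid-searches both, minimizing residual
edge overshoot subject to the fitted edge width staying within 110% of a
reference width. The honest reference is the *contact* (absorption-only,
source-blurred) edge width: diffraction fringes bias an erf fit of the raw
propagated edge several-fold too narrow, so "width did not grow" measured
against that biased number would be unreasonably strict. On a bone knife
edge at the F ~ 0.61 geometry the tuned correction removes > 99% of the
overshoot while ending *sharper* than the contact image.

## Reconstruction

Retrieved intensities are converted to sinograms by `-ln I` (clamped at
1e-6, hard failure above 1% clamped pixels), one sinogram per detector row.

**Ring suppression**: the per-column mean over angles is compared with its
moving median (window 9 columns, configurable); the deviation — the stripe a
miscalibrated column produces — is subtracted from every row, and the
sinogram mean is restored. The scheme is deterministic and near-identity on
smooth data (< 0.1% RMS change); an injected constant column offset loses
>= 99% of its stripe content.

**FBP**: slice-wise filtered backprojection with frequency-domain filtering
of zero-padded projections (2x the next power of two). The ramp is built
from the discrete real-space kernel (`h[0] = 1/4`, `h[odd] = -1/(pi n)^2`),
which fixes the DC term at its analytic limit and avoids cupping; Shepp-
Logan and Hann apodizations are available. Backprojection uses per-pixel
linear interpolation with the detector coordinate `s = y cos(theta) -
x sin(theta)`, the convention that round-trips the package's own projector
(asserted by an off-center-disc test and cross-checked against
scikit-image's `iradon` as an independent reference). Angle weights are half
the neighbouring gaps, so non-uniform angle lists integrate correctly;
full-circle data get an extra factor 1/2 for the double coverage. Output is
scaled to 1/mm using the effective pixel. Grey values after BAC mix
absorption and phase contributions; no absolute calibration is attempted.
360-degree stacks are used as-is (no rebinning to 180 degrees).

A uniform analytic disc reconstructs to 0.03% in its core at 800 angles, and
the error against the angle-converged reconstruction falls strictly
monotonically from 50 through 800 angles. The end-to-end self-consistency
test (phantom -> project -> exp -> -log -> FBP) uses a 1-voxel Gaussian
band-limited phantom: FBP inverts the ray transform of band-limited
functions, and a binary voxel phantom violates that assumption with
irreducible edge-discretization error (~7.5% of dynamic range at 64^3,
against < 5% for the band-limited object — the number the test asserts).

## Quality metrics

* **Radial PSD**: azimuthal mean of `|FFT|^2 / Npix^2` in one-sample annuli,
  normalized by its maximum; raw bin means and counts are kept so Parseval
  (`sum(counts * raw) = mean(frame^2)`) is testable. A fixed-threshold
  rolloff frequency (normalized PSD falling below 1e-7, 5-bin smoothed)
  serves as a robust "transition to noise" marker across a defocus series.
* **Even/odd split**: disjoint exhaustive half-stacks from alternating
  projections, the standard construction of two independent reconstructions.
* **FSC**: per-shell normalized cross-correlation of the central cube
  (default up to 1000^3), shell width one frequency sample. The 1/2-bit
  threshold uses the van Heel–Schatz closed form
  `T(n) = (0.2071 + 1.9102/sqrt(n)) / (1.2071 + 0.9102/sqrt(n))` with `n`
  the count of *independent* Fourier samples per shell — half the voxel
  count, since a real volume's spectrum is Hermitian. The crossover is the
  first shell where FSC falls below threshold, refined by linear
  interpolation; a never-crossing curve reports Nyquist with a flag (small
  test volumes hit this). Half-period resolution is
  `voxel_um / (2 nu_c)` with `nu_c` in cycles/voxel — one voxel at Nyquist.
* **Edge resolution**: least-squares `a erf((x - x0)/(sqrt(2) sigma)) + b`,
  initialized from the extrema and steepest gradient; half-period =
  `FWHM/2 * pixel` with `FWHM = 2 sqrt(2 ln 2) sigma`. A companion
  plateau-based overshoot measure (medians of the outer profile quarters)
  is used where fringing makes the erf fit unreliable.
* **SNR**: `(mean(signal ROI) - mean(background ROI)) / std(background)`,
  a contrast-to-background-noise ratio between, e.g., bone and air ROIs.
  This operational definition is an assumption — reported SNR conventions
  vary — so only *relative* SNR statements (before/after correction,
  between configurations) are meaningful, never absolute comparisons to
  published values.

## Defocus-series study conditions

The defocus analysis fixes the source (98 um FWHM, the ~41.5 um rms spot of
the modelled compact source) and object distance, and sweeps the detector
through z_eff = 85.5, 351.4, 844.0 mm. Two targets are probed: a bone edge
with a ~30 um intrinsic width (6 px at 5 um sampling — anatomical
boundaries are not knife edges; with a sub-pixel edge the growing penumbra
at high magnification wipes the sub-pixel fringes faster than the contrast
transfer builds them, and the overshoot ordering genuinely inverts), and a
noisy phantom projection for the PSD (10^4 counts — photon noise is part of
the measurement this emulates; the noise floor is what the rolloff metric
detects). Under these conditions edge overshoot and mid-band (0.006–0.015
cycles/um) PSD rise monotonically with distance while the rolloff frequency
falls — contrast is bought with resolution, the trade the defocus experiment
exists to exhibit. At the shortest distance the edge shows essentially no
overshoot (2e-4): a pure absorption image.

## Problem sizes and determinism

Desk-scale stand-ins are used throughout: 48–96^3 phantoms with 60–200
angles for end-to-end runs, 128^3 volumes for FSC statistics, 128–256 px
frames for retrieval benchmarks — sizes chosen so the full suite and the
acceptance script each complete in minutes on one core while every
qualitative property (regime orderings, identities, convergence rates)
is preserved. Consequences of the scale: FSC shell counts are thousands,
not millions (the 1/2-bit threshold sits visibly above its asymptote), and
the synthetic FSC half-periods land near 1.4 voxels rather than the 2–3
voxel half-periods typical of real scans. What passing tests demonstrate is
the correctness and internal consistency of the machinery, not the field
performance of any instrument: the synthetic data contain no polychromatic
beam hardening, no scatter, no detector PSF beyond the source penumbra, no
partial-coherence structure beyond a Gaussian spot, and no motion or drift.

All randomness flows from one integer seed through named streams; identical
config + seed reproduce every artifact byte-for-byte (HDF5 datasets are
written with `track_times=False`). Computation is float64, storage float32.

## Known limitations

* Parallel-beam reduction everywhere: fine for low-divergence geometries,
  increasingly wrong for wide cones (a true cone-beam engine would slot in
  at the `fbp` interface).
* The MBA/BAC pair assumes the TIE regime; at F well below ~0.5 the
  linearization error grows and `tune_bac` compensates only empirically.
* `tune_bac` optimizes a single row's edge profile; it is a convenience for
  synthetic benchmarks, not a replacement for visual parameter selection on
  real data.
* The ring filter removes *constant* stripes only; time-varying gain or
  partial rings are out of scope.
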