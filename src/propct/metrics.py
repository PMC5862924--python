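"""Image-quality metrics: angularly averaged PSD, even/odd projection
splitting, Fourier shell correlation with the 1/2-bit threshold, erf
edge-profile resolution, and ROI signal-to-noise.

Resolution conventions
----------------------
* FSC frequencies are in cycles/voxel; the "half-period resolution" at the
  first threshold crossing nu_c is ``voxel_um / (2 * nu_c)`` — at Nyquist
  (0.5 cycles/voxel) exactly one voxel.
* The 1/2-bit information threshold uses the van Heel & Schatz closed form
  ``T(n) = (0.2071 + 1.9102/sqrt(n)) / (1.2071 + 0.9102/sqrt(n))`` with n the
  number of *independent* Fourier samples per shell (half space, because the
  spectrum of a real volume is Hermitian).
* Edge resolution is half the FWHM of an error function fitted to an edge
  profile: ``half_period = FWHM/2 * pixel_um`` with ``FWHM =
  2*sqrt(2 ln 2)*sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import erf

from .waveprop import ProjectionStack

__all__ = [
    "RadialPSD",
    "FSCResult",
    "EdgeFit",
    "radial_psd",
    "psd_rolloff_frequency",
    "split_even_odd",
    "fsc",
    "half_bit_threshold",
    "edge_resolution",
    "edge_overshoot",
    "profile_overshoot",
    "snr_measure",
]


@dataclass
class RadialPSD:
    """Angularly averaged power spectral density of a 2D frame."""

    freqs: np.ndarray        # radial frequency per bin
    power: np.ndarray        # normalized by the maximum, in [0, 1]
    power_raw: np.ndarray    # pre-normalization bin means, |F|^2 / Npix^2
    counts: np.ndarray       # samples per annular bin
    freq_unit: str           # "cycles/um" or "cycles/pixel"


@dataclass
class FSCResult:
    """Fourier shell correlation of two volumes with 1/2-bit threshold."""

    shell_freqs: np.ndarray  # cycles/voxel
    fsc: np.ndarray
    n_shell: np.ndarray      # independent Fourier samples per shell
    threshold: np.ndarray    # 1/2-bit values per shell
    crossover_freq: float    # cycles/voxel
    half_period_um: float
    never_crossed: bool = False


@dataclass
class EdgeFit:
    """Error-function fit of an edge profile."""

    center: float            # edge position, pixels
    sigma: float             # Gaussian width, pixels
    amplitude: float         # half step height (signed)
    offset: float            # mid-step level
    residual_rms: float
    pixel_um: float = 1.0

    @property
    def fwhm(self) -> float:
        return 2.0 * np.sqrt(2.0 * np.log(2.0)) * self.sigma

    @property
    def half_period_um(self) -> float:
        return 0.5 * self.fwhm * self.pixel_um


def radial_psd(frame: np.ndarray, pixel_um: float | None = None) -> RadialPSD:
    """Azimuthal average of |FFT|^2 in annular bins one frequency sample wide.

    The returned curve is normalized by its maximum; the raw bin means are
    kept so that the Parseval identity
    ``sum(counts * power_raw) == mean(frame**2)`` can be checked.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2 or not np.all(np.isfinite(frame)):
        raise ValueError("expected a finite 2D frame")
    h, w = frame.shape
    psd = np.abs(np.fft.fft2(frame)) ** 2 / frame.size**2
    fy = np.fft.fftfreq(h)  # cycles/pixel
    fx = np.fft.fftfreq(w)
    r = np.hypot(fy[:, None], fx[None, :])
    nbin = min(h, w)  # bin width = one frequency sample of the smaller axis
    idx = np.round(r * nbin).astype(int)
    n_shells = idx.max() + 1
    counts = np.bincount(idx.ravel(), minlength=n_shells)
    sums = np.bincount(idx.ravel(), weights=psd.ravel(), minlength=n_shells)
    power_raw = sums / np.maximum(counts, 1)
    freqs = np.arange(n_shells) / nbin  # cycles/pixel
    if pixel_um is not None:
        freqs = freqs / pixel_um
        unit = "cycles/um"
    else:
        unit = "cycles/pixel"
    return RadialPSD(freqs, power_raw / power_raw.max(), power_raw, counts, unit)


def psd_rolloff_frequency(
    psd: RadialPSD, threshold: float = 1e-7, smooth: int = 5
) -> float:
    """Frequency where the normalized PSD falls below a fixed threshold.

    A moving-average smoothing (``smooth`` bins) suppresses per-bin sampling
    scatter; the first three bins (DC and its immediate neighbors) are
    excluded. Returns the last frequency if the curve never drops below the
    threshold. Used to compare resolution loss across a defocus series: a
    larger source penumbra pushes this transition to lower frequencies.
    """
    kernel = np.ones(smooth) / smooth
    sm = np.convolve(psd.power, kernel, mode="same")
    idx = np.nonzero(sm[3:] <= threshold)[0]
    return float(psd.freqs[idx[0] + 3]) if idx.size else float(psd.freqs[-1])


def split_even_odd(stack: ProjectionStack) -> tuple[ProjectionStack, ProjectionStack]:
    """Disjoint, exhaustive even-index / odd-index projection subsets."""
    if stack.n_angles < 2:
        raise ValueError("need at least 2 frames to split")

    def subset(sl: slice) -> ProjectionStack:
        return ProjectionStack(
            frames=stack.frames[sl].copy(),
            angles_deg=stack.angles_deg[sl].copy(),
            pixel_um=stack.pixel_um,
            geometry=stack.geometry,
            meta=dict(stack.meta),
        )

    return subset(slice(0, None, 2)), subset(slice(1, None, 2))


def half_bit_threshold(n_shell) -> np.ndarray | float:
    """1/2-bit information threshold for n independent samples per shell.

    ``(0.2071 + 1.9102/sqrt(n)) / (1.2071 + 0.9102/sqrt(n))``; equals 1 at
    n = 1 and decreases monotonically to 0.2071/1.2071 ~= 0.1716.
    """
    n = np.asarray(n_shell, dtype=np.float64)
    if np.any(n < 1):
        raise ValueError("shell sample counts must be >= 1")
    rs = 1.0 / np.sqrt(n)
    out = (0.2071 + 1.9102 * rs) / (1.2071 + 0.9102 * rs)
    return float(out) if np.isscalar(n_shell) else out


def _central_crop(vol: np.ndarray, size: int) -> np.ndarray:
    slices = []
    for s in vol.shape:
        c = min(size, s)
        start = (s - c) // 2
        slices.append(slice(start, start + c))
    return vol[tuple(slices)]


def fsc(
    vol_a: np.ndarray,
    vol_b: np.ndarray,
    central_crop: int = 1000,
    voxel_um: float = 1.0,
) -> FSCResult:
    """Fourier shell correlation between two independent reconstructions.

    Volumes are first cropped to the central cube (default up to 1000^3).
    Per shell of width one frequency sample:
    ``Re<F_A conj(F_B)> / sqrt(<|F_A|^2><|F_B|^2>)``. The resolution is read
    at the first crossing below the 1/2-bit threshold, refined by linear
    interpolation; if the curve never crosses, Nyquist is reported with
    ``never_crossed=True``.
    """
    a = np.asarray(vol_a, dtype=np.float64)
    b = np.asarray(vol_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("volumes must share a shape")
    a = _central_crop(a, central_crop)
    b = _central_crop(b, central_crop)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("FSC undefined for zero-variance volumes")

    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    grids = np.meshgrid(*[np.fft.fftfreq(s) * s for s in a.shape], indexing="ij")
    r = np.sqrt(sum(g**2 for g in grids))
    n_half = min(a.shape) // 2
    idx = np.round(r).astype(int).ravel()
    valid = idx <= n_half
    idx = idx[valid]

    cross = (fa * np.conj(fb)).real.ravel()[valid]
    pa = (np.abs(fa) ** 2).ravel()[valid]
    pb = (np.abs(fb) ** 2).ravel()[valid]
    num = np.bincount(idx, weights=cross, minlength=n_half + 1)
    da = np.bincount(idx, weights=pa, minlength=n_half + 1)
    db = np.bincount(idx, weights=pb, minlength=n_half + 1)
    counts = np.bincount(idx, minlength=n_half + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = num / np.sqrt(da * db)
    curve = np.nan_to_num(curve, nan=0.0)

    n_indep = np.maximum(counts / 2.0, 1.0)  # Hermitian half space
    thresh = half_bit_threshold(n_indep)
    freqs = np.arange(n_half + 1) / min(a.shape)  # cycles/voxel

    below = np.nonzero(curve < thresh)[0]
    below = below[below > 0]
    if below.size == 0:
        crossover = freqs[-1]
        never = True
    else:
        j = below[0]
        d0 = curve[j - 1] - thresh[j - 1]
        d1 = curve[j] - thresh[j]
        frac = d0 / (d0 - d1) if d0 != d1 else 0.0
        crossover = float(freqs[j - 1] + frac * (freqs[j] - freqs[j - 1]))
        never = False
    half_period = voxel_um / (2.0 * crossover) if crossover > 0 else np.inf
    return FSCResult(freqs, curve, n_indep, thresh, crossover, half_period, never)


def _erf_model(x, amplitude, center, sigma, offset):
    return amplitude * erf((x - center) / (np.sqrt(2.0) * sigma)) + offset


def edge_resolution(profile: np.ndarray, pixel_um: float = 1.0) -> EdgeFit:
    """Least-squares erf fit to a single monotone edge profile.

    Initialization: offset and amplitude from the profile extrema, center at
    the steepest gradient. The fitted sigma is floored at a hundredth of a
    pixel (an ideal step edge fits to sigma ~ 0).
    """
    p = np.asarray(profile, dtype=np.float64)
    if p.ndim != 1 or p.size < 8:
        raise ValueError("expected a 1D profile with >= 8 samples")
    x = np.arange(p.size, dtype=np.float64)
    grad = np.gradient(p)
    i0 = int(np.argmax(np.abs(grad)))
    amp0 = (p[-1] - p[0]) / 2.0 or (p.max() - p.min()) / 2.0
    off0 = (p.max() + p.min()) / 2.0
    sig0 = max(1.0, p.size / 20.0)
    try:
        popt, _ = curve_fit(
            _erf_model,
            x,
            p,
            p0=[amp0, float(i0), sig0, off0],
            bounds=(
                [-np.inf, 0.0, 1e-2, -np.inf],
                [np.inf, float(p.size), float(p.size), np.inf],
            ),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"edge fit failed to converge (init center={i0}, sigma={sig0}): {exc}"
        ) from exc
    resid = p - _erf_model(x, *popt)
    return EdgeFit(
        center=float(popt[1]),
        sigma=float(popt[2]),
        amplitude=float(popt[0]),
        offset=float(popt[3]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        pixel_um=pixel_um,
    )


def edge_overshoot(profile: np.ndarray, trim: float = 0.1) -> tuple[float, float]:
    """Relative overshoot amplitude and fitted width of an edge profile.

    Fits the erf model, then measures how far the profile exceeds the fitted
    asymptotic plateaus on either side, relative to the full step height.
    A ``trim`` fraction is dropped from each end first (frame borders carry
    windowing artifacts unrelated to the edge response).
    Returns ``(overshoot_fraction, sigma_pixels)``.
    """
    p = np.asarray(profile, dtype=np.float64)
    k = int(trim * p.size)
    if k:
        p = p[k:-k]
    fit = edge_resolution(p)
    step = 2.0 * abs(fit.amplitude)
    if step == 0:
        return 0.0, fit.sigma
    hi = fit.offset + abs(fit.amplitude)
    lo = fit.offset - abs(fit.amplitude)
    over = max(float(p.max() - hi), float(lo - p.min()), 0.0)
    return over / step, fit.sigma


def profile_overshoot(profile: np.ndarray, trim: float = 0.1) -> float:
    """Fringe overshoot of an edge profile from median plateau estimates.

    The plateaus are taken as the medians of the outer quarters of the
    (trimmed) profile — robust when diffraction fringes make an erf fit
    unreliable. Returns the excursion beyond the plateaus relative to the
    step height.
    """
    p = np.asarray(profile, dtype=np.float64)
    k = int(trim * p.size)
    if k:
        p = p[k:-k]
    q = p.size // 4
    lo, hi = sorted((float(np.median(p[:q])), float(np.median(p[-q:]))))
    step = hi - lo
    if step <= 0:
        return 0.0
    return max(float(p.max()) - hi, lo - float(p.min()), 0.0) / step


def snr_measure(
    image: np.ndarray, roi_signal: np.ndarray, roi_background: np.ndarray
) -> float:
    """Contrast-to-background-noise ratio between two ROIs.

    ``(mean(signal) - mean(background)) / std(background)``, the package's
    operational SNR between e.g. bone and air on a virtual slice. ROIs are
    boolean masks; they must be disjoint and contain >= 25 pixels each.
    """
    image = np.asarray(image, dtype=np.float64)
    sig = np.asarray(roi_signal, dtype=bool)
    bkg = np.asarray(roi_background, dtype=bool)
    if np.any(sig & bkg):
        raise ValueError("signal and background ROIs must be disjoint")
    if sig.sum() < 25 or bkg.sum() < 25:
        raise ValueError("each ROI must contain at least 25 pixels")
    noise = image[bkg].std(ddof=1)
    if noise == 0:
        raise ValueError("background ROI has zero standard deviation")
    return float((image[sig].mean() - image[bkg].mean()) / noise)
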