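"""Forward contrast formation: TIE and Fresnel propagation, source blur,
counting noise, and flat/dark-field handling.

The cone-beam setup is reduced to effective parallel-beam variables (Fresnel
scaling theorem): propagation over ``z_eff`` sampled at ``p_eff``. Two
forward models are provided:

* :func:`tie_forward` — the linearized transport-of-intensity contrast
  ``I_z = I_0 * (1 - (z/k) * laplacian(phi))``, valid for slowly varying
  absorption and large Fresnel numbers;
* :func:`fresnel_forward` — full free-space (Fresnel/angular-spectrum)
  propagation ``|IFFT[FFT[sqrt(I_0) e^{i phi}] * H]|**2`` with
  ``H(nu) = exp(-i pi lambda z |nu|**2)``, valid at any Fresnel number as
  long as the quadratic kernel phase is sampled adequately.

The detection chain used by the pipeline is: propagation -> source blur ->
flat-field multiplication -> Poisson noise -> dark offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from ._fft import pad_mirror
from .geometry import ConeBeamGeometry
from .phantom import ExitWave
from .retrieval import fourier_laplacian

__all__ = [
    "ProjectionStack",
    "tie_forward",
    "fresnel_forward",
    "source_blur",
    "add_counting_noise",
    "flat_dark_correct",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ProjectionStack:
    """An angle-ordered stack of detector-plane intensity frames."""

    frames: np.ndarray          # (n_angles, n_rows, n_cols)
    angles_deg: np.ndarray      # (n_angles,)
    pixel_um: float
    flats: np.ndarray | None = None
    darks: np.ndarray | None = None
    geometry: ConeBeamGeometry | None = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3D (angle, row, col) array")
        if len(self.frames) != len(self.angles_deg):
            raise ValueError(
                f"{len(self.frames)} frames but {len(self.angles_deg)} angles"
            )
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)


def tie_forward(wave: ExitWave, z_eff_mm: float, wavelength_um: float) -> np.ndarray:
    """TIE intensity at distance z: ``I_0 * (1 - (z/k) * laplacian(phi))``.

    ``z/k = z * lambda / (2 pi)`` in um**2; the Laplacian is evaluated
    spectrally in physical units (1/um**2). Negative values (a sign the
    linearization broke down) are clipped to zero with a warning.
    """
    if z_eff_mm < 0:
        raise ValueError("z_eff must be >= 0")
    z_um = z_eff_mm * 1e3
    z_over_k = z_um * wavelength_um / (2.0 * np.pi)
    lap = fourier_laplacian(wave.phase, pixel_um=wave.pixel_um)
    out = wave.exit_intensity * (1.0 - z_over_k * lap)
    if np.any(out < 0):
        warnings.warn(
            "TIE linearization produced negative intensities; clipped at 0",
            stacklevel=2,
        )
        out = np.clip(out, 0.0, None)
    return out


def fresnel_forward(
    wave: ExitWave,
    z_eff_mm: float,
    wavelength_um: float,
    pixel_um: float | None = None,
) -> np.ndarray:
    """Fresnel free-space propagation of the exit wave to distance z.

    The complex exit wave ``sqrt(I_0) * exp(i phi)`` is mirror-padded to the
    next power of two, multiplied in Fourier space by the Fresnel transfer
    function ``H = exp(-i pi lambda z |nu|**2)`` (nu in cycles/um) and
    transformed back; the returned quantity is the cropped intensity.
    z = 0 returns ``I_0`` exactly. Warns when the kernel's quadratic phase is
    under-sampled (``lambda * z > pixel**2 * N``), recommending padding.
    """
    p = wave.pixel_um if pixel_um is None else pixel_um
    z_um = z_eff_mm * 1e3
    if z_um == 0:
        return wave.exit_intensity.astype(np.float64, copy=True)
    psi = np.sqrt(np.asarray(wave.exit_intensity, dtype=np.float64)) * np.exp(
        1j * np.asarray(wave.phase, dtype=np.float64)
    )
    padded, crop = pad_mirror(psi)
    n = min(padded.shape)
    if wavelength_um * z_um > p * p * n:
        warnings.warn(
            "Fresnel kernel under-sampled at this distance; pad the frame to "
            f">= {int(np.ceil(wavelength_um * z_um / p**2))} pixels",
            stacklevel=2,
        )
    fy = np.fft.fftfreq(padded.shape[0], d=p)
    fx = np.fft.fftfreq(padded.shape[1], d=p)
    nusq = fy[:, None] ** 2 + fx[None, :] ** 2
    h = np.exp(-1j * np.pi * wavelength_um * z_um * nusq)
    prop = np.fft.ifft2(np.fft.fft2(padded) * h)
    return np.abs(prop[crop]) ** 2


def source_blur(
    frame: np.ndarray, source_fwhm_um: float, geom: ConeBeamGeometry
) -> np.ndarray:
    """Penumbral blur of a finite Gaussian source spot.

    A source of FWHM ``s`` casts a penumbra of width ``s * z12/z01 =
    s * (M-1)`` in the detector plane, i.e. ``s * (M-1)/M`` in the effective
    object plane; that FWHM in effective pixels sets the Gaussian kernel.
    Identity for a point source or contact geometry.
    """
    if source_fwhm_um < 0:
        raise ValueError("source FWHM must be >= 0")
    m = geom.magnification
    if source_fwhm_um == 0 or m == 1:
        return np.asarray(frame, dtype=np.float64).copy()
    fwhm_px = source_fwhm_um * (m - 1.0) / m / geom.effective_pixel_um
    sigma = fwhm_px * _FWHM_TO_SIGMA
    return ndimage.gaussian_filter(
        np.asarray(frame, dtype=np.float64), sigma, mode="nearest"
    )


def add_counting_noise(frame: np.ndarray, mean_counts: float, seed) -> np.ndarray:
    """Poisson photon-counting noise at ``mean_counts`` photons per unit signal.

    Draws per-pixel Poisson counts with mean ``frame * mean_counts`` and
    rescales back by ``1/mean_counts``. ``seed`` may be an int or a sequence
    (e.g. ``(run_seed, frame_index)``) for reproducible per-frame streams.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if not mean_counts > 0:
        raise ValueError("mean_counts must be positive")
    if np.any(frame < 0):
        raise ValueError("cannot draw Poisson counts from negative intensities")
    rng = np.random.default_rng(seed)
    return rng.poisson(frame * mean_counts).astype(np.float64) / mean_counts


def flat_dark_correct(raw: ProjectionStack) -> ProjectionStack:
    """Empty-beam (flat) and dark-field correction.

    Per pixel: ``(raw - mean(darks)) / (mean(flats) - mean(darks))``. Darks
    default to zero when absent. Pixels where the flat-dark difference is
    non-positive raise, reporting how many pixels are affected.
    """
    if raw.flats is None:
        raise ValueError("flat-field frames required for empty-beam correction")
    flat = np.mean(np.asarray(raw.flats, dtype=np.float64), axis=0)
    if raw.darks is not None:
        dark = np.mean(np.asarray(raw.darks, dtype=np.float64), axis=0)
    else:
        dark = np.zeros_like(flat)
    denom = flat - dark
    n_bad = int(np.count_nonzero(denom <= 0))
    if n_bad:
        raise ValueError(
            f"flat minus dark is non-positive on {n_bad} pixels; cannot normalize"
        )
    corrected = (np.asarray(raw.frames, dtype=np.float64) - dark) / denom
    return ProjectionStack(
        frames=np.clip(corrected, 0.0, None),
        angles_deg=raw.angles_deg.copy(),
        pixel_um=raw.pixel_um,
        geometry=raw.geometry,
        meta={**raw.meta, "flat_corrected": True},
    )
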