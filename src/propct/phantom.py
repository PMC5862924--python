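"""Synthetic cochlea-like phantoms and parallel-ray forward projection.

The phantom mimics the gross structure of a small-animal cochlea as seen in
propagation-based micro-CT: a spiral bone shell (the otic capsule / osseous
spiral lamina analog) enclosing a soft-tissue-filled duct, one or more thin
membranes spanning the duct (basilar-membrane analog), and optionally a
near-opaque curved metal wire emulating an electrical cochlear-implant
electrode. Each material is described by its refractive index
``n = 1 - delta + i*beta``; the linear attenuation coefficient follows as
``mu = 4*pi*beta / lambda``.

Projection uses the rotate-then-sum scheme: the volume is rotated in-plane
about the vertical grid axis by the projection angle (counterclockwise viewed
from the +axis; theta = 0 projects along +x), then summed along the beam with
trapezoid-free voxel-length weighting. The exit wave follows the projection
approximation:

    phase       phi   = -(2*pi/lambda) * integral(delta dL)
    intensity   I_0   = exp(-integral(mu dL)),   mu = 4*pi*beta/lambda
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "MaterialSpec",
    "PhantomParams",
    "VoxelPhantom",
    "ExitWave",
    "default_materials",
    "build_cochlea_phantom",
    "forward_project",
    "attenuation_coefficient",
    "edge_exit_wave",
]

# label codes in VoxelPhantom.labels
AIR, SOFT, BONE, MEMBRANE, METAL = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class MaterialSpec:
    """One material: refractive-index decrement and absorption index."""

    name: str
    delta: float
    beta: float

    def __post_init__(self) -> None:
        if self.delta < 0 or self.beta < 0:
            raise ValueError(f"material {self.name}: delta and beta must be >= 0")


def default_materials() -> dict[str, MaterialSpec]:
    """Order-of-magnitude realistic constants for ~25 keV photons.

    Only the contrast structure (three-material histogram, near-opaque metal)
    matters for the synthetic studies; absolute values are documented
    defaults, not fits. The metal beta is chosen so that a wire a few tens of
    um thick transmits well below 1%.
    """
    return {
        "air": MaterialSpec("air", 0.0, 0.0),
        "soft": MaterialSpec("soft", 4e-7, 2e-10),
        "bone": MaterialSpec("bone", 9e-7, 2e-9),
        "membrane": MaterialSpec("membrane", 5e-7, 3e-10),
        "metal": MaterialSpec("metal", 1e-6, 1e-6),
    }


@dataclass
class PhantomParams:
    """Geometry and material parameters of the synthetic cochlea phantom."""

    grid_size: int = 64
    voxel_um: float = 5.0
    n_turns: float = 2.0
    shell_thickness_um: float = 25.0
    membrane_thickness_um: float = 6.0
    include_metal: bool = False
    wire_diameter_um: float = 30.0
    membranes_ruptured: bool = False
    materials: dict[str, MaterialSpec] = field(default_factory=default_materials)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 32:
            raise ValueError("grid_size must be >= 32")
        if self.n_turns <= 0:
            raise ValueError("n_turns must be positive")
        if self.membrane_thickness_um < self.voxel_um:
            raise ValueError(
                "membrane thinner than one voxel "
                f"({self.membrane_thickness_um} um < {self.voxel_um} um)"
            )


@dataclass
class VoxelPhantom:
    """3D material grids: delta, beta and an integer material label map."""

    delta_grid: np.ndarray
    beta_grid: np.ndarray
    labels: np.ndarray
    voxel_um: float

    def __post_init__(self) -> None:
        if not (self.delta_grid.shape == self.beta_grid.shape == self.labels.shape):
            raise ValueError("delta, beta and label grids must share a shape")

    def mu_grid(self, wavelength_um: float) -> np.ndarray:
        """Linear attenuation coefficient 4*pi*beta/lambda, 1/um."""
        return 4.0 * np.pi * self.beta_grid / wavelength_um


@dataclass
class ExitWave:
    """Object-exit-plane phase and intensity for one projection angle."""

    phase: np.ndarray
    exit_intensity: np.ndarray
    angle_deg: float
    pixel_um: float

    def __post_init__(self) -> None:
        if self.phase.shape != self.exit_intensity.shape:
            raise ValueError("phase and intensity must share a shape")


def attenuation_coefficient(beta: float, wavelength_um: float) -> float:
    """mu = 4*pi*beta/lambda, 1/um."""
    return 4.0 * np.pi * beta / wavelength_um


def _spiral_curve(params: PhantomParams, n_samples: int = 4000):
    """Sample the conical spiral centerline of the cochlear duct.

    Returns (points[n,3] in voxel coords z,y,x; duct radius in voxels).
    All structure stays within 0.45*N of the center so in-plane rotations
    never clip material (mass conservation under projection).
    """
    n = params.grid_size
    c = (n - 1) / 2.0
    t = np.linspace(0.0, 1.0, n_samples)
    turns = params.n_turns
    # spiral radius shrinks toward the apex, height climbs
    r_max = 0.33 * n
    r_min = 0.10 * n
    radius = r_max - (r_max - r_min) * t
    angle = 2.0 * np.pi * turns * t
    height = (t - 0.5) * 0.55 * n
    x = c + radius * np.cos(angle)
    y = c + radius * np.sin(angle)
    z = c + height
    duct_r = 0.085 * n  # lumen radius in voxels
    return np.column_stack([z, y, x]), duct_r


def build_cochlea_phantom(params: PhantomParams) -> VoxelPhantom:
    """Build the spiral-shell phantom (deterministic for a given seed).

    The duct interior is soft tissue, the wall of thickness
    ``shell_thickness_um`` is bone, a thin sheet through the duct mid-plane is
    the membrane, and (optionally) a curved wire running along the basal turn
    is metal. With ``membranes_ruptured`` the membrane gets seeded gaps,
    mimicking the tears that drying introduces in real specimens.
    """
    n = params.grid_size
    rng = np.random.default_rng(params.seed)
    pts, duct_r = _spiral_curve(params)
    shell_vox = params.shell_thickness_um / params.voxel_um

    zz, yy, xx = np.meshgrid(*(np.arange(n, dtype=np.float64),) * 3, indexing="ij")
    coords = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])

    tree = cKDTree(pts)
    # only query voxels near the spiral to keep the search cheap
    reach = duct_r + shell_vox + 2.0
    dist, idx = tree.query(coords, workers=-1, distance_upper_bound=reach)
    dist = dist.reshape((n, n, n))
    idx = idx.reshape((n, n, n))

    labels = np.full((n, n, n), AIR, dtype=np.int8)
    lumen = dist < duct_r
    shell = (dist >= duct_r) & (dist < duct_r + shell_vox)
    labels[shell] = BONE
    labels[lumen] = SOFT

    # membrane: thin sheet across the duct at the local spiral height
    memb_half = 0.5 * params.membrane_thickness_um / params.voxel_um
    near_idx = np.minimum(idx, len(pts) - 1)
    local_z = pts[near_idx.ravel(), 0].reshape((n, n, n))
    membrane = lumen & (np.abs(zz - local_z) <= memb_half)
    if params.membranes_ruptured:
        n_gaps = max(2, int(params.n_turns * 3))
        gap_centers = pts[rng.integers(0, len(pts), size=n_gaps)]
        gap_r = 2.5 * duct_r / 3.0
        keep = np.ones((n, n, n), dtype=bool)
        for gz, gy, gx in gap_centers:
            keep &= (zz - gz) ** 2 + (yy - gy) ** 2 + (xx - gx) ** 2 > gap_r**2
        membrane &= keep
    labels[membrane] = MEMBRANE

    if params.include_metal:
        # implant wire: follows the basal (outer) third of the spiral,
        # offset slightly inward so it sits inside the duct
        wire_pts = pts[: len(pts) // 3].copy()
        wire_pts[:, 0] -= 0.25 * duct_r
        wtree = cKDTree(wire_pts)
        wr = 0.5 * params.wire_diameter_um / params.voxel_um
        wdist, _ = wtree.query(coords, workers=-1, distance_upper_bound=wr + 1.5)
        wire = wdist.reshape((n, n, n)) < wr
        labels[wire] = METAL

    mats = params.materials
    name_for = {AIR: "air", SOFT: "soft", BONE: "bone", MEMBRANE: "membrane", METAL: "metal"}
    delta = np.zeros((n, n, n), dtype=np.float64)
    beta = np.zeros((n, n, n), dtype=np.float64)
    for code, name in name_for.items():
        if name in mats:
            sel = labels == code
            delta[sel] = mats[name].delta
            beta[sel] = mats[name].beta
    return VoxelPhantom(delta, beta, labels, params.voxel_um)


def _rotate_inplane(vol: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the vertical (first) axis, CCW viewed from +axis."""
    return ndimage.rotate(
        vol, angle_deg, axes=(2, 1), reshape=False, order=1, mode="constant", cval=0.0
    )


def forward_project(
    phantom: VoxelPhantom,
    angle_deg: float,
    wavelength_um: float,
    pixel_um: float | None = None,
) -> ExitWave:
    """Parallel-ray exit wave of the phantom at one projection angle.

    Line integrals of delta and mu are taken along +x after rotating the
    volume in-plane by ``angle_deg``; detector rows map to the vertical axis.
    ``pixel_um`` must be an integer multiple of the voxel size (block
    binning); default equals the voxel size.
    """
    if pixel_um is None:
        pixel_um = phantom.voxel_um
    if pixel_um + 1e-9 < phantom.voxel_um:
        raise ValueError("detector pixel cannot be finer than the voxel grid")
    theta = float(angle_deg) % 360.0
    if theta != angle_deg:
        warnings.warn(f"angle {angle_deg} normalized to {theta} deg", stacklevel=2)

    mu = phantom.mu_grid(wavelength_um)
    stacked = np.stack([phantom.delta_grid, mu])
    rot = ndimage.rotate(
        stacked, theta, axes=(3, 2), reshape=False, order=1, mode="constant", cval=0.0
    )
    path_delta = rot[0].sum(axis=2) * phantom.voxel_um
    path_mu = rot[1].sum(axis=2) * phantom.voxel_um

    ratio = pixel_um / phantom.voxel_um
    if abs(ratio - round(ratio)) > 1e-6:
        raise ValueError("pixel_um must be an integer multiple of voxel_um")
    k = int(round(ratio))
    if k > 1:
        n0, n1 = (s - s % k for s in path_delta.shape)
        path_delta = path_delta[:n0, :n1].reshape(n0 // k, k, n1 // k, k).mean(axis=(1, 3))
        path_mu = path_mu[:n0, :n1].reshape(n0 // k, k, n1 // k, k).mean(axis=(1, 3))

    phase = -(2.0 * np.pi / wavelength_um) * path_delta
    exit_intensity = np.exp(-path_mu)
    return ExitWave(phase, exit_intensity, theta, pixel_um)


def edge_exit_wave(
    n: int,
    pixel_um: float,
    wavelength_um: float,
    material: MaterialSpec,
    thickness_um: float,
    edge_softness_px: float = 1.0,
) -> ExitWave:
    """Exit wave of a knife-edge target: a uniform slab covering half the field.

    The slab of the given material and thickness (along the beam) fills the
    right half of the frame; its edge runs vertically, softened over
    ``edge_softness_px`` (a hard material edge still has finite extent on the
    detector grid). Useful for defocus-series and edge-response studies.
    """
    x = np.arange(n, dtype=np.float64) - (n - 1) / 2.0
    if edge_softness_px > 0:
        step = 0.5 * (1.0 + np.tanh(x / edge_softness_px))
    else:
        step = (x >= 0).astype(np.float64)
    path = thickness_um * step[None, :] * np.ones((n, 1))
    phase = -(2.0 * np.pi / wavelength_um) * material.delta * path
    mu = attenuation_coefficient(material.beta, wavelength_um)
    return ExitWave(phase, np.exp(-mu * path), 0.0, pixel_um)
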