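"""Pipeline configuration: YAML parsing, validation and provenance hashing.

All physical numbers carry unit-suffixed keys (``z01_mm``, ``pixel_um``,
``energy_kev``) so stacks, volumes and metrics can never silently mix units.
Every artifact the pipeline writes is stamped with the SHA-256 hash of the
canonical JSON form of its configuration plus the seed, so any output can be
regenerated bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import ConeBeamGeometry
from .phantom import PhantomParams
from .recon import FILTERS
from .retrieval import RetrievalParams

__all__ = [
    "SimulationConfig",
    "ReconstructionConfig",
    "MetricsConfig",
    "PipelineConfig",
    "load_config",
    "config_hash",
]


@dataclass
class SimulationConfig:
    """Projection-stack synthesis parameters."""

    n_angles: int = 90
    angular_range_deg: float = 360.0
    mean_counts: float | None = 1e4      # photons per unit intensity; None = noiseless
    n_flats: int = 8
    n_darks: int = 4
    dark_level: float = 0.0              # constant detector offset, intensity units
    flat_gain_sigma: float = 0.02        # per-column detector gain spread
    model: str = "fresnel"               # "fresnel" or "tie"
    defocus_z02_mm: list[float] | None = None  # alternative defocus-series mode

    def __post_init__(self) -> None:
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.model not in ("fresnel", "tie"):
            raise ValueError(f"unknown forward model {self.model!r}")
        if self.mean_counts is not None and not self.mean_counts > 0:
            raise ValueError("mean_counts must be positive (or null for noiseless)")


@dataclass
class ReconstructionConfig:
    filter_name: str = "ram-lak"
    ring_window: int = 9
    ring_removal: bool = True

    def __post_init__(self) -> None:
        if self.filter_name not in FILTERS:
            raise ValueError(f"filter must be one of {FILTERS}")
        if self.ring_window < 3 or self.ring_window % 2 == 0:
            raise ValueError("ring window must be an odd integer >= 3")


@dataclass
class MetricsConfig:
    fsc_crop: int = 1000


@dataclass
class PipelineConfig:
    """Full end-to-end configuration (phantom -> volume -> metrics)."""

    geometry: ConeBeamGeometry
    phantom: PhantomParams
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    retrieval: RetrievalParams = field(default_factory=lambda: RetrievalParams(alpha=0.005, gamma=0.025))
    reconstruction: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    seed: int = 0
    output_dir: Path | None = None

    def to_canonical_dict(self) -> dict:
        d = {
            "geometry": dataclasses.asdict(self.geometry),
            "phantom": {
                k: v for k, v in dataclasses.asdict(self.phantom).items()
                if k != "materials"
            },
            "materials": {
                name: dataclasses.asdict(m) for name, m in sorted(self.phantom.materials.items())
            },
            "simulation": dataclasses.asdict(self.simulation),
            "retrieval": dataclasses.asdict(self.retrieval),
            "reconstruction": dataclasses.asdict(self.reconstruction),
            "metrics": dataclasses.asdict(self.metrics),
            "seed": self.seed,
        }
        return d


def config_hash(cfg: PipelineConfig) -> str:
    """SHA-256 of the canonical JSON configuration (provenance stamp)."""
    blob = json.dumps(cfg.to_canonical_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "geometry" not in raw:
        raise ValueError(f"{path}: config must contain at least a 'geometry' block")
    geom = ConeBeamGeometry(**raw["geometry"])
    phantom = PhantomParams(**raw.get("phantom", {}))
    sim = SimulationConfig(**raw.get("simulation", {}))
    retr = RetrievalParams(**raw.get("retrieval", {"alpha": 0.005, "gamma": 0.025}))
    rec = ReconstructionConfig(**raw.get("reconstruction", {}))
    met = MetricsConfig(**raw.get("metrics", {}))
    out = raw.get("output_dir")
    return PipelineConfig(
        geometry=geom,
        phantom=phantom,
        simulation=sim,
        retrieval=retr,
        reconstruction=rec,
        metrics=met,
        seed=int(raw.get("seed", 0)),
        output_dir=Path(out) if out else None,
    )
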