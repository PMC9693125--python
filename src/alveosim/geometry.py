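"""Alveolar-duct geometry: 18 tangent spheres in a cube, shell placement, voxel mapping.

The duct is modelled as 3 stacked rings of 6 equal tangent spheres (alveoli)
inside a cubic simulation space.  Six spheres of radius ``r`` are mutually
tangent when their centres sit on a circle of radius ``2r`` (regular hexagon
chord ``2R sin(pi/6) = R``), and rings stacked at vertical spacing ``2r`` are
tangent between layers.  Cells live on concentric spherical shells around
each alveolus centre: epithelial cells at exactly one alveolar radius,
mesenchymal cells slightly outside (interstitium) and macrophages slightly
inside (lumen).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property

import numpy as np

__all__ = [
    "Shell",
    "DuctGeometry",
    "Alveolus",
    "GeometryConfig",
    "build_duct",
    "voxel_of",
    "sample_on_sphere",
    "alveolus_volume_cm3",
]

UM_PER_CM = 1.0e4


class Shell(str, Enum):
    """Radial band a cell type occupies around its alveolus centre."""

    EPITHELIAL = "epithelial"
    INTERSTITIAL = "interstitial"
    LUMINAL = "luminal"


@dataclass(frozen=True)
class GeometryConfig:
    """Geometry block of the run configuration (lengths in micrometres)."""

    alveolus_radius_um: float = 125.0
    cube_side_um: float = 2000.0
    voxel_side_um: float = 500.0
    n_layers: int = 3
    alveoli_per_layer: int = 6
    # shell_factor * alveolus_radius = distance of the shell from the centre
    shell_factors: dict = field(
        default_factory=lambda: {
            Shell.EPITHELIAL: 1.0,
            Shell.INTERSTITIAL: 1.08,
            Shell.LUMINAL: 0.92,
        }
    )
    # agent radii by coarse category, micrometres
    epithelial_cell_radius_um: float = 15.0
    mesenchymal_cell_radius_um: float = 15.0
    macrophage_radius_um: float = 10.0

    def shell_radius(self, shell: Shell) -> float:
        return self.alveolus_radius_um * self.shell_factors[shell]

    @property
    def n_voxels_per_side(self) -> int:
        n = self.cube_side_um / self.voxel_side_um
        if abs(n - round(n)) > 1e-9:
            raise ValueError("cube_side_um must be an integer multiple of voxel_side_um")
        return int(round(n))


def alveolus_volume_cm3(radius_um: float) -> float:
    """Three-quarter-sphere volume of one alveolus in cm^3.

    An alveolus is a three-quarter sphere (the missing quarter is the mouth
    opening onto the duct lumen): V = 0.75 * (4/3) pi r^3 = pi r^3.
    """
    r_cm = radius_um / UM_PER_CM
    return float(np.pi * r_cm**3)


@dataclass(frozen=True)
class Alveolus:
    id: int
    center: np.ndarray  # (3,) um
    radius: float  # um
    layer: int
    ring_slot: int

    @property
    def volume_cm3(self) -> float:
        return alveolus_volume_cm3(self.radius)


@dataclass(frozen=True)
class DuctGeometry:
    config: GeometryConfig
    alveoli: tuple

    @property
    def alveolus_radius(self) -> float:
        return self.config.alveolus_radius_um

    @property
    def duct_circle_radius(self) -> float:
        # tangency of 6 equal spheres on a circle
        return 2.0 * self.config.alveolus_radius_um

    @property
    def n_alveoli(self) -> int:
        return len(self.alveoli)

    @cached_property
    def centers(self) -> np.ndarray:
        return np.stack([a.center for a in self.alveoli])


def build_duct(config: GeometryConfig | None = None) -> DuctGeometry:
    """Build the duct: ``n_layers`` rings of ``alveoli_per_layer`` tangent spheres.

    Ring centres lie on a circle of radius 2r about the cube's vertical axis;
    layer k sits at height (2k+1)r above the stack's floor offset, so adjacent
    layers are tangent.  Raises ``ValueError`` naming the violated containment
    inequality when the duct does not fit into the cube.
    """
    cfg = config or GeometryConfig()
    r = cfg.alveolus_radius_um
    side = cfg.cube_side_um
    if r <= 0:
        raise ValueError("alveolus_radius_um must be positive")
    ring_r = 2.0 * r
    if 2.0 * (ring_r + r) > side:
        raise ValueError(
            f"containment violated: 2*(duct_circle_radius + r) = {2*(ring_r + r):g} um "
            f"> cube_side {side:g} um"
        )
    stack_height = cfg.n_layers * 2.0 * r
    if stack_height > side:
        raise ValueError(
            f"containment violated: n_layers*2*r = {stack_height:g} um > cube_side {side:g} um"
        )

    cx = cy = side / 2.0
    z0 = (side - stack_height) / 2.0  # vertical offset of the stack floor
    alveoli = []
    aid = 0
    for layer in range(cfg.n_layers):
        z = z0 + (2 * layer + 1) * r
        for slot in range(cfg.alveoli_per_layer):
            ang = 2.0 * np.pi * slot / cfg.alveoli_per_layer
            center = np.array([cx + ring_r * np.cos(ang), cy + ring_r * np.sin(ang), z])
            alveoli.append(Alveolus(id=aid, center=center, radius=r, layer=layer, ring_slot=slot))
            aid += 1
    return DuctGeometry(config=cfg, alveoli=tuple(alveoli))


def voxel_of(position: np.ndarray, config: GeometryConfig) -> tuple:
    """Voxel index triple for a point, half-open intervals [i*h, (i+1)*h).

    Raises ``ValueError`` for positions outside the cube (the upper cube face
    is excluded).
    """
    p = np.asarray(position, dtype=float)
    if p.shape != (3,):
        raise ValueError("position must be a 3-vector")
    if np.any(p < 0.0) or np.any(p >= config.cube_side_um):
        raise ValueError(f"position {p} outside the simulation cube")
    idx = np.floor(p / config.voxel_side_um).astype(int)
    return (int(idx[0]), int(idx[1]), int(idx[2]))


def voxel_indices(positions: np.ndarray, config: GeometryConfig) -> np.ndarray:
    """Vectorised ``voxel_of`` for an (n, 3) position array (no bounds check)."""
    n = config.n_voxels_per_side
    idx = np.floor(positions / config.voxel_side_um).astype(np.intp)
    return np.clip(idx, 0, n - 1)


def sample_on_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    """Area-uniform unit vectors on the sphere, shape (n, 3).

    cos(theta) uniform on [-1, 1], phi uniform on [0, 2pi).
    """
    cos_t = rng.uniform(-1.0, 1.0, size=n)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
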