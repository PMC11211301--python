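"""Voxelized NEMA IEC body phantom with permutable sphere inserts.

The NEMA IEC body phantom carries six fillable spheres on a ring in one
transaxial plane.  Two variants are modelled: the PET variant (sphere
diameters 10/13/17/22/28/37 mm) and the SPECT variant used for Lu-177
harmonization, where the 10 mm sphere is replaced by a 60 mm sphere.
Assigning the six diameters to the six ring positions in every possible
way yields 6! = 720 configurations; this module enumerates them and
voxelizes each one into paired activity / attenuation maps plus
high-resolution fractional occupancy masks for recovery analysis.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

PET_DIAMETERS: tuple[float, ...] = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
SPECT_DIAMETERS: tuple[float, ...] = (13.0, 17.0, 22.0, 28.0, 37.0, 60.0)

#: Radius of the circle on which the six sphere centers sit (standard
#: NEMA IEC insert layout; centers 60 degrees apart).
RING_RADIUS_MM = 57.2

N_POSITIONS = 6

# Sagittal mirror (x -> -x) maps ring positions onto each other.  With
# position 1 at 12 o'clock and positions counted clockwise (seen from the
# gantry front), 1 and 4 are self-mirrored and 2<->6, 3<->5 swap.
_MIRROR_POSITION = {1: 1, 2: 6, 3: 5, 4: 4, 5: 3, 6: 2}


def position_angle_deg(position: int) -> float:
    """In-plane angle of a ring position (deg, y-up; position 1 = top)."""
    if not 1 <= position <= N_POSITIONS:
        raise ValueError(f"position must be 1..6, got {position}")
    return 90.0 - 60.0 * (position - 1)


def sphere_volume(diameter_mm: float) -> float:
    """Volume of a sphere in mL given its diameter in mm."""
    if diameter_mm < 0:
        raise ValueError("diameter must be non-negative")
    return math.pi / 6.0 * diameter_mm**3 / 1000.0


def sphere_diameter(volume_ml: float) -> float:
    """Diameter in mm of the sphere with the given volume in mL."""
    if volume_ml < 0:
        raise ValueError("volume must be non-negative")
    return (6.0 * volume_ml * 1000.0 / math.pi) ** (1.0 / 3.0)


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid; ``origin`` is the world position (mm) of the
    center of voxel (0, 0, 0).  Right-handed, z along the gantry axis."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")

    @classmethod
    def centered(cls, shape: Sequence[int], voxel_size) -> "VoxelGrid":
        """Grid whose world center coincides with the origin (rotation axis)."""
        if np.isscalar(voxel_size):
            voxel_size = (float(voxel_size),) * 3
        origin = tuple(-(n - 1) / 2.0 * v for n, v in zip(shape, voxel_size))
        return cls(tuple(int(n) for n in shape), tuple(map(float, voxel_size)), origin)

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + self.voxel_size[axis] * np.arange(n)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    def extent(self, axis: int) -> tuple[float, float]:
        """World extent (voxel edges) along an axis."""
        c = self.axis_coords(axis)
        h = self.voxel_size[axis] / 2.0
        return float(c[0] - h), float(c[-1] + h)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and fill of one NEMA phantom variant.

    The body cross-section is the standard IEC outline approximated as a
    300 x 230 mm rounded rectangle (two 115 mm half-discs joined by a
    70 mm straight section), water-filled, 180 mm long.  Sphere walls and
    the lung insert are ignored; attenuation is water-equivalent at
    208 keV.
    """

    phantom_type: str
    diameters: tuple[float, ...]
    ring_radius: float = RING_RADIUS_MM
    body_half_width: float = 150.0
    body_half_height: float = 115.0
    body_length: float = 180.0
    sphere_plane_z: float = 0.0
    concentration: float = 2.0  # MBq/mL in the spheres
    background_concentration: float = 0.0
    mu_water: float = 0.0137  # 1/mm at 208 keV

    def __post_init__(self):
        if len(self.diameters) != N_POSITIONS:
            raise ValueError("exactly six sphere diameters required")
        if self.ring_radius <= max(self.diameters) / 2.0:
            raise ValueError("ring_radius must exceed the largest sphere radius")
        if self.concentration < 0 or self.background_concentration < 0:
            raise ValueError("concentrations must be non-negative")

    @classmethod
    def nema_pet(cls, **kw) -> "PhantomConfig":
        return cls("NEMA_PET", PET_DIAMETERS, **kw)

    @classmethod
    def nema_spect(cls, **kw) -> "PhantomConfig":
        return cls("NEMA_SPECT", SPECT_DIAMETERS, **kw)

    def center(self, position: int) -> np.ndarray:
        """World coordinates (mm) of a ring position's sphere center."""
        a = math.radians(position_angle_deg(position))
        return np.array(
            [
                self.ring_radius * math.cos(a),
                self.ring_radius * math.sin(a),
                self.sphere_plane_z,
            ]
        )


@dataclass(frozen=True)
class SpherePermutation:
    """One assignment of the six diameters to ring positions 1..6.

    ``assignment[p-1]`` is the diameter (mm) placed at position ``p``.
    """

    index: int
    assignment: tuple[float, ...]

    def diameter_at(self, position: int) -> float:
        return self.assignment[position - 1]

    def position_of(self, diameter: float) -> int:
        return self.assignment.index(diameter) + 1

    def mirrored(self) -> tuple[float, ...]:
        """Assignment after sagittal reflection of the phantom."""
        return tuple(
            self.assignment[_MIRROR_POSITION[p] - 1] for p in range(1, N_POSITIONS + 1)
        )


def enumerate_permutations(diameters: Sequence[float]) -> list[SpherePermutation]:
    """All bijections diameters -> positions, lexicographically ordered.

    Raises if the diameters are not distinct (the assignment would not be
    a bijection).  For the six NEMA diameters this returns 720 entries.
    """
    diameters = tuple(float(d) for d in diameters)
    if len(set(diameters)) != len(diameters):
        raise ValueError("sphere diameters must be distinct")
    perms = itertools.permutations(sorted(diameters))
    return [SpherePermutation(i, p) for i, p in enumerate(perms)]


def mirror_classes(perms: Sequence[SpherePermutation]) -> dict[int, int]:
    """Map permutation index -> mirror-equivalence class id.

    A sagittal reflection of the phantom maps each arrangement onto an
    equivalent one; the class id is the smaller index of the pair.  All
    members are kept (a real detector orbit need not be mirror
    symmetric), the classes are metadata only.
    """
    by_assignment = {p.assignment: p.index for p in perms}
    out = {}
    for p in perms:
        j = by_assignment.get(p.mirrored(), p.index)
        out[p.index] = min(p.index, j)
    return out


def identity_permutation(diameters: Sequence[float]) -> SpherePermutation:
    """The ascending (lexicographically first) assignment."""
    return enumerate_permutations(diameters)[0]


def permutation_from_assignment(assignment: Sequence[float]) -> SpherePermutation:
    """Look up the canonical index of an explicit assignment."""
    perms = enumerate_permutations(tuple(assignment))
    lut = {p.assignment: p for p in perms}
    key = tuple(float(d) for d in assignment)
    return lut[key]


# ---------------------------------------------------------------------------
# voxelization


def _inside_body(config: PhantomConfig, x, y, z):
    """Boolean mask of points inside the IEC body outline."""
    w, h = config.body_half_width, config.body_half_height
    straight = w - h  # half-length of the flat section
    ax = np.abs(x)
    inplane = ((ax <= straight) & (np.abs(y) <= h)) | (
        (ax - straight) ** 2 + y**2 <= h**2
    )
    return inplane & (np.abs(z) <= config.body_length / 2.0)


def _subvoxel_offsets(voxel_size, supersample: int):
    s = int(supersample)
    offs = [(np.arange(s) + 0.5) / s - 0.5 for _ in range(3)]
    return [o * v for o, v in zip(offs, voxel_size)]


def sphere_occupancy(
    grid: VoxelGrid, center, diameter: float, supersample: int = 4
) -> np.ndarray:
    """Fractional voxel occupancy of a sphere via subvoxel subdivision.

    Each voxel in the sphere's bounding box is split into supersample^3
    subvoxels and the fraction of subvoxel centers inside the sphere is
    recorded.  Volume error cancels over the boundary and shrinks
    monotonically with the supersampling factor.
    """
    r = diameter / 2.0
    out = np.zeros(grid.shape, dtype=np.float64)
    if r <= 0:
        return out
    coords = [grid.axis_coords(a) for a in range(3)]
    sel = []
    for a in range(3):
        lo = center[a] - r - grid.voxel_size[a]
        hi = center[a] + r + grid.voxel_size[a]
        idx = np.nonzero((coords[a] >= lo) & (coords[a] <= hi))[0]
        if idx.size == 0:
            return out
        sel.append(idx)
    cx, cy, cz = (coords[a][sel[a]] - center[a] for a in range(3))
    ox, oy, oz = _subvoxel_offsets(grid.voxel_size, supersample)
    count = np.zeros((cx.size, cy.size, cz.size), dtype=np.int32)
    r2 = r * r
    for dx in ox:
        x2 = (cx + dx) ** 2
        for dy in oy:
            y2 = (cy + dy) ** 2
            for dz in oz:
                z2 = (cz + dz) ** 2
                count += (
                    x2[:, None, None] + y2[None, :, None] + z2[None, None, :]
                ) <= r2
    occ = count / float(supersample**3)
    out[np.ix_(sel[0], sel[1], sel[2])] = occ
    return out


@lru_cache(maxsize=8)
def body_mu_map(config: PhantomConfig, grid: VoxelGrid, supersample: int = 2) -> np.ndarray:
    """Linear attenuation map (1/mm) of the water-filled body.

    Shared by every sphere permutation of a phantom type (the thin,
    near-water sphere walls are ignored), mirroring the reuse of a single
    density map across all configurations.
    """
    coords = [grid.axis_coords(a) for a in range(3)]
    ox, oy, oz = _subvoxel_offsets(grid.voxel_size, supersample)
    frac = np.zeros(grid.shape, dtype=np.float64)
    for dx in ox:
        for dy in oy:
            for dz in oz:
                frac += _inside_body(
                    config,
                    (coords[0] + dx)[:, None, None],
                    (coords[1] + dy)[None, :, None],
                    (coords[2] + dz)[None, None, :],
                )
    frac /= supersample**3
    return config.mu_water * frac


@dataclass(frozen=True)
class VoxelPhantom:
    """Paired activity/attenuation fields plus per-sphere occupancy masks."""

    config: PhantomConfig
    permutation: SpherePermutation
    sim_grid: VoxelGrid
    mask_grid: VoxelGrid
    activity: np.ndarray  # MBq/mL on sim_grid
    mu_map: np.ndarray  # 1/mm on sim_grid
    masks: Mapping[int, np.ndarray]  # position -> occupancy on mask_grid

    def nominal_activity(self, position: int) -> float:
        """True activity (MBq) in the sphere at a ring position."""
        d = self.permutation.diameter_at(position)
        return self.config.concentration * sphere_volume(d)


def build_phantom(
    config: PhantomConfig,
    perm: SpherePermutation,
    sim_grid: VoxelGrid,
    mask_grid: VoxelGrid,
    supersample: int = 4,
) -> VoxelPhantom:
    """Voxelize one sphere arrangement.

    Activity = concentration x fractional occupancy on the simulation
    grid (cold background by default); occupancy masks are produced on
    the finer mask grid; the attenuation map is the permutation-
    independent water body.
    """
    if any(m > s + 1e-9 for m, s in zip(mask_grid.voxel_size, sim_grid.voxel_size)):
        raise ValueError("mask_grid must be at least as fine as sim_grid")
    gaps = neighbor_surface_gaps(config, perm)
    bad = {k: g for k, g in gaps.items() if g < 0}
    if bad:
        raise ValueError(f"overlapping spheres at adjacent positions: {bad}")

    activity = np.zeros(sim_grid.shape, dtype=np.float64)
    masks = {}
    sphere_union = np.zeros(sim_grid.shape, dtype=np.float64)
    for p in range(1, N_POSITIONS + 1):
        d = perm.diameter_at(p)
        c = config.center(p)
        occ_sim = sphere_occupancy(sim_grid, c, d, supersample)
        activity += config.concentration * occ_sim
        sphere_union += occ_sim
        masks[p] = sphere_occupancy(mask_grid, c, d, supersample)
    if config.background_concentration > 0:
        body = body_mu_map(config, sim_grid) / config.mu_water
        bg = np.clip(body - sphere_union, 0.0, 1.0)
        activity += config.background_concentration * bg
    mu = body_mu_map(config, sim_grid)
    return VoxelPhantom(config, perm, sim_grid, mask_grid, activity, mu, masks)


def neighbor_surface_gaps(
    config: PhantomConfig, perm: SpherePermutation
) -> dict[tuple[int, int], float]:
    """Surface-to-surface gap (mm) between each pair of adjacent spheres.

    Adjacent centers are 60 degrees apart on the ring, so the chord
    between them equals the ring radius; the gap is chord - r_i - r_j.
    With the default 57.2 mm ring the 37/60 mm pair comes out at 8.7 mm.
    """
    gaps = {}
    for p in range(1, N_POSITIONS + 1):
        q = p % N_POSITIONS + 1
        chord = float(np.linalg.norm(config.center(p) - config.center(q)))
        gaps[(p, q)] = chord - (perm.diameter_at(p) + perm.diameter_at(q)) / 2.0
    return gaps
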