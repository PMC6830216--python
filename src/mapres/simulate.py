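"""Density simulation from point-scatterer models, and synthetic structures.

Each atom deposits an isotropic Gaussian (per-element amplitude and width,
from a packaged table) at its real-valued coordinate.  Synthetic structures
are compactness-biased, loosely self-avoiding random walks of pseudo-carbon
atoms; they stand in for a large training corpus so the whole train/predict
cycle runs without downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .map_io import AtomicModel, DensityMap, ValidationError

__all__ = [
    "ScatteringKernel",
    "SyntheticStructureSpec",
    "NoiseSpec",
    "model_to_density",
    "generate_synthetic_structure",
    "add_noise",
]

DEFAULT_PADDING = 8.0  # Angstrom; keeps filter wrap-around off the molecule


def _load_default_table() -> tuple[dict[str, tuple[float, float]], str]:
    text = resources.files("mapres.data").joinpath("scattering.json").read_text()
    raw = json.loads(text)
    table = {
        el: (float(entry["amplitude"]), float(entry["sigma"]))
        for el, entry in raw["elements"].items()
    }
    return table, raw["fallback"]


@dataclass
class ScatteringKernel:
    """Per-element single-Gaussian form factors.

    ``table`` maps element symbol -> (amplitude, sigma[A]).  Unknown elements
    fall back to the carbon entry.
    """

    table: dict[str, tuple[float, float]] | None = None
    fallback: str = "C"

    def __post_init__(self) -> None:
        if self.table is None:
            self.table, self.fallback = _load_default_table()
        for el, (amp, sigma) in self.table.items():
            if sigma <= 0:
                raise ValidationError(f"kernel width for {el} must be > 0, got {sigma}")
            if amp <= 0:
                raise ValidationError(f"kernel amplitude for {el} must be > 0, got {amp}")
        if self.fallback not in self.table:
            raise ValidationError(f"fallback element {self.fallback!r} missing from table")

    def lookup(self, element: str) -> tuple[float, float]:
        return self.table.get(element.capitalize(), self.table[self.fallback])


@dataclass
class SyntheticStructureSpec:
    """Parameters of the pseudo-polymer generator.

    ``satellites_per_atom`` > 0 decorates each backbone atom with short-bond
    (~1.5 A) satellite scatterers, mimicking the bonded fine structure that
    gives real macromolecular maps their high-resolution texture; 0 (the
    default) yields the plain backbone walk.
    """

    n_atoms: int = 800
    step: float = 3.8  # Angstrom, CA-CA-like bond length
    compactness: float = 0.3  # bias of each step toward the walk centroid
    seed: int = 0
    min_separation: float = 3.0  # soft self-avoidance radius, Angstrom
    satellites_per_atom: float = 0.0  # mean satellites per backbone atom
    satellite_bond: float = 1.5  # Angstrom

    def __post_init__(self) -> None:
        if self.n_atoms < 1:
            raise ValidationError(f"n_atoms must be >= 1, got {self.n_atoms}")
        if self.step <= 0:
            raise ValidationError(f"step must be > 0, got {self.step}")
        if self.compactness < 0:
            raise ValidationError("compactness must be >= 0")
        if self.satellites_per_atom < 0:
            raise ValidationError("satellites_per_atom must be >= 0")
        if self.satellite_bond <= 0:
            raise ValidationError("satellite_bond must be > 0")


@dataclass
class NoiseSpec:
    """Additive iid Gaussian noise, zero mean."""

    sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError(f"noise sd must be >= 0, got {self.sd}")


def model_to_density(
    model: AtomicModel,
    voxel_size: float,
    padding: float = DEFAULT_PADDING,
    kernel: ScatteringKernel | None = None,
) -> DensityMap:
    """Rasterise a point-scatterer model to a density grid.

    The grid covers the model bounding box plus ``padding`` on every side.
    Each atom adds ``occupancy * amplitude * exp(-r^2 / 2 sigma^2)`` evaluated
    at the exact real-valued atom position, truncated at 4 sigma.
    """
    if len(model) == 0:
        raise ValidationError("cannot simulate an empty model")
    if voxel_size <= 0:
        raise ValidationError(f"voxel_size must be > 0, got {voxel_size}")
    kernel = kernel or ScatteringKernel()

    max_sigma = max(self_sigma for (_, self_sigma) in (kernel.lookup(e) for e in model.elements))
    if padding < 4 * max_sigma:
        padding = 4 * max_sigma  # guarantee kernel support inside the grid

    lo = model.coords.min(axis=0) - padding  # (x, y, z)
    hi = model.coords.max(axis=0) + padding
    n_xyz = np.ceil((hi - lo) / voxel_size).astype(int) + 1
    origin = lo
    nz, ny, nx = int(n_xyz[2]), int(n_xyz[1]), int(n_xyz[0])
    grid = np.zeros((nz, ny, nx), dtype=np.float64)

    for element, pos, occ in zip(model.elements, model.coords, model.occupancy):
        if occ == 0.0:
            continue
        amp, sigma = kernel.lookup(element)
        reach = 4.0 * sigma
        frac = (pos - origin) / voxel_size  # fractional grid coords (x, y, z)
        r_vox = reach / voxel_size
        lo_idx = np.maximum(np.floor(frac - r_vox).astype(int), 0)
        hi_idx = np.minimum(np.ceil(frac + r_vox).astype(int), n_xyz - 1)
        axes = [
            (np.arange(lo_idx[d], hi_idx[d] + 1) - frac[d]) * voxel_size
            for d in range(3)
        ]
        dx2, dy2, dz2 = (a**2 for a in axes)
        r2 = dz2[:, None, None] + dy2[None, :, None] + dx2[None, None, :]
        blob = (occ * amp) * np.exp(-r2 / (2.0 * sigma * sigma))
        grid[
            lo_idx[2] : hi_idx[2] + 1,
            lo_idx[1] : hi_idx[1] + 1,
            lo_idx[0] : hi_idx[0] + 1,
        ] += blob

    return DensityMap(data=grid.astype(np.float32), voxel_size=float(voxel_size), origin=origin)


def generate_synthetic_structure(spec: SyntheticStructureSpec) -> AtomicModel:
    """Generate a compact pseudo-polymer of carbon scatterers.

    A biased random walk: each step direction is a unit vector drawn
    isotropically, nudged toward the current centroid by ``compactness``;
    candidate positions closer than ``min_separation`` to a previous atom are
    re-drawn a few times (soft self-avoidance).  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(spec.seed)
    coords = np.empty((spec.n_atoms, 3))
    coords[0] = 0.0
    centroid = np.zeros(3)
    for i in range(1, spec.n_atoms):
        prev = coords[i - 1]
        placed = False
        for _attempt in range(20):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            toward = centroid - prev
            norm = np.linalg.norm(toward)
            if norm > 1e-9:
                direction = direction + spec.compactness * (toward / norm)
                direction /= np.linalg.norm(direction)
            candidate = prev + spec.step * direction
            d2 = np.sum((coords[: max(i - 1, 1)] - candidate) ** 2, axis=1)
            if d2.size == 0 or d2.min() >= spec.min_separation**2:
                placed = True
                break
        if not placed:  # accept the last draw rather than stall
            candidate = prev + spec.step * direction
        coords[i] = candidate
        centroid = centroid + (candidate - centroid) / (i + 1)

    if spec.satellites_per_atom == 0:
        return AtomicModel(elements=["C"] * spec.n_atoms, coords=coords)

    # decorate with short-bond satellites for genuine fine-scale texture
    all_coords = [coords]
    all_elements = ["C"] * spec.n_atoms
    n_sat = rng.poisson(spec.satellites_per_atom, size=spec.n_atoms)
    for i, k in enumerate(n_sat):
        for _ in range(int(k)):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            all_coords.append(coords[i] + spec.satellite_bond * direction)
            all_elements.append(str(rng.choice(["C", "N", "O"])))
    coords_full = np.vstack([all_coords[0]] + [c[None] for c in all_coords[1:]])
    return AtomicModel(elements=all_elements, coords=coords_full)


def add_noise(dmap: DensityMap, noise: NoiseSpec) -> DensityMap:
    """Add iid zero-mean Gaussian noise; bit-reproducible under the seed.

    The caller is expected to have normalised the clean map to unit maximum
    first so the stated sd is meaningful (see :func:`normalize_to_unit_max`).
    """
    if noise.sd == 0.0:
        return dmap.with_data(dmap.data.copy())
    rng = np.random.default_rng(noise.seed)
    out = dmap.data + rng.normal(0.0, noise.sd, size=dmap.shape).astype(np.float32)
    return dmap.with_data(out.astype(np.float32))


def normalize_to_unit_max(dmap: DensityMap) -> DensityMap:
    """Scale so the maximum density equals 1 (reference scale for noise sd)."""
    peak = float(dmap.data.max())
    if peak <= 0:
        raise ValidationError("cannot normalise a map with non-positive maximum")
    return dmap.with_data(dmap.data / peak)
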