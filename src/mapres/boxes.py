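"""Labeled box extraction for training and sliding-window enumeration for inference.

A box is a 13x13x13 density cube divided by its L2 norm.  Training boxes
carry the resolution label (A) of the low-pass filter that produced their
source map; inference boxes carry the grid index of their centre voxel so
the prediction can be written back there.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterator

import h5py
import numpy as np

from .map_io import DensityMap, Mask, ValidationError
from .spectral import FilterBankSpec

__all__ = [
    "BOX_EDGE",
    "LabeledBox",
    "BandSpec",
    "extract_training_boxes",
    "enumerate_inference_boxes",
    "save_boxes",
    "load_boxes",
    "BoxSet",
]

logger = logging.getLogger(__name__)

BOX_EDGE = 13
NORM_TOL = 1e-6


@dataclass
class LabeledBox:
    cube: np.ndarray  # (13, 13, 13), unit L2 norm
    label: float  # resolution in Angstrom

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=np.float32)
        if self.cube.shape != (BOX_EDGE,) * 3:
            raise ValidationError(f"box must be {BOX_EDGE}^3, got {self.cube.shape}")
        norm = float(np.linalg.norm(self.cube))
        if abs(norm - 1.0) > 1e-4:
            raise ValidationError(f"box norm {norm} deviates from 1")


@dataclass
class BandSpec:
    """Working sampling rate and filter bank of one training band."""

    voxel_size: float  # A/voxel; 1.0 (wide band) or 0.5 (high-res band)
    bank: FilterBankSpec
    box_edge: int = BOX_EDGE

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValidationError("band voxel_size must be > 0")
        if self.bank.d_min < 2.0 * self.voxel_size:
            raise ValidationError(
                f"bank d_min {self.bank.d_min} A violates Nyquist at "
                f"{self.voxel_size} A/voxel"
            )

    @property
    def label_range(self) -> tuple[float, float]:
        return (self.bank.d_min, self.bank.d_max)

    @property
    def physical_edge(self) -> float:
        """Box edge length in Angstrom."""
        return self.box_edge * self.voxel_size

    def to_dict(self) -> dict:
        return {
            "voxel_size": self.voxel_size,
            "d_min": self.bank.d_min,
            "d_max": self.bank.d_max,
            "step": self.bank.step,
            "box_edge": self.box_edge,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BandSpec":
        return cls(
            voxel_size=float(d["voxel_size"]),
            bank=FilterBankSpec(float(d["d_min"]), float(d["d_max"]), float(d["step"])),
            box_edge=int(d.get("box_edge", BOX_EDGE)),
        )


#: the two bands described by the method: wide (1.0 A/voxel, 2.5-13 A) and
#: high-resolution (0.5 A/voxel, 1.5-6 A)
def wide_band(step: float = 0.1) -> BandSpec:
    return BandSpec(voxel_size=1.0, bank=FilterBankSpec(2.5, 13.0, step))


def highres_band(step: float = 0.1) -> BandSpec:
    return BandSpec(voxel_size=0.5, bank=FilterBankSpec(1.5, 6.0, step))


def _unit_normalize(cube: np.ndarray) -> np.ndarray | None:
    norm = float(np.linalg.norm(cube))
    if norm == 0.0:
        return None
    return (cube / norm).astype(np.float32)


def extract_training_boxes(
    dmap: DensityMap,
    mask: Mask,
    label: float,
    stride: int = 5,
    occupancy_min: float = 0.5,
) -> list[LabeledBox]:
    """Tile the map at ``stride`` and keep sufficiently masked boxes.

    A box is kept when at least ``occupancy_min`` of its voxels lie inside
    the mask; kept cubes are divided by their L2 norm.  All-zero cubes are
    skipped and counted in the log.
    """
    dmap.check_boxable()
    mask.check_congruent(dmap)
    if stride < 1:
        raise ValidationError(f"stride must be >= 1, got {stride}")
    if mask.n_voxels() == 0:  # unreachable via Mask invariant; belt and braces
        logger.warning("empty mask: no training boxes extracted")
        return []

    e = BOX_EDGE
    out: list[LabeledBox] = []
    n_skipped = 0
    nz, ny, nx = dmap.shape
    min_inside = occupancy_min * e**3
    for z0 in range(0, nz - e + 1, stride):
        for y0 in range(0, ny - e + 1, stride):
            for x0 in range(0, nx - e + 1, stride):
                inside = mask.data[z0 : z0 + e, y0 : y0 + e, x0 : x0 + e].sum()
                if inside < min_inside or inside == 0:
                    continue
                cube = _unit_normalize(dmap.data[z0 : z0 + e, y0 : y0 + e, x0 : x0 + e])
                if cube is None:
                    n_skipped += 1
                    continue
                out.append(LabeledBox(cube=cube, label=float(label)))
    if n_skipped:
        logger.info("skipped %d all-zero boxes at label %.2f A", n_skipped, label)
    return out


def enumerate_inference_boxes(
    dmap: DensityMap,
    mask: Mask,
    stride: int = 1,
) -> Iterator[tuple[tuple[int, int, int], np.ndarray]]:
    """Yield ``(center_index, unit-norm cube)`` for masked voxels.

    One box per masked voxel whose full 13^3 neighbourhood fits inside the
    grid, sampled every ``stride`` voxels per axis.  Normalisation is
    identical to training.  Masked voxels whose window leaves the grid are
    reported (debug log) but produce no box.
    """
    dmap.check_boxable()
    mask.check_congruent(dmap)
    half = BOX_EDGE // 2
    nz, ny, nx = dmap.shape
    centers = np.argwhere(mask.data > 0)
    uncovered = 0
    for cz, cy, cx in centers:
        if stride > 1 and (cz % stride or cy % stride or cx % stride):
            continue
        if not (
            half <= cz < nz - half and half <= cy < ny - half and half <= cx < nx - half
        ):
            uncovered += 1
            continue
        cube = _unit_normalize(
            dmap.data[
                cz - half : cz + half + 1,
                cy - half : cy + half + 1,
                cx - half : cx + half + 1,
            ]
        )
        if cube is None:
            uncovered += 1
            continue
        yield (int(cz), int(cy), int(cx)), cube
    if uncovered:
        logger.debug("%d masked voxels not coverable by a full window", uncovered)


# ---------------------------------------------------------------------------
# HDF5 container
#
# Layout: datasets "cubes" (n, 13, 13, 13) float32 and "labels" (n,) float32;
# root attrs "band" (JSON BandSpec) and "provenance" (JSON free-form).
# ---------------------------------------------------------------------------


@dataclass
class BoxSet:
    """In-memory stack of labeled boxes plus band metadata."""

    cubes: np.ndarray  # (n, 13, 13, 13) float32
    labels: np.ndarray  # (n,) float32
    band: BandSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cubes = np.asarray(self.cubes, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.float32).reshape(-1)
        if len(self.cubes) != len(self.labels):
            raise ValidationError("cubes/labels length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_boxes(cls, boxes: list[LabeledBox], band: BandSpec, provenance: dict | None = None) -> "BoxSet":
        if boxes:
            cubes = np.stack([b.cube for b in boxes])
            labels = np.array([b.label for b in boxes], dtype=np.float32)
        else:
            cubes = np.zeros((0, BOX_EDGE, BOX_EDGE, BOX_EDGE), np.float32)
            labels = np.zeros(0, np.float32)
        return cls(cubes=cubes, labels=labels, band=band, provenance=provenance or {})

    def label_counts(self) -> dict[float, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return {float(v): int(c) for v, c in zip(values, counts)}


def save_boxes(path, box_set: BoxSet) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("cubes", data=box_set.cubes, dtype="f4")
        fh.create_dataset("labels", data=box_set.labels, dtype="f4")
        fh.attrs["band"] = json.dumps(box_set.band.to_dict())
        fh.attrs["provenance"] = json.dumps(box_set.provenance)


def load_boxes(path) -> BoxSet:
    with h5py.File(path, "r") as fh:
        return BoxSet(
            cubes=fh["cubes"][...],
            labels=fh["labels"][...],
            band=BandSpec.from_dict(json.loads(fh.attrs["band"])),
            provenance=json.loads(fh.attrs.get("provenance", "{}")),
        )
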