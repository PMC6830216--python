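"""Volume and model I/O.

Volumes are exchanged in MRC/CCP4 format.  Internally every grid is stored
as a C-ordered ``(z, y, x)`` float32 array together with an isotropic voxel
size in Angstrom and a physical origin; the MRC axis-correspondence header
words (``MAPC``/``MAPR``/``MAPS``) are honoured on read and normalised so
that the rest of the package never sees a permuted grid.  Atomic models are
read from and written to PDB files via :mod:`biotite`.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "DensityMap",
    "Mask",
    "AtomicModel",
    "MapIOError",
    "ValidationError",
    "read_map",
    "write_map",
    "read_model",
    "write_model",
    "mask_from_threshold",
]

#: residue names treated as water and excluded by default on model read
WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD", "H2O"})

MIN_GRID_EDGE = 13  # smallest grid edge usable by box extraction / inference


class MapIOError(IOError):
    """Raised for unreadable or malformed volume / model files."""


class ValidationError(ValueError):
    """Raised when data violates a documented invariant."""


@dataclass
class DensityMap:
    """A 3D scalar grid with isotropic sampling.

    Attributes
    ----------
    data :
        ``(nz, ny, nx)`` float32 (or float64) array, C order, 0-based ``(z, y, x)``.
    voxel_size :
        Edge length of one voxel in Angstrom (isotropic).
    origin :
        Physical position of voxel ``(0, 0, 0)`` in Angstrom, as ``(x, y, z)``.
        Carried through all operations but never used for resolution math.
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float32)
        self.data = data
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(f"density grid must be 3D, got ndim={self.data.ndim}")
        if not np.isfinite(self.voxel_size) or self.voxel_size <= 0:
            raise ValidationError(f"voxel_size must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("density grid contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "DensityMap":
        """New map sharing this map's sampling metadata."""
        return DensityMap(data=data, voxel_size=self.voxel_size, origin=self.origin.copy())

    def check_boxable(self) -> None:
        if min(self.shape) < MIN_GRID_EDGE:
            raise ValidationError(
                f"grid {self.shape} is smaller than {MIN_GRID_EDGE}^3; too small for boxing"
            )


@dataclass
class Mask:
    """Binary grid congruent with an associated :class:`DensityMap`."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        values = np.unique(arr)
        if not np.all(np.isin(values, (0, 1))):
            raise ValidationError("mask values must be strictly in {0, 1}")
        if arr.ndim != 3:
            raise ValidationError("mask must be 3D")
        if not arr.any():
            raise ValidationError("mask has no nonzero voxel")
        self.data = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_congruent(self, dmap: DensityMap) -> None:
        if self.shape != dmap.shape:
            raise ValidationError(f"mask shape {self.shape} != map shape {dmap.shape}")


@dataclass
class AtomicModel:
    """Point-scatterer model: element symbols, coordinates (A), occupancies."""

    elements: list[str]
    coords: np.ndarray  # (n, 3) Angstrom, columns x, y, z
    occupancy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        n = len(self.coords)
        if len(self.elements) != n:
            raise ValidationError("elements and coords length mismatch")
        if n and not np.all(np.isfinite(self.coords)):
            raise ValidationError("model coordinates must be finite")
        if any(not e for e in self.elements):
            raise ValidationError("empty element symbol in model")
        if self.occupancy is None:
            self.occupancy = np.ones(n)
        else:
            self.occupancy = np.asarray(self.occupancy, dtype=np.float64).reshape(-1)
            if len(self.occupancy) != n:
                raise ValidationError("occupancy length mismatch")

    def __len__(self) -> int:
        return len(self.coords)


# ---------------------------------------------------------------------------
# MRC / CCP4 volumes
#
# Header layout follows the MRC2014 standard: 1024-byte header of 4-byte
# words; word 1-3 = NX/NY/NZ (fast to slow file axes), word 4 = MODE,
# words 8-10 = MX/MY/MZ sampling grid, words 11-13 = CELLA in Angstrom,
# words 17-19 = MAPC/MAPR/MAPS axis correspondences (1=x, 2=y, 3=z),
# words 50-52 = ORIGIN in Angstrom, word 53 = b"MAP ".
# ---------------------------------------------------------------------------

_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def read_map(path: str | Path) -> DensityMap:
    """Read an MRC/CCP4 volume, normalising axis order to internal (z, y, x).

    Raises
    ------
    MapIOError
        If the file is missing, truncated, or of an unsupported mode.
    ValidationError
        If the voxel size is missing/zero (supply it via the CLI ``--voxel``
        flag after fixing the header) or anisotropic.
    """
    path = Path(path)
    if not path.exists():
        raise MapIOError(f"no such volume file: {path}")
    raw = path.read_bytes()
    if len(raw) < 1024:
        raise MapIOError(f"{path}: shorter than the 1024-byte MRC header")

    ints = struct.unpack_from("<10i", raw, 0)
    nx, ny, nz, mode = ints[0], ints[1], ints[2], ints[3]
    mx, my, mz = ints[7], ints[8], ints[9]
    cella = struct.unpack_from("<3f", raw, 40)
    mapc, mapr, maps = struct.unpack_from("<3i", raw, 64)
    origin = struct.unpack_from("<3f", raw, 196)

    if mode not in _MODE_DTYPES:
        raise MapIOError(f"{path}: unsupported MRC mode {mode}")
    if sorted((mapc, mapr, maps)) != [1, 2, 3]:
        # Tolerate the occasional all-zero header written by sloppy tools.
        if (mapc, mapr, maps) == (0, 0, 0):
            mapc, mapr, maps = 1, 2, 3
        else:
            raise MapIOError(f"{path}: invalid axis correspondence {(mapc, mapr, maps)}")

    (nsymbt,) = struct.unpack_from("<i", raw, 92)  # extended header bytes
    dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
    count = nx * ny * nz
    offset = 1024 + max(nsymbt, 0)
    if len(raw) < offset + count * dtype.itemsize:
        raise MapIOError(f"{path}: data block truncated")
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)
    grid = data.reshape(nz, ny, nx).astype(np.float32)

    # File axes slow->fast carry physical axes (maps, mapr, mapc); permute to (z, y, x).
    file_axes = (maps, mapr, mapc)
    perm = tuple(file_axes.index(want) for want in (3, 2, 1))
    grid = np.ascontiguousarray(grid.transpose(perm))

    m = {1: mx, 2: my, 3: mz}
    samplings = []
    for phys, n_samples in m.items():
        if n_samples == 0 or cella[phys - 1] == 0.0:
            raise ValidationError(
                f"{path}: missing/zero voxel size in header; supply one with the "
                f"CLI --voxel flag (cella={cella}, m=({mx},{my},{mz}))"
            )
        samplings.append(cella[phys - 1] / n_samples)
    samplings = np.array(samplings)
    if not np.allclose(samplings, samplings[0], rtol=1e-3):
        raise ValidationError(
            f"{path}: anisotropic voxel sizes {tuple(samplings)}; this method "
            "assumes isotropic sampling — resample the map externally first"
        )
    return DensityMap(data=grid, voxel_size=float(samplings.mean()), origin=np.array(origin))


def write_map(path: str | Path, dmap: DensityMap) -> None:
    """Write a volume as MRC mode 2 (float32) with MAPC/MAPR/MAPS = 1/2/3."""
    data = np.ascontiguousarray(dmap.data, dtype="<f4")
    nz, ny, nx = data.shape
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # nxstart/nystart/nzstart
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into(
        "<3f", header, 40, nx * dmap.voxel_size, ny * dmap.voxel_size, nz * dmap.voxel_size
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<i", header, 88, 1)  # ISPG = 1 (volume)
    struct.pack_into("<3f", header, 196, *np.asarray(dmap.origin, dtype=np.float64))
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0, 0))  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


# ---------------------------------------------------------------------------
# PDB models
# ---------------------------------------------------------------------------


def read_model(path: str | Path, include_hetatm: bool = True, include_waters: bool = False) -> AtomicModel:
    """Read ATOM/HETATM records from a PDB file.

    HETATM records are kept by default; waters are excluded by default.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise MapIOError(f"no such model file: {path}")
    try:
        pdb = PDBFile.read(str(path))
        structure = pdb.get_structure(model=1, extra_fields=["occupancy"])
    except Exception as exc:  # noqa: BLE001 - biotite raises various types
        raise MapIOError(f"{path}: cannot parse PDB file ({exc})") from exc

    keep = np.ones(structure.array_length(), dtype=bool)
    if not include_hetatm:
        keep &= ~structure.hetero
    if not include_waters:
        keep &= ~np.isin(structure.res_name, list(WATER_RESIDUES))
    structure = structure[keep]
    if structure.array_length() == 0:
        raise MapIOError(f"{path}: no parseable atom records after filtering")

    elements = [e.capitalize() if e else "C" for e in structure.element]
    return AtomicModel(
        elements=elements,
        coords=np.asarray(structure.coord, dtype=np.float64),
        occupancy=np.asarray(structure.occupancy, dtype=np.float64),
    )


def write_model(path: str | Path, model: AtomicModel) -> None:
    """Write a model as a standard PDB file (one pseudo-residue per atom)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(model)
    if n == 0:
        raise ValidationError("cannot write an empty model")
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(model.coords, dtype=np.float32)
    arr.element = np.array([e.upper() for e in model.elements])
    arr.atom_name = np.array([e.upper() for e in model.elements])
    arr.res_name = np.full(n, "UNK")
    arr.res_id = np.arange(1, n + 1)
    arr.chain_id = np.full(n, "A")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("occupancy", np.asarray(model.occupancy, dtype=float))
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------


def mask_from_threshold(dmap: DensityMap, threshold: float) -> Mask:
    """Binarise ``data > threshold`` and keep only the largest connected component.

    A convenience for runs where no mask volume is supplied.
    """
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    binary = dmap.data > threshold
    if not binary.any():
        raise ValidationError(
            f"threshold {threshold} leaves an empty mask (map max {dmap.data.max():.4g}); "
            "use a lower threshold"
        )
    labels, n_components = ndimage.label(binary)
    if n_components > 1:
        sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n_components + 1))
        binary = labels == (int(np.argmax(sizes)) + 1)
    return Mask(data=binary.astype(np.uint8))
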