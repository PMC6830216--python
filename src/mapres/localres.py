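"""End-to-end local resolution estimation and the oversharpening audit.

``estimate`` takes a density map, a mask and a trained regressor, resamples
both volumes to the regressor's working sampling rate, slides a 13^3 window
over the masked voxels and writes each prediction to the window's centre
voxel.  ``summarize`` reduces a resolution map to voxel-wise statistics.
``audit_sharpening`` sweeps candidate B factors, re-estimates after each
sharpening and matches a chosen percentile against an externally supplied
SNR-based reference distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .boxes import BandSpec, enumerate_inference_boxes
from .map_io import DensityMap, Mask, ValidationError
from .network import TrainedRegressor, predict
from .spectral import bfactor_apply, resample, resample_mask

__all__ = [
    "ResolutionMap",
    "ResolutionSummary",
    "OversharpenConfig",
    "AuditReport",
    "estimate",
    "summarize",
    "audit_sharpening",
]


@dataclass
class ResolutionMap:
    """Grid of predicted local resolutions (A); 0 outside mask/coverage."""

    data: np.ndarray
    voxel_size: float
    band: BandSpec
    coverage: np.ndarray  # uint8, 1 where a voxel received a prediction
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.coverage = np.asarray(self.coverage, dtype=np.uint8)
        if self.data.shape != self.coverage.shape:
            raise ValidationError("resolution data and coverage shape mismatch")

    def covered_values(self) -> np.ndarray:
        return self.data[self.coverage > 0]

    def as_density_map(self) -> DensityMap:
        return DensityMap(data=self.data, voxel_size=self.voxel_size, origin=self.origin)


@dataclass
class ResolutionSummary:
    median: float
    sd: float
    percentiles: dict[float, float]
    histogram_edges: np.ndarray
    histogram_counts: np.ndarray
    n_voxels: int
    n_at_clip: int = 0  # voxels pinned at the band edge (extrapolation flag)

    def to_dict(self) -> dict:
        return {
            "median": self.median,
            "sd": self.sd,
            "percentiles": {str(k): v for k, v in self.percentiles.items()},
            "histogram_edges": [float(x) for x in self.histogram_edges],
            "histogram_counts": [int(x) for x in self.histogram_counts],
            "n_voxels": self.n_voxels,
            "n_at_clip": self.n_at_clip,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class OversharpenConfig:
    b_grid: list[float] = field(default_factory=lambda: [0.0, -20.0, -40.0, -60.0, -80.0, -100.0])
    percentile: float = 20.0

    def __post_init__(self) -> None:
        if not self.b_grid:
            raise ValidationError("b_grid must be non-empty")
        if not 0.0 < self.percentile < 100.0:
            raise ValidationError("percentile must be in (0, 100)")


def estimate(
    dmap: DensityMap,
    mask: Mask,
    reg: TrainedRegressor,
    stride: int = 1,
    batch: int = 16,
    return_original_grid: bool = False,
) -> ResolutionMap:
    """Predict a local resolution map over the masked region.

    The map and mask are resampled to the regressor band's voxel size
    before the sliding window is enumerated.  ``stride`` subsamples the
    predicted centres (1 = the full per-voxel sliding window; larger values
    trade coverage for speed and leave the skipped voxels uncovered).
    With ``return_original_grid`` the result is carried back to the input
    grid by nearest-value resampling.
    """
    mask.check_congruent(dmap)
    band = reg.band
    work = resample(dmap, band.voxel_size)
    work_mask = (
        resample_mask(mask, dmap.voxel_size, band.voxel_size)
        if abs(band.voxel_size - dmap.voxel_size) / dmap.voxel_size > 1e-9
        else Mask(mask.data.copy())
    )
    if work_mask.shape != work.shape:  # rounding mismatch between the two resamples
        raise ValidationError("internal: mask/map resampling disagreement")
    work.check_boxable()

    out = np.zeros(work.shape, np.float32)
    coverage = np.zeros(work.shape, np.uint8)
    centers: list[tuple[int, int, int]] = []
    cubes: list[np.ndarray] = []

    def flush() -> None:
        if not cubes:
            return
        values = predict(reg, np.stack(cubes), batch=batch)
        for (cz, cy, cx), val in zip(centers, values):
            out[cz, cy, cx] = val
            coverage[cz, cy, cx] = 1
        centers.clear()
        cubes.clear()

    for center, cube in enumerate_inference_boxes(work, work_mask, stride=stride):
        centers.append(center)
        cubes.append(cube)
        if len(cubes) >= 4096:
            flush()
    flush()

    if not coverage.any():
        raise ValidationError(
            "no masked voxel could be covered by a full sliding window; "
            "the mask may be empty after resampling or hug the map border"
        )

    rmap = ResolutionMap(
        data=out, voxel_size=band.voxel_size, band=band, coverage=coverage, origin=dmap.origin.copy()
    )
    if return_original_grid and work.shape != dmap.shape:
        zoom = np.array(dmap.shape) / np.array(work.shape)
        data = ndimage.zoom(out, zoom, order=0, grid_mode=True, mode="nearest")
        cov = ndimage.zoom(coverage, zoom, order=0, grid_mode=True, mode="nearest")
        rmap = ResolutionMap(
            data=data,
            voxel_size=dmap.voxel_size,
            band=band,
            coverage=cov,
            origin=dmap.origin.copy(),
        )
    return rmap


def summarize(
    rmap: ResolutionMap,
    percentiles: tuple[float, ...] = (20.0, 50.0, 80.0),
    bin_width: float = 0.1,
) -> ResolutionSummary:
    """Voxel-wise statistics over covered voxels; histogram at the bank step."""
    values = rmap.covered_values()
    if values.size == 0:
        raise ValidationError("resolution map has no covered voxels to summarise")
    d_min, d_max = rmap.band.label_range
    lo = np.floor(d_min / bin_width) * bin_width
    hi = np.ceil(d_max / bin_width) * bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    eps = 1e-4
    n_clip = int(np.sum(values <= d_min + eps) + np.sum(values >= d_max - eps))
    return ResolutionSummary(
        median=float(np.median(values)),
        sd=float(np.std(values)),
        percentiles={float(p): float(np.percentile(values, p)) for p in percentiles},
        histogram_edges=edges,
        histogram_counts=counts,
        n_voxels=int(values.size),
        n_at_clip=n_clip,
    )


@dataclass
class AuditReport:
    """Outcome of the B-factor sweep against an SNR-based reference."""

    percentile: float
    reference_value: float
    rows: list[dict]  # per B: {"b_factor", "percentile_value", "median", "oversharpened"}
    recommended_b: float

    def to_dict(self) -> dict:
        return {
            "percentile": self.percentile,
            "reference_value": self.reference_value,
            "rows": self.rows,
            "recommended_b": self.recommended_b,
        }

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["b_factor", "percentile_value", "median", "oversharpened"]
            )
            writer.writeheader()
            for row in self.rows:
                writer.writerow(row)

    def describe(self) -> str:
        lines = [
            f"reference {self.percentile:g}% percentile: {self.reference_value:.2f} A",
            f"recommended B factor: {self.recommended_b:g} A^2",
        ]
        for row in self.rows:
            flag = "  [oversharpened]" if row["oversharpened"] else ""
            lines.append(
                f"  B={row['b_factor']:>7g}: {self.percentile:g}% -> "
                f"{row['percentile_value']:.2f} A{flag}"
            )
        return "\n".join(lines)


def _reference_percentile(reference, percentile: float) -> float:
    """Percentile of the reference distribution (map or precomputed summary)."""
    if isinstance(reference, ResolutionMap):
        values = reference.covered_values()
        return float(np.percentile(values, percentile))
    if isinstance(reference, ResolutionSummary):
        for p, v in reference.percentiles.items():
            if abs(p - percentile) < 1e-9:
                return float(v)
        raise ValidationError(
            f"reference summary lacks the {percentile:g}% percentile; "
            f"available: {sorted(reference.percentiles)}"
        )
    raise ValidationError("reference must be a ResolutionMap or ResolutionSummary")


def audit_sharpening(
    unsharpened: DensityMap,
    mask: Mask,
    reg: TrainedRegressor,
    reference,
    cfg: OversharpenConfig | None = None,
    stride: int = 1,
) -> AuditReport:
    """Sweep B factors and match the chosen percentile against the reference.

    For every B in the grid the unsharpened map is sharpened, re-estimated
    and summarised.  The recommended B is the one whose percentile value is
    closest to the reference's; any B whose percentile is strictly better
    (numerically lower) than the reference is flagged as oversharpening.
    """
    cfg = cfg or OversharpenConfig()
    ref_value = _reference_percentile(reference, cfg.percentile)
    rows = []
    for b in cfg.b_grid:
        sharpened = bfactor_apply(unsharpened, b)
        rmap = estimate(sharpened, mask, reg, stride=stride)
        summary = summarize(rmap, percentiles=(cfg.percentile, 50.0))
        value = summary.percentiles[float(cfg.percentile)]
        rows.append(
            {
                "b_factor": float(b),
                "percentile_value": float(value),
                "median": summary.median,
                "oversharpened": bool(value < ref_value - 1e-9),
            }
        )
    recommended = min(rows, key=lambda r: abs(r["percentile_value"] - ref_value))
    return AuditReport(
        percentile=cfg.percentile,
        reference_value=ref_value,
        rows=rows,
        recommended_b=recommended["b_factor"],
    )
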