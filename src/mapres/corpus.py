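"""Training-corpus construction: models -> filtered maps -> labeled boxes."""

from __future__ import annotations

import logging

import numpy as np

from .boxes import BandSpec, BoxSet, extract_training_boxes
from .map_io import AtomicModel, ValidationError, mask_from_threshold
from .simulate import ScatteringKernel, add_noise, model_to_density, normalize_to_unit_max
from .simulate import NoiseSpec
from .spectral import FilterBankSpec, FilterSpec, lowpass_raised_cosine

__all__ = ["make_corpus", "envelope_mask"]

logger = logging.getLogger(__name__)

MASK_SMOOTH_CUTOFF = 10.0  # A; low-pass applied before thresholding
MASK_REL_THRESHOLD = 0.1  # fraction of the smoothed map maximum


def envelope_mask(
    dmap,
    smooth_cutoff: float = MASK_SMOOTH_CUTOFF,
    rel_threshold: float = MASK_REL_THRESHOLD,
):
    """Molecular envelope: threshold a low-pass-smoothed copy of the map.

    Thresholding the raw simulated density fails for sharp atomic kernels
    (isolated blobs around atoms); smoothing first yields a connected
    envelope, as masks are conventionally drawn.
    """
    smooth = lowpass_raised_cosine(dmap, FilterSpec(smooth_cutoff, transition_width=0.1))
    return mask_from_threshold(smooth, rel_threshold * float(smooth.data.max()))


def make_corpus(
    models: list[AtomicModel],
    band: BandSpec,
    bank: FilterBankSpec | None = None,
    stride: int = 5,
    occupancy_min: float = 0.5,
    boxes_per_label_per_model: int | None = None,
    noise_sd: float | tuple[float, ...] = 0.0,
    seed: int = 0,
    kernel: ScatteringKernel | None = None,
) -> BoxSet:
    """Build a balanced labeled-box corpus for one band.

    For each model: simulate density at the band's voxel size, normalise to
    unit maximum, low-pass filter at every bank cutoff and extract unit-norm
    boxes labeled with that cutoff.  Per-label counts are balanced to the
    global minimum (optionally capped) by seeded subsampling and logged.
    ``noise_sd`` adds post-filter Gaussian noise so the corpus also covers
    the noisy-map regime; a tuple of levels is cycled across the filtered
    maps so the corpus spans all of them.
    """
    if not models:
        raise ValidationError("make_corpus needs at least one model")
    bank = bank or band.bank
    for cutoff in bank.cutoffs():
        FilterSpec(float(cutoff)).check_nyquist(band.voxel_size)  # fail before any work
        if cutoff < band.bank.d_min - 1e-9 or cutoff > band.bank.d_max + 1e-9:
            raise ValidationError(
                f"bank cutoff {cutoff} A outside the band label range {band.label_range}"
            )

    rng = np.random.default_rng(seed)
    kernel = kernel or ScatteringKernel()
    per_label: dict[float, list[np.ndarray]] = {float(c): [] for c in bank.cutoffs()}

    for i_model, model in enumerate(models):
        clean = normalize_to_unit_max(model_to_density(model, band.voxel_size, kernel=kernel))
        if min(clean.shape) < 13:
            logger.warning("model %d gives a grid %s too small to box; skipped", i_model, clean.shape)
            continue
        mask = envelope_mask(clean)
        noise_levels = (noise_sd,) if np.isscalar(noise_sd) else tuple(noise_sd)
        for i_cut, cutoff in enumerate(bank.cutoffs()):
            filtered = lowpass_raised_cosine(clean, FilterSpec(float(cutoff)))
            sd = float(noise_levels[(i_model + i_cut) % len(noise_levels)])
            if sd > 0:
                noise_seed = int(rng.integers(0, 2**31 - 1))
                filtered = add_noise(filtered, NoiseSpec(sd=sd, seed=noise_seed))
            found = extract_training_boxes(
                filtered, mask, label=float(cutoff), stride=stride, occupancy_min=occupancy_min
            )
            per_label[float(cutoff)].extend(b.cube for b in found)

    counts = {lab: len(v) for lab, v in per_label.items()}
    if min(counts.values()) == 0:
        empty = [lab for lab, c in counts.items() if c == 0]
        raise ValidationError(f"no boxes extracted for labels {empty}")
    target = min(counts.values())
    if boxes_per_label_per_model is not None:
        target = min(target, boxes_per_label_per_model * len(models))

    cubes, labels = [], []
    for lab in sorted(per_label):
        stack = per_label[lab]
        pick = rng.permutation(len(stack))[:target]
        pick.sort()
        cubes.extend(stack[i] for i in pick)
        labels.extend([lab] * target)
    logger.info("corpus: %d labels x %d boxes (raw counts %s)", len(per_label), target, counts)

    return BoxSet(
        cubes=np.stack(cubes),
        labels=np.array(labels, np.float32),
        band=band,
        provenance={
            "n_models": len(models),
            "bank": {"d_min": bank.d_min, "d_max": bank.d_max, "step": bank.step},
            "stride": stride,
            "occupancy_min": occupancy_min,
            "noise_sd": noise_sd,
            "seed": seed,
            "boxes_per_label": target,
            "raw_counts": {f"{k:g}": v for k, v in counts.items()},
        },
    )
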