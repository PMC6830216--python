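# mapres

Voxel-wise **local resolution estimation for cryoEM density maps** with a
learned 3D convolutional regressor, plus the full simulation/validation
protocol it is trained with and an oversharpening audit.

The idea: simulate density maps from atomic (or synthetic pseudo-atomic)
models, low-pass filter them with a raised-cosine filter bank at known
cutoffs, cut them into 13×13×13 unit-norm boxes labeled by the cutoff, and
train a small 3D CNN (conv 32×13³ 'same' + ReLU → dropout 0.25 → dense 512 →
dense 1, Adam, MSE) to regress the label. At inference a map and a mask are
resampled to the training sampling rate (1.0 or 0.5 Å/voxel), a sliding
13³ window is evaluated over masked voxels and each prediction is assigned
to the window's centre voxel. Because boxes are L2-normalised, predictions
are invariant to global intensity scaling but — unlike SNR-based local
resolution methods — *sensitive* to B-factor sharpening, which enables an
oversharpening check against an SNR-based reference distribution.

The network is implemented in pure numpy + BLAS (forward, backward, Adam),
validated against an independent float64 reference in the test suite. No
GPU or deep-learning framework is required.

## Layout

| module | role |
|---|---|
| `mapres.map_io` | MRC/CCP4 volume read/write (axis order normalised), PDB models, threshold masks |
| `mapres.simulate` | model → density rasterisation, synthetic polymer generator, Gaussian noise |
| `mapres.spectral` | raised-cosine low-pass, B-factor, phase randomization, Fourier resampling |
| `mapres.boxes` | labeled training boxes, sliding-window inference boxes, HDF5 container |
| `mapres.network` | the 3D-CNN regressor: build / train / predict / checkpoint |
| `mapres.localres` | end-to-end `estimate`, `summarize`, `audit_sharpening` |
| `mapres.corpus` | model lists → balanced labeled-box corpora |
| `mapres.cli` | `mapres` command-line interface |

## CLI

```sh
# synthetic model -> PDB, then PDB -> density map
mapres simulate synth --n-atoms 800 --seed 7 --out model.pdb
mapres simulate --pdb model.pdb --voxel 1.0 --out map.mrc

# Fourier transforms
mapres xform lowpass   --cutoff 4.0 --in map.mrc --out filt.mrc
mapres xform bfactor   --b -60     --in map.mrc --out sharp.mrc
mapres xform phaserand --beyond 4.0 --seed 1 --in map.mrc --out rand.mrc
mapres xform resample  --voxel 1.0 --in map.mrc --out rs.mrc

# corpus -> training -> prediction
mapres make-corpus --n-synth 20 --band wide --d-min 3 --d-max 12 --step 1 \
                   --noise-sd 0.08 --seed 0 --out boxes.h5
mapres train --boxes boxes.h5 --epochs 15 --out band1.ckpt --loss-csv loss.csv
mapres predict --map map.mrc --mask mask.mrc --checkpoint band1.ckpt \
               --out res.mrc --summary summary.json

# oversharpening audit against an SNR-based reference resolution map
mapres audit --map map.mrc --mask mask.mrc --checkpoint band1.ckpt \
             --reference ref_res.mrc --b-grid 0,-20,-40,-60,-80,-100 --out audit.csv
```

Exit codes: 0 success, 2 validation error, 3 I/O error. Every command
writes a `<out>.provenance.json` (config snapshot, versions, seeds). A flat
`key = value` config file can be passed as `mapres --config run.cfg ...`;
explicit flags override file values.

Resolution maps are MRC volumes (background = 0) loadable directly in
standard viewers for surface colouring.

## Behaviour notes

- Training corpora may mix noise levels (`make-corpus --noise-sd`, or a
  tuple via the API) and use rotation augmentation; both are needed at
  small corpus sizes and are recorded in every checkpoint's provenance.
- The direction of the B-factor response depends on the training noise
  model: a regressor trained on noise-bearing maps reads strongly
  oversharpened (noise-amplified) maps as *worse*, whereas a clean-trained
  regressor is credulous about amplified noise and reads them as *better*.
  The `audit` percentile-matching report is meaningful in both regimes, but
  the "oversharpened" flag follows the clean-trained reading.

## Conventions

- Grids are stored `(z, y, x)`, C order; MRC axis-correspondence header
  words are honoured on read and normalised away.
- Voxel sizes must be isotropic; anisotropic headers are rejected.
- Normalised frequency is in cycles/voxel (Nyquist 0.5); a cutoff of
  `d` Å at sampling `v` Å/voxel sits at `f = v/d`.
- The raised-cosine transition width (default 0.02 cycles/voxel) is the
  *full* width of the cosine roll-off.
- Training labels and predictions are resolutions in Å; predictions are
  clipped to the training band ([2.5, 13] Å at 1.0 Å/voxel, [1.5, 6] Å at
  0.5 Å/voxel) and clipped voxels are counted in the summary.
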