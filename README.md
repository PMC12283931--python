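# tubemech

Quantitative characterisation of semiflexible protein filaments and designed
protein nanotubes from light-microscopy and spectroscopy data:

- **Persistence length from shape fluctuations.** A filament confined to two
  dimensions and fluctuating thermally behaves as a worm-like chain (WLC).
  Its contour length *L* and mean-square end-to-end distance ⟨*R*²⟩ obey

  ⟨*R*²⟩ = 4 *L*ₚ² [ 2 e^(−*L*/2*L*ₚ) − 2 + *L*/*L*ₚ ],

  where *L*ₚ is the persistence length. Each filament is tracked over
  100–200 movie frames, contributes one (*L*, ⟨*R*²⟩) point, and *L*ₚ is
  estimated by nonlinear least squares over the pooled points. An
  independent tangent-autocorrelation estimator (decay exp(−*s*/2*L*ₚ) in
  2D) is provided as a cross-check.
- **Filament tracking.** Skeleton tracing of fluorescence movies
  (threshold → skeletonise → longest path → sub-pixel ridge refinement →
  resample at 1 px node spacing) with greedy nearest-centroid linking
  across frames. Externally tracked snake-style traces can be read in
  directly.
- **Tube-length morphometry.** Tube lengths as half the perimeter of traced
  closed outlines, longest-*N* selection (*N* = 150 by default) and
  two-sided Welch's *t* test between conditions.
- **Thermal-melt fitting.** Four-parameter logistic fits of CD melting
  curves (ellipticity at 222 nm vs temperature) returning the denaturation
  midpoint *T*m.
- **Synthetic data.** An equilibrium 2D WLC sampler with known ground-truth
  *L*ₚ and a TIRFM-like fluorescence renderer (Gaussian PSF, Poisson shot
  noise, read noise, 8/16-bit quantisation, multi-page TIFF), plus a
  sigmoidal melt-curve generator — so every stage of the pipeline can be
  validated against known ground truth.

The package is written for experimentalists characterising cytoskeletal
filaments or engineered filamentous assemblies who want the estimation
chain to be testable end to end without raw-image downloads.

## Worked example

Simulate a study-scale ensemble (55 filaments × 150 independent equilibrium
frames, ground-truth *L*ₚ = 19.7 µm, contour lengths uniform in 2–15 µm)
and fit the WLC relation:

```python
import tubemech as tm

cfg = tm.SyntheticConfig.uniform_lengths(
    19.7, 55, (2.0, 15.0), n_frames=150, ds=0.05, rng_seed=1
)
stacks = tm.sample_ensemble(cfg)
fit = tm.PersistenceLengthModel.from_stacks(stacks).fit()
print(fit.summary())
```

```
Worm-like-chain persistence length fit
==========================================
  Lp estimate             19.6606 µm
  Lp standard error        0.2153 µm
  n points                     55
  residual norm             5.696 µm²
  converged                  True
```

The fitted 19.66 ± 0.22 µm recovers the ground-truth 19.7 µm: each of the
55 points is a frame-averaged (*L*, ⟨*R*²⟩) pair, and the standard error
comes from the fit covariance. `fit.plot()` overlays the points and the
fitted curve; `tm.tangent_correlation_lp(stacks)` gives the independent
tangent-decay estimate.

Melt-curve fitting works the same way (signals in mean residue
ellipticity; the fit is direction-agnostic):

```python
import numpy as np
curve = tm.simulate_melt_curve(
    46.2, 2.0, (-18000.0, -2000.0), 320.0,
    np.arange(20.0, 71.0), np.random.default_rng(0),
)
print(tm.fit_sigmoid_tm(curve).summary())
```

```
Thermal denaturation sigmoid fit
========================================
  Tm                     46.299 °C
  Tm standard error       0.066 °C
  slope k                 2.159 °C
  folded baseline    -1.808e+04
  unfolded baseline       -1755
  converged                True
```

At 2% amplitude noise the midpoint is recovered within 0.1 °C of the
46.2 °C ground truth.

## Command line

The same pipeline is exposed as subcommands of `tubemech`:

```sh
tubemech simulate --config cfg.yaml --seed 1 --out traces.tsv
tubemech render   --traces traces.tsv --config cfg.yaml --out movie.tif
tubemech track    --stack movie.tif --config cfg.yaml --out tracked.tsv
tubemech fit-lp   --traces tracked.tsv --unit px --pixel-size 0.267 --cross-check
tubemech tubelen  --outlines outlines.tsv --top-n 150 --out lengths.tsv
tubemech compare  --a before.tsv --b after.tsv
tubemech melt     --data melt.tsv --out tm.json
```

YAML configs carry `synthetic:`, `optics:` and `tracking:` sections
mirroring the config dataclasses. Trace tables are TSV with columns
`filament_id, frame, node_index, x, y, unit`.

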