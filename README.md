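# neumannmri

Parallel MRI reconstruction from under-sampled multi-coil k-space with
unrolled Neumann-series networks, including a multi-domain variant with
learned coil sensitivity maps, the classical zero-filled and GRAPPA
comparators, and a synthetic multi-coil acquisition simulator so everything
is testable without external data.

## The problem and the model

Accelerated MRI acquires only a subset of k-space lines.  With multiple
receiver coils the measurement is

    y = A x + ε,      A = M ∘ F ∘ S,

where `S` multiplies the image by each coil's complex sensitivity map, `F` is
the (centered, orthonormal) 2-D Fourier transform, `M` keeps the sampled
columns, and `ε` is complex Gaussian noise.  Regularized least squares

    x̂ = argmin_x  ½‖Ax − y‖² + λ R(x)

is solved by an unrolled, truncated Neumann series trained end-to-end:

    x₀ = λ A<sup>H</sup> y,
    x_j = x_{j−1} − λ A<sup>H</sup>A x_{j−1} − λ R(x_{j−1}),
    x̂  = Σ_{j=0}^{N} x_j,

with `R` a CNN.  The multi-domain variant with sensitivity maps (MDNNSM)
applies `F∘S` to both sides and runs the recursion on multi-coil k-space:

    k₀ = λ M y,
    k_j = k_{j−1} − λ M k_{j−1} − λ F S R(S<sup>H</sup> F<sup>−1</sup> k_{j−1}),
    k̂  = Σ_j k_j,      x̂ = RSS(F<sup>−1</sup> k̂),

where `R(x) = CNN_I(x) + F⁻¹(CNN_F(F x))` regularizes in the image and
frequency domains in parallel, and the maps themselves are estimated by a CNN
from the fully sampled ACS block, `S = CNN_C(F⁻¹ M_ACS y)`, trained jointly
with the reconstruction under an SSIM loss.  Because no deep-learning
framework is required at runtime, the networks (U-Nets with instance
normalization and leaky ReLU), Adam, and the differentiable SSIM loss are
implemented on a small numpy reverse-mode autodiff engine in `neumannmri.nn`.

## Worked example

```bash
python examples/simulate_and_baselines.py
```

```
sampled columns: 40/64 (acceleration 2, ACS 16 columns)
zero-filled NMSE: 0.00743
GRAPPA      NMSE: 0.00014
```

A noiseless 8-coil scene is undersampled 2×; zero-filling leaves aliased
replicas (NMSE 7.4e-3 against the fully sampled reference), while GRAPPA
fills the missing columns with ACS-calibrated kernels and reduces the error
by a factor of ~50.  The other examples follow the same pattern:
`neumann_closed_forms.py` checks the regularizer-free recursion against its
geometric-series and pseudoinverse closed forms,
`sensitivity_maps.py` shows self-calibrated map error growing as the ACS
shrinks (mean magnitude error 0.0035 at 25% ACS vs 0.049 at 4%), and
`train_trend_experiment.py` runs the scaled-down trained comparison (a few
CPU minutes).

There is also a thin CLI:

```bash
neumannmri simulate --scenes 4 --coils 4 --size 64 --accel 4 --acs-fraction 0.08 --seed 0 --out scenes.h5
neumannmri recon --method grappa --in scenes.h5 --out recon.h5
neumannmri eval --pred recon.h5 --ref scenes.h5 --report report.json
```

Volumes are fastMRI-dialect HDF5 (`kspace`, `reconstruction_rss`,
`sensitivity_maps`); `train` and `mask` subcommands complete the pipeline.

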