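# Methods

## Acquisition model and conventions

All arrays are laid out `(coils, rows, cols)`.  The Fourier transform is
centered (DC at `rows//2, cols//2`) and orthonormal, so `fft2c` is unitary and
its adjoint equals its inverse; masks act on a centered spectrum.  The
undersampled axis is the last (column / phase-encode) axis, producing the
familiar vertical-stripe equispaced patterns.  An equispaced mask with
acceleration `R` samples the columns congruent to `offset (mod R)` plus a
contiguous, centered auto-calibration (ACS) block of
`round(acs_fraction · num_cols)` columns (minimum 1, otherwise an error); the
standard settings are (R, ACS) = (2, 10%), (4, 8%), (8, 4%).  Complex data
enters real-valued CNNs by concatenating all real channels then all imaginary
channels, so C complex coils become 2C real channels; the packing is an exact
bijection.

Sensitivity maps are normalized pixelwise so Σ_c |S_c|² = 1 wherever there is
signal (zeroed where the coil RSS falls below 1e-3 of its maximum).  Under
that normalization the conjugate combine Σ_c conj(S_c)·(·) is simultaneously
the adjoint and the exact left inverse of the coil expansion, which is the
reading adopted for the inverse-like symbols in the derivation: a map from
one image to C coil images has no literal inverse, and only the adjoint makes
the gradient-descent interpretation of the recursion correct.  The same
reasoning replaces A⁻¹ by A^H = S^H∘F⁻¹∘M throughout.

## The unrolled recursion

`neumann_reconstruct` implements

    x₀ = λ₀ A^H y,   x_j = x_{j−1} − λ_j A^H A x_{j−1} − λ_j R(x_{j−1}),
    x̂ = Σ_{j=0}^N x_j,

with N = 6 blocks by default and one trainable λ per block, initialized
to 1.  The published recursion omits λ on the regularizer term while the
series expansion it truncates includes it; the series-consistent form is the
default and `lambda_on_regularizer=False` reproduces the literal recursion.
With `maps=None` the operator acts per coil (A = M∘F) and the regularizer
sees the 2C-channel multi-coil image — this no-maps mode is the image-domain
baseline, matching a comparator that "does not consider" sensitivity maps.

`mdnnsm_reconstruct` runs the same recursion on k-space
(`k₀ = λMy`, data-consistency block `I − λM`, regularizer applied to the
coil-combined image and re-expanded by `F∘S`), accumulates the k-space
iterates, and combines the result by root-sum-of-squares.  For single-coil
data (S ≡ 1) the k-space accumulation is exactly the Fourier transform of the
image-domain accumulation — the algebraic anchor tested to 1e-8.  For
multi-coil data S·S^H is a pixelwise projection, not the identity, so the
k-space recursion is taken as the definition (faithful to its printed form)
rather than an identity with the image-domain recursion.

Closed forms with R ≡ 0 pin the implementation down: full mask and λ = 1
terminate the series after x₀ and recover the image exactly; full mask and
λ = 0.5 give the geometric sum (1 − 0.5^{N+1})·x; and on an 8×8 undersampled
system 200 blocks reproduce the dense-pseudoinverse (minimum-norm
least-squares) solution to better than 1e-4 relative error.

## Sensitivity estimation

Both estimators start from the ACS-only zero-filled coil images
F⁻¹(M_ACS y).  `acs_lowres_maps` divides them by their RSS — the classical
low-resolution self-calibration, which is exact for constant maps and serves
as the non-learned comparator (a full eigendecomposition estimator is out of
scope).  `cnn_maps` refines the channel-packed images with a CNN before the
RSS normalization; during training the normalization uses an eps-regularized
denominator (eps = 1e-12) so it is differentiable, leaving Σ|S_c|² within
1e-12 of 1.  The map-estimator network is residual (t + UNet(t)), so with the
zero-initialized output layer the learned maps coincide with the classical
estimate at initialization and the forward model is well-posed from step 0.
Maps are estimated once per input and held fixed across the unrolled blocks;
gradients flow through them, so they train jointly with the reconstruction
loss.

## Networks and training

All three learned components (map estimator, image-domain regularizer,
frequency-domain regularizer) share one U-Net architecture: two 3×3
convolution + instance-norm + leaky-ReLU(0.2) stages per level, 2×2 average
pooling, nearest-neighbour upsampling with 1×1 channel-reduction and skip
concatenation, and a zero-initialized 1×1 output convolution.  Zero padding
is used in the convolutions and nearest-neighbour upsampling in the decoder —
chosen for exact, simple adjoints in the in-package autodiff engine.  Odd
spatial sizes are zero-padded to the next multiple of 2^depth and cropped on
output.  Depth 4 / base width 32 is a full-scale configuration; the toy
simulation profile used by the tests runs depth 2 / base width 8.  The
zero-initialized output layers make every unrolled model equal its
regularizer-free closed form at initialization (the no-maps baseline starts
exactly at zero-filling), which both stabilizes early training and gives the
trend experiment an interpretable starting point.

Training uses Adam (lr 1e-4), batch size 1, loss 1 − SSIM between the model's
magnitude output and the reference magnitude image (RSS of the fully sampled
acquisition), with the per-sample reference maximum as the SSIM data range.
Regularizer parameters are per-block by default (unshared), with a
shared-parameter mode as configuration.  Runs are deterministic given the
seed; the checkpoint kept is the best by mean validation NMSE.  Checkpoints
are flat name→array `.npz` archives with a JSON config sidecar.

Because the runtime environment provides no deep-learning framework, the
package carries a minimal reverse-mode autodiff engine (`neumannmri.nn`):
numpy arrays with vector-Jacobian closures, complex nodes under the
conjugate-Wirtinger gradient convention (so C-linear maps backpropagate
through their adjoints — the FFT through the inverse FFT), convolution as
per-tap matmuls, and a box-filter primitive for the SSIM loss.  Every
primitive is finite-difference checked in the test suite.

## Metrics

NMSE is ‖x̂ − x_ref‖²/‖x_ref‖².  SSIM uses a 7×7 uniform window, constants
K₁ = 0.01, K₂ = 0.03, sample-covariance normalization, averaged over valid
windows; it matches both an explicitly coded direct-formula oracle and an
independent library implementation to ~1e-12.  Evaluation computes both
metrics on physical-scale magnitudes with the per-slice reference range as
the SSIM data range, which makes scores invariant to joint positive
rescaling; the 12-bit 0–4095 min-max rescale is used for display and
difference-map export and is available as an evaluation option.

## The simulator

`phantom.make_scene` generates what the model assumes and nothing more:

* anatomy: superpositions of randomly placed ellipses with positive
  intensities over a large base ellipse, clipped to [0, 1] — piecewise-smooth
  and nonnegative like a magnitude structural image, with no zero-signal
  holes inside the object (real tissue is dark, not silent);
* coil profiles: Gaussian magnitude bumps centered on a circle of radius
  1.3 FOV around the image, with gentle random linear phase ramps, normalized
  to pixelwise RSS 1;
* noise: i.i.d. complex Gaussian per k-space entry, equal across coils,
  with per-entry variance σ²; σ defaults to 2% of the RMS magnitude of the
  clean k-space (a high-SNR structural scan);
* sampling: the equispaced masks above.

Scenes are bit-reproducible from their seed.  What the simulator does *not*
emulate — anatomical texture, contrast physics, motion or ringing artifacts,
inter-coil noise correlation, off-grid trajectories — bounds what passing
tests show: they validate the operators, the recursions, calibration and the
qualitative method ordering, not clinical image quality.

`object_support(image)` (pixels above 0.1 with two erosion rounds) defines
"inside the object" for map-accuracy statements; the excluded boundary ring
is where any self-calibration ratio is undefined.

## The scaled-down trend experiment

The full-scale comparison (thousands of slices, 50 epochs, GPU) is replaced
by a fixed toy profile: 64×64 scenes, 4 coils, 64 training / 16 validation
scenes, 5 epochs, lr 1e-4, 6 blocks, depth-2/width-8 U-Nets, at 4×/8% ACS
(`experiments.TOY_PROFILE`).  The claims checked are orderings, not absolute
values: multi-domain-with-maps < image-only unrolled < zero-filled in mean
validation NMSE, and strictly increasing zero-filled NMSE across 2×→4×→8×.
At this 320-step budget the image-only baseline moves only marginally from
its zero-filling initialization (both start identical by construction), so
its margin over zero-filling is small, while the multi-domain network with
learned maps roughly halves the error — the qualitative gap the method is
designed to produce.

## Degenerate inputs and numerical choices

Masks with no ACS line, empty coil axes, odd packed-channel counts, constant
reference images, window-larger-than-image SSIM calls, and non-finite
unrolled iterates (reported with their block index) all raise typed errors.
GRAPPA calibration solves Tikhonov-damped least squares with damping 1e-4
relative to the spectral norm of the normal matrix (0 = plain minimum-norm
least squares); kernel geometry is 5 rows × 2 acquired source columns per
side, rows wrap circularly, and out-of-range source columns at the array
edges contribute zero.  The RSS used inside training adds 1e-20 under the
square root so the gradient is defined at exact zeros; inference-facing RSS
is exact.

## Known limitations

Single 2-D slices only (no volumetric transforms or non-Cartesian
trajectories); no learning-rate schedules, augmentation, or multi-device
training; the non-learned map comparator is the ACS low-resolution estimate,
not an eigenvector method; CPU-scale problem sizes throughout — the toy
profile demonstrates mechanism and ordering, not state-of-the-art scores.
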