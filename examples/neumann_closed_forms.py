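"""Closed-form anchors of the truncated Neumann series.

With the regularizer off, the unrolled network is pure linear algebra and its
output is known in closed form.  This script verifies, on a small scene:

* full mask, λ=1: the series terminates after the first term and recovers the
  image exactly;
* full mask, λ=0.5: the accumulated output is the geometric sum
  (1 − 0.5^(N+1))·x;
* undersampled 8x8 system, 200 blocks: the series converges to the
  minimum-norm least-squares solution (dense pseudoinverse).

The printed numbers are the corresponding errors; all should be tiny.
"""

import numpy as np

import neumannmri as nm
from neumannmri.recon import ForwardModel, NeumannConfig

img = nm.make_phantom(16, 16, seed=0)
maps = nm.make_coil_maps(16, 16, 4, seed=1)
full = ForwardModel(nm.make_equispaced_mask(16, 1, 1.0), maps)
y = nm.forward_apply(full, img)

xhat = nm.neumann_reconstruct(y, full, NeumannConfig(num_blocks=6))
print(f"full mask, lambda=1: max recovery error {np.abs(xhat - img).max():.2e}")

for N in (0, 3, 6):
    xh = nm.neumann_reconstruct(y, full, NeumannConfig(num_blocks=N, lambdas=0.5))
    err = np.abs(xh - (1 - 0.5 ** (N + 1)) * img).max()
    print(f"geometric series N={N}: deviation from closed form {err:.2e}")

maps8 = nm.make_coil_maps(8, 8, 4, seed=3)
A8 = ForwardModel(nm.make_equispaced_mask(8, 2, 0.25), maps8)
M = np.zeros((4 * 64, 64), complex)
for i in range(64):
    e = np.zeros(64)
    e[i] = 1.0
    M[:, i] = nm.forward_apply(A8, e.reshape(8, 8)).ravel()
x = np.random.default_rng(2).random((8, 8))
y8 = nm.forward_apply(A8, x)
x_pinv = (np.linalg.pinv(M) @ y8.ravel()).reshape(8, 8)
xh = nm.neumann_reconstruct(y8, A8, NeumannConfig(num_blocks=200, lambdas=1.0))
rel = np.linalg.norm(xh - x_pinv) / np.linalg.norm(x_pinv)
print(f"undersampled 8x8, N=200 vs dense pseudoinverse: relative error {rel:.2e}")
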