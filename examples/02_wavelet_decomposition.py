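"""Wavelet analysis of a statistic curve.

Decomposes the diversity (pi) curve of a sweep-like region into its
orthonormal wavelet coefficients, demonstrates energy conservation and
exact reconstruction, and shows how the coefficient count is invariant
to the truncation level.
"""

import numpy as np

from wavesweep import (
    FixtureSpec,
    WaveletBasisSpec,
    build_layout,
    dwt,
    featurize,
    filter_minor_allele_count,
    generate_haplotypes,
    idwt,
)
from wavesweep.wavelet_core import level_grid

region = filter_minor_allele_count(generate_haplotypes(
    FixtureSpec(pattern="trough", n_snps=645, noise_sd=0.02, seed=21)
))
pi_curve = featurize(region, build_layout(), obs_id="demo").curves[0]

print(f"candidate truncation levels at p=128: {level_grid(128)}")
for family, vm in (("haar", 1), ("daubechies_least_asymmetric", 8)):
    spec = WaveletBasisSpec(family=family, vanishing_moments=vm, p=128, j0=2)
    seg = dwt(pi_curve, spec)
    energy_gap = abs(np.linalg.norm(seg) - np.linalg.norm(pi_curve))
    rt_err = np.abs(idwt(seg, spec) - pi_curve).max()
    n_big = int(np.sum(np.abs(seg) > 0.1 * np.abs(seg).max()))
    print(f"{family:>28}: {seg.size} coefficients, "
          f"energy gap {energy_gap:.2e}, round-trip error {rt_err:.2e}, "
          f"{n_big} coefficients carry >10% of the peak magnitude")

print("\nThe transform is an orthonormal rotation: no information is "
      "lost, but the\nsweep signal concentrates in a handful of "
      "coefficients, which is what the\nsparsity-penalized regression "
      "exploits.")
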