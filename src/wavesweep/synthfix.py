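"""Synthetic fixtures with controllable spatial diversity patterns.

These generators exist to exercise the statistical machinery — they are
NOT population-genetic simulations (no coalescent, no recombination).
Haplotype matrices are built column-by-column so that windowed summary
statistics follow a chosen spatial pattern in expectation: a central
diversity trough with extended haplotype sharing (sweep-like), optional
flanking diversity crests (adaptive-introgression-like), or a flat
profile (neutral-like).  Curve-space fixtures provide class templates
and known affine response maps for classifier/predictor recovery tests.
Users training models for real data must supply feature tables computed
from proper forward or coalescent simulations.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hapio import HaplotypeMatrix
from .sumstats import N_STATS, FeatureCurves

PATTERNS = ("flat", "trough", "trough_plus_crest")

# baseline statistic levels for curve-space templates, in row order
# (pi, H1, H12, H2/H1, hapfreq1..5); roughly what a 10-SNP window in a
# moderately diverse sample shows
_BASE = np.array([3.0, 0.12, 0.18, 0.55, 0.22, 0.18, 0.12, 0.08, 0.05])
# loading of the central trough component on each statistic: diversity
# drops, haplotype homozygosity and the top haplotype frequency rise
_TROUGH_LOAD = np.array([-2.2, 0.45, 0.55, -0.35, 0.5, -0.05, -0.06, -0.05, -0.04])
# loading of the flanking crest component: diversity rises above baseline
_CREST_LOAD = np.array([1.6, -0.05, -0.08, 0.2, -0.1, 0.02, 0.02, 0.02, 0.02])


class PackingError(RuntimeError):
    """Missing-data blocks cannot be placed disjointly."""


@dataclass(frozen=True)
class FixtureSpec:
    """Shape controls for one fixture class.

    ``trough_width`` is in units of the generated axis (SNPs for
    haplotype matrices, windows for curve fixtures).  ``noise_sd`` is a
    per-entry allele flip probability for haplotypes and an additive
    Gaussian SD for curves.
    """

    n_haplotypes: int = 50
    n_snps: int = 645
    pattern: str = "flat"
    trough_depth: float = 0.9
    trough_width: float = 80.0
    crest_height: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if not 0.0 <= self.trough_depth <= 1.0:
            raise ValueError("trough_depth must lie in [0, 1]")
        if not 0.0 <= self.crest_height <= 1.0:
            raise ValueError("crest_height must lie in [0, 1]")
        if self.trough_width <= 0:
            raise ValueError("trough_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _diversity_profile(spec: FixtureSpec, n: int) -> tuple[np.ndarray, np.ndarray]:
    """(trough weight, crest weight) per position, each in [0, 1]."""
    t = np.arange(n, dtype=float)
    center = (n - 1) / 2.0
    w = spec.trough_width
    trough = np.zeros(n)
    crest = np.zeros(n)
    if spec.pattern in ("trough", "trough_plus_crest"):
        trough = spec.trough_depth * np.exp(-0.5 * ((t - center) / w) ** 2)
    if spec.pattern == "trough_plus_crest":
        for sign in (-1.0, 1.0):
            mu = center + sign * 2.2 * w
            crest += np.exp(-0.5 * ((t - mu) / (0.8 * w)) ** 2)
        crest = np.clip(spec.crest_height * crest, 0.0, 1.0)
    return trough, crest


def generate_haplotypes(spec: FixtureSpec) -> HaplotypeMatrix:
    """Haplotype matrix whose windowed statistics follow the spec pattern.

    Baseline columns cycle through five balanced bit templates of the
    haplotype index (period five, so every 10-SNP window sees the same
    column multiset and a flat noiseless fixture has identical window
    spectra).  Inside the trough a shared carrier haplotype overrides
    the template for the leading haplotypes, creating the low-diversity
    high-homozygosity signature of a sweep; crest positions inject
    random intermediate-frequency columns that raise diversity above the
    baseline.  Every emitted column keeps minor allele count >= 3.
    """
    if spec.n_haplotypes < 4:
        raise ValueError("need at least 4 haplotypes")
    if spec.n_snps < 10:
        raise ValueError("need at least 10 SNPs")
    rng = np.random.default_rng(spec.seed)
    n, S = spec.n_haplotypes, spec.n_snps
    trough, crest = _diversity_profile(spec, S)
    idx = np.arange(n)
    # five distinct square-wave templates at ~25% derived frequency
    # (heterozygosity below the 0.5 ceiling, leaving crest headroom);
    # polymorphic with MAC >= 3 for n >= 16
    templates = [
        (((idx // (k + 1)) % 4) == 0).astype(np.uint8) for k in range(5)
    ]
    cols = np.empty((n, S), dtype=np.uint8)
    for t in range(S):
        if crest[t] > 0 and rng.random() < crest[t]:
            q = rng.uniform(0.35, 0.65)
            col = (rng.random(n) < q).astype(np.uint8)
        else:
            col = templates[t % 5].copy()
        k_carriers = int(round(n * trough[t] * 0.9))
        k_carriers = min(k_carriers, n - 6)
        if k_carriers >= 2:
            # leading haplotypes share the swept haplotype; the rest keep
            # their template alleles so flanking diversity survives
            col = col.copy()
            col[:k_carriers] = 1
        cols[:, t] = col
    if spec.noise_sd > 0:
        flips = rng.random((n, S)) < min(spec.noise_sd, 0.5)
        cols = np.where(flips, 1 - cols, cols)
    # guarantee polymorphism even under heavy noise
    sums = cols.sum(axis=0)
    for t in np.flatnonzero((sums < 3) | (sums > n - 3)):
        cols[:, t] = templates[t % 5]
    positions = (np.arange(S, dtype=np.int64) + 1) * 10
    return HaplotypeMatrix(cols, positions, chrom="synthetic")


def _curve_components(p: int, width: float) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(p, dtype=float)
    center = (p - 1) / 2.0
    shape1 = np.exp(-0.5 * ((t - center) / width) ** 2)
    shape2 = np.zeros(p)
    for sign in (-1.0, 1.0):
        shape2 += np.exp(-0.5 * ((t - (center + sign * 2.2 * width)) / (0.8 * width)) ** 2)
    return shape1, shape2


def class_template(spec: FixtureSpec, p: int) -> np.ndarray:
    """Noise-free 9 x p curve template for one fixture class."""
    shape1, shape2 = _curve_components(p, spec.trough_width)
    curves = np.tile(_BASE[:, None], (1, p))
    if spec.pattern in ("trough", "trough_plus_crest"):
        curves = curves + spec.trough_depth * np.outer(_TROUGH_LOAD, shape1)
    if spec.pattern == "trough_plus_crest":
        curves = curves + spec.crest_height * np.outer(_CREST_LOAD, shape2)
    return curves


def generate_feature_fixtures(
    class_specs: dict[str, FixtureSpec],
    n_per_class: int,
    p: int = 16,
    response_map: dict[str, tuple[float, float, float]] | None = None,
    seed: int = 0,
) -> tuple[list[FeatureCurves], list[str], pd.DataFrame | None]:
    """Labeled curve-space fixtures: class template + iid Gaussian noise.

    When ``response_map`` maps response names to ``(w1, w2, b)``, each
    observation draws latent amplitudes ``u1, u2 ~ U(0.7, 1.3)`` scaling
    the trough and crest components, the curves are linear in
    ``(u1, u2)``, and the responses are the affine values
    ``w1*u1 + w2*u2 + b`` — a known linear ground truth for
    parameter-recovery tests.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    templates = {lab: class_template(sp, p) for lab, sp in class_specs.items()}
    if len({tpl.tobytes() for tpl in templates.values()}) < len(templates):
        raise ValueError("class templates are not distinct")
    rng = np.random.default_rng(seed)
    features: list[FeatureCurves] = []
    labels: list[str] = []
    resp_rows: list[dict[str, float]] = []
    for lab, sp in class_specs.items():
        shape1, shape2 = _curve_components(p, sp.trough_width)
        base = np.tile(_BASE[:, None], (1, p))
        for i in range(n_per_class):
            if response_map is not None:
                u1, u2 = rng.uniform(0.7, 1.3, size=2)
            else:
                u1 = u2 = 1.0
            curves = base.copy()
            if sp.pattern in ("trough", "trough_plus_crest"):
                curves += u1 * sp.trough_depth * np.outer(_TROUGH_LOAD, shape1)
            if sp.pattern == "trough_plus_crest":
                curves += u2 * sp.crest_height * np.outer(_CREST_LOAD, shape2)
            curves += rng.normal(0.0, sp.noise_sd, size=curves.shape)
            features.append(
                FeatureCurves(obs_id=f"{lab}_{i}", curves=curves)
            )
            labels.append(lab)
            if response_map is not None:
                resp_rows.append(
                    {name: w1 * u1 + w2 * u2 + b
                     for name, (w1, w2, b) in response_map.items()}
                )
    responses = pd.DataFrame(resp_rows) if response_map is not None else None
    return features, labels, responses


def missing_data_mask(
    S: int,
    n_blocks: int = 10,
    frac_per_block: float = 0.03,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> np.ndarray:
    """Indices of SNPs removed by the block missing-data protocol.

    ``n_blocks`` contiguous non-overlapping blocks, each of
    ``round(frac_per_block * S)`` SNPs, placed uniformly at random by
    rejection sampling; the defaults remove ten blocks of 3% each, 30%
    of the data in total.
    """
    if n_blocks < 0 or frac_per_block < 0:
        raise ValueError("n_blocks and frac_per_block must be >= 0")
    if n_blocks * frac_per_block > 1.0 + 1e-12:
        raise ValueError("blocks would exceed the total number of SNPs")
    block = int(round(frac_per_block * S))
    if n_blocks == 0 or block == 0:
        return np.empty(0, dtype=np.int64)
    if n_blocks * block > S:
        raise PackingError(
            f"{n_blocks} blocks of {block} SNPs cannot fit in {S}"
        )
    rng = np.random.default_rng(seed)
    placed: list[tuple[int, int]] = []  # half-open [start, end)
    attempts = 0
    while len(placed) < n_blocks:
        if attempts >= max_attempts:
            raise PackingError(
                f"could not place {n_blocks} disjoint blocks of {block} "
                f"in {S} SNPs after {max_attempts} attempts"
            )
        attempts += 1
        start = int(rng.integers(0, S - block + 1))
        end = start + block
        if any(start < e and s < end for s, e in placed):
            continue
        placed.append((start, end))
    removed = np.concatenate(
        [np.arange(s, e, dtype=np.int64) for s, e in sorted(placed)]
    )
    return removed


def apply_missing_mask(
    h: HaplotypeMatrix, removed: np.ndarray
) -> HaplotypeMatrix:
    """Drop the masked SNP indices from a haplotype matrix."""
    keep = np.setdiff1d(np.arange(h.n_sites), removed)
    return h.take_sites(keep)
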