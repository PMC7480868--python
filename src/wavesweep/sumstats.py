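"""Windowed summary statistics and feature-curve assembly.

Nine one-dimensional statistics are computed per window: the mean
pairwise sequence difference pi-hat, the haplotype-homozygosity
statistics H1, H12 and H2/H1, and the frequencies of the five most
common haplotypes.  Optionally, four two-dimensional statistics — the
mean, variance, skewness and kurtosis of pairwise r^2 between the
non-overlapping windows — are assembled into symmetric (p/2 x p/2)
blocks.  Feature curves are standardized per (statistic, window) cell
against training-set moments before wavelet transformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hapio import HaplotypeMatrix
from .windowing import WindowLayout

logger = logging.getLogger(__name__)

STAT_NAMES = (
    "pi", "H1", "H12", "H2_H1",
    "hapfreq1", "hapfreq2", "hapfreq3", "hapfreq4", "hapfreq5",
)
MOMENT_NAMES = ("r2_mean", "r2_var", "r2_skew", "r2_kurt")
N_STATS = len(STAT_NAMES)


class ContractError(ValueError):
    pass


@dataclass
class FeatureCurves:
    """One observation's m=9 statistic curves over p windows.

    ``twod_blocks`` maps moment name -> symmetric (p/2, p/2) matrix when
    two-dimensional r^2 statistics are enabled.
    """

    obs_id: str
    curves: np.ndarray  # (9, p)
    twod_blocks: dict[str, np.ndarray] | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.curves = np.asarray(self.curves, dtype=float)
        if self.curves.ndim != 2 or self.curves.shape[0] != N_STATS:
            raise ValueError(f"curves must be ({N_STATS}, p)")

    @property
    def p(self) -> int:
        return self.curves.shape[1]


@dataclass
class StandardizationParams:
    """Per-(statistic, window) training means and SDs (population SD).

    Zero-variance cells get SD 1 with a logged warning so standardization
    is always defined.
    """

    means: np.ndarray
    sds: np.ndarray
    block_means: dict[str, np.ndarray] | None = None
    block_sds: dict[str, np.ndarray] | None = None


def pi_hat(window_alleles: np.ndarray) -> float:
    """Mean pairwise Hamming distance over all C(n,2) haplotype pairs."""
    w = np.asarray(window_alleles)
    n = w.shape[0]
    if n < 2:
        raise ValueError("pi_hat requires at least 2 haplotypes")
    k = w.sum(axis=0, dtype=np.int64)
    # each site with k derived copies contributes k*(n-k) differing pairs
    diff_pairs = int(np.sum(k * (n - k)))
    return diff_pairs / (n * (n - 1) / 2)


def haplotype_spectrum(window_alleles: np.ndarray) -> np.ndarray:
    """Descending frequencies of distinct full-window haplotypes; sums to 1."""
    w = np.ascontiguousarray(np.asarray(window_alleles, dtype=np.uint8))
    _, counts = np.unique(w, axis=0, return_counts=True)
    freqs = np.sort(counts)[::-1] / w.shape[0]
    return freqs


def h_statistics(spectrum: np.ndarray) -> tuple[float, float, float]:
    """(H1, H12, H2/H1) from a descending, normalized haplotype spectrum.

    H1 = sum p_i^2; H12 pools the top two haplotypes,
    (p1+p2)^2 + sum_{i>=3} p_i^2; H2 = H1 - p1^2.  A single-haplotype
    spectrum yields (1, 1, 0).
    """
    s = np.asarray(spectrum, dtype=float)
    if s.size == 0 or np.any(np.diff(s) > 1e-12):
        raise ContractError("spectrum must be sorted descending")
    if abs(s.sum() - 1.0) > 1e-8:
        raise ContractError("spectrum must sum to 1")
    h1 = float(np.sum(s**2))
    if s.size == 1:
        return 1.0, 1.0, 0.0
    h12 = float((s[0] + s[1]) ** 2 + np.sum(s[2:] ** 2))
    h2 = h1 - float(s[0] ** 2)
    return h1, h12, h2 / h1


def r2_pair(site_a: np.ndarray, site_b: np.ndarray) -> float:
    """Squared Pearson correlation of allelic states at two sites."""
    a = np.asarray(site_a, dtype=float)
    b = np.asarray(site_b, dtype=float)
    va = a.var()
    vb = b.var()
    if va == 0 or vb == 0:
        raise ValueError("r2 undefined for a monomorphic site")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def _r2_cross(wa: np.ndarray, wb: np.ndarray) -> np.ndarray:
    """All pairwise r^2 between columns of two windows (vectorized)."""
    a = np.asarray(wa, dtype=float)
    b = np.asarray(wb, dtype=float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    n = a.shape[0]
    cov = ac.T @ bc / n
    var_a = (ac**2).mean(axis=0)
    var_b = (bc**2).mean(axis=0)
    denom = np.outer(var_a, var_b)
    return (cov**2) / denom


def r2_moments(
    window_a: np.ndarray,
    window_b: np.ndarray | None = None,
) -> tuple[float, float, float, float]:
    """(mean, variance, skewness, kurtosis) of pairwise r^2.

    For two distinct windows all w_a x w_b cross pairs are used; for a
    window with itself (``window_b`` None or identical) the C(w,2)
    distinct within-window pairs.  Population moments; kurtosis is
    non-excess (m4/m2^2).  A zero-variance pair set returns
    (mean, 0, 0, 0).
    """
    a = np.asarray(window_a, dtype=float)
    self_pair = window_b is None or window_b is window_a
    if self_pair:
        mat = _r2_cross(a, a)
        iu = np.triu_indices(mat.shape[0], k=1)
        vals = mat[iu]
    else:
        vals = _r2_cross(a, np.asarray(window_b, dtype=float)).ravel()
    if vals.size == 0:
        raise ContractError("empty r^2 pair set")
    mean = float(vals.mean())
    d = vals - mean
    m2 = float((d**2).mean())
    if m2 < 1e-14:
        return mean, 0.0, 0.0, 0.0
    m3 = float((d**3).mean())
    m4 = float((d**4).mean())
    return mean, m2, m3 / m2**1.5, m4 / m2**2


def featurize(
    h: HaplotypeMatrix,
    layout: WindowLayout,
    anchor_offset: int = 0,
    include_2d: bool = False,
    obs_id: str = "obs",
) -> FeatureCurves:
    """Compute all statistic curves for one placement of the layout.

    When ``include_2d`` is set, the four r^2-moment blocks over the
    alternating non-overlapping windows are filled; each unordered
    window pair is evaluated once and mirrored by symmetry.
    """
    if anchor_offset + layout.span > h.n_sites:
        raise ValueError(
            f"anchor at {anchor_offset} + span {layout.span} exceeds "
            f"{h.n_sites} sites"
        )
    # defensive: windows are SNP-delimited on filtered polymorphic sites
    sums = h.alleles.sum(axis=0)
    region = slice(anchor_offset, anchor_offset + layout.span)
    if np.any(sums[region] == 0) or np.any(sums[region] == h.n_haplotypes):
        raise ContractError("monomorphic site inside placement; filter first")

    curves = np.empty((N_STATS, layout.p))
    for i, (first, last) in enumerate(layout.windows):
        w = h.alleles[:, anchor_offset + first : anchor_offset + last + 1]
        spectrum = haplotype_spectrum(w)
        h1, h12, h2h1 = h_statistics(spectrum)
        top5 = np.zeros(5)
        top5[: min(5, spectrum.size)] = spectrum[:5]
        curves[:, i] = (pi_hat(w), h1, h12, h2h1, *top5)

    blocks = None
    if include_2d:
        ids = layout.nonoverlapping_ids
        q = len(ids)
        blocks = {name: np.empty((q, q)) for name in MOMENT_NAMES}
        wins = [
            h.alleles[:, anchor_offset + layout.windows[wid][0] :
                      anchor_offset + layout.windows[wid][1] + 1]
            for wid in ids
        ]
        for i in range(q):
            for j in range(i, q):
                mom = r2_moments(wins[i]) if i == j else r2_moments(wins[i], wins[j])
                for name, val in zip(MOMENT_NAMES, mom):
                    blocks[name][i, j] = val
                    blocks[name][j, i] = val
    return FeatureCurves(obs_id=obs_id, curves=curves, twod_blocks=blocks)


def fit_standardization(training: list[FeatureCurves]) -> StandardizationParams:
    """Per-cell means and population SDs estimated on the training set."""
    if not training:
        raise ValueError("training set must be non-empty")
    stack = np.stack([fc.curves for fc in training])
    means = stack.mean(axis=0)
    sds = stack.std(axis=0)
    n_zero = int(np.sum(sds == 0))
    if n_zero:
        logger.warning("%d zero-variance cells; SD guarded to 1", n_zero)
    sds = np.where(sds == 0, 1.0, sds)
    block_means = block_sds = None
    if all(fc.twod_blocks is not None for fc in training):
        block_means, block_sds = {}, {}
        for name in MOMENT_NAMES:
            bstack = np.stack([fc.twod_blocks[name] for fc in training])
            bm = bstack.mean(axis=0)
            bs = bstack.std(axis=0)
            bs = np.where(bs == 0, 1.0, bs)
            block_means[name] = bm
            block_sds[name] = bs
    return StandardizationParams(means, sds, block_means, block_sds)


def standardize(fc: FeatureCurves, sp: StandardizationParams) -> FeatureCurves:
    """Z-score one observation's curves against frozen training moments."""
    if fc.standardized:
        raise ContractError(f"{fc.obs_id}: already standardized")
    curves = (fc.curves - sp.means) / sp.sds
    blocks = None
    if fc.twod_blocks is not None:
        if sp.block_means is None:
            raise ContractError("standardization lacks two-dimensional moments")
        blocks = {
            name: (fc.twod_blocks[name] - sp.block_means[name])
            / sp.block_sds[name]
            for name in MOMENT_NAMES
        }
    return FeatureCurves(
        obs_id=fc.obs_id, curves=curves, twod_blocks=blocks, standardized=True
    )


# ---------------------------------------------------------------------------
# feature-table TSV (one row per observation; columns stat:window, plus the
# upper triangle of each 2-D block as moment:i:j, row-major, i <= j)


def _columns(p: int, with_2d: bool) -> list[str]:
    cols = [f"{s}:{w}" for s in STAT_NAMES for w in range(p)]
    if with_2d:
        q = p // 2
        for name in MOMENT_NAMES:
            cols.extend(
                f"{name}:{i}:{j}" for i in range(q) for j in range(i, q)
            )
    return cols


def write_feature_table(features: list[FeatureCurves], path: str) -> None:
    if not features:
        raise ValueError("no observations to write")
    p = features[0].p
    with_2d = features[0].twod_blocks is not None
    rows = []
    for fc in features:
        vals = list(fc.curves.ravel())
        if with_2d:
            q = p // 2
            iu = np.triu_indices(q)
            for name in MOMENT_NAMES:
                vals.extend(fc.twod_blocks[name][iu])
        rows.append(vals)
    df = pd.DataFrame(rows, columns=_columns(p, with_2d),
                      index=[fc.obs_id for fc in features])
    df.index.name = "obs_id"
    df.to_csv(path, sep="\t")


def read_feature_table(path: str) -> list[FeatureCurves]:
    df = pd.read_csv(path, sep="\t", index_col="obs_id")
    stat_cols = [c for c in df.columns if c.split(":")[0] in STAT_NAMES]
    p = len(stat_cols) // N_STATS
    with_2d = any(c.split(":")[0] in MOMENT_NAMES for c in df.columns)
    out = []
    for obs_id, row in df.iterrows():
        curves = row[_columns(p, False)].to_numpy(dtype=float).reshape(N_STATS, p)
        blocks = None
        if with_2d:
            q = p // 2
            iu = np.triu_indices(q)
            blocks = {}
            for name in MOMENT_NAMES:
                cols = [f"{name}:{i}:{j}" for i in range(q) for j in range(i, q)]
                mat = np.zeros((q, q))
                mat[iu] = row[cols].to_numpy(dtype=float)
                mat = mat + mat.T - np.diag(np.diag(mat))
                blocks[name] = mat
        out.append(FeatureCurves(obs_id=str(obs_id), curves=curves,
                                 twod_blocks=blocks))
    return out
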