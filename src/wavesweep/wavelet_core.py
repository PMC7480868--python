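"""Orthonormal discrete wavelet transform on dyadic statistic curves.

Supports the Haar family and Daubechies' least-asymmetric (symlet)
family with periodic boundary handling, which is the only mode giving an
exactly orthonormal p -> p map.  A curve of length p = 2^J is analysed
down to a truncation (coarsest-father) level ``j0``; the coefficient
segment is laid out as the 2^j0 father coefficients followed by the
mother coefficients from level j0 (coarse) to J-1 (fine), within each
level by location k ascending.  Regardless of j0 the segment length is
exactly 2^J, so truncation changes the basis, never the dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pywt


HAAR = "haar"
LEAST_ASYMMETRIC = "daubechies_least_asymmetric"


@dataclass(frozen=True)
class WaveletBasisSpec:
    """Wavelet family, truncation level and curve length.

    ``j0`` ranges over {0, ..., J-2} where J = log2(p): six candidate
    levels at the default p = 128.
    """

    family: str = LEAST_ASYMMETRIC
    vanishing_moments: int = 8
    p: int = 128
    j0: int = 0

    def __post_init__(self) -> None:
        if self.family not in (HAAR, LEAST_ASYMMETRIC):
            raise ValueError(f"unknown wavelet family {self.family!r}")
        if self.p < 4 or (self.p & (self.p - 1)) != 0:
            raise ValueError(f"p={self.p} must be a power of two >= 4")
        if not 0 <= self.j0 <= self.J - 2:
            raise ValueError(
                f"j0={self.j0} outside {{0,...,{self.J - 2}}} for p={self.p}"
            )

    @property
    def J(self) -> int:
        return int(np.log2(self.p))

    @property
    def pywt_name(self) -> str:
        if self.family == HAAR:
            return "haar"
        return f"sym{self.vanishing_moments}"

    @property
    def level_grid(self) -> tuple[int, ...]:
        """All admissible truncation levels {0, ..., J-2} for this p."""
        return tuple(range(self.J - 1))


def level_grid(p: int) -> tuple[int, ...]:
    """Candidate truncation levels for curve length ``p``: {0,...,log2(p)-2}."""
    if p < 4 or (p & (p - 1)) != 0:
        raise ValueError(f"p={p} must be a power of two >= 4")
    return tuple(range(int(np.log2(p)) - 1))


def segment_lengths(spec: WaveletBasisSpec) -> list[int]:
    """[2^j0 fathers, 2^j0, 2^(j0+1), ..., 2^(J-1) mothers]; sums to p."""
    return [2**spec.j0] + [2**j for j in range(spec.j0, spec.J)]


def dwt(curve: np.ndarray, spec: WaveletBasisSpec) -> np.ndarray:
    """Analyse a length-p curve into its length-p coefficient segment."""
    x = np.asarray(curve, dtype=float)
    if x.shape != (spec.p,):
        raise ValueError(f"curve length {x.shape} != p={spec.p}")
    with warnings.catch_warnings():
        # pywt warns about boundary effects at deep levels; under
        # periodization the map stays exactly orthonormal regardless
        warnings.filterwarnings(
            "ignore", message="Level value of .* is too high"
        )
        coeffs = pywt.wavedec(
            x, spec.pywt_name, mode="periodization", level=spec.J - spec.j0
        )
    return np.concatenate(coeffs)


def idwt(segment: np.ndarray, spec: WaveletBasisSpec) -> np.ndarray:
    """Exact inverse of :func:`dwt`."""
    z = np.asarray(segment, dtype=float)
    if z.shape != (spec.p,):
        raise ValueError(f"segment length {z.shape} != p={spec.p}")
    lengths = segment_lengths(spec)
    parts = np.split(z, np.cumsum(lengths)[:-1])
    return pywt.waverec(list(parts), spec.pywt_name, mode="periodization")


@lru_cache(maxsize=16)
def _transform_matrix(spec: WaveletBasisSpec) -> np.ndarray:
    """Orthonormal matrix W with dwt(x) = W @ x (cached per spec)."""
    eye = np.eye(spec.p)
    return np.stack([dwt(eye[:, k], spec) for k in range(spec.p)], axis=1)


def transform_matrix(spec: WaveletBasisSpec) -> np.ndarray:
    return _transform_matrix(spec)


def dwt2(block: np.ndarray, spec: WaveletBasisSpec) -> np.ndarray:
    """Separable row-then-column transform of a square dyadic block.

    Returns the coefficient matrix flattened row-major; Parseval holds
    because W (x) W is orthonormal.
    """
    b = np.asarray(block, dtype=float)
    if b.ndim != 2 or b.shape[0] != b.shape[1]:
        raise ValueError("block must be square")
    side = b.shape[0]
    if side & (side - 1) or side < 4:
        raise ValueError(f"block side {side} must be a power of two >= 4")
    sub = WaveletBasisSpec(
        family=spec.family,
        vanishing_moments=spec.vanishing_moments,
        p=side,
        j0=min(spec.j0, int(np.log2(side)) - 2),
    )
    w = _transform_matrix(sub)
    return (w @ b @ w.T).ravel()


def idwt2(segment: np.ndarray, spec: WaveletBasisSpec, side: int) -> np.ndarray:
    """Inverse of :func:`dwt2` for a block of the given side."""
    sub = WaveletBasisSpec(
        family=spec.family,
        vanishing_moments=spec.vanishing_moments,
        p=side,
        j0=min(spec.j0, int(np.log2(side)) - 2),
    )
    w = _transform_matrix(sub)
    m = np.asarray(segment, dtype=float).reshape(side, side)
    return w.T @ m @ w


def reconstruct_beta(zeta: np.ndarray, spec: WaveletBasisSpec) -> np.ndarray:
    """Synthesize a coefficient function beta(t) at the p window midpoints.

    The fitted regression coefficients live in the wavelet domain; this
    applies the same synthesis operator as :func:`idwt` so the result is
    the curve-domain weight function, used for inspection/plotting.
    """
    return idwt(zeta, spec)
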