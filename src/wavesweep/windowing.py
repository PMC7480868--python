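"""SNP-delimited window layout and genome-scan anchor placement.

A region is summarized over ``p`` overlapping windows of ``window_snps``
SNPs each, every window sharing ``overlap_snps`` SNPs with its neighbor.
With the defaults (p=128, 10-SNP windows, 5-SNP overlap) a placement
spans 645 SNPs; the classified SNP sits at the middle of the overlap of
the two central windows and is reported as the putative selected site.
The alternating (even-indexed) windows are non-overlapping and carry the
two-dimensional linkage-disequilibrium statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class WindowLayout:
    p: int
    window_snps: int
    overlap_snps: int
    windows: tuple[tuple[int, int], ...]  # inclusive (first, last) SNP indices
    central_snp_index: int
    nonoverlapping_ids: tuple[int, ...]

    @property
    def step(self) -> int:
        return self.window_snps - self.overlap_snps

    @property
    def span(self) -> int:
        """Total count of distinct SNPs covered by one placement."""
        return self.window_snps + (self.p - 1) * self.step


def build_layout(
    p: int = 128, window_snps: int = 10, overlap_snps: int = 5
) -> WindowLayout:
    """Construct the window layout for one classification placement.

    ``p`` must be a power of two (the wavelet transform requires dyadic
    curve length).  The classified SNP is the median SNP of the overlap
    between windows p/2 and p/2+1 (1-based window numbering); an
    even-length overlap takes the lower median.
    """
    if p < 2 or (p & (p - 1)) != 0:
        raise ConfigurationError(f"p={p} must be a power of two >= 2")
    if not 0 <= overlap_snps < window_snps:
        raise ConfigurationError(
            f"need 0 <= overlap_snps < window_snps, got {overlap_snps}, {window_snps}"
        )
    step = window_snps - overlap_snps
    windows = tuple(
        (i * step, i * step + window_snps - 1) for i in range(p)
    )
    # overlap of windows p/2 and p/2 + 1 (1-based) = 0-based p/2-1 and p/2
    left = windows[p // 2 - 1]
    right = windows[p // 2]
    lo, hi = right[0], left[1]
    if overlap_snps == 0:
        # degenerate: no shared SNPs; classify the boundary SNP
        central = right[0]
    else:
        overlap = list(range(lo, hi + 1))
        central = overlap[(len(overlap) - 1) // 2]  # lower median
    nonoverlap = tuple(range(0, p, 2))
    return WindowLayout(
        p=p,
        window_snps=window_snps,
        overlap_snps=overlap_snps,
        windows=windows,
        central_snp_index=central,
        nonoverlapping_ids=nonoverlap,
    )


def scan_anchors(S: int, layout: WindowLayout) -> list[tuple[int, int]]:
    """Anchor offsets for a scan over ``S`` filtered SNPs.

    The placement shifts one window per iteration, so consecutive
    classified SNPs are ``layout.step`` SNPs apart.  Returns
    ``(first_snp_offset, classified_snp_index)`` pairs; empty when the
    region is shorter than one placement.
    """
    if S < 0:
        raise ValueError("S must be >= 0")
    anchors = []
    offset = 0
    while offset + layout.span <= S:
        anchors.append((offset, offset + layout.central_snp_index))
        offset += layout.step
    if not anchors:
        logger.info(
            "region too short (%d SNPs < span %d), no classification",
            S, layout.span,
        )
    return anchors
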