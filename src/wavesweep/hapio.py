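"""Haplotype and mask I/O.

Reads phased biallelic haplotype data from VCF or ms-style text blocks,
applies minor-allele-count and region-mask filters, and (de)serializes
fitted models as versioned JSON.

Coordinate conventions: SNP positions are 1-based base pairs; region
masks follow the BED convention (0-based, half-open ``[start, end)``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

MODEL_SCHEMA = "wavesweep-model-v1"


class FormatError(ValueError):
    """Input file does not parse under the declared dialect."""


class EmptyInputError(ValueError):
    """No polymorphic sites remain after parsing/filtering."""


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 alleles, ``n`` haplotypes x ``S`` segregating sites.

    ``positions`` are strictly increasing 1-based bp coordinates, one per
    site (column).
    """

    alleles: np.ndarray
    positions: np.ndarray
    chrom: str = "1"
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1 (biallelic, phased)")
        if self.positions.shape != (self.alleles.shape[1],):
            raise ValueError("positions length must equal the site count")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def take_sites(self, index: np.ndarray) -> "HaplotypeMatrix":
        """New matrix restricted to the given (sorted) site indices."""
        return HaplotypeMatrix(
            self.alleles[:, index],
            self.positions[index],
            chrom=self.chrom,
            sample_ids=self.sample_ids,
        )


@dataclass
class RegionMask:
    """Half-open 0-based bp intervals to RETAIN, per chromosome."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")
        self.intervals = self._normalize(self.intervals)

    @staticmethod
    def _normalize(
        intervals: list[tuple[str, int, int]],
    ) -> list[tuple[str, int, int]]:
        # sort and merge overlapping/adjacent intervals per chromosome
        out: list[tuple[str, int, int]] = []
        for chrom, start, end in sorted(intervals):
            if out and out[-1][0] == chrom and start <= out[-1][2]:
                prev = out.pop()
                out.append((chrom, prev[1], max(prev[2], end)))
            else:
                out.append((chrom, start, end))
        return out

    def chroms(self) -> set[str]:
        return {c for c, _, _ in self.intervals}


def read_bed_mask(path: str) -> RegionMask:
    """Read a BED file of retained intervals into a :class:`RegionMask`."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                intervals.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return RegionMask(intervals)


def _positions_to_bp(fractions: list[float], locus_length: int) -> np.ndarray:
    """Map fractional ms positions to bp, bumping rounding ties by +1."""
    bp = [int(round(f * locus_length)) for f in fractions]
    for i in range(1, len(bp)):
        if bp[i] <= bp[i - 1]:
            bp[i] = bp[i - 1] + 1
    return np.asarray(bp, dtype=np.int64)


def _read_ms(path: str, locus_length: int, chrom: str) -> HaplotypeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    seg_idx = None
    for i, ln in enumerate(lines):
        if ln.startswith("segsites:"):
            seg_idx = i
            break
    if seg_idx is None:
        raise FormatError(f"{path}: no 'segsites:' line found")
    try:
        segsites = int(lines[seg_idx].split()[1])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}:{seg_idx + 1}: bad segsites line") from exc
    pos_line = lines[seg_idx + 1] if seg_idx + 1 < len(lines) else ""
    if not pos_line.startswith("positions:"):
        raise FormatError(f"{path}:{seg_idx + 2}: expected 'positions:' line")
    raw = [float(tok) for tok in pos_line.split()[1:]]
    if len(raw) != segsites:
        raise FormatError(
            f"{path}:{seg_idx + 2}: {len(raw)} positions for {segsites} segsites"
        )
    if raw and max(raw) <= 1.0:
        positions = _positions_to_bp(raw, locus_length)
    else:
        positions = np.asarray([int(round(x)) for x in raw], dtype=np.int64)
        for i in range(1, len(positions)):
            if positions[i] <= positions[i - 1]:
                positions[i] = positions[i - 1] + 1
    haps = []
    for j, ln in enumerate(lines[seg_idx + 2 :], start=seg_idx + 3):
        ln = ln.strip()
        if not ln:
            continue
        if set(ln) - {"0", "1"}:
            raise FormatError(f"{path}:{j}: non-0/1 haplotype line {ln[:20]!r}")
        if len(ln) != segsites:
            raise FormatError(
                f"{path}:{j}: haplotype length {len(ln)} != segsites {segsites}"
            )
        haps.append([int(ch) for ch in ln])
    if not haps:
        raise FormatError(f"{path}: no haplotype rows after positions line")
    alleles = np.asarray(haps, dtype=np.uint8)
    return _drop_monomorphic(
        HaplotypeMatrix(alleles, positions, chrom=chrom), path
    )


def _read_vcf(path: str) -> HaplotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids: list[str] = []
    for s in vcf.samples:
        sample_ids.extend([f"{s}_1", f"{s}_2"])
    cols: list[np.ndarray] = []
    positions: list[int] = []
    chrom = None
    skipped = 0
    for var in vcf:
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise FormatError(
                f"{path}: multiple chromosomes ({chrom}, {var.CHROM}); "
                "supply one chromosome per file"
            )
        gts = var.genotypes  # [allele_a, allele_b, phased] per sample
        if (
            len(var.ALT) != 1
            or not var.is_snp
            or any(not g[2] for g in gts)  # unphased
            or any(g[0] < 0 or g[1] < 0 for g in gts)  # missing call
            or any(g[0] > 1 or g[1] > 1 for g in gts)
        ):
            skipped += 1
            continue
        col = np.fromiter(
            (a for g in gts for a in (g[0], g[1])), dtype=np.uint8
        )
        cols.append(col)
        positions.append(var.POS)
    if skipped:
        logger.info("%s: skipped %d non-biallelic/unphased/missing records",
                    path, skipped)
    if not cols:
        raise EmptyInputError(f"{path}: no usable phased biallelic sites")
    alleles = np.stack(cols, axis=1)
    h = HaplotypeMatrix(
        alleles, np.asarray(positions), chrom=chrom or "1",
        sample_ids=sample_ids,
    )
    return _drop_monomorphic(h, path)


def _drop_monomorphic(h: HaplotypeMatrix, source: str) -> HaplotypeMatrix:
    sums = h.alleles.sum(axis=0)
    keep = np.flatnonzero((sums > 0) & (sums < h.n_haplotypes))
    if keep.size == 0:
        raise EmptyInputError(f"{source}: zero polymorphic sites")
    if keep.size < h.n_sites:
        logger.info("%s: dropped %d monomorphic sites", source,
                    h.n_sites - keep.size)
    return h.take_sites(keep)


def read_haplotypes(
    path: str,
    format: str = "ms",
    locus_length: int = 1_000_000,
    chrom: str = "1",
) -> HaplotypeMatrix:
    """Read phased haplotypes from ``vcf`` or ``ms``-dialect text.

    The ms dialect is a ``segsites:`` line, a ``positions:`` line
    (fractions of ``locus_length`` or raw bp) and one 0/1 string per
    haplotype.  Multi-allelic, unphased and partially missing VCF records
    are excluded with a logged count, never coerced.
    """
    if format == "ms":
        return _read_ms(path, locus_length, chrom)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}; expected 'vcf' or 'ms'")


def write_ms(h: HaplotypeMatrix, path: str) -> None:
    """Write a matrix in the ms dialect with bp positions (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write(f"segsites: {h.n_sites}\n")
        fh.write("positions: " + " ".join(str(p) for p in h.positions) + "\n")
        for row in h.alleles:
            fh.write("".join(str(int(a)) for a in row) + "\n")


def filter_minor_allele_count(
    h: HaplotypeMatrix, min_count: int = 3
) -> HaplotypeMatrix:
    """Drop sites whose minor allele count is below ``min_count``.

    The default of 3 removes singletons and doubletons, which damps the
    discrepancy between simulated and empirical site frequency spectra.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    sums = h.alleles.sum(axis=0)
    mac = np.minimum(sums, h.n_haplotypes - sums)
    return h.take_sites(np.flatnonzero(mac >= min_count))


def apply_region_mask(h: HaplotypeMatrix, mask: RegionMask) -> HaplotypeMatrix:
    """Retain sites whose position falls in a retained interval.

    No coordinate shifting is performed: downstream windows are
    SNP-delimited, so dropped sites simply vanish from the SNP axis.
    """
    if h.chrom not in mask.chroms() and mask.intervals:
        raise ValueError(
            f"mask covers {sorted(mask.chroms())}, not chromosome {h.chrom!r}"
        )
    keep = np.zeros(h.n_sites, dtype=bool)
    zero_based = h.positions - 1  # 1-based bp -> BED coordinates
    for chrom, start, end in mask.intervals:
        if chrom == h.chrom:
            keep |= (zero_based >= start) & (zero_based < end)
    return h.take_sites(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# model serialization


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def save_model(model, path: str) -> None:
    """Serialize a fitted classifier or predictor model to versioned JSON."""
    payload = {"schema": MODEL_SCHEMA}
    payload.update(_to_jsonable(model.to_dict()))
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str):
    """Load a model written by :func:`save_model`."""
    from . import funreg_classify, funreg_predict

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema") != MODEL_SCHEMA:
        raise FormatError(f"{path}: unknown model schema {payload.get('schema')!r}")
    kind = payload.get("kind")
    if kind == "classifier":
        return funreg_classify.ClassifierModel.from_dict(payload)
    if kind == "predictor":
        return funreg_predict.PredictorModel.from_dict(payload)
    raise FormatError(f"{path}: unknown model kind {kind!r}")
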