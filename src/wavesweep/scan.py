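"""Genome-scan driver.

Slides the window layout one window (five SNPs by default) at a time
across a filtered chromosome, classifies the central SNP of every
placement, and attaches selection-parameter predictions to non-neutral
calls.  Output is a sorted, BED-like results track.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .funreg_classify import (
    DEFAULT_SWEEP_THRESHOLD,
    NEUTRAL_LABEL,
    ClassifierModel,
    call_class,
    predict_proba,
)
from .funreg_predict import PredictorModel, SelectionParameters, predict_params
from .hapio import HaplotypeMatrix
from .sumstats import featurize
from .windowing import WindowLayout, build_layout, scan_anchors

logger = logging.getLogger(__name__)


@dataclass
class ScanRecord:
    chrom: str
    classified_position: int  # 1-based bp of the central SNP
    window_span: tuple[int, int]  # (first bp, last bp) of the placement
    probabilities: dict[str, float]
    call: str
    parameters: SelectionParameters | None = None


def run_scan(
    h: HaplotypeMatrix,
    classifier: ClassifierModel,
    predictor: PredictorModel | None = None,
    layout: WindowLayout | None = None,
    threshold: float = DEFAULT_SWEEP_THRESHOLD,
    emit_all: bool = False,
) -> list[ScanRecord]:
    """Classify every placement of the layout along the chromosome.

    ``h`` must already be filtered (minor-allele-count and any region
    mask applied).  Parameter predictions are computed for every anchor
    when a predictor is supplied but reported only on non-neutral calls
    unless ``emit_all`` is set.  Regions shorter than one placement
    yield no records, with a logged notice.
    """
    if layout is None:
        layout = build_layout(p=classifier.basis.p)
    if layout.p != classifier.basis.p:
        raise ValueError(
            f"layout p={layout.p} does not match classifier p={classifier.basis.p}"
        )
    if predictor is not None and predictor.basis.p != classifier.basis.p:
        raise ValueError("predictor and classifier disagree on p")
    anchors = scan_anchors(h.n_sites, layout)
    if not anchors:
        logger.info(
            "%s: %d SNPs < span %d; region cannot be classified",
            h.chrom, h.n_sites, layout.span,
        )
    records = []
    for offset, snp_index in anchors:
        fc = featurize(
            h, layout, anchor_offset=offset,
            include_2d=classifier.include_2d,
            obs_id=f"{h.chrom}:{h.positions[snp_index]}",
        )
        probs = predict_proba(classifier, fc)
        call = call_class(probs, classifier.classes, sweep_threshold=threshold)
        params = None
        if predictor is not None:
            params = predict_params(predictor, fc)
            if call == NEUTRAL_LABEL and not emit_all:
                params = None
        records.append(
            ScanRecord(
                chrom=h.chrom,
                classified_position=int(h.positions[snp_index]),
                window_span=(
                    int(h.positions[offset]),
                    int(h.positions[offset + layout.span - 1]),
                ),
                probabilities={
                    c: float(p) for c, p in zip(classifier.classes, probs)
                },
                call=call,
                parameters=params,
            )
        )
    records.sort(key=lambda r: r.classified_position)
    return records


def summarize_gene(
    records: list[ScanRecord],
    gene_interval: tuple[str, int, int],
) -> ScanRecord:
    """Best record within a gene: maximal non-neutral probability.

    The interval is BED-style (0-based, half-open).  Ties break to the
    smallest classified position; no overlapping record raises KeyError.
    """
    if not records:
        raise ValueError("no scan records supplied")
    chrom, start, end = gene_interval
    inside = [
        r for r in records
        if r.chrom == chrom and start <= r.classified_position - 1 < end
    ]
    if not inside:
        raise KeyError(f"no classified SNP in {chrom}:{start}-{end}")

    def non_neutral(r: ScanRecord) -> float:
        return sum(p for c, p in r.probabilities.items() if c != NEUTRAL_LABEL)

    best = max(inside, key=lambda r: (non_neutral(r), -r.classified_position))
    return best


def records_to_frame(records: list[ScanRecord]) -> pd.DataFrame:
    """BED-like table: chrom, pos-1, pos, call, class probabilities and
    any predicted parameters."""
    rows = []
    for r in records:
        row = {
            "chrom": r.chrom,
            "start": r.classified_position - 1,
            "end": r.classified_position,
            "call": r.call,
            "span_start": r.window_span[0],
            "span_end": r.window_span[1],
        }
        for c, p in r.probabilities.items():
            row[f"P_{c}"] = p
        if r.parameters is not None:
            for k, v in r.parameters.as_dict().items():
                row[k] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_records_tsv(records: list[ScanRecord], path: str) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False,
                                     na_rep="NA")
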