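"""Promoter-proximal and intronic RNAPII stalling indexes.

A stalling index is the density ratio between the best (highest-count)
fixed-width window in a search region and the length-normalized signal
of the whole feature.  The promoter-proximal index scans 100 bp windows
over [TSS - 100 bp, TSS + 300 bp] against the whole gene; the intronic
index (ISI) scans 10 bp windows within each intron longer than 50 bp
against the whole intron.  Both are invariant under scaling the track,
so they can be computed from raw or normalized coverage.  Expressed
introns (FPKM > 10) are classified as strong (ISI >= 5.5), medium
(3.5 < ISI < 5.5) or weak (ISI <= 3.5).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core import AnnotationSet, GeneModel, StrandedTrack


@dataclasses.dataclass
class StallingRecord:
    feature_id: str
    summit: int  # genomic position of the best-window center
    window: tuple[int, int]  # genomic half-open best window
    index: float
    stalling_class: str | None = None
    offset_from_5ss: int | None = None  # introns only, transcription-oriented


@dataclasses.dataclass
class ExpressionRecord:
    feature_id: str
    tag_count: float
    length_bp: int
    fpkm: float


def fpkm(tag_count: float, length_bp: int, library_size: float) -> float:
    """Tags per kilobase of feature per million library tags."""
    if length_bp <= 0:
        raise ValueError("feature length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return (tag_count / (length_bp / 1000.0)) / (library_size / 1e6)


def expression_record(
    track: StrandedTrack, feature_id: str, chrom: str, start: int, end: int,
    strand: str, library_size: float,
) -> ExpressionRecord:
    count = float(track.get(chrom, strand)[start:end].sum())
    return ExpressionRecord(feature_id, count, end - start, fpkm(count, end - start, library_size))


def _best_window(signal: np.ndarray, window_bp: int) -> tuple[int, float]:
    """Leftmost window of ``window_bp`` with the maximal sum.

    Returns (start offset, window sum); requires len(signal) >= window_bp.
    """
    csum = np.concatenate(([0.0], np.cumsum(signal)))
    sums = csum[window_bp:] - csum[:-window_bp]
    start = int(np.argmax(sums))  # argmax returns the leftmost maximum
    return start, float(sums[start])


def promoter_stalling_index(
    track: StrandedTrack,
    gene: GeneModel,
    search: tuple[int, int] = (-100, 300),
    window_bp: int = 100,
    min_gene_length: int = 1000,
) -> StallingRecord | None:
    """Best 100 bp window in [TSS-100, TSS+300] vs whole-gene density.

    The search interval is oriented along transcription and may extend
    upstream of the gene; upstream coverage counts toward the window but
    not toward the gene denominator.  Leftmost (most 5') window wins
    ties.  Returns None for short genes or genes with zero coverage.
    """
    if gene.length <= min_gene_length:
        return None
    arr = track.get(gene.chrom, gene.strand)
    gene_sum = float(arr[gene.start : gene.end].sum())
    if gene_sum == 0:
        return None
    lo, hi = search
    # oriented positions TSS+lo .. TSS+hi inclusive
    offsets = np.arange(lo, hi + 1)
    positions = (
        gene.tss + offsets if gene.strand == "+" else gene.tss - offsets
    )
    valid = (positions >= 0) & (positions < len(arr))
    signal = np.zeros(len(offsets))
    signal[valid] = arr[positions[valid]]
    if len(signal) < window_bp:
        return None
    w0, wsum = _best_window(signal, window_bp)
    index = (wsum / window_bp) / (gene_sum / gene.length)
    center_off = int(offsets[w0] + window_bp // 2)
    summit = gene.position_at_offset(center_off)
    win_start_g = gene.position_at_offset(int(offsets[w0]))
    win_end_g = gene.position_at_offset(int(offsets[w0] + window_bp - 1))
    window = (min(win_start_g, win_end_g), max(win_start_g, win_end_g) + 1)
    return StallingRecord(gene.gene_id, summit, window, float(index))


def promoter_stalling_indexes(
    track: StrandedTrack, annotation: AnnotationSet, **kwargs
) -> tuple[list[StallingRecord], dict]:
    """Batch promoter index; tallies genes excluded as short or silent."""
    records, excluded = [], {"short": 0, "zero_coverage": 0}
    min_len = kwargs.get("min_gene_length", 1000)
    for g in annotation:
        if g.length <= min_len:
            excluded["short"] += 1
            continue
        rec = promoter_stalling_index(track, g, **kwargs)
        if rec is None:
            excluded["zero_coverage"] += 1
        else:
            records.append(rec)
    return records, excluded


def stalled_gene_fraction(
    records: list[StallingRecord],
    expression: dict[str, float],
    si_threshold: float = 3.0,
    fpkm_threshold: float = 1.0,
) -> float:
    """Percentage of expressed genes (FPKM >= threshold) with a
    promoter-proximal stalling index >= ``si_threshold``."""
    by_id = {r.feature_id: r for r in records}
    expressed = [gid for gid, f in expression.items() if f >= fpkm_threshold]
    if not expressed:
        raise ValueError("no expressed genes; stalled fraction undefined")
    stalled = sum(
        1 for gid in expressed if gid in by_id and by_id[gid].index >= si_threshold
    )
    return 100.0 * stalled / len(expressed)


def intronic_stalling_index(
    track: StrandedTrack,
    gene: GeneModel,
    intron: tuple[int, int],
    window_bp: int = 10,
    min_intron_length: int = 50,
) -> StallingRecord | None:
    """Best 10 bp window within the intron vs whole-intron density.

    ``offset_from_5ss`` is the summit's distance past the donor site in
    the direction of transcription.  Introns of <=50 bp are excluded;
    zero-coverage introns return None.
    """
    gs, ge = intron
    if ge - gs <= min_intron_length:
        return None
    arr = track.get(gene.chrom, gene.strand)
    signal = arr[gs:ge].astype(float)
    if gene.strand == "-":
        signal = signal[::-1]  # orient 5' -> 3'
    total = float(signal.sum())
    if total == 0:
        return None
    w0, wsum = _best_window(signal, window_bp)
    ilen = ge - gs
    index = (wsum / window_bp) / (total / ilen)
    center_off = w0 + window_bp // 2  # offset into the intron, 5'->3'
    summit = gs + center_off if gene.strand == "+" else ge - 1 - center_off
    donor = gene.donor_of_intron(intron)
    offset = abs(summit - donor)
    if gene.strand == "+":
        window = (gs + w0, gs + w0 + window_bp)
    else:
        window = (ge - w0 - window_bp, ge - w0)
    intron_idx = gene.introns.index(intron) + 1
    return StallingRecord(
        f"{gene.gene_id}.intron{intron_idx}",
        summit,
        window,
        float(index),
        offset_from_5ss=int(offset),
    )


def classify_isi(
    record: StallingRecord,
    coverage_fpkm: float,
    min_fpkm: float = 10.0,
    strong_threshold: float = 5.5,
    weak_threshold: float = 3.5,
) -> str | None:
    """strong (ISI >= 5.5) / medium (3.5 < ISI < 5.5) / weak (ISI <= 3.5);
    introns at or below the expression cutoff stay unclassified."""
    if coverage_fpkm <= min_fpkm:
        return None
    if record.index >= strong_threshold:
        return "strong"
    if record.index <= weak_threshold:
        return "weak"
    return "medium"


def intronic_stalling_indexes(
    track: StrandedTrack,
    annotation: AnnotationSet,
    library_size: float | None = None,
    window_bp: int = 10,
    min_intron_length: int = 50,
) -> tuple[list[StallingRecord], dict]:
    """Batch ISI over all introns, with classification when a library
    size is supplied (for the intron FPKM filter)."""
    records, excluded = [], {"short": 0, "zero_coverage": 0}
    for g in annotation:
        for intron in g.introns:
            gs, ge = intron
            if ge - gs <= min_intron_length:
                excluded["short"] += 1
                continue
            rec = intronic_stalling_index(
                track, g, intron, window_bp=window_bp,
                min_intron_length=min_intron_length,
            )
            if rec is None:
                excluded["zero_coverage"] += 1
                continue
            if library_size is not None:
                cov = float(track.get(g.chrom, g.strand)[gs:ge].sum())
                rec.stalling_class = classify_isi(
                    rec, fpkm(cov, ge - gs, library_size)
                )
            records.append(rec)
    return records, excluded


def intron_peak_offset_mode(
    records: list[StallingRecord],
) -> tuple[int, bool]:
    """Modal 5'SS offset across intron records; on a tie the smaller
    offset is reported and the tie is flagged."""
    offsets = [r.offset_from_5ss for r in records if r.offset_from_5ss is not None]
    if not offsets:
        raise ValueError("no intron records with offsets")
    values, counts = np.unique(offsets, return_counts=True)
    best = counts.max()
    modes = values[counts == best]
    return int(modes.min()), len(modes) > 1


def records_to_tsv(records: list[StallingRecord], path: str) -> None:
    rows = [
        {
            "feature_id": r.feature_id,
            "summit": r.summit,
            "window_start": r.window[0],
            "window_end": r.window[1],
            "index": r.index,
            "stalling_class": r.stalling_class,
            "offset_from_5ss": r.offset_from_5ss,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
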