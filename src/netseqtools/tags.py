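"""From aligned reads to filtered RNAPII position tags and coverage tracks.

The 3'-terminal base of the (strand-flipped) read is the last base added
by the polymerase and therefore marks the RNAPII active-site position.
This module extracts those single-base tags from a BAM file, applies the
standard NET-seq cleanup filters -- structural-RNA proximity, mapping
quality, splicing intermediates at splice sites, split reads -- and
builds strand-specific per-base coverage tracks plus track-level QC
metrics (replicate correlation, splice-intermediate percentage,
exon/intron ratio, count matrices).

Every filter returns the kept tags together with the number removed so
the bookkeeping (kept + removed = input) can be audited in the run
report.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import STRANDS, AnnotationSet, StrandedTrack, TagSet

STRUCTURAL_BIOTYPES = ("rRNA", "tRNA", "snRNA", "snoRNA")


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract_tags(bam_path: str, flip_strand: bool = True) -> tuple[TagSet, int]:
    """One tag per aligned read at the 3'-terminal base after the strand flip.

    Returns ``(tags, n_unmapped_skipped)``.  With ``flip_strand`` the
    read orientation is inverted to restore the strandedness of the
    original nascent RNA; the tag sits at the 3' end of the *flipped*
    read (rightmost base for a + tag, leftmost for a - tag).
    """
    import pysam

    rows = []
    skipped = 0
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        chrom_sizes = dict(zip(bam.references, bam.lengths))
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped:
                skipped += 1
                continue
            aligned = "-" if read.is_reverse else "+"
            strand = aligned
            if flip_strand:
                strand = "-" if aligned == "+" else "+"
            position = read.reference_end - 1 if strand == "+" else read.reference_start
            is_split = any(op == 3 for op, _ in (read.cigartuples or []))
            rows.append(
                (read.reference_name, position, strand, read.mapping_quality, is_split)
            )
    if rows:
        df = pd.DataFrame(rows, columns=["chrom", "position", "strand", "mapq", "is_split"])
    else:
        df = TagSet.empty_frame()
    return TagSet(df, chrom_sizes), skipped


# ---------------------------------------------------------------------------
# Filters (each returns kept tags + removed count)
# ---------------------------------------------------------------------------

def filter_structural_rna(
    tags: TagSet,
    annotation: AnnotationSet,
    distance: int = 100,
    biotypes: tuple[str, ...] = STRUCTURAL_BIOTYPES,
) -> tuple[TagSet, int]:
    """Drop tags within ``distance`` bp (gap-wise, inclusive) of any
    structural-RNA gene, on either strand."""
    for g in annotation:
        if g.biotype is None:
            raise ValueError(
                f"gene {g.gene_id} has no biotype; structural-RNA filtering "
                "requires biotype labels in the annotation"
            )
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in annotation:
        if g.biotype in biotypes:
            spans.setdefault(g.chrom, []).append(
                (g.start - distance, g.end + distance)
            )
    if not spans:
        return tags, 0
    keep = np.ones(len(tags), dtype=bool)
    for chrom, ivals in spans.items():
        merged = _merge_intervals(ivals)
        starts = np.array([s for s, _ in merged])
        ends = np.array([e for _, e in merged])
        sel = (tags.df["chrom"] == chrom).to_numpy()
        pos = tags.df.loc[sel, "position"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        keep[np.flatnonzero(sel)[inside]] = False
    removed = int((~keep).sum())
    return tags.subset(keep), removed


def filter_mapq(tags: TagSet, min_mapq: int = 10) -> tuple[TagSet, int]:
    """Drop tags with MAPQ strictly below ``min_mapq``."""
    keep = (tags.df["mapq"] >= min_mapq).to_numpy()
    removed = int((~keep).sum())
    if removed == len(tags) and len(tags) > 0:
        warnings.warn("all tags fall below the MAPQ threshold")
    return tags.subset(keep), removed


def filter_splice_intermediates(
    tags: TagSet, splice_sites: set[tuple[str, int, str]]
) -> tuple[TagSet, int]:
    """Drop tags whose position coincides with a splice-site base on the
    same strand (spliceosome co-IP intermediates)."""
    if not splice_sites:
        warnings.warn("empty splice-site set; no splicing intermediates removed")
        return tags, 0
    keys = pd.MultiIndex.from_frame(tags.df[["chrom", "position", "strand"]])
    hit = keys.isin(splice_sites)
    removed = int(hit.sum())
    return tags.subset(~hit), removed


def remove_split_reads(tags: TagSet) -> tuple[TagSet, int]:
    """Drop tags from split (gapped) alignments -- mature-RNA contaminants."""
    keep = ~tags.df["is_split"].to_numpy()
    return tags.subset(keep), int((~keep).sum())


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

def build_track(tags: TagSet) -> StrandedTrack:
    """Per-base counts per strand; the track sums to the tag count."""
    return StrandedTrack.from_tags(tags)


def normalize_track(
    track: StrandedTrack,
    annotation: AnnotationSet,
    exclude_chroms: tuple[str, ...] = ("ChrM", "ChrC"),
) -> StrandedTrack:
    """Scale to one million tags in nuclear protein-coding gene bodies.

    The factor is 1e6 / (tags inside protein-coding genes on the
    matching strand, organellar chromosomes excluded).
    """
    coding = annotation.coding_genes(exclude_chroms=exclude_chroms)
    total = 0.0
    for g in coding:
        total += float(track.get(g.chrom, g.strand)[g.start : g.end].sum())
    if total == 0:
        raise ValueError("no tags in nuclear protein-coding genes; cannot normalize")
    factor = 1e6 / total
    out = track.scaled(factor)
    out.normalization_factor = factor
    return out


def track_correlation(a: StrandedTrack, b: StrandedTrack, bin_bp: int = 100) -> float:
    """Pearson r over binned, strand-concatenated signal.

    Returns NaN (with a warning) for zero-variance input.
    """
    if a.chrom_sizes != b.chrom_sizes:
        raise ValueError("tracks cover different genomes")
    if bin_bp < 1:
        raise ValueError("bin_bp must be >= 1")
    va, vb = [], []
    for chrom in sorted(a.chrom_sizes):
        size = a.chrom_sizes[chrom]
        edges = np.arange(0, size, bin_bp)
        for strand in STRANDS:
            va.append(np.add.reduceat(a.get(chrom, strand), edges))
            vb.append(np.add.reduceat(b.get(chrom, strand), edges))
    x, y = np.concatenate(va), np.concatenate(vb)
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance track; correlation undefined")
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


# ---------------------------------------------------------------------------
# QC metrics
# ---------------------------------------------------------------------------

def splice_intermediate_fraction(
    tags: TagSet, donor_sites: set[tuple[str, int, str]]
) -> float:
    """Percentage of tags sitting exactly on 5' splice-site bases
    (same strand), computed on tags *before* intermediate filtering."""
    if len(tags) == 0:
        warnings.warn("no tags; splice-intermediate fraction undefined")
        return float("nan")
    keys = pd.MultiIndex.from_frame(tags.df[["chrom", "position", "strand"]])
    return 100.0 * float(keys.isin(donor_sites).sum()) / len(tags)


def exon_intron_ratio(tags: TagSet, annotation: AnnotationSet) -> float:
    """(tags in exons) / (tags in introns), same-strand assignment."""
    track = StrandedTrack.from_tags(tags)
    exon_sum = intron_sum = 0.0
    for g in annotation:
        arr = track.get(g.chrom, g.strand)
        for s, e in g.exons:
            exon_sum += arr[s:e].sum()
        for s, e in g.introns:
            intron_sum += arr[s:e].sum()
    if intron_sum == 0:
        warnings.warn("no intronic tags; exon/intron ratio undefined")
        return float("nan")
    return float(exon_sum / intron_sum)


def count_matrix(
    samples: dict[str, TagSet],
    features: pd.DataFrame,
    out_tsv: str | None = None,
) -> pd.DataFrame:
    """Raw per-feature tag counts per sample (DESeq2-style input).

    ``features`` needs columns feature_id/chrom/start/end/strand;
    duplicate feature ids are an error.  Overlapping features each count
    their own tags independently.
    """
    ids = features["feature_id"]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"duplicate feature id {dup!r}")
    out = pd.DataFrame(index=ids)
    for sample, tags in samples.items():
        track = StrandedTrack.from_tags(tags)
        counts = []
        for row in features.itertuples(index=False):
            if row.chrom in track.data:
                counts.append(
                    int(track.get(row.chrom, row.strand)[row.start : row.end].sum())
                )
            else:
                counts.append(0)
        out[sample] = counts
    out.index.name = "feature_id"
    if out_tsv:
        out.to_csv(out_tsv, sep="\t")
    return out


# ---------------------------------------------------------------------------
# End-to-end BAM processing
# ---------------------------------------------------------------------------

def process_bam(
    bam_path: str,
    annotation: AnnotationSet,
    splice_sites: set[tuple[str, int, str]],
    *,
    flip_strand: bool = True,
    min_mapq: int = 10,
    structural_distance: int = 100,
) -> tuple[TagSet, dict]:
    """Full extraction + filtering path; returns tags and a tally report."""
    tags, skipped = extract_tags(bam_path, flip_strand=flip_strand)
    report = {"unmapped_skipped": skipped, "extracted": len(tags)}
    tags, report["structural_removed"] = filter_structural_rna(
        tags, annotation, distance=structural_distance
    )
    tags, report["mapq_removed"] = filter_mapq(tags, min_mapq=min_mapq)
    tags, report["splice_intermediates_removed"] = filter_splice_intermediates(
        tags, splice_sites
    )
    tags, report["split_removed"] = remove_split_reads(tags)
    report["kept"] = len(tags)
    return tags, report
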