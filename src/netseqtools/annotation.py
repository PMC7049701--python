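"""Annotation operations: TSS/PAS tag clusters, border adjustment,
splice-site unions and chromatin-state grouping.

Reference annotations (Araport11-style) carry unrealistically long
UTRs; 5' and 3' gene borders are therefore re-anchored on the summit of
the strongest TSS-seq / DR-seq tag cluster linked to the gene.  The
chromatin-state grouping collapses a 36-state segmentation into five
transcription-cycle groups (promoter, promoter-to-early-elongation,
early elongation, late elongation, termination).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .core import STRANDS, AnnotationSet, GeneModel, StrandedTrack


@dataclasses.dataclass(frozen=True)
class TagCluster:
    """A maximal run of signal positions, typed as TSS or PAS."""

    chrom: str
    start: int
    end: int
    strand: str
    summit: int
    score: float
    cluster_type: str = "TSS"

    def __post_init__(self):
        if not self.start <= self.summit < self.end:
            raise ValueError("summit must lie inside the cluster interval")
        if self.score <= 0:
            raise ValueError("cluster score must be positive")


def call_tag_clusters(
    track: StrandedTrack,
    min_signal: float = 1.0,
    max_gap_bp: int = 25,
    cluster_type: str = "TSS",
) -> list[TagCluster]:
    """Maximal same-strand runs of bases with signal >= ``min_signal``,
    merging runs separated by <= ``max_gap_bp``.

    Score is the summed signal over the cluster interval; the summit is
    the argmax (leftmost on ties).
    """
    clusters: list[TagCluster] = []
    for chrom in sorted(track.chrom_sizes):
        for strand in STRANDS:
            arr = track.get(chrom, strand)
            above = np.flatnonzero(arr >= min_signal)
            if len(above) == 0:
                continue
            breaks = np.flatnonzero(np.diff(above) > max_gap_bp + 1) + 1
            for group in np.split(above, breaks):
                start, end = int(group[0]), int(group[-1]) + 1
                window = arr[start:end]
                score = float(window.sum())
                if score <= 0:
                    continue
                summit = start + int(np.argmax(window))
                clusters.append(
                    TagCluster(chrom, start, end, strand, summit, score, cluster_type)
                )
    return clusters


def clusters_to_bed(clusters: list[TagCluster], path: str) -> None:
    """BED6 of clusters; the score column holds the cluster score."""
    with open(path, "w") as fh:
        for i, c in enumerate(
            sorted(clusters, key=lambda c: (c.chrom, c.start, c.strand)), 1
        ):
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.cluster_type}{i}\t"
                f"{c.score:g}\t{c.strand}\n"
            )


# ---------------------------------------------------------------------------
# Border adjustment
# ---------------------------------------------------------------------------

def adjust_gene_borders(
    gene: GeneModel,
    tss_clusters: list[TagCluster],
    pas_clusters: list[TagCluster],
    link_window_bp: int = 500,
) -> GeneModel:
    """Replace gene borders with the summit of the strongest linked cluster.

    A cluster is linked to the gene if its summit lies within
    ``link_window_bp`` of the *original* annotated border (same chrom
    and strand); linking against the original border makes re-running
    the adjustment with the same clusters a no-op.  Equal scores break
    ties toward the cluster nearest the original border, then leftmost.
    An adjustment that would invert the gene (TSS not upstream of PAS)
    is rejected with a warning.
    """
    five_border = gene.original_start if gene.strand == "+" else gene.original_end - 1
    three_border = gene.original_end - 1 if gene.strand == "+" else gene.original_start

    def pick(clusters, border):
        linked = [
            c
            for c in clusters
            if c.chrom == gene.chrom
            and c.strand == gene.strand
            and abs(c.summit - border) <= link_window_bp
        ]
        if not linked:
            return None
        return min(linked, key=lambda c: (-c.score, abs(c.summit - border), c.summit))

    tss_pick = pick(tss_clusters, five_border)
    pas_pick = pick(pas_clusters, three_border)
    if tss_pick is None and pas_pick is None:
        return gene

    new_tss = tss_pick.summit if tss_pick else gene.tss
    new_pas = pas_pick.summit if pas_pick else gene.pas
    if gene.strand == "+":
        ns, ne = new_tss, new_pas + 1
    else:
        ns, ne = new_pas, new_tss + 1
    if ns >= ne:
        warnings.warn(
            f"{gene.gene_id}: border adjustment would invert the gene; keeping original"
        )
        return gene
    clipped = [(max(s, ns), min(e, ne)) for s, e in gene.exons if max(s, ns) < min(e, ne)]
    if not clipped:
        clipped = [(ns, ne)]
    clipped[0] = (ns, clipped[0][1])
    clipped[-1] = (clipped[-1][0], ne)
    return GeneModel(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        start=ns,
        end=ne,
        exons=clipped,
        biotype=gene.biotype,
        adjusted=True,
        original_start=gene.original_start,
        original_end=gene.original_end,
    )


def adjust_annotation(
    annotation: AnnotationSet,
    tss_clusters: list[TagCluster],
    pas_clusters: list[TagCluster],
    link_window_bp: int = 500,
) -> AnnotationSet:
    genes = [
        adjust_gene_borders(g, tss_clusters, pas_clusters, link_window_bp)
        for g in annotation
    ]
    return AnnotationSet(genes, annotation.chrom_sizes)


# ---------------------------------------------------------------------------
# Splice sites
# ---------------------------------------------------------------------------

def splice_site_union(*annotations: AnnotationSet) -> set[tuple[str, int, str]]:
    """Strand-aware union of donor and acceptor bases across sources."""
    sites: set[tuple[str, int, str]] = set()
    for ann in annotations:
        for g in ann:
            for p in g.donor_sites():
                sites.add((g.chrom, p, g.strand))
            for p in g.acceptor_sites():
                sites.add((g.chrom, p, g.strand))
    return sites


def donor_site_set(*annotations: AnnotationSet) -> set[tuple[str, int, str]]:
    """Strand-aware union of 5' splice-site (donor) bases only."""
    sites: set[tuple[str, int, str]] = set()
    for ann in annotations:
        for g in ann:
            for p in g.donor_sites():
                sites.add((g.chrom, p, g.strand))
    return sites


# ---------------------------------------------------------------------------
# Chromatin-state grouping (36-state segmentation -> 5 groups)
# ---------------------------------------------------------------------------

_STATE_GROUPS: dict[int, str] = {}
for _s in [13, *range(15, 22)]:
    _STATE_GROUPS[_s] = "Promoter"
for _s in (22, 23):
    _STATE_GROUPS[_s] = "Promoter to early elongation"
for _s in range(24, 27):
    _STATE_GROUPS[_s] = "Early elongation"
for _s in [*range(3, 13), 27, 28]:
    _STATE_GROUPS[_s] = "Late elongation"
for _s in (1, 2):
    _STATE_GROUPS[_s] = "Termination"

CHROMATIN_STATE_GROUPS = (
    "Promoter",
    "Promoter to early elongation",
    "Early elongation",
    "Late elongation",
    "Termination",
)


def chromatin_state_group(state_id: int) -> str:
    """Map a chromatin state (1..36) to its transcription-cycle group.

    States 14 and 29-36 are not part of any group and return
    ``"unassigned"``; they are excluded from grouped analyses.
    """
    if not 1 <= state_id <= 36:
        raise ValueError(f"chromatin state id {state_id} outside 1..36")
    return _STATE_GROUPS.get(state_id, "unassigned")
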