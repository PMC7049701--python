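"""Core containers for NET-seq downstream analysis.

NET-seq reads report the 3'-terminal base of the nascent RNA, i.e. the
genomic position of the RNAPII active site, at single-nucleotide
resolution.  Everything downstream of alignment operates on three
containers defined here:

* :class:`TagSet` -- a table of single-base polymerase position tags,
* :class:`StrandedTrack` -- per-base, strand-specific coverage arrays,
* :class:`GeneModel` / :class:`AnnotationSet` -- transcription units with
  exon/intron structure and adjustable borders.

All coordinates are 0-based half-open internally.  GFF3 (1-based closed)
and bedGraph (0-based half-open) are converted at the I/O boundary.
"""

from __future__ import annotations

import io
import os
import tempfile
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STRANDS = ("+", "-")

TAG_COLUMNS = ["chrom", "position", "strand", "mapq", "is_split"]


@dataclass(frozen=True)
class PolymeraseTag:
    """One single-nucleotide RNAPII position.

    ``position`` is the 3'-terminal base of the strand-flipped read,
    i.e. the active-site position; ``strand`` is the strand of the
    original nascent RNA (after the flip).
    """

    chrom: str
    position: int
    strand: str
    mapq: int = 255
    is_split: bool = False


class TagSet:
    """Table of polymerase position tags backed by a pandas DataFrame."""

    def __init__(self, df: pd.DataFrame, chrom_sizes: dict[str, int]):
        missing = [c for c in TAG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"tag table missing columns: {missing}")
        self.df = df.reset_index(drop=True)
        self.chrom_sizes = dict(chrom_sizes)

    # -- construction ------------------------------------------------
    @classmethod
    def from_tags(cls, tags: list[PolymeraseTag], chrom_sizes: dict[str, int]) -> "TagSet":
        if tags:
            df = pd.DataFrame([t.__dict__ for t in tags])
        else:
            df = cls.empty_frame()
        return cls(df, chrom_sizes)

    @staticmethod
    def empty_frame() -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "position": pd.Series(dtype=np.int64),
                "strand": pd.Series(dtype=str),
                "mapq": pd.Series(dtype=np.int64),
                "is_split": pd.Series(dtype=bool),
            }
        )

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "TagSet":
        return TagSet(self.df[np.asarray(mask)], self.chrom_sizes)

    def sort(self) -> "TagSet":
        df = self.df.sort_values(
            ["chrom", "position", "strand", "mapq", "is_split"], kind="mergesort"
        )
        return TagSet(df, self.chrom_sizes)

    # -- I/O ---------------------------------------------------------
    def to_tsv(self, path: str) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, chrom_sizes: dict[str, int]) -> "TagSet":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        if len(df) == 0:
            df = cls.empty_frame()
        df["is_split"] = df["is_split"].astype(bool)
        return cls(df, chrom_sizes)


class StrandedTrack:
    """Per-base, strand-specific numeric signal over a genome.

    ``data[chrom][strand]`` is a float array of per-base values.  A raw
    track sums to the tag count; normalisation multiplies by
    ``normalization_factor`` (tags-per-million-in-coding-genes units).
    """

    def __init__(self, chrom_sizes: dict[str, int], normalization_factor: float = 1.0):
        self.chrom_sizes = dict(chrom_sizes)
        self.normalization_factor = float(normalization_factor)
        self.data: dict[str, dict[str, np.ndarray]] = {
            chrom: {s: np.zeros(size, dtype=float) for s in STRANDS}
            for chrom, size in chrom_sizes.items()
        }

    # -- accessors ---------------------------------------------------
    def get(self, chrom: str, strand: str) -> np.ndarray:
        return self.data[chrom][strand]

    def total(self) -> float:
        return float(sum(arr.sum() for d in self.data.values() for arr in d.values()))

    def copy(self) -> "StrandedTrack":
        out = StrandedTrack(self.chrom_sizes, self.normalization_factor)
        for chrom in self.data:
            for s in STRANDS:
                out.data[chrom][s] = self.data[chrom][s].copy()
        return out

    def scaled(self, factor: float) -> "StrandedTrack":
        out = self.copy()
        for chrom in out.data:
            for s in STRANDS:
                out.data[chrom][s] *= factor
        return out

    # -- construction ------------------------------------------------
    @classmethod
    def from_tags(cls, tags: TagSet) -> "StrandedTrack":
        track = cls(tags.chrom_sizes)
        for (chrom, strand), grp in tags.df.groupby(["chrom", "strand"], sort=False):
            arr = track.data[chrom][strand]
            np.add.at(arr, grp["position"].to_numpy(), 1.0)
        return track

    # -- bedGraph I/O (two files per sample: .fwd = plus, .rev = minus)
    def write_bedgraph(self, prefix: str) -> tuple[str, str]:
        paths = (prefix + ".fwd.bedgraph", prefix + ".rev.bedgraph")
        for strand, path in zip(STRANDS, paths):
            with open(path, "w") as fh:
                for chrom in sorted(self.data):
                    arr = self.data[chrom][strand]
                    for start, end, value in _runs(arr):
                        if value != 0:
                            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
        return paths

    @classmethod
    def read_bedgraph(
        cls, plus_path: str, minus_path: str, chrom_sizes: dict[str, int]
    ) -> "StrandedTrack":
        track = cls(chrom_sizes)
        for strand, path in zip(STRANDS, (plus_path, minus_path)):
            df = pd.read_csv(
                path,
                sep="\t",
                comment="#",
                header=None,
                names=["chrom", "start", "end", "value"],
                dtype={"chrom": str},
            )
            for row in df.itertuples(index=False):
                track.data[row.chrom][strand][row.start : row.end] = row.value
        return track

    # -- BigWig I/O --------------------------------------------------
    def write_bigwig(self, prefix: str) -> tuple[str, str]:
        import pyBigWig

        paths = (prefix + ".fwd.bw", prefix + ".rev.bw")
        header = sorted(self.chrom_sizes.items())
        for strand, path in zip(STRANDS, paths):
            bw = pyBigWig.open(path, "w")
            bw.addHeader(header)
            for chrom, _size in header:
                arr = self.data[chrom][strand]
                starts, ends, values = [], [], []
                for start, end, value in _runs(arr):
                    if value != 0:
                        starts.append(start)
                        ends.append(end)
                        values.append(float(value))
                if starts:
                    bw.addEntries(
                        [chrom] * len(starts), starts, ends=ends, values=values
                    )
            bw.close()
        return paths

    @classmethod
    def read_bigwig(cls, plus_path: str, minus_path: str) -> "StrandedTrack":
        import pyBigWig

        with_sizes = None
        track = None
        for strand, path in zip(STRANDS, (plus_path, minus_path)):
            bw = pyBigWig.open(path)
            if track is None:
                with_sizes = dict(bw.chroms())
                track = cls(with_sizes)
            for chrom, size in with_sizes.items():
                vals = bw.values(chrom, 0, size, numpy=True)
                vals = np.nan_to_num(vals, nan=0.0)
                track.data[chrom][strand] = vals.astype(float)
            bw.close()
        return track


def _runs(arr: np.ndarray):
    """Yield (start, end, value) runs of constant value in arr."""
    if len(arr) == 0:
        return
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(arr)]))
    for s, e in zip(starts, ends):
        yield int(s), int(e), float(arr[s])


# ---------------------------------------------------------------------------
# Gene models and annotation sets
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A transcription unit with exon/intron structure.

    ``start``/``end`` are 0-based half-open genomic bounds.  ``exons``
    are genomic-order non-overlapping intervals covering the gene ends.
    Introns are the gaps between consecutive exons.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    biotype: str | None = "protein_coding"
    adjusted: bool = False
    original_start: int | None = None
    original_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if self.original_start is None:
            self.original_start = self.start
        if self.original_end is None:
            self.original_end = self.end

    # -- derived coordinates ----------------------------------------
    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Position of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def pas(self) -> int:
        """Position of the last transcribed base (poly(A) site)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]

    def donor_sites(self) -> list[int]:
        """Last exonic base upstream of each intron (5' splice site)."""
        if self.strand == "+":
            return [gs - 1 for gs, _ in self.introns]
        return [ge for _, ge in self.introns]

    def acceptor_sites(self) -> list[int]:
        """First exonic base downstream of each intron (3' splice site)."""
        if self.strand == "+":
            return [ge for _, ge in self.introns]
        return [gs - 1 for gs, _ in self.introns]

    def donor_of_intron(self, intron: tuple[int, int]) -> int:
        gs, ge = intron
        return gs - 1 if self.strand == "+" else ge

    def offset_from_tss(self, position: int) -> int:
        """Signed distance from the TSS in the direction of transcription."""
        return position - self.tss if self.strand == "+" else self.tss - position

    def position_at_offset(self, offset: int) -> int:
        """Genomic position at a transcription-direction offset from the TSS."""
        return self.tss + offset if self.strand == "+" else self.tss - offset


class AnnotationSet:
    """A collection of gene models plus chromosome sizes."""

    def __init__(self, genes: list[GeneModel], chrom_sizes: dict[str, int]):
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            self.genes[g.gene_id] = g
        self.chrom_sizes = dict(chrom_sizes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def by_biotype(self, biotype: str) -> list[GeneModel]:
        return [g for g in self if g.biotype == biotype]

    def coding_genes(self, exclude_chroms: tuple[str, ...] = ()) -> list[GeneModel]:
        """Nuclear protein-coding genes (organellar chromosomes excluded)."""
        return [
            g
            for g in self
            if g.biotype == "protein_coding" and g.chrom not in exclude_chroms
        ]

    # -- interval helpers -------------------------------------------
    def intergenic_intervals(self, buffer_bp: int = 0) -> list[tuple[str, int, int]]:
        """Maximal intervals outside all genes (either strand) +/- buffer."""
        out = []
        for chrom, size in sorted(self.chrom_sizes.items()):
            spans = sorted(
                (max(0, g.start - buffer_bp), min(size, g.end + buffer_bp))
                for g in self
                if g.chrom == chrom
            )
            cursor = 0
            for s, e in spans:
                if s > cursor:
                    out.append((chrom, cursor, s))
                cursor = max(cursor, e)
            if cursor < size:
                out.append((chrom, cursor, size))
        return out

    # -- GFF3 I/O ----------------------------------------------------
    def to_gff3(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, size in sorted(self.chrom_sizes.items()):
                fh.write(f"##sequence-region {chrom} 1 {size}\n")
            for g in sorted(self.genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id)):
                attrs = f"ID={g.gene_id};biotype={g.biotype}"
                if g.adjusted:
                    attrs += ";border_adjusted=true"
                fh.write(
                    f"{g.chrom}\tnetseqtools\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
                for i, (s, e) in enumerate(g.exons, 1):
                    fh.write(
                        f"{g.chrom}\tnetseqtools\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                    )

    @classmethod
    def from_gff3(cls, path: str, chrom_sizes: dict[str, int] | None = None) -> "AnnotationSet":
        import gffutils

        sizes: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, chrom, _start, end = line.split()[:4]
                    sizes[chrom] = int(end)
                elif not line.startswith("#"):
                    break
        db = gffutils.create_db(
            path, dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        genes = []
        for feat in db.features_of_type("gene"):
            exons = [
                (child.start - 1, child.end)
                for child in db.children(feat, featuretype="exon")
            ]
            bt = feat.attributes.get("biotype") or feat.attributes.get("gene_biotype")
            biotype = bt[0] if bt else None
            adjusted = feat.attributes.get("border_adjusted", ["false"])[0] == "true"
            genes.append(
                GeneModel(
                    gene_id=feat.id,
                    chrom=feat.seqid,
                    strand=feat.strand,
                    start=feat.start - 1,
                    end=feat.end,
                    exons=exons or [(feat.start - 1, feat.end)],
                    biotype=biotype,
                    adjusted=adjusted,
                )
            )
        if chrom_sizes is None:
            if not sizes:
                sizes = {}
                for g in genes:
                    sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.end)
            chrom_sizes = sizes
        return cls(genes, chrom_sizes)
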