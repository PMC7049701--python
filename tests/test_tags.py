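import itertools

import numpy as np
import pandas as pd
import pytest

from netseqtools.core import AnnotationSet, GeneModel
from netseqtools import tags as tag_ops

from conftest import make_tagset


def _write_bam(path, chrom_sizes, reads):
    """reads: (chrom, start, end, reverse, mapq, cigar_or_None, unmapped)."""
    import pysam

    chroms = sorted(chrom_sizes)
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": c, "LN": chrom_sizes[c]} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for i, (chrom, start, end, reverse, mapq, cigar, unmapped) in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = f"r{i}"
            if unmapped:
                a.flag = 4
                a.query_sequence = "N" * 10
                bam.write(a)
                continue
            a.reference_id = tid[chrom]
            a.reference_start = start
            a.mapping_quality = mapq
            span = end - start
            a.cigarstring = cigar or f"{span}M"
            qlen = sum(
                n for op, n in a.cigartuples if op in (0, 1, 4)
            )
            a.query_sequence = "N" * qlen
            a.flag = 16 if reverse else 0
            bam.write(a)
    return path


class TestExtractTags:
    def test_flip_places_tag_at_flipped_three_prime_end(self, tmp_path):
        # read aligned on + strand over [100, 150); after the flip the
        # tag strand is '-' and its 3' end is the leftmost base, 100
        bam = _write_bam(
            str(tmp_path / "a.bam"), {"chr1": 1000},
            [("chr1", 100, 150, False, 30, None, False)],
        )
        tags, skipped = tag_ops.extract_tags(bam, flip_strand=True)
        assert skipped == 0
        row = tags.df.iloc[0]
        assert (row.chrom, row.position, row.strand, row.mapq) == ("chr1", 100, "-", 30)

    def test_no_flip_keeps_aligned_orientation(self, tmp_path):
        bam = _write_bam(
            str(tmp_path / "a.bam"), {"chr1": 1000},
            [("chr1", 100, 150, False, 30, None, False)],
        )
        tags, _ = tag_ops.extract_tags(bam, flip_strand=False)
        row = tags.df.iloc[0]
        assert (row.position, row.strand) == (149, "+")

    def test_unmapped_skipped_and_split_flagged(self, tmp_path):
        bam = _write_bam(
            str(tmp_path / "a.bam"), {"chr1": 1000},
            [
                ("chr1", 0, 0, False, 0, None, True),
                ("chr1", 10, 80, False, 30, "20M30N20M", False),
            ],
        )
        tags, skipped = tag_ops.extract_tags(bam)
        assert skipped == 1
        assert len(tags) == 1
        assert bool(tags.df.iloc[0].is_split)

    def test_empty_bam(self, tmp_path):
        bam = _write_bam(str(tmp_path / "a.bam"), {"chr1": 1000}, [])
        tags, skipped = tag_ops.extract_tags(bam)
        assert len(tags) == 0 and skipped == 0


@pytest.fixture
def structural_annotation():
    genes = [
        GeneModel("trna1", "chr1", "+", 1000, 1100, biotype="tRNA"),
        GeneModel("pc1", "chr1", "+", 3000, 4000, biotype="protein_coding"),
    ]
    return AnnotationSet(genes, {"chr1": 10_000})


class TestFilters:
    def test_structural_rna_either_strand_inclusive_distance(self, structural_annotation):
        tags = make_tagset(
            [
                ("chr1", 950, "-"),   # 50 bp gap, opposite strand -> removed
                ("chr1", 900, "+"),   # exactly 100 bp away -> removed
                ("chr1", 899, "+"),   # 101 bp away -> kept
                ("chr1", 3500, "+"),  # inside a coding gene -> kept
            ],
            {"chr1": 10_000},
        )
        kept, removed = tag_ops.filter_structural_rna(tags, structural_annotation)
        assert removed == 2
        assert sorted(kept.df["position"]) == [899, 3500]

    def test_structural_identity_without_structural_genes(self, toy_annotation):
        tags = make_tagset([("chr1", 1500, "+")], {"chr1": 6000})
        kept, removed = tag_ops.filter_structural_rna(tags, toy_annotation)
        assert removed == 0 and len(kept) == 1

    def test_missing_biotype_raises(self):
        g = GeneModel("x", "chr1", "+", 0, 100, biotype=None)
        ann = AnnotationSet([g], {"chr1": 1000})
        tags = make_tagset([("chr1", 50, "+")], {"chr1": 1000})
        with pytest.raises(ValueError, match="biotype"):
            tag_ops.filter_structural_rna(tags, ann)

    def test_mapq_boundary(self):
        tags = make_tagset(
            [("chr1", 1, "+", 9), ("chr1", 2, "+", 10)], {"chr1": 100}
        )
        kept, removed = tag_ops.filter_mapq(tags, min_mapq=10)
        assert removed == 1
        assert kept.df.iloc[0].mapq == 10
        ident, r0 = tag_ops.filter_mapq(tags, min_mapq=0)
        assert r0 == 0 and len(ident) == 2

    def test_mapq_all_removed_warns(self):
        tags = make_tagset([("chr1", 1, "+", 3)], {"chr1": 100})
        with pytest.warns(UserWarning, match="MAPQ"):
            kept, removed = tag_ops.filter_mapq(tags)
        assert len(kept) == 0 and removed == 1

    def test_splice_intermediates_strand_aware(self, toy_annotation):
        from netseqtools.annotation import splice_site_union

        sites = splice_site_union(toy_annotation)
        tags = make_tagset(
            [
                ("chr1", 1399, "+"),  # donor, same strand -> removed
                ("chr1", 1399, "-"),  # same base, opposite strand -> kept
                ("chr1", 1200, "+"),  # mid-exon -> kept
            ],
            {"chr1": 6000},
        )
        kept, removed = tag_ops.filter_splice_intermediates(tags, sites)
        assert removed == 1
        assert set(kept.df["strand"]) == {"-", "+"}
        assert 1399 not in kept.df[kept.df.strand == "+"]["position"].values

    def test_empty_splice_set_is_identity_with_warning(self):
        tags = make_tagset([("chr1", 1, "+")], {"chr1": 100})
        with pytest.warns(UserWarning, match="splice"):
            kept, removed = tag_ops.filter_splice_intermediates(tags, set())
        assert removed == 0 and len(kept) == 1

    def test_remove_split_reads(self):
        tags = make_tagset(
            [("chr1", 1, "+", 30, True), ("chr1", 2, "+", 30, False)], {"chr1": 100}
        )
        kept, removed = tag_ops.remove_split_reads(tags)
        assert removed == 1
        assert not kept.df.iloc[0].is_split

    def test_filters_commute_and_conserve(self, structural_annotation, rng):
        """Structural/MAPQ/split filters have set-intersection semantics:
        any application order yields the same kept set, and
        kept + removed = input for every filter."""
        n = 300
        tags = make_tagset(
            [
                (
                    "chr1",
                    int(rng.integers(0, 10_000)),
                    rng.choice(["+", "-"]),
                    int(rng.integers(0, 40)),
                    bool(rng.random() < 0.2),
                )
                for _ in range(n)
            ],
            {"chr1": 10_000},
        )
        filters = {
            "structural": lambda t: tag_ops.filter_structural_rna(t, structural_annotation),
            "mapq": lambda t: tag_ops.filter_mapq(t, 10),
            "split": tag_ops.remove_split_reads,
        }
        results = []
        for order in itertools.permutations(filters):
            current = tags
            for name in order:
                nxt, removed = filters[name](current)
                assert len(nxt) + removed == len(current)
                current = nxt
            results.append(
                current.sort().df.reset_index(drop=True)[
                    ["chrom", "position", "strand", "mapq", "is_split"]
                ]
            )
        for other in results[1:]:
            assert results[0].equals(other)


class TestTracksAndMetrics:
    def test_build_track_counts(self):
        tags = make_tagset(
            [("chr1", 7, "+")] * 3 + [("chr1", 7, "-")], {"chr1": 20}
        )
        track = tag_ops.build_track(tags)
        assert track.get("chr1", "+")[7] == 3
        assert track.get("chr1", "-")[7] == 1
        empty = tag_ops.build_track(make_tagset([], {"chr1": 20}))
        assert empty.total() == 0

    def test_normalize_track_factor(self, toy_annotation):
        # 2000 tags inside coding genes -> factor 1e6/2000 = 500
        tags = make_tagset([("chr1", 1100, "+")] * 2000, {"chr1": 6000})
        track = tag_ops.build_track(tags)
        norm = tag_ops.normalize_track(track, toy_annotation, exclude_chroms=())
        assert norm.normalization_factor == pytest.approx(500.0)
        assert norm.get("chr1", "+")[1100] == pytest.approx(2000 * 500.0)

    def test_normalize_requires_coding_tags(self, toy_annotation):
        tags = make_tagset([("chr1", 10, "+")], {"chr1": 6000})  # intergenic only
        with pytest.raises(ValueError, match="protein-coding"):
            tag_ops.normalize_track(tag_ops.build_track(tags), toy_annotation)

    def test_track_correlation_extremes(self, rng):
        from netseqtools.core import StrandedTrack

        a = StrandedTrack({"chr1": 1000})
        for strand in "+-":
            a.get("chr1", strand)[:] = rng.poisson(2.0, 1000)
        assert tag_ops.track_correlation(a, a, bin_bp=50) == pytest.approx(1.0)
        b = a.copy()
        top = max(a.get("chr1", s).max() for s in "+-")
        for strand in "+-":
            arr = b.get("chr1", strand)
            arr[:] = top - arr  # anti-correlated complement
        r = tag_ops.track_correlation(a, b, bin_bp=1)
        assert r == pytest.approx(-1.0)

    def test_track_correlation_independent_poisson_near_zero(self, rng):
        from netseqtools.core import StrandedTrack

        a = StrandedTrack({"chr1": 50_000})
        b = StrandedTrack({"chr1": 50_000})
        for t in (a, b):
            for strand in "+-":
                t.get("chr1", strand)[:] = rng.poisson(1.0, 50_000)
        r = tag_ops.track_correlation(a, b, bin_bp=100)
        assert abs(r) < 0.1

    def test_track_correlation_zero_variance_nan(self):
        from netseqtools.core import StrandedTrack

        a = StrandedTrack({"chr1": 100})
        with pytest.warns(UserWarning, match="zero-variance"):
            assert np.isnan(tag_ops.track_correlation(a, a, bin_bp=10))

    def test_splice_fraction_extremes(self, toy_annotation):
        from netseqtools.annotation import donor_site_set

        donors = donor_site_set(toy_annotation)
        none = make_tagset([("chr1", 1200, "+")], {"chr1": 6000})
        assert tag_ops.splice_intermediate_fraction(none, donors) == 0.0
        all_donor = make_tagset([("chr1", 1399, "+")] * 5, {"chr1": 6000})
        assert tag_ops.splice_intermediate_fraction(all_donor, donors) == 100.0

    def test_exon_intron_ratio_uniform(self, toy_annotation):
        # uniform 1 tag/bp over gplus: exons 800 bp, intron 200 bp -> 4.0
        rows = [("chr1", p, "+") for p in range(1000, 2000)]
        tags = make_tagset(rows, {"chr1": 6000})
        assert tag_ops.exon_intron_ratio(tags, toy_annotation) == pytest.approx(4.0)

    def test_exon_intron_ratio_intronless_undefined(self):
        ann = AnnotationSet(
            [GeneModel("g", "chr1", "+", 0, 100)], {"chr1": 200}
        )
        tags = make_tagset([("chr1", 10, "+")], {"chr1": 200})
        with pytest.warns(UserWarning, match="intronic"):
            assert np.isnan(tag_ops.exon_intron_ratio(tags, ann))

    def test_count_matrix(self, tmp_path):
        features = pd.DataFrame(
            {
                "feature_id": ["a", "b", "c"],
                "chrom": ["chr1"] * 3,
                "start": [0, 50, 40],
                "end": [100, 150, 120],
                "strand": ["+", "+", "-"],
            }
        )
        tags = make_tagset([("chr1", 60, "+")] * 7, {"chr1": 200})
        out = tag_ops.count_matrix({"s1": tags}, features, str(tmp_path / "m.tsv"))
        assert out.loc["a", "s1"] == 7  # inside both a and b independently
        assert out.loc["b", "s1"] == 7
        assert out.loc["c", "s1"] == 0  # opposite strand
        back = pd.read_csv(tmp_path / "m.tsv", sep="\t", index_col=0)
        assert back.loc["a", "s1"] == 7

    def test_count_matrix_duplicate_ids_rejected(self):
        features = pd.DataFrame(
            {
                "feature_id": ["a", "a"],
                "chrom": ["chr1", "chr1"],
                "start": [0, 10],
                "end": [5, 20],
                "strand": ["+", "+"],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            tag_ops.count_matrix({}, features)

    def test_splice_fraction_recovers_planted(self, small_sim, small_annotation):
        from netseqtools.annotation import donor_site_set
        from scipy import stats

        tags, truth = small_sim
        frac = tag_ops.splice_intermediate_fraction(
            tags, donor_site_set(small_annotation)
        )
        # measured donor fraction equals the bookkept planted fraction
        assert frac == pytest.approx(100 * truth.totals["splice_fraction_planted"])
        # and recovers the configured fraction of gene tags within binomial CI
        n = truth.totals["gene_tags"]
        lo, hi = stats.binom.interval(0.99, n, 0.05)
        assert lo / n <= truth.totals["splice_fraction_of_gene_tags"] <= hi / n

    def test_index_metrics_invariant_to_normalization(self, small_sim, small_annotation):
        """SI/ISI and exon/intron ratios are density ratios of one track,
        hence unchanged by the library-size normalization."""
        from netseqtools import stalling

        tags, _ = small_sim
        raw = tag_ops.build_track(tags)
        norm = tag_ops.normalize_track(raw, small_annotation, exclude_chroms=())
        for g in list(small_annotation)[:3]:
            r1 = stalling.promoter_stalling_index(raw, g)
            r2 = stalling.promoter_stalling_index(norm, g)
            if r1 is not None:
                assert r2.index == pytest.approx(r1.index)
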