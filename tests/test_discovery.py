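import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netseqtools.core import AnnotationSet, GeneModel
from netseqtools import discovery as d

from conftest import make_tagset


def path_logprob(counts, path, params):
    loge = d._emission_loglik(np.asarray(counts), params)
    with np.errstate(divide="ignore"):
        logA = np.log(params.transition)
        logpi = np.log(params.startprob)
    lp = logpi[path[0]] + loge[0, path[0]]
    for t in range(1, len(counts)):
        lp += logA[path[t - 1], path[t]] + loge[t, path[t]]
    return float(lp)


def brute_force_best(counts, params):
    """Independent oracle: exhaustive maximization over all 2^n paths."""
    return max(
        path_logprob(counts, path, params)
        for path in itertools.product((0, 1), repeat=len(counts))
    )


def random_params(rng):
    return d.HMMParams(
        np.vstack([rng.dirichlet([5, 1]), rng.dirichlet([1, 5])]),
        np.sort(rng.uniform(0.3, 12.0, 2)),
        np.array([np.inf, float(rng.uniform(0.5, 50))]),
        rng.dirichlet([1, 1]),
    )


class TestBinning:
    def test_counts_partition_tags(self):
        tags = make_tagset([("chr1", p, "+") for p in (0, 24, 25, 99)], {"chr1": 100})
        counts = d.bin_counts(tags, 25, "chr1", "+")
        assert counts.tolist() == [2, 1, 0, 1]
        assert counts.sum() == 4

    def test_empty_bins(self):
        tags = make_tagset([], {"chr1": 100})
        assert d.bin_counts(tags, 10, "chr1", "+").sum() == 0

    def test_boundary_tag_in_half_open_bin(self):
        tags = make_tagset([("chr1", 50, "+")], {"chr1": 100})
        counts = d.bin_counts(tags, 50, "chr1", "+")
        assert counts.tolist() == [0, 1]


class TestViterbi:
    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 12))
    def test_matches_exhaustive_path_maximum(self, seed, length):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(rng.uniform(0.5, 8.0), size=length)
        params = random_params(rng)
        path = d.viterbi_path(counts, params)
        assert path_logprob(counts, path, params) == pytest.approx(
            brute_force_best(counts, params), abs=1e-9
        )

    def test_all_zero_counts_yield_no_segments(self):
        params = d.HMMParams(
            np.array([[0.9, 0.1], [0.1, 0.9]]),
            np.array([0.1, 10.0]),
            np.array([np.inf, np.inf]),
        )
        assert d.viterbi_segments(np.zeros(40, dtype=int), params) == []

    def test_single_block_single_segment(self):
        params = d.HMMParams(
            np.array([[0.95, 0.05], [0.05, 0.95]]),
            np.array([0.1, 10.0]),
            np.array([np.inf, np.inf]),
            bin_bp=25,
        )
        counts = np.zeros(30, dtype=int)
        counts[10:20] = 12
        segs = d.viterbi_segments(counts, params, "chr1", "+")
        assert segs == [("chr1", 250, 500, "+")]


class TestFitHMM:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(5)
        true_trans = np.array([[0.97, 0.03], [0.05, 0.95]])
        states = [0]
        for _ in range(4000):
            states.append(rng.choice(2, p=true_trans[states[-1]]))
        states = np.array(states)
        counts = np.where(
            states == 0,
            rng.poisson(0.5, len(states)),
            rng.negative_binomial(5, 5 / 13, len(states)),  # mean 8, size 5
        )
        fit, trace = d.fit_hmm(counts, d.init_params(counts), max_iter=50, tol=1e-5)
        assert abs(fit.means[0] - 0.5) / 0.5 < 0.10
        assert abs(fit.means[1] - 8.0) / 8.0 < 0.10
        assert np.abs(fit.transition - true_trans).max() < 0.05

    @pytest.mark.parametrize("seed", range(4))
    def test_loglik_monotone_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(rng.uniform(0.5, 6.0, size=300))
        _, trace = d.fit_hmm(counts, d.init_params(counts), max_iter=25, tol=0.0)
        diffs = np.diff(trace)
        assert (diffs > -1e-8).all()

    def test_init_near_fixed_point_moves_little(self):
        rng = np.random.default_rng(9)
        params = d.HMMParams(
            np.array([[0.95, 0.05], [0.05, 0.95]]),
            np.array([0.5, 8.0]),
            np.array([np.inf, np.inf]),
        )
        states = [0]
        for _ in range(2000):
            states.append(rng.choice(2, p=params.transition[states[-1]]))
        counts = rng.poisson(params.means[np.array(states)])
        _, trace = d.fit_hmm(counts, params, max_iter=10, tol=0.0)
        assert (np.diff(trace) > -1e-8).all()

    def test_infinite_tol_returns_init(self):
        init = d.HMMParams(
            np.array([[0.9, 0.1], [0.1, 0.9]]),
            np.array([1.0, 5.0]),
            np.array([np.inf, np.inf]),
        )
        out, trace = d.fit_hmm(np.array([1, 5, 1, 5]), init, tol=np.inf)
        assert trace == []
        np.testing.assert_array_equal(out.means, init.means)

    def test_degenerate_input_rejected(self):
        init = d.HMMParams(
            np.array([[0.9, 0.1], [0.1, 0.9]]),
            np.array([1.0, 5.0]),
            np.array([np.inf, np.inf]),
        )
        with pytest.raises(ValueError, match="degenerate"):
            d.fit_hmm(np.full(50, 3), init)


class TestNovelty:
    def test_reciprocal_rule(self):
        known = [("chr1", 0, 100, "+")]
        # 60% overlap both ways -> not novel
        assert d.identify_novel([("chr1", 40, 140, "+")], known) == []
        # zero overlap -> novel
        assert d.identify_novel([("chr1", 200, 300, "+")], known) == [
            ("chr1", 200, 300, "+")
        ]
        # asymmetric 60/40: called 100 bp with 60 in a 150 bp unit
        known2 = [("chr1", 0, 150, "+")]
        called = [("chr1", 90, 190, "+")]
        assert d.identify_novel(called, known2) == called

    def test_opposite_strand_is_always_novel(self):
        known = [("chr1", 0, 100, "+")]
        assert d.identify_novel([("chr1", 0, 100, "-")], known) == [
            ("chr1", 0, 100, "-")
        ]

    def test_brute_force_pairs(self, rng):
        """Rule agrees with explicit min-overlap-fraction computation."""
        for _ in range(100):
            s1, s2 = rng.integers(0, 500, 2)
            l1, l2 = rng.integers(20, 300, 2)
            called = [("chr1", int(s1), int(s1 + l1), "+")]
            known = [("chr1", int(s2), int(s2 + l2), "+")]
            ov = max(0, min(s1 + l1, s2 + l2) - max(s1, s2))
            novel_expected = min(ov / l1, ov / l2) < 0.5
            assert (d.identify_novel(called, known) == called) == novel_expected


class TestMerging:
    def test_overlapping_calls_merge_to_union(self):
        merged = d.merge_across_samples(
            {"a": [("chr1", 0, 100, "+")], "b": [("chr1", 50, 150, "+")]}
        )
        assert len(merged) == 1
        assert merged[0].interval == ("chr1", 0, 150, "+")
        assert merged[0].samples == ("a", "b")

    def test_disjoint_and_strand_separated(self):
        merged = d.merge_across_samples(
            {"a": [("chr1", 0, 100, "+"), ("chr1", 0, 100, "-")]}
        )
        assert len(merged) == 2

    def test_transitive_chain(self):
        merged = d.merge_across_samples(
            {
                "a": [("chr1", 0, 100, "+"), ("chr1", 180, 300, "+")],
                "b": [("chr1", 90, 200, "+")],
            }
        )
        assert len(merged) == 1
        assert merged[0].interval == ("chr1", 0, 300, "+")


@pytest.fixture
def host_genes():
    # plus-strand host [10000, 14000), L = 4000
    genes = [GeneModel("host", "chr1", "+", 10_000, 14_000)]
    return AnnotationSet(genes, {"chr1": 40_000})


class TestClassification:
    @pytest.mark.parametrize(
        "interval,strand,expected",
        [
            # antisense unit initiating 300 bp upstream of the TSS
            ((9200, 9701), "-", "divergent"),
            # sense unit starting upstream, overlapping the host
            ((9700, 10_500), "+", "upstream"),
            # antisense initiating at 30% of host length
            ((10_800, 11_201), "-", "convergent"),
            # antisense initiating in the 3' half
            ((12_500, 13_001), "-", "pas_antisense"),
            # antisense initiating 10% of host length past the PAS
            ((13_500, 14_401), "-", "pas_antisense"),
            # sense unit starting inside, running past the PAS
            ((13_000, 14_500), "+", "downstream"),
            # antisense initiating 30% past the PAS but overlapping
            ((13_500, 15_201), "-", "distal_antisense"),
            # far away from everything
            ((30_000, 30_500), "+", "intergenic"),
        ],
    )
    def test_rule_examples(self, host_genes, interval, strand, expected):
        start, end = interval
        out = d.classify_novel([("chr1", start, end, strand)], host_genes)
        assert len(out) == 1
        assert out[0].transcript_class == expected
        if expected != "intergenic":
            assert out[0].host_gene == "host"

    def test_total_and_deterministic(self, host_genes, rng):
        novel = []
        for _ in range(200):
            s = int(rng.integers(0, 39_000))
            e = s + int(rng.integers(50, 1000))
            novel.append(("chr1", s, min(e, 40_000), str(rng.choice(["+", "-"]))))
        out1 = d.classify_novel(novel, host_genes)
        out2 = d.classify_novel(novel, host_genes)
        assert all(t.transcript_class in d.CLASS_ORDER for t in out1)
        assert [t.transcript_class for t in out1] == [
            t.transcript_class for t in out2
        ]

    def test_simulator_confusion_matrix_is_diagonal(self):
        from netseqtools import SimulationConfig, make_annotation, simulate_tags

        cfg = SimulationConfig(n_genes=80, seed=21)
        ann = make_annotation(cfg)
        _, truth = simulate_tags(ann, cfg)
        units = [
            (r.chrom, r.start, r.end, r.strand)
            for r in truth.antisense.itertuples(index=False)
        ]
        assert len(units) > 50
        classified = d.classify_novel(units, ann)
        for t, row in zip(classified, truth.antisense.itertuples(index=False)):
            assert t.transcript_class == row.unit_class

    def test_offset_table(self, host_genes):
        out = d.classify_novel([("chr1", 9200, 9701, "-")], host_genes)
        table = d.initiation_offset_table(out, host_genes)
        assert table.iloc[0]["offset_bp"] == 300
        assert table.iloc[0]["transcript_class"] == "divergent"


class TestEndToEndCalling:
    def test_noiseless_segment_recovery_within_one_bin(self):
        """With high rate, zero background and no extra features, called
        segment borders sit within one bin of the planted gene borders."""
        from netseqtools import SimulationConfig, make_annotation, simulate_tags

        cfg = SimulationConfig(
            n_genes=6,
            seed=17,
            gene_body_rate=2.0,
            intergenic_rate=0.0,
            body_dispersion_shape=np.inf,
            splice_intermediate_fraction=0.0,
        )
        cfg.rt_profile.rt_length_bp = 0
        for spec in cfg.antisense_spec.values():
            spec.probability = 0.0
        ann = make_annotation(cfg)
        tags, _ = simulate_tags(ann, cfg)
        called = d.call_transcripts(tags, bin_bp=25)
        genes = sorted(ann, key=lambda g: g.start)
        by_strand = {
            s: sorted(iv for iv in called if iv[3] == s) for s in "+-"
        }
        for g in genes:
            matches = [
                iv
                for iv in by_strand[g.strand]
                if abs(iv[1] - g.start) <= 25 and abs(iv[2] - g.end) <= 25
            ]
            assert matches, f"no segment recovered for {g.gene_id}"
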