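"""De novo transcript discovery and classification.

Transcribed intervals are called per strand with a two-state hidden
Markov model over binned tag counts (untranscribed vs transcribed,
negative-binomial emissions with a Poisson limit), fitted by Baum-Welch
EM in log space and decoded with Viterbi.  Calls with <50% reciprocal
overlap against every same-strand known transcription unit are novel;
novel calls are merged across samples and classified into seven classes
by the position of their initiation point (their own 5'-most base)
relative to the nearest qualifying host gene:

divergent        antisense, initiates <=500 bp upstream of a host TSS
upstream         sense, initiates upstream and partially overlaps the host
convergent       antisense, initiates within the 5' half of the host body
pas_antisense    antisense, initiates in the 3' half or <=20% of the host
                 length past the PAS
downstream       sense, initiates inside the host and runs past its PAS
distal_antisense antisense overlap, initiates >20% of the host length
                 past the PAS
intergenic       none of the above

The rules are evaluated in that order; an initiation point exactly on a
rule boundary goes to the earlier class.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core import STRANDS, AnnotationSet, GeneModel, StrandedTrack, TagSet

CLASS_ORDER = (
    "divergent",
    "upstream",
    "convergent",
    "pas_antisense",
    "downstream",
    "distal_antisense",
    "intergenic",
)

Interval = tuple[str, int, int, str]


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def bin_counts(
    tags: TagSet, bin_bp: int, chrom: str, strand: str
) -> np.ndarray:
    """Integer tag counts per half-open bin of ``bin_bp`` bases."""
    if bin_bp < 1:
        raise ValueError("bin_bp must be >= 1")
    size = tags.chrom_sizes[chrom]
    n_bins = -(-size // bin_bp)
    sel = (tags.df["chrom"] == chrom) & (tags.df["strand"] == strand)
    pos = tags.df.loc[sel, "position"].to_numpy()
    counts = np.bincount(pos // bin_bp, minlength=n_bins)
    return counts.astype(np.int64)


def bin_track(track: StrandedTrack, bin_bp: int, chrom: str, strand: str) -> np.ndarray:
    size = track.chrom_sizes[chrom]
    edges = np.arange(0, size, bin_bp)
    return np.add.reduceat(track.get(chrom, strand), edges).astype(np.int64)


# ---------------------------------------------------------------------------
# Two-state negative-binomial HMM
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HMMParams:
    """Two-state HMM over binned counts.

    State 0 is untranscribed, state 1 transcribed.  Emissions are
    negative binomial with per-state mean and dispersion ``r`` (the NB
    size; ``r = inf`` is the Poisson limit).
    """

    transition: np.ndarray  # 2x2, rows sum to 1
    means: np.ndarray  # per-state emission mean
    dispersions: np.ndarray  # per-state NB size r (inf = Poisson)
    startprob: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([0.5, 0.5])
    )
    bin_bp: int = 25

    def __post_init__(self):
        self.transition = np.asarray(self.transition, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.dispersions = np.asarray(self.dispersions, dtype=float)
        self.startprob = np.asarray(self.startprob, dtype=float)
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
        if not self.means[1] > self.means[0]:
            raise ValueError("transcribed-state mean must exceed untranscribed mean")

    def copy(self) -> "HMMParams":
        return HMMParams(
            self.transition.copy(),
            self.means.copy(),
            self.dispersions.copy(),
            self.startprob.copy(),
            self.bin_bp,
        )


def _nb_logpmf(counts: np.ndarray, mean: float, r: float) -> np.ndarray:
    mean = max(mean, 1e-10)
    if np.isinf(r):
        return stats.poisson.logpmf(counts, mean)
    p = r / (r + mean)
    return stats.nbinom.logpmf(counts, r, p)


def _emission_loglik(counts: np.ndarray, params: HMMParams) -> np.ndarray:
    return np.column_stack(
        [_nb_logpmf(counts, params.means[k], params.dispersions[k]) for k in (0, 1)]
    )


def _forward_backward(loge: np.ndarray, params: HMMParams):
    T = loge.shape[0]
    with np.errstate(divide="ignore"):
        logA = np.log(params.transition)
        logpi = np.log(params.startprob)
    la = np.zeros((T, 2))
    la[0] = logpi + loge[0]
    for t in range(1, T):
        la[t] = special.logsumexp(la[t - 1][:, None] + logA, axis=0) + loge[t]
    ll = float(special.logsumexp(la[-1]))
    lb = np.zeros((T, 2))
    for t in range(T - 2, -1, -1):
        lb[t] = special.logsumexp(logA + (loge[t + 1] + lb[t + 1])[None, :], axis=1)
    gamma = np.exp(la + lb - ll)
    # expected transition counts
    xi = np.zeros((2, 2))
    for t in range(T - 1):
        m = la[t][:, None] + logA + (loge[t + 1] + lb[t + 1])[None, :] - ll
        xi += np.exp(m)
    return ll, gamma, xi


def _weighted_nb_negll(counts, weights, mean, r):
    return -float(np.sum(weights * _nb_logpmf(counts, mean, r)))


def _fit_state_emission(counts, weights, old_mean, old_r, allow_nb=True):
    """Guarded weighted NB fit: returns params at least as good as the old
    ones under the expected complete-data emission log-likelihood.

    With ``allow_nb=False`` the state stays Poisson (used for the
    untranscribed state, whose background is Poisson by model; a free
    dispersion there can acquire a heavy tail that swallows signal peaks).
    """
    wsum = weights.sum()
    if wsum <= 0:
        return old_mean, old_r
    mean = float(np.sum(weights * counts) / wsum)
    if mean <= 0:
        mean = 1e-10
    var = float(np.sum(weights * (counts - mean) ** 2) / wsum)
    candidates = [(mean, np.inf)]
    if allow_nb and var > mean > 0:
        r0 = mean**2 / (var - mean)
        res = optimize.minimize_scalar(
            lambda logr: _weighted_nb_negll(counts, weights, mean, np.exp(logr)),
            bracket=None,
            bounds=(np.log(1e-3), np.log(1e6)),
            method="bounded",
        )
        candidates.append((mean, float(np.exp(res.x))))
        candidates.append((mean, max(1e-3, r0)))
    best = min(
        candidates + [(old_mean, old_r)],
        key=lambda mr: _weighted_nb_negll(counts, weights, mr[0], mr[1]),
    )
    return best


def fit_hmm(
    counts: np.ndarray,
    init: HMMParams,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> tuple[HMMParams, list[float]]:
    """Baum-Welch EM in log space; returns fitted params and the
    log-likelihood trace (non-decreasing by construction).

    The M-step is guarded (generalized EM): each emission update is kept
    only if it improves the expected complete-data log-likelihood, so
    the trace never decreases.  ``tol=inf`` returns the init untouched.
    """
    counts = np.asarray(counts)
    if len(np.unique(counts)) < 2:
        raise ValueError(
            "degenerate input: all bin counts identical; the two emission "
            "states cannot be separated (increase rate separation)"
        )
    params = init.copy()
    ll_trace: list[float] = []
    if not np.isfinite(tol) or max_iter == 0:
        return params, ll_trace
    prev_ll = None
    for _ in range(max_iter):
        loge = _emission_loglik(counts, params)
        ll, gamma, xi = _forward_backward(loge, params)
        ll_trace.append(ll)
        if prev_ll is not None and abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
        # M-step
        trans = xi / np.maximum(xi.sum(axis=1, keepdims=True), 1e-300)
        startprob = gamma[0] / gamma[0].sum()
        new_means = params.means.copy()
        new_disp = params.dispersions.copy()
        for k in (0, 1):
            m, r = _fit_state_emission(
                counts, gamma[:, k], params.means[k], params.dispersions[k],
                allow_nb=(k == 1),
            )
            new_means[k], new_disp[k] = m, r
        if new_means[1] <= new_means[0]:  # keep state identities fixed
            new_means, new_disp = params.means, params.dispersions
        params = HMMParams(trans, new_means, new_disp, startprob, params.bin_bp)
    return params, ll_trace


def viterbi_path(counts: np.ndarray, params: HMMParams) -> np.ndarray:
    """Most probable state path; ties break toward the untranscribed state."""
    loge = _emission_loglik(np.asarray(counts), params)
    T = loge.shape[0]
    with np.errstate(divide="ignore"):
        logA = np.log(params.transition)
        logpi = np.log(params.startprob)
    delta = np.zeros((T, 2))
    psi = np.zeros((T, 2), dtype=int)
    delta[0] = logpi + loge[0]
    for t in range(1, T):
        scores = delta[t - 1][:, None] + logA
        psi[t] = np.argmax(scores, axis=0)  # first index (state 0) wins ties
        delta[t] = scores[psi[t], (0, 1)] + loge[t]
    path = np.zeros(T, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def viterbi_segments(
    counts: np.ndarray, params: HMMParams, chrom: str = "chr", strand: str = "+"
) -> list[Interval]:
    """Maximal runs of transcribed-state bins as bp intervals."""
    path = viterbi_path(counts, params)
    segments = []
    in_seg = False
    start = 0
    for i, s in enumerate(path):
        if s == 1 and not in_seg:
            in_seg, start = True, i
        elif s == 0 and in_seg:
            segments.append((chrom, start * params.bin_bp, i * params.bin_bp, strand))
            in_seg = False
    if in_seg:
        segments.append(
            (chrom, start * params.bin_bp, len(path) * params.bin_bp, strand)
        )
    return segments


def init_params(counts: np.ndarray, bin_bp: int = 25) -> HMMParams:
    """Deterministic initialisation by a 1-D two-means split of the counts."""
    counts = np.asarray(counts, dtype=float)
    if len(np.unique(counts)) < 2:
        raise ValueError("degenerate input: all bin counts identical")
    c0, c1 = float(counts.min()), float(counts.max())
    for _ in range(50):
        assign = np.abs(counts - c0) <= np.abs(counts - c1)
        n0, n1 = float(assign.sum()), float((~assign).sum())
        if n0 == 0 or n1 == 0:
            break
        nc0, nc1 = counts[assign].mean(), counts[~assign].mean()
        if nc0 == c0 and nc1 == c1:
            break
        c0, c1 = nc0, nc1
    lo, hi = sorted((c0, c1))
    if hi <= lo:
        hi = lo + 1.0
    return HMMParams(
        transition=np.array([[0.95, 0.05], [0.10, 0.90]]),
        means=np.array([max(lo, 1e-3), hi]),
        dispersions=np.array([np.inf, np.inf]),
        startprob=np.array([0.5, 0.5]),
        bin_bp=bin_bp,
    )


def call_transcripts(
    tags: TagSet,
    bin_bp: int = 25,
    max_iter: int = 30,
    tol: float = 1e-3,
) -> list[Interval]:
    """Fit and decode the HMM per chromosome and strand; returns called
    transcribed intervals in bp."""
    intervals: list[Interval] = []
    for chrom in sorted(tags.chrom_sizes):
        for strand in STRANDS:
            counts = bin_counts(tags, bin_bp, chrom, strand)
            if len(np.unique(counts)) < 2 or counts.sum() == 0:
                continue
            params = init_params(counts, bin_bp)
            params, _ = fit_hmm(counts, params, max_iter=max_iter, tol=tol)
            intervals.extend(viterbi_segments(counts, params, chrom, strand))
    return sorted(intervals)


# ---------------------------------------------------------------------------
# Novelty, merging, classification
# ---------------------------------------------------------------------------

def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def identify_novel(
    called: list[Interval],
    known: list[Interval],
    min_reciprocal: float = 0.5,
) -> list[Interval]:
    """Keep called intervals with <``min_reciprocal`` reciprocal overlap
    against every same-strand known transcription unit."""
    novel = []
    for c in called:
        chrom, start, end, strand = c
        is_novel = True
        for kchrom, kstart, kend, kstrand in known:
            if kchrom != chrom or kstrand != strand:
                continue
            if reciprocal_overlap((start, end), (kstart, kend)) >= min_reciprocal:
                is_novel = False
                break
        if is_novel:
            novel.append(c)
    return novel


def annotation_units(annotation: AnnotationSet) -> list[Interval]:
    return [(g.chrom, g.start, g.end, g.strand) for g in annotation]


@dataclasses.dataclass
class MergedInterval:
    chrom: str
    start: int
    end: int
    strand: str
    samples: tuple[str, ...]

    @property
    def interval(self) -> Interval:
        return (self.chrom, self.start, self.end, self.strand)


def merge_across_samples(
    novel_by_sample: dict[str, list[Interval]]
) -> list[MergedInterval]:
    """Union-merge same-strand overlapping calls across samples, keeping
    sample provenance (transitive closure of pairwise overlap)."""
    tagged = [
        (iv, sample)
        for sample, ivs in novel_by_sample.items()
        for iv in ivs
    ]
    tagged.sort(key=lambda t: (t[0][0], t[0][3], t[0][1], t[0][2]))
    merged: list[MergedInterval] = []
    cur = None
    cur_samples: set[str] = set()
    for (chrom, start, end, strand), sample in tagged:
        if (
            cur is not None
            and chrom == cur[0]
            and strand == cur[3]
            and start < cur[2]
        ):
            cur = (chrom, cur[1], max(cur[2], end), strand)
            cur_samples.add(sample)
        else:
            if cur is not None:
                merged.append(
                    MergedInterval(cur[0], cur[1], cur[2], cur[3], tuple(sorted(cur_samples)))
                )
            cur = (chrom, start, end, strand)
            cur_samples = {sample}
    if cur is not None:
        merged.append(
            MergedInterval(cur[0], cur[1], cur[2], cur[3], tuple(sorted(cur_samples)))
        )
    return merged


@dataclasses.dataclass
class NovelTranscript:
    chrom: str
    start: int
    end: int
    strand: str
    transcript_class: str
    host_gene: str | None
    init_position: int
    init_offset: float  # bp upstream (negative) for divergent/upstream,
    # else fraction of host length from the host TSS; 0 for intergenic
    samples: tuple[str, ...] = ()


def _init_point(start: int, end: int, strand: str) -> int:
    return start if strand == "+" else end - 1


def _overlaps(start, end, g: GeneModel) -> bool:
    return start < g.end and g.start < end


def classify_novel(
    novel: list[Interval] | list[MergedInterval],
    genes: AnnotationSet,
    divergent_window_bp: int = 500,
    pas_downstream_frac: float = 0.2,
) -> list[NovelTranscript]:
    """Assign exactly one of the seven classes to each novel transcript.

    Rules are evaluated in CLASS_ORDER; among several qualifying hosts
    the gene nearest the initiation point wins.
    """
    gene_list = list(genes)
    out = []
    for item in novel:
        if isinstance(item, MergedInterval):
            chrom, start, end, strand = item.interval
            samples = item.samples
        else:
            chrom, start, end, strand = item
            samples = ()
        p = _init_point(start, end, strand)
        assigned = None
        for cls in CLASS_ORDER[:-1]:
            hits = []
            for g in gene_list:
                if g.chrom != chrom:
                    continue
                anti = g.strand != strand
                d = g.offset_from_tss(p)
                L = g.length
                ok = False
                if cls == "divergent":
                    ok = anti and -divergent_window_bp <= d <= 0
                elif cls == "upstream":
                    ok = (not anti) and d < 0 and _overlaps(start, end, g)
                elif cls == "convergent":
                    ok = anti and 0 < d <= 0.5 * L
                elif cls == "pas_antisense":
                    ok = anti and 0.5 * L < d <= (1.0 + pas_downstream_frac) * L
                elif cls == "downstream":
                    past_pas = end > g.end if g.strand == "+" else start < g.start
                    ok = (not anti) and 0 <= d < L and past_pas
                elif cls == "distal_antisense":
                    ok = (
                        anti
                        and d > (1.0 + pas_downstream_frac) * L
                        and _overlaps(start, end, g)
                    )
                if ok:
                    dist = 0 if g.start <= p < g.end else min(
                        abs(p - g.start), abs(p - (g.end - 1))
                    )
                    hits.append((dist, g.gene_id, g, d, L))
            if hits:
                hits.sort(key=lambda h: (h[0], h[1]))
                _, _, g, d, L = hits[0]
                offset = float(d) if cls in ("divergent", "upstream") else d / L
                assigned = NovelTranscript(
                    chrom, start, end, strand, cls, g.gene_id, p, offset, samples
                )
                break
        if assigned is None:
            assigned = NovelTranscript(
                chrom, start, end, strand, "intergenic", None, p, 0.0, samples
            )
        out.append(assigned)
    return out


def initiation_offset_table(
    classified: list[NovelTranscript], genes: AnnotationSet
) -> pd.DataFrame:
    """Histogram-ready per-class initiation offsets.

    ``offset_bp`` is the absolute distance to the host TSS (divergent
    transcripts), ``offset_frac`` the fraction of host length from the
    host TSS, and ``offset_first_span_frac`` locates convergent
    initiation between the host's first and second 5' splice sites
    (NaN when the host has fewer than two introns).
    """
    rows = []
    for t in classified:
        if t.host_gene is None:
            continue
        g = genes[t.host_gene]
        d = g.offset_from_tss(t.init_position)
        row = {
            "transcript_class": t.transcript_class,
            "host_gene": t.host_gene,
            "offset_bp": abs(d),
            "offset_frac": d / g.length,
            "offset_first_span_frac": np.nan,
        }
        donors = g.donor_sites()
        if t.transcript_class == "convergent" and len(donors) >= 2:
            d1 = g.offset_from_tss(donors[0] if g.strand == "+" else donors[-1])
            d2 = g.offset_from_tss(donors[1] if g.strand == "+" else donors[-2])
            if d2 != d1:
                row["offset_first_span_frac"] = (d - d1) / (d2 - d1)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_class", "host_gene", "offset_bp", "offset_frac",
            "offset_first_span_frac",
        ],
    )


def novel_to_tsv(classified: list[NovelTranscript], path: str) -> None:
    pd.DataFrame([dataclasses.asdict(t) for t in classified]).to_csv(
        path, sep="\t", index=False
    )
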