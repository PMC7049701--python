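# Methods

`netseqtools` implements the downstream analysis of NET-seq-style
nascent transcription data: from filtered single-nucleotide RNAPII
position tags to coverage tracks, metagene profiles, de novo transcript
discovery, stalling indexes and read-through (RT) length estimation,
together with a synthetic-data generator that plants a fully known
ground truth for every stage.

## Coordinate and signal conventions

All coordinates are 0-based half-open internally; GFF3 (1-based closed)
and bedGraph/BED (0-based half-open) are converted at the I/O boundary.
A *tag* is the 3'-terminal base of the strand-flipped read: the last
base added by the polymerase and hence the genomic position of the
RNAPII active site. Tag strand is the strand of the original nascent
RNA. A `StrandedTrack` holds per-base float signal per chromosome and
strand; a raw track sums to the tag count.

Splice-site bases are defined strand-aware: the donor (5'SS) is the
last exonic base upstream of an intron in the direction of
transcription, the acceptor (3'SS) the first exonic base downstream.
The splice-intermediate filter removes tags sitting exactly on either
site on the matching strand (tolerance 0 bp); these are
spliceosome-protected 3' ends co-purified with RNAPII, not polymerase
positions.

## Tag filtering

Four filters with set-intersection semantics (they commute, and
kept + removed = input for each): (i) tags within 100 bp, gap-wise and
inclusive, of any rRNA/tRNA/snRNA/snoRNA gene on either strand;
(ii) MAPQ < 10; (iii) splice-site tags as above; (iv) split (gapped)
alignments, which are mature-RNA contaminants. Tracks are normalized to
one million tags in nuclear protein-coding gene bodies (organellar
chromosomes excludable by name); all density-ratio statistics below
are invariant to this scaling.

## Metagene profiles

Intervals are optionally trimmed (default 5 bp per side for exons and
introns, suppressing splice-site edge artifacts), excluded when they
overlap two or more annotated transcription units, then length-scaled
into `n` bins with boundaries at `round(i*L/n)`, or anchored on a fixed
position with symmetric flanks. Minus-strand rows are reversed so
bin 0 is 5'. The confidence band is the normal approximation
`mean ± z(level)·sd/√n`; no bootstrap is used. With fewer than two
rows the band is flagged undefined rather than fabricated.

## Transcript discovery

Per strand, tag counts in 25 bp bins feed a two-state HMM
(untranscribed / transcribed). Emissions: the transcribed state is
negative binomial (mean, size `r`; `r = ∞` is the Poisson limit), the
untranscribed state is constrained to Poisson. The constraint is
deliberate: background is Poisson by model (consistent with the RT
"random" model below), and a free dispersion on the background state
can fit a heavy tail that absorbs promoter-peak bins and splits gene
segments. Fitting is Baum-Welch EM in log space with a guarded
(generalized EM) M-step — an emission update is kept only when it
improves the expected complete-data log-likelihood — so the
log-likelihood trace is non-decreasing on every input. Initialisation
is a deterministic two-means split of the bin counts. Decoding is
Viterbi with ties broken toward the untranscribed state.

Called intervals with <50% reciprocal overlap (the minimum of the two
mutual overlap fractions) against every same-strand known transcription
unit are novel; novel calls are union-merged across samples (transitive
closure of same-strand overlap, sample provenance retained) and
classified by the position of their initiation point (their own
5'-most base) relative to the nearest qualifying host gene, evaluating
the rules in order and sending boundary cases to the earlier class:

1. **divergent** — antisense, initiates 0-500 bp upstream of a TSS;
2. **upstream** — sense, initiates upstream and partially overlaps;
3. **convergent** — antisense, initiates within the 5' half of the body;
4. **pas_antisense** — antisense, initiates in the 3' half or ≤20% of
   the gene length past the PAS;
5. **downstream** — sense, initiates inside and runs past the PAS;
6. **distal_antisense** — antisense overlap, initiates >20% past the PAS;
7. **intergenic** — none of the above.

## Stalling indexes

The promoter-proximal stalling index for genes longer than 1 kb scans
100 bp windows (1 bp steps, leftmost tie-break) over the
transcription-oriented interval [TSS-100, TSS+300]; the index is the
best window's density divided by the whole-gene density. The search
window may reach upstream of the gene; that coverage counts toward the
window but not the gene denominator (the literal reading of the
definition), and the gene denominator includes the promoter window. A
gene is *stalled* at index ≥ 3 among expressed genes (FPKM ≥ 1). The
intronic stalling index (ISI) does the same with 10 bp windows inside
each intron longer than 50 bp; introns with FPKM > 10 are classed
strong (ISI ≥ 5.5), medium (3.5 < ISI < 5.5) or weak (ISI ≤ 3.5). The
summit is the center of the best window; for introns its
transcription-oriented distance past the donor site is the peak offset,
whose mode across introns is reported (ties: smaller offset, flagged).

## Read-through length

For strongly transcribed genes (FPKM > 5), the candidate region runs
from the PAS to the nearest downstream TSS on either strand
(defaulting to other genes' TSSs; cluster-adjusted TSSs can be
supplied). Two models compete per 100 bp window: the gene-specific
"transcription" model — the ECDF of tag counts in 100 bp windows slid
at 10 bp steps along the gene body — and the "random" model — Poisson
with rate λ estimated as the mean count in non-overlapping 100 bp
intergenic windows (both strands, genes buffered by `buffer_bp`,
default 500 bp so typical read-through zones stay out of the
background estimate). Scanning windows anchored at PAS + k·10 (partial
final window skipped), the first window whose probability ratio
R = P_T(X ≤ c) / P_R(X ≥ c) drops strictly below 1 ends the region;
its start offset is the RT length. R is non-decreasing in c, so each
window decision is a count-threshold rule. Degenerate windows:
P_R = 0 with P_T > 0 gives R = +∞ (still transcribed); both zero gives
R = 0 (terminates). Genes with no drop before the downstream TSS are
censored there; summaries are reported with and without censored
genes. Counts are raw integers — the ECDF/Poisson comparison is only
meaningful on unnormalized counts.

### Calibration of the ratio rule

The rule's accuracy depends on the low tail of the gene-body ECDF. If
every gene window holds ≥ m counts, any window below m gets P_T = 0
and terminates, which for a sharp RT endpoint fires while roughly
m/rate bases of plateau remain (≈ half a window for uniform bodies).
The estimator is approximately unbiased exactly when the ECDF has
enough low-count mass that the termination threshold sits near the
background scale — which is the regime of real nascent data, whose
coverage is strongly bursty. The simulator therefore models gene-body
burstiness explicitly (below), and the recovery experiment uses strong
signal/background separation (0.4 vs 0.002 tags/bp) and a 1 kb
intergenic buffer so planted read-through cannot inflate λ.

## Synthetic data generator

The generator emulates the anatomy of a strand-specific single-base
3'-end tag dataset on a toy genome (default one chromosome, 30
non-overlapping genes of 2-4 kb, 2-4 exons, short 60-250 bp / long
250-1000 bp introns, gaps ≥ 2 kb):

* Poisson intergenic background (0.01 tags/bp by default);
* uniform gene-body rate (0.2 tags/bp) modulated by per-100 bp-tile
  gamma multipliers (shape 0.7, mean 1) emulating transcriptional
  burstiness — the multipliers are a property of the gene, drawn from
  the config seed alone, so replicates and condition pairs share the
  underlying field; the shape was chosen from the threshold analysis
  above so the RT estimator operates in its calibrated regime;
* a promoter-proximal peak (5× body rate over 50 bp at TSS+150,
  mimicking +1-nucleosome stalling);
* an intronic peak whose window-scan summit lies exactly 25 nt past
  the 5'SS (width 10 bp = the ISI scan window, so the planted summit
  is the exact scan optimum);
* elevated signal over the last 10 bp of donor-adjacent exons;
* a post-PAS read-through plateau at the body rate with a hard step to
  background at the true endpoint (optional linear decay); per-gene
  endpoints either fixed or drawn from a range, truncated with a truth
  flag when the downstream gap is too small;
* antisense/sense/intergenic units of the seven classes with
  initiation offsets kept away from the classification rule boundaries
  and from every other gene (600 bp guard), so planted classes are
  unambiguous;
* splicing-intermediate spikes exactly at donor bases. Every other
  rate component is masked at splice-site bases, so the splice filter
  removes exactly the planted spikes; each pre-spike gene tag recruits
  a spike with odds f/(1-f), making spikes the fraction f of gene tags
  in expectation.

Sampling is Poisson per component (background, body, each peak, RT,
each unit), which by Poisson additivity matches sampling the summed
rate while giving the ground truth an exact per-feature tag tally
(conservation: components sum to the total). All randomness flows
through `numpy` Generators seeded from the config, so identical
config + seed reproduces outputs byte-identically. The cold condition
applies multipliers to the control configuration: RT length ×0.9,
exon-end peak ×1.5, splice fraction ×0.5 by default.

What the generator does **not** model: sequence content (no FASTA),
UMIs and PCR duplicates, sequencing error, mappability, overlapping
genes and isoforms, organellar chromosomes, chromatin tracks. Passing
tests therefore demonstrate algorithmic correctness under the stated
signal anatomy, not robustness to every artifact of real libraries.

## Border adjustment and chromatin states

TSS/PAS tag clusters are maximal runs of signal ≥ `min_signal`
(default 1) merged across gaps ≤ `max_gap` (default 25 bp); score is
the summed signal over the cluster, summit the leftmost argmax. A
cluster is linked to a gene when its summit lies within 500 bp of the
original annotated border (either side — the true border may sit on
either side of an over-long annotated UTR); the strongest linked
cluster's summit replaces the border, ties going to the nearest then
leftmost cluster, and adjustments that would invert the gene are
rejected with a warning. Linking against the *original* border makes
the operation idempotent. The 36-state chromatin segmentation is
grouped into Promoter (13, 15-21), Promoter-to-early-elongation
(22-23), Early elongation (24-26), Late elongation (3-12, 27-28) and
Termination (1-2); states 14 and 29-36 are unassigned and excluded
from grouped analyses.

## Problem sizes and tolerances

The test suite and the acceptance script run desk-scale simulations:
8-30 genes (~50-200 kb) for pipeline smoke and condition pairs, 200
genes (~1.1 Mb) for read-through recovery, 150 genes with all unit
classes planted (>500 units) for classification recovery, and 20
seeded replicate pairs of 25 genes for the cold-effect direction
check. Numerical choices: EM tolerance 1e-3 on the log-likelihood
(guarded updates, max 30 iterations in the calling pipeline), Viterbi
ties toward untranscribed, window-scan ties leftmost, binomial
intervals for planted-fraction recovery, and a -1e-8 slack on EM
monotonicity assertions for float round-off.

## Known limitations

* The RT estimator carries the discretization of its 10 bp scan and a
  small negative bias (≈ one scan step) on sharp endpoints; censored
  genes are reported, not imputed.
* The HMM is fit per strand per chromosome with a single parameter
  set; strong promoter peaks are absorbed by the NB transcribed state
  rather than modeled separately.
* `classify_novel` assigns one host per transcript (nearest qualifying
  gene); overlapping-gene genomes would need a richer host model.
* The border adjuster replaces single borders only; it does not
  re-annotate UTR structure.
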