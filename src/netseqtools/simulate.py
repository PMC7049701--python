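"""Synthetic nascent-transcription data with planted ground truth.

The generator emulates the signal anatomy of a strand-specific,
single-base 3'-end tag dataset (NET-seq style): Poisson intergenic
background, uniform gene-body signal, a promoter-proximal peak near the
+1 nucleosome, an intronic stalling peak ~25 nt downstream of the 5'
splice site, elevated signal at exon 3' ends, a post-PAS read-through
plateau decaying to background at a known endpoint, antisense units of
known classes, and splicing-intermediate spikes placed exactly at donor
sites.  Every planted feature is recorded in a :class:`GroundTruth`
object so downstream estimators can be validated against known values.

Tag counts are Poisson-sampled component by component (background,
gene body, each peak, read-through, each antisense unit) so the ground
truth carries an exact per-feature tag tally; by Poisson additivity the
summed counts are distributed identically to sampling the summed rate.
Donor-site bases carry zero rate from every other component -- the only
tags at a donor base are the planted splicing intermediates.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import STRANDS, AnnotationSet, GeneModel, TagSet

ANTISENSE_CLASSES = (
    "divergent",
    "upstream",
    "convergent",
    "pas_antisense",
    "downstream",
    "distal_antisense",
    "intergenic",
)


@dataclass
class PeakSpec:
    """A localized rate elevation: ``amplitude`` multiplies the gene-body
    rate over a window of ``width_bp`` bases at ``offset_bp`` from its
    anchor (TSS for the promoter peak, donor site for the intron peak)."""

    offset_bp: int = 0
    amplitude: float = 5.0
    width_bp: int = 5


@dataclass
class ExonEndPeakSpec:
    width_bp: int = 10
    amplitude: float = 3.0


@dataclass
class RtProfileSpec:
    """Read-through signal past the PAS.

    ``decay='step'`` keeps the full rate up to the true endpoint and
    drops to background there (an unambiguous recovery target);
    ``decay='linear'`` ramps the rate linearly down to zero across the
    region.  With ``rt_length_range`` set, each gene draws its own true
    length uniformly from the inclusive range instead of the fixed value.
    """

    rt_length_bp: int = 500
    decay: str = "step"
    rate_multiplier: float = 1.0
    rt_length_range: tuple[int, int] | None = None


@dataclass
class AntisenseClassSpec:
    """Per-class planting rule.

    ``offset_range`` is interpreted per class: bp upstream of the host
    TSS for divergent/upstream; fraction of host gene length from the
    host TSS for convergent/pas_antisense/downstream; fraction of host
    length *past the PAS* for distal_antisense; ignored for intergenic.
    Defaults keep every initiation point well away from the
    classification rule boundaries (500 bp, 50 %, 20 %).
    """

    probability: float = 0.0
    rate: float = 0.1
    offset_range: tuple[float, float] = (0.0, 0.0)
    length_range: tuple[int, int] = (300, 700)


def _default_antisense_spec() -> dict[str, AntisenseClassSpec]:
    return {
        "divergent": AntisenseClassSpec(0.35, 0.1, (100, 400), (300, 700)),
        "upstream": AntisenseClassSpec(0.10, 0.1, (100, 400), (400, 700)),
        "convergent": AntisenseClassSpec(0.25, 0.1, (0.15, 0.40), (300, 600)),
        "pas_antisense": AntisenseClassSpec(0.25, 0.1, (0.60, 0.90), (300, 600)),
        "downstream": AntisenseClassSpec(0.10, 0.1, (0.60, 0.85), (300, 600)),
        "distal_antisense": AntisenseClassSpec(0.10, 0.1, (0.30, 0.45), (0, 0)),
        "intergenic": AntisenseClassSpec(0.30, 0.1, (0.0, 0.0), (300, 600)),
    }


@dataclass
class ColdEffectSpec:
    """Multipliers applied to the cold member of a condition pair."""

    rt_length_multiplier: float = 0.9
    exon_peak_multiplier: float = 1.5
    splice_fraction_multiplier: float = 0.5


@dataclass
class SimulationConfig:
    n_genes: int = 30
    chrom: str = "chr1"
    chrom_length: int | None = None
    gene_length_range: tuple[int, int] = (2000, 4000)
    exons_per_gene_range: tuple[int, int] = (2, 4)
    intron_length_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"short": (60, 250), "long": (250, 1000)}
    )
    long_intron_prob: float = 0.2
    min_exon_bp: int = 80
    min_gap_bp: int = 2000
    gene_body_rate: float = 0.2
    exon_rate_multiplier: float = 1.0
    # gamma shape of per-100bp-tile rate multipliers over gene bodies
    # (mean 1): emulates the bursty, "spiky" coverage of real nascent
    # transcription data; inf = uniform body
    body_dispersion_shape: float = 0.7
    intergenic_rate: float = 0.01
    promoter_peak: PeakSpec = field(
        default_factory=lambda: PeakSpec(offset_bp=150, amplitude=5.0, width_bp=50)
    )
    # intron peak width matches the 10 bp ISI scan window so the planted
    # summit (25 nt past the 5'SS) is the exact window-scan optimum
    intron_peak: PeakSpec = field(
        default_factory=lambda: PeakSpec(offset_bp=25, amplitude=5.0, width_bp=10)
    )
    exon_end_peak: ExonEndPeakSpec = field(default_factory=ExonEndPeakSpec)
    rt_profile: RtProfileSpec = field(default_factory=RtProfileSpec)
    antisense_spec: dict[str, AntisenseClassSpec] = field(
        default_factory=_default_antisense_spec
    )
    splice_intermediate_fraction: float = 0.05
    cold_effect: ColdEffectSpec = field(default_factory=ColdEffectSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        for name in ("gene_body_rate", "intergenic_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rt_profile.rt_length_bp < 0:
            raise ValueError("rt_length_bp must be >= 0")
        if not 0.0 <= self.splice_intermediate_fraction <= 1.0:
            raise ValueError("splice_intermediate_fraction must lie in [0, 1]")
        if self.rt_profile.decay not in ("step", "linear"):
            raise ValueError("rt decay must be 'step' or 'linear'")
        for cls, spec in self.antisense_spec.items():
            if cls not in ANTISENSE_CLASSES:
                raise ValueError(f"unknown antisense class {cls!r}")
            if not 0.0 <= spec.probability <= 1.0:
                raise ValueError(f"{cls}: probability must lie in [0, 1]")
            if spec.rate < 0:
                raise ValueError(f"{cls}: rate must be >= 0")

    # -- (de)serialisation -------------------------------------------
    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        kwargs = dict(raw)
        if "promoter_peak" in kwargs:
            kwargs["promoter_peak"] = PeakSpec(**kwargs["promoter_peak"])
        if "intron_peak" in kwargs:
            kwargs["intron_peak"] = PeakSpec(**kwargs["intron_peak"])
        if "exon_end_peak" in kwargs:
            kwargs["exon_end_peak"] = ExonEndPeakSpec(**kwargs["exon_end_peak"])
        if "rt_profile" in kwargs:
            rp = dict(kwargs["rt_profile"])
            if rp.get("rt_length_range") is not None:
                rp["rt_length_range"] = tuple(rp["rt_length_range"])
            kwargs["rt_profile"] = RtProfileSpec(**rp)
        if "cold_effect" in kwargs:
            kwargs["cold_effect"] = ColdEffectSpec(**kwargs["cold_effect"])
        if "antisense_spec" in kwargs:
            kwargs["antisense_spec"] = {
                k: AntisenseClassSpec(**_tupled(v))
                for k, v in kwargs["antisense_spec"].items()
            }
        for name in ("gene_length_range", "exons_per_gene_range"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        if "intron_length_ranges" in kwargs:
            kwargs["intron_length_ranges"] = {
                k: tuple(v) for k, v in kwargs["intron_length_ranges"].items()
            }
        return cls(**kwargs)


def _tupled(d: dict) -> dict:
    out = dict(d)
    for name in ("offset_range", "length_range"):
        if name in out:
            out[name] = tuple(out[name])
    return out


# ---------------------------------------------------------------------------
# Annotation generation
# ---------------------------------------------------------------------------

def make_annotation(config: SimulationConfig) -> AnnotationSet:
    """Place non-overlapping genes with exon/intron structure on a chromosome.

    Deterministic for a given config (seeded RNG).  Raises if the genes
    cannot be packed into a user-fixed chromosome length.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    gaps = config.min_gap_bp + rng.integers(
        0, max(1, config.min_gap_bp // 2), size=config.n_genes + 1
    )
    needed = int(lengths.sum() + gaps.sum())
    if config.chrom_length is None:
        chrom_length = needed
    else:
        chrom_length = config.chrom_length
        if needed > chrom_length:
            raise ValueError(
                f"cannot pack {config.n_genes} genes (need {needed} bp) into "
                f"chromosome of {chrom_length} bp with min_gap {config.min_gap_bp}"
            )
    strands = rng.choice(np.array(STRANDS), size=config.n_genes)
    genes = []
    cursor = int(gaps[0])
    for i in range(config.n_genes):
        L = int(lengths[i])
        exons = _make_exons(cursor, L, config, rng)
        genes.append(
            GeneModel(
                gene_id=f"gene{i + 1:04d}",
                chrom=config.chrom,
                strand=str(strands[i]),
                start=cursor,
                end=cursor + L,
                exons=exons,
            )
        )
        cursor += L + int(gaps[i + 1])
    return AnnotationSet(genes, {config.chrom: chrom_length})


def _make_exons(
    start: int, gene_length: int, config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    lo, hi = config.exons_per_gene_range
    n_exons = int(rng.integers(lo, hi + 1))
    while n_exons > 1:
        intron_lengths = []
        for _ in range(n_exons - 1):
            kind = "long" if rng.random() < config.long_intron_prob else "short"
            ilo, ihi = config.intron_length_ranges[kind]
            intron_lengths.append(int(rng.integers(ilo, ihi + 1)))
        if sum(intron_lengths) + n_exons * config.min_exon_bp <= gene_length:
            break
        n_exons -= 1
    if n_exons == 1:
        return [(start, start + gene_length)]
    spare = gene_length - sum(intron_lengths) - n_exons * config.min_exon_bp
    cuts = np.sort(rng.integers(0, spare + 1, size=n_exons - 1))
    parts = np.diff(np.concatenate(([0], cuts, [spare])))
    exon_lengths = [config.min_exon_bp + int(p) for p in parts]
    exons = []
    cursor = start
    for i, el in enumerate(exon_lengths):
        exons.append((cursor, cursor + el))
        cursor += el
        if i < len(intron_lengths):
            cursor += intron_lengths[i]
    return exons


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream validation."""

    genes: pd.DataFrame
    introns: pd.DataFrame
    antisense: pd.DataFrame
    totals: dict

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.genes.to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t", index=False)
        self.introns.to_csv(
            os.path.join(outdir, "truth_introns.tsv"), sep="\t", index=False
        )
        self.antisense.to_csv(
            os.path.join(outdir, "truth_antisense.tsv"), sep="\t", index=False
        )
        with open(os.path.join(outdir, "truth_totals.json"), "w") as fh:
            json.dump(self.totals, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, outdir: str) -> "GroundTruth":
        genes = pd.read_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t")
        introns = pd.read_csv(os.path.join(outdir, "truth_introns.tsv"), sep="\t")
        antisense = pd.read_csv(os.path.join(outdir, "truth_antisense.tsv"), sep="\t")
        for df in (genes, introns, antisense):
            for col in df.columns:
                if df[col].dtype == object:
                    df[col] = df[col].astype(str)
        with open(os.path.join(outdir, "truth_totals.json")) as fh:
            totals = json.load(fh)
        return cls(genes, introns, antisense, totals)

    def antisense_bed(self, path: str) -> None:
        """BED6 of planted antisense/intergenic units, class in the name field."""
        with open(path, "w") as fh:
            for row in self.antisense.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t"
                    f"{row.unit_id}|{row.unit_class}\t0\t{row.strand}\n"
                )


# ---------------------------------------------------------------------------
# Tag simulation
# ---------------------------------------------------------------------------

class _Sampler:
    """Accumulates Poisson draws per component with donor bases masked out."""

    def __init__(self, chrom_sizes, site_mask, rng):
        self.counts = {
            c: {s: np.zeros(n, dtype=np.int64) for s in STRANDS}
            for c, n in chrom_sizes.items()
        }
        self.site_mask = site_mask
        self.rng = rng

    def add(self, chrom: str, strand: str, start: int, end: int, rate) -> int:
        """Poisson-sample ``rate`` (scalar or per-base array) over the
        half-open span and add to the counts; returns tags drawn."""
        size = len(self.counts[chrom][strand])
        start, end = max(0, start), min(size, end)
        if end <= start:
            return 0
        lam = np.broadcast_to(np.asarray(rate, dtype=float), (end - start,)).copy()
        lam[self.site_mask[chrom][strand][start:end]] = 0.0
        drawn = self.rng.poisson(lam)
        self.counts[chrom][strand][start:end] += drawn
        return int(drawn.sum())


def simulate_tags(
    annotation: AnnotationSet,
    config: SimulationConfig,
    *,
    seed: int | None = None,
    rt_multiplier: float = 1.0,
    exon_peak_multiplier: float = 1.0,
    splice_fraction_multiplier: float = 1.0,
    condition: str = "control",
) -> tuple[TagSet, GroundTruth]:
    """Poisson-sample a tag dataset over ``annotation`` and record truth.

    The per-condition multipliers rescale the read-through length, the
    exon-3'-end peak amplitude and the splicing-intermediate fraction
    relative to the config values (all 1.0 for the control condition).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    chrom_sizes = annotation.chrom_sizes

    # splice-site bases (donors and acceptors) carry no signal from any
    # rate component; the only tags ever placed at donors are the
    # planted splicing-intermediate spikes, so filter bookkeeping is exact
    splice_mask = {
        c: {s: np.zeros(n, dtype=bool) for s in STRANDS}
        for c, n in chrom_sizes.items()
    }
    for g in annotation:
        for d in g.donor_sites() + g.acceptor_sites():
            splice_mask[g.chrom][g.strand][d] = True

    sampler = _Sampler(chrom_sizes, splice_mask, rng)
    body = config.gene_body_rate
    # burst multipliers are a property of the gene (chromatin context,
    # local elongation rate), not of the sampling: derive them from the
    # config seed alone so replicates and condition pairs share them
    body_rng = np.random.default_rng([config.seed, 0xB0D7])

    # background everywhere, both strands
    background_tags = 0
    for chrom, size in sorted(chrom_sizes.items()):
        for strand in STRANDS:
            background_tags += sampler.add(chrom, strand, 0, size, config.intergenic_rate)

    genes_sorted = sorted(annotation, key=lambda g: (g.chrom, g.start))
    gene_rows, intron_rows = [], []
    splice_frac = min(
        1.0, config.splice_intermediate_fraction * splice_fraction_multiplier
    )
    rt_range = config.rt_profile.rt_length_range

    for gi, g in enumerate(genes_sorted):
        row: dict = {"gene_id": g.gene_id}
        # gene body: introns at body rate, exons scaled; per-100bp-tile
        # gamma multipliers give the body the bursty count distribution
        # of real nascent data (the RT model's ECDF needs a low tail)
        k = config.body_dispersion_shape
        if np.isfinite(k):
            n_tiles = -(-g.length // 100)
            mult = np.repeat(body_rng.gamma(k, 1.0 / k, size=n_tiles), 100)[: g.length]
        else:
            mult = np.ones(g.length)
        body_tags = 0
        for s, e in g.exons:
            body_tags += sampler.add(
                g.chrom, g.strand, s, e,
                body * config.exon_rate_multiplier * mult[s - g.start : e - g.start],
            )
        for s, e in g.introns:
            body_tags += sampler.add(
                g.chrom, g.strand, s, e, body * mult[s - g.start : e - g.start]
            )

        # promoter-proximal peak
        pk = config.promoter_peak
        summit = g.position_at_offset(pk.offset_bp)
        w0 = summit - pk.width_bp // 2
        prom_tags = sampler.add(
            g.chrom, g.strand, min(w0, w0 + pk.width_bp),
            max(w0, w0 + pk.width_bp), pk.amplitude * body,
        )
        row["promoter_summit"] = summit
        row["promoter_tags"] = prom_tags

        # intronic peaks 25 nt past the 5'SS
        ip = config.intron_peak
        for ii, intron in enumerate(g.introns, 1):
            gs, ge = intron
            ilen = ge - gs
            if ilen < ip.offset_bp + ip.width_bp + 5:
                continue
            donor = g.donor_of_intron(intron)
            if g.strand == "+":
                p_summit = donor + ip.offset_bp
                p0 = p_summit - ip.width_bp // 2
            else:
                p_summit = donor - ip.offset_bp
                p0 = p_summit - (ip.width_bp - 1 - ip.width_bp // 2)
            tags = sampler.add(
                g.chrom, g.strand, p0, p0 + ip.width_bp, ip.amplitude * body
            )
            intron_rows.append(
                {
                    "intron_id": f"{g.gene_id}.intron{ii}",
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "start": gs,
                    "end": ge,
                    "strand": g.strand,
                    "summit": p_summit,
                    "offset_from_5ss": abs(p_summit - donor),
                    "tags": tags,
                }
            )

        # exon-3'-end peaks on exons followed by an intron
        ep = config.exon_end_peak
        ep_amp = ep.amplitude * exon_peak_multiplier * body
        exon_end_tags = 0
        donor_adjacent = g.exons[:-1] if g.strand == "+" else g.exons[1:]
        for s, e in donor_adjacent:
            if g.strand == "+":
                exon_end_tags += sampler.add(g.chrom, g.strand, e - ep.width_bp, e, ep_amp)
            else:
                exon_end_tags += sampler.add(g.chrom, g.strand, s, s + ep.width_bp, ep_amp)
        row["exon_end_tags"] = exon_end_tags

        # read-through plateau past the PAS
        if rt_range is not None:
            base_rt = int(rng.integers(rt_range[0], rt_range[1] + 1))
        else:
            base_rt = config.rt_profile.rt_length_bp
        rt_len_nominal = int(round(base_rt * rt_multiplier))
        nxt = genes_sorted[gi + 1] if gi + 1 < len(genes_sorted) else None
        if g.strand == "+":
            room = (nxt.start - g.end - 100) if (nxt and nxt.chrom == g.chrom) else (
                chrom_sizes[g.chrom] - g.end
            )
        else:
            prev = genes_sorted[gi - 1] if gi > 0 else None
            room = (g.start - prev.end - 100) if (prev and prev.chrom == g.chrom) else g.start
        rt_len = min(rt_len_nominal, max(0, room))
        row["rt_length"] = rt_len
        row["rt_truncated"] = rt_len < rt_len_nominal
        rt_rate = body * config.rt_profile.rate_multiplier
        rt_tags = 0
        if rt_len > 0:
            if config.rt_profile.decay == "step":
                rates = np.full(rt_len, rt_rate)
            else:
                rates = rt_rate * (1.0 - np.arange(rt_len) / rt_len)
            if g.strand == "+":
                rt_tags = sampler.add(g.chrom, g.strand, g.end, g.end + rt_len, rates)
            else:
                rt_tags = sampler.add(
                    g.chrom, g.strand, g.start - rt_len, g.start, rates[::-1]
                )
        row["rt_tags"] = rt_tags
        row["body_tags"] = body_tags
        gene_rows.append(row)

    # antisense / intergenic units
    antisense_rows = _plant_units(annotation, genes_sorted, config, sampler, rng)

    # splicing-intermediate spikes exactly at donor bases: each is planted
    # with odds f/(1-f) per pre-spike gene tag, so spikes form fraction f
    # of the gene's tags in expectation
    splice_total = 0
    gene_tag_total = 0
    for row, g in zip(gene_rows, genes_sorted):
        donors = g.donor_sites()
        gene_tags = int(sampler.counts[g.chrom][g.strand][g.start : g.end].sum())
        spikes = 0
        if donors and splice_frac > 0:
            p = min(1.0, splice_frac / (1.0 - splice_frac)) if splice_frac < 1 else 1.0
            spikes = int(rng.binomial(gene_tags, p))
            alloc = rng.multinomial(spikes, np.full(len(donors), 1.0 / len(donors)))
            for d, k in zip(donors, alloc):
                sampler.counts[g.chrom][g.strand][d] += int(k)
        row["splice_intermediate_tags"] = spikes
        row["gene_tags_prespike"] = gene_tags
        splice_total += spikes
        gene_tag_total += gene_tags + spikes

    tags = _counts_to_tagset(sampler.counts, chrom_sizes)
    total = len(tags)
    component_total = (
        background_tags
        + sum(r["body_tags"] + r["promoter_tags"] + r["exon_end_tags"] + r["rt_tags"]
              for r in gene_rows)
        + sum(r["tags"] for r in intron_rows)
        + sum(r["tags"] for r in antisense_rows)
        + splice_total
    )
    totals = {
        "condition": condition,
        "total_tags": total,
        "component_total_tags": component_total,
        "background_tags": background_tags,
        "splice_intermediate_tags": splice_total,
        "gene_tags": gene_tag_total,
        "splice_fraction_planted": (splice_total / total) if total else 0.0,
        "splice_fraction_of_gene_tags": (
            splice_total / gene_tag_total if gene_tag_total else 0.0
        ),
        "splice_fraction_config": splice_frac,
        "rt_multiplier": rt_multiplier,
        "exon_peak_multiplier": exon_peak_multiplier,
        "splice_fraction_multiplier": splice_fraction_multiplier,
    }
    truth = GroundTruth(
        genes=pd.DataFrame(gene_rows),
        introns=pd.DataFrame(
            intron_rows,
            columns=[
                "intron_id", "gene_id", "chrom", "start", "end", "strand",
                "summit", "offset_from_5ss", "tags",
            ],
        ),
        antisense=pd.DataFrame(
            antisense_rows,
            columns=[
                "unit_id", "chrom", "start", "end", "strand", "unit_class",
                "host_gene", "init_position", "init_offset", "tags",
            ],
        ),
        totals=totals,
    )
    return tags, truth


def _plant_units(annotation, genes_sorted, config, sampler, rng):
    """Plant antisense/sense/intergenic units with class-specific geometry."""
    rows = []
    opposite = {"+": "-", "-": "+"}
    counter = 0
    # geometric guard: a planted unit's initiation point must stay clear
    # of every OTHER gene (600 bp > the 500 bp divergent window), so the
    # planted class is unambiguous under the ordered rule set
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g2 in genes_sorted:
        by_chrom.setdefault(g2.chrom, []).append((g2.start, g2.end, g2.gene_id))

    def init_is_clear(chrom: str, init: int, host_id: str) -> bool:
        return all(
            not (s - 600 <= init < e + 600)
            for s, e, gid in by_chrom.get(chrom, [])
            if gid != host_id
        )

    def emit(chrom, start, end, strand, unit_class, host, init_pos, init_offset):
        nonlocal counter
        counter += 1
        spec = config.antisense_spec[unit_class]
        tags = sampler.add(chrom, strand, start, end, spec.rate)
        rows.append(
            {
                "unit_id": f"unit{counter:04d}",
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "strand": strand,
                "unit_class": unit_class,
                "host_gene": host,
                "init_position": int(init_pos),
                "init_offset": float(init_offset),
                "tags": tags,
            }
        )

    for g in genes_sorted:
        L = g.length
        for unit_class in ANTISENSE_CLASSES:
            if unit_class == "intergenic":
                continue
            spec = config.antisense_spec.get(unit_class)
            if spec is None or rng.random() >= spec.probability:
                continue
            lo, hi = spec.offset_range
            if unit_class in ("divergent", "upstream"):
                off = int(rng.integers(int(lo), int(hi) + 1))
                init = g.position_at_offset(-off)
            elif unit_class == "distal_antisense":
                frac = rng.uniform(lo, hi)
                off = L + int(round(frac * L))
                init = g.position_at_offset(off)
            else:
                frac = rng.uniform(lo, hi)
                off = int(round(frac * L))
                init = g.position_at_offset(off)
            if unit_class in ("divergent", "convergent", "pas_antisense"):
                strand = opposite[g.strand]
                ulen = int(rng.integers(*_as_span(spec.length_range)))
                # antisense units elongate away from the host 3' end
                start, end = _interval_from_init(init, strand, ulen)
            elif unit_class == "distal_antisense":
                strand = opposite[g.strand]
                # must still overlap the host on the antisense strand
                ulen = (off - L) + max(100, L // 4)
                start, end = _interval_from_init(init, strand, ulen)
            elif unit_class == "upstream":
                strand = g.strand
                ulen = int(rng.integers(*_as_span(spec.length_range)))
                ulen = min(ulen, off + max(100, L // 4))  # partial host overlap
                start, end = _interval_downstream(init, strand, ulen)
            else:  # downstream
                strand = g.strand
                ext = int(rng.integers(100, 400))
                ulen = (L - off) + ext
                start, end = _interval_downstream(init, strand, ulen)
            chrom_len = annotation.chrom_sizes[g.chrom]
            if start < 0 or end > chrom_len or end <= start:
                continue
            if not init_is_clear(g.chrom, init, g.gene_id):
                continue
            emit(g.chrom, start, end, strand, unit_class, g.gene_id, init,
                 off if unit_class not in ("divergent", "upstream") else -off)

    # intergenic units, planted in gaps far from any gene's divergent window
    spec = config.antisense_spec.get("intergenic")
    if spec is not None and spec.probability > 0:
        for chrom, gs, ge in annotation.intergenic_intervals(buffer_bp=600):
            if ge - gs < spec.length_range[1] + 200:
                continue
            if rng.random() >= spec.probability:
                continue
            ulen = int(rng.integers(*_as_span(spec.length_range)))
            mid = (gs + ge) // 2
            start = mid - ulen // 2
            end = start + ulen
            strand = "+" if rng.random() < 0.5 else "-"
            init = start if strand == "+" else end - 1
            emit(chrom, start, end, strand, "intergenic", "", init, 0.0)
    return rows


def _as_span(rng_tuple):
    lo, hi = int(rng_tuple[0]), int(rng_tuple[1])
    return lo, max(lo + 1, hi + 1)


def _interval_from_init(init: int, strand: str, length: int) -> tuple[int, int]:
    """Half-open interval whose 5'-most base on ``strand`` is ``init``."""
    if strand == "+":
        return init, init + length
    return init - length + 1, init + 1


def _interval_downstream(init: int, strand: str, length: int) -> tuple[int, int]:
    return _interval_from_init(init, strand, length)


def _counts_to_tagset(counts, chrom_sizes) -> TagSet:
    frames = []
    for chrom in sorted(counts):
        for strand in STRANDS:
            arr = counts[chrom][strand]
            pos = np.flatnonzero(arr)
            if len(pos) == 0:
                continue
            reps = arr[pos]
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "position": np.repeat(pos, reps),
                        "strand": strand,
                        "mapq": 255,
                        "is_split": False,
                    }
                )
            )
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = TagSet.empty_frame()
    return TagSet(df, chrom_sizes)


# ---------------------------------------------------------------------------
# Condition pairs
# ---------------------------------------------------------------------------

@dataclass
class ConditionPair:
    annotation: AnnotationSet
    control_tags: TagSet
    control_truth: GroundTruth
    cold_tags: TagSet
    cold_truth: GroundTruth


def simulate_condition_pair(config: SimulationConfig) -> ConditionPair:
    """Simulate paired control/cold datasets over one annotation.

    The cold dataset applies the configured multipliers: shorter
    read-through, taller exon-end peak, fewer splicing intermediates.
    """
    annotation = make_annotation(config)
    control_tags, control_truth = simulate_tags(
        annotation, config, seed=config.seed, condition="control"
    )
    ce = config.cold_effect
    cold_tags, cold_truth = simulate_tags(
        annotation,
        config,
        seed=config.seed + 1_000_003,
        rt_multiplier=ce.rt_length_multiplier,
        exon_peak_multiplier=ce.exon_peak_multiplier,
        splice_fraction_multiplier=ce.splice_fraction_multiplier,
        condition="cold",
    )
    return ConditionPair(annotation, control_tags, control_truth, cold_tags, cold_truth)


# ---------------------------------------------------------------------------
# File outputs
# ---------------------------------------------------------------------------

def write_bam(tags: TagSet, path: str, read_length: int = 30) -> str:
    """Write a minimal coordinate-sorted BAM of unspliced one-block reads.

    Reads are written in the pre-flip orientation: a tag on the + strand
    (nascent RNA strand) becomes a reverse-strand read whose flipped 3'
    end is the tag position, and vice versa, so the full extraction path
    (strand flip + 3'-end logic) is exercised on simulator output.
    """
    import pysam

    chroms = sorted(tags.chrom_sizes)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(tags.chrom_sizes[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    records = []
    for i, row in enumerate(tags.df.itertuples(index=False)):
        size = tags.chrom_sizes[row.chrom]
        p = int(row.position)
        if row.strand == "+":
            # flipped read is +, 3' end = reference_end - 1 = p; BAM read reverse
            ref_start = max(0, p - read_length + 1)
            ref_end = p + 1
            reverse = True
        else:
            ref_start = p
            ref_end = min(size, p + read_length)
            reverse = False
        records.append((tid[row.chrom], ref_start, ref_end, reverse, int(row.mapq), i))
    records.sort(key=lambda r: (r[0], r[1], r[5]))
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for rtid, ref_start, ref_end, reverse, mapq, i in records:
            a = pysam.AlignedSegment()
            a.query_name = f"tag{i:08d}"
            a.reference_id = rtid
            a.reference_start = ref_start
            a.mapping_quality = mapq
            a.cigartuples = [(0, ref_end - ref_start)]
            a.query_sequence = "N" * (ref_end - ref_start)
            a.flag = 16 if reverse else 0
            bam.write(a)
    pysam.index(path)
    return path


def write_outputs(
    outdir: str,
    annotation: AnnotationSet,
    tags: TagSet,
    truth: GroundTruth,
    config: SimulationConfig,
    *,
    bam: bool = True,
    prefix: str = "sim",
) -> dict[str, str]:
    """Write GFF3 + bedGraph pair + BED6 + truth tables + config snapshot
    (and optionally a BAM) into ``outdir``; returns the path manifest."""
    from .core import StrandedTrack

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    gff = os.path.join(outdir, f"{prefix}.annotation.gff3")
    annotation.to_gff3(gff)
    paths["annotation"] = gff
    track = StrandedTrack.from_tags(tags)
    fwd, rev = track.write_bedgraph(os.path.join(outdir, prefix))
    paths["bedgraph_fwd"], paths["bedgraph_rev"] = fwd, rev
    bed = os.path.join(outdir, f"{prefix}.antisense_units.bed")
    truth.antisense_bed(bed)
    paths["antisense_bed"] = bed
    truth.save(outdir)
    paths["truth_dir"] = outdir
    snap = os.path.join(outdir, f"{prefix}.config.yaml")
    config.to_yaml(snap)
    paths["config"] = snap
    tag_tsv = os.path.join(outdir, f"{prefix}.tags.tsv")
    tags.to_tsv(tag_tsv)
    paths["tags"] = tag_tsv
    if bam:
        bam_path = os.path.join(outdir, f"{prefix}.bam")
        write_bam(tags, bam_path)
        paths["bam"] = bam_path
    return paths
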