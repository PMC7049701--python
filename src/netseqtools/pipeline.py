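"""End-to-end orchestration: simulate -> tags -> tracks -> analyses.

A :class:`RunConfig` collects every stage parameter (defaults are the
standard analysis constants: 100 bp / 10 bp read-through windows,
stalling-index threshold 3, ISI classes at 5.5/3.5, FPKM filters
1/5/10, 500 bp divergent window, 50% reciprocal-overlap novelty rule,
20% PAS-antisense allowance, 5 bp metagene trimming, 100 bp
structural-RNA distance, MAPQ 10).  :func:`run_pipeline` executes the
stages in dependency order and writes a JSON run report echoing every
parameter and listing planted-vs-recovered comparisons when the input
is simulated.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import annotation as ann_ops
from . import discovery, metagene, readthrough, stalling, tags as tag_ops
from .core import AnnotationSet, StrandedTrack, TagSet
from .simulate import (
    ConditionPair,
    GroundTruth,
    SimulationConfig,
    simulate_condition_pair,
)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    outdir: str = "netseq_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # tag processing
    flip_strand: bool = True
    min_mapq: int = 10
    structural_distance_bp: int = 100
    # transcript discovery
    bin_bp: int = 25
    min_reciprocal_overlap: float = 0.5
    divergent_window_bp: int = 500
    pas_downstream_frac: float = 0.2
    # stalling
    si_threshold: float = 3.0
    expressed_fpkm: float = 1.0
    isi_min_fpkm: float = 10.0
    # read-through
    rt_min_fpkm: float = 5.0
    rt_window_bp: int = 100
    rt_step_bp: int = 10
    # metagene
    metagene_bins: int = 40
    metagene_trim_bp: int = 5
    exon_end_flank_bp: int = 50

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "simulation" in kwargs and isinstance(kwargs["simulation"], dict):
            kwargs["simulation"] = SimulationConfig.from_dict(kwargs["simulation"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Per-condition analysis
# ---------------------------------------------------------------------------

def exon_end_peak_height(
    track: StrandedTrack, annotation: AnnotationSet, flank_bp: int = 50
) -> float:
    """Mean normalized signal in the 10 bases immediately upstream of 5'
    splice sites (the exon-3'-end stalling zone), from an anchored
    metagene at donor positions."""
    anchors = [
        (g.chrom, d, g.strand) for g in annotation for d in g.donor_sites()
    ]
    if not anchors:
        return float("nan")
    matrix, _ = metagene.anchored_matrix(track, anchors, flank_bp)
    profile = metagene.profile_with_ci(matrix)
    center = flank_bp
    sel = profile.table["mean"].to_numpy()[center - 10 : center]
    return float(sel.mean())


def analyze_condition(
    tags: TagSet,
    annotation: AnnotationSet,
    config: RunConfig,
    truth: GroundTruth | None = None,
) -> dict:
    """Run filtering, discovery, stalling, read-through and metagene
    analyses for one tag dataset; returns a result dictionary."""
    result: dict = {}
    donor_sites = ann_ops.donor_site_set(annotation)
    splice_sites = ann_ops.splice_site_union(annotation)

    result["splice_intermediate_pct"] = tag_ops.splice_intermediate_fraction(
        tags, donor_sites
    )
    filtered, removed = tag_ops.filter_splice_intermediates(tags, splice_sites)
    result["splice_intermediates_removed"] = removed
    result["tags_total"] = len(tags)
    result["tags_kept"] = len(filtered)

    track = tag_ops.build_track(filtered)
    norm = tag_ops.normalize_track(track, annotation, exclude_chroms=())
    result["normalization_factor"] = norm.normalization_factor
    result["exon_intron_ratio"] = tag_ops.exon_intron_ratio(filtered, annotation)

    # transcript discovery
    called = discovery.call_transcripts(filtered, bin_bp=config.bin_bp)
    novel = discovery.identify_novel(
        called, discovery.annotation_units(annotation),
        min_reciprocal=config.min_reciprocal_overlap,
    )
    classified = discovery.classify_novel(
        novel, annotation,
        divergent_window_bp=config.divergent_window_bp,
        pas_downstream_frac=config.pas_downstream_frac,
    )
    result["n_called"] = len(called)
    result["n_novel"] = len(novel)
    class_counts: dict[str, int] = {}
    for t in classified:
        class_counts[t.transcript_class] = class_counts.get(t.transcript_class, 0) + 1
    result["novel_class_counts"] = class_counts

    # stalling
    library = track.total()
    records, _ = stalling.promoter_stalling_indexes(track, annotation)
    expression = {
        g.gene_id: stalling.fpkm(
            float(track.get(g.chrom, g.strand)[g.start : g.end].sum()),
            g.length,
            library,
        )
        for g in annotation
    }
    try:
        result["stalled_gene_pct"] = stalling.stalled_gene_fraction(
            records, expression,
            si_threshold=config.si_threshold,
            fpkm_threshold=config.expressed_fpkm,
        )
    except ValueError:
        result["stalled_gene_pct"] = float("nan")
    isi_records, _ = stalling.intronic_stalling_indexes(
        track, annotation, library_size=library
    )
    if isi_records:
        mode, tie = stalling.intron_peak_offset_mode(isi_records)
        result["intron_peak_offset_mode_bp"] = mode
        result["intron_peak_offset_tie"] = tie

    # read-through
    rt = readthrough.readthrough_lengths(
        track, annotation,
        min_fpkm=config.rt_min_fpkm,
        window_bp=config.rt_window_bp,
        step_bp=config.rt_step_bp,
    )
    result["rt_n_genes"] = int(len(rt))
    if len(rt):
        summary = readthrough.rt_summary(rt, exclude_censored=False)
        result["rt_median_bp"] = summary["median_bp"]
        result["rt_summary"] = summary
    result["_rt_table"] = rt

    # exon-end metagene peak (on the normalized track)
    result["exon_end_peak_height"] = exon_end_peak_height(
        norm, annotation, flank_bp=config.exon_end_flank_bp
    )

    if truth is not None:
        result["planted_vs_recovered"] = _compare_with_truth(result, truth)
    return result


def _compare_with_truth(result: dict, truth: GroundTruth) -> dict:
    comp: dict = {}
    comp["splice_fraction"] = {
        "planted_pct": 100.0 * truth.totals["splice_fraction_planted"],
        "recovered_pct": result["splice_intermediate_pct"],
        "planted_count": truth.totals["splice_intermediate_tags"],
        "removed_count": result["splice_intermediates_removed"],
    }
    rt = result["_rt_table"]
    if len(rt):
        merged = rt.merge(
            truth.genes[["gene_id", "rt_length"]].rename(
                columns={"rt_length": "rt_length_true"}
            ),
            on="gene_id",
        )
        comp["rt_median"] = {
            "planted_bp": float(np.median(merged["rt_length_true"])),
            "recovered_bp": float(np.median(merged["rt_length"])),
        }
    return comp


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a control/cold condition pair and run every analysis
    stage on both; writes artifacts and a run report under outdir."""
    os.makedirs(config.outdir, exist_ok=True)
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    pair = simulate_condition_pair(sim)
    from .simulate import write_outputs

    report: dict = {
        "version": __version__,
        "parameters": dataclasses.asdict(config),
        "conditions": {},
    }
    for name, cond_tags, truth in (
        ("control", pair.control_tags, pair.control_truth),
        ("cold", pair.cold_tags, pair.cold_truth),
    ):
        outdir = os.path.join(config.outdir, name)
        write_outputs(outdir, pair.annotation, cond_tags, truth, sim, bam=False, prefix=name)
        res = analyze_condition(cond_tags, pair.annotation, config, truth)
        rt = res.pop("_rt_table")
        rt.to_csv(os.path.join(outdir, f"{name}.readthrough.tsv"), sep="\t", index=False)
        report["conditions"][name] = res
    ctrl = report["conditions"]["control"]
    cold = report["conditions"]["cold"]
    report["cold_vs_control"] = {
        "rt_median_delta_bp": cold.get("rt_median_bp", float("nan"))
        - ctrl.get("rt_median_bp", float("nan")),
        "exon_end_peak_ratio": cold["exon_end_peak_height"]
        / ctrl["exon_end_peak_height"]
        if ctrl["exon_end_peak_height"]
        else float("nan"),
        "splice_pct_delta": cold["splice_intermediate_pct"]
        - ctrl["splice_intermediate_pct"],
    }
    with open(os.path.join(config.outdir, "run_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
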