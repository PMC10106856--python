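"""End-to-end orchestration: probes -> tracks -> regions -> dating -> stats.

``run_pipeline`` executes probe mapping, density tracks, compartment
calling, LTR dating (from a GFF3 annotation when given, otherwise the
simplified structural finder), per-centromere identity matrices,
repeat discovery and compartment statistics, writing every intermediate
table so each reported number is recomputable from the emitted files.
All parameters are echoed into a JSON snapshot next to the outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as cio
from .discovery import discover_novel_repeats
from .identity import identity_matrix, plot_heatmap, segment_blocks
from .ltr import (
    date_elements,
    detect_nested,
    elements_to_frame,
    find_ltr_structural,
    read_ltr_annotations,
    composition_table,
)
from .probes import density_track, detect_telomeres, map_probes
from .regions import CENTROMERE, PERICENTROMERE, call_compartments
from .stats import compartment_stats

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (JSON-serialisable)."""

    genome_fasta: str = ""
    probe_fasta: str = ""
    ltr_gff3: str | None = None
    out_dir: str = "centroscape_out"
    min_identity: float = 0.8
    window_size: int = 500_000
    step: int = 100_000
    threshold: float = 0.1
    min_run: int = 2
    merge_gap: int = 2
    mu: float = 1.5e-8
    model: str = "JC69"
    young_threshold_mya: float = 0.5
    bin_size: int = 10_000
    heatmaps: bool = True
    discovery: bool = True
    discovery_min_self: int = 50
    discovery_min_peri_hits: int = 1000
    telomere_motif: str = "TTTAGGG"

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return a report dict (also written as JSON)."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    genome = cio.read_fasta(config.genome_fasta)
    if not genome:
        raise ValueError(f"no sequences in {config.genome_fasta}")
    probe_set = cio.read_probe_fasta(config.probe_fasta)
    logger.info("loaded %d chromosomes, %d probes", len(genome), len(probe_set))

    report: dict = {"params": asdict(config), "chromosomes": {}}

    hits = map_probes(genome, probe_set, min_identity=config.min_identity)
    cio.write_hits_tsv(hits, out / "probe_hits.tsv")
    logger.info("mapped %d probe hits", len(hits))

    telo = detect_telomeres(genome, config.telomere_motif)
    with open(out / "telomeres.tsv", "w") as fh:
        fh.write("chrom\tend\tfraction\tpresent\n")
        for c in telo:
            fh.write(f"{c.chrom}\t{c.end}\t{c.fraction:.4f}\t{c.present}\n")
    report["n_telomeres"] = sum(c.present for c in telo)

    all_regions = []
    for chrom, seq in genome.items():
        chrom_hits = [h for h in hits if h.chrom == chrom]
        ct = density_track(chrom_hits, len(seq), config.window_size, config.step,
                           role="centromeric", chrom=chrom)
        pt = density_track(chrom_hits, len(seq), config.window_size, config.step,
                           role="pericentromeric", chrom=chrom)
        cio.write_bedgraph(ct, out / f"{chrom}.centromeric.bedgraph")
        cio.write_bedgraph(pt, out / f"{chrom}.pericentromeric.bedgraph")
        regs = call_compartments(
            ct, pt, hits=chrom_hits, threshold=config.threshold,
            min_run=config.min_run, merge_gap=config.merge_gap,
        )
        all_regions.extend(regs)
        report["chromosomes"][chrom] = {
            "length": len(seq),
            "regions": [
                {"start": r.start, "end": r.end, "role": r.role,
                 "evidence": round(r.evidence, 4)}
                for r in regs
            ],
        }
    cio.write_bed(all_regions, out / "regions.bed")
    cio.write_params_json(
        {"threshold": config.threshold, "min_run": config.min_run,
         "merge_gap": config.merge_gap, "window_size": config.window_size,
         "step": config.step},
        out / "regions.params.json",
    )

    if config.ltr_gff3:
        elements = read_ltr_annotations(config.ltr_gff3)
        logger.info("read %d annotated elements", len(elements))
    else:
        logger.info("no GFF3 given: running simplified structural LTR finder "
                    "(not equivalent to a full structural annotator)")
        elements = []
        for chrom, seq in genome.items():
            sat_mask = [
                (h.start, h.end)
                for h in hits
                if h.chrom == chrom and h.role in ("centromeric", "pericentromeric")
            ]
            elements.extend(
                find_ltr_structural(seq, chrom=chrom, mask_intervals=sat_mask or None)
            )
    date_elements(elements, genome, mu=config.mu, model=config.model)
    elements_to_frame(elements).to_csv(out / "elements.tsv", sep="\t", index=False)
    nested = detect_nested(elements)
    with open(out / "nested.tsv", "w") as fh:
        fh.write("parent_id\tchild_id\tconsistent\n")
        for p in nested:
            fh.write(f"{p.parent_id}\t{p.child_id}\t{p.consistent}\n")
    report["n_elements"] = len(elements)
    report["n_nested_events"] = len(nested)

    fam, sup = composition_table(elements, all_regions)
    fam.to_csv(out / "composition_family.tsv", sep="\t", index=False)
    sup.to_csv(out / "composition_superfamily.tsv", sep="\t", index=False)

    stats = compartment_stats(
        elements, all_regions,
        chrom_lengths={c: len(s) for c, s in genome.items()},
        satellite_hits=hits,
        young_threshold=config.young_threshold_mya,
    )
    stats.table.to_csv(out / "compartment_stats.tsv", sep="\t", index=False)
    with open(out / "contrasts.tsv", "w") as fh:
        fh.write("group_a\tgroup_b\tt\tp\tmean_a\tmean_b\tn_a\tn_b\n")
        for c in stats.contrasts:
            fh.write(f"{c.group_a}\t{c.group_b}\t{c.t:.4f}\t{c.p:.3e}\t"
                     f"{c.mean_a:.4f}\t{c.mean_b:.4f}\t{c.n_a}\t{c.n_b}\n")
    report["compartment_stats"] = stats.table.to_dict(orient="records")
    report["contrast_footnotes"] = list(stats.footnotes)

    if config.heatmaps:
        for r in all_regions:
            if r.role != CENTROMERE:
                continue
            seq = genome[r.chrom][r.start : r.end]
            if len(seq) < 2 * config.bin_size:
                continue
            mat = identity_matrix(seq, bin_size=config.bin_size,
                                  region=f"{r.chrom}:{r.start}-{r.end}",
                                  start=r.start)
            mat.to_frame().to_csv(out / f"{r.chrom}.identity.tsv", sep="\t")
            blocks = segment_blocks(mat)
            with open(out / f"{r.chrom}.identity_blocks.bed", "w") as fh:
                for lo, hi in blocks:
                    fh.write(f"{r.chrom}\t{mat.bins[lo][0]}\t{mat.bins[hi - 1][1]}\t"
                             f"block_{lo}\n")
            plot_heatmap(mat, str(out / f"{r.chrom}.identity.png"))

    if config.discovery:
        peri_seqs, elem_seqs = [], []
        for r in all_regions:
            if r.role == PERICENTROMERE:
                peri_seqs.append(genome[r.chrom][r.start : r.end])
        peri_labels = {
            (r.chrom, r.start, r.end) for r in all_regions if r.role == PERICENTROMERE
        }
        from .regions import assign_compartments

        labels = assign_compartments(all_regions, elements)
        for e, lab in zip(elements, labels):
            if lab == PERICENTROMERE:
                elem_seqs.append(genome[e.chrom][e.start : e.end])
        if len(elem_seqs) >= 2 and peri_seqs:
            novel, clustered = discover_novel_repeats(
                elem_seqs, peri_seqs, known_probes=probe_set,
                min_self=config.discovery_min_self,
                min_peri_hits=config.discovery_min_peri_hits,
            )
            with open(out / "novel_repeats.tsv", "w") as fh:
                fh.write("length\tself_occurrences\tperi_hits\tknown_overlap\n")
                for c in novel:
                    fh.write(f"{c.length}\t{c.self_occurrences}\t{c.peri_hits}\t"
                             f"{c.known_overlap}\n")
            if novel:
                cio.write_fasta(
                    {f"novel_repeat_{i}": c.sequence for i, c in enumerate(novel)},
                    str(out / "novel_repeats.fasta"),
                )
            report["n_novel_repeats"] = len(novel)
            report["n_clustered_units"] = len(clustered)
        else:
            logger.info("discovery skipped: not enough pericentromeric input")
            report["n_novel_repeats"] = 0

    report["runtime_s"] = round(time.time() - t0, 2)
    cio.write_params_json(report, out / "report.json")
    logger.info("pipeline finished in %.1fs", report["runtime_s"])
    return report
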