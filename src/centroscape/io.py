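"""Readers and writers for the plain-text genomics formats the pipeline uses.

FASTA goes through Biopython.  BED and bedGraph are 0-based half-open;
GFF3 (handled in :mod:`centroscape.ltr`) is 1-based inclusive on disk.
"""

from __future__ import annotations

import json

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .probes import Probe, ProbeSet, ProbeHit, WindowTrack


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str, descriptions: dict[str, str] | None = None) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description=(descriptions or {}).get(name, ""))
        for name, s in seqs.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_probe_fasta(path: str) -> ProbeSet:
    """Probe FASTA with the role in the description, e.g. '>CentBr1 role=centromeric'."""
    probes = []
    for rec in SeqIO.parse(path, "fasta"):
        role = None
        for tok in rec.description.split():
            if tok.startswith("role="):
                role = tok.split("=", 1)[1]
        if role is None:
            raise ValueError(f"probe {rec.id} lacks a 'role=' tag in its description")
        probes.append(Probe(rec.id, role, str(rec.seq).upper()))
    return ProbeSet(probes)


def write_probe_fasta(probe_set: ProbeSet, path: str) -> None:
    with open(path, "w") as fh:
        for p in probe_set:
            fh.write(f">{p.id} role={p.role}\n{p.sequence}\n")


def write_bed(intervals, path: str, name_of=None) -> None:
    """Intervals with .chrom/.start/.end (and optional name) as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = name_of(iv) if name_of else getattr(iv, "role", ".")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def write_bedgraph(track: WindowTrack, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            f'track type=bedGraph name="{track.role}" '
            f"description=\"window={track.window_size} step={track.step}\"\n"
        )
        for s, e, v in zip(track.starts, track.ends, track.values):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v:.6f}\n")


def write_hits_tsv(hits, path: str) -> None:
    """Probe/alignment hits as a tab-separated table (outfmt6-like)."""
    cols = ["probe_id", "chrom", "start", "end", "strand", "identity", "role", "score"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            if isinstance(h, ProbeHit):
                row = [h.probe_id, h.chrom, h.start, h.end, h.strand,
                       f"{h.identity:.4f}", h.role, h.score]
            else:
                row = [h.query_id, h.target_id, h.tstart, h.tend, h.strand,
                       f"{h.identity:.4f}", ".", h.score]
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_hits_bed(hits, path: str) -> None:
    """Hit target intervals as BED (name = query/probe id, score = alignment score)."""
    with open(path, "w") as fh:
        for h in hits:
            if isinstance(h, ProbeHit):
                chrom, start, end, name = h.chrom, h.start, h.end, h.probe_id
            else:
                chrom, start, end, name = h.target_id, h.tstart, h.tend, h.query_id
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{h.score}\t{h.strand}\n")


def write_params_json(params: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
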