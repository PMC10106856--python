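"""Novel pericentromeric repeat discovery by occurrence filtering.

The procedure mirrors how a satellite-like unit hiding inside
retrotransposon sequences can be pulled out of an annotation: all
pericentromere-enriched full-length element sequences are aligned
all-vs-all; recurrent intervals are clustered into candidate units; units
carried by at least ``min_self`` distinct element sequences survive; the
survivors are then mapped onto the pericentromere sequences and kept only
when they hit strictly more than ``min_peri_hits`` times (merged disjoint
intervals, so tandem staircase hits are not inflated); finally any
candidate resembling an already-known satellite probe is flagged and
excluded from the novel list.

Occurrence counting is per sequence record: duplicating an input element
doubles its contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import PreparedSeq, local_align
from .probes import ProbeSet

MIN_SELF_DEFAULT = 50       # keep units occurring in >= 50 element records
MIN_PERI_HITS_DEFAULT = 1000  # keep units with > 1000 merged pericentromere hits


@dataclass
class CandidateRepeat:
    """A candidate repeat unit produced by self-clustering."""

    sequence: str
    self_occurrences: int
    source_element: int  # index of the element carrying the representative
    source_interval: tuple[int, int]
    peri_hits: int | None = None
    known_overlap: bool | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def self_cluster(
    element_seqs: list[str],
    min_identity: float = 0.8,
    min_length: int = 100,
    min_occurrences: int = 2,
) -> list[CandidateRepeat]:
    """Cluster recurrent intervals from all-vs-all element self-alignment.

    Every pairwise local alignment contributes its query and target
    intervals as nodes; nodes on the same element with reciprocal overlap
    >= 50% are linked, as are the two sides of each alignment
    (single linkage).  A cluster's representative is its highest-scoring
    interval and ``self_occurrences`` counts distinct element records in
    the cluster.
    """
    if len(element_seqs) < 2:
        raise ValueError("need at least two element sequences")
    nodes: list[tuple[int, tuple[int, int], int]] = []  # (elem, interval, best score)
    edges: list[tuple[int, int]] = []

    def _add_node(elem: int, interval: tuple[int, int], score: int) -> int:
        nodes.append((elem, interval, score))
        return len(nodes) - 1

    prepared = [PreparedSeq(s) for s in element_seqs]
    for i in range(len(prepared)):
        for j in range(i + 1, len(prepared)):
            hits = local_align(
                prepared[i],
                prepared[j],
                min_identity=min_identity,
                min_length=min_length,
                query_id=str(i),
                target_id=str(j),
            )
            for h in hits:
                a = _add_node(i, (h.qstart, h.qend), h.score)
                b = _add_node(j, (h.tstart, h.tend), h.score)
                edges.append((a, b))

    if not nodes:
        return []
    uf = _UnionFind(len(nodes))
    for a, b in edges:
        uf.union(a, b)
    # link overlapping intervals on the same element
    by_elem: dict[int, list[int]] = {}
    for idx, (elem, iv, _s) in enumerate(nodes):
        by_elem.setdefault(elem, []).append(idx)
    for elem, idxs in by_elem.items():
        idxs.sort(key=lambda x: nodes[x][1])
        for a_pos, a in enumerate(idxs):
            for b in idxs[a_pos + 1 :]:
                if nodes[b][1][0] >= nodes[a][1][1]:
                    break
                if _reciprocal_overlap(nodes[a][1], nodes[b][1]) >= 0.5:
                    uf.union(a, b)

    clusters: dict[int, list[int]] = {}
    for idx in range(len(nodes)):
        clusters.setdefault(uf.find(idx), []).append(idx)
    out = []
    for members in clusters.values():
        elems = {nodes[m][0] for m in members}
        if len(elems) < min_occurrences:
            continue
        rep = max(members, key=lambda m: (nodes[m][2], -(nodes[m][1][1] - nodes[m][1][0])))
        elem, (s, e), _score = nodes[rep]
        out.append(
            CandidateRepeat(
                sequence=element_seqs[elem][s:e],
                self_occurrences=len(elems),
                source_element=elem,
                source_interval=(s, e),
            )
        )
    out.sort(key=lambda c: (-c.self_occurrences, -c.length))
    return out


def count_peri_hits(
    candidate: CandidateRepeat,
    peri_seqs: list[str],
    min_identity: float = 0.8,
    min_length: int = 100,
) -> int:
    """Merged disjoint-interval hit count of the unit on pericentromere sequences."""
    total = 0
    for seq in peri_seqs:
        hits = local_align(
            candidate.sequence,
            seq,
            min_identity=min_identity,
            min_length=min(min_length, max(13, candidate.length // 2)),
        )
        total += _count_disjoint((h.tstart, h.tend) for h in hits)
    return total


def _count_disjoint(intervals) -> int:
    """Number of intervals after merging strict overlaps (abutting stays split)."""
    ivs = sorted(intervals)
    count = 0
    ce = None
    for s, e in ivs:
        if ce is None or s >= ce:
            count += 1
            ce = e
        else:
            ce = max(ce, e)
    return count


def filter_candidates(
    candidates: list[CandidateRepeat],
    peri_seqs: list[str],
    min_self: int = MIN_SELF_DEFAULT,
    min_peri_hits: int = MIN_PERI_HITS_DEFAULT,
    min_identity: float = 0.8,
    min_length: int = 100,
) -> list[CandidateRepeat]:
    """Apply the two occurrence filters.

    Candidates occurring in fewer than ``min_self`` element records are
    dropped; survivors keep their pericentromere hit count and are retained
    only when it is strictly greater than ``min_peri_hits``.
    """
    if not peri_seqs:
        raise ValueError("empty pericentromere sequence set")
    kept = []
    for c in candidates:
        if c.self_occurrences < min_self:
            continue
        c.peri_hits = count_peri_hits(c, peri_seqs, min_identity, min_length)
        if c.peri_hits > min_peri_hits:
            kept.append(c)
    return kept


def filter_known(
    candidates: list[CandidateRepeat],
    known_probes: ProbeSet | list,
    max_identity: float = 0.5,
    min_length: int = 100,
) -> list[CandidateRepeat]:
    """Flag candidates similar to known satellite probes.

    A candidate is flagged when any local alignment against a known probe
    reaches ``max_identity`` over at least ``min_length`` aligned columns;
    flagged candidates are excluded from the returned novel list (the flag
    stays set on the input objects).
    """
    novel = []
    for c in candidates:
        c.known_overlap = False
        for probe in known_probes:
            probe_seq = probe.sequence if hasattr(probe, "sequence") else str(probe)
            if len(probe_seq) < 13 or not c.sequence:
                continue
            hits = local_align(
                c.sequence,
                probe_seq,
                min_identity=max_identity,
                min_length=min(min_length, max(13, len(probe_seq) // 2)),
            )
            if hits:
                c.known_overlap = True
                break
        if not c.known_overlap:
            novel.append(c)
    return novel


def discover_novel_repeats(
    element_seqs: list[str],
    peri_seqs: list[str],
    known_probes: ProbeSet | list = (),
    min_identity: float = 0.8,
    min_length: int = 100,
    min_self: int = MIN_SELF_DEFAULT,
    min_peri_hits: int = MIN_PERI_HITS_DEFAULT,
) -> tuple[list[CandidateRepeat], list[CandidateRepeat]]:
    """End-to-end discovery; returns (novel candidates, all clustered units)."""
    clustered = self_cluster(element_seqs, min_identity, min_length)
    survivors = filter_candidates(
        clustered, peri_seqs, min_self, min_peri_hits, min_identity, min_length
    )
    novel = filter_known(survivors, known_probes, min_length=min_length)
    return novel, clustered
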