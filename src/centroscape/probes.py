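"""Probe mapping, sliding-window density tracks and telomere detection.

Satellite monomers ("probes") carry a role — centromeric, pericentromeric
or telomeric — and are mapped to the genome on both strands.  Enrichment is
summarised as the fraction of each sliding window covered by the union of
role-specific hits (default 500 kb windows advanced in 100 kb steps), which
is robust to monomer fragmentation: overlapping hits are unioned before
windowing so tandem arrays are not double counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import AlignmentHit, local_align, revcomp

ROLES = ("centromeric", "pericentromeric", "telomeric")

DEFAULT_WINDOW = 500_000
DEFAULT_STEP = 100_000


@dataclass(frozen=True)
class Probe:
    id: str
    role: str
    sequence: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown probe role {self.role!r}; expected one of {ROLES}")


@dataclass
class ProbeSet:
    probes: list[Probe]

    def __post_init__(self):
        ids = [p.id for p in self.probes]
        if len(set(ids)) != len(ids):
            raise ValueError("probe ids must be unique")

    def by_role(self, role: str) -> list[Probe]:
        return [p for p in self.probes if p.role == role]

    def __iter__(self):
        return iter(self.probes)

    def __len__(self):
        return len(self.probes)


_DEFAULT_MONOMER_SEED = 987_654_321
# synthetic stand-ins for the real monomers (whose sequences are not public
# inputs here): one 176 bp centromeric unit, 238 bp and 1022 bp
# pericentromeric units, and the 7 bp plant telomere motif
_DEFAULT_LENGTHS = (("CentSat176", "centromeric", 176),
                    ("PeriSat238", "pericentromeric", 238),
                    ("PeriSat1022", "pericentromeric", 1022))
TELOMERE_MOTIF = "TTTAGGG"


def default_probe_set() -> ProbeSet:
    """Deterministic synthetic probe monomers (not the real satellites)."""
    rng = np.random.default_rng(_DEFAULT_MONOMER_SEED)
    probes = []
    for pid, role, length in _DEFAULT_LENGTHS:
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
        probes.append(Probe(pid, role, seq))
    probes.append(Probe("TeloMotif", "telomeric", TELOMERE_MOTIF))
    return ProbeSet(probes)


@dataclass
class ProbeHit:
    """A probe monomer alignment, tagged with the probe's role."""

    probe_id: str
    role: str
    chrom: str
    start: int
    end: int
    strand: str
    identity: float
    score: int = 0

    @classmethod
    def from_alignment(cls, hit: AlignmentHit, role: str, chrom: str) -> "ProbeHit":
        return cls(
            probe_id=hit.query_id,
            role=role,
            chrom=chrom,
            start=hit.tstart,
            end=hit.tend,
            strand=hit.strand,
            identity=hit.identity,
            score=hit.score,
        )


def map_probes(
    genome: dict[str, str],
    probe_set: ProbeSet,
    min_identity: float = 0.8,
    min_length_fraction: float = 0.5,
) -> list[ProbeHit]:
    """Map every probe monomer to every chromosome on both strands.

    The minimum alignment length is ``min_length_fraction`` of the monomer
    length (at least the seed size), so heavily truncated fragments are
    ignored while diverged full-length copies are kept.
    """
    if len(probe_set) == 0:
        raise ValueError("empty probe set")
    hits: list[ProbeHit] = []
    for chrom, seq in genome.items():
        for probe in probe_set:
            min_len = max(13, int(min_length_fraction * len(probe.sequence)))
            if len(probe.sequence) < 13:
                # short motifs (telomere repeats) are matched exactly instead
                for s, e, strand in _motif_occurrences(seq, probe.sequence):
                    hits.append(
                        ProbeHit(probe.id, probe.role, chrom, s, e, strand, 1.0,
                                 len(probe.sequence))
                    )
                continue
            for hit in local_align(
                probe.sequence,
                seq,
                min_identity=min_identity,
                min_length=min_len,
                query_id=probe.id,
                target_id=chrom,
            ):
                hits.append(ProbeHit.from_alignment(hit, probe.role, chrom))
    return hits


def _motif_occurrences(seq: str, motif: str):
    """Exact occurrences of motif and its reverse complement."""
    for m, strand in ((motif.upper(), "+"), (revcomp(motif.upper()), "-")):
        i = seq.upper().find(m)
        while i != -1:
            yield i, i + len(m), strand
            i = seq.upper().find(m, i + 1)


# ---------------------------------------------------------------------------
# interval utilities


def merge_intervals(intervals) -> np.ndarray:
    """Union of half-open intervals as a (n, 2) array sorted by start."""
    arr = np.asarray(list(intervals), dtype=np.int64).reshape(-1, 2)
    if arr.shape[0] == 0:
        return arr
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    out = []
    cs, ce = int(arr[0, 0]), int(arr[0, 1])
    for s, e in arr[1:]:
        if s <= ce:
            ce = max(ce, int(e))
        else:
            out.append((cs, ce))
            cs, ce = int(s), int(e)
    out.append((cs, ce))
    return np.array(out, dtype=np.int64)


def covered_bp(merged: np.ndarray, lo: int, hi: int) -> int:
    """Base pairs of [lo, hi) covered by already-merged intervals."""
    if merged.shape[0] == 0 or hi <= lo:
        return 0
    s = np.clip(merged[:, 0], lo, hi)
    e = np.clip(merged[:, 1], lo, hi)
    return int(np.maximum(0, e - s).sum())


# ---------------------------------------------------------------------------
# density tracks


@dataclass
class WindowTrack:
    """Per-window covered-bp fraction of one probe role along a chromosome.

    Windows start every ``step`` bp and extend ``window_size`` bp (clipped at
    the chromosome end; a trailing partial window is normalised by its
    actual width).
    """

    chrom: str
    chrom_length: int
    role: str
    window_size: int
    step: int
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def __len__(self):
        return self.starts.size


def window_grid(chrom_length: int, window_size: int, step: int):
    starts = np.arange(0, chrom_length, step, dtype=np.int64)
    ends = np.minimum(starts + window_size, chrom_length)
    return starts, ends


def density_track(
    hits,
    chrom_length: int,
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    role: str | None = None,
    chrom: str = "chr",
) -> WindowTrack:
    """Sliding-window covered-bp fraction for hits of one role.

    ``hits`` may be ProbeHit records (filtered by ``role`` when given) or
    bare (start, end) intervals.  Overlapping hits are unioned first.
    """
    if step > window_size:
        raise ValueError(f"step {step} exceeds window size {window_size}")
    intervals = []
    for h in hits:
        if isinstance(h, ProbeHit):
            if role is not None and h.role != role:
                continue
            intervals.append((h.start, h.end))
        else:
            intervals.append((int(h[0]), int(h[1])))
    merged = merge_intervals(intervals)
    starts, ends = window_grid(chrom_length, window_size, step)
    values = np.zeros(starts.size, dtype=float)
    for i, (s, e) in enumerate(zip(starts, ends)):
        width = e - s
        values[i] = covered_bp(merged, int(s), int(e)) / width if width else 0.0
    return WindowTrack(
        chrom=chrom,
        chrom_length=chrom_length,
        role=role or "all",
        window_size=window_size,
        step=step,
        starts=starts,
        ends=ends,
        values=values,
    )


# ---------------------------------------------------------------------------
# telomeres


@dataclass
class TelomereCall:
    chrom: str
    end: str  # "left" | "right"
    fraction: float
    present: bool


def detect_telomeres(
    genome: dict[str, str],
    telomere_motif: str = TELOMERE_MOTIF,
    end_window: int = 10_000,
    min_fraction: float = 0.2,
) -> list[TelomereCall]:
    """Flag chromosome ends whose terminal window is motif-covered.

    An end is telomeric when the fraction of the terminal ``end_window``
    covered by exact occurrences of the motif (either strand) reaches
    ``min_fraction``.  Chromosomes shorter than the window are evaluated
    over their full length.
    """
    if len(telomere_motif) < 5:
        raise ValueError("telomere motif must be at least 5 bp")
    calls = []
    for chrom, seq in genome.items():
        n = len(seq)
        w = min(end_window, n)
        for side, (lo, hi) in (("left", (0, w)), ("right", (n - w, n))):
            sub = seq[lo:hi]
            merged = merge_intervals(
                (s, e) for s, e, _ in _motif_occurrences(sub, telomere_motif)
            )
            frac = covered_bp(merged, 0, w) / w if w else 0.0
            calls.append(TelomereCall(chrom, side, frac, frac >= min_fraction))
    return calls
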