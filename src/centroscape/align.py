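"""Alignment and distance primitives shared by every analysis stage.

Local alignment is seed-and-extend: exact k-mer seeds are located by
vectorised hashing, clustered by diagonal, and each cluster is resolved
exactly (within its diagonal band) by a banded local Gotoh dynamic
programme.  Global identity between near-equal-length sequences comes from
an exact edit-distance alignment (edlib), with gap columns counted as
alignment columns.  Divergence between repeat copies is corrected to
substitutions per site with the Jukes–Cantor (JC69) or Kimura two-parameter
(K2P) model.

An explicit (identity, length) threshold pair plays the role that an
e-value cutoff plays in a database search: hits below either threshold are
suppressed.  No e-value statistics are computed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._kernels import banded_local_align

_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_CIGAR_RE = re.compile(r"(\d+)([=XMID])")


class SaturationError(ValueError):
    """Observed divergence beyond the domain of the substitution model."""


class BandError(ValueError):
    """Alignment band too small to connect the corners of the matrix."""


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Scoring:
    """Affine alignment scoring; a length-L gap scores gap_open + (L-1)*gap_extend."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1


DEFAULT_SCORING = Scoring()


@dataclass
class AlignmentHit:
    """A local alignment of a query against a target.

    Intervals are 0-based half-open; the target interval is always on
    forward-strand coordinates, with ``strand`` recording which query strand
    aligned.
    """

    query_id: str
    target_id: str
    qstart: int
    qend: int
    tstart: int
    tend: int
    strand: str
    aligned_columns: int
    matches: int
    score: int

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_columns if self.aligned_columns else 0.0

    @property
    def tlength(self) -> int:
        return self.tend - self.tstart


@dataclass
class DistanceEstimate:
    """Model-corrected substitution distance between two sequences."""

    p_obs: float
    K: float
    model: str = "JC69"


# ---------------------------------------------------------------------------
# substitution-model distances


def jc69_distance(p_obs: float) -> float:
    """Jukes–Cantor correction K = -(3/4) ln(1 - (4/3) p).

    Raises :class:`SaturationError` for p_obs >= 0.75, where the model is
    undefined (saturated divergence).
    """
    if p_obs < 0:
        raise ValueError(f"negative mismatch fraction: {p_obs}")
    if p_obs >= 0.75:
        raise SaturationError(f"p_obs={p_obs} >= 0.75 saturates the JC69 model")
    return -0.75 * math.log1p(-4.0 * p_obs / 3.0)


def k2p_distance(p_transitions: float, q_transversions: float) -> float:
    """Kimura two-parameter distance K = -(1/2)ln(1-2p-q) - (1/4)ln(1-2q)."""
    if p_transitions < 0 or q_transversions < 0:
        raise ValueError("transition/transversion fractions must be nonnegative")
    a = 1.0 - 2.0 * p_transitions - q_transversions
    b = 1.0 - 2.0 * q_transversions
    if a <= 0 or b <= 0:
        raise SaturationError(
            f"p={p_transitions}, q={q_transversions} saturate the K2P model"
        )
    return -0.5 * math.log(a) - 0.25 * math.log(b)


_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def classify_substitutions(a: str, b: str) -> tuple[int, int, int]:
    """Count (matches, transitions, transversions) over equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences must be of equal length")
    matches = transitions = transversions = 0
    for x, y in zip(a.upper(), b.upper()):
        if x == y:
            matches += 1
        elif (x in _PURINES and y in _PURINES) or (
            x in _PYRIMIDINES and y in _PYRIMIDINES
        ):
            transitions += 1
        else:
            transversions += 1
    return matches, transitions, transversions


# ---------------------------------------------------------------------------
# global alignment


@dataclass
class GlobalAlignment:
    """Column statistics of a global (end-to-end) pairwise alignment."""

    matches: int
    transitions: int
    transversions: int
    gap_columns: int

    @property
    def mismatches(self) -> int:
        return self.transitions + self.transversions

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.gap_columns

    @property
    def identity(self) -> float:
        """Matches over all columns; gap columns count as columns."""
        return self.matches / self.columns if self.columns else 1.0

    @property
    def p_obs(self) -> float:
        """Mismatch fraction over match/mismatch columns only (gap-excluded)."""
        mm = self.matches + self.mismatches
        return self.mismatches / mm if mm else 0.0


def global_alignment(a: str, b: str, band: int | None = None) -> GlobalAlignment:
    """Exact end-to-end alignment of a and b (minimum edit distance).

    ``band`` bounds the permissible length difference: if |len(a)-len(b)|
    exceeds it the band cannot connect the matrix corners and
    :class:`BandError` is raised.  The alignment itself is computed exactly
    (unbanded), which can only improve on a banded score.
    """
    if not a or not b:
        raise ValueError("empty sequence in global alignment")
    if band is not None and abs(len(a) - len(b)) > band:
        raise BandError(
            f"band {band} cannot absorb length difference {abs(len(a) - len(b))}"
        )
    au, bu = a.upper(), b.upper()
    res = edlib.align(au, bu, mode="NW", task="path")
    matches = transitions = transversions = gaps = 0
    qi = ti = 0
    for length, op in _CIGAR_RE.findall(res["cigar"]):
        length = int(length)
        if op in "M=X":
            xs = au[qi : qi + length]
            ys = bu[ti : ti + length]
            for x, y in zip(xs, ys):
                if x == y and x in "ACGT":
                    matches += 1
                elif (x in _PURINES and y in _PURINES) or (
                    x in _PYRIMIDINES and y in _PYRIMIDINES
                ):
                    transitions += 1
                else:
                    transversions += 1
            qi += length
            ti += length
        elif op == "I":  # edlib: insertion in query, consumes query
            gaps += length
            qi += length
        else:  # "D": deletion from query, consumes target
            gaps += length
            ti += length
    return GlobalAlignment(matches, transitions, transversions, gaps)


def global_identity(a: str, b: str, band: int | None = None) -> tuple[float, int]:
    """Identity fraction (gap columns counted) and number of aligned columns."""
    g = global_alignment(a, b, band=band)
    return g.identity, g.columns


# ---------------------------------------------------------------------------
# seed-and-extend local alignment


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit k-mer codes and a validity mask (no non-ACGT base)."""
    n = codes.size
    if n < k:
        return np.empty(0, np.int64), np.empty(0, bool)
    m = n - k + 1
    out = np.zeros(m, dtype=np.int64)
    bad = np.zeros(m, dtype=bool)
    for j in range(k):
        c = codes[j : j + m]
        out |= (c.astype(np.int64) & 3) << (2 * j)
        bad |= c >= 4
    return out, ~bad


class PreparedSeq:
    """Precomputed encoding and sorted k-mer index of one sequence.

    Preparing sequences once makes all-vs-all comparisons cheap: seed
    matching between two prepared sequences is two binary searches.
    """

    __slots__ = ("seq", "codes", "k", "kmer_codes", "kmer_pos", "_rc")

    def __init__(self, seq: str, k: int = 13):
        self.seq = seq
        self.codes = encode(seq)
        self.k = k
        kc, ok = _kmer_codes(self.codes, k)
        pos = np.nonzero(ok)[0]
        kc = kc[pos]
        order = np.argsort(kc, kind="stable")
        self.kmer_codes = kc[order]
        self.kmer_pos = pos[order]
        self._rc: "PreparedSeq | None" = None

    def __len__(self):
        return len(self.seq)

    @property
    def rc(self) -> "PreparedSeq":
        if self._rc is None:
            self._rc = PreparedSeq(revcomp(self.seq), self.k)
        return self._rc


def prepare(seq: str, k: int = 13) -> PreparedSeq:
    return PreparedSeq(seq, k)


_EMPTY = np.empty(0, np.int64)


def _seeds_prepared(qp: PreparedSeq, tp: PreparedSeq):
    """All exact shared k-mer positions between two prepared sequences."""
    if qp.kmer_codes.size == 0 or tp.kmer_codes.size == 0:
        return _EMPTY, _EMPTY
    lo = np.searchsorted(tp.kmer_codes, qp.kmer_codes, "left")
    hi = np.searchsorted(tp.kmer_codes, qp.kmer_codes, "right")
    reps = hi - lo
    sel = reps > 0
    if not np.any(sel):
        return _EMPTY, _EMPTY
    reps_s = reps[sel]
    total = int(reps_s.sum())
    qpos = np.repeat(qp.kmer_pos[sel], reps_s)
    start_off = np.cumsum(reps_s) - reps_s
    idx = np.arange(total) - np.repeat(start_off, reps_s) + np.repeat(lo[sel], reps_s)
    tpos = tp.kmer_pos[idx]
    return qpos, tpos


def _find_seeds(
    qcodes: np.ndarray, tcodes: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """All exact k-mer matches as (query_pos, target_pos) arrays."""
    qp = PreparedSeq.__new__(PreparedSeq)
    tp = PreparedSeq.__new__(PreparedSeq)
    for obj, codes in ((qp, qcodes), (tp, tcodes)):
        kc, ok = _kmer_codes(codes, k)
        pos = np.nonzero(ok)[0]
        kc = kc[pos]
        order = np.argsort(kc, kind="stable")
        obj.kmer_codes = kc[order]
        obj.kmer_pos = pos[order]
    return _seeds_prepared(qp, tp)


def _cluster_seeds(
    qpos: np.ndarray, tpos: np.ndarray, diag_gap: int, pos_gap: int
) -> list[tuple[int, int, int, int]]:
    """Group seeds into (dmin, dmax, tmin, tmax) clusters by diagonal."""
    diag = tpos - qpos
    order = np.lexsort((tpos, diag))
    d = diag[order]
    tp = tpos[order]
    breaks = np.nonzero(
        (np.diff(d) > diag_gap) | ((np.diff(d) == 0) & (np.diff(tp) > pos_gap))
    )[0]
    bounds = np.concatenate(([0], breaks + 1, [d.size]))
    clusters = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        clusters.append(
            (int(d[s:e].min()), int(d[s:e].max()), int(tp[s:e].min()), int(tp[s:e].max()))
        )
    return clusters


def _align_strand(
    qp: PreparedSeq,
    tp: PreparedSeq,
    scoring: Scoring,
    band_pad: int,
) -> list[tuple[int, int, int, int, int, int, int]]:
    """Raw (score, qb, qe, tb, te, matches, cols) tuples for one query strand."""
    qpos, tpos = _seeds_prepared(qp, tp)
    if qpos.size == 0:
        return []
    n = qp.codes.size
    m = tp.codes.size
    out = []
    for dmin, dmax, _tmin, _tmax in _cluster_seeds(
        qpos, tpos, band_pad, 2 * n + 4 * band_pad
    ):
        wlo = max(0, dmin - band_pad)
        whi = min(m, dmax + n + band_pad)
        dlo = dmin - band_pad - wlo
        dhi = dmax + band_pad - wlo
        res = banded_local_align(
            qp.codes,
            tp.codes[wlo:whi],
            dlo,
            dhi,
            scoring.match,
            scoring.mismatch,
            scoring.gap_open,
            scoring.gap_extend,
        )
        score, qb, qe, tb, te, matches, cols = res
        if score > 0:
            out.append((score, qb, qe, tb + wlo, te + wlo, matches, cols))
    return out


def _suppress_overlaps(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Keep the highest-scoring hit among target-overlapping alternatives.

    Two hits conflict when their target intervals overlap by more than half
    of the shorter interval; the lower-scoring one is dropped.
    """
    if not hits:
        return []
    hits = sorted(hits, key=lambda h: (-h.score, h.tstart, h.qstart, h.strand))
    kept: list[AlignmentHit] = []
    starts: list[int] = []
    ends: list[int] = []
    for h in hits:
        if kept:
            s = np.maximum(np.array(starts), h.tstart)
            e = np.minimum(np.array(ends), h.tend)
            ov = np.maximum(0, e - s)
            shorter = np.minimum(np.array(ends) - np.array(starts), h.tlength)
            if np.any(ov > 0.5 * shorter):
                continue
        kept.append(h)
        starts.append(h.tstart)
        ends.append(h.tend)
    kept.sort(key=lambda h: (h.tstart, h.tend))
    return kept


def local_align(
    query: "str | PreparedSeq",
    target: "str | PreparedSeq",
    min_identity: float = 0.8,
    min_length: int = 30,
    scoring: Scoring = DEFAULT_SCORING,
    *,
    k: int = 13,
    band_pad: int = 32,
    both_strands: bool = True,
    query_id: str = "query",
    target_id: str = "target",
) -> list[AlignmentHit]:
    """Local alignments of query against target above identity/length cutoffs.

    Seed-and-extend with exact ``k``-mer seeds; each diagonal cluster of
    seeds is resolved by a banded local Gotoh DP (band ±``band_pad`` around
    the seeded diagonals).  Both query strands are searched unless
    ``both_strands`` is false; minus-strand hits are reported with the
    target interval on forward coordinates.  Overlapping hits are reduced to
    the highest-scoring one.
    """
    if isinstance(query, PreparedSeq):
        qp = query
        k = qp.k
    else:
        if not query:
            raise ValueError("empty query")
        qp = PreparedSeq(query, k)
    if isinstance(target, PreparedSeq):
        tp = target
    else:
        if not target:
            raise ValueError("empty target")
        tp = PreparedSeq(target, k)
    if not len(qp) or not len(tp):
        raise ValueError("empty query or target")
    if min_length < k:
        raise ValueError(f"min_length {min_length} is below the seed length {k}")
    n = len(qp)
    raw = []
    for score, qb, qe, tb, te, matches, cols in _align_strand(qp, tp, scoring, band_pad):
        raw.append((score, qb, qe, tb, te, matches, cols, "+"))
    if both_strands:
        for score, qb, qe, tb, te, matches, cols in _align_strand(
            qp.rc, tp, scoring, band_pad
        ):
            raw.append((score, n - qe, n - qb, tb, te, matches, cols, "-"))
    hits = []
    for score, qb, qe, tb, te, matches, cols, strand in raw:
        if cols < min_length:
            continue
        if matches / cols < min_identity:
            continue
        hits.append(
            AlignmentHit(
                query_id=query_id,
                target_id=target_id,
                qstart=qb,
                qend=qe,
                tstart=tb,
                tend=te,
                strand=strand,
                aligned_columns=cols,
                matches=matches,
                score=score,
            )
        )
    return _suppress_overlaps(hits)
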