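"""Pairwise sequence-identity landscapes over non-overlapping bins.

A region (typically a called centromere) is cut into non-overlapping bins
(default 10 kb, trailing partial bin dropped) and every bin pair is aligned
end to end; identity counts gap columns as columns.  The resulting
symmetric matrix exposes the block structure of satellite arrays.  A fast
k-mer containment estimator is available as an explicitly labelled
estimate, and a minimal change-point heuristic segments the matrix into
homogeneous blocks as an interpretive aid.

Identity is computed on the forward strand by default; a
reverse-complement-aware option exists and is recorded in the matrix
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import global_identity, revcomp, encode, _kmer_codes

DEFAULT_BIN = 10_000


@dataclass
class IdentityMatrix:
    """Symmetric bin-by-bin identity matrix of one region."""

    region: str
    start: int  # region start on its chromosome (for bin coordinates)
    bin_size: int
    bins: list[tuple[int, int]]
    values: np.ndarray
    method: str = "global"
    revcomp_aware: bool = False

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def to_frame(self):
        import pandas as pd

        idx = [f"{s}-{e}" for s, e in self.bins]
        return pd.DataFrame(self.values, index=idx, columns=idx)


def identity_matrix(
    region_seq: str,
    bin_size: int = DEFAULT_BIN,
    method: str = "global",
    band_fraction: float = 0.1,
    region: str = "region",
    start: int = 0,
    revcomp_aware: bool = False,
) -> IdentityMatrix:
    """All-pairs identity between the region's non-overlapping bins.

    ``method="global"`` aligns each pair end to end; ``method="kmer"`` uses
    a containment estimate (shared k-mer fraction raised to 1/k), labelled
    as an estimate in the result.  With ``revcomp_aware`` the larger of the
    forward and reverse-complement identities is reported.
    """
    n = len(region_seq) // bin_size
    if n < 2:
        raise ValueError(
            f"region of {len(region_seq)} bp yields fewer than two {bin_size} bp bins"
        )
    seqs = [region_seq[i * bin_size : (i + 1) * bin_size] for i in range(n)]
    bins = [(start + i * bin_size, start + (i + 1) * bin_size) for i in range(n)]
    values = np.ones((n, n), dtype=float)
    if method == "global":
        band = max(16, int(band_fraction * bin_size))
        for i in range(n):
            for j in range(i + 1, n):
                ident, _ = global_identity(seqs[i], seqs[j], band=band)
                if revcomp_aware:
                    ident_rc, _ = global_identity(seqs[i], revcomp(seqs[j]), band=band)
                    ident = max(ident, ident_rc)
                values[i, j] = values[j, i] = ident
    elif method == "kmer":
        k = 15
        sets = [_kmer_set(s, k) for s in seqs]
        rc_sets = [_kmer_set(revcomp(s), k) for s in seqs] if revcomp_aware else None
        for i in range(n):
            for j in range(i + 1, n):
                est = _containment_identity(sets[i], sets[j], k)
                if revcomp_aware:
                    est = max(est, _containment_identity(sets[i], rc_sets[j], k))
                values[i, j] = values[j, i] = est
    else:
        raise ValueError(f"unknown method {method!r}")
    return IdentityMatrix(
        region=region,
        start=start,
        bin_size=bin_size,
        bins=bins,
        values=values,
        method=method,
        revcomp_aware=revcomp_aware,
    )


def _kmer_set(seq: str, k: int) -> np.ndarray:
    codes, ok = _kmer_codes(encode(seq), k)
    return np.unique(codes[ok])


def _containment_identity(a: np.ndarray, b: np.ndarray, k: int) -> float:
    """ANI-style estimate: containment of the smaller k-mer set, ^(1/k)."""
    if a.size == 0 or b.size == 0:
        return 0.0
    shared = np.intersect1d(a, b, assume_unique=True).size
    c = shared / min(a.size, b.size)
    return float(c ** (1.0 / k))


# ---------------------------------------------------------------------------
# block segmentation


def segment_blocks(matrix: IdentityMatrix, cut: float = 0.1) -> list[tuple[int, int]]:
    """Contiguous bin intervals of internally similar blocks.

    Recursive bisection: a split is accepted when mean within-block
    identity exceeds mean between-block identity by at least ``cut``.  A
    uniform matrix yields a single block.  This is an interpretive aid, not
    an inference procedure.
    """
    v = matrix.values
    n = v.shape[0]
    cum = np.zeros((n + 1, n + 1))
    cum[1:, 1:] = v.cumsum(0).cumsum(1)

    def boxsum(r0, r1, c0, c1):
        return cum[r1, c1] - cum[r0, c1] - cum[r1, c0] + cum[r0, c0]

    def within_mean(lo, hi):
        m = hi - lo
        if m < 2:
            return None  # no off-diagonal pairs
        total = boxsum(lo, hi, lo, hi) - m  # minus unit diagonal
        return total / (m * m - m)

    def split(lo, hi):
        if hi - lo < 2:
            return [(lo, hi)]
        best_gap = -np.inf
        best_c = None
        for c in range(lo + 1, hi):
            between = boxsum(lo, c, c, hi) / ((c - lo) * (hi - c))
            wm = [w for w in (within_mean(lo, c), within_mean(c, hi)) if w is not None]
            if not wm:
                continue
            gap = float(np.mean(wm)) - between
            if gap > best_gap:
                best_gap = gap
                best_c = c
        if best_c is None or best_gap < cut:
            return [(lo, hi)]
        return split(lo, best_c) + split(best_c, hi)

    return split(0, n)


def plot_heatmap(matrix: IdentityMatrix, path: str, cmap: str = "viridis") -> None:
    """Render the identity matrix as a static heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.values, vmin=0, vmax=1, cmap=cmap, origin="lower")
    ax.set_title(f"{matrix.region} ({matrix.bin_size // 1000} kb bins, {matrix.method})")
    ax.set_xlabel("bin")
    ax.set_ylabel("bin")
    fig.colorbar(im, ax=ax, label="identity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
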