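"""Full-length LTR retrotransposon dating and compartment composition.

An intact LTR retrotransposon carries two long terminal repeats that were
identical at insertion time; divergence between them clocks the insertion.
The two LTR copies are aligned end to end, the mismatch fraction over
match/mismatch columns (gaps excluded) is corrected to substitutions per
site with JC69 (default) or K2P, and the age is T = K / (2 mu) with mu the
substitution rate per site per year (default 1.5e-8, a standard
Brassicaceae rate; both model and rate are configuration, not constants).

Elements with age <= 0.5 MYA are classified young, older ones old.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import regions as _regions
from .align import (
    GlobalAlignment,
    SaturationError,
    classify_substitutions,
    global_alignment,
    jc69_distance,
    k2p_distance,
    encode,
)

logger = logging.getLogger(__name__)

DEFAULT_MU = 1.5e-8  # substitutions / site / year
YOUNG_OLD_THRESHOLD_MYA = 0.5

SUPERFAMILY_OF = {
    # Copia lineages
    "ALE": "Copia",
    "Angela": "Copia",
    "Ivana": "Copia",
    "Tork": "Copia",
    "Bianca": "Copia",
    "SIRE": "Copia",
    # Gypsy lineages
    "CRM": "Gypsy",
    "Tekay": "Gypsy",
    "Retand": "Gypsy",
    "Athila": "Gypsy",
    "Ogre": "Gypsy",
    "Reina": "Gypsy",
}


def superfamily_of(family: str) -> str:
    return SUPERFAMILY_OF.get(family, "unknown")


@dataclass
class LTRElement:
    """A full-length LTR retrotransposon (coordinates 0-based half-open)."""

    id: str
    chrom: str
    start: int
    end: int
    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    family: str = "unknown"
    superfamily: str = "unknown"
    parent_id: str | None = None
    p_obs: float | None = None
    K: float | None = None
    age_mya: float | None = None
    age_class: str | None = None
    age_reliable: bool = True
    true_age_mya: float | None = None  # set only by the simulator

    def __post_init__(self):
        if not (
            self.start <= self.ltr5_start < self.ltr5_end
            <= self.ltr3_start < self.ltr3_end <= self.end
        ):
            raise ValueError(f"inconsistent LTR intervals for element {self.id}")
        if self.superfamily == "unknown" and self.family in SUPERFAMILY_OF:
            self.superfamily = SUPERFAMILY_OF[self.family]

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def ltr_sequences(self, genome: dict[str, str]) -> tuple[str, str]:
        seq = genome[self.chrom]
        return (
            seq[self.ltr5_start : self.ltr5_end],
            seq[self.ltr3_start : self.ltr3_end],
        )


# ---------------------------------------------------------------------------
# GFF3 round trip (1-based inclusive on disk, 0-based half-open in memory)

_ELEMENT_TYPES = {"LTR_retrotransposon", "repeat_region", "mobile_genetic_element"}
_LTR_TYPES = {"long_terminal_repeat", "LTR"}


def read_ltr_annotations(path: str) -> list[LTRElement]:
    """Read full-length LTR elements from a GFF3 file.

    Expects element records (``LTR_retrotransposon``) with two
    ``long_terminal_repeat`` children referencing them via ``Parent``.
    Elements lacking either LTR sub-feature are skipped with a logged
    warning.  Attributes ``family`` and ``superfamily`` are optional.
    """
    elements: dict[str, dict] = {}
    ltrs: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                continue
            chrom, _src, ftype, start, end, _score, _strand, _phase, attrs = cols[:9]
            a = _parse_attrs(attrs)
            s0, e0 = int(start) - 1, int(end)  # to 0-based half-open
            if ftype in _ELEMENT_TYPES:
                eid = a.get("ID", f"elem_{len(elements)}")
                elements[eid] = {
                    "chrom": chrom,
                    "start": s0,
                    "end": e0,
                    "family": a.get("family", "unknown"),
                    "superfamily": a.get("superfamily", "unknown"),
                    "parent_id": a.get("nested_in") or None,
                }
            elif ftype in _LTR_TYPES:
                parent = a.get("Parent")
                if parent:
                    ltrs.setdefault(parent, []).append((s0, e0))
    out = []
    skipped = 0
    for eid, rec in elements.items():
        pair = sorted(ltrs.get(eid, []))
        if len(pair) != 2:
            skipped += 1
            continue
        (l5s, l5e), (l3s, l3e) = pair
        out.append(
            LTRElement(
                id=eid,
                chrom=rec["chrom"],
                start=rec["start"],
                end=rec["end"],
                ltr5_start=l5s,
                ltr5_end=l5e,
                ltr3_start=l3s,
                ltr3_end=l3e,
                family=rec["family"],
                superfamily=rec["superfamily"],
                parent_id=rec["parent_id"],
            )
        )
    if skipped:
        logger.warning(
            "skipped %d element(s) without exactly two LTR sub-features", skipped
        )
    out.sort(key=lambda e: (e.chrom, e.start, e.end))
    return out


def write_ltr_annotations(elements: list[LTRElement], path: str) -> None:
    """Write elements and their LTR sub-features as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for e in elements:
            attrs = [f"ID={e.id}", f"family={e.family}", f"superfamily={e.superfamily}"]
            if e.parent_id:
                attrs.append(f"nested_in={e.parent_id}")
            if e.true_age_mya is not None:
                attrs.append(f"true_age_mya={e.true_age_mya:.6f}")
            fh.write(
                "\t".join(
                    [
                        e.chrom,
                        "centroscape",
                        "LTR_retrotransposon",
                        str(e.start + 1),
                        str(e.end),
                        ".",
                        "+",
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
            for tag, (s, t) in (
                ("five_prime", (e.ltr5_start, e.ltr5_end)),
                ("three_prime", (e.ltr3_start, e.ltr3_end)),
            ):
                fh.write(
                    "\t".join(
                        [
                            e.chrom,
                            "centroscape",
                            "long_terminal_repeat",
                            str(s + 1),
                            str(t),
                            ".",
                            "+",
                            ".",
                            f"ID={e.id}_ltr_{tag};Parent={e.id}",
                        ]
                    )
                    + "\n"
                )


def _parse_attrs(attrs: str) -> dict:
    out = {}
    for part in attrs.split(";"):
        part = part.strip()
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# dating


def estimate_age(
    element: LTRElement,
    genome: dict[str, str],
    mu: float = DEFAULT_MU,
    model: str = "JC69",
) -> LTRElement:
    """Date an element from the divergence of its two LTR copies (in place).

    p_obs is the mismatch fraction over match/mismatch columns (gap columns
    excluded), corrected to K by the chosen model; age_mya = K / (2 mu) / 1e6.
    Equal-length LTR copies are compared site by site (the substitution
    clock assumes no indels, and a minimum-edit alignment of diverged copies
    would otherwise trade pairs of substitutions for spurious gaps);
    unequal-length copies are aligned end to end first.  Saturated
    divergence marks the age unreliable instead of raising.
    """
    ltr5, ltr3 = element.ltr_sequences(genome)
    if len(ltr5) == len(ltr3):
        matches, ti, tv = classify_substitutions(ltr5, ltr3)
        g = GlobalAlignment(matches, ti, tv, 0)
    else:
        g = global_alignment(ltr5, ltr3)
    element.p_obs = g.p_obs
    try:
        if model.upper() == "JC69":
            element.K = jc69_distance(g.p_obs)
        elif model.upper() == "K2P":
            mm = g.matches + g.mismatches
            if mm == 0:
                element.K = 0.0
            else:
                element.K = k2p_distance(g.transitions / mm, g.transversions / mm)
        else:
            raise ValueError(f"unknown model {model!r}")
    except SaturationError:
        element.K = None
        element.age_mya = None
        element.age_class = None
        element.age_reliable = False
        return element
    element.age_mya = element.K / (2.0 * mu) / 1e6
    element.age_class = classify_age(element.age_mya)
    element.age_reliable = True
    return element


def date_elements(
    elements: list[LTRElement],
    genome: dict[str, str],
    mu: float = DEFAULT_MU,
    model: str = "JC69",
) -> list[LTRElement]:
    for e in elements:
        estimate_age(e, genome, mu=mu, model=model)
    return elements


def classify_age(age_mya: float, threshold: float = YOUNG_OLD_THRESHOLD_MYA) -> str:
    """Young iff age <= threshold (0.5 MYA), old strictly above."""
    if not np.isfinite(age_mya):
        raise ValueError("age must be finite")
    return "young" if age_mya <= threshold else "old"


# ---------------------------------------------------------------------------
# nested insertions


@dataclass(frozen=True)
class NestedPair:
    parent_id: str
    child_id: str
    consistent: bool = True


def detect_nested(
    elements: list[LTRElement], age_tolerance: float = 0.1
) -> list[NestedPair]:
    """Containment-based nested insertion events on one chromosome.

    (parent, child) is emitted iff the child's span lies strictly inside
    the parent's span; chains yield one pair per containing ancestor.  A
    pair is flagged inconsistent when the child is dated older than the
    parent by more than ``age_tolerance`` MYA (insertion into an element
    that did not exist yet).
    """
    out = []
    srt = sorted(elements, key=lambda e: (e.start, -e.end))
    for i, parent in enumerate(srt):
        for child in srt[i + 1 :]:
            if child.start >= parent.end:
                break
            if parent.start < child.start and child.end < parent.end:
                consistent = True
                pa = parent.age_mya if parent.age_mya is not None else parent.true_age_mya
                ca = child.age_mya if child.age_mya is not None else child.true_age_mya
                if pa is not None and ca is not None and ca > pa + age_tolerance:
                    consistent = False
                out.append(NestedPair(parent.id, child.id, consistent))
    return out


# ---------------------------------------------------------------------------
# composition tables


def composition_table(
    elements: list[LTRElement],
    region_list: list[_regions.RegionAnnotation],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts and ages per (compartment x family) and (compartment x superfamily).

    Returns two DataFrames.  The superfamily table carries percentages that
    sum to 100 within each compartment; both carry mean and median ages of
    the reliably dated elements (true ages are never used here).
    """
    labels = _regions.assign_compartments(region_list, elements)
    rows = []
    for e, lab in zip(elements, labels):
        rows.append(
            {
                "compartment": lab,
                "family": e.family,
                "superfamily": e.superfamily,
                "age_mya": e.age_mya if e.age_reliable else np.nan,
            }
        )
    df = pd.DataFrame(
        rows, columns=["compartment", "family", "superfamily", "age_mya"]
    )
    if df.empty:
        empty = pd.DataFrame(
            columns=["compartment", "family", "count", "mean_age_mya", "median_age_mya"]
        )
        return empty, empty.rename(columns={"family": "superfamily"})
    fam = (
        df.groupby(["compartment", "family"], as_index=False)
        .agg(count=("family", "size"), mean_age_mya=("age_mya", "mean"),
             median_age_mya=("age_mya", "median"))
    )
    sup = (
        df.groupby(["compartment", "superfamily"], as_index=False)
        .agg(count=("superfamily", "size"), mean_age_mya=("age_mya", "mean"),
             median_age_mya=("age_mya", "median"))
    )
    totals = sup.groupby("compartment")["count"].transform("sum")
    sup["percent"] = 100.0 * sup["count"] / totals
    return fam, sup


# ---------------------------------------------------------------------------
# simplified structural LTR finder (synthetic data only)


def find_ltr_structural(
    seq: str,
    chrom: str = "chr",
    k: int = 15,
    min_ltr: int = 200,
    max_ltr: int = 3000,
    min_separation: int = 1000,
    max_separation: int = 20_000,
    max_kmer_freq: int = 32,
    min_seeds: int = 5,
    mask_intervals=None,
    id_prefix: str = "denovoLTR",
) -> list[LTRElement]:
    """Annotation-free LTR element detection for simulated chromosomes.

    A deliberately simple repeat-pair search: exact k-mer self-matches at a
    plausible LTR separation are clustered by diagonal; a cluster whose
    matched region looks like an LTR pair (bounded length, non-overlapping
    copies) becomes an element.  k-mers occurring more than
    ``max_kmer_freq`` times are dropped first, which removes homogeneous
    satellite arrays (whose units recur thousands of times) from
    consideration; diverged array copies can still mimic LTR pairs, so
    ``mask_intervals`` (e.g. satellite probe hits) should be supplied
    whenever they are available — candidates with more than half of either
    copy inside the mask are discarded.  This is NOT equivalent to a
    structural annotator such as LTR_retriever and exists only so the
    pipeline can run on synthetic genomes without a GFF3 input.
    """
    from .align import _kmer_codes

    codes = encode(seq.upper())
    kc, ok = _kmer_codes(codes, k)
    pos = np.nonzero(ok)[0]
    kc = kc[pos]
    order = np.argsort(kc, kind="stable")
    kc_s, pos_s = kc[order], pos[order]
    uniq, start, counts = np.unique(kc_s, return_index=True, return_counts=True)
    keep_unique = counts <= max_kmer_freq
    # all (qpos, tpos) self-match pairs among kept k-mers
    q_list, t_list = [], []
    for u0, c in zip(start[keep_unique], counts[keep_unique]):
        if c < 2:
            continue
        group = np.sort(pos_s[u0 : u0 + c])
        qq, tt = np.meshgrid(group, group, indexing="ij")
        sel = tt > qq
        q_list.append(qq[sel])
        t_list.append(tt[sel])
    if not q_list:
        return []
    qpos = np.concatenate(q_list)
    tpos = np.concatenate(t_list)
    d = tpos - qpos
    sel = (d >= min_separation) & (d <= max_separation)
    qpos, tpos, d = qpos[sel], tpos[sel], d[sel]
    if qpos.size == 0:
        return []
    order = np.lexsort((tpos, d))
    d, qpos, tpos = d[order], qpos[order], tpos[order]
    breaks = np.nonzero((np.diff(d) > 30) | (np.diff(qpos) > max_ltr))[0]
    bounds = np.concatenate(([0], breaks + 1, [d.size]))
    candidates = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e - s < min_seeds:
            continue
        q0, q1 = int(qpos[s:e].min()), int(qpos[s:e].max()) + k
        t0, t1 = int(tpos[s:e].min()), int(tpos[s:e].max()) + k
        ltr_len = max(q1 - q0, t1 - t0)
        if ltr_len < min_ltr or ltr_len > max_ltr:
            continue
        if t0 <= q1:  # overlapping copies: tandem repeat, not an LTR pair
            continue
        candidates.append((t1 - q0, -(e - s), q0, q1, t0, t1))
    if mask_intervals is not None:
        from .probes import covered_bp, merge_intervals

        mask = merge_intervals(mask_intervals)
        candidates = [
            c
            for c in candidates
            if covered_bp(mask, c[2], c[3]) <= 0.5 * (c[3] - c[2])
            and covered_bp(mask, c[4], c[5]) <= 0.5 * (c[5] - c[4])
        ]
    # shortest span first: a true LTR pair is the minimal repeat structure,
    # while cross-element matches span two elements and lose on conflict
    candidates.sort()
    accepted: list[tuple[int, int]] = []
    elements = []
    for _span, _negseeds, q0, q1, t0, t1 in candidates:
        span = (q0, t1)
        if _conflicts(span, accepted):
            continue
        accepted.append(span)
        elements.append(
            LTRElement(
                id=f"{id_prefix}_{len(elements):04d}",
                chrom=chrom,
                start=q0,
                end=t1,
                ltr5_start=q0,
                ltr5_end=q1,
                ltr3_start=t0,
                ltr3_end=t1,
            )
        )
    elements.sort(key=lambda e: e.start)
    return elements


def _conflicts(span: tuple[int, int], accepted: list[tuple[int, int]]) -> bool:
    """True when span partially overlaps an accepted span (strict nesting is fine)."""
    s, e = span
    for a0, a1 in accepted:
        if e <= a0 or s >= a1:
            continue
        if (a0 < s and e < a1) or (s < a0 and a1 < e):
            continue
        return True
    return False


def elements_to_frame(elements: list[LTRElement]) -> pd.DataFrame:
    """Flat table of elements (the TSV the pipeline writes)."""
    return pd.DataFrame(
        [
            {
                "id": e.id,
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "ltr5_start": e.ltr5_start,
                "ltr5_end": e.ltr5_end,
                "ltr3_start": e.ltr3_start,
                "ltr3_end": e.ltr3_end,
                "family": e.family,
                "superfamily": e.superfamily,
                "parent_id": e.parent_id or "",
                "p_obs": e.p_obs,
                "K": e.K,
                "age_mya": e.age_mya,
                "age_class": e.age_class or "",
                "age_reliable": e.age_reliable,
                "true_age_mya": e.true_age_mya,
            }
            for e in elements
        ]
    )
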