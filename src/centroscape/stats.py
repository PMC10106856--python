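"""Compartment-level statistics and age contrasts.

Ages are contrasted between compartments with a two-sided Welch (unequal
variance) t-test by default; a pooled-variance option exists.  No multiple
testing correction is applied across the small fixed set of compartment
contrasts; report footnotes state this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import regions as _regions
from .ltr import LTRElement
from .probes import merge_intervals


def coverage_fraction(region_intervals, feature_intervals) -> float:
    """Fraction of the regions' base pairs covered by the features.

    Overlapping features are merged before intersecting; regions are
    treated as a union as well.  Raises on an empty region set.
    """
    regions = merge_intervals(_as_intervals(region_intervals))
    if regions.shape[0] == 0:
        raise ValueError("empty region set")
    features = merge_intervals(_as_intervals(feature_intervals))
    region_bp = int((regions[:, 1] - regions[:, 0]).sum())
    if features.shape[0] == 0:
        return 0.0
    covered = 0
    for s, e in regions:
        cs = np.clip(features[:, 0], s, e)
        ce = np.clip(features[:, 1], s, e)
        covered += int(np.maximum(0, ce - cs).sum())
    return covered / region_bp


def _as_intervals(items):
    out = []
    for it in items:
        if hasattr(it, "start") and hasattr(it, "end"):
            out.append((int(it.start), int(it.end)))
        else:
            out.append((int(it[0]), int(it[1])))
    return out


@dataclass
class ContrastResult:
    group_a: str
    group_b: str
    t: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def age_contrast(
    ages_a,
    ages_b,
    equal_var: bool = False,
    group_a: str = "a",
    group_b: str = "b",
) -> ContrastResult:
    """Two-sided t-test between two age samples (Welch by default).

    When both groups have zero variance and equal means the test is
    degenerate; p = 1 and t = 0 by convention.
    """
    a = np.asarray(list(ages_a), dtype=float)
    b = np.asarray(list(ages_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite ages")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    return ContrastResult(group_a, group_b, t, p, float(a.mean()), float(b.mean()),
                          a.size, b.size)


@dataclass
class CompartmentStats:
    """Per-compartment summary table plus pairwise age contrasts."""

    table: pd.DataFrame
    contrasts: list[ContrastResult] = field(default_factory=list)
    footnotes: tuple[str, ...] = (
        "two-sided Welch t-test; no multiple-testing correction across contrasts",
    )


def compartment_stats(
    elements: list[LTRElement],
    region_list: list[_regions.RegionAnnotation],
    chrom_lengths: dict[str, int] | None = None,
    satellite_hits=None,
    young_threshold: float = 0.5,
    equal_var: bool = False,
    include_whole_genome: bool = True,
) -> CompartmentStats:
    """Element counts, ages, superfamily shares and coverages per compartment."""
    labels = _regions.assign_compartments(region_list, elements)
    groups: dict[str, list[LTRElement]] = {}
    for e, lab in zip(elements, labels):
        groups.setdefault(lab, []).append(e)
    if include_whole_genome:
        groups["whole_genome"] = list(elements)

    region_ivs: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for r in region_list:
        region_ivs.setdefault(r.role, {}).setdefault(r.chrom, []).append(
            (r.start, r.end)
        )
    if chrom_lengths:
        region_ivs["whole_genome"] = {
            c: [(0, n)] for c, n in chrom_lengths.items()
        }

    sat_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if satellite_hits is not None:
        for h in satellite_hits:
            sat_by_chrom.setdefault(h.chrom, []).append((h.start, h.end))

    rows = []
    for comp, elems in sorted(groups.items()):
        ages = np.array(
            [e.age_mya for e in elems if e.age_reliable and e.age_mya is not None]
        )
        sup = pd.Series([e.superfamily for e in elems])
        n = len(elems)
        row = {
            "compartment": comp,
            "n_elements": n,
            "mean_age_mya": float(ages.mean()) if ages.size else np.nan,
            "median_age_mya": float(np.median(ages)) if ages.size else np.nan,
            "young_fraction": float((ages <= young_threshold).mean()) if ages.size else np.nan,
            "copia_percent": 100.0 * float((sup == "Copia").mean()) if n else np.nan,
            "gypsy_percent": 100.0 * float((sup == "Gypsy").mean()) if n else np.nan,
        }
        ivs = region_ivs.get(comp)
        if ivs:
            te_cov = sat_cov = reg_bp = 0
            for chrom, intervals in ivs.items():
                merged_r = merge_intervals(intervals)
                reg_bp += int((merged_r[:, 1] - merged_r[:, 0]).sum())
                te_iv = [
                    (e.start, e.end) for e in elements if e.chrom == chrom
                ]
                te_cov += _covered(merged_r, te_iv)
                sat_cov += _covered(merged_r, sat_by_chrom.get(chrom, []))
            row["te_covered_fraction"] = te_cov / reg_bp if reg_bp else np.nan
            row["satellite_covered_fraction"] = (
                sat_cov / reg_bp if (reg_bp and satellite_hits is not None) else np.nan
            )
        else:
            row["te_covered_fraction"] = np.nan
            row["satellite_covered_fraction"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)

    contrasts = []
    age_by_comp = {
        comp: np.array(
            [e.age_mya for e in elems if e.age_reliable and e.age_mya is not None]
        )
        for comp, elems in groups.items()
    }
    for a, b in combinations(sorted(age_by_comp), 2):
        if age_by_comp[a].size >= 2 and age_by_comp[b].size >= 2:
            contrasts.append(
                age_contrast(
                    age_by_comp[a], age_by_comp[b], equal_var=equal_var,
                    group_a=a, group_b=b,
                )
            )
    return CompartmentStats(table=table, contrasts=contrasts)


def _covered(merged_regions: np.ndarray, feature_intervals) -> int:
    feats = merge_intervals(feature_intervals)
    if feats.shape[0] == 0:
        return 0
    total = 0
    for s, e in merged_regions:
        cs = np.clip(feats[:, 0], s, e)
        ce = np.clip(feats[:, 1], s, e)
        total += int(np.maximum(0, ce - cs).sum())
    return total
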