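"""Synthetic chromosome simulator with planted ground truth.

A simulated chromosome follows the canonical layout
telomere - arm - pericentromere - centromere - pericentromere - arm - telomere.
Arms are i.i.d. background at a configured GC content; the centromere and
pericentromere carry head-to-tail satellite arrays of role-specific
monomers (each copy lightly mutated), full-length LTR retrotransposon
insertions with compartment-specific age distributions (young in the
centromere, old in the pericentromere), optional nested insertions, and an
optional hidden repeat unit dispersed through the pericentromere and
embedded in a subset of the pericentromeric elements.

Mutation is substitution-only under a Jukes-Cantor process: applying
``mutate_sequence`` with divergence K to each of two copies of a template
yields an expected observed pairwise mismatch fraction of
(3/4)(1 - exp(-4*(2K)/3)), which is exactly what the dating step inverts.
Everything is driven by one seeded generator, so a fixed SimConfig gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .ltr import LTRElement, superfamily_of
from .probes import TELOMERE_MOTIF, default_probe_set

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class HiddenRepeatConfig:
    """A planted novel repeat: unit length, free copies in the
    pericentromere, and how many pericentromeric elements embed it."""

    length: int = 630
    peri_copies: int = 1200
    element_embeddings: int = 60
    copy_divergence: float = 0.02  # K applied to every planted copy


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated chromosome.

    Spans are in bp; ages in MYA; ``mu`` in substitutions/site/year.  Age
    distributions are truncated normals bounded below at 0 with the
    centromere young (mean 0.14 MYA) and the pericentromere old
    (mean 0.51 MYA).
    """

    chromosome_length: int = 3_000_000
    cent_span: int = 500_000
    peri_spans: tuple[int, int] = (400_000, 400_000)
    telomere_span: int = 5_000
    arm_gc: float = 0.36
    telomere_motif: str = TELOMERE_MOTIF
    telomeres: tuple[bool, bool] = (True, True)
    satellite_divergence: float = 0.02  # K per satellite copy
    n_ltr_per_compartment: dict = field(
        default_factory=lambda: {
            "centromere": {"ALE": 10, "CRM": 6, "Angela": 2},
            "pericentromere": {"Tekay": 8, "Retand": 6, "Athila": 4},
            "arm": {"ALE": 2, "Athila": 2},
        }
    )
    age_distribution: dict = field(
        default_factory=lambda: {
            "centromere": (0.14, 0.15),
            "pericentromere": (0.51, 0.35),
            "arm": (0.32, 0.30),
        }
    )
    mu: float = 1.5e-8
    nested_fraction: float = 0.1
    ltr_length: int = 1000
    internal_length: int = 3000
    hidden_repeat: HiddenRepeatConfig | None = None
    seed: int = 0

    def validate(self) -> None:
        fixed = (
            2 * self.telomere_span + sum(self.peri_spans) + self.cent_span
        )
        if fixed > self.chromosome_length:
            raise ValueError(
                f"spans ({fixed} bp) exceed chromosome length "
                f"{self.chromosome_length}"
            )
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        for comp, (mean, sd) in self.age_distribution.items():
            if mean < 0 or sd <= 0:
                raise ValueError(f"bad age distribution for {comp}: {(mean, sd)}")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated chromosome."""

    chrom: str
    regions: dict[str, list[tuple[int, int]]]
    elements: list[LTRElement]
    hidden_repeat: str | None = None
    hidden_copies: list[tuple[int, int]] = field(default_factory=list)
    probe_copy_counts: dict[str, int] = field(default_factory=dict)
    config: SimConfig | None = None

    def region(self, role: str) -> list[tuple[int, int]]:
        return self.regions.get(role, [])


# ---------------------------------------------------------------------------
# sequence-level operations


def _require_acgt(arr: np.ndarray, what: str) -> None:
    ok = (arr == 65) | (arr == 67) | (arr == 71) | (arr == 84)
    if not ok.all():
        bad = chr(int(arr[~ok][0]))
        raise ValueError(f"non-ACGT character {bad!r} in {what}")


def mutate_array(arr: np.ndarray, K: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor substitutions at divergence K on a uint8 ASCII array."""
    if K < 0:
        raise ValueError("K must be nonnegative")
    _require_acgt(arr, "sequence to mutate")
    if K == 0:
        return arr.copy()
    p = 0.75 * (1.0 - np.exp(-4.0 * K / 3.0))
    out = arr.copy()
    sites = np.nonzero(rng.random(arr.size) < p)[0]
    if sites.size:
        code = np.zeros(256, dtype=np.uint8)
        code[65], code[67], code[71], code[84] = 0, 1, 2, 3
        old = code[out[sites]]
        new = (old + 1 + rng.integers(0, 3, sites.size, dtype=np.uint8)) % 4
        out[sites] = _BASES[new]
    return out


def mutate_sequence(seq: str, K: float, seed: int | np.random.Generator) -> str:
    """Substitution-only JC69 mutation of a nucleotide string.

    The expected observed mismatch fraction against the input is
    (3/4)(1 - exp(-4K/3)); no indels are introduced, so the output has the
    same length.  Non-ACGT characters are rejected.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return mutate_array(arr, K, rng).tobytes().decode("ascii")


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


_TRUNC_LOC_CACHE: dict[tuple[float, float], float] = {}


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Zero-truncated normal draws whose realised mean equals ``mean``.

    Truncating N(mean, sd) at zero would inflate the mean, so the location
    parameter is solved (monotone in the truncated mean) such that the
    distribution actually averages to the configured compartment age.
    """
    key = (mean, sd)
    if key not in _TRUNC_LOC_CACHE:
        from scipy.optimize import brentq

        def realised_mean(loc):
            return sps.truncnorm.mean((0.0 - loc) / sd, np.inf, loc=loc, scale=sd)

        _TRUNC_LOC_CACHE[key] = brentq(
            lambda loc: realised_mean(loc) - mean, mean - 50 * sd, mean + sd
        )
    loc = _TRUNC_LOC_CACHE[key]
    a = (0.0 - loc) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=loc, scale=sd, size=n, random_state=rng)


# ---------------------------------------------------------------------------
# LTR element construction


@dataclass
class _FamilyTemplate:
    ltr: np.ndarray
    internal: np.ndarray


def _family_template(rng: np.random.Generator, ltr_len: int, internal_len: int):
    ltr = _random_seq(rng, ltr_len)
    ltr[0:2] = np.frombuffer(b"TG", dtype=np.uint8)
    ltr[-2:] = np.frombuffer(b"CA", dtype=np.uint8)
    return _FamilyTemplate(ltr=ltr, internal=_random_seq(rng, internal_len))


@dataclass(eq=False)
class _BuiltElement:
    """An element sequence plus feature offsets relative to its own start."""

    seq: np.ndarray
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    family: str
    true_age_mya: float
    children: list["_BuiltElement"] = field(default_factory=list)
    child_offsets: list[int] = field(default_factory=list)
    embedded_unit: tuple[int, int] | None = None


def _build_element(
    template: _FamilyTemplate,
    family: str,
    true_age_mya: float,
    mu: float,
    rng: np.random.Generator,
    embed: np.ndarray | None = None,
) -> _BuiltElement:
    K = mu * true_age_mya * 1e6  # per-branch divergence since insertion
    ltr5 = mutate_array(template.ltr, K, rng)
    ltr3 = mutate_array(template.ltr, K, rng)
    internal = mutate_array(template.internal, K, rng)
    embedded = None
    if embed is not None:
        off = int(rng.integers(50, max(51, internal.size - embed.size - 50)))
        internal = np.concatenate([internal[:off], embed, internal[off:]])
        embedded = (ltr5.size + off, ltr5.size + off + embed.size)
    seq = np.concatenate([ltr5, internal, ltr3])
    return _BuiltElement(
        seq=seq,
        ltr5=(0, ltr5.size),
        ltr3=(seq.size - ltr3.size, seq.size),
        family=family,
        true_age_mya=float(true_age_mya),
        embedded_unit=embedded,
    )


def _nest(parent: _BuiltElement, child: _BuiltElement, rng: np.random.Generator):
    """Insert child into parent's internal region, shifting parent features."""
    lo = parent.ltr5[1] + 10
    hi = parent.ltr3[0] - 10
    off = int(rng.integers(lo, hi))
    parent.seq = np.concatenate([parent.seq[:off], child.seq, parent.seq[off:]])
    shift = child.seq.size
    parent.ltr3 = (parent.ltr3[0] + shift, parent.ltr3[1] + shift)
    if parent.embedded_unit is not None and parent.embedded_unit[0] >= off:
        parent.embedded_unit = (
            parent.embedded_unit[0] + shift,
            parent.embedded_unit[1] + shift,
        )
    for i, o in enumerate(parent.child_offsets):
        if o >= off:
            parent.child_offsets[i] = o + shift
    parent.children.append(child)
    parent.child_offsets.append(off)


def plant_ltr(
    genome: str,
    family: str,
    true_age_mya: float,
    position: int,
    mu: float = 1.5e-8,
    seed: int | np.random.Generator = 0,
    ltr_length: int = 1000,
    internal_length: int = 3000,
    chrom: str = "chr",
) -> tuple[str, LTRElement]:
    """Insert one aged LTR element at ``position`` and return the truth record.

    The element's two LTR copies start identical and are each mutated with
    per-branch divergence K = mu * age_years, so their expected pairwise
    divergence is 2 mu T — the exact inverse of the dating step.
    """
    if not 0 <= position <= len(genome):
        raise ValueError(f"position {position} outside genome of {len(genome)} bp")
    if true_age_mya < 0:
        raise ValueError("age must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    template = _family_template(rng, ltr_length, internal_length)
    built = _build_element(template, family, true_age_mya, mu, rng)
    new = genome[:position] + built.seq.tobytes().decode("ascii") + genome[position:]
    element = LTRElement(
        id="planted_0",
        chrom=chrom,
        start=position,
        end=position + built.seq.size,
        ltr5_start=position + built.ltr5[0],
        ltr5_end=position + built.ltr5[1],
        ltr3_start=position + built.ltr3[0],
        ltr3_end=position + built.ltr3[1],
        family=family,
        superfamily=superfamily_of(family),
        true_age_mya=float(true_age_mya),
    )
    return new, element


# ---------------------------------------------------------------------------
# compartment assembly


def _satellite_filler(
    monomers: list[np.ndarray],
    length: int,
    divergence: float,
    rng: np.random.Generator,
    copy_counter: dict[str, int] | None = None,
    monomer_ids: list[str] | None = None,
) -> np.ndarray:
    """Head-to-tail satellite arrays filling exactly ``length`` bp.

    The filler alternates between blocks of the provided monomers; each
    copy is independently mutated at the configured divergence.
    """
    if length <= 0:
        return np.empty(0, dtype=np.uint8)
    parts = []
    total = 0
    mi = int(rng.integers(0, len(monomers)))
    while total < length:
        monomer = monomers[mi]
        block_copies = int(rng.integers(50, 200))
        for _ in range(block_copies):
            if total >= length:
                break
            copy = mutate_array(monomer, divergence, rng)
            take = min(copy.size, length - total)
            parts.append(copy[:take])
            total += take
            if copy_counter is not None and monomer_ids is not None:
                copy_counter[monomer_ids[mi]] = copy_counter.get(monomer_ids[mi], 0) + 1
        mi = (mi + 1) % len(monomers)
    return np.concatenate(parts)


def _assemble_compartment(
    span: int,
    items: list[tuple[str, np.ndarray, object]],
    filler_fn,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[str, int, object]]]:
    """Distribute items through satellite filler to exactly ``span`` bp.

    Returns the compartment sequence and (kind, offset, payload) records
    giving each item's offset within the compartment.
    """
    item_total = sum(seq.size for _, seq, _ in items)
    filler_len = span - item_total
    if filler_len < 0:
        raise ValueError(
            f"compartment span {span} too small for {item_total} bp of items"
        )
    filler = filler_fn(filler_len)
    order = rng.permutation(len(items))
    cuts = np.sort(rng.integers(0, filler_len + 1, size=len(items)))
    parts = []
    placed = []
    prev = 0
    pos = 0
    for idx, cut in zip(order, cuts):
        cut = int(cut)
        parts.append(filler[prev:cut])
        pos += cut - prev
        kind, seq, payload = items[int(idx)]
        placed.append((kind, pos, payload))
        parts.append(seq)
        pos += seq.size
        prev = cut
    parts.append(filler[prev:])
    out = np.concatenate(parts) if parts else np.empty(0, np.uint8)
    return out, placed


# ---------------------------------------------------------------------------
# the simulator


def simulate_chromosome(config: SimConfig, chrom: str = "chrS1"):
    """Simulate one chromosome; returns (sequence string, SyntheticTruth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    probe_set = default_probe_set()
    cent_monomers = [
        np.frombuffer(p.sequence.encode(), np.uint8) for p in probe_set.by_role("centromeric")
    ]
    cent_ids = [p.id for p in probe_set.by_role("centromeric")]
    peri_monomers = [
        np.frombuffer(p.sequence.encode(), np.uint8) for p in probe_set.by_role("pericentromeric")
    ]
    peri_ids = [p.id for p in probe_set.by_role("pericentromeric")]

    arm_total = (
        config.chromosome_length
        - 2 * config.telomere_span
        - sum(config.peri_spans)
        - config.cent_span
    )
    arm_spans = (arm_total - arm_total // 2, arm_total // 2)

    templates: dict[str, _FamilyTemplate] = {}
    copy_counts: dict[str, int] = {}

    hidden_unit = None
    if config.hidden_repeat is not None:
        hidden_unit = _random_seq(rng, config.hidden_repeat.length)

    def _elements_for(compartment: str, n_embed: int = 0) -> list[_BuiltElement]:
        fams = config.n_ltr_per_compartment.get(compartment, {})
        mean, sd = config.age_distribution.get(compartment, (0.3, 0.3))
        built: list[_BuiltElement] = []
        fam_list = [f for f, n in sorted(fams.items()) for _ in range(n)]
        if not fam_list:
            return built
        ages = _truncnorm(rng, mean, sd, len(fam_list))
        embed_flags = np.zeros(len(fam_list), dtype=bool)
        if n_embed:
            if n_embed > len(fam_list):
                raise ValueError(
                    f"{n_embed} embeddings requested but only "
                    f"{len(fam_list)} {compartment} elements"
                )
            embed_flags[rng.choice(len(fam_list), n_embed, replace=False)] = True
        for fam, age, do_embed in zip(fam_list, ages, embed_flags):
            if fam not in templates:
                templates[fam] = _family_template(
                    rng, config.ltr_length, config.internal_length
                )
            embed = None
            if do_embed and hidden_unit is not None:
                embed = mutate_array(
                    hidden_unit, config.hidden_repeat.copy_divergence, rng
                )
            built.append(
                _build_element(templates[fam], fam, float(age), config.mu, rng, embed)
            )
        # nesting: a fraction of elements are re-inserted inside another
        n_nest = int(round(config.nested_fraction * len(built)))
        for _ in range(n_nest):
            if len(built) < 2:
                break
            ci = int(rng.integers(0, len(built)))
            child = built[ci]
            hosts = [
                j
                for j, b in enumerate(built)
                if j != ci and b.true_age_mya >= child.true_age_mya
                and child not in b.children
            ]
            if not hosts:
                continue
            parent = built[int(rng.choice(hosts))]
            built.pop(ci)
            _nest(parent, child, rng)
        return built

    def _compartment_items(compartment: str, n_embed: int = 0, n_hidden: int = 0):
        items = [("element", b.seq, b) for b in _elements_for(compartment, n_embed)]
        for _ in range(n_hidden):
            copy = mutate_array(
                hidden_unit, config.hidden_repeat.copy_divergence, rng
            )
            items.append(("hidden", copy, None))
        return items

    def _cent_filler(n):
        return _satellite_filler(
            cent_monomers, n, config.satellite_divergence, rng, copy_counts, cent_ids
        )

    def _peri_filler(n):
        return _satellite_filler(
            peri_monomers, n, config.satellite_divergence, rng, copy_counts, peri_ids
        )

    # distribute pericentromeric element/hidden budgets between the two flanks
    peri_fams = config.n_ltr_per_compartment.get("pericentromere", {})
    n_peri_elem = sum(peri_fams.values())
    hr = config.hidden_repeat
    n_embed_total = hr.element_embeddings if hr else 0
    n_hidden_total = hr.peri_copies if hr else 0
    if hr and n_embed_total > n_peri_elem:
        raise ValueError("more embeddings requested than pericentromeric elements")

    # build both pericentromere item lists from one shared element pool
    peri_built = _elements_for("pericentromere", n_embed_total)
    rng.shuffle(peri_built)
    half = len(peri_built) // 2
    peri_parts_items = []
    for side, side_built in enumerate((peri_built[:half], peri_built[half:])):
        items = [("element", b.seq, b) for b in side_built]
        n_hidden_side = n_hidden_total // 2 if side == 0 else n_hidden_total - n_hidden_total // 2
        for _ in range(n_hidden_side):
            copy = mutate_array(hidden_unit, hr.copy_divergence, rng)
            items.append(("hidden", copy, None))
        peri_parts_items.append(items)

    cent_items = _compartment_items("centromere")
    arm_built = _elements_for("arm")
    arm_half = len(arm_built) // 2
    arm_items = (
        [("element", b.seq, b) for b in arm_built[:arm_half]],
        [("element", b.seq, b) for b in arm_built[arm_half:]],
    )

    def _telomere(present: bool) -> np.ndarray:
        if not present:
            return _random_seq(rng, config.telomere_span, config.arm_gc)
        motif = np.frombuffer(config.telomere_motif.encode(), np.uint8)
        reps = config.telomere_span // motif.size + 1
        return np.tile(motif, reps)[: config.telomere_span]

    def _arm(span: int, items) -> tuple[np.ndarray, list]:
        return _assemble_compartment(
            span, items, lambda n: _random_seq(rng, n, config.arm_gc), rng
        )

    segments = []
    regions: dict[str, list[tuple[int, int]]] = {
        "telomere": [],
        "arm": [],
        "pericentromere": [],
        "centromere": [],
    }
    elements: list[LTRElement] = []
    hidden_copies: list[tuple[int, int]] = []
    eid = [0]

    def _record_element(b: _BuiltElement, abs_start: int, parent_id: str | None):
        this_id = f"sim_ltr_{eid[0]:04d}"
        eid[0] += 1
        elements.append(
            LTRElement(
                id=this_id,
                chrom=chrom,
                start=abs_start,
                end=abs_start + b.seq.size,
                ltr5_start=abs_start + b.ltr5[0],
                ltr5_end=abs_start + b.ltr5[1],
                ltr3_start=abs_start + b.ltr3[0],
                ltr3_end=abs_start + b.ltr3[1],
                family=b.family,
                superfamily=superfamily_of(b.family),
                parent_id=parent_id,
                true_age_mya=b.true_age_mya,
            )
        )
        if b.embedded_unit is not None:
            hidden_copies.append(
                (abs_start + b.embedded_unit[0], abs_start + b.embedded_unit[1])
            )
        for child, off in zip(b.children, b.child_offsets):
            _record_element(child, abs_start + off, this_id)

    pos = 0

    def _push(seq: np.ndarray, role: str, placed=None):
        nonlocal pos
        start = pos
        segments.append(seq)
        pos += seq.size
        regions[role].append((start, start + seq.size))
        if placed:
            for kind, off, payload in placed:
                if kind == "element":
                    _record_element(payload, start + off, None)
                else:
                    hidden_len = (
                        config.hidden_repeat.length if config.hidden_repeat else 0
                    )
                    hidden_copies.append((start + off, start + off + hidden_len))

    _push(_telomere(config.telomeres[0]), "telomere")
    seq, placed = _arm(arm_spans[0], arm_items[0])
    _push(seq, "arm", placed)
    seq, placed = _assemble_compartment(
        config.peri_spans[0], peri_parts_items[0], _peri_filler, rng
    )
    _push(seq, "pericentromere", placed)
    seq, placed = _assemble_compartment(config.cent_span, cent_items, _cent_filler, rng)
    _push(seq, "centromere", placed)
    seq, placed = _assemble_compartment(
        config.peri_spans[1], peri_parts_items[1], _peri_filler, rng
    )
    _push(seq, "pericentromere", placed)
    seq, placed = _arm(arm_spans[1], arm_items[1])
    _push(seq, "arm", placed)
    _push(_telomere(config.telomeres[1]), "telomere")

    genome = np.concatenate(segments).tobytes().decode("ascii")
    elements.sort(key=lambda e: (e.start, e.end))
    truth = SyntheticTruth(
        chrom=chrom,
        regions=regions,
        elements=elements,
        hidden_repeat=hidden_unit.tobytes().decode("ascii") if hidden_unit is not None else None,
        hidden_copies=sorted(hidden_copies),
        probe_copy_counts=copy_counts,
        config=config,
    )
    return genome, truth


def simulate_genome(
    base_config: SimConfig, n_chromosomes: int, seed: int | None = None
) -> tuple[dict[str, str], dict[str, SyntheticTruth]]:
    """Simulate several chromosomes with per-chromosome derived seeds."""
    base_seed = base_config.seed if seed is None else seed
    genome = {}
    truths = {}
    for i in range(n_chromosomes):
        cfg = replace(base_config, seed=(base_seed * 1_000_003 + i) % (2**31 - 1))
        name = f"chrS{i + 1}"
        seq, truth = simulate_chromosome(cfg, chrom=name)
        genome[name] = seq
        truths[name] = truth
    return genome, truths


def discovery_sim_config(seed: int, hidden: bool = True) -> SimConfig:
    """Study conditions for repeat-discovery runs.

    A pericentromere-heavy chromosome: 70 pericentromeric elements across
    three families (each family well below the self-occurrence cutoff) and,
    when ``hidden`` is set, one hidden repeat unit embedded in 60 elements
    with 1200 free copies dispersed through the pericentromere.
    """
    return SimConfig(
        chromosome_length=2_600_000,
        cent_span=300_000,
        peri_spans=(600_000, 600_000),
        n_ltr_per_compartment={
            "centromere": {"ALE": 4, "CRM": 3},
            "pericentromere": {"Tekay": 25, "Retand": 25, "Athila": 20},
            "arm": {},
        },
        nested_fraction=0.0,
        hidden_repeat=HiddenRepeatConfig() if hidden else None,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# truth serialisation (BED + TSV + FASTA)


def write_truth(truth: SyntheticTruth, prefix: str) -> None:
    """Write regions as BED, elements as TSV + GFF3, hidden repeat as FASTA."""
    from .ltr import elements_to_frame, write_ltr_annotations

    write_ltr_annotations(truth.elements, f"{prefix}.elements.gff3")
    with open(f"{prefix}.regions.bed", "w") as fh:
        for role, ivs in truth.regions.items():
            for s, e in ivs:
                fh.write(f"{truth.chrom}\t{s}\t{e}\t{role}\n")
    elements_to_frame(truth.elements).to_csv(
        f"{prefix}.elements.tsv", sep="\t", index=False
    )
    if truth.hidden_repeat is not None:
        with open(f"{prefix}.hidden_repeat.fasta", "w") as fh:
            fh.write(f">hidden_repeat length={len(truth.hidden_repeat)}\n")
            fh.write(truth.hidden_repeat + "\n")
        with open(f"{prefix}.hidden_copies.bed", "w") as fh:
            for s, e in truth.hidden_copies:
                fh.write(f"{truth.chrom}\t{s}\t{e}\thidden_repeat\n")
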