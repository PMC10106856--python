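"""Alignment primitives: distances, global identity, seed-and-extend local alignment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from centroscape.align import (
    BandError,
    PreparedSeq,
    SaturationError,
    Scoring,
    encode,
    global_alignment,
    global_identity,
    jc69_distance,
    k2p_distance,
    local_align,
    revcomp,
)
from centroscape.simulate import mutate_sequence

from _oracles import edit_distance_nw, full_local_gotoh


def _rand(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# substitution-model distances


class TestDistances:
    def test_jc69_zero(self):
        assert jc69_distance(0.0) == 0.0

    def test_jc69_closed_form(self):
        assert jc69_distance(0.10) == pytest.approx(0.107326, abs=1e-6)

    def test_jc69_saturation(self):
        with pytest.raises(SaturationError):
            jc69_distance(0.75)

    def test_k2p_zero(self):
        assert k2p_distance(0.0, 0.0) == 0.0

    def test_k2p_closed_form(self):
        expected = -0.5 * math.log(0.85) - 0.25 * math.log(0.90)
        assert k2p_distance(0.05, 0.05) == pytest.approx(expected, abs=1e-12)
        assert k2p_distance(0.05, 0.05) == pytest.approx(0.10760, abs=1e-4)

    def test_k2p_saturation(self):
        with pytest.raises(SaturationError):
            k2p_distance(0.45, 0.2)

    @given(p=st.floats(min_value=1e-6, max_value=0.74))
    @settings(max_examples=50, deadline=None)
    def test_jc69_exceeds_p_and_increases(self, p):
        k = jc69_distance(p)
        assert k >= p
        assert jc69_distance(p * 0.5) < k

    @given(p=st.floats(min_value=0.0, max_value=0.2))
    @settings(max_examples=30, deadline=None)
    def test_k2p_at_least_jc69_for_transition_bias(self, p):
        # all mismatches being transitions is the most JC69-underestimated case
        assert k2p_distance(p, 0.0) >= jc69_distance(p) - 1e-12


# ---------------------------------------------------------------------------
# global identity


class TestGlobalIdentity:
    def test_identical(self):
        ident, cols = global_identity("ACGTACGTAC" * 20, "ACGTACGTAC" * 20)
        assert ident == 1.0
        assert cols == 200

    def test_expected_identity_after_mutation(self):
        rng = np.random.default_rng(5)
        a = _rand(rng, 20_000)
        b = mutate_sequence(a, 0.05, 6)
        # single-branch K=0.05: expected p = (3/4)(1-exp(-4*0.05/3))
        p = 0.75 * (1 - math.exp(-0.2 / 3))
        sd = math.sqrt(p * (1 - p) / 20_000)
        ident, _ = global_identity(a, b)
        assert ident == pytest.approx(1 - p, abs=3 * sd)

    def test_band_infeasible(self):
        with pytest.raises(BandError):
            global_identity("A" * 100, "A" * 300, band=50)

    def test_gap_columns_counted(self):
        g = global_alignment("AAAATTTT", "AAAA")
        assert g.gap_columns == 4
        assert g.columns == 8
        assert g.identity == pytest.approx(0.5)

    def test_agrees_with_unbanded_dp_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(50, 1000))
            a = _rand(rng, n)
            if rng.random() < 0.5:
                b = mutate_sequence(a, rng.uniform(0, 0.2), int(rng.integers(1 << 30)))
                # also add indels so the oracle check exercises gaps
                cut = int(rng.integers(0, n - 5))
                b = b[:cut] + b[cut + int(rng.integers(0, 5)) :]
            else:
                b = _rand(rng, int(rng.integers(50, 1000)))
            g = global_alignment(a, b)
            dist = g.mismatches + g.gap_columns
            assert dist == edit_distance_nw(a, b)


# ---------------------------------------------------------------------------
# local alignment


class TestLocalAlign:
    def test_exact_substring(self):
        rng = np.random.default_rng(1)
        t = _rand(rng, 10_000)
        q = t[4000:4200]
        hits = local_align(q, t, min_identity=0.9, min_length=50)
        assert len(hits) == 1
        h = hits[0]
        assert (h.tstart, h.tend, h.strand) == (4000, 4200, "+")
        assert h.identity == 1.0
        assert h.aligned_columns == 200

    def test_absent_query_no_hits(self):
        rng = np.random.default_rng(2)
        t = _rand(rng, 10_000)
        q = _rand(rng, 100)
        oracle = full_local_gotoh(encode(q), encode(t), 1, -2, -3, -1)
        hits = local_align(q, t, min_identity=0.9, min_length=50)
        # brute-force oracle confirms no >=90%-identity alignment exists
        if oracle[6] > 0:
            assert oracle[5] / oracle[6] < 0.9 or oracle[6] < 50
        assert hits == []

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT" * 10)
        with pytest.raises(ValueError):
            local_align("ACGT" * 10, "")

    def test_strand_symmetry(self):
        rng = np.random.default_rng(3)
        t = _rand(rng, 5_000)
        q = t[1000:1300]
        fwd = local_align(q, t, min_identity=0.8, min_length=50)
        rev = local_align(revcomp(q), t, min_identity=0.8, min_length=50)
        assert [(h.tstart, h.tend) for h in fwd] == [(h.tstart, h.tend) for h in rev]
        assert {h.strand for h in fwd} == {"+"}
        assert {h.strand for h in rev} == {"-"}
        assert [h.score for h in fwd] == [h.score for h in rev]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle_on_small_instances(self, seed):
        """Planted-homology instances <=2 kb: best hit equals full-matrix DP."""
        rng = np.random.default_rng(1000 + seed)
        for _ in range(8):
            tlen = int(rng.integers(300, 2000))
            qlen = int(rng.integers(80, 300))
            t = _rand(rng, tlen)
            core = _rand(rng, qlen)
            pos = int(rng.integers(0, tlen - qlen))
            t = t[:pos] + core + t[pos + qlen :]
            q = mutate_sequence(core, rng.uniform(0, 0.08), int(rng.integers(1 << 30)))
            hits = local_align(q, t, min_identity=0.5, min_length=30)
            o_score, oqb, oqe, otb, ote, om, oc = full_local_gotoh(
                encode(q), encode(t), 1, -2, -3, -1
            )
            assert hits, "seeded aligner missed a planted >=92%-identity copy"
            best = max(hits, key=lambda h: h.score)
            assert best.score == o_score
            assert (best.qstart, best.qend) == (oqb, oqe)
            assert (best.tstart, best.tend) == (otb, ote)
            assert (best.matches, best.aligned_columns) == (om, oc)

    def test_prepared_sequences_give_same_hits(self):
        rng = np.random.default_rng(9)
        t = _rand(rng, 8_000)
        q = mutate_sequence(t[2000:2400], 0.05, 3)
        plain = local_align(q, t, min_identity=0.8, min_length=50)
        prep = local_align(
            PreparedSeq(q), PreparedSeq(t), min_identity=0.8, min_length=50
        )
        assert [(h.tstart, h.tend, h.score) for h in plain] == [
            (h.tstart, h.tend, h.score) for h in prep
        ]

    def test_n_bases_never_seed_or_match(self):
        t = "ACGT" * 50 + "N" * 100 + "ACGT" * 50
        hits = local_align("N" * 40, t, min_identity=0.5, min_length=20)
        assert hits == []

    def test_scoring_is_configurable(self):
        rng = np.random.default_rng(4)
        t = _rand(rng, 2_000)
        q = t[500:700]
        lenient = local_align(
            q, t, min_identity=0.5, min_length=50, scoring=Scoring(mismatch=-1)
        )
        assert lenient and lenient[0].identity == 1.0
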