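"""Simulator: mutation model calibration, planting, determinism, conservation."""

import math

import numpy as np
import pytest

from centroscape.align import global_alignment
from centroscape.simulate import (
    HiddenRepeatConfig,
    SimConfig,
    mutate_sequence,
    plant_ltr,
    simulate_chromosome,
    simulate_genome,
)


def _rand(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestMutateSequence:
    def test_zero_divergence_identity(self):
        s = "ACGTACGTTTGGCCA"
        assert mutate_sequence(s, 0.0, 1) == s

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            mutate_sequence("ACGTN", 0.1, 1)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            mutate_sequence("ACGT", -0.1, 1)

    def test_same_length_substitutions_only(self):
        rng = np.random.default_rng(0)
        s = _rand(rng, 5_000)
        m = mutate_sequence(s, 0.2, 42)
        assert len(m) == len(s)
        assert set(m) <= set("ACGT")

    def test_observed_mismatch_matches_closed_form(self):
        """K=0.03 on 100 kb: mismatch fraction within 3 sd of JC expectation."""
        rng = np.random.default_rng(1)
        s = _rand(rng, 100_000)
        m = mutate_sequence(s, 0.03, 7)
        p = 0.75 * (1 - math.exp(-0.04))
        sd = math.sqrt(p * (1 - p) / 100_000)
        obs = np.mean(
            np.frombuffer(s.encode(), np.uint8) != np.frombuffer(m.encode(), np.uint8)
        )
        assert obs == pytest.approx(p, abs=3 * sd)

    def test_two_branches_compose_to_double_divergence(self):
        """Two copies mutated at K each diverge as one branch of 2K (JC chain)."""
        rng = np.random.default_rng(2)
        s = _rand(rng, 100_000)
        a = mutate_sequence(s, 0.03, 10)
        b = mutate_sequence(s, 0.03, 11)
        p = 0.75 * (1 - math.exp(-4 * 0.06 / 3))
        sd = math.sqrt(p * (1 - p) / 100_000)
        obs = np.mean(
            np.frombuffer(a.encode(), np.uint8) != np.frombuffer(b.encode(), np.uint8)
        )
        assert obs == pytest.approx(p, abs=3 * sd)


class TestPlantLtr:
    def test_zero_age_gives_identical_ltrs(self):
        rng = np.random.default_rng(3)
        genome = _rand(rng, 10_000)
        new, elem = plant_ltr(genome, "ALE", 0.0, 5_000, seed=4)
        l5 = new[elem.ltr5_start : elem.ltr5_end]
        l3 = new[elem.ltr3_start : elem.ltr3_end]
        assert l5 == l3
        assert elem.superfamily == "Copia"

    def test_expected_pairwise_ltr_divergence(self):
        """age=1 MYA, mu=1.5e-8: pairwise LTR p_obs near (3/4)(1-e^(-0.04))."""
        rng = np.random.default_rng(4)
        genome = _rand(rng, 4_000)
        p_exp = 0.75 * (1 - math.exp(-4 * 0.03 / 3))
        ps = []
        for seed in range(30):
            new, elem = plant_ltr(
                genome, "CRM", 1.0, 2_000, mu=1.5e-8, seed=seed, ltr_length=1_000
            )
            g = global_alignment(
                new[elem.ltr5_start : elem.ltr5_end],
                new[elem.ltr3_start : elem.ltr3_end],
            )
            ps.append(g.p_obs)
        se = math.sqrt(p_exp * (1 - p_exp) / (30 * 1_000))
        assert np.mean(ps) == pytest.approx(p_exp, abs=3 * se)

    def test_insertion_preserves_flanks(self):
        rng = np.random.default_rng(5)
        genome = _rand(rng, 2_000)
        new, elem = plant_ltr(genome, "ALE", 0.2, 700, seed=6)
        assert new[:700] == genome[:700]
        assert new[elem.end :] == genome[700:]
        assert len(new) == len(genome) + (elem.end - elem.start)

    def test_position_out_of_bounds(self):
        with pytest.raises(ValueError):
            plant_ltr("ACGT" * 100, "ALE", 0.1, 5_000)


class TestSimulateChromosome:
    def test_layout_and_conservation(self, default_sim):
        seq, truth = default_sim
        cfg = truth.config
        assert len(seq) == cfg.chromosome_length
        # regions tile the chromosome exactly
        ivs = sorted(iv for ivlist in truth.regions.values() for iv in ivlist)
        assert ivs[0][0] == 0
        assert ivs[-1][1] == cfg.chromosome_length
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 == s2
        cent = truth.regions["centromere"][0]
        assert cent[1] - cent[0] == cfg.cent_span

    def test_determinism_byte_identical(self):
        cfg = SimConfig(
            chromosome_length=400_000, cent_span=100_000, peri_spans=(60_000, 60_000),
            telomere_span=2_000, seed=99,
            n_ltr_per_compartment={"centromere": {"ALE": 2}, "pericentromere": {"Tekay": 2}, "arm": {}},
        )
        s1, t1 = simulate_chromosome(cfg)
        s2, t2 = simulate_chromosome(cfg)
        assert s1 == s2
        assert [(e.id, e.start, e.end, e.true_age_mya) for e in t1.elements] == [
            (e.id, e.start, e.end, e.true_age_mya) for e in t2.elements
        ]

    def test_elements_inside_one_compartment(self, default_sim):
        seq, truth = default_sim
        for e in truth.elements:
            containing = [
                role
                for role, ivs in truth.regions.items()
                for s, t in ivs
                if s <= e.start and e.end <= t
            ]
            assert len(containing) == 1

    def test_nested_children_strictly_inside_parent(self, default_sim):
        _, truth = default_sim
        byid = {e.id: e for e in truth.elements}
        nested = [e for e in truth.elements if e.parent_id]
        assert nested, "default config should plant some nested elements"
        for child in nested:
            parent = byid[child.parent_id]
            assert parent.start < child.start and child.end < parent.end

    def test_infeasible_layout_rejected(self):
        with pytest.raises(ValueError):
            simulate_chromosome(
                SimConfig(chromosome_length=500_000, cent_span=400_000,
                          peri_spans=(100_000, 100_000))
            )

    def test_divergence_calibration_over_many_elements(self):
        """Mean observed LTR-pair divergence tracks 2*mu*T over >=100 elements."""
        rng = np.random.default_rng(6)
        genome = _rand(rng, 4_000)
        t_true = 0.8
        k_pair = 2 * 1.5e-8 * t_true * 1e6
        p_exp = 0.75 * (1 - math.exp(-4 * k_pair / 3))
        ps = []
        for seed in range(100):
            new, elem = plant_ltr(genome, "Tekay", t_true, 2_000, seed=seed)
            g = global_alignment(
                new[elem.ltr5_start : elem.ltr5_end],
                new[elem.ltr3_start : elem.ltr3_end],
            )
            ps.append(g.p_obs)
        se = np.std(ps, ddof=1) / math.sqrt(len(ps))
        assert np.mean(ps) == pytest.approx(p_exp, abs=3 * se)

    def test_hidden_repeat_planting(self):
        cfg = SimConfig(
            chromosome_length=900_000, cent_span=150_000, peri_spans=(250_000, 250_000),
            telomere_span=2_000, seed=13,
            n_ltr_per_compartment={
                "centromere": {"ALE": 2},
                "pericentromere": {"Tekay": 5, "Retand": 5},
                "arm": {},
            },
            hidden_repeat=HiddenRepeatConfig(length=400, peri_copies=50,
                                             element_embeddings=6),
        )
        seq, truth = simulate_chromosome(cfg)
        assert len(truth.hidden_repeat) == 400
        assert len(truth.hidden_copies) == 56  # 50 free + 6 embedded
        peri = truth.regions["pericentromere"]
        for s, e in truth.hidden_copies:
            assert any(ps <= s and e <= pe for ps, pe in peri)

    def test_multi_chromosome_genome(self):
        cfg = SimConfig(
            chromosome_length=300_000, cent_span=80_000, peri_spans=(40_000, 40_000),
            telomere_span=2_000, seed=3,
            n_ltr_per_compartment={"centromere": {"ALE": 1}, "pericentromere": {"Tekay": 1}, "arm": {}},
        )
        genome, truths = simulate_genome(cfg, 3)
        assert set(genome) == {"chrS1", "chrS2", "chrS3"}
        assert genome["chrS1"] != genome["chrS2"]
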