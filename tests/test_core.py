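import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inclufit.core import (
    ACTOR_ROLE,
    CompensationPool,
    ConsanguinitySet,
    Deviation,
    IFModel,
    SpecificationError,
    UndefinedRelatednessError,
    conservation_table,
    effect_curve,
    inclusive_fitness_effect,
    primary_effect,
    relatedness,
    secondary_effect,
)
from inclufit.demography import ClassStructure
from inclufit.interface import reference_effect


def homogeneous_model(delta_i, delta_j, R_ii, R_ij, R_ik, R_im=None):
    """actor + one recipient in a single class with c = u = 1."""
    if R_im is None:
        R_im = R_ik
    return IFModel(
        structure=ClassStructure.homogeneous(),
        actor_class="X",
        deviations=(
            Deviation(ACTOR_ROLE, "X", delta_i, "k"),
            Deviation("j", "X", delta_j, "m"),
        ),
        consanguinity=ConsanguinitySet(R_ii=R_ii, R_to={"j": R_ij}),
        pools={
            "k": CompensationPool("k", "X", R_ik),
            "m": CompensationPool("m", "X", R_im),
        },
    )


def two_class_model(delta_i, delta_j, R_ii, R_ij, w_x, w_y, R_ik=0.0, R_im=0.0):
    """actor in class X, recipient in class Y, with chosen per-capita weights."""
    structure = ClassStructure(("X", "Y"), {"X": 1.0, "Y": 1.0}, {"X": 0.5, "Y": 0.5})
    return IFModel(
        structure=structure,
        actor_class="X",
        deviations=(
            Deviation(ACTOR_ROLE, "X", delta_i, "k", class_weight_override=w_x),
            Deviation("j", "Y", delta_j, "m", class_weight_override=w_y),
        ),
        consanguinity=ConsanguinitySet(R_ii=R_ii, R_to={"j": R_ij}),
        pools={
            "k": CompensationPool("k", "X", R_ik),
            "m": CompensationPool("m", "Y", R_im),
        },
    )


class TestPrimaryEffect:
    def test_no_deviation_no_effect(self):
        total, _ = primary_effect(homogeneous_model(0.0, 0.0, 0.5, 0.125, 0.0))
        assert total == 0.0

    def test_homogeneous_substitution(self):
        # (1/2)(-0.01) + (1/8)(0.06) = 0.0025
        total, terms = primary_effect(homogeneous_model(-0.01, 0.06, 0.5, 0.125, 0.0))
        assert total == pytest.approx(0.0025, abs=1e-15)
        assert len(terms) == 2

    def test_class_weighted_substitution(self):
        # 1 * 0.3 * (-0.1) + 0.5 * 0.2 * 0.4 = 0.01
        total, _ = primary_effect(two_class_model(-0.1, 0.4, 1.0, 0.5, w_x=0.3, w_y=0.2))
        assert total == pytest.approx(0.01, abs=1e-15)


class TestSecondaryEffect:
    def test_global_compensation_vanishes(self):
        total, _ = secondary_effect(homogeneous_model(-0.01, 0.06, 0.5, 0.125, 0.0))
        assert total == 0.0

    def test_shared_local_pool(self):
        # -F(-C + B) = F(C - B)
        C, B, F = 0.02, 0.05, 0.3
        total, _ = secondary_effect(homogeneous_model(-C, B, 0.5, 0.125, F, R_im=F))
        assert total == pytest.approx(F * (C - B), abs=1e-15)

    @pytest.mark.parametrize("seed", range(25))
    def test_unweighted_balance_per_class_and_episode(self, seed, random_model_factory):
        model, _ = random_model_factory(seed)
        for value in conservation_table(model).values():
            assert value == 0.0


class TestRelatedness:
    def test_competition_cancels_kinship(self):
        assert relatedness(0.3, 0.3, 0.5, 0.1) == 0.0

    def test_outbred_global_competition(self):
        assert relatedness(0.125, 0.0, 0.5, 0.0) == 0.25

    def test_self_relatedness_is_one(self):
        assert relatedness(0.5, 0.1, 0.5, 0.1) == 1.0

    def test_can_be_negative(self):
        assert relatedness(0.0, 0.2, 0.5, 0.0) < 0.0

    def test_degenerate_pool_raises(self):
        with pytest.raises(UndefinedRelatednessError):
            relatedness(0.2, 0.1, 0.5, 0.5)


class TestInclusiveFitnessEffect:
    def test_hamiltons_rule_case(self):
        # global compensation: effect = -C + rB = -0.01 + 0.25 * 0.06
        result = inclusive_fitness_effect(homogeneous_model(-0.01, 0.06, 0.5, 0.125, 0.0))
        assert result.effect == pytest.approx(0.005, abs=1e-15)
        assert result.verdict == "favoured"
        assert result.leading_factor == 0.5

    def test_fully_local_compensation_cancels_benefit(self):
        # R_ij = R_ik = R_im = F makes r = 0: helping is pure cost for any B
        C = 0.03
        for B in (0.0, 0.1, 5.0):
            result = inclusive_fitness_effect(homogeneous_model(-C, B, 0.5, 0.2, 0.2, R_im=0.2))
            assert result.effect == pytest.approx(-C, abs=1e-15)
            assert result.verdict == "disfavoured"

    def test_zero_deltas_equilibrium(self):
        result = inclusive_fitness_effect(homogeneous_model(0.0, 0.0, 0.5, 0.125, 0.0))
        assert result.effect == 0.0
        assert result.verdict == "equilibrium"

    def test_effect_equals_sum_of_terms(self, random_model_factory):
        model, _ = random_model_factory(99)
        result = inclusive_fitness_effect(model)
        assert result.effect == pytest.approx(sum(t.contribution for t in result.terms), abs=1e-14)

    def test_negative_leading_factor_warns_but_reports(self):
        model = homogeneous_model(-0.01, 0.06, 0.4, 0.125, 0.9)
        with pytest.warns(RuntimeWarning, match="leading factor"):
            result = inclusive_fitness_effect(model)
        assert result.leading_factor == pytest.approx(-0.5)

    def test_missing_coefficient_and_bad_pool_rejected(self):
        with pytest.raises(SpecificationError, match="consanguinity"):
            IFModel(
                structure=ClassStructure.homogeneous(),
                actor_class="X",
                deviations=(
                    Deviation(ACTOR_ROLE, "X", -0.01, "k"),
                    Deviation("j", "X", 0.06, "k"),
                ),
                consanguinity=ConsanguinitySet(R_ii=0.5),
                pools={"k": CompensationPool("k", "X", 0.0)},
            )
        with pytest.raises(SpecificationError, match="within each class"):
            two = ClassStructure(("X", "Y"), {"X": 1, "Y": 1}, {"X": 0.5, "Y": 0.5})
            IFModel(
                structure=two,
                actor_class="X",
                deviations=(Deviation(ACTOR_ROLE, "X", -0.01, "wrong"),),
                consanguinity=ConsanguinitySet(R_ii=0.5),
                pools={"wrong": CompensationPool("wrong", "Y", 0.0)},
            )


class TestAlgebraicProperties:
    @given(
        alpha=st.floats(-8.0, 8.0, allow_nan=False),
        seed=st.integers(0, 500),
    )
    @settings(max_examples=60, deadline=None)
    def test_linearity_in_deltas(self, alpha, seed):
        from inclufit.interface import generate_fixture, model_from_dict

        doc, _ = generate_fixture(seed)
        model = model_from_dict(doc)
        base = inclusive_fitness_effect(model).effect
        scaled = inclusive_fitness_effect(model.scaled(alpha)).effect
        assert scaled == pytest.approx(alpha * base, rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("alpha", [2.0, 0.5, -4.0, 8.0])
    def test_linearity_exact_for_binary_scalings(self, alpha):
        model = homogeneous_model(-0.013, 0.057, 0.5, 0.125, 0.1, R_im=0.3)
        base = inclusive_fitness_effect(model).effect
        assert inclusive_fitness_effect(model.scaled(alpha)).effect == alpha * base

    @given(
        R_ii=st.floats(0.3, 1.0),
        R_ij=st.floats(0.0, 1.0),
        R_ik=st.floats(0.0, 0.25),
        R_im=st.floats(0.0, 1.0),
        d_i=st.floats(-0.5, 0.5),
        d_j=st.floats(-0.5, 0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_net_effect_factorization(self, R_ii, R_ij, R_ik, R_im, d_i, d_j):
        """The raw primary+secondary sum equals (R_ii - R_ik) x the bracket."""
        model = homogeneous_model(d_i, d_j, R_ii, R_ij, R_ik, R_im=R_im)
        net = primary_effect(model)[0] + secondary_effect(model)[0]
        result = inclusive_fitness_effect(model)
        assert net == pytest.approx(result.leading_factor * result.effect, rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("seed", range(40))
    def test_assembly_matches_reference_evaluator(self, seed, random_model_factory):
        model, expected = random_model_factory(seed)
        assert inclusive_fitness_effect(model).effect == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestReductions:
    def test_single_class_reduces_to_homogeneous_formula(self):
        # class-structured assembly with c = u = 1 equals the flat formula
        params = dict(delta_i=-0.04, delta_j=0.11, R_ii=0.5, R_ij=0.125, R_ik=0.05)
        model = homogeneous_model(**params, R_im=0.02)
        r = relatedness(0.125, 0.02, 0.5, 0.05)
        expected = params["delta_i"] + r * params["delta_j"]
        assert inclusive_fitness_effect(model).effect == pytest.approx(expected, abs=1e-14)

    def test_two_recipient_classes_sum_independently(self):
        structure = ClassStructure(
            ("X", "Y1", "Y2"), {"X": 1.0, "Y1": 2.0, "Y2": 4.0}, {"X": 0.2, "Y1": 0.3, "Y2": 0.5}
        )
        pools = {
            "k": CompensationPool("k", "X", 0.0),
            "m1": CompensationPool("m1", "Y1", 0.1),
            "m2": CompensationPool("m2", "Y2", 0.0),
        }
        cons = ConsanguinitySet(R_ii=0.5, R_to={"j1": 0.25, "j2": 0.125})
        model = IFModel(
            structure=structure,
            actor_class="X",
            deviations=(
                Deviation(ACTOR_ROLE, "X", -0.02, "k"),
                Deviation("j1", "Y1", 0.3, "m1"),
                Deviation("j2", "Y2", 0.1, "m2"),
            ),
            consanguinity=cons,
            pools=pools,
        )
        r1 = relatedness(0.25, 0.1, 0.5, 0.0)
        r2 = relatedness(0.125, 0.0, 0.5, 0.0)
        expected = 0.2 / 1.0 * (-0.02) + r1 * (0.3 / 2.0) * 0.3 + r2 * (0.5 / 4.0) * 0.1
        assert inclusive_fitness_effect(model).effect == pytest.approx(expected, abs=1e-14)

    def test_episode_labels_do_not_change_arithmetic(self):
        """Two same-class recipients at different times with identical (unprimed)
        coefficients give the same effect as a single-episode model."""
        structure = ClassStructure(("X", "Y"), {"X": 1.0, "Y": 3.0}, {"X": 0.4, "Y": 0.6})
        pools = {
            "k": CompensationPool("k", "X", 0.0),
            "m": CompensationPool("m", "Y", 0.05),
            "m_prime": CompensationPool("m_prime", "Y", 0.05),
        }
        cons = ConsanguinitySet(R_ii=0.5, R_to={"j": 0.2, "ell": 0.2})
        def build(episodes):
            return IFModel(
                structure=structure,
                actor_class="X",
                deviations=(
                    Deviation(ACTOR_ROLE, "X", -0.01, "k"),
                    Deviation("j", "Y", 0.07, "m", episode=episodes[0]),
                    Deviation("ell", "Y", 0.07, "m_prime", episode=episodes[1]),
                ),
                consanguinity=cons,
                pools=pools,
            )
        same = inclusive_fitness_effect(build(("t0", "t0"))).effect
        primed = inclusive_fitness_effect(build(("t0", "t1"))).effect
        assert primed == same

    def test_primed_class_weight_override(self):
        """A later episode may carry its own (primed) class weight."""
        structure = ClassStructure.homogeneous()
        pools = {"k": CompensationPool("k", "X", 0.0), "m": CompensationPool("m", "X", 0.0)}
        model = IFModel(
            structure=structure,
            actor_class="X",
            deviations=(
                Deviation(ACTOR_ROLE, "X", 0.0, "k"),
                Deviation("ell", "X", 0.1, "m", episode="t1", class_weight_override=0.25),
            ),
            consanguinity=ConsanguinitySet(R_ii=0.5, R_to={"ell": 0.25}),
            pools=pools,
        )
        assert inclusive_fitness_effect(model).effect == pytest.approx(0.5 * 0.25 * 0.1, abs=1e-15)


class TestEffectCurve:
    def test_constant_and_linear_families(self):
        const = lambda t: homogeneous_model(-0.01, 0.06, 0.5, 0.125, 0.0)
        curve = effect_curve(const, [0.0, 0.5, 1.0])
        assert [e for _, e in curve] == pytest.approx([0.005] * 3)

        a, b = 0.04, 0.08
        linear = lambda t: homogeneous_model(a - b * t, 0.0, 0.5, 0.0, 0.0)
        curve = effect_curve(linear, [0.0, a / b, 2 * a / b])
        assert [e for _, e in curve] == pytest.approx([a, 0.0, -a], abs=1e-15)

    def test_generator_failure_names_trait(self):
        def bad(t):
            if t > 0.5:
                raise ValueError("boom")
            return homogeneous_model(0.0, 0.0, 0.5, 0.125, 0.0)

        with pytest.raises(RuntimeError, match="0.7"):
            effect_curve(bad, [0.1, 0.7])


class TestResultSerialization:
    def test_tsv_and_json_round_numbers(self):
        result = inclusive_fitness_effect(homogeneous_model(-0.01, 0.06, 0.5, 0.125, 0.0))
        tsv = result.to_tsv()
        lines = tsv.strip().splitlines()
        assert lines[0].split("\t")[0] == "participant_role"
        assert len(lines) == 1 + len(result.terms)
        contribs = [float(line.split("\t")[-1]) for line in lines[1:]]
        assert sum(contribs) == pytest.approx(result.effect, abs=1e-12)
        as_json = result.to_json_dict()
        assert as_json["verdict"] == "favoured"
        frame = result.to_frame()
        assert list(frame["contribution"]) == [t.contribution for t in result.terms]
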