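import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metacontrol import (
    DesignSpec,
    InsufficientDataError,
    InvalidInputError,
    SyntheticConfig,
    combine_sequential_proportions,
    generate_mortality,
    mortality_metareg,
    mortality_weight,
    pool_mortality,
)
from metacontrol.data_io import MortalityRecord
from metacontrol.mortality import (
    SE_INVERSE_SQRT_N,
    WEIGHT_INVERSE_SQRT_N,
    record_proportion,
)


class TestSequentialCombination:
    def test_printed_formula_arithmetic(self):
        wp = combine_sequential_proportions(1, 10, 2, 10)
        assert wp.proportion == pytest.approx(0.28, rel=1e-12)
        assert wp.n_effective == 10.0

    def test_zero_second_stage_is_absorbing(self):
        wp = combine_sequential_proportions(3, 12, 0, 9)
        assert wp.proportion == pytest.approx(3 / 12, rel=1e-12)

    def test_total_mortality_saturates_at_one(self):
        wp = combine_sequential_proportions(10, 10, 1, 8)
        assert wp.proportion == 1.0

    def test_invalid_totals_rejected(self):
        with pytest.raises(InvalidInputError):
            combine_sequential_proportions(0, 0, 1, 10)
        with pytest.raises(InvalidInputError):
            combine_sequential_proportions(5, 4, 0, 10)

    @given(
        st.tuples(st.integers(0, 20), st.integers(1, 20)).filter(lambda t: t[0] <= t[1]),
        st.tuples(st.integers(0, 20), st.integers(1, 20)).filter(lambda t: t[0] <= t[1]),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_stage_symmetry(self, s1, s2):
        a = combine_sequential_proportions(s1[0], s1[1], s2[0], s2[1])
        b = combine_sequential_proportions(s2[0], s2[1], s1[0], s1[1])
        assert a.proportion == pytest.approx(b.proportion, abs=1e-12)
        assert a.n_effective == b.n_effective

    @given(
        st.lists(
            st.tuples(st.integers(0, 10), st.integers(1, 20)).filter(lambda t: t[0] <= t[1]),
            min_size=3, max_size=3,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_survival_product_is_associative(self, stages):
        """1 - p_total = prod(1 - p_j): pairwise combination in any order
        gives identical p_total to 1e-12."""
        def surv(d, t):
            return 1 - d / t

        expected = 1.0 - surv(*stages[0]) * surv(*stages[1]) * surv(*stages[2])

        def chain(order):
            p = 1.0
            for i in order:
                p *= surv(*stages[i])
            return 1.0 - p

        for order in ((0, 1, 2), (2, 0, 1), (1, 2, 0)):
            assert chain(order) == pytest.approx(expected, abs=1e-12)


class TestWeights:
    def test_literal_convention(self):
        assert mortality_weight(16, WEIGHT_INVERSE_SQRT_N) == 0.25

    def test_default_convention_proportional_to_n(self):
        assert mortality_weight(16, SE_INVERSE_SQRT_N) / mortality_weight(4, SE_INVERSE_SQRT_N) == 4.0

    def test_nonpositive_n_rejected(self):
        with pytest.raises(InvalidInputError):
            mortality_weight(0)

    def test_convention_recorded_in_outputs(self):
        rec = MortalityRecord(study_id="x", deaths=1, total=10)
        wp = record_proportion(rec, WEIGHT_INVERSE_SQRT_N)
        assert wp.convention == WEIGHT_INVERSE_SQRT_N


def _records(counts, follow_ups=None, occlusions=None):
    recs = []
    for i, (d, t) in enumerate(counts):
        recs.append(
            MortalityRecord(
                study_id=f"m{i}", phase="peri", deaths=d, total=t,
                follow_up_hours=(follow_ups[i] if follow_ups else 168.0),
                occlusion=(occlusions[i] if occlusions else "temporary"),
                ischemia_minutes=(
                    40.0 + 5.0 * i
                    if (occlusions[i] if occlusions else "temporary") == "temporary"
                    else None
                ),
            )
        )
    return recs


class TestPooling:
    def test_all_zero_deaths_pools_to_zero(self):
        fit = pool_mortality(_records([(0, 10), (0, 12), (0, 8)]))
        assert fit.mu == 0.0 and fit.ci_low == 0.0

    def test_single_record_identity_with_degenerate_flag(self):
        fit = pool_mortality(_records([(5, 100)]))
        assert fit.mu == pytest.approx(5.0, rel=1e-12)
        assert fit.degenerate and fit.k == 1

    def test_empty_collection_errors(self):
        with pytest.raises(InsufficientDataError):
            pool_mortality([])

    def test_ci_clipped_to_unit_interval(self):
        fit = pool_mortality(_records([(0, 4), (1, 4), (0, 3)]))
        assert fit.ci_low >= 0.0

    @pytest.mark.parametrize("convention", [SE_INVERSE_SQRT_N, WEIGHT_INVERSE_SQRT_N])
    def test_both_conventions_recover_the_rate(self, convention):
        rng = np.random.default_rng(6)
        counts = [(int(rng.binomial(n, 0.167)), n) for n in rng.integers(20, 60, 80)]
        fit = pool_mortality(_records(counts), convention=convention)
        assert fit.mu / 100 == pytest.approx(0.167, abs=0.03)


class TestMetaRegression:
    def test_doubling_every_n_leaves_betas_unchanged(self):
        counts = [(1, 10), (2, 16), (0, 12), (3, 20), (2, 14)]
        fu = [24.0, 72.0, 168.0, 336.0, 672.0]
        fit1 = mortality_metareg(_records(counts, fu), moderators=["follow_up_hours"])
        doubled = [(2 * d, 2 * t) for d, t in counts]
        fit2 = mortality_metareg(_records(doubled, fu), moderators=["follow_up_hours"])
        assert fit1.coefficients["follow_up_hours"] == pytest.approx(
            fit2.coefficients["follow_up_hours"], rel=1e-9
        )

    def test_ischemia_term_restricts_to_temporary_occlusion(self):
        occl = ["temporary"] * 6 + ["permanent"] * 4
        counts = [(i % 3, 12 + i) for i in range(10)]
        recs = _records(counts, occlusions=occl)
        fit = mortality_metareg(recs, moderators=["ischemia_minutes"])
        assert fit.k == 6  # permanent-occlusion rows have no ischemia duration

    def test_null_rejection_rate_near_alpha(self):
        """No moderator effects: the omnibus test rejects at roughly alpha."""
        rejections = 0
        reps = 120
        for rep in range(reps):
            cfg = SyntheticConfig(k_studies=60, seed=900 + rep,
                                  second_stage_fraction=0.0)
            recs = generate_mortality(cfg, "peri")
            fit = mortality_metareg(recs, DesignSpec(), moderators=["species"])
            if fit.omnibus_p < 0.05:
                rejections += 1
        assert 0.005 <= rejections / reps <= 0.12

    def test_positive_follow_up_effect_recovered_in_points_per_hour(self):
        cfg = SyntheticConfig(
            k_studies=300, mortality_base_rate=0.05,
            mortality_logit_effects={"follow_up_hours": 0.0015},
            mortality_n_range=(20, 40), second_stage_fraction=0.2, seed=31,
        )
        recs = generate_mortality(cfg, "post")
        fit = mortality_metareg(recs, moderators=["follow_up_hours"])
        assert fit.coefficients["follow_up_hours"] > 0
        assert fit.weights_convention == SE_INVERSE_SQRT_N
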