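import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from photoscreen import (
    DMAConfig,
    DMATrajectory,
    ReferencePS,
    SensitizerSpec,
    SimConfig,
    absorbed_fraction,
    blank_correct,
    delta_od,
    relative_yield,
    score_extract,
    score_plate,
    simulate_dma_plate,
    validate_controls,
)

DOSES = np.array([0.0, 6.2, 12.4, 18.5, 24.7])


def linear_traj(od0=0.40, od_final=0.20):
    slope = (od_final - od0) / DOSES[-1]
    od = od0 + slope * DOSES
    return DMATrajectory("s", DOSES, od, np.zeros_like(DOSES))


class TestDeltaOD:
    def test_endpoint_is_first_minus_last(self):
        traj = DMATrajectory(
            "s", DOSES, [0.40, 0.35, 0.30, 0.25, 0.20], np.zeros(5)
        )
        assert delta_od(traj, "endpoint")[0] == pytest.approx(0.20)

    def test_constant_series_gives_zero(self):
        traj = DMATrajectory("s", DOSES, np.full(5, 0.3), np.zeros(5))
        assert delta_od(traj, "endpoint")[0] == 0.0
        assert delta_od(traj, "slope")[0] == pytest.approx(0.0, abs=1e-12)

    def test_slope_matches_endpoint_on_collinear_data(self):
        # closed-form least squares on collinear points equals the endpoint drop
        assert delta_od(linear_traj(), "slope")[0] == pytest.approx(0.20, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            DMATrajectory("s", [0.0], [0.4], [0.0])


class TestAbsorbedFraction:
    @pytest.mark.parametrize(
        "a,expected",
        [(0.0, 0.0), (0.2, 0.369043), (3.0, 0.999)],
    )
    def test_beer_lambert_probability(self, a, expected):
        assert absorbed_fraction(a) == pytest.approx(expected, abs=5e-7)

    def test_negative_beyond_noise_floor_rejected(self):
        with pytest.raises(ValueError):
            absorbed_fraction(-0.05)

    @given(st.floats(0, 5))
    def test_in_unit_interval(self, a):
        assert 0 <= absorbed_fraction(a) < 1


class TestRelativeYield:
    REF = ReferencePS("berberine", a_irr=0.2, delta_od377=0.1)

    def test_reference_scores_exactly_100(self):
        assert relative_yield(0.1, 0.2, self.REF) == 100.0

    def test_no_bleaching_scores_zero(self):
        assert relative_yield(0.0, 0.2, self.REF) == 0.0

    def test_hand_evaluated_example(self):
        # 100 * (0.2/0.1) * ((1-10^-0.2)/(1-10^-0.1)) = 358.86
        assert relative_yield(0.2, 0.1, self.REF) == pytest.approx(358.86, abs=0.05)

    def test_transparent_sample_with_signal_is_inconsistent(self):
        with pytest.raises(ValueError, match="inconsistent"):
            relative_yield(0.2, 0.0, self.REF)

    def test_zero_reference_bleaching_invalid(self):
        with pytest.raises(ValueError):
            ReferencePS("bad", a_irr=0.2, delta_od377=0.0)

    @given(
        st.floats(0.02, 0.5),
        st.floats(0.05, 2.0),
        st.floats(0.001, 0.2),
        st.floats(0.05, 2.0),
    )
    def test_monotone_in_signal_and_absorbance(self, d, a, dd, da):
        y = relative_yield(d, a, self.REF)
        assert relative_yield(d + dd, a, self.REF) > y  # increasing in dOD
        assert relative_yield(d, a + da, self.REF) < y  # decreasing in A


class TestValidateControls:
    def test_strong_quench_confirmed(self):
        ratio, ok, side = validate_controls(0.20, 0.02, 0.005)
        assert ratio == pytest.approx(0.1)
        assert ok and not side

    def test_unquenched_signal_not_confirmed(self):
        ratio, ok, _ = validate_controls(0.20, 0.18, 0.0)
        assert ratio == pytest.approx(0.9)
        assert not ok

    def test_drift_flags_side_reaction_regardless_of_ratio(self):
        _, _, side = validate_controls(0.20, 0.02, 0.10)
        assert side

    def test_no_signal_defines_ratio_one(self):
        ratio, ok, _ = validate_controls(0.005, 0.001, 0.0)
        assert ratio == 1.0 and not ok


class TestScoreExtract:
    def test_strong_clean_extract_positive(self, seeded_plate):
        r = score_extract(seeded_plate, "strong")
        assert r.dma_positive and r.quench_confirmed and not r.side_reaction_flag
        assert r.relative_yield_pct > 100
        assert r.absorbed_fraction == pytest.approx(
            1 - 10 ** (-r.a_irr), abs=1e-12
        )

    def test_null_extract_scores_near_zero(self, seeded_plate):
        r = score_extract(seeded_plate, "null")
        assert abs(r.relative_yield_pct) < 15
        assert not r.dma_positive

    def test_unquenchable_bleacher_reported_non_singlet_oxygen(self, seeded_plate):
        r = score_extract(seeded_plate, "type1")
        assert r.relative_yield_pct > 50  # bleaches DMA...
        assert not r.quench_confirmed  # ...but ascorbate does nothing
        assert not r.dma_positive

    def test_missing_arm_error_names_arm(self, seeded_plate):
        with pytest.raises(ValueError, match="dma_probe"):
            score_extract(seeded_plate, "nonexistent")

    def test_side_reaction_flagged(self):
        specs = [
            SensitizerSpec("drifty", a_irr=0.5, effective_phi=1.0,
                           side_reaction_drift=0.1)
        ]
        ds = simulate_dma_plate(specs, SimConfig(seed=2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = score_extract(blank_correct(ds), "drifty")
        assert r.side_reaction_flag

    def test_solvent_like_sample_scores_zero_within_noise(self):
        specs = [SensitizerSpec("like_solvent", a_irr=0.3, effective_phi=0.0)]
        ds = simulate_dma_plate(specs, SimConfig(seed=5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = score_extract(blank_correct(ds), "like_solvent")
        assert abs(r.relative_yield_pct) <= 3 * max(r.relative_yield_se, 5.0)


class TestRecovery:
    def test_equal_absorbance_yield_ratio_matches_phi_ratio_within_3se(self):
        specs = [
            SensitizerSpec("a", a_irr=0.5, effective_phi=2.0),
            SensitizerSpec("b", a_irr=0.5, effective_phi=1.0),
        ]
        ds = simulate_dma_plate(specs, SimConfig(seed=17))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ra, rb = score_plate(blank_correct(ds))
        ratio = ra.relative_yield_pct / rb.relative_yield_pct
        se_ratio = ratio * np.hypot(
            ra.relative_yield_se / ra.relative_yield_pct,
            rb.relative_yield_se / rb.relative_yield_pct,
        )
        assert abs(ratio - 2.0) <= 3 * se_ratio

    def test_noise_free_kinetic_mode_recovers_phi_exactly(self):
        specs = [
            SensitizerSpec("x", a_irr=0.7, effective_phi=1.7),
            SensitizerSpec("y", a_irr=0.2, effective_phi=0.4),
        ]
        ds = simulate_dma_plate(specs, SimConfig(seed=1, noise_sd=0.0, blank_od=0.0))
        results = score_plate(ds, DMAConfig(mode="kinetic"))
        assert results[0].relative_yield_pct == pytest.approx(170.0, abs=1e-6)
        assert results[1].relative_yield_pct == pytest.approx(40.0, abs=1e-6)
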