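"""Exponential rate extraction, NOE propagation and ΔR2 segments."""

import numpy as np
import pandas as pd
import pytest

from nmrbind.relaxation import (CPMG_DELAYS, R1_DELAYS, RelaxationResult,
                                RelaxationSeries, call_dynamic_segments,
                                delta_r2_profile, fit_decay, het_noe,
                                rate_summary, read_relaxation_csv)
from nmrbind.synthetic import simulate_decay


class TestFitDecay:
    @pytest.mark.parametrize("rate, amplitude, delays", [
        (1.94, 100.0, R1_DELAYS),   # free-state average R1 scale
        (8.06, 50.0, CPMG_DELAYS),  # fastest bound-state R2 scale
    ])
    def test_noiseless_round_trip_at_printed_schedules(self, rate,
                                                       amplitude, delays):
        result = fit_decay(simulate_decay(rate, amplitude, delays))
        assert result.converged
        assert result.rate == pytest.approx(rate, rel=1e-6)
        assert result.amplitude == pytest.approx(amplitude, rel=1e-6)

    @pytest.mark.parametrize("rate", [0.1, 1.0, 5.0, 20.0, 50.0])
    @pytest.mark.parametrize("delays", [R1_DELAYS, CPMG_DELAYS])
    def test_round_trip_across_rate_range(self, rate, delays):
        result = fit_decay(simulate_decay(rate, 100.0, delays))
        assert result.rate == pytest.approx(rate, rel=1e-6)

    def test_constant_intensities_give_zero_rate(self):
        result = fit_decay(simulate_decay(0.0, 42.0, R1_DELAYS))
        assert result.rate == pytest.approx(0.0, abs=1e-9)

    def test_mostly_nonpositive_intensities_rejected(self):
        series = RelaxationSeries("Y65", R1_DELAYS,
                                  [-1.0] * 5 + [1.0] * 4, "R1")
        with pytest.raises(ValueError, match="non-positive"):
            fit_decay(series)

    def test_too_few_delays_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            RelaxationSeries("Y65", (0.1, 0.1), (1.0, 1.0), "R1")

    def test_noisy_recovery_median_within_five_percent(self, rng):
        """2% amplitude noise, 200 replicates: median rate error < 5%."""
        truths = {1.0: R1_DELAYS, 2.0: R1_DELAYS,
                  5.0: CPMG_DELAYS, 10.0: CPMG_DELAYS}
        for rate, delays in truths.items():
            recovered = [
                fit_decay(simulate_decay(rate, 100.0, delays,
                                         noise_frac=0.02, seed=rng)).rate
                for _ in range(50)]
            assert np.median(recovered) == pytest.approx(rate, rel=0.05)


class TestHetNoe:
    def test_equal_intensities_unit_noe_and_propagated_error(self):
        rec = het_noe(100.0, 100.0, 1.0, 1.0)
        assert rec.noe == 1.0
        assert rec.noe_error == pytest.approx(np.sqrt(2) * 0.01)

    def test_negative_noe_scale_of_disordered_backbone(self):
        rec = het_noe(-20.0, 100.0, 0.0, 0.0)
        assert rec.noe == pytest.approx(-0.2)
        assert rec.noe_error == 0.0

    def test_zero_saturated_intensity_branch(self):
        rec = het_noe(0.0, 100.0, 2.0, 1.0)
        assert rec.noe == 0.0
        assert rec.noe_error == pytest.approx(0.02)

    def test_zero_unsaturated_intensity_is_an_error(self):
        with pytest.raises(ValueError, match="I_unsat"):
            het_noe(10.0, 0.0, 1.0, 1.0)

    def test_error_agrees_with_monte_carlo(self, rng):
        """First-order propagation within 5% of MC for <=5% noise."""
        I_sat, I_unsat = 80.0, 100.0
        for rel in (0.01, 0.05):
            s_sat, s_unsat = rel * I_sat, rel * I_unsat
            rec = het_noe(I_sat, I_unsat, s_sat, s_unsat)
            draws = (rng.normal(I_sat, s_sat, 100_000)
                     / rng.normal(I_unsat, s_unsat, 100_000))
            assert rec.noe_error == pytest.approx(np.std(draws), rel=0.05)


def _rates(values: dict[int, float], err=0.05, aa="A"):
    return [RelaxationResult(f"{aa}{pos}", rate, err, 100.0, True, "R2")
            for pos, rate in values.items()]


class TestDeltaR2:
    def test_identical_inputs_give_zero_profile(self):
        rates = _rates({i: 2.0 for i in range(40, 50)})
        profile = delta_r2_profile(rates, rates)
        assert np.allclose(profile["delta_r2"], 0.0)
        assert np.allclose(profile["error"], np.hypot(0.05, 0.05))

    def test_elevated_regions_recovered(self):
        free = {i: 2.0 for i in range(38, 108)}
        bound = {i: (5.0 if (62 <= i <= 68 or 83 <= i <= 99) else 2.0)
                 for i in range(38, 108)}
        profile = delta_r2_profile(_rates(free), _rates(bound))
        inside = profile[(profile.position >= 83) & (profile.position <= 99)]
        outside = profile[profile.position < 60]
        assert np.allclose(inside["delta_r2"], 3.0)
        assert np.allclose(outside["delta_r2"], 0.0)

    def test_partial_overlap_warns_and_omits(self):
        free = _rates({i: 2.0 for i in range(40, 50)})
        bound = _rates({i: 2.0 for i in range(45, 55)})
        with pytest.warns(UserWarning, match="omitted"):
            profile = delta_r2_profile(free, bound)
        assert set(profile.position) == set(range(45, 50))

    def test_disjoint_residue_sets_error(self):
        with pytest.raises(ValueError, match="no residues"):
            delta_r2_profile(_rates({1: 2.0, 2: 2.0}),
                             _rates({10: 2.0, 11: 2.0}))


def _dr2_frame(values: dict[int, float]) -> pd.DataFrame:
    return pd.DataFrame({"residue": [f"A{p}" for p in values],
                         "position": list(values),
                         "delta_r2": list(values.values()),
                         "error": 0.1})


class TestDynamicSegments:
    def test_two_regions_with_interior_exceptions(self):
        """Elevated 62-68 and 83-99 with two fast interior residues."""
        values = {i: 0.0 for i in range(38, 108)}
        for i in list(range(62, 69)) + list(range(83, 100)):
            values[i] = 3.0
        values[85] = values[92] = 0.0       # interior exceptions
        for pro in (50, 69, 82, 93, 96, 97, 98):
            values.pop(pro)                 # prolines unmeasured
        segments = call_dynamic_segments(_dr2_frame(values))
        assert segments == [(62, 68), (83, 99)]

    def test_flat_profile_gives_no_segments(self):
        assert call_dynamic_segments(
            _dr2_frame({i: 0.5 for i in range(40, 60)})) == []

    def test_three_exceptions_split_the_run(self):
        values = {i: 3.0 for i in range(80, 100)}
        values.update({i: 0.1 for i in range(60, 80)})
        for pos in (84, 89, 94):
            values[pos] = 0.1
        segments = call_dynamic_segments(_dr2_frame(values),
                                         max_exceptions=2)
        # only two dips can be absorbed; the third starts a new run
        assert segments == [(80, 93), (95, 99)]


class TestSummariesAndIo:
    def test_summary_over_converged_only(self):
        results = _rates({1: 1.0, 2: 2.0, 3: 3.0})
        results.append(RelaxationResult("A4", 99.0, 1.0, 100.0, False, "R2"))
        summary = rate_summary(results)
        assert summary == {"n": 3, "min": 1.0, "max": 3.0, "mean": 2.0}

    def test_read_long_and_wide_csv(self, tmp_path):
        long = tmp_path / "long.csv"
        long.write_text("residue,delay_s,intensity\n"
                        "Y65,0.0016,100\nY65,0.4,50\nY65,1.2,10\n")
        series = read_relaxation_csv(long, "R1")
        assert len(series) == 1 and len(series[0].delays) == 3

        wide = tmp_path / "wide.csv"
        wide.write_text("residue,0.064,0.128,0.25\nY65,80,60,30\nT95,90,70,40\n")
        series = read_relaxation_csv(wide, "R2")
        assert len(series) == 2
        assert series[1].intensities[-1] == 40
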