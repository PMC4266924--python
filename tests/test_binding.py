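"""Depletion isotherm, K_D fitting and saturation views."""

import numpy as np
import pytest

from nmrbind.binding import (fit_binding, fraction_bound, global_fit,
                             saturation_from_trajectory)
from nmrbind.csp import ShiftTrajectory, build_trajectories
from nmrbind.synthetic import (RECEPTOR_TOTAL, TITRATION_RATIOS,
                               default_mbp_scenario,
                               fraction_bound_equilibrium, simulate_titration)

P = RECEPTOR_TOTAL


class TestFractionBound:
    def test_no_ligand_gives_zero(self):
        assert fraction_bound(0.0, P, 1.0, 7.6e-6) == 0.0

    def test_kd_zero_limit_is_stoichiometric(self):
        assert fraction_bound(P, P, 1.0, 0.0) == 1.0
        assert fraction_bound(0.4 * P, P, 1.0, 0.0) == pytest.approx(0.4)

    def test_equivalence_point_value(self):
        # independent bisection oracle gives 0.90717 at 1:1, K_D 7.6 uM
        assert fraction_bound(P, P, 1.0, 7.6e-6) == pytest.approx(
            0.90717, abs=5e-6)

    def test_agrees_with_bisection_oracle_over_random_draws(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            recep = 10 ** rng.uniform(-5, -2)
            n = rng.uniform(0.5, 2.0)
            lig = rng.uniform(0.0, 2.0 * n * recep)
            kd = 10 ** rng.uniform(-9, -2)  # 1 nM - 10 mM
            closed = fraction_bound(lig, recep, n, kd)
            oracle = fraction_bound_equilibrium(lig, recep, n, kd)
            assert abs(closed - oracle) < 1e-10

    def test_monotone_in_ligand_and_kd(self):
        ligands = np.linspace(0, 2 * P, 50)
        f = fraction_bound(ligands, P, 1.0, 5e-6)
        assert np.all(np.diff(f) >= 0)
        kds = np.logspace(-9, -3, 30)
        fk = [fraction_bound(0.5 * P, P, 1.0, k) for k in kds]
        assert np.all(np.diff(fk) <= 0)

    def test_weak_binding_limit(self):
        # K_D = 1 M >> F, nP: f -> F/K_D to first order
        f = fraction_bound(1e-4, P, 1.0, 1.0)
        assert f == pytest.approx(1e-4, rel=2e-3)

    def test_saturation_limit(self):
        assert fraction_bound(1e6 * P, P, 1.0, 5e-6) == pytest.approx(
            1.0, abs=1e-6)


def _noiseless_trajectory(kd, n=1.0, dmax=0.12, ratios=TITRATION_RATIOS):
    f = np.array([fraction_bound_equilibrium(r * P, P, n, kd)
                  for r in ratios])
    lig = np.array(ratios) * P
    csp = dmax * f
    return ShiftTrajectory("Y65", lig, np.zeros_like(csp),
                           np.zeros_like(csp), csp)


class TestFitBinding:
    @pytest.mark.parametrize("kd_true", [7.6e-6, 4.0e-6])
    def test_round_trip_recovers_reported_scale_kds(self, kd_true):
        """Noiseless generation (bisection) -> closed-form fit round trip."""
        traj = _noiseless_trajectory(kd_true)
        fit = fit_binding(traj, P)
        assert fit.converged
        assert fit.kd == pytest.approx(kd_true, rel=1e-4)
        assert fit.n == pytest.approx(1.0, rel=1e-4)
        assert fit.delta_max == pytest.approx(0.12, rel=1e-4)
        assert len(fit.residuals) == len(TITRATION_RATIOS) - 1

    def test_round_trip_with_fixed_stoichiometry(self):
        traj = _noiseless_trajectory(4.0e-6)
        fit = fit_binding(traj, P, fix_n=1.0)
        assert fit.kd == pytest.approx(4.0e-6, rel=1e-4)
        assert fit.n_fixed and fit.n == 1.0

    def test_round_trip_across_kd_range(self):
        for kd in (1e-6, 1e-5, 1e-4):
            fit = fit_binding(_noiseless_trajectory(kd), P)
            assert fit.kd == pytest.approx(kd, rel=1e-4)

    def test_flat_trajectory_is_an_error(self):
        traj = _noiseless_trajectory(5e-6, dmax=0.12)
        traj.csp[:] = 0.0
        with pytest.raises(ValueError, match="no perturbation"):
            fit_binding(traj, P)

    def test_too_few_points_is_an_error(self):
        traj = _noiseless_trajectory(5e-6, ratios=(0, 0.5, 1.0))
        with pytest.raises(ValueError, match="insufficient titration points"):
            fit_binding(traj, P)  # n free needs >= 4 non-apo points
        fit = fit_binding(_noiseless_trajectory(5e-6, ratios=(0, 0.4, 0.8, 1.2)),
                          P, fix_n=1.0)
        assert fit.kd == pytest.approx(5e-6, rel=1e-3)


class TestGlobalFit:
    def test_shared_kd_recovered_from_two_residues(self):
        t1 = _noiseless_trajectory(5e-6, dmax=0.12)
        t2 = _noiseless_trajectory(5e-6, dmax=0.15)
        t2.residue_label = "T95"
        result = global_fit([t1, t2], P)
        assert result.kd == pytest.approx(5e-6, rel=1e-4)
        assert result.delta_max["Y65"] == pytest.approx(0.12, rel=1e-4)
        assert result.delta_max["T95"] == pytest.approx(0.15, rel=1e-4)

    def test_single_trajectory_reduces_to_fit_binding(self):
        traj = _noiseless_trajectory(7.6e-6)
        single = fit_binding(traj, P)
        shared = global_fit([traj], P)
        assert shared.kd == pytest.approx(single.kd, rel=1e-9)
        assert shared.n == pytest.approx(single.n, rel=1e-9)

    def test_heterogeneous_affinities_inflate_residuals(self):
        rng = np.random.default_rng(0)
        sigma = 1e-4

        def noisy(kd, label):
            traj = _noiseless_trajectory(kd)
            traj.residue_label = label
            traj.csp[1:] += rng.normal(0, sigma, len(traj) - 1)
            traj.csp = np.abs(traj.csp)
            traj.csp[0] = 0.0
            return traj

        same = global_fit([noisy(5e-6, "Y65"), noisy(5e-6, "T95")], P)
        mixed = global_fit([noisy(1e-6, "Y65"), noisy(50e-6, "T95")], P)
        assert mixed.converged
        # a single shared K_D cannot explain 1 uM + 50 uM data at noise level
        assert mixed.redchi > 10 * same.redchi


class TestSaturationView:
    def test_final_point_normalization_ends_at_one(self):
        traj = _noiseless_trajectory(4.0e-6)
        _, sat = saturation_from_trajectory(traj, "final_point")
        assert sat[-1] == pytest.approx(1.0)

    def test_fitted_amplitude_endpoint_matches_fraction_bound(self):
        traj = _noiseless_trajectory(4.0e-6)
        _, sat = saturation_from_trajectory(traj, "fitted_amplitude",
                                            receptor_total=P)
        expected = fraction_bound(1.2 * P, P, 1.0, 4.0e-6)
        assert sat[-1] == pytest.approx(expected, rel=1e-4)
        assert sat[-1] < 1.0

    def test_flat_trajectory_rejected(self):
        traj = _noiseless_trajectory(4.0e-6)
        traj.csp[:] = 0.0
        with pytest.raises(ValueError, match="no perturbation"):
            saturation_from_trajectory(traj, "final_point")


def test_pipeline_identity_generator_vs_fitter():
    """Full simulate -> track -> fit loop recovers truth across K_D range."""
    for kd in (1e-6, 5e-6, 2e-5, 1e-4):
        config = default_mbp_scenario(kd=kd)
        series = simulate_titration(config)
        trajs = build_trajectories(series)
        fit = fit_binding(trajs["T95"], series.receptor_total)
        assert fit.kd == pytest.approx(kd, rel=1e-4)
        assert fit.n == pytest.approx(1.0, rel=1e-4)
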