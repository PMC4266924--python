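"""Weighted CSP, peak tracking, trajectories and segment calling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nmrbind._util import NmrbindWarning
from nmrbind.csp import (CSPProfile, build_trajectories, call_binding_segments,
                         csp_profile, track_peaks, weighted_csp)
from nmrbind.io import Peak, PeakList, TitrationPoint, TitrationSeries
from nmrbind.synthetic import default_mbp_scenario, simulate_titration

finite = st.floats(min_value=-2.0, max_value=2.0)


class TestWeightedCsp:
    @pytest.mark.parametrize("dh, dn, expected", [
        (0.0, 0.0, 0.0),
        (0.1, 0.0, 0.1),                 # proton-only reduces to |dH|
        (0.05, 0.4, 0.20615528128088306),  # sqrt(0.0025 + 0.25*0.16)
    ])
    def test_reference_values(self, dh, dn, expected):
        assert weighted_csp(dh, dn) == pytest.approx(expected, abs=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            weighted_csp(np.nan, 0.1)

    @given(finite, finite)
    def test_symmetric_under_sign_flips(self, dh, dn):
        base = weighted_csp(dh, dn)
        assert weighted_csp(-dh, dn) == pytest.approx(base)
        assert weighted_csp(dh, -dn) == pytest.approx(base)

    @given(finite, finite, finite, finite)
    def test_triangle_inequality(self, h1, n1, h2, n2):
        """Δδ is a norm on (Δδ_H, Δδ_N/2)."""
        lhs = weighted_csp(h1 + h2, n1 + n2)
        assert lhs <= weighted_csp(h1, n1) + weighted_csp(h2, n2) + 1e-12


def _grid_list(positions, labels=None):
    peaks = []
    for k, (h, n) in enumerate(positions):
        lab = labels[k] if labels else None
        peaks.append(Peak(delta_H=h, delta_N=n, residue_label=lab))
    return PeakList(peaks=tuple(peaks))


class TestTrackPeaks:
    POSITIONS = [(8.0, 118.0), (8.3, 121.0), (7.9, 125.0), (8.5, 110.0)]

    def test_identity_maps_with_zero_distance(self):
        pl = _grid_list(self.POSITIONS)
        matching = track_peaks(pl, pl)
        assert matching.as_dict() == {i: i for i in range(4)}
        assert all(d == 0 for _, _, d in matching.pairs)

    def test_small_shift_matched_at_expected_distance(self):
        moved = list(self.POSITIONS)
        moved[1] = (moved[1][0] + 0.01, moved[1][1] + 0.05)
        matching = track_peaks(_grid_list(self.POSITIONS), _grid_list(moved))
        assert matching.as_dict() == {i: i for i in range(4)}
        dist = dict((i, d) for i, _, d in matching.pairs)[1]
        # brute-force weighted distance sqrt(0.01^2 + 0.25*0.05^2)
        assert dist == pytest.approx(0.026925824035672520, abs=1e-12)

    def test_large_jump_left_unmatched_by_cutoff(self):
        moved = list(self.POSITIONS)
        moved[2] = (moved[2][0] + 1.0, moved[2][1])
        matching = track_peaks(_grid_list(self.POSITIONS), _grid_list(moved))
        assert 2 in matching.unmatched_reference
        assert 2 in matching.unmatched_target

    def test_assigned_labels_override_geometry(self):
        ref = _grid_list([(8.0, 118.0), (8.02, 118.1)], ["Y65", "T95"])
        # target peaks swapped in space but carrying labels
        tgt = _grid_list([(8.02, 118.1), (8.0, 118.0)], ["Y65", "T95"])
        matching = track_peaks(ref, tgt)
        assert matching.as_dict() == {0: 0, 1: 1}

    @given(st.permutations(list(range(4))))
    def test_invariant_to_input_order(self, order):
        ref = _grid_list(self.POSITIONS)
        shuffled = _grid_list([self.POSITIONS[i] for i in order])
        matching = track_peaks(ref, shuffled)
        for i, j, d in matching.pairs:
            assert order[j] == i
            assert d == 0


class TestTrajectories:
    def test_noiseless_scenario_reaches_saturation_fraction(self):
        """Endpoint CSP equals fraction_bound x Δδ_max for every residue."""
        config = default_mbp_scenario()
        series = simulate_titration(config)
        trajs = build_trajectories(series)
        f = config.fractions_bound
        for label, traj in trajs.items():
            assert len(traj) == len(series)
            dh, dn = config.delta_max.get(label, (0.0, 0.0))
            expected = f * weighted_csp(dh, dn)
            np.testing.assert_allclose(traj.csp, expected, atol=1e-9)

    def test_one_point_series_gives_zero_csp(self, simple_peaklist):
        series = TitrationSeries(points=(
            TitrationPoint(simple_peaklist, 0.0, 8e-4),))
        trajs = build_trajectories(series)
        assert all(len(t) == 1 and t.csp[0] == 0 for t in trajs.values())

    def test_missing_peak_truncates_with_warning(self):
        apo = _grid_list([(8.0, 118.0), (8.4, 122.0)], ["Y65", "T95"])
        # T95 peak disappears at the second point
        second = _grid_list([(8.01, 118.0)], ["Y65"])
        series = TitrationSeries(points=(
            TitrationPoint(apo, 0.0, 8e-4),
            TitrationPoint(second, 8e-5, 8e-4)))
        with pytest.warns(NmrbindWarning, match="truncated"):
            trajs = build_trajectories(series)
        assert trajs["T95"].truncated and len(trajs["T95"]) == 1
        assert not trajs["Y65"].truncated and len(trajs["Y65"]) == 2

    def test_unassigned_apo_only_is_an_error(self):
        apo = _grid_list([(8.0, 118.0)])
        series = TitrationSeries(points=(TitrationPoint(apo, 0.0, 8e-4),))
        with pytest.raises(ValueError, match="assigned"):
            build_trajectories(series)


def _profile(values: dict[int, float], aa="A") -> CSPProfile:
    return CSPProfile(values={f"{aa}{pos}": v for pos, v in values.items()},
                      point_index=0)


class TestSegmentCalling:
    def test_flat_profile_has_no_segments(self):
        profile = _profile({i: 0.1 for i in range(40, 60)})
        assert call_binding_segments(profile) == []

    def test_single_elevated_run_with_proline_gaps(self):
        # elevated 83-93 except prolines 93 missing entirely (no amide)
        values = {i: 0.01 for i in range(38, 108)}
        for i in range(83, 94):
            values[i] = 0.2
        for pro in (50, 69, 82, 93, 96, 97, 98):
            values.pop(pro, None)
        segments = call_binding_segments(_profile(values))
        assert segments == [(83, 92)]

    def test_two_elevated_runs_give_two_segments(self):
        values = {i: 0.01 for i in range(38, 108)}
        for i in list(range(62, 69)) + list(range(83, 94)):
            values[i] = 0.2
        segments = call_binding_segments(_profile(values))
        assert segments == [(62, 68), (83, 93)]

    def test_proline_triple_bridged_inside_run(self):
        """A 3-residue unmeasured stretch must not split a region."""
        values = {i: 0.2 for i in range(83, 100)}
        for pro in (93, 96, 97, 98):
            values.pop(pro)
        values.update({i: 0.0 for i in range(40, 80)})
        segments = call_binding_segments(_profile(values))
        assert segments == [(83, 99)]

    def test_min_run_filters_short_runs(self):
        values = {i: 0.0 for i in range(40, 60)}
        values[45] = values[46] = 1.0  # run of 2 < min_run 3
        assert call_binding_segments(_profile(values), min_run=3) == []

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            CSPProfile(values={}, point_index=0)

    def test_absolute_threshold_rule(self):
        values = {i: (0.2 if 50 <= i <= 54 else 0.05)
                  for i in range(40, 60)}
        segments = call_binding_segments(_profile(values),
                                         threshold_rule="absolute",
                                         absolute=0.1)
        assert segments == [(50, 54)]


def test_csp_profile_excludes_truncated_trajectories():
    config = default_mbp_scenario()
    series = simulate_titration(config)
    trajs = build_trajectories(series)
    profile = csp_profile(trajs)
    # all 63 non-proline residues present, none negative
    assert len(profile) == 63
    assert all(v >= 0 for v in profile.values.values())
    # prolines absent
    assert not any(lab.startswith("P") for lab in profile.values)
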