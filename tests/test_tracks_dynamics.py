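"""Focus-track simulation and movement/kinetics/ROI statistics."""

import numpy as np
import pandas as pd
import pytest

from drwhite import (
    accumulation_fraction,
    compare_conditions,
    fraction_outside_at,
    median_resolution_time,
    roi_relative_enrichment,
    simulate_focus_tracks,
    simulate_roi_intensities,
    state_at,
)
from drwhite.tracks import (
    INSIDE,
    NOT_DETECTABLE,
    OUTSIDE,
    RESOLVED,
    FocusTrack,
    TrackPreset,
)


def track(*states, focus_id="f"):
    return FocusTrack(focus_id=focus_id, states=tuple(states))


# ---------------------------------------------------------------------------
# track model
# ---------------------------------------------------------------------------


def test_tracks_must_start_inside():
    with pytest.raises(ValueError, match="born inside"):
        track((0.0, OUTSIDE))


def test_resolved_is_absorbing():
    with pytest.raises(ValueError, match="absorbing"):
        track((0.0, INSIDE), (5.0, RESOLVED), (10.0, INSIDE))


def test_unknown_preset_error_lists_presets():
    with pytest.raises(ValueError, match="atrip_control"):
        simulate_focus_tracks("no_such_preset", 5, seed=1)


def test_all_inside_when_p_out_zero():
    preset = TrackPreset("stay", p_out=0.0, p_accumulate=1.0)
    tracks = simulate_focus_tracks(preset, 200, seed=2)
    assert all(state_at(t, 10.0) == INSIDE for t in tracks)


def test_zero_hazard_never_resolves():
    preset = TrackPreset("eternal", p_out=0.5, median_resolution_min=np.inf)
    tracks = simulate_focus_tracks(preset, 100, seed=3)
    assert all(t.resolution_time() is None for t in tracks)
    assert median_resolution_time(tracks) is None


def test_simulation_deterministic_under_seed():
    a = simulate_focus_tracks("atrip_control", 50, seed=7)
    b = simulate_focus_tracks("atrip_control", 50, seed=7)
    assert a == b


# ---------------------------------------------------------------------------
# state_at
# ---------------------------------------------------------------------------


def test_resolved_persists_beyond_last_observation():
    t = track((0.0, INSIDE), (5.0, RESOLVED))
    assert state_at(t, 10.0) == RESOLVED


def test_state_at_lag_zero_is_always_inside():
    tracks = simulate_focus_tracks("mu2_isceI_control", 50, seed=5)
    assert all(state_at(t, 0.0) == INSIDE for t in tracks)


def test_states_match_hand_enumeration():
    fixture = [
        (track((0, INSIDE), (5, OUTSIDE), (10, OUTSIDE)), OUTSIDE),
        (track((0, INSIDE), (5, INSIDE), (10, INSIDE)), INSIDE),
        (track((0, INSIDE), (5, RESOLVED)), RESOLVED),
        (track((0, INSIDE), (5, NOT_DETECTABLE), (10, NOT_DETECTABLE)), NOT_DETECTABLE),
        (track((0, INSIDE), (5, OUTSIDE), (10, OUTSIDE), (15, RESOLVED)), OUTSIDE),
    ]
    for t, expected in fixture:
        assert state_at(t, 10.0) == expected


def test_query_snaps_to_nearest_timepoint():
    t = track((0, INSIDE), (10, OUTSIDE))  # 10-min imaging interval
    assert state_at(t, 9.0) == OUTSIDE
    assert state_at(t, 4.0) == INSIDE


# ---------------------------------------------------------------------------
# movement summaries
# ---------------------------------------------------------------------------


def test_fraction_outside_exact_on_fixture():
    tracks = [track((0, INSIDE), (5, OUTSIDE), (10, OUTSIDE), focus_id=f"o{i}") for i in range(3)]
    tracks += [track((0, INSIDE), (5, INSIDE), (10, INSIDE), focus_id=f"i{i}") for i in range(2)]
    summary = fraction_outside_at(tracks, lag_minutes=10.0)
    assert summary.pct_outside == pytest.approx(60.0)
    assert summary.n_outside_at_t == 3 and summary.n_inside_at_t == 2


def test_all_inside_gives_zero_pct_outside():
    tracks = [track((0, INSIDE), (5, INSIDE), (10, INSIDE))]
    assert fraction_outside_at(tracks).pct_outside == 0.0


def test_atrip_control_preset_recovers_published_percentage():
    n = 2000
    tracks = simulate_focus_tracks("atrip_control", n, seed=11)
    summary = fraction_outside_at(tracks, lag_minutes=10.0)
    sd_pct = 100 * np.sqrt(0.77 * 0.23 / n)
    assert abs(summary.pct_outside - 77.0) <= 4 * sd_pct


def test_pct_outside_invariant_to_order_and_padding():
    tracks = simulate_focus_tracks("mu2_isceI_control", 300, seed=9)
    base = fraction_outside_at(tracks).pct_outside
    shuffled = list(reversed(tracks))
    assert fraction_outside_at(shuffled).pct_outside == base
    padded = [
        FocusTrack(t.focus_id, t.states + ((t.states[-1][0] + 5.0, RESOLVED),))
        if t.states[-1][1] == RESOLVED
        else t
        for t in tracks
    ]
    assert fraction_outside_at(padded).pct_outside == base


def test_parameter_recovery_across_seeds():
    n, p = 2000, 0.53
    estimates = [
        fraction_outside_at(simulate_focus_tracks("atrip_dUtx", n, seed=s)).pct_outside
        for s in range(10)
    ]
    sd_pct = 100 * np.sqrt(p * (1 - p) / n)
    assert abs(np.mean(estimates) - 53.0) < 3 * sd_pct


# ---------------------------------------------------------------------------
# kinetics and accumulation
# ---------------------------------------------------------------------------


def test_median_resolution_simple_cases():
    resolved = [track((0, INSIDE), (40, RESOLVED), focus_id=f"r{i}") for i in range(4)]
    assert median_resolution_time(resolved) == 40.0
    unresolved = [track((0, INSIDE), (40, INSIDE), focus_id=f"u{i}") for i in range(4)]
    assert median_resolution_time(unresolved) is None


def test_mu2_median_resolution_within_published_range():
    """Half the foci resolve within 30-80 min (long-horizon observation)."""
    tracks = simulate_focus_tracks("mu2_isceI_control", 2000, seed=13, horizon_min=150)
    med = median_resolution_time(tracks)
    assert med is not None and 30.0 <= med <= 80.0


def test_accumulation_fraction_fixtures():
    exit_all = [track((0, INSIDE), (5, OUTSIDE), focus_id=f"e{i}") for i in range(4)]
    assert accumulation_fraction(exit_all) == 0.0
    stay_all = [track((0, INSIDE), (5, INSIDE), (10, RESOLVED), focus_id=f"s{i}") for i in range(4)]
    assert accumulation_fraction(stay_all) == 100.0
    mixed = exit_all[:3] + stay_all[:1]
    assert accumulation_fraction(mixed) == pytest.approx(25.0)


# ---------------------------------------------------------------------------
# ROI enrichment
# ---------------------------------------------------------------------------


def test_identical_intensities_give_unit_ratio():
    table = pd.DataFrame(
        {"cell_id": ["a", "b"], "dsb_mean_intensity": [5.0, 7.0], "domain_mean_intensity": [5.0, 7.0]}
    )
    result = roi_relative_enrichment(table)
    assert result.mean_ratio == 1.0 and result.pct_drop == 0.0


def test_two_row_fixture_mean_ratio():
    table = pd.DataFrame(
        {"cell_id": ["a", "b"], "dsb_mean_intensity": [0.8, 1.0], "domain_mean_intensity": [1.0, 1.0]}
    )
    assert roi_relative_enrichment(table).mean_ratio == pytest.approx(0.9)


def test_nonpositive_domain_rows_rejected_with_warning():
    table = pd.DataFrame(
        {"cell_id": ["a", "b"], "dsb_mean_intensity": [1.0, 1.0], "domain_mean_intensity": [0.0, 2.0]}
    )
    with pytest.warns(UserWarning, match="rejected"):
        result = roi_relative_enrichment(table)
    assert result.n_rejected == 1 and len(result.ratios) == 1


def test_damaged_control_preset_recovers_ten_percent_drop():
    n = 300
    table = simulate_roi_intensities("damaged_control", n, seed=2)
    result = roi_relative_enrichment(table)
    # delta-method SD of the mean per-cell ratio: 0.9 * sigma / sqrt(n)
    sd = 0.9 * np.sqrt(np.exp(0.1**2) - 1) / np.sqrt(n)
    assert abs(result.mean_ratio - 0.90) <= 4 * sd
    assert result.pct_drop == pytest.approx(10.0, abs=4 * sd * 100)


def test_noise_free_unit_ratio_preset():
    from drwhite.plates import RoiPreset

    preset = RoiPreset("exact", true_ratio=1.0, ratio_sigma=0.0)
    table = simulate_roi_intensities(preset, 50, seed=3)
    np.testing.assert_allclose(
        table["dsb_mean_intensity"] / table["domain_mean_intensity"], 1.0
    )


def test_empty_roi_table_allowed():
    table = simulate_roi_intensities("damaged_control", 0, seed=1)
    assert len(table) == 0


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------


def test_identical_conditions_give_p_one():
    tracks = simulate_focus_tracks("atrip_control", 200, seed=4)
    a = fraction_outside_at(tracks)
    stat, df, p = compare_conditions(a, a)
    assert stat == 0.0 and p == 1.0


def test_different_presets_detected():
    a = fraction_outside_at(simulate_focus_tracks("atrip_control", 1000, seed=6))
    b = fraction_outside_at(simulate_focus_tracks("atrip_dUtx", 1000, seed=6))
    _, _, p = compare_conditions(a, b)
    assert p < 1e-6
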