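import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actiplace import features, synth
from actiplace.features import (
    FEATURE_NAMES,
    TriaxialWindow,
    extract_feature_table,
    featurize_window,
    frequency_features,
    segment_windows,
    time_features,
    vector_magnitude,
)
from actiplace.placements import PLACEMENTS


def make_window(samples, rate=100.0):
    return TriaxialWindow(
        samples=np.asarray(samples, dtype=float),
        sample_rate=rate,
        window_start=pd.Timestamp("2024-01-01T00:00:00Z"),
        participant_id="P001",
        activity_name="act",
        placement="hip",
    )


def vm_window(vm_values, rate=100.0):
    """Embed a target VM sequence on the x-axis (VM == |x|, so the sequence
    must be non-negative to survive the magnitude)."""
    vm_values = np.asarray(vm_values, dtype=float)
    assert (vm_values >= 0).all(), "vm_window needs a non-negative sequence"
    n = len(vm_values)
    samples = np.zeros((n, 3))
    samples[:, 0] = vm_values
    return make_window(samples, rate)


def brute_force_dft_features(vm, rate, band=(0.6, 2.5)):
    """Independent oracle: direct DFT summation over positive frequencies."""
    vm = np.asarray(vm, dtype=float)
    n = vm.size
    centered = vm - vm.mean()
    ks = np.arange(1, n // 2 + 1)
    moduli = np.empty(ks.size)
    for i, k in enumerate(ks):
        acc = 0.0 + 0.0j
        for m in range(n):
            acc += centered[m] * np.exp(-2j * np.pi * k * m / n)
        moduli[i] = abs(acc)
    freqs = ks * rate / n
    total = moduli.sum()
    if total == 0:
        return {"power_frac_band": 0.0, "dom_freq": 0.0, "frac_at_dom": 0.0}
    sel = (freqs >= band[0]) & (freqs <= band[1])
    k_dom = int(np.argmax(moduli))
    return {
        "power_frac_band": moduli[sel].sum() / total,
        "dom_freq": freqs[k_dom],
        "frac_at_dom": moduli[k_dom] / total,
    }


class TestSegmentation:
    def _session(self, duration_s, rate=100.0):
        n = int(round(duration_s * rate))
        return synth.RecordingSession(
            participant_id="P001",
            activity_name="act",
            placement="hip",
            sample_rate=rate,
            samples=np.zeros((n, 3)) + [0, 0, 1],
            start_time=pd.Timestamp("2024-01-01T00:00:00Z"),
            stop_time=pd.Timestamp("2024-01-01T00:00:00Z")
            + pd.to_timedelta(duration_s, unit="s"),
        )

    def test_360s_gives_22_windows(self):
        wins = segment_windows(self._session(360.0), 16.0)
        assert len(wins) == 22
        assert all(w.samples.shape == (1600, 3) for w in wins)

    def test_exact_window_gives_one(self):
        assert len(segment_windows(self._session(16.0), 16.0)) == 1

    def test_partial_window_discarded(self):
        assert segment_windows(self._session(15.0), 16.0) == []

    def test_windows_are_contiguous(self):
        wins = segment_windows(self._session(48.0), 16.0)
        starts = [w.window_start for w in wins]
        assert starts == sorted(starts)
        assert (starts[1] - starts[0]).total_seconds() == 16.0

    def test_bad_window_size(self):
        with pytest.raises(ValueError):
            segment_windows(self._session(32.0), 0.0)

    @given(duration=st.floats(min_value=1.0, max_value=500.0))
    @settings(max_examples=25, deadline=None)
    def test_window_count_is_floor(self, duration):
        wins = segment_windows(self._session(duration), 16.0)
        assert len(wins) == int(round(duration * 100)) // 1600


class TestVectorMagnitude:
    def test_pythagorean_triple(self):
        assert vector_magnitude(make_window([[3, 4, 0]] * 4))[0] == pytest.approx(5.0)

    def test_unit_gravity(self):
        assert np.allclose(vector_magnitude(make_window([[0, 0, 1]] * 8)), 1.0)

    def test_ones(self):
        assert vector_magnitude(make_window([[1, 1, 1]] * 4))[0] == pytest.approx(
            np.sqrt(3)
        )


class TestTimeFeatures:
    def test_constant_vm_degenerates(self):
        feats = time_features(make_window([[0, 0, 1]] * 64))
        assert feats["sd_vm"] == 0.0
        assert feats["entropy_vm"] == 0.0
        assert feats["cv_vm"] == 0.0
        assert feats["skew_vm"] == 0.0

    def test_identical_axes_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=64)
        samples = np.column_stack([x, x, rng.normal(size=64)])
        feats = time_features(make_window(samples))
        assert feats["corr_xy"] == pytest.approx(1.0)

    def test_mean_angle_orthogonal_gravity(self):
        # x-axis orthogonal to the VM direction -> arccos(0) = pi/2
        feats = time_features(make_window([[0, 0, 1]] * 64))
        assert feats["mean_angle"] == pytest.approx(np.pi / 2)
        assert feats["sd_angle"] == 0.0

    def test_two_point_entropy_closed_form(self):
        # 3/4 of samples at one value, 1/4 at another:
        # H = -(0.75 log2 0.75 + 0.25 log2 0.25)
        vm = np.array([1.0] * 48 + [2.0] * 16)
        feats = time_features(vm_window(vm))
        expected = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        assert feats["entropy_vm"] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_sequence_zero_skew(self):
        vm = np.concatenate([np.linspace(1, 2, 32), np.linspace(2, 1, 32)])
        feats = time_features(vm_window(vm))
        assert abs(feats["skew_vm"]) < 1e-12

    def test_cv_arithmetic(self):
        vm = np.array([1.0, 2.0] * 32)
        feats = time_features(vm_window(vm))
        assert feats["cv_vm"] == pytest.approx(100 * vm.std(ddof=1) / vm.mean())

    def test_autocov_lag1(self):
        rng = np.random.default_rng(1)
        vm = rng.normal(10, 1, size=200)
        feats = time_features(vm_window(vm))
        c = vm - vm.mean()
        assert feats["autocov_vm"] == pytest.approx(
            np.sum(c[:-1] * c[1:]) / (len(vm) - 2)
        )

    def test_autocov_lag0_is_variance(self):
        rng = np.random.default_rng(2)
        vm = rng.normal(10, 1, size=200)
        feats = time_features(vm_window(vm), autocov_lag=0)
        assert feats["autocov_vm"] == pytest.approx(vm.var(ddof=1))

    def test_zero_variance_axis_warns_and_zeroes(self):
        samples = np.column_stack(
            [np.random.default_rng(0).normal(size=64), np.zeros(64), np.ones(64)]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            feats = time_features(make_window(samples))
        assert feats["corr_xy"] == 0.0

    def test_all_zero_vm_flags_angles(self):
        with pytest.warns(UserWarning):
            feats = time_features(make_window(np.zeros((64, 3))))
        assert np.isnan(feats["mean_angle"])

    def test_excess_kurtosis_of_normal_near_zero(self):
        vm = np.random.default_rng(3).normal(10, 1, size=100_000)
        feats = time_features(vm_window(vm))
        assert abs(feats["kurt_vm"]) < 0.05


class TestFrequencyFeatures:
    def test_on_grid_tone_in_band(self):
        t = np.arange(1600) / 100.0
        vm = 1.0 + np.cos(2 * np.pi * 2.0 * t)
        feats = frequency_features(vm_window(vm))
        assert feats["dom_freq"] == pytest.approx(2.0)
        assert feats["frac_at_dom"] == pytest.approx(1.0, abs=1e-9)
        assert feats["power_frac_band"] == pytest.approx(1.0, abs=1e-9)

    def test_out_of_band_tone(self):
        t = np.arange(1600) / 100.0
        vm = 1.0 + np.cos(2 * np.pi * 5.0 * t)
        feats = frequency_features(vm_window(vm))
        assert feats["power_frac_band"] == pytest.approx(0.0, abs=1e-9)
        assert feats["dom_freq"] == pytest.approx(5.0)

    def test_constant_vm_degenerate(self):
        feats = frequency_features(make_window([[0, 0, 1]] * 64))
        assert feats == {"power_frac_band": 0.0, "dom_freq": 0.0, "frac_at_dom": 0.0}

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_n64(self, seed):
        rng = np.random.default_rng(seed)
        vm = np.abs(rng.normal(1.0, 0.3, size=64)) + 0.1
        rate = 4.0  # grid spans 0.0625..2.0 Hz, straddling the band edge
        feats = frequency_features(vm_window(vm, rate=rate))
        oracle = brute_force_dft_features(vm, rate)
        for key in feats:
            assert feats[key] == pytest.approx(oracle[key], rel=1e-9, abs=1e-12)

    def test_tie_breaks_to_lowest_frequency(self):
        n, rate = 64, 64.0
        t = np.arange(n) / rate
        vm = 3.0 + np.cos(2 * np.pi * 3.0 * t) + np.cos(2 * np.pi * 7.0 * t)
        feats = frequency_features(vm_window(vm, rate=rate))
        assert feats["dom_freq"] == pytest.approx(3.0)


class TestScaleBehavior:
    @given(
        c=st.floats(min_value=0.1, max_value=10.0),
        seed=st.integers(min_value=0, max_value=1000),
    )
    @settings(max_examples=20, deadline=None)
    def test_scaling_axes(self, c, seed):
        rng = np.random.default_rng(seed)
        samples = rng.normal(0.5, 0.3, size=(128, 3))
        base = featurize_window(make_window(samples))
        scaled = featurize_window(make_window(c * samples))
        assert scaled["mean_vm"] == pytest.approx(c * base["mean_vm"], rel=1e-9)
        assert scaled["sd_vm"] == pytest.approx(c * base["sd_vm"], rel=1e-9)
        for key in ("cv_vm", "mean_angle", "sd_angle", "corr_xy", "corr_yz",
                    "corr_xz", "power_frac_band", "dom_freq", "frac_at_dom",
                    "skew_vm", "kurt_vm", "entropy_vm"):
            assert scaled[key] == pytest.approx(base[key], rel=1e-6, abs=1e-9)


class TestFeatureTable:
    def _sessions(self, duration=360.0, placements=PLACEMENTS):
        roster = synth.build_default_roster(2, 1, seed=0)
        activity = roster[1]
        participant = synth.ParticipantSpec("P001")
        start = pd.Timestamp("2024-01-01T08:00:00Z")
        sessions = [
            synth.simulate_session(
                participant, activity, p, duration, i, start_time=start
            )
            for i, p in enumerate(placements)
        ]
        log = pd.DataFrame(
            [{
                "participant_id": "P001",
                "activity": activity.name,
                "category": activity.category,
                "start": start,
                "stop": start + pd.to_timedelta(duration, unit="s"),
            }]
        )
        return sessions, log

    def test_full_placement_table_shape(self):
        sessions, log = self._sessions()
        table = extract_feature_table(sessions, log)
        assert len(table) == 22
        feature_cols = [c for c in table.columns if any(c.endswith(f) for f in FEATURE_NAMES)]
        assert len(feature_cols) == 75

    def test_empty_log_gives_empty_table(self):
        sessions, _ = self._sessions()
        table = extract_feature_table(sessions, pd.DataFrame(columns=["participant_id"]))
        assert table.empty

    def test_trimmed_log_drops_boundary_windows(self):
        sessions, log = self._sessions()
        log["stop"] = log["start"] + pd.to_timedelta(32.0, unit="s")
        table = extract_feature_table(sessions, log)
        assert len(table) == 2

    def test_every_row_has_15_features_per_placement(self):
        sessions, log = self._sessions()
        table = extract_feature_table(sessions, log)
        for p in PLACEMENTS:
            cols = [f"{p}_{f}" for f in FEATURE_NAMES]
            assert len(cols) == 15
            assert table[cols].notna().all().all()

    def test_missing_placement_leaves_nan(self):
        sessions, log = self._sessions(placements=("hip", "wrist"))
        table = extract_feature_table(sessions, log)
        assert {c.split("_")[0] for c in table.columns if c.endswith("mean_vm")} == {
            "hip", "wrist"
        }

    def test_met_labels_joined(self):
        sessions, log = self._sessions()
        met = pd.DataFrame(
            {"participant_id": ["P001"], "activity": [sessions[0].activity_name],
             "met_value": [2.5]}
        )
        table = extract_feature_table(sessions, log, met_labels=met)
        assert (table["met"] == 2.5).all()

    def test_category_flags(self, tiny_table):
        flags = tiny_table[["is_sedentary", "is_locomotion", "is_lifestyle"]]
        assert (flags.sum(axis=1) == 1).all()


def test_locomotion_band_power_exceeds_sedentary_everywhere(tiny_table):
    # the stated category-separability effect: locomotion windows carry more
    # 0.6-2.5 Hz spectral mass than sedentary windows at every placement
    for p in PLACEMENTS:
        col = f"{p}_power_frac_band"
        loco = tiny_table.loc[tiny_table["is_locomotion"], col].mean()
        sed = tiny_table.loc[tiny_table["is_sedentary"], col].mean()
        assert loco > sed, p
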