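import numpy as np
import pandas as pd
import pytest

from benthoval import synthdata as sd


class TestGenerateMesh:
    def test_same_seed_gives_identical_mesh(self):
        m1, _ = sd.generate_mesh(n_nodes=80, seed=3)
        m2, _ = sd.generate_mesh(n_nodes=80, seed=3)
        np.testing.assert_array_equal(m1.x, m2.x)
        np.testing.assert_array_equal(m1.h, m2.h)
        np.testing.assert_array_equal(m1.elements, m2.elements)

    def test_bathymetry_within_bounds(self):
        mesh, _ = sd.generate_mesh(n_nodes=100, depth_range=(5.0, 290.0), seed=4)
        assert mesh.h.min() >= 5.0 and mesh.h.max() <= 290.0

    def test_every_node_belongs_to_an_element(self):
        mesh, _ = sd.generate_mesh(n_nodes=100, seed=5)
        used = set(np.unique(mesh.elements))
        assert used == set(mesh.node_ids.tolist())

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_mesh(extent=(0.0, 1000.0), seed=1)


class TestGenerateFields:
    def test_zero_bias_means_model_equals_truth(self, small_mesh):
        mesh, scheme = small_mesh
        tam = sd.generate_fields(mesh, scheme, start="2016-01-01", end="2016-01-03",
                                 bias=sd.BiasSchedule.constant(0.0), seed=1)
        np.testing.assert_array_equal(tam.model.temp, tam.truth.temp)

    def test_constant_bias_is_additive_everywhere(self, small_mesh):
        mesh, scheme = small_mesh
        tam = sd.generate_fields(mesh, scheme, start="2016-01-01", end="2016-01-03",
                                 bias=sd.BiasSchedule.constant(0.5), seed=1)
        np.testing.assert_allclose(tam.model.temp - tam.truth.temp, 0.5)

    def test_summer_stratification_magnitude(self, small_mesh):
        # July mean surface-minus-bottom contrast should sit in the 1-2 degC
        # band the site shows at the height of summer stratification
        mesh, scheme = small_mesh
        tam = sd.generate_fields(mesh, scheme, start="2016-07-01", end="2016-08-01",
                                 bias=sd.BiasSchedule.constant(0.0), seed=2)
        contrast = (tam.truth.temp[:, :, 0] - tam.truth.temp[:, :, -1]).mean()
        assert 1.0 <= contrast <= 2.0

    def test_seasonal_range_approximately_6_to_16(self, small_mesh):
        mesh, scheme = small_mesh
        tam = sd.generate_fields(mesh, scheme, start="2016-01-01", end="2017-01-01",
                                 bias=sd.BiasSchedule.constant(0.0), seed=3)
        bottom = tam.truth.bottom()
        assert 5.0 < bottom.min() < 7.5
        assert 14.5 < bottom.max() < 17.0


class TestBiasSchedule:
    def test_two_period_offsets_switch_at_date(self, small_mesh):
        mesh, _ = small_mesh
        hours = pd.date_range("2016-12-31 22:00", periods=6, freq="h")
        off = sd.BiasSchedule.two_period("2017-01-01", 0.53, -0.045).offsets(hours, mesh)
        np.testing.assert_allclose(off[:2], 0.53)
        np.testing.assert_allclose(off[2:], -0.045)

    def test_depth_class_rule_applies_to_matching_nodes_only(self, small_mesh):
        mesh, _ = small_mesh
        hours = pd.date_range("2016-06-01", periods=2, freq="h")
        sched = sd.BiasSchedule((sd.BiasRule("2016-01-01", "2017-01-01", 1.0, "deep"),))
        off = sched.offsets(hours, mesh)
        deep = mesh.h >= sd.SHALLOW_CUTOFF_M
        np.testing.assert_allclose(off[:, deep], 1.0)
        np.testing.assert_allclose(off[:, ~deep], 0.0)


class TestSimulateTrack:
    def test_zero_step_scale_is_stationary(self, small_mesh):
        mesh, _ = small_mesh
        track = sd.simulate_track(mesh, "2016-06-01", "2016-06-02",
                                  step_sd=0.0, home=(2500.0, 2500.0), seed=1)
        assert track["x"].nunique() == 1 and track["y"].nunique() == 1

    def test_positions_stay_inside_hull(self, small_mesh):
        mesh, _ = small_mesh
        track = sd.simulate_track(mesh, "2016-06-01", "2016-06-08",
                                  step_sd=300.0, home_strength=0.0, seed=2)
        assert track["x"].between(mesh.x.min(), mesh.x.max()).all()
        assert track["y"].between(mesh.y.min(), mesh.y.max()).all()

    def test_depth_tracks_local_bathymetry_within_offset(self, small_mesh):
        mesh, _ = small_mesh
        track = sd.simulate_track(mesh, "2016-06-01", "2016-06-02",
                                  max_offset=0.5, seed=3)
        gap = track["seabed_m"] - track["depth_m"]
        assert (gap >= 0).all() and (gap <= 0.5).all()
        np.testing.assert_array_equal(
            track["seabed_m"], mesh.h[mesh.index_of(track["node_id"].values)]
        )


class TestSampleArchival:
    def test_noiseless_unquantised_equals_truth(self, june_fields):
        mesh, scheme, tam = june_fields
        track = sd.simulate_track(mesh, "2016-06-02", "2016-06-03", seed=4)
        spec = sd.TagSpec(temp_resolution=0.0, temp_accuracy_sd=0.0,
                          depth_resolution=0.0, depth_accuracy_sd=0.0)
        arch = sd.sample_archival(track, tam.truth, mesh, spec, seed=5)
        t_idx = sd._hour_index(tam.truth.hours, pd.DatetimeIndex(track["timestamp"]))
        n_idx = mesh.index_of(track["node_id"].values)
        np.testing.assert_array_equal(arch["temp_c"], tam.truth.bottom()[t_idx, n_idx])
        np.testing.assert_array_equal(arch["depth_m"], track["depth_m"])

    def test_temperatures_are_quantisation_multiples(self, june_fields):
        mesh, scheme, tam = june_fields
        track = sd.simulate_track(mesh, "2016-06-02", "2016-06-03", seed=4)
        arch = sd.sample_archival(track, tam.truth, mesh, seed=6)
        steps = arch["temp_c"] / 0.032
        np.testing.assert_allclose(steps, np.round(steps), atol=1e-9)

    def test_mean_error_vanishes_by_law_of_large_numbers(self, june_fields):
        mesh, scheme, tam = june_fields
        track = sd.simulate_track(mesh, "2016-06-02", "2016-06-16", seed=7)
        arch = sd.sample_archival(track, tam.truth, mesh, seed=8)
        t_idx = sd._hour_index(tam.truth.hours, pd.DatetimeIndex(track["timestamp"]))
        n_idx = mesh.index_of(track["node_id"].values)
        err = arch["temp_c"].values - tam.truth.bottom()[t_idx, n_idx]
        n = len(err)
        assert n >= 10_000
        # 3 sigma of the mean, plus a quantisation-bias allowance
        assert abs(err.mean()) < 3 * 0.1 / np.sqrt(n) + 0.032 / 4


class TestSimulateDetections:
    @staticmethod
    def _parked_track(mesh, where, days=2):
        end = pd.Timestamp("2016-06-02") + pd.Timedelta(days=days)
        return sd.simulate_track(mesh, "2016-06-02", end, step_sd=0.0,
                                 home=where, seed=9)

    def test_detection_rate_at_receiver_matches_binomial(self, small_mesh):
        mesh, _ = small_mesh
        rx = pd.DataFrame({"receiver_id": ["R00"], "x": [2500.0], "y": [2500.0]})
        model = sd.DetectionModel(delay_jitter_s=0.0, false_rate_per_day=0.0)
        track = self._parked_track(mesh, (2500.0, 2500.0))
        det = sd.simulate_detections(track, rx, model, seed=10)
        n_tx = int((track["timestamp"].iloc[-1] - track["timestamp"].iloc[0])
                   .total_seconds() // model.nominal_delay_s)
        p0 = float(model.probability(0.0))
        sd_count = np.sqrt(n_tx * p0 * (1 - p0))
        assert abs(len(det) - n_tx * p0) < 5 * sd_count + 3

    def test_probability_is_half_at_the_p50_range(self, small_mesh):
        mesh, _ = small_mesh
        rx = pd.DataFrame({"receiver_id": ["R00"], "x": [1000.0], "y": [2500.0]})
        model = sd.DetectionModel(delay_jitter_s=0.0, false_rate_per_day=0.0)
        track = self._parked_track(mesh, (1425.0, 2500.0), days=3)
        det = sd.simulate_detections(track, rx, model, seed=11)
        n_tx = int((track["timestamp"].iloc[-1] - track["timestamp"].iloc[0])
                   .total_seconds() // model.nominal_delay_s)
        p_hat = len(det) / n_tx
        assert abs(p_hat - 0.5) < 4 * np.sqrt(0.25 / n_tx)

    def test_transmissions_respect_minimum_spacing(self, small_mesh):
        mesh, _ = small_mesh
        rx = pd.DataFrame({"receiver_id": ["R00"], "x": [2500.0], "y": [2500.0]})
        model = sd.DetectionModel(delay_jitter_s=15.0, false_rate_per_day=0.0)
        track = self._parked_track(mesh, (2500.0, 2500.0))
        det = sd.simulate_detections(track, rx, model, seed=12)
        gaps = det["timestamp"].diff().dt.total_seconds().dropna()
        assert gaps.min() >= model.nominal_delay_s - model.delay_jitter_s - 1e-6

    def test_no_false_rate_means_no_unknown_transmitters(self, small_mesh):
        mesh, _ = small_mesh
        rx = pd.DataFrame({"receiver_id": ["R00"], "x": [2500.0], "y": [2500.0]})
        model = sd.DetectionModel(false_rate_per_day=0.0)
        track = self._parked_track(mesh, (2500.0, 2500.0))
        det = sd.simulate_detections(track, rx, model, transmitter_id="tag-7", seed=13)
        assert set(det["transmitter_id"]) == {"tag-7"}
        assert not det["is_false"].any()


class TestSimulateAngling:
    @pytest.fixture()
    def angling(self, june_fields):
        mesh, scheme, tam = june_fields
        track = sd.simulate_track(mesh, "2016-06-01", "2016-06-09", seed=14)
        arch = sd.sample_archival(track, tam.truth, mesh, seed=15)
        events, arch2 = sd.simulate_angling(track, arch, tam.truth, mesh, scheme,
                                            n_events=4, seed=16)
        return track, arch, events, arch2

    def test_durations_drawn_within_8_to_20_minutes(self, angling):
        _, _, events, _ = angling
        assert events["drawn_duration_min"].between(8.0, 20.0).all()

    def test_each_event_ends_at_the_surface(self, angling):
        _, _, events, arch2 = angling
        for _, ev in events.iterrows():
            win = arch2[(arch2["timestamp"] > ev["event_time"])
                        & (arch2["timestamp"] <= ev["event_time"] + pd.Timedelta(minutes=25))]
            assert win["depth_m"].min() <= 1.0

    def test_start_depth_matches_preevent_seabed(self, angling):
        track, _, events, arch2 = angling
        tt = pd.DatetimeIndex(track["timestamp"])
        for _, ev in events.iterrows():
            i = tt.get_indexer([ev["event_time"]], method="nearest")[0]
            seabed = track["depth_m"].iloc[i]
            rec = arch2.loc[arch2["timestamp"] == ev["event_time"], "depth_m"].iloc[0]
            # tag depth noise is 4.77 m (1 sd); allow 4 sd plus quantisation
            assert abs(rec - seabed) < 4 * 4.77 + 0.24

    def test_last_event_is_the_retrieval(self, angling):
        _, _, events, _ = angling
        assert events["event_type"].tolist() == ["liberty"] * 3 + ["retrieval"]
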