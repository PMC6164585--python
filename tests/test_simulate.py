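"""Scene synthesis: hen call, rendering fidelity, grids and evaluation."""

import numpy as np
import pytest
from scipy.signal import welch

from coopssl.geometry import axis_to_boresight, solve_angle
from coopssl.simulate import (
    REFERENCE_BEARINGS_DEG,
    ArrayPose,
    HenCallModel,
    SceneSource,
    SceneSpec,
    bearing_scene,
    evaluate_localiser,
    reference_grid,
    render_scene,
    synth_hen_call,
)
from coopssl.tdoa import AudioFrame, estimate_delay, measure_frame, sound_present

FS = 16_000


class TestHenCall:
    def test_sample_count_for_nominal_call(self):
        assert synth_hen_call(2.48, FS, seed=0).size == 39_680

    def test_seeded_determinism(self):
        assert np.array_equal(synth_hen_call(seed=11), synth_hen_call(seed=11))
        assert not np.array_equal(synth_hen_call(seed=11),
                                  synth_hen_call(seed=12))

    def test_spectral_peak_in_fundamental_band(self):
        for seed in range(5):
            x = synth_hen_call(2.48, FS, seed=seed)
            f, p = welch(x, fs=FS, nperseg=4096)
            assert 400.0 <= f[np.argmax(p)] <= 800.0

    def test_loops_seamlessly(self, hen_call_model):
        t = np.array([0.1, 0.7])
        assert hen_call_model.evaluate(t) == pytest.approx(
            hen_call_model.evaluate(t + hen_call_model.duration), abs=1e-9
        )


class TestRenderScene:
    def test_noiseless_channel_delays_match_geometry(self, hen_call_model):
        pose = ArrayPose(name="A", height=0.0)
        src = (0.4, 1.5)
        spec = SceneSpec(
            sources=(SceneSource(position=src, signal=hen_call_model),),
            arrays=(pose,), snr_db=None, duration=1.0,
            pen=(-2, 2, -2, 2),
        )
        waves, _ = render_scene(spec)
        r = pose.mic_distances(src)
        i, j, k = pose.geometry.solver_triple
        for p, q in ((i, j), (j, k)):
            truth = (r[p] - r[q]) / pose.geometry.c
            est, _ = estimate_delay(
                waves["A"][p], waves["A"][q], FS, 5e-4
            )
            assert est * FS == pytest.approx(truth * FS, abs=0.05)

    def test_signal_off_means_no_sound_present(self, hen_call_model):
        spec = SceneSpec(
            sources=(SceneSource(position=(0.2, 0.3), signal=hen_call_model,
                                 schedule=()),),
            snr_db=None, duration=2.0,
        )
        waves, truth = render_scene(spec)
        for name, wave in waves.items():
            frame = AudioFrame(wave[:, :FS], FS)
            assert not sound_present(frame, 1e-12)
        assert not truth["active"].any()

    def test_seeded_renders_identical(self, hen_call_model):
        spec = SceneSpec(
            sources=(SceneSource(position=(0.2, 0.3), signal=hen_call_model),),
            duration=1.0, seed=42,
        )
        w1, t1 = render_scene(spec)
        w2, t2 = render_scene(spec)
        for name in w1:
            assert np.array_equal(w1[name], w2[name])
        assert t1.equals(t2)

    def test_source_outside_pen_rejected(self, hen_call_model):
        with pytest.raises(ValueError):
            SceneSpec(sources=(SceneSource(position=(5.0, 0.0),
                                           signal=hen_call_model),))

    def test_sampled_signal_source_delay(self, hen_call_model):
        """Array (sampled) source signals go through windowed-sinc fractional
        delay and must land within 0.05 sample of the geometric truth."""
        pose = ArrayPose(name="A", height=0.0)
        src = (0.3, 1.2)
        samples = hen_call_model.sample(1.0, FS)
        spec = SceneSpec(
            sources=(SceneSource(position=src, signal=samples),),
            arrays=(pose,), snr_db=None, duration=1.0, pen=(-2, 2, -2, 2),
        )
        waves, _ = render_scene(spec)
        r = pose.mic_distances(src)
        i, j, _ = pose.geometry.solver_triple
        truth = (r[i] - r[j]) / pose.geometry.c
        est, _ = estimate_delay(waves["A"][i], waves["A"][j], FS, 5e-4)
        assert est * FS == pytest.approx(truth * FS, abs=0.05)

    def test_ground_truth_active_seconds_audible(self, hen_call_model):
        spec = SceneSpec(
            sources=(SceneSource(position=(0.2, 0.3), signal=hen_call_model,
                                 schedule=((0.0, 2.0),)),),
            snr_db=30.0, duration=4.0, seed=1,
        )
        waves, truth = render_scene(spec)
        wave = waves["A"]
        rms = [AudioFrame(wave[:, s * FS:(s + 1) * FS], FS).rms()
               for s in range(4)]
        floor = min(rms)
        for row in truth.itertuples(index=False):
            if row.active:
                assert rms[row.second] > 3 * floor


class TestReferenceGrid:
    def test_grid_size_and_centre(self):
        grid = reference_grid()
        assert len(grid) == 63
        centre = grid[(grid.x == 0) & (grid.y == 0)].iloc[0]
        assert centre.bearing_A == pytest.approx(0.0)
        assert centre.bearing_B == pytest.approx(0.0)

    def test_outer_columns_reach_reference_extremes(self):
        grid = reference_grid()
        row = grid[(grid.x == grid.x.max()) & (grid.y == 0)].iloc[0]
        assert row.bearing_A == pytest.approx(28.0, abs=1.0)
        row = grid[(grid.x == grid.x.min()) & (grid.y == 0)].iloc[0]
        assert row.bearing_A == pytest.approx(-28.0, abs=1.0)

    def test_mirror_symmetry_of_bearings(self):
        grid = reference_grid()
        for rec in grid.itertuples(index=False):
            twin = grid[(grid.x == -rec.x) & (grid.y == rec.y)].iloc[0]
            assert twin.bearing_A == pytest.approx(-rec.bearing_A)


class TestEvaluateLocaliser:
    def test_exact_delays_perfect_on_interior_points(self):
        """In the analytic-TDOA oracle limit every grid point strictly inside
        an area (off the array axes) must be assigned correctly."""
        grid = reference_grid()
        interior = grid[
            (grid.bearing_A.abs() > 0.5) & (grid.bearing_B.abs() > 0.5)
        ].reset_index(drop=True)
        table, errors = evaluate_localiser(grid=interior, exact=True)
        assert table.loc["Total", "accuracy_pct"] == 100.0
        err = errors[["abs_err_A", "abs_err_B"]].astype(float).to_numpy()
        assert np.nanmax(err) < 1e-9

    def test_rendered_audio_reference_bearings_within_two_degrees(self,
                                                                  geometry):
        """Rendered 16 kHz audio at the nine reference bearings (1.8 m range,
        20 dB SNR) must localise to a mean absolute error of 2 deg or less."""
        errs = []
        for i, brg in enumerate(REFERENCE_BEARINGS_DEG):
            spec = bearing_scene(brg, seed=100 + i, snr_db=20.0,
                                 duration=2.0)
            waves, _ = render_scene(spec)
            for f in range(2):
                frame = AudioFrame(waves["A"][:, f * FS:(f + 1) * FS], FS)
                meas = measure_frame(frame, geometry)
                phi = axis_to_boresight(solve_angle(meas, geometry))
                errs.append(abs(phi - brg))
        assert np.mean(errs) <= 2.0

    def test_rendered_grid_self_consistent(self):
        """A small rendered evaluation produces a coherent accuracy table."""
        grid = reference_grid().iloc[::9].reset_index(drop=True)
        table, errors = evaluate_localiser(grid=grid, exact=False,
                                           snr_db=10.0, seed=5)
        assert (table["total"] == table["correct"] + table["incorrect"]).all()
        areas = table.drop(index="Total")
        assert table.loc["Total", "total"] == areas["total"].sum()
        assert ((areas["accuracy_pct"] >= 0) & (areas["accuracy_pct"] <= 100)).all()
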