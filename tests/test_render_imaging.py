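from dataclasses import replace

import numpy as np
import pytest

from guvflux.calibration import ph_to_intensity
from guvflux.imaging import (Detection, detect_vesicles, measure_background,
                             measure_lumen_intensity, measure_stack,
                             track_vesicles)
from guvflux.render import (ImageRenderConfig, read_timelapse,
                            render_timelapse, write_timelapse)
from guvflux.simulate import SimulationConfig, simulate_acidification

NOISELESS = dict(poisson_scale=0.0, read_noise_sd=0.0, seed=None,
                 dtype="float64")


@pytest.fixture(scope="module")
def short_trace():
    """Short default-scenario trace for rendering (radius = 20 px)."""
    cfg = SimulationConfig(radius=20 * 0.5e-4, duration=60.0)
    return simulate_acidification(cfg)


@pytest.fixture(scope="module")
def noiseless_stack(short_trace, curve):
    cfg = ImageRenderConfig(shape=(128, 128), positions=((64.0, 64.0),),
                            **NOISELESS)
    return render_timelapse([short_trace], curve, cfg)


class TestRender:
    def test_noiseless_lumen_and_background_exact(self, short_trace, curve,
                                                  noiseless_stack):
        det = Detection(0, (64.0, 64.0), 20.0, 1.0)
        lum = measure_lumen_intensity(noiseless_stack[0, 1], det)
        assert lum == pytest.approx(
            ph_to_intensity(short_trace.pH_i[0], curve), rel=1e-12)
        bg = measure_background(noiseless_stack[3, 1], [det])
        assert bg == pytest.approx(
            ph_to_intensity(short_trace.pH_o[3], curve), rel=1e-12)

    def test_fixed_seed_renders_are_bit_identical(self, short_trace, curve):
        cfg = ImageRenderConfig(shape=(128, 128), positions=((64.0, 64.0),),
                                seed=11)
        a = render_timelapse([short_trace], curve, cfg)
        b = render_timelapse([short_trace], curve, cfg)
        assert np.array_equal(a, b)
        c = render_timelapse([short_trace], curve, replace(cfg, seed=12))
        assert not np.array_equal(a, c)

    def test_noise_requires_seed(self, short_trace, curve):
        cfg = ImageRenderConfig(shape=(128, 128), positions=((64.0, 64.0),),
                                seed=None)
        with pytest.raises(ValueError, match="seed"):
            render_timelapse([short_trace], curve, cfg)

    def test_vesicle_leaving_frame_rejected(self, short_trace, curve):
        cfg = ImageRenderConfig(shape=(64, 64), positions=((60.0, 60.0),),
                                **NOISELESS)
        with pytest.raises(ValueError, match="leaves the frame"):
            render_timelapse([short_trace], curve, cfg)

    def test_tiff_round_trip(self, noiseless_stack, tmp_path):
        path = tmp_path / "stack.tif"
        write_timelapse(path, noiseless_stack)
        back = read_timelapse(path)
        np.testing.assert_array_equal(back, noiseless_stack)


class TestDetect:
    def test_blank_frame_yields_nothing(self):
        assert detect_vesicles(np.full((64, 64), 7.0), (5, 20)) == []

    def test_render_detect_round_trip(self, noiseless_stack):
        dets = detect_vesicles(noiseless_stack[0, 0], (12, 30))
        assert len(dets) == 1
        d = dets[0]
        assert d.center[0] == pytest.approx(64.0, abs=1.0)
        assert d.center[1] == pytest.approx(64.0, abs=1.0)
        assert d.radius == pytest.approx(20.0, abs=1.0)

    def test_two_separated_rings(self, short_trace, curve):
        cfg = ImageRenderConfig(shape=(128, 188),
                                positions=((64.0, 64.0), (64.0, 124.0)),
                                **NOISELESS)
        stack = render_timelapse([short_trace, short_trace], curve, cfg)
        dets = detect_vesicles(stack[0, 0], (12, 30))
        assert len(dets) == 2

    def test_radius_bias_across_range(self, curve):
        """Radius estimates stay within 5% over the working range."""
        for r_px in (14, 17, 20, 24):
            cfg_sim = SimulationConfig(radius=r_px * 0.5e-4, duration=10.0)
            tr = simulate_acidification(cfg_sim)
            cfg = ImageRenderConfig(shape=(128, 128),
                                    positions=((64.0, 64.0),), **NOISELESS)
            stack = render_timelapse([tr], curve, cfg)
            det = detect_vesicles(stack[0, 0], (10, 30))[0]
            assert abs(det.radius - r_px) / r_px <= 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            detect_vesicles(np.zeros((0, 0)), (5, 10))
        with pytest.raises(ValueError):
            detect_vesicles(np.zeros((32, 32)), (10, 5))


def _det(frame, y, x, r=10.0):
    return Detection(frame, (float(y), float(x)), r, 1.0)


class TestTracking:
    def test_static_detections_keep_one_id(self):
        frames = [[_det(f, 30, 30), _det(f, 80, 80)] for f in range(10)]
        tracks = track_vesicles(frames, max_displacement=5.0)
        assert len(tracks) == 2
        assert all(len(t) == 10 for t in tracks)

    def test_assignment_ignores_input_order(self):
        a = [[_det(0, 30, 30), _det(0, 80, 80)],
             [_det(1, 31, 30), _det(1, 81, 80)]]
        b = [list(reversed(fr)) for fr in a]
        ta = track_vesicles(a, 5.0)
        tb = track_vesicles(b, 5.0)
        assert [t.centers for t in ta] == [t.centers for t in tb]

    def test_no_identity_swap_between_neighbours(self):
        # two vesicles approach but stay distinct; nearest-neighbour
        # linking must keep the original IDs
        frames = []
        for f in range(6):
            frames.append([_det(f, 30.0 + f, 50), _det(f, 70.0 - f, 50)])
        tracks = track_vesicles(frames, max_displacement=4.0)
        assert len(tracks) == 2
        ys0 = [c[0] for c in tracks[0].centers]
        assert ys0 == [30.0 + f for f in range(6)]

    def test_displacement_gate_opens_new_id(self):
        frames = [[_det(0, 30, 30)], [], [_det(2, 90, 90)]]
        tracks = track_vesicles(frames, max_displacement=10.0, max_gap=1)
        assert len(tracks) == 2
        assert tracks[0].frames == [0]
        assert tracks[1].frames == [2]

    def test_gap_bridging(self):
        frames = [[_det(0, 30, 30)], [], [_det(2, 31, 30)]]
        tracks = track_vesicles(frames, max_displacement=5.0, max_gap=1)
        assert len(tracks) == 1
        assert tracks[0].frames == [0, 2]


class TestMeasurement:
    def _ring_image(self, lumen=500.0, ring=2000.0, bg=800.0, r=20):
        img = np.full((100, 100), bg)
        yy, xx = np.mgrid[0:100, 0:100]
        d = np.hypot(yy - 50, xx - 50)
        img[d <= r] = lumen
        img[np.abs(d - r) <= 1.5] = ring
        return img

    def test_uniform_disc_is_exact(self):
        img = self._ring_image()
        assert measure_lumen_intensity(img, _det(0, 50, 50, 20)) == 500.0

    def test_shrink_excludes_membrane_ring(self):
        img = self._ring_image()
        inner = measure_lumen_intensity(img, _det(0, 50, 50, 20), shrink=0.7)
        wide = measure_lumen_intensity(img, _det(0, 50, 50, 20), shrink=0.99)
        assert inner == 500.0
        assert wide > 500.0

    def test_poisson_disc_mean_within_sampling_error(self):
        rng = np.random.default_rng(5)
        img = rng.poisson(500.0, size=(100, 100)).astype(float)
        got = measure_lumen_intensity(img, _det(0, 50, 50, 20), shrink=0.7)
        n = np.pi * (0.7 * 20) ** 2
        assert abs(got - 500.0) < 3 * np.sqrt(500.0 / n)

    def test_background_excludes_lumen(self):
        img = self._ring_image(lumen=500.0, bg=800.0)
        got = measure_background(img, [_det(0, 50, 50, 20)])
        assert got == 800.0

    def test_background_of_empty_frame_is_global_mean(self):
        img = np.full((50, 50), 123.0)
        assert measure_background(img, []) == 123.0

    def test_disc_outside_frame_rejected(self):
        img = np.zeros((50, 50))
        with pytest.raises(ValueError, match="exits the frame"):
            measure_lumen_intensity(img, _det(0, 2, 2, 10))

    def test_no_background_pixels_rejected(self):
        img = np.zeros((20, 20))
        with pytest.raises(ValueError, match="background"):
            measure_background(img, [_det(0, 10, 10, 20)])

    def test_shrink_validation(self):
        with pytest.raises(ValueError):
            measure_lumen_intensity(np.zeros((50, 50)), _det(0, 25, 25, 5),
                                    shrink=1.5)


class TestMeasureStack:
    def test_noiseless_stack_end_to_end(self, noiseless_stack, short_trace,
                                        curve):
        df = measure_stack(noiseless_stack, pixel_size=0.5,
                           frame_interval=5.0, radius_range=(12, 30))
        assert df["vesicle_id"].nunique() == 1
        assert len(df) == len(short_trace.times)
        expected = ph_to_intensity(short_trace.pH_i, curve)
        np.testing.assert_allclose(
            df.sort_values("frame")["lumen_intensity"], expected, rtol=1e-12)
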