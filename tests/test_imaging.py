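"""HSB conversion and green-pixel segmentation."""

import colorsys

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from PIL import Image

from canospec import (
    HSBThresholds,
    batch_green_fraction,
    generate_image,
    rgb_to_hsb,
    segment_green,
)


def hsb_oracle(r, g, b):
    """Independent byte-scale HSB via the stdlib hexcone implementation."""
    h, s, v = colorsys.rgb_to_hsv(r / 255.0, g / 255.0, b / 255.0)
    return round(h * 255), round(s * 255), round(v * 255)


class TestRgbToHsb:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((255, 0, 0), (0, 255, 255)),     # pure red
            ((0, 255, 0), (85, 255, 255)),    # pure green: 120 deg -> byte 85
            ((0, 0, 255), (170, 255, 255)),   # pure blue
            ((128, 128, 128), (0, 0, 128)),   # achromatic gray
            ((0, 0, 0), (0, 0, 0)),
            ((255, 255, 255), (0, 0, 255)),
        ],
    )
    def test_hexcone_landmarks(self, rgb, expected):
        out = rgb_to_hsb(np.array([[rgb]], dtype=np.uint8))
        assert tuple(out[0, 0]) == expected

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.tuples(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255)))
    def test_matches_stdlib_oracle(self, rgb):
        out = rgb_to_hsb(np.array([[rgb]], dtype=np.uint8))
        assert tuple(int(c) for c in out[0, 0]) == hsb_oracle(*rgb)

    def test_rejects_wrong_channel_count(self):
        with pytest.raises(ValueError):
            rgb_to_hsb(np.zeros((4, 4, 4), dtype=np.uint8))


class TestThresholds:
    def test_defaults_are_the_byte_scale_green_band(self):
        t = HSBThresholds()
        assert (t.hue_lo, t.hue_hi) == (45, 120)
        assert (t.sat_lo, t.sat_hi) == (0, 255)
        assert (t.bri_lo, t.bri_hi) == (0, 255)

    @pytest.mark.parametrize("kw", [{"hue_lo": 130, "hue_hi": 120}, {"bri_hi": 300}, {"sat_lo": -1}])
    def test_invalid_intervals_rejected(self, kw):
        with pytest.raises(ValueError):
            HSBThresholds(**kw)


class TestSegmentGreen:
    def test_all_green_image(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        img[..., 1] = 200  # pure green, hue byte 85
        res = segment_green(img)
        assert res.green_pct == 100.0
        assert res.green_count == res.total_count == 64

    def test_pure_browns_are_zero(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        img[..., 0] = 139
        img[..., 1] = 69
        img[..., 2] = 19  # saddle brown, hue byte < 45
        res = segment_green(img)
        assert res.green_pct == 0.0

    def test_achromatic_pixels_never_plant(self):
        img = np.full((4, 4, 3), 180, dtype=np.uint8)
        wide = HSBThresholds(0, 255, 0, 255, 0, 255)
        # even fully open hue band counts gray (hue 0 in [0,255]) — but the
        # default green band excludes hue 0:
        assert segment_green(img).green_pct == 0.0
        assert segment_green(img, wide).green_pct == 100.0

    def test_exact_round_trip_with_generator(self):
        img, planted = generate_image(25.0, 128, 128, seed=9)
        res = segment_green(img)
        assert planted == 4096
        assert res.green_count == planted
        assert res.green_pct == 25.0

    def test_zero_size_image_rejected(self):
        with pytest.raises(ValueError):
            segment_green(np.zeros((0, 5, 3), dtype=np.uint8))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        before = segment_green(img).green_pct
        flat = img.reshape(-1, 3)[rng.permutation(256)]
        after = segment_green(flat.reshape(16, 16, 3)).green_pct
        assert before == after

    def test_widening_thresholds_monotone(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        narrow = segment_green(img, HSBThresholds(45, 120, 40, 200, 40, 200))
        wider = segment_green(img, HSBThresholds(40, 130, 20, 220, 20, 220))
        assert wider.green_count >= narrow.green_count


class TestBatch:
    def _write(self, tmp_path, name, pct, seed):
        img, _ = generate_image(pct, 32, 32, seed=seed)
        Image.fromarray(img).save(tmp_path / name)

    def test_three_valid_files(self, tmp_path):
        for i, pct in enumerate([0.0, 50.0, 100.0]):
            self._write(tmp_path, f"p{i}_d1.png", pct, seed=i)
        table, errors = batch_green_fraction(sorted(tmp_path.glob("*.png")))
        assert len(table) == 3 and not errors
        assert list(table["green_pct"]) == [0.0, 50.0, 100.0]
        assert set(table["plot_id"]) == {"p0", "p1", "p2"}

    def test_empty_list(self):
        table, errors = batch_green_fraction([])
        assert len(table) == 0 and not errors

    def test_corrupt_file_reported_not_dropped(self, tmp_path):
        self._write(tmp_path, "p0_d1.png", 10.0, seed=0)
        self._write(tmp_path, "p1_d1.png", 20.0, seed=1)
        bad = tmp_path / "p2_d1.png"
        bad.write_bytes(b"not a png")
        table, errors = batch_green_fraction(sorted(tmp_path.glob("*.png")))
        assert len(table) == 2
        assert len(errors) == 1 and errors[0]["path"].endswith("p2_d1.png")

    def test_crop_is_applied(self, tmp_path):
        # left half all green, right half brown; crop to the left half
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        img[:, :8, 1] = 200
        img[:, 8:] = (139, 69, 19)
        Image.fromarray(img).save(tmp_path / "p0_d1.png")
        table, _ = batch_green_fraction([tmp_path / "p0_d1.png"], crop=(0, 0, 8, 16))
        assert table["green_pct"].iloc[0] == 100.0
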