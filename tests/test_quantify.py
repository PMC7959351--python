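"""Color quantization, the green rule, and green-proportion measurement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from weedcover import quantify as q
from weedcover import synthetic as sy

SIX_WEED_CODES = [
    (0, 43, 0),
    (51, 85, 51),
    (102, 128, 102),
    (153, 170, 102),
    (102, 128, 51),
    (51, 85, 0),
]


class TestGreenRule:
    @pytest.mark.parametrize("code", SIX_WEED_CODES)
    def test_characteristic_weed_codes_are_green(self, code):
        assert q.is_green(code)

    @pytest.mark.parametrize(
        "code",
        [(51, 51, 51), (170, 170, 170), (153, 102, 51), (0, 43, 43), (43, 43, 0)],
    )
    def test_ties_and_browns_are_not_green(self, code):
        """G must strictly exceed both R and B; grays and browns fail."""
        assert not q.is_green(code)


class TestQuantize:
    def test_single_color_image(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[..., :] = (51, 85, 0)
        h = q.quantize_colors(img, 256)
        assert h.counts == {(51, 85, 0): 4}
        assert h.total_pixels == 4

    def test_identity_quantization_preserves_raw_colors(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        h = q.quantize_colors(img, 256)
        # brute-force per-pixel tally
        expect = {}
        for px in img.reshape(-1, 3):
            expect[tuple(int(v) for v in px)] = expect.get(tuple(int(v) for v in px), 0) + 1
        assert dict(h.counts) == expect

    def test_six_level_quantization_matches_brute_force(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
        h = q.quantize_colors(img, 6)
        assert h.total_pixels == 64 * 64
        allowed = {0, 51, 102, 153, 204, 255}
        assert all(set(c) <= allowed for c in h.counts)
        # independent per-pixel oracle: nearest of the 6 levels, half rounds up
        levels = np.array(sorted(allowed), dtype=float)
        expect = {}
        for px in img.reshape(-1, 3).astype(float):
            code = []
            for v in px:
                idx = int(np.floor(v / (255 / 5) + 0.5))
                code.append(int(np.floor(idx * (255 / 5) + 0.5)))
            t = tuple(code)
            expect[t] = expect.get(t, 0) + 1
        assert dict(h.counts) == expect

    def test_alpha_masked_pixels_excluded(self):
        img = np.zeros((2, 2, 4), dtype=np.uint8)
        img[..., :3] = (10, 20, 30)
        img[..., 3] = 255
        img[0, 0, 3] = 0
        h = q.quantize_colors(img, 256)
        assert h.total_pixels == 3 and h.masked_pixels == 1

    def test_empty_image_raises(self):
        img = np.zeros((2, 2, 4), dtype=np.uint8)  # all alpha 0
        with pytest.raises(q.EmptyImageError):
            q.quantize_colors(img, 256)

    @given(st.integers(2, 256), st.integers(0, 2**32 - 1))
    def test_quantization_idempotent(self, levels, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
        once = q.quantize_channel(img, levels)
        twice = q.quantize_channel(once, levels)
        assert np.array_equal(once, twice)


class TestSelectGreenCodes:
    def _hist(self, counts, label=None):
        return q.PixelHistogram(counts=counts, total_pixels=sum(counts.values()), label=label)

    def test_no_green_codes_gives_empty_set(self):
        h = self._hist({(100, 50, 20): 10, (80, 80, 80): 5})
        assert q.select_green_codes([h], q.GreenSelection(top_k="all")) == set()

    def test_all_keeps_exactly_the_rule_passers(self):
        h = self._hist({(0, 43, 0): 3, (100, 50, 20): 10, (51, 85, 0): 1})
        got = q.select_green_codes([h], q.GreenSelection(top_k="all"))
        assert got == {(0, 43, 0), (51, 85, 0)}

    def test_top_k_picks_largest_summed_counts(self):
        # 8 green codes with known counts split over two histograms
        greens = [(i, 200, i // 2) for i in range(0, 80, 10)]
        h1 = self._hist({c: 10 * (i + 1) for i, c in enumerate(greens[:5])})
        h2 = self._hist({c: 7 * (i + 1) for i, c in enumerate(greens)})
        got = q.select_green_codes([h1, h2], q.GreenSelection(top_k=6))
        totals = {}
        for h in (h1, h2):
            for c, n in h.counts.items():
                totals[c] = totals.get(c, 0) + n
        expect = set(sorted(totals, key=lambda c: (-totals[c], c))[:6])
        assert got == expect

    def test_shared_across_groups_drops_group_private_codes(self):
        ha = self._hist({(0, 43, 0): 5, (51, 85, 0): 2})
        hb = self._hist({(0, 43, 0): 4, (10, 200, 10): 9})
        got = q.select_green_codes(
            {"C": [ha], "T": [hb]},
            q.GreenSelection(top_k="all", require_shared_across_groups=True),
        )
        assert got == {(0, 43, 0)}

    def test_warns_when_fewer_codes_than_requested(self):
        h = self._hist({(0, 43, 0): 5})
        with pytest.warns(UserWarning, match="fewer than top_k"):
            got = q.select_green_codes([h], q.GreenSelection(top_k=6))
        assert got == {(0, 43, 0)}


class TestGreenProportion:
    def test_simple_fraction(self):
        h = q.PixelHistogram(
            counts={(0, 43, 0): 30, (100, 50, 20): 70}, total_pixels=100
        )
        assert q.green_proportion(h, {(0, 43, 0)}) == pytest.approx(0.30)

    def test_empty_code_set_gives_zero(self):
        h = q.PixelHistogram(counts={(0, 43, 0): 10}, total_pixels=10)
        assert q.green_proportion(h, set()) == 0.0

    def test_render_measure_round_trip(self):
        img = sy.render_pot_image(200, 200, 0.42, seed=5)
        h = q.quantize_colors(img, 256)
        codes = q.select_green_codes([h], q.GreenSelection(top_k="all"))
        assert q.green_proportion(h, codes) == pytest.approx(0.42, abs=2 / 40000)

    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_code_set(self, seed):
        """Enlarging the green-code set never decreases the proportion."""
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(12, 12, 3), dtype=np.uint8)
        h = q.quantize_colors(img, 6)
        codes = sorted(h.counts)
        prev = 0.0
        for k in range(len(codes) + 1):
            cur = q.green_proportion(h, set(codes[:k]))
            assert cur >= prev - 1e-15
            prev = cur
        assert prev == pytest.approx(1.0)  # every code selected => 1

    def test_partition_green_plus_nongreen(self):
        img = sy.render_pot_image(50, 50, 0.3, seed=9)
        h = q.quantize_colors(img, 256)
        green = sum(n for c, n in h.counts.items() if q.is_green(c))
        nongreen = sum(n for c, n in h.counts.items() if not q.is_green(c))
        assert green + nongreen == h.total_pixels


class TestTabularIO:
    def test_csv_round_trip(self, tmp_path):
        img = sy.render_pot_image(40, 40, 0.25, seed=3)
        h = q.quantize_colors(img, 6, label="pot1")
        path = tmp_path / "hists.csv"
        q.write_histograms_csv([h], path)
        (back,) = q.read_histograms_csv(path)
        assert dict(back.counts) == dict(h.counts)
        assert back.total_pixels == h.total_pixels

    def test_code_text_format(self):
        assert q.format_code((0, 43, 0)) == "0-43-0"
        assert q.parse_code("153-170-102") == (153, 170, 102)
        with pytest.raises(ValueError):
            q.parse_code("300-0-0")
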