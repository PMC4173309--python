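"""Stimulus geometry, rasterization and set generation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mlhmax import stimuli
from mlhmax.stimuli import (FigureSpec, StimulusSpec, figure_segments,
                            figures_overlap, generate_set, render_figure,
                            render_stimulus, sample_stimulus_spec,
                            stimulus_in_bounds, _segment_mask)
from _oracles import segment_mask_oracle


def spec_with(top=None, bottom=None, category="long", delta=10,
              set_kind="ml20", jitter_mode="HV"):
    top = top or FigureSpec("top", 130, "arrowtail", 20, 20, 70, 0)
    bottom = bottom or FigureSpec("bottom", 120, "arrowhead", 20, 20, 180, 0)
    return StimulusSpec(top, bottom, category, delta, set_kind, jitter_mode)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

class TestSampling:
    def test_training_spec_ranges(self, rng):
        s = sample_stimulus_spec(rng, "train_cross", "long", "random", "HV")
        assert s.top.fin_style == s.bottom.fin_style == "cross"
        assert 10 <= s.top.fin_angle <= 90 and 10 <= s.bottom.fin_angle <= 90
        assert 2 <= abs(s.delta) <= 62 and s.delta > 0
        assert max(s.top.shaft_length, s.bottom.shaft_length) in range(120, 241)

    def test_ml_v_mode_spec(self, rng):
        s = sample_stimulus_spec(rng, "ml20", "short", 60, "V")
        assert s.top.fin_style == "arrowtail" and s.bottom.fin_style == "arrowhead"
        assert s.top.fin_angle == s.bottom.fin_angle == 20
        assert s.top.x_offset == s.bottom.x_offset == 0
        assert s.delta == -60
        assert 48 <= s.top.y_position <= 108 and 148 <= s.bottom.y_position <= 208

    def test_ctl_shares_fin_angle(self, rng):
        s = sample_stimulus_spec(rng, "ctl", "long", 10, "HV")
        assert s.top.fin_angle == s.bottom.fin_angle
        assert (s.top.fin_style, s.bottom.fin_style) == ("arrow_left", "arrow_right")

    def test_seeded_determinism(self):
        a = sample_stimulus_spec(np.random.default_rng(5), "ctl", "long", 10, "HV")
        b = sample_stimulus_spec(np.random.default_rng(5), "ctl", "long", 10, "HV")
        assert a == b

    @pytest.mark.parametrize("set_kind,delta", [
        ("ml20", 15), ("ml40", 70), ("train_cross", 1), ("train_cross", 63),
        ("ml20", "random"),
    ])
    def test_invalid_delta_rejected(self, rng, set_kind, delta):
        with pytest.raises(ValueError):
            sample_stimulus_spec(rng, set_kind, "long", delta, "HV")

    def test_category_delta_consistency(self, rng):
        for cat in ("long", "short"):
            s = sample_stimulus_spec(rng, "ml40", cat, 30, "HV")
            assert (s.delta > 0) == (cat == "long")
            assert s.top.shaft_length - s.bottom.shaft_length == s.delta

    def test_uniform_marginals(self):
        """Pre-rejection marginals hit their stated bounds and pass a
        chi-squared uniformity check on 10 bins at alpha = 0.01."""
        rng = np.random.default_rng(123)
        n = 10_000
        fields = {"shaft": [], "fin_len": [], "angle": [], "y_top": [], "x_off": []}
        for _ in range(n):
            s = sample_stimulus_spec(rng, "train_cross", "long", "random", "HV")
            fields["shaft"].append(s.top.shaft_length)  # top is the longer line
            fields["fin_len"].append(s.top.fin_length)
            fields["angle"].append(s.top.fin_angle)
            fields["y_top"].append(s.top.y_position)
            fields["x_off"].append(s.top.x_offset)
        bounds = {"shaft": (120, 240), "fin_len": (15, 40), "angle": (10, 90),
                  "y_top": (58, 88), "x_off": (-30, 30)}
        for name, vals in fields.items():
            lo, hi = bounds[name]
            assert min(vals) == lo and max(vals) == hi, name
            edges = np.histogram_bin_edges([], bins=10, range=(lo - 0.5, hi + 0.5))
            counts, _ = np.histogram(vals, bins=edges)
            # integer support: expected frequency proportional to the number
            # of integers falling in each bin
            support, _ = np.histogram(np.arange(lo, hi + 1), bins=edges)
            expected = len(vals) * support / support.sum()
            p = stats.chisquare(counts, expected).pvalue
            assert p > 0.01, f"{name}: chi2 uniformity rejected (p={p:.4g})"


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

class TestRendering:
    def test_matches_per_pixel_oracle(self):
        """Fast rasterizer mask equals the naive per-pixel oracle exactly."""
        rng = np.random.default_rng(42)
        shape = (64, 64)
        for _ in range(100):
            p0 = tuple(rng.uniform(2, 62, 2))
            p1 = tuple(rng.uniform(2, 62, 2))
            fast = _segment_mask(p0, p1, shape)
            assert np.array_equal(fast, segment_mask_oracle(p0, p1, shape))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.tuples(*[st.floats(2.0, 44.0) for _ in range(4)]))
    def test_any_segment_matches_oracle(self, coords):
        """Property: the vectorized rasterizer agrees with the scalar oracle
        for arbitrary segment endpoints, including degenerate ones."""
        u0, v0, u1, v1 = coords
        fast = _segment_mask((u0, v0), (u1, v1), (48, 48))
        assert np.array_equal(fast, segment_mask_oracle((u0, v0), (u1, v1), (48, 48)))

    def test_figure_mask_matches_oracle(self, rng):
        for _ in range(5):
            s = sample_stimulus_spec(rng, "ctl", "long", 20, "HV")
            ref = np.zeros((256, 256), bool)
            for p0, p1 in figure_segments(s.top):
                ref |= segment_mask_oracle(p0, p1, (256, 256))
            assert np.array_equal(render_figure(s.top), ref)

    def test_finless_shaft_pixel_count(self):
        fig = FigureSpec("top", 120, "cross", 30, 0, 70, 0)
        mask = render_figure(fig)
        assert abs(int(mask.sum()) - 120 * 2) <= 2 * 2  # corner convention slack
        rows = np.unique(np.nonzero(mask)[0])
        assert len(rows) == 2  # 2-px-thick horizontal stroke

    def test_binary_levels(self, rng):
        s = sample_stimulus_spec(rng, "train_cross", "short", "random", "HV")
        img = render_stimulus(s)
        assert img.dtype == np.uint8
        assert set(np.unique(img)) == {0, 255}

    def test_shaft_independent_of_fin_angle(self):
        a = spec_with(top=FigureSpec("top", 130, "arrowtail", 20, 20, 70, 0))
        b = spec_with(top=FigureSpec("top", 130, "arrowtail", 40, 20, 70, 0))
        shaft_only_a = render_figure(FigureSpec("top", 130, "arrowtail", 20, 0, 70, 0))
        ma, mb = render_figure(a.top), render_figure(b.top)
        assert np.array_equal(ma & shaft_only_a, shaft_only_a)
        assert np.array_equal(mb & shaft_only_a, shaft_only_a)
        assert not np.array_equal(ma, mb)  # fins differ


# ---------------------------------------------------------------------------
# overlap / bounds
# ---------------------------------------------------------------------------

class TestOverlap:
    def test_disjoint_bands_no_overlap(self):
        s = spec_with(top=FigureSpec("top", 130, "arrowtail", 20, 15, 58, 0),
                      bottom=FigureSpec("bottom", 120, "arrowhead", 20, 15, 198, 0))
        assert not figures_overlap(s)

    def test_long_steep_fins_touch(self):
        # top fins reach down, bottom fins reach up, overlapping x extent
        top = FigureSpec("top", 240, "cross", 80, 40, 88, 0)
        bot = FigureSpec("bottom", 240, "cross", 80, 40, 168, 0)
        s = StimulusSpec(top, bot, "long", 10, "train_cross", "HV")
        mt, mb = render_figure(top), render_figure(bot)
        assert np.any(mt & mb) or figures_overlap(s)  # masks meet -> rule fires
        assert figures_overlap(s)

    def test_single_shared_pixel_counts(self):
        # found by search: masks sharing very few pixels still flagged
        top = FigureSpec("top", 150, "cross", 60, 40, 88, 0)
        bot = FigureSpec("bottom", 150, "cross", 60, 40, 168, 0)
        s = StimulusSpec(top, bot, "long", 10, "train_cross", "HV")
        mt, mb = render_figure(top), render_figure(bot)
        if np.any(mt & mb):
            assert figures_overlap(s)

    def test_within_figure_arrowhead_crossing(self):
        # short shaft + long shallow arrowhead fins: opposite-end fins cross
        fig = FigureSpec("bottom", 58, "arrowhead", 20, 40, 180, 0)
        s = spec_with(bottom=fig, category="short", delta=-60)
        assert figures_overlap(s)

    def test_bounds_rule(self):
        wide = spec_with(top=FigureSpec("top", 240, "arrowtail", 20, 40, 70, 30))
        assert not stimulus_in_bounds(wide)
        ok = spec_with()
        assert stimulus_in_bounds(ok)


# ---------------------------------------------------------------------------
# set generation
# ---------------------------------------------------------------------------

class TestGenerateSet:
    def test_counts_and_balance(self):
        ss = generate_set("train_cross", "HV", seed=3, n_per_category=8)
        assert len(ss.manifest) == len(ss.images) == 16
        assert (ss.manifest["category"].value_counts() == 8).all()

    def test_per_delta_counts(self):
        ss = generate_set("ml40", "HV", seed=3, deltas=(10, 60), n_per_condition=4)
        assert len(ss.manifest) == 16
        cells = ss.manifest.groupby(["delta", "category"]).size()
        assert (cells == 4).all()
        assert sorted(ss.manifest["delta"].unique()) == [-60, -10, 10, 60]

    def test_seeded_byte_identical_manifests(self):
        a = generate_set("ctl", "V", seed=11, n_per_category=5)
        b = generate_set("ctl", "V", seed=11, n_per_category=5)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        assert all(np.array_equal(x, y) for x, y in zip(a.images, b.images))

    def test_no_emitted_overlap_or_border_contact(self):
        ss = generate_set("ml20", "HV", seed=5, deltas=(10,), n_per_condition=10)
        for spec, img in zip(ss.specs, ss.images):
            assert not figures_overlap(spec)
            strokes = img == 0
            assert not strokes[:2, :].any() and not strokes[-2:, :].any()
            assert not strokes[:, :2].any() and not strokes[:, -2:].any()

    def test_jitter_mode_center_variance(self):
        hv = generate_set("ctl", "HV", seed=9, n_per_category=15)
        v = generate_set("ctl", "V", seed=9, n_per_category=15)
        assert v.manifest["top_x_offset"].var() == 0
        assert v.manifest["bottom_x_offset"].var() == 0
        assert hv.manifest["top_x_offset"].var() > 0
        assert hv.manifest["top_y_position"].var() > 0

    def test_roundtrip_to_disk(self, tmp_path):
        ss = generate_set("ctl", "HV", seed=2, n_per_category=2, out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "config.json").exists()
        assert len(list(tmp_path.glob("*.png"))) == 4

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            generate_set("ctl", "HV", seed=1)
        with pytest.raises(ValueError):
            generate_set("ctl", "HV", seed=1, n_per_category=0)
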