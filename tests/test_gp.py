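"""Ratiometric GP computation: calibration, pixel maps, ROI summaries, render."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from matplotlib.colors import rgb_to_hsv

from macpheno.gp import (CalibrationReference, ChannelPair, calibration_g,
                         gp_pixelwise, m1_m2_intensity_ratio,
                         raw_reference_gp, render_gp_map, summaries_to_frame,
                         summarize_roi)


@pytest.mark.parametrize("io,id_,expected", [
    (3.0, 1.0, 0.5),
    (7.0, 7.0, 0.0),
    (1.0, 3.0, -0.5),
])
def test_raw_reference_gp(io, id_, expected):
    assert raw_reference_gp(io, id_) == pytest.approx(expected)


def test_raw_reference_gp_zero_total():
    with pytest.raises(ValueError, match="undefined"):
        raw_reference_gp(0.0, 0.0)


@pytest.mark.parametrize("ref,mes,expected", [
    (0.3, 0.3, 1.0),
    (0.6, 0.4, 0.56 / 0.96),        # (1-0.6)(1.4) / ((1-0.4)(1.6))
    (0.4, 0.6, (0.6 * 1.6) / (0.4 * 1.4)),
])
def test_calibration_g_values(ref, mes, expected):
    assert calibration_g(ref, mes) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("ref,mes", [(1.0, 0.0), (0.0, -1.0), (1.5, 0.2)])
def test_calibration_g_domain(ref, mes):
    with pytest.raises(ValueError):
        calibration_g(ref, mes)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(-0.9, 0.9), st.floats(-0.9, 0.9), st.floats(0.1, 100))
def test_calibration_round_trip(gp_ref, gp_mes, total):
    """Applying GP with G = calibration_g to intensities of raw GP = gp_mes
    recovers gp_ref (identity, tolerance 1e-9)."""
    g = calibration_g(gp_ref, gp_mes)
    io = total * (1 + gp_mes) / 2
    id_ = total * (1 - gp_mes) / 2
    pair = ChannelPair(np.full((2, 2), io), np.full((2, 2), id_))
    gp_map = gp_pixelwise(pair, g)
    assert gp_map.gp[0, 0] == pytest.approx(gp_ref, abs=1e-9)


def test_calibration_reference_from_pairs():
    pairs = [(700.0, 300.0), (7.0, 3.0)]  # raw GP 0.4 each
    ref = CalibrationReference.from_intensity_pairs(pairs, gp_ref=0.6)
    assert ref.gp_mes == pytest.approx(0.4)
    assert ref.g_factor == pytest.approx(calibration_g(0.6, 0.4))


def test_gp_pixelwise_values(uniform_pair):
    m = gp_pixelwise(uniform_pair, 1.0)
    assert np.allclose(m.gp, 0.5)
    m2 = gp_pixelwise(ChannelPair(np.full((2, 2), 2.0), np.ones((2, 2))),
                      0.583333)
    assert m2.gp[0, 0] == pytest.approx((2 - 0.583333) / (2 + 0.583333))


def test_gp_pixelwise_masks_dark_pixels():
    io = np.array([[0.0, 3.0], [1.0, 0.0]])
    id_ = np.array([[0.0, 1.0], [1.0, 2.0]])
    m = gp_pixelwise(ChannelPair(io, id_), 1.0, intensity_floor=0.0)
    assert not m.valid_mask[0, 0]           # zero total: invalid, not 0
    assert np.isnan(m.gp[0, 0])
    assert m.valid_mask[0, 1] and m.valid_mask[1, 0] and m.valid_mask[1, 1]
    m_floor = gp_pixelwise(ChannelPair(io, id_), 1.0, intensity_floor=2.5)
    assert not m_floor.valid_mask[1, 0]     # total 2 <= floor


def test_gp_monotone_in_channel_ratio():
    ratios = np.linspace(0.1, 10, 50)
    io = np.tile(ratios, (1, 1))
    id_ = np.ones_like(io)
    gp = gp_pixelwise(ChannelPair(io, id_), 0.7).gp.ravel()
    assert np.all(np.diff(gp) > 0)
    assert np.all(np.abs(gp) < 1)


def test_channel_validation():
    with pytest.raises(ValueError, match="mismatch"):
        ChannelPair(np.ones((3, 3)), np.ones((3, 4)))
    with pytest.raises(ValueError, match=">= 0"):
        ChannelPair(-np.ones((2, 2)), np.ones((2, 2)))
    with pytest.raises(ValueError):
        gp_pixelwise(ChannelPair(np.ones((2, 2)), np.ones((2, 2))), -1.0)


def test_summarize_roi_means_and_scale():
    gp = np.array([[0.2, 0.4], [0.9, 0.9]])
    valid = np.array([[True, True], [True, False]])
    from macpheno.gp import GPMap
    m = GPMap(gp=np.where(valid, gp, np.nan), valid_mask=valid,
              intensity_floor=0.0, g_factor_used=1.0)
    roi = np.array([[True, True], [False, True]])
    s = summarize_roi(m, roi, "c1", "M1")
    # ROI covers 3 pixels but (1,1) is invalid: mean over {0.2, 0.4} only
    assert s.mean_gp_internal == pytest.approx(0.3)
    assert s.n_pixels == 2
    assert s.mean_gp_reported == pytest.approx(30.0)  # exactly 100x internal
    with pytest.raises(ValueError, match="no valid"):
        summarize_roi(m, np.array([[False, False], [False, True]]), "c2")


def test_render_gp_map_contract(uniform_pair):
    m = gp_pixelwise(uniform_pair, 1.0)
    rgb = render_gp_map(m, uniform_pair, gp_range=(-1, 1))
    assert rgb.shape == (*uniform_pair.shape, 3)

    # all-invalid map renders black
    from macpheno.gp import GPMap
    dark = GPMap(gp=np.full((4, 4), np.nan), valid_mask=np.zeros((4, 4), bool),
                 intensity_floor=0.0, g_factor_used=1.0)
    black = render_gp_map(dark, ChannelPair(np.ones((4, 4)), np.ones((4, 4))))
    assert np.all(black == 0)

    # endpoints: GP at range max -> blue hue (2/3), at range min -> red (0);
    # equal GP with 2x brightness -> same hue, 2x value
    io = np.array([[4.0, 4.0], [8.0, 1.0]])
    id_ = np.array([[0.0, 0.0], [0.0, 50.0]])
    pair = ChannelPair(io, id_)
    m2 = gp_pixelwise(pair, 1.0)
    rgb2 = render_gp_map(m2, pair, gp_range=(-1, 1),
                         brightness_percentile=100)
    hsv = rgb_to_hsv(rgb2)
    assert hsv[0, 0, 0] == pytest.approx(2 / 3)  # GP=1 -> blue
    # GP = (1-50)/51 ~ -0.96 -> hue near the red end of the map
    assert hsv[1, 1, 0] < 0.02
    assert hsv[0, 0, 0] == pytest.approx(hsv[1, 0, 0])  # same GP, same hue
    assert hsv[1, 0, 2] == pytest.approx(2 * hsv[0, 0, 2])  # 2x brightness

    with pytest.raises(ValueError, match="degenerate"):
        render_gp_map(m2, pair, gp_range=(0.5, 0.5))


def test_m1_m2_intensity_ratio():
    from macpheno.gp import GPSummary
    s = [GPSummary("a", "M1", 0.6356, 100), GPSummary("b", "M2", 0.6999, 100)]
    out = m1_m2_intensity_ratio(s)
    assert out["ratio_m1_m2"] == pytest.approx(63.56 / 69.99)
    equal = [GPSummary("a", "M1", 0.5, 10), GPSummary("b", "M2", 0.5, 10)]
    assert m1_m2_intensity_ratio(equal)["ratio_m1_m2"] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="at least one"):
        m1_m2_intensity_ratio([GPSummary("a", "M1", 0.5, 10)])
    zero = [GPSummary("a", "M1", 0.5, 10), GPSummary("b", "M2", 0.0, 10)]
    with pytest.raises(ValueError, match="undefined"):
        m1_m2_intensity_ratio(zero)


def test_summaries_frame_columns():
    from macpheno.gp import GPSummary
    frame = summaries_to_frame([GPSummary("a", "M0", 0.5698, 60)])
    assert list(frame.columns) == ["cell_id", "phenotype", "n_pixels",
                                   "mean_gp_internal", "mean_gp_reported"]
    assert frame.loc[0, "mean_gp_reported"] == pytest.approx(56.98)
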