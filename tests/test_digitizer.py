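"""Panel localization, axis calibration and curve tracing on rendered
synthetic report pages, checked against the renderer's ground truth."""

import dataclasses

import numpy as np
import pytest

from fvlsad.curve import FLOW_EPSILON
from fvlsad.digitizer import (
    DEFAULT_CONFIG,
    DigitizerConfig,
    PanelRegion,
    ReportPage,
    _window_hash_distances,
    calibrate_axes,
    digitize_page,
    find_axis_origin,
    locate_panel,
    trace_expiratory_curve,
)
from fvlsad.errors import CalibrationError, InvalidInputError, PanelNotFoundError, TraceError
from fvlsad.synthetic import CurveSpec, PageLayout, generate_curve, render_report


def blank_page(layout, value=255):
    return np.full((layout.page_h, layout.page_w), value, dtype=np.uint8)


class TestLocatePanel:
    def test_exact_paste_found_at_distance_zero(self, layout, templates):
        label, _, _ = templates
        px = blank_page(layout)
        r, c = 120, 400
        th, tw = label.shape
        px[r : r + th, c : c + tw] = label.pixels
        region = locate_panel(ReportPage(px), label)
        assert region.match_distance == 0
        assert region.x0 <= c < region.x1 and region.y0 <= r < region.y1

    def test_noise_page_raises_panel_not_found(self, layout, templates):
        label, _, _ = templates
        rng = np.random.default_rng(11)
        px = rng.integers(0, 256, (layout.page_h, layout.page_w), dtype=np.uint8)
        # oracle: exhaustive window scan confirms min distance > threshold
        best = int(_window_hash_distances(px, label).min())
        assert best > DEFAULT_CONFIG.hash_threshold
        with pytest.raises(PanelNotFoundError) as err:
            locate_panel(ReportPage(px), label)
        assert err.value.best_distance == best

    def test_duplicate_label_ties_to_first_in_scan_order(self, layout, templates):
        label, _, _ = templates
        px = blank_page(layout)
        th, tw = label.shape
        positions = [(200, 100), (60, 500)]  # second one is earlier in scan order
        for r, c in positions:
            px[r : r + th, c : c + tw] = label.pixels
        dist = _window_hash_distances(px, label)
        expect_r, expect_c = divmod(int(np.argmin(dist)), dist.shape[1])
        region = locate_panel(ReportPage(px), label)
        assert (expect_r, expect_c) == (60, 500)
        assert region.y0 == expect_r - DEFAULT_CONFIG.margin_top
        assert region.x0 == expect_c - DEFAULT_CONFIG.margin_left

    def test_wrong_role_rejected(self, templates, layout):
        _, digit_x, _ = templates
        with pytest.raises(InvalidInputError):
            locate_panel(ReportPage(blank_page(layout)), digit_x)


class TestCalibrateAxes:
    def test_recovers_rendered_scales(self, rendered_page, layout, templates):
        page, true_cal, _, _ = rendered_page
        label, digit_x, digit_y = templates
        region = locate_panel(page, label)
        cal = calibrate_axes(page, region, digit_x, digit_y)
        assert cal.x_scale == pytest.approx(true_cal.x_scale, rel=0.02)
        assert abs(cal.y_scale) == pytest.approx(abs(true_cal.y_scale), rel=0.02)
        assert cal.x_origin_px == pytest.approx(true_cal.x_origin_px, abs=1.0)
        assert cal.y_origin_px == pytest.approx(true_cal.y_origin_px, abs=1.0)

    def test_erased_x_digit_fails_naming_the_axis(self, layout, templates):
        curve, _ = generate_curve(CurveSpec())
        page, _ = render_report(curve, layout)
        label, digit_x, digit_y = templates
        px = page.pixels.copy()
        px[layout.origin_row + 1 :, :] = 255  # wipe everything below the x axis
        page2 = ReportPage(px)
        region = locate_panel(page2, label)
        with pytest.raises(CalibrationError) as err:
            calibrate_axes(page2, region, digit_x, digit_y)
        assert err.value.axis == "x"

    def test_dpi_doubling_preserves_value_space_mapping(self):
        base = PageLayout()
        doubled = dataclasses.replace(
            base,
            page_w=base.page_w * 2, page_h=base.page_h * 2,
            panel_x0=base.panel_x0 * 2, panel_y0=base.panel_y0 * 2,
            panel_w=base.panel_w * 2, panel_h=base.panel_h * 2,
            label_dx=base.label_dx * 2, label_dy=base.label_dy * 2,
            origin_dx=base.origin_dx * 2,
            origin_dy_from_bottom=base.origin_dy_from_bottom * 2,
            px_per_l=base.px_per_l * 2, px_per_lps=base.px_per_lps * 2,
            glyph_scale=base.glyph_scale * 2,
        )
        curve, _ = generate_curve(CurveSpec())
        cals = []
        for lay in (base, doubled):
            page, _ = render_report(curve, lay)
            cfg = DigitizerConfig(
                margin_right=DEFAULT_CONFIG.margin_right
                * (2 if lay is doubled else 1),
                margin_bottom=DEFAULT_CONFIG.margin_bottom
                * (2 if lay is doubled else 1),
            )
            region = locate_panel(page, lay.label_template(), cfg)
            dx, dy = lay.digit_templates(2)
            cals.append((calibrate_axes(page, region, dx, dy, config=cfg), lay))
        (c1, l1), (c2, l2) = cals
        # same physical value at corresponding pixels after dpi mapping
        for v in (0.5, 2.0, 3.5):
            assert c1.volume_at(c1.col_of(v)) == pytest.approx(
                c2.volume_at(c2.col_of(v)), abs=1e-9
            )
        assert c2.x_scale == pytest.approx(c1.x_scale / 2, rel=0.02)
        assert abs(c2.y_scale) == pytest.approx(abs(c1.y_scale) / 2, rel=0.02)

    def test_calibration_affinity_is_exact(self, rendered_page):
        _, cal, _, _ = rendered_page
        p1, p2 = 412.0, 519.0
        assert cal.volume_at(p2) - cal.volume_at(p1) == pytest.approx(
            cal.x_scale * (p2 - p1), abs=1e-12
        )


class TestTrace:
    def test_round_trip_recovers_flow_within_one_pixel(self, rendered_page, templates):
        page, true_cal, curve, _ = rendered_page
        label, digit_x, digit_y = templates
        traced, region, cal = digitize_page(page, label, digit_x, digit_y)
        assert traced.source == "traced"
        # resample truth onto traced volumes; 1 px-equivalent in flow
        truth_flow = np.interp(traced.volume, curve.volume, curve.flow)
        tol = abs(true_cal.y_scale) * 1.0
        # exclude the steep rising limb where sub-pixel column quantization
        # legitimately spans several flow values per column
        mask = traced.volume > curve.volume[np.argmax(curve.flow)] + 2 * cal.x_scale
        assert np.max(np.abs(traced.flow[mask] - truth_flow[mask])) <= tol + 1e-9
        assert traced.fvc == pytest.approx(curve.fvc, rel=0.02)
        assert traced.peak_flow == pytest.approx(curve.peak_flow, rel=0.02)

    def test_blank_panel_raises_trace_failed(self, layout, templates):
        label, *_ = templates
        px = blank_page(layout)
        th, tw = label.shape
        r, c = layout.panel_y0 + 4, layout.panel_x0 + 4
        px[r : r + th, c : c + tw] = label.pixels
        page = ReportPage(px)
        region = locate_panel(page, label)
        cal = PageLayout().calibration()
        with pytest.raises(TraceError):
            trace_expiratory_curve(page, region, cal)

    def test_inspiratory_limb_is_excluded(self, layout, templates):
        curve, _ = generate_curve(CurveSpec())
        page, _ = render_report(curve, layout, draw_inspiratory=True)
        label, digit_x, digit_y = templates
        traced, _, _ = digitize_page(page, label, digit_x, digit_y)
        assert np.all(traced.flow >= -FLOW_EPSILON)
        # and the expiratory geometry still matches
        assert traced.fvc == pytest.approx(curve.fvc, rel=0.02)

    def test_identical_pages_give_identical_curves(self, rendered_page, templates):
        page, _, _, _ = rendered_page
        label, digit_x, digit_y = templates
        page2 = ReportPage(page.pixels.copy(), dpi=page.dpi, source_id=page.source_id)
        a, _, _ = digitize_page(page, label, digit_x, digit_y)
        b, _, _ = digitize_page(page2, label, digit_x, digit_y)
        assert np.array_equal(a.volume, b.volume)
        assert np.array_equal(a.flow, b.flow)


def test_axis_origin_found_at_rendered_origin(rendered_page, layout, templates):
    page, _, _, _ = rendered_page
    label, *_ = templates
    region = locate_panel(page, label)
    col, row = find_axis_origin(page, region)
    assert (col, row) == (layout.origin_col, layout.origin_row)


def test_page_validation():
    with pytest.raises(InvalidInputError):
        ReportPage(np.zeros((100, 100), dtype=np.uint8))  # too small
    with pytest.raises(InvalidInputError):
        ReportPage(np.full((300, 300), 300.0))  # out of range
    with pytest.raises(InvalidInputError):
        PanelRegion(10, 10, 5, 20)
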