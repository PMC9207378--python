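"""Synthetic expiratory curves and rendered report pages.

The generator produces expiratory flow-volume limbs with *known*
flattening geometry so the whole digitization -> index -> cohort chain
can be exercised end-to-end without clinical data:

* ``piecewise_linear`` curves rise straight from (0, 0) to the peak at
  ``(v_peak, PEF)``, then descend along two exact line segments whose
  inclinations (``theta_ab``, ``theta_bc``, in degrees under a 1 L/s
  per L aspect) are the ground truth: ∠ABC = 180° − (θ_AB − θ_BC),
  ∠BCX = θ_BC.  B sits exactly at 75% of FVC and C at (FVC, 0); the
  peak flow is therefore implied by the two inclinations, and a
  contradictory user-supplied PEF is rejected.
* ``smooth_power`` curves decay as
  ``flow(v) = PEF · ((FVC − v)/(FVC − v_peak))^gamma`` after the peak;
  their ground-truth indices are obtained by running the index code on
  a dense noise-free sampling (oracle by construction).

:func:`render_report` draws a curve into a report-like page — axes,
ticks, a "2" digit glyph on each axis and the "F/V ex" locator label,
all from the bundled bitmap font — and returns the exact pixel -> value
calibration used, so digitizer output can be compared against ground
truth.  :func:`generate_cohort` emulates the two expert-labelled
groups: per-subject B–C inclinations are drawn so that ∠ABC follows
Gaussians with the flattening-group and non-flattening-group moments
(144.8 ± 8.5° and 163.8 ± 14.1°), truncated to the geometrically
feasible angle range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw
from scipy import stats

from .curve import ExpiratoryCurve
from .digitizer import PanelCalibration, ReportPage
from .errors import InvalidLayoutError, InvalidSpecError
from .glyphs import GlyphTemplate, render_text
from .sad_index import compute_indices

#: Fig.-style group moments of ∠ABC (degrees) used by generate_cohort
FLATTENING_MEAN, FLATTENING_SD = 144.8, 8.5
NONFLATTENING_MEAN, NONFLATTENING_SD = 163.8, 14.1


@dataclass(frozen=True)
class CurveSpec:
    """Parameters of one synthetic expiratory limb.

    ``pef`` (L/s) may be left None: for piecewise_linear it is implied
    by the inclinations and checked if given; for smooth_power it
    defaults to 8 L/s.
    """

    fvc: float = 4.0
    v_peak: float = 0.4
    flatten_theta_ab: float = 60.0
    flatten_theta_bc: float = 40.0
    shape: str = "piecewise_linear"
    gamma: float = 2.0
    pef: float | None = None
    noise_sd: float = 0.0
    n_samples: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.v_peak < 0.75 * self.fvc:
            raise InvalidSpecError("need 0 < v_peak < 0.75 * fvc")
        if not 0 <= self.flatten_theta_bc <= self.flatten_theta_ab < 90:
            raise InvalidSpecError("need 0 <= theta_bc <= theta_ab < 90")
        if self.shape not in ("piecewise_linear", "smooth_power"):
            raise InvalidSpecError(f"unknown shape {self.shape!r}")
        if self.n_samples < 50:
            raise InvalidSpecError("n_samples must be >= 50")
        if self.noise_sd < 0 or self.gamma <= 0:
            raise InvalidSpecError("noise_sd must be >= 0 and gamma > 0")
        if self.pef is not None and self.pef <= 0:
            raise InvalidSpecError("pef must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form (or oracle-by-construction) indices of a spec."""

    angle_abc: float
    angle_bcx: float
    log_bc_over_ax: float
    peak_flow: float
    fvc: float


def implied_pef(spec: CurveSpec) -> float:
    """Peak flow implied by a piecewise-linear spec's inclinations."""
    vb = 0.75 * spec.fvc
    flow_b = math.tan(math.radians(spec.flatten_theta_bc)) * (spec.fvc - vb)
    return flow_b + math.tan(math.radians(spec.flatten_theta_ab)) * (
        vb - spec.v_peak
    )


def _sample_volumes(spec: CurveSpec, knots: np.ndarray) -> np.ndarray:
    grid = np.linspace(0.0, spec.fvc, spec.n_samples)
    v = np.union1d(np.round(grid, 12), np.round(knots, 12))
    return v


def generate_curve(spec: CurveSpec) -> tuple[ExpiratoryCurve, GroundTruth]:
    """Generate one expiratory limb plus its ground-truth indices."""
    if spec.shape == "piecewise_linear":
        pef = implied_pef(spec)
        if pef <= 0:
            raise InvalidSpecError("inclinations imply a non-positive peak flow")
        if spec.pef is not None and abs(spec.pef - pef) > 1e-6 * max(1.0, pef):
            raise InvalidSpecError(
                f"supplied pef {spec.pef:.4f} contradicts the inclinations "
                f"(implied {pef:.4f})"
            )
        vb = 0.75 * spec.fvc
        flow_b = math.tan(math.radians(spec.flatten_theta_bc)) * (spec.fvc - vb)
        knots_v = np.array([0.0, spec.v_peak, vb, spec.fvc])
        knots_f = np.array([0.0, pef, flow_b, 0.0])
        v = _sample_volumes(spec, knots_v)
        f = np.interp(v, knots_v, knots_f)
        slope_bc = -math.tan(math.radians(spec.flatten_theta_bc))
        truth = GroundTruth(
            angle_abc=180.0 - (spec.flatten_theta_ab - spec.flatten_theta_bc),
            angle_bcx=spec.flatten_theta_bc,
            log_bc_over_ax=(
                math.log10(abs(slope_bc) / pef) if slope_bc != 0 else math.nan
            ),
            peak_flow=pef,
            fvc=spec.fvc,
        )
    else:  # smooth_power
        pef = spec.pef if spec.pef is not None else 8.0
        v = _sample_volumes(spec, np.array([0.0, spec.v_peak, spec.fvc]))
        f = np.where(
            v <= spec.v_peak,
            pef * v / spec.v_peak,
            pef
            * ((spec.fvc - v).clip(0.0) / (spec.fvc - spec.v_peak)) ** spec.gamma,
        )
        dense = np.linspace(0.0, spec.fvc, 2001)
        dense_f = np.where(
            dense <= spec.v_peak,
            pef * dense / spec.v_peak,
            pef
            * ((spec.fvc - dense).clip(0.0) / (spec.fvc - spec.v_peak))
            ** spec.gamma,
        )
        oracle = compute_indices(
            ExpiratoryCurve(dense, dense_f, source="synthetic")
        )
        truth = GroundTruth(
            angle_abc=oracle.angle_abc,
            angle_bcx=oracle.angle_bcx,
            log_bc_over_ax=oracle.log_bc_over_ax,
            peak_flow=pef,
            fvc=spec.fvc,
        )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd, f.size)
        noise[0] = noise[-1] = 0.0  # endpoints stay on the axis
        f = np.clip(f + noise, 0.0, None)
        f[-1] = 0.0
    curve = ExpiratoryCurve(
        v, f, source="synthetic", source_id=f"synthetic-{spec.seed}"
    )
    return curve, truth


# ---------------------------------------------------------------------------
# report-page rendering


@dataclass(frozen=True)
class PageLayout:
    """Geometry of the emulated report page (all px, origin top-left)."""

    page_w: int = 800
    page_h: int = 600
    panel_x0: int = 340
    panel_y0: int = 40
    panel_w: int = 440
    panel_h: int = 520
    #: locator label anchor, relative to the panel's top-left corner
    label_dx: int = 4
    label_dy: int = 4
    #: axis origin, relative to the panel
    origin_dx: int = 100
    origin_dy_from_bottom: int = 50
    px_per_l: float = 60.0
    px_per_lps: float = 50.0
    stroke: int = 2
    tick_len: int = 4
    glyph_scale: int = 2
    background: int = 255
    ink: int = 0

    @property
    def origin_col(self) -> int:
        return self.panel_x0 + self.origin_dx

    @property
    def origin_row(self) -> int:
        return self.panel_y0 + self.panel_h - self.origin_dy_from_bottom

    @property
    def plot_w(self) -> int:
        return self.panel_x0 + self.panel_w - self.origin_col - 6

    @property
    def plot_h(self) -> int:
        return self.origin_row - self.panel_y0 - 26

    def calibration(self) -> PanelCalibration:
        return PanelCalibration(
            x_scale=1.0 / self.px_per_l,
            x_origin_px=float(self.origin_col),
            y_scale=-1.0 / self.px_per_lps,
            y_origin_px=float(self.origin_row),
        )

    def label_template(self) -> GlyphTemplate:
        return GlyphTemplate(
            render_text("F/V ex", scale=self.glyph_scale, ink=self.ink,
                        background=self.background),
            role="panel_label",
        )

    def digit_templates(self, digit: int = 2) -> tuple[GlyphTemplate, GlyphTemplate]:
        """(x-axis, y-axis) templates for the tick digit, with the
        anchor -> tick offsets the renderer uses."""
        px = render_text(str(digit), scale=self.glyph_scale, ink=self.ink,
                         background=self.background)
        gh, gw = px.shape
        x_tpl = GlyphTemplate(
            px, role="axis_digit", value=float(digit),
            tick_offset=(gw / 2.0, -(self.tick_len + 3 + gh) + gh),
        )
        y_tpl = GlyphTemplate(
            px, role="axis_digit", value=float(digit),
            tick_offset=(gw + self.tick_len + 3, gh / 2.0),
        )
        return x_tpl, y_tpl


def _draw_curve_band(
    canvas: np.ndarray,
    cal: PanelCalibration,
    volume: np.ndarray,
    flow: np.ndarray,
    stroke: int,
    ink: int,
) -> None:
    """Rasterize the curve as a vertically-stroked band, centred on the
    true curve in every pixel column.

    For each column the ink covers the rows the curve passes through
    over that column's x-interval, widened by half the stroke — so the
    column-wise ink centroid sits on the curve to within quantization,
    which is what the tracer's accuracy contract is measured against.
    """
    x = np.asarray(cal.col_of(volume), float)
    y = np.asarray(cal.row_of(flow), float)
    half = (stroke - 1) / 2.0
    c0, c1 = int(np.ceil(x[0])), int(np.floor(x[-1]))
    for c in range(c0, c1 + 1):
        xs = np.clip([c - 0.5, c, c + 0.5], x[0], x[-1])
        ys = np.interp(xs, x, y)
        r_lo = int(np.floor(ys.min() - half + 0.5))
        r_hi = int(np.floor(ys.max() + half + 0.5))
        canvas[max(r_lo, 0) : r_hi + 1, c] = ink


def _paste(canvas: np.ndarray, glyph: np.ndarray, row: int, col: int) -> None:
    h, w = glyph.shape
    canvas[row : row + h, col : col + w] = np.minimum(
        canvas[row : row + h, col : col + w], glyph
    )


def render_report(
    curve: ExpiratoryCurve,
    layout: PageLayout = PageLayout(),
    source_id: str = "",
    draw_inspiratory: bool = False,
) -> tuple[ReportPage, PanelCalibration]:
    """Draw the curve into a report-like page; return page + the exact
    calibration (the oracle for digitizer tests)."""
    cal = layout.calibration()
    if curve.fvc * layout.px_per_l > layout.plot_w:
        raise InvalidLayoutError("curve volume range exceeds the plot area")
    if curve.peak_flow * layout.px_per_lps > layout.plot_h:
        raise InvalidLayoutError("curve flow range exceeds the plot area")

    img = Image.new("L", (layout.page_w, layout.page_h), layout.background)
    draw = ImageDraw.Draw(img)
    ox, oy = layout.origin_col, layout.origin_row
    # axes (1 px stroke so the axis band stays narrow for tracing)
    draw.line([(ox, oy), (ox + layout.plot_w, oy)], fill=layout.ink, width=1)
    draw.line([(ox, oy), (ox, oy - layout.plot_h)], fill=layout.ink, width=1)
    # ticks at every integer value
    for v in range(1, int(layout.plot_w / layout.px_per_l) + 1):
        c = ox + round(v * layout.px_per_l)
        draw.line([(c, oy + 1), (c, oy + layout.tick_len)], fill=layout.ink)
    for fval in range(1, int(layout.plot_h / layout.px_per_lps) + 1):
        r = oy - round(fval * layout.px_per_lps)
        draw.line([(ox - layout.tick_len, r), (ox - 1, r)], fill=layout.ink)
    canvas = np.asarray(img).copy()
    _draw_curve_band(canvas, cal, curve.volume, curve.flow,
                     layout.stroke, layout.ink)
    if draw_inspiratory:
        vv = np.linspace(0.0, curve.fvc, 400)
        ff = -0.6 * curve.peak_flow * np.sin(np.pi * vv / curve.fvc)
        _draw_curve_band(canvas, cal, vv, ff, layout.stroke, layout.ink)
    # locator label and the digit "2" on each axis
    label = layout.label_template()
    _paste(canvas, label.pixels,
           layout.panel_y0 + layout.label_dy, layout.panel_x0 + layout.label_dx)
    x_tpl, y_tpl = layout.digit_templates(2)
    gh, gw = x_tpl.pixels.shape
    tick_col = ox + round(2 * layout.px_per_l)
    _paste(canvas, x_tpl.pixels, oy + layout.tick_len + 3, tick_col - gw // 2)
    tick_row = oy - round(2 * layout.px_per_lps)
    _paste(canvas, y_tpl.pixels, tick_row - gh // 2,
           ox - layout.tick_len - 3 - gw)
    page = ReportPage(canvas, dpi=200.0, source_id=source_id or curve.source_id)
    return page, cal


def random_renderable_spec(
    rng: np.random.Generator, layout: PageLayout | None = None
) -> CurveSpec:
    """Draw a random piecewise-linear spec that fits the layout's plot
    area (rejection sampling; deterministic given the generator state)."""
    if layout is None:
        layout = PageLayout()
    max_pef = layout.plot_h / layout.px_per_lps
    max_fvc = layout.plot_w / layout.px_per_l
    while True:
        theta_ab = float(rng.uniform(50.0, 75.0))
        theta_bc = float(rng.uniform(5.0, theta_ab - 5.0))
        spec = CurveSpec(
            fvc=float(rng.uniform(3.0, min(5.0, max_fvc))),
            v_peak=float(rng.uniform(0.2, 0.6)),
            flatten_theta_ab=theta_ab,
            flatten_theta_bc=theta_bc,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        if implied_pef(spec) <= max_pef:
            return spec


# ---------------------------------------------------------------------------
# cohort generation


def feasible_angle_range(theta_ab: float, margin: float = 0.5) -> tuple[float, float]:
    """∠ABC values reachable with a fixed A-B inclination: the B-C
    inclination must lie in [margin, theta_ab], so ∠ABC is confined to
    [180 − theta_ab + margin, 180]."""
    return 180.0 - theta_ab + margin, 180.0


def generate_cohort(
    n_flat: int,
    n_nonflat: int,
    seed: int = 0,
    theta_ab: float = 60.0,
    fvc: float = 4.0,
    v_peak: float = 0.4,
    n_samples: int = 120,
) -> tuple[pd.DataFrame, list[CurveSpec]]:
    """Simulate an expert-labelled cohort of synthetic limbs.

    Per-subject target ∠ABC values are drawn from the two group
    Gaussians (flattening 144.8 ± 8.5°, non-flattening 163.8 ± 14.1°),
    truncated to the feasible range under the fixed A-B inclination;
    each target fixes the B-C inclination of a piecewise-linear spec
    and the indices are computed by the index code on the generated
    noise-free curve.

    Returns a DataFrame with columns ``subject_id``, ``label``
    (``flattening`` / ``non-flattening``), ``theta_bc_deg`` and all
    index-record columns, plus the per-subject specs.
    """
    rng = np.random.default_rng(seed)
    lo, hi = feasible_angle_range(theta_ab)
    rows, specs = [], []
    groups = [
        ("flattening", n_flat, FLATTENING_MEAN, FLATTENING_SD),
        ("non-flattening", n_nonflat, NONFLATTENING_MEAN, NONFLATTENING_SD),
    ]
    sid = 0
    for label, count, mu, sigma in groups:
        if count < 0:
            raise InvalidSpecError("group sizes must be >= 0")
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        targets = stats.truncnorm.rvs(a, b, loc=mu, scale=sigma,
                                      size=count, random_state=rng)
        for target in targets:
            theta_bc = target - (180.0 - theta_ab)
            spec = CurveSpec(
                fvc=fvc, v_peak=v_peak, flatten_theta_ab=theta_ab,
                flatten_theta_bc=float(theta_bc), n_samples=n_samples,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            curve, _ = generate_curve(spec)
            curve = replace_source_id(curve, f"subject-{sid:04d}")
            rec = compute_indices(curve).to_record()
            rec["subject_id"] = f"subject-{sid:04d}"
            rec["label"] = label
            rec["theta_bc_deg"] = theta_bc
            rows.append(rec)
            specs.append(spec)
            sid += 1
    cols = ["subject_id", "label", "theta_bc_deg"]
    df = pd.DataFrame(rows)
    df = df[cols + [c for c in df.columns if c not in cols]]
    return df, specs


def replace_source_id(curve: ExpiratoryCurve, source_id: str) -> ExpiratoryCurve:
    return ExpiratoryCurve(
        curve.volume, curve.flow, source=curve.source, source_id=source_id
    )
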