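"""Locate, calibrate and trace the flow-volume loop on a report page.

The pipeline mirrors how a human reads a rendered PFT report:

1. :func:`locate_panel` — slide a locator-glyph template over the page
   and keep the window whose 64-bit average hash is closest (Hamming
   distance) to the template's hash; expand that window by configured
   margins to the panel bounds.
2. :func:`calibrate_axes` — find the axis origin as the intersection of
   the longest horizontal and vertical dark runs inside the panel, find
   the digit glyph below the x axis and left of the y axis, apply the
   glyph's tick offset, and fit the affine pixel -> value maps.
3. :func:`trace_expiratory_curve` — for each pixel column right of the
   origin, take the centroid of the topmost dark band above the x axis
   (the expiratory limb lies above the inspiratory one) and map it to
   (volume, flow).

Input pages are raster images (PNG/TIFF/JPEG); vector reports should be
rasterized upstream at ~200 dpi before being fed to this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .curve import ExpiratoryCurve, MIN_SAMPLES
from .errors import (
    CalibrationError,
    InvalidInputError,
    PanelNotFoundError,
    TraceError,
)
from .glyphs import _GRID, GlyphTemplate, _block_bounds

MIN_PAGE_SIZE = 200


@dataclass(frozen=True)
class ReportPage:
    """A rendered report page as a grayscale raster (origin top-left)."""

    pixels: np.ndarray
    dpi: float = 200.0
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise InvalidInputError("page must be a 2-D grayscale raster")
        if px.shape[0] < MIN_PAGE_SIZE or px.shape[1] < MIN_PAGE_SIZE:
            raise InvalidInputError(
                f"page must be at least {MIN_PAGE_SIZE}x{MIN_PAGE_SIZE} px"
            )
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise InvalidInputError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        if self.dpi <= 0:
            raise InvalidInputError("dpi must be positive")
        object.__setattr__(self, "pixels", px)

    @classmethod
    def from_file(cls, path: str | Path, dpi: float = 200.0) -> "ReportPage":
        img = Image.open(path).convert("L")
        return cls(np.asarray(img), dpi=dpi, source_id=Path(path).stem)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class PanelRegion:
    """Pixel bounds of the located FVL panel (half-open, x1/y1 exclusive)."""

    x0: int
    y0: int
    x1: int
    y1: int
    match_distance: int = 0

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise InvalidInputError("panel region must have positive extent")


@dataclass(frozen=True)
class PanelCalibration:
    """Affine pixel -> value maps for both axes of a located panel.

    ``x_scale`` is L per pixel column; ``y_scale`` is L/s per pixel row
    and carries a negative sign because raster rows grow downward while
    flow grows upward.
    """

    x_scale: float
    x_origin_px: float
    y_scale: float
    y_origin_px: float

    def __post_init__(self) -> None:
        if not (self.x_scale > 0 and self.y_scale != 0):
            raise InvalidInputError("degenerate calibration scales")

    def volume_at(self, col: np.ndarray | float) -> np.ndarray | float:
        return (np.asarray(col, float) - self.x_origin_px) * self.x_scale

    def flow_at(self, row: np.ndarray | float) -> np.ndarray | float:
        return (np.asarray(row, float) - self.y_origin_px) * self.y_scale

    def col_of(self, volume: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(volume, float) / self.x_scale + self.x_origin_px

    def row_of(self, flow: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(flow, float) / self.y_scale + self.y_origin_px


@dataclass(frozen=True)
class DigitizerConfig:
    """Tunable knobs of the digitizer.

    The margin defaults are sized to the bundled synthetic report
    layout, where the locator label sits just inside the panel's
    top-left corner; for other layouts pass explicit margins.
    """

    #: maximum Hamming distance for a glyph match
    hash_threshold: int = 4
    #: intensities strictly below this count as ink
    intensity_threshold: int = 128
    #: px added around the winning label window to reach the panel bounds
    margin_left: int = 8
    margin_top: int = 8
    margin_right: int = 380
    margin_bottom: int = 520
    #: half-width of the band treated as axis stroke when tracing, px
    axis_mask_px: int = 1
    #: rasterization resolution used for file input, dots per inch
    dpi: float = 200.0


DEFAULT_CONFIG = DigitizerConfig()


def _window_hash_distances(
    pixels: np.ndarray, template: GlyphTemplate
) -> np.ndarray:
    """Hamming distance of every template-sized window's average hash.

    Vectorized over all window positions via an integral image: block
    boundaries are fixed relative to the window, so each of the 64 block
    sums is four integral-image lookups.  Produces exactly the same bits
    as :func:`fvlsad.glyphs.hash_glyph` on the cropped window.
    """
    th, tw = template.shape
    h, w = pixels.shape
    if th > h or tw > w:
        raise InvalidInputError("template larger than search area")
    if th < _GRID or tw < _GRID:
        raise InvalidInputError("template must be at least 8x8 px")
    integral = np.zeros((h + 1, w + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(pixels.astype(np.int64), 0), 1)
    rb, cb = _block_bounds(th), _block_bounds(tw)
    ny, nx = h - th + 1, w - tw + 1
    means = np.empty((_GRID * _GRID, ny, nx))
    k = 0
    for i in range(_GRID):
        r0, r1 = rb[i], rb[i + 1]
        for j in range(_GRID):
            c0, c1 = cb[j], cb[j + 1]
            block = (
                integral[r1 : r1 + ny, c1 : c1 + nx]
                - integral[r0 : r0 + ny, c1 : c1 + nx]
                - integral[r1 : r1 + ny, c0 : c0 + nx]
                + integral[r0 : r0 + ny, c0 : c0 + nx]
            )
            means[k] = block / ((r1 - r0) * (c1 - c0))
            k += 1
    bits = means >= means.mean(axis=0, keepdims=True)
    tbits = template.hash_bits.reshape(_GRID * _GRID, 1, 1)
    return np.count_nonzero(bits != tbits, axis=0)


def find_glyph_matches(
    pixels: np.ndarray,
    template: GlyphTemplate,
    threshold: int,
    origin: tuple[int, int] = (0, 0),
) -> list[tuple[int, int, int]]:
    """All non-overlapping glyph matches as (row, col, distance).

    Matches within one template size of a better match are suppressed;
    ties resolve to the first window in row-major scan order.  Returned
    coordinates are absolute (offset by *origin* = (row0, col0)).
    """
    dist = _window_hash_distances(pixels, template)
    th, tw = template.shape
    hits: list[tuple[int, int, int]] = []
    d = dist.copy()
    while True:
        idx = int(np.argmin(d))  # first minimum in row-major order
        r, c = divmod(idx, d.shape[1])
        if d[r, c] > threshold:
            break
        hits.append((r + origin[0], c + origin[1], int(dist[r, c])))
        r0, r1 = max(0, r - th + 1), min(d.shape[0], r + th)
        c0, c1 = max(0, c - tw + 1), min(d.shape[1], c + tw)
        d[r0:r1, c0:c1] = threshold + 1
    hits.sort(key=lambda h: (h[2], h[0], h[1]))
    return hits


def locate_panel(
    page: ReportPage,
    label: GlyphTemplate,
    config: DigitizerConfig = DEFAULT_CONFIG,
) -> PanelRegion:
    """Find the FVL panel by sliding-window hash search for the label."""
    if label.role != "panel_label":
        raise InvalidInputError("locate_panel needs a panel_label template")
    dist = _window_hash_distances(page.pixels, label)
    idx = int(np.argmin(dist))  # tie rule: first in row-major scan order
    r, c = divmod(idx, dist.shape[1])
    best = int(dist[r, c])
    if best > config.hash_threshold:
        raise PanelNotFoundError(
            f"no label match within Hamming {config.hash_threshold} "
            f"(best distance {best})",
            best_distance=best,
        )
    h, w = page.shape
    th, tw = label.shape
    return PanelRegion(
        x0=max(0, c - config.margin_left),
        y0=max(0, r - config.margin_top),
        x1=min(w, c + tw + config.margin_right),
        y1=min(h, r + th + config.margin_bottom),
        match_distance=best,
    )


def _longest_run(mask_1d: np.ndarray) -> tuple[int, int, int]:
    """(length, start, end) of the longest True run in a boolean vector."""
    padded = np.concatenate(([False], mask_1d, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    if edges.size == 0:
        return 0, 0, 0
    starts, ends = edges[0::2], edges[1::2]
    k = int(np.argmax(ends - starts))
    return int(ends[k] - starts[k]), int(starts[k]), int(ends[k])


def find_axis_origin(
    page: ReportPage,
    region: PanelRegion,
    config: DigitizerConfig = DEFAULT_CONFIG,
) -> tuple[int, int]:
    """Axis origin (col, row) in page coordinates.

    The x axis is the row with the longest horizontal dark run inside
    the panel; the y axis the column with the longest vertical run.
    """
    crop = page.pixels[region.y0 : region.y1, region.x0 : region.x1]
    dark = crop < config.intensity_threshold
    row_runs = [_longest_run(dark[i])[0] for i in range(dark.shape[0])]
    col_runs = [_longest_run(dark[:, j])[0] for j in range(dark.shape[1])]
    axis_row = int(np.argmax(row_runs))
    axis_col = int(np.argmax(col_runs))
    if row_runs[axis_row] < 10 or col_runs[axis_col] < 10:
        raise CalibrationError("no axis lines found inside the panel")
    return region.x0 + axis_col, region.y0 + axis_row


def calibrate_axes(
    page: ReportPage,
    region: PanelRegion,
    digit: GlyphTemplate,
    digit_y: GlyphTemplate | None = None,
    config: DigitizerConfig = DEFAULT_CONFIG,
) -> PanelCalibration:
    """Fit the affine pixel -> value maps from the axis digit glyph.

    *digit* is searched below the x axis; *digit_y* (same raster, its
    own tick offset; defaults to *digit*) left of the y axis.  All
    accepted matches enter a least-squares affine fit together with the
    axis origin at value 0.
    """
    if digit.role != "axis_digit":
        raise InvalidInputError("calibrate_axes needs an axis_digit template")
    if digit_y is None:
        digit_y = digit
    origin_col, origin_row = find_axis_origin(page, region, config)
    px = page.pixels

    # x axis: digits live strictly below the axis row
    band = px[origin_row + 1 : region.y1, region.x0 : region.x1]
    try:
        hits_x = find_glyph_matches(
            band, digit, config.hash_threshold, origin=(origin_row + 1, region.x0)
        )
    except InvalidInputError:
        hits_x = []
    if not hits_x:
        raise CalibrationError("axis digit not found below the x axis", axis="x")

    # y axis: digits live strictly left of the y-axis column
    band = px[region.y0 : region.y1, region.x0 : origin_col]
    try:
        hits_y = find_glyph_matches(
            band, digit_y, config.hash_threshold, origin=(region.y0, region.x0)
        )
    except InvalidInputError:
        hits_y = []
    if not hits_y:
        raise CalibrationError("axis digit not found left of the y axis", axis="y")

    dx, dy = digit.tick_offset
    cols = np.array([c + dx for r, c, _ in hits_x] + [origin_col], float)
    vals = np.array([digit.value] * len(hits_x) + [0.0])
    mx, bx = np.polyfit(cols, vals, 1) if cols.size > 2 else (
        (vals[0] - vals[-1]) / (cols[0] - cols[-1]),
        0.0,
    )
    if cols.size == 2:
        bx = vals[1] - mx * cols[1]
    dx, dy = digit_y.tick_offset
    rows = np.array([r + dy for r, c, _ in hits_y] + [origin_row], float)
    vals_y = np.array([digit_y.value] * len(hits_y) + [0.0])
    if rows.size > 2:
        my, by = np.polyfit(rows, vals_y, 1)
    else:
        my = (vals_y[0] - vals_y[-1]) / (rows[0] - rows[-1])
        by = vals_y[1] - my * rows[1]
    if mx <= 0 or my == 0:
        raise CalibrationError("degenerate axis fit")
    cal = PanelCalibration(
        x_scale=float(mx),
        x_origin_px=float(-bx / mx),
        y_scale=float(my),
        y_origin_px=float(-by / my),
    )
    # round-trip self check: value -> pixel -> value must be tight
    for v, fwd, inv, scale, axis in (
        (digit.value, cal.col_of, cal.volume_at, cal.x_scale, "x"),
        (digit_y.value, cal.row_of, cal.flow_at, abs(cal.y_scale), "y"),
    ):
        if abs(inv(fwd(v)) - v) >= 0.5 * scale:
            raise CalibrationError("round-trip error too large", axis=axis)
    return cal


def trace_expiratory_curve(
    page: ReportPage,
    region: PanelRegion,
    cal: PanelCalibration,
    config: DigitizerConfig = DEFAULT_CONFIG,
    source_id: str | None = None,
) -> ExpiratoryCurve:
    """Trace the expiratory limb above the x axis into value space.

    Column by column, ink runs at or above the axis row are curve
    candidates; the topmost run (greatest flow) is taken — when the
    in- and expiratory limbs overlap near the origin the expiratory
    limb lies above.  A run must reach strictly above the axis row to
    count (a run consisting of the axis stroke alone is ignored), and
    the centroid is taken over its above-axis rows, so a flat tail that
    merges into the axis line is still traced out to C while trailing
    axis-only columns terminate the trace.
    """
    axis_row = int(round(cal.y_origin_px))
    axis_col = int(round(cal.x_origin_px))
    m = config.axis_mask_px
    row_top = region.y0
    col_lo, col_hi = axis_col + m + 1, region.x1
    dark = page.pixels[row_top : axis_row + 1, col_lo:col_hi] < config.intensity_threshold
    axis_band_top = axis_row - row_top  # local row index of the axis line

    cols: list[int] = []
    rows_c: list[float] = []
    for j in range(dark.shape[1]):
        col = dark[:, j]
        if not col.any():
            continue
        padded = np.concatenate(([False], col, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[0::2], edges[1::2]
        # drop runs that never rise above the axis line (axis stroke only)
        keep = starts < axis_band_top
        if not keep.any():
            continue
        s, e = starts[keep][0], ends[keep][0]  # topmost surviving run
        e = min(e, axis_band_top)  # centroid over above-axis rows only
        rows_c.append(row_top + (s + e - 1) / 2.0)
        cols.append(col_lo + j)
    if len(cols) < MIN_SAMPLES:
        raise TraceError(
            f"only {len(cols)} traceable columns (need {MIN_SAMPLES})"
        )
    volume = np.asarray(cal.volume_at(np.array(cols, float)))
    flow = np.asarray(cal.flow_at(np.array(rows_c)))
    # trim to the span where flow is non-negative
    ok = np.flatnonzero(flow >= 0)
    if ok.size < MIN_SAMPLES:
        raise TraceError("too few non-negative flow samples")
    volume, flow = volume[ok[0] : ok[-1] + 1], flow[ok[0] : ok[-1] + 1]
    sid = source_id if source_id is not None else page.source_id
    return ExpiratoryCurve(volume, flow, source="traced", source_id=sid)


def digitize_page(
    page: ReportPage,
    label: GlyphTemplate,
    digit: GlyphTemplate,
    digit_y: GlyphTemplate | None = None,
    config: DigitizerConfig = DEFAULT_CONFIG,
) -> tuple[ExpiratoryCurve, PanelRegion, PanelCalibration]:
    """Full chain: locate panel, calibrate axes, trace the curve."""
    region = locate_panel(page, label, config)
    cal = calibrate_axes(page, region, digit, digit_y, config)
    curve = trace_expiratory_curve(page, region, cal, config)
    return curve, region, cal
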