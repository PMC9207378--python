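"""Glyph templates and the perceptual hash used to find them.

Report panels are located by searching the page for a small locator
glyph ("F/V ex" in the emulated layout) via a 64-bit average hash, and
axes are calibrated by finding the digit "2" glyph near each axis.  The
hash is deliberately simple and fully specified so that matches are
reproducible bit-for-bit:

* the raster is partitioned into an 8 x 8 grid of blocks (block edges at
  ``floor(linspace(0, size, 9))``; rasters smaller than 8 px in a
  dimension are first integer-upsampled by repetition),
* each block's mean intensity is compared against the mean of the 64
  block means,
* tie rule: a block whose mean is **greater than or equal to** the
  overall mean maps to bit 1 (so a constant raster hashes to all ones).

Glyph rasters are generated from a bundled 5x7 bitmap font so no
external font files are ever needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

HASH_BITS = 64
_GRID = 8

# 5x7 bitmap font; '#' = ink.  Only the characters the emulated report
# layout needs are defined.
_FONT: dict[str, tuple[str, ...]] = {
    "0": (".###.", "#...#", "#..##", "#.#.#", "##..#", "#...#", ".###."),
    "1": ("..#..", ".##..", "..#..", "..#..", "..#..", "..#..", ".###."),
    "2": (".###.", "#...#", "....#", "...#.", "..#..", ".#...", "#####"),
    "3": ("####.", "....#", "....#", ".###.", "....#", "....#", "####."),
    "4": ("...#.", "..##.", ".#.#.", "#..#.", "#####", "...#.", "...#."),
    "5": ("#####", "#....", "####.", "....#", "....#", "#...#", ".###."),
    "6": ("..##.", ".#...", "#....", "####.", "#...#", "#...#", ".###."),
    "7": ("#####", "....#", "...#.", "..#..", ".#...", ".#...", ".#..."),
    "8": (".###.", "#...#", "#...#", ".###.", "#...#", "#...#", ".###."),
    "9": (".###.", "#...#", "#...#", ".####", "....#", "...#.", ".##.."),
    "F": ("#####", "#....", "#....", "####.", "#....", "#....", "#...."),
    "V": ("#...#", "#...#", "#...#", "#...#", "#...#", ".#.#.", "..#.."),
    "/": ("....#", "...#.", "...#.", "..#..", ".#...", ".#...", "#...."),
    "e": (".....", ".....", ".###.", "#...#", "#####", "#....", ".###."),
    "x": (".....", ".....", "#...#", ".#.#.", "..#..", ".#.#.", "#...#"),
    " ": (".....", ".....", ".....", ".....", ".....", ".....", "....."),
}

CHAR_H, CHAR_W = 7, 5


def render_text(
    text: str, scale: int = 2, ink: int = 0, background: int = 255
) -> np.ndarray:
    """Rasterize *text* with the bundled font at an integer *scale*.

    Returns a uint8 grayscale raster (rows x cols) with one blank column
    between characters.
    """
    if scale < 1:
        raise InvalidInputError("scale must be >= 1")
    cols: list[np.ndarray] = []
    for i, ch in enumerate(text):
        if ch not in _FONT:
            raise InvalidInputError(f"character {ch!r} not in bundled font")
        bitmap = np.array(
            [[c == "#" for c in row] for row in _FONT[ch]], dtype=bool
        )
        if i:
            cols.append(np.zeros((CHAR_H, 1), dtype=bool))
        cols.append(bitmap)
    mask = np.concatenate(cols, axis=1)
    mask = np.repeat(np.repeat(mask, scale, axis=0), scale, axis=1)
    out = np.full(mask.shape, background, dtype=np.uint8)
    out[mask] = ink
    return out


def _block_bounds(size: int) -> np.ndarray:
    return np.floor(np.linspace(0, size, _GRID + 1)).astype(int)


def hash_glyph(pixels: np.ndarray) -> np.ndarray:
    """64-bit average hash of a grayscale raster.

    Returns a flat boolean array of length 64 (row-major over the 8x8
    block grid).  Deterministic: identical rasters yield identical
    hashes.
    """
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidInputError("glyph raster must be a non-empty 2-D array")
    h, w = arr.shape
    if h < _GRID:
        arr = np.repeat(arr, -(-_GRID // h), axis=0)
    if w < _GRID:
        arr = np.repeat(arr, -(-_GRID // w), axis=1)
    h, w = arr.shape
    rb, cb = _block_bounds(h), _block_bounds(w)
    means = np.empty((_GRID, _GRID))
    for i in range(_GRID):
        for j in range(_GRID):
            means[i, j] = arr[rb[i] : rb[i + 1], cb[j] : cb[j + 1]].mean()
    return (means >= means.mean()).ravel()


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance between two 64-bit hashes."""
    a = np.asarray(a, dtype=bool).ravel()
    b = np.asarray(b, dtype=bool).ravel()
    if a.size != HASH_BITS or b.size != HASH_BITS:
        raise InvalidInputError(f"hashes must be {HASH_BITS} bits")
    return int(np.count_nonzero(a != b))


@dataclass(frozen=True)
class GlyphTemplate:
    """A small raster to be located on a page by perceptual hash.

    Parameters
    ----------
    pixels : ndarray
        Grayscale template raster.
    role : str
        ``panel_label`` for the FVL locator glyph, ``axis_digit`` for a
        numeric axis label.
    value : float
        Number the glyph represents when ``role == 'axis_digit'``.
    tick_offset : (float, float)
        (dx, dy) displacement, in px, from the template's top-left
        anchor to the axis tick the glyph labels.
    """

    pixels: np.ndarray
    role: str = "panel_label"
    value: float = float("nan")
    tick_offset: tuple[float, float] = (0.0, 0.0)
    hash_bits: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.role not in ("panel_label", "axis_digit"):
            raise InvalidInputError(f"unknown glyph role {self.role!r}")
        if not all(np.isfinite(self.tick_offset)):
            raise InvalidInputError("tick_offset must be finite")
        px = np.asarray(self.pixels, dtype=np.uint8)
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "hash_bits", hash_glyph(px))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def default_label_template(scale: int = 2) -> GlyphTemplate:
    """Locator glyph for the FVL panel, mimicking the 'F/V ex' label."""
    return GlyphTemplate(render_text("F/V ex", scale=scale), role="panel_label")


def default_digit_template(
    digit: int = 2, scale: int = 2, tick_offset: tuple[float, float] = (0.0, 0.0)
) -> GlyphTemplate:
    return GlyphTemplate(
        render_text(str(digit), scale=scale),
        role="axis_digit",
        value=float(digit),
        tick_offset=tick_offset,
    )
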