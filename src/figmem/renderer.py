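"""Deterministic rasterisation of emblems, frames and stimulus sheets.

Learning sheets place the framed emblems in a 5 x 4 matrix (row-major by
``learning_cell``, cell 0 top-left).  Answer sheets re-order the emblems by
``recall_position`` and show four candidate frames under each emblem, either
again as a 5 x 4 matrix of option blocks or vertically one unit per row (the
format used in web surveys where a wide matrix cannot be guaranteed to fit
the screen).

All drawing is done without antialiasing so that rendering is a pure
function of ``(spec, config)``: repeated calls produce byte-identical PNGs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw

from .stimulus import (
    AssociationUnit,
    EmblemSpec,
    FrameSpec,
    ItemSpec,
    option_orders,
)

__all__ = [
    "RenderConfig",
    "render_emblem",
    "render_unit",
    "render_learning_sheet",
    "render_answer_sheet",
    "scoring_manifest",
]

BG = 255  # white
FG = 0  # black


@dataclass(frozen=True)
class RenderConfig:
    cell_px: int = 96
    line_width_px: int = 3
    margin_px: int = 12
    image_format: str = "PNG"

    def __post_init__(self):
        if self.cell_px < 32:
            raise ValueError("cell_px must be >= 32")
        if self.line_width_px < 1:
            raise ValueError("line_width_px must be >= 1")
        if self.image_format != "PNG":
            raise ValueError("only PNG output is supported")


# --- frame geometry -------------------------------------------------------
# Vertices in unit coordinates, y pointing up, ordered counter-clockwise.
# Edge k (1-based) joins vertex k-1 to vertex k; edge 1 starts at the
# bottom(-most) edge, so "missing_line" indexes counter-clockwise from the
# bottom edge.


def _regular_polygon(n: int, flat_bottom: bool = True):
    # vertices of a regular n-gon inscribed in a circle of radius .42
    # centred at (.5,.5); rotated so one edge lies flat at the bottom
    off = -math.pi / 2 + (math.pi / n if flat_bottom else 0.0)
    pts = [
        (0.5 + 0.42 * math.cos(off + 2 * math.pi * k / n),
         0.5 + 0.42 * math.sin(off + 2 * math.pi * k / n))
        for k in range(n)
    ]
    return pts


def _star_polygon(n: int, r_in: float = 0.2, r_out: float = 0.45):
    pts = []
    for k in range(2 * n):
        r = r_out if k % 2 == 0 else r_in
        a = -math.pi / 2 + math.pi * k / n
        pts.append((0.5 + r * math.cos(a), 0.5 + r * math.sin(a)))
    return pts


FRAME_VERTICES: dict[str, list[tuple[float, float]]] = {
    "rectangle": [(0.08, 0.18), (0.92, 0.18), (0.92, 0.82), (0.08, 0.82)],
    "trapeze": [(0.08, 0.15), (0.92, 0.15), (0.72, 0.85), (0.28, 0.85)],
    "pentagon": _regular_polygon(5),
    "hexagon": _regular_polygon(6),
    "square": [(0.15, 0.15), (0.85, 0.15), (0.85, 0.85), (0.15, 0.85)],
    "triangle": [(0.08, 0.12), (0.92, 0.12), (0.5, 0.9)],
    "right_trapezoid": [(0.1, 0.15), (0.9, 0.15), (0.9, 0.85), (0.42, 0.85)],
    "parallelogram": [(0.05, 0.15), (0.75, 0.15), (0.95, 0.85), (0.25, 0.85)],
    "rhombus": [(0.5, 0.05), (0.9, 0.5), (0.5, 0.95), (0.1, 0.5)],
    "heptagon": _regular_polygon(7),
    "octagon": _regular_polygon(8),
    "house": [(0.15, 0.1), (0.85, 0.1), (0.85, 0.6), (0.5, 0.92), (0.15, 0.6)],
    "cross_frame": [
        (0.35, 0.05), (0.65, 0.05), (0.65, 0.35), (0.95, 0.35), (0.95, 0.65),
        (0.65, 0.65), (0.65, 0.95), (0.35, 0.95), (0.35, 0.65), (0.05, 0.65),
        (0.05, 0.35), (0.35, 0.35),
    ],
    "arrow_frame": [
        (0.35, 0.08), (0.65, 0.08), (0.65, 0.55), (0.9, 0.55), (0.5, 0.95),
        (0.1, 0.55), (0.35, 0.55),
    ],
    "chevron_frame": [
        (0.1, 0.1), (0.5, 0.35), (0.9, 0.1), (0.9, 0.55), (0.5, 0.8),
        (0.1, 0.55),
    ],
    "six_star_frame": _star_polygon(6, r_in=0.24, r_out=0.46),
    "l_frame": [
        (0.2, 0.1), (0.9, 0.1), (0.9, 0.4), (0.5, 0.4), (0.5, 0.9), (0.2, 0.9),
    ],
    "t_frame": [
        (0.38, 0.1), (0.62, 0.1), (0.62, 0.6), (0.92, 0.6), (0.92, 0.9),
        (0.08, 0.9), (0.08, 0.6), (0.38, 0.6),
    ],
    "tall_rectangle": [(0.3, 0.05), (0.7, 0.05), (0.7, 0.95), (0.3, 0.95)],
    "notched_square": [
        (0.12, 0.12), (0.88, 0.12), (0.88, 0.88), (0.62, 0.88), (0.62, 0.62),
        (0.38, 0.62), (0.38, 0.88), (0.12, 0.88),
    ],
}


def _to_px(pt, size: int):
    # unit coords (y up) -> integer pixel coords (y down)
    x, y = pt
    return (round(x * (size - 1)), round((1.0 - y) * (size - 1)))


def _draw_frame(draw: ImageDraw.ImageDraw, frame: FrameSpec, box, cfg: RenderConfig):
    """Draw the frame outline into ``box = (x0, y0, size)``, omitting the
    erased edge when ``missing_line != 0``."""
    x0, y0, size = box
    verts = FRAME_VERTICES[frame.base_shape]
    n = len(verts)
    pts = [_to_px(v, size) for v in verts]
    pts = [(x0 + px, y0 + py) for px, py in pts]
    for k in range(1, n + 1):
        if k == frame.missing_line:
            continue
        a = pts[k - 1]
        b = pts[k % n]
        draw.line([a, b], fill=FG, width=cfg.line_width_px)


# --- emblem geometry ------------------------------------------------------


def _emblem_tile(emblem: EmblemSpec, size: int, lw: int) -> Image.Image:
    """Draw the emblem at orientation 0 / gap top, then rotate or relocate.

    Rotations are exact 90-degree pixel permutations (no resampling), so a
    rendered orientation-180 emblem equals the 180-degree rotation of the
    orientation-0 render.
    """
    img = Image.new("L", (size, size), BG)
    d = ImageDraw.Draw(img)
    s = size

    def P(x, y):  # unit coords, y up
        return (round(x * (s - 1)), round((1.0 - y) * (s - 1)))

    def poly(pts):
        d.polygon([P(*p) for p in pts], fill=FG)

    def ellipse(x0, y0, x1, y1, fill=FG):
        d.ellipse([P(x0, y1), P(x1, y0)], fill=fill)

    sid = emblem.shape_id
    if sid == "right_triangle":
        poly([(0.12, 0.12), (0.88, 0.12), (0.12, 0.88)])
    elif sid == "quadrant_gap_circle":
        ellipse(0.1, 0.1, 0.9, 0.9)
        # erase the top-right quadrant
        d.rectangle([P(0.5, 1.0), P(1.0, 0.5)], fill=BG)
    elif sid == "prong_circle":
        ellipse(0.15, 0.15, 0.85, 0.85)
        # prong to the top right
        d.line([P(0.72, 0.72), P(0.95, 0.95)], fill=FG, width=max(lw, s // 12))
    elif sid == "l_shape":
        poly([(0.2, 0.1), (0.45, 0.1), (0.45, 0.65), (0.8, 0.65),
              (0.8, 0.9), (0.2, 0.9)])
    elif sid == "black_ring":
        ellipse(0.1, 0.1, 0.9, 0.9)
        ellipse(0.3, 0.3, 0.7, 0.7, fill=BG)
        if emblem.gap_position != "none":
            w = 0.14
            gaps = {
                "top": [P(0.5 - w, 1.0), P(0.5 + w, 0.68)],
                "bottom": [P(0.5 - w, 0.32), P(0.5 + w, 0.0)],
                "left": [P(0.0, 0.5 + w), P(0.32, 0.5 - w)],
                "right": [P(0.68, 0.5 + w), P(1.0, 0.5 - w)],
            }
            d.rectangle(gaps[emblem.gap_position], fill=BG)
    elif sid == "plus_sign":
        poly([(0.38, 0.1), (0.62, 0.1), (0.62, 0.38), (0.9, 0.38), (0.9, 0.62),
              (0.62, 0.62), (0.62, 0.9), (0.38, 0.9), (0.38, 0.62), (0.1, 0.62),
              (0.1, 0.38), (0.38, 0.38)])
    elif sid == "black_circle":
        ellipse(0.12, 0.12, 0.88, 0.88)
    elif sid == "black_square":
        d.rectangle([P(0.15, 0.85), P(0.85, 0.15)], fill=FG)
    elif sid == "diamond":
        poly([(0.5, 0.05), (0.92, 0.5), (0.5, 0.95), (0.08, 0.5)])
    elif sid == "five_star":
        poly(_star_polygon(5, r_in=0.18, r_out=0.45))
    elif sid == "arrow_up":
        poly([(0.4, 0.1), (0.6, 0.1), (0.6, 0.55), (0.85, 0.55), (0.5, 0.92),
              (0.15, 0.55), (0.4, 0.55)])
    elif sid == "cross_x":
        w = max(lw, s // 10)
        d.line([P(0.12, 0.12), P(0.88, 0.88)], fill=FG, width=w)
        d.line([P(0.12, 0.88), P(0.88, 0.12)], fill=FG, width=w)
    elif sid == "crescent":
        ellipse(0.1, 0.1, 0.9, 0.9)
        ellipse(0.3, 0.18, 1.02, 0.82, fill=BG)
    elif sid == "t_shape":
        poly([(0.1, 0.68), (0.9, 0.68), (0.9, 0.9), (0.62, 0.9)])
        poly([(0.1, 0.9), (0.9, 0.9), (0.9, 0.68), (0.1, 0.68)])
        poly([(0.38, 0.1), (0.62, 0.1), (0.62, 0.68), (0.38, 0.68)])
    elif sid == "u_shape":
        poly([(0.15, 0.9), (0.38, 0.9), (0.38, 0.3), (0.62, 0.3), (0.62, 0.9),
              (0.85, 0.9), (0.85, 0.1), (0.15, 0.1)])
    elif sid == "z_shape":
        poly([(0.12, 0.7), (0.88, 0.7), (0.88, 0.9), (0.12, 0.9)])
        poly([(0.12, 0.1), (0.88, 0.1), (0.88, 0.3), (0.12, 0.3)])
        poly([(0.62, 0.3), (0.88, 0.3), (0.38, 0.7), (0.12, 0.7)])
    elif sid == "bowtie":
        poly([(0.1, 0.2), (0.5, 0.5), (0.1, 0.8)])
        poly([(0.9, 0.2), (0.5, 0.5), (0.9, 0.8)])
    elif sid == "black_triangle":
        poly([(0.1, 0.15), (0.9, 0.15), (0.5, 0.88)])
    elif sid == "half_circle":
        d.pieslice([P(0.08, 0.92), P(0.92, 0.08)], 180, 360, fill=FG)
    elif sid == "four_arrows":
        w = 0.09
        poly([(0.5 - w, 0.25), (0.5 + w, 0.25), (0.5 + w, 0.75), (0.5 - w, 0.75)])
        poly([(0.25, 0.5 - w), (0.75, 0.5 - w), (0.75, 0.5 + w), (0.25, 0.5 + w)])
        poly([(0.35, 0.72), (0.65, 0.72), (0.5, 0.95)])
        poly([(0.35, 0.28), (0.65, 0.28), (0.5, 0.05)])
        poly([(0.28, 0.35), (0.28, 0.65), (0.05, 0.5)])
        poly([(0.72, 0.35), (0.72, 0.65), (0.95, 0.5)])
    else:
        raise ValueError(f"unknown emblem shape {sid!r}")

    if emblem.orientation_deg:
        # PIL rotates counter-clockwise; exact for multiples of 90
        img = img.rotate(emblem.orientation_deg, expand=False, fillcolor=BG)
    return img


def render_emblem(emblem: EmblemSpec, cfg: RenderConfig) -> Image.Image:
    """Render a single emblem into a ``cell_px`` square tile."""
    return _emblem_tile(emblem, cfg.cell_px, cfg.line_width_px)


def render_unit(unit: AssociationUnit, cfg: RenderConfig) -> Image.Image:
    """Render one framed emblem (the learning-phase appearance of a unit)."""
    s = cfg.cell_px
    img = Image.new("L", (s, s), BG)
    d = ImageDraw.Draw(img)
    _draw_frame(d, unit.correct_frame, (0, 0, s), cfg)
    inner = int(s * 0.42)
    tile = _emblem_tile(unit.emblem, inner, max(1, cfg.line_width_px - 1))
    off = (s - inner) // 2
    img.paste(tile, (off, off))
    return img


def _frame_tile(frame: FrameSpec, size: int, cfg: RenderConfig) -> Image.Image:
    img = Image.new("L", (size, size), BG)
    _draw_frame(ImageDraw.Draw(img), frame, (0, 0, size), cfg)
    return img


GRID_COLS, GRID_ROWS = 5, 4


def render_learning_sheet(item: ItemSpec, cfg: RenderConfig) -> Image.Image:
    """5 x 4 learning matrix; unit with learning_cell c sits at row c//5,
    column c%5 (cell 0 top-left); cells beyond n_units stay blank."""
    s, m = cfg.cell_px, cfg.margin_px
    img = Image.new("L", (GRID_COLS * s + 2 * m, GRID_ROWS * s + 2 * m), BG)
    for u in item.units:
        r, c = divmod(u.learning_cell, GRID_COLS)
        img.paste(render_unit(u, cfg), (m + c * s, m + r * s))
    return img


def _option_block(unit: AssociationUnit, order: list[int], cfg: RenderConfig) -> Image.Image:
    """Emblem on top, its four frame options (shuffled) in a strip below."""
    s = cfg.cell_px
    half = s // 2
    w, h = 4 * half, s + half
    img = Image.new("L", (w, h), BG)
    img.paste(render_emblem(unit.emblem, cfg), ((w - s) // 2, 0))
    options = [unit.correct_frame, *unit.distractors]
    for slot, opt_idx in enumerate(order):
        img.paste(_frame_tile(options[opt_idx], half, cfg), (slot * half, s))
    return img


def render_answer_sheet(item: ItemSpec, cfg: RenderConfig, layout: str = "matrix") -> Image.Image:
    """Answer sheet: emblems ordered by recall_position, each above its four
    frame options in a seeded random order.  ``layout`` is ``"matrix"``
    (5 x 4 grid of option blocks) or ``"vertical"`` (one unit per row)."""
    if layout not in ("matrix", "vertical"):
        raise ValueError(f"layout must be 'matrix' or 'vertical', got {layout!r}")
    s, m = cfg.cell_px, cfg.margin_px
    orders = option_orders(item)
    by_recall = sorted(item.units, key=lambda u: u.recall_position)
    unit_index = {id(u): j for j, u in enumerate(item.units)}
    bw, bh = 4 * (s // 2), s + s // 2
    if layout == "matrix":
        img = Image.new("L", (GRID_COLS * bw + 2 * m, GRID_ROWS * bh + 2 * m), BG)
        for u in by_recall:
            r, c = divmod(u.recall_position, GRID_COLS)
            block = _option_block(u, orders[unit_index[id(u)]], cfg)
            img.paste(block, (m + c * bw, m + r * bh))
    else:
        img = Image.new("L", (bw + 2 * m, item.n_units * bh + 2 * m), BG)
        for u in by_recall:
            block = _option_block(u, orders[unit_index[id(u)]], cfg)
            img.paste(block, (m, m + u.recall_position * bh))
    return img


def scoring_manifest(item: ItemSpec, layout: str = "matrix") -> dict:
    """Scoring key for an answer sheet: recall position -> correct option slot.

    Also carries the item metadata and the (advisory, not enforced) one-minute
    learning time of the original administration.
    """
    orders = option_orders(item)
    key = {}
    for j, u in enumerate(item.units):
        # slot whose drawn option is the correct frame (option index 0)
        key[u.recall_position] = orders[j].index(0)
    return {
        "version": 1,
        "radical_level": item.radical_level,
        "incidental_seed": item.incidental_seed,
        "n_units": item.n_units,
        "layout": layout,
        "learning_time_s": 60,
        "correct_option_by_recall_position": {str(k): v for k, v in sorted(key.items())},
    }
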