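"""Shared fixtures and independent geometric oracles.

The rasterisation oracle evaluates element membership directly from the
polar definition of the flower (or by a crossing-number test on parsed SVG
polygons) on a fine pixel grid — independent of the closed-form areas and
shapely clipping used by the implementation.
"""

from __future__ import annotations

import re

import numpy as np
import pytest

from acuitrap import WFT
from acuitrap.design import PatternElement, TrapCard


@pytest.fixture
def wft():
    return WFT


def _bbox_grid(cx, cy, half, card_w, card_h, px):
    x0, x1 = max(0.0, cx - half), min(card_w, cx + half)
    y0, y1 = max(0.0, cy - half), min(card_h, cy + half)
    xs = np.arange(x0 + px / 2, x1, px)
    ys = np.arange(y0 + px / 2, y1, px)
    return np.meshgrid(xs, ys)


def rasterized_element_area(
    el: PatternElement, card_w: float, card_h: float, px: float = 0.02
) -> float:
    """Pixel-counted area of the flower clipped to the card, from the polar
    membership test r <= (R/2)(c0 + (1-c0)cos(k theta))."""
    cx, cy = el.center
    X, Y = _bbox_grid(cx, cy, el.size_cm / 2, card_w, card_h, px)
    dx, dy = X - cx, Y - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    r_max = (el.size_cm / 2) * (
        el.roundness + (1 - el.roundness) * np.cos(el.petals * theta)
    )
    return float(np.sum(r <= r_max)) * px * px


def rasterized_percent_cover(card: TrapCard, px: float = 0.02) -> float:
    """Pixel-counted pattern cover of a card (elements assumed disjoint)."""
    total = sum(
        rasterized_element_area(el, card.width_cm, card.height_cm, px)
        for el in card.elements
    )
    return 100.0 * total / (card.width_cm * card.height_cm)


def parse_svg_polygons(svg: str) -> list[np.ndarray]:
    """Extract flower outlines (card coordinates, cm) from an SVG document."""
    m = re.search(r'viewBox="0 0 ([\d.]+) ([\d.]+)"', svg)
    h_mm = float(m.group(2))
    polys = []
    for d in re.findall(r'<path d="M ([^"]+) Z"', svg):
        pts = np.array(
            [[float(v) for v in pair.split(",")] for pair in d.split(" L ")]
        )
        pts[:, 1] = h_mm - pts[:, 1]  # back to y-up
        polys.append(pts / 10.0)  # mm -> cm
    return polys


def points_in_polygon(px_arr: np.ndarray, py_arr: np.ndarray, poly: np.ndarray):
    """Crossing-number point-in-polygon test, vectorised over points."""
    x0, y0 = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    inside = np.zeros(px_arr.shape, dtype=bool)
    for ax, ay, bx, by in zip(x0, y0, x1, y1):
        if ay == by:
            continue
        crosses = (ay > py_arr) != (by > py_arr)
        xi = ax + (py_arr - ay) * (bx - ax) / (by - ay)
        inside ^= crosses & (px_arr < xi)
    return inside


def rasterized_svg_percent(svg: str, card: TrapCard, px: float = 0.02) -> float:
    """Pattern cover measured by rasterising the polygons parsed back out
    of the rendered SVG."""
    total = 0.0
    for poly in parse_svg_polygons(svg):
        cx = (poly[:, 0].min() + poly[:, 0].max()) / 2
        cy = (poly[:, 1].min() + poly[:, 1].max()) / 2
        half = max(poly[:, 0].max() - cx, poly[:, 1].max() - cy) + px
        X, Y = _bbox_grid(cx, cy, half, card.width_cm, card.height_cm, px)
        total += float(np.sum(points_in_polygon(X, Y, poly))) * px * px
    return 100.0 * total / (card.width_cm * card.height_cm)
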