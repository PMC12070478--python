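"""Compose and render patterned sticky-trap cards.

A card is a coloured rectangle carrying one or more "geometric flower"
elements sized so that each is resolvable at a chosen design distance.  The
flower is a polar rosette

    r(theta) = (R/2) * (c0 + (1 - c0) * cos(k * theta))

where ``R`` is the element's maximal linear extent, ``k`` the petal count
and ``c0`` a roundness parameter in (0.5, 1]; ``c0 = 1`` is a circle.  Its
area has the closed form ``pi * (R/2)**2 * (c0**2 + (1 - c0)**2 / 2)``, so
the fraction of the circumscribed circle the shape covers is
``c0**2 + (1 - c0)**2 / 2``.

The default roundness is calibrated once so that six 3.68 cm flowers on a
12.5 x 24.5 cm card cover close to a fifth of it, matching the blue:yellow
ratio used in published thrips-trap designs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, box

from .acuity import VisualSystem, resolvable_distance, resolvable_size, _check_positive

__all__ = [
    "PatternElement",
    "TrapCard",
    "flower_fill_fraction",
    "flower_polygon",
    "element_area",
    "percent_cover",
    "choose_element_count",
    "layout_elements",
    "design_trap",
    "render_svg",
    "DEFAULT_PETALS",
    "DEFAULT_ROUNDNESS",
]

logger = logging.getLogger(__name__)

DEFAULT_PETALS = 6
#: Calibrated so the six-flower small-element card reproduces the published
#: ~20% yellow cover; implies the flower fills ~97% of its circumscribed
#: circle (see docs/methods.md for the calibration and its residuals).
DEFAULT_ROUNDNESS = 0.9865

#: Default card colours: sRGB stand-ins for the printed blue and yellow.
BLUE = "#2457C5"
YELLOW = "#FFD500"


def flower_fill_fraction(roundness: float) -> float:
    """Fraction of the circumscribed circle covered by the rosette."""
    c0 = roundness
    return c0**2 + (1.0 - c0) ** 2 / 2.0


@dataclass(frozen=True)
class PatternElement:
    """A geometric flower of maximal linear extent ``size_cm`` centred at
    ``center`` (card coordinates, cm, origin lower-left)."""

    size_cm: float
    center: tuple[float, float] = (0.0, 0.0)
    petals: int = DEFAULT_PETALS
    roundness: float = DEFAULT_ROUNDNESS
    shape: str = "geometric_flower"

    def __post_init__(self) -> None:
        _check_positive("size_cm", self.size_cm)
        if self.petals < 3:
            raise ValueError(f"petals must be >= 3, got {self.petals}")
        if not 0.5 < self.roundness <= 1.0:
            raise ValueError(
                f"roundness must lie in (0.5, 1], got {self.roundness}"
            )
        if self.shape != "geometric_flower":
            raise ValueError(f"unknown shape {self.shape!r}")

    @property
    def fill_fraction(self) -> float:
        """Fraction of the circumscribed circle covered by the shape."""
        return flower_fill_fraction(self.roundness)


@dataclass
class TrapCard:
    """A rectangular sticky card with flower elements on a plain background.

    Coordinates are centimetres with the origin at the card's lower-left
    corner, x to the right, y up.
    """

    width_cm: float
    height_cm: float
    elements: list[PatternElement] = field(default_factory=list)
    background_color: str = BLUE
    pattern_color: str = YELLOW
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_positive("width_cm", self.width_cm)
        _check_positive("height_cm", self.height_cm)


def flower_polygon(el: PatternElement, n_vertices: int = 720) -> Polygon:
    """Discretise the rosette outline into a shapely polygon."""
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    r = (el.size_cm / 2.0) * (
        el.roundness + (1.0 - el.roundness) * np.cos(el.petals * theta)
    )
    cx, cy = el.center
    return Polygon(np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)]))


def element_area(el: PatternElement) -> float:
    """Exact area (cm^2) of the unclipped rosette."""
    return el.fill_fraction * math.pi * (el.size_cm / 2.0) ** 2


def _clipped_area(el: PatternElement, card: TrapCard) -> float:
    cx, cy = el.center
    half = el.size_cm / 2.0
    inside = (
        cx - half >= -1e-9
        and cy - half >= -1e-9
        and cx + half <= card.width_cm + 1e-9
        and cy + half <= card.height_cm + 1e-9
    )
    if inside:
        return element_area(el)
    logger.info(
        "element at (%.2f, %.2f) clipped by the card boundary", cx, cy
    )
    poly = flower_polygon(el, n_vertices=2880)
    return poly.intersection(box(0.0, 0.0, card.width_cm, card.height_cm)).area


def percent_cover(card: TrapCard) -> float:
    """Percentage of the card covered by pattern elements, boundary-clipped.

    Raises if any two elements overlap; published layouts never overlap.
    """
    if not card.elements:
        return 0.0
    polys = [flower_polygon(el) for el in card.elements]
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            if polys[i].intersects(polys[j]) and polys[i].intersection(polys[j]).area > 1e-12:
                raise ValueError(f"elements {i} and {j} overlap")
    total = sum(_clipped_area(el, card) for el in card.elements)
    return 100.0 * total / (card.width_cm * card.height_cm)


def choose_element_count(
    card_dims: tuple[float, float],
    size_cm: float,
    target_percent: float,
    fill_fraction: float = flower_fill_fraction(DEFAULT_ROUNDNESS),
) -> tuple[int, float]:
    """Number of elements whose total area best matches a cover target.

    Rounds half up and floors at one element.  Returns ``(n, achieved
    percent)``.
    """
    w, h = card_dims
    _check_positive("size_cm", size_cm)
    if not 0.0 < target_percent < 100.0:
        raise ValueError(f"target_percent must lie in (0, 100), got {target_percent}")
    if size_cm > min(w, h):
        raise ValueError(
            f"element of size {size_cm} cm cannot fit on a {w} x {h} cm card"
        )
    el_area = fill_fraction * math.pi * (size_cm / 2.0) ** 2
    card_area = w * h
    n = max(1, math.floor(target_percent / 100.0 * card_area / el_area + 0.5))
    achieved = 100.0 * n * el_area / card_area
    return n, achieved


def _grid_positions(lo: float, hi: float, k: int) -> np.ndarray:
    if k == 1:
        return np.asarray([(lo + hi) / 2.0])
    return np.linspace(lo, hi, k)


def layout_elements(
    card_dims: tuple[float, float],
    n: int,
    size_cm: float,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Place ``n`` element centres so every element lies inside the card and
    every pairwise edge-to-edge gap exceeds the element size (each flower
    independently resolvable).

    Deterministic: exact grid factorisations anchored to the card margins
    are tried first; a seeded rejection sampler is the fallback.  Raises
    when no admissible placement is found.
    """
    w, h = card_dims
    _check_positive("size_cm", size_cm)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    half = size_cm / 2.0
    if size_cm > min(w, h):
        raise ValueError(
            f"element of size {size_cm} cm does not fit on a {w} x {h} cm card"
        )
    if n == 1:
        return [(w / 2.0, h / 2.0)]

    min_dist = 2.0 * size_cm  # centre spacing for an edge-to-edge gap > size

    def admissible(centers: list[tuple[float, float]]) -> bool:
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if math.dist(centers[i], centers[j]) <= min_dist:
                    return False
        return True

    # exact factorisations, longest axis first for the larger count
    for rows in range(1, n + 1):
        if n % rows:
            continue
        cols = n // rows
        # rows along the longer card axis
        if h >= w:
            ys = _grid_positions(half, h - half, rows)
            xs = _grid_positions(half, w - half, cols)
        else:
            ys = _grid_positions(half, h - half, cols)
            xs = _grid_positions(half, w - half, rows)
        centers = [(float(x), float(y)) for y in ys for x in xs]
        if len(centers) == n and admissible(centers):
            return centers

    rng = np.random.default_rng(seed)
    for _ in range(200):
        centers: list[tuple[float, float]] = []
        for _ in range(10000):
            c = (
                float(rng.uniform(half, w - half)),
                float(rng.uniform(half, h - half)),
            )
            if all(math.dist(c, o) > min_dist for o in centers):
                centers.append(c)
                if len(centers) == n:
                    return centers
    raise ValueError(
        f"cannot place {n} elements of size {size_cm} cm on a {w} x {h} cm "
        f"card with pairwise edge-to-edge gaps above {size_cm} cm"
    )


def design_trap(
    d_target_cm: float,
    vs: VisualSystem,
    card_dims: tuple[float, float],
    target_percent: float | None = None,
    petals: int = DEFAULT_PETALS,
    roundness: float = DEFAULT_ROUNDNESS,
    seed: int = 0,
) -> TrapCard:
    """Design a card whose flower pattern is resolvable at ``d_target_cm``.

    The element size comes from the acuity relation at the receiver's design
    angle.  With ``target_percent`` set, the element count is chosen to
    match that pattern-cover percentage; otherwise a single centred element
    is used.  The card's ``meta`` records the achieved percentage and the
    predicted resolvable distance.
    """
    w, h = card_dims
    size = resolvable_size(d_target_cm, vs.design_angle)
    if target_percent is None:
        n = 1
    else:
        n, _ = choose_element_count(
            card_dims, size, target_percent, flower_fill_fraction(roundness)
        )
    centers = layout_elements(card_dims, n, size, seed=seed)
    elements = [
        PatternElement(size_cm=size, center=c, petals=petals, roundness=roundness)
        for c in centers
    ]
    card = TrapCard(width_cm=w, height_cm=h, elements=elements)
    card.meta.update(
        {
            "design_distance_cm": d_target_cm,
            "design_angle_deg": vs.design_angle,
            "element_size_cm": size,
            "n_elements": n,
            "achieved_percent": percent_cover(card),
            "predicted_resolvable_distance_cm": resolvable_distance(
                size, vs.design_angle
            ),
        }
    )
    return card


def render_svg(card: TrapCard, n_vertices: int = 720) -> str:
    """Render the card as an SVG document at physical scale.

    One SVG user unit is 1 mm.  Card coordinates (origin lower-left, y up)
    are converted to the SVG top-left / y-down convention.
    """
    w_mm = card.width_cm * 10.0
    h_mm = card.height_cm * 10.0
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w_mm:g}mm" '
        f'height="{h_mm:g}mm" viewBox="0 0 {w_mm:g} {h_mm:g}">',
        f'  <rect x="0" y="0" width="{w_mm:g}" height="{h_mm:g}" '
        f'fill="{card.background_color}"/>',
    ]
    for el in card.elements:
        poly = flower_polygon(el, n_vertices=n_vertices)
        coords = np.asarray(poly.exterior.coords)[:-1] * 10.0  # cm -> mm
        coords[:, 1] = h_mm - coords[:, 1]  # flip to top-left origin
        d = "M " + " L ".join(f"{x:.3f},{y:.3f}" for x, y in coords) + " Z"
        parts.append(f'  <path d="{d}" fill="{card.pattern_color}"/>')
    parts.append("</svg>")
    return "\n".join(parts)
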