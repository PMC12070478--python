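"""Visibility geometry of a trap hung above a horizontal crop canopy.

A trap whose pattern element is resolvable out to a slant distance ``d_max``
and which hangs ``h`` above the canopy is resolvable from canopy positions
within a disc of radius ``sqrt(d_max**2 - h**2)`` directly beneath it (the
visibility cone).  A multi-trap layout is "no-choice" when even the finest
assumed eye cannot resolve a whole neighbouring card at the trap spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Sequence

import pandas as pd

from .acuity import VisualSystem, SizeRange, size_range, _check_positive

__all__ = [
    "TrapPlacement",
    "VisibilityCone",
    "slant_distance",
    "horizontal_visible_range",
    "card_max_dimension",
    "classify_choice_design",
    "visibility_table",
]


@dataclass(frozen=True)
class TrapPlacement:
    """A trap card at a height above the canopy, with the maximum slant
    distance at which its pattern element is resolvable."""

    height_above_canopy_cm: float
    element_resolvable_distance_cm: float
    card: Any | None = None
    element_size_cm: float | None = None

    def __post_init__(self) -> None:
        if self.height_above_canopy_cm < 0:
            raise ValueError(
                f"height_above_canopy_cm must be >= 0, got "
                f"{self.height_above_canopy_cm}"
            )
        _check_positive(
            "element_resolvable_distance_cm", self.element_resolvable_distance_cm
        )


@dataclass(frozen=True)
class VisibilityCone:
    """Where, at canopy level, a hung trap's pattern is resolvable.

    ``resolvable_below`` is False when the pattern is not resolvable even
    from directly beneath the trap; ``horizontal_range_cm`` is the radius of
    the resolvable disc (0 when only directly below, None when nowhere).
    """

    resolvable_below: bool
    horizontal_range_cm: float | None

    def __post_init__(self) -> None:
        if self.resolvable_below:
            if self.horizontal_range_cm is None or self.horizontal_range_cm < 0:
                raise ValueError("resolvable cone requires a range >= 0")
        elif self.horizontal_range_cm is not None:
            raise ValueError("unresolvable placement cannot have a range")


def slant_distance(height_cm: float, horizontal_cm: float) -> float:
    """Euclidean distance from a canopy point to the trap (cm)."""
    if height_cm < 0 or horizontal_cm < 0:
        raise ValueError(
            f"height_cm and horizontal_cm must be >= 0, got "
            f"({height_cm}, {horizontal_cm})"
        )
    return math.hypot(height_cm, horizontal_cm)


def horizontal_visible_range(d_max_cm: float, height_cm: float) -> VisibilityCone:
    """Radius of the canopy-level disc from which the pattern is resolvable.

    The pattern of a trap hung at ``height_cm`` is resolvable out to slant
    distance ``d_max_cm``; solving the right triangle gives the horizontal
    radius.  ``d_max == height`` (resolvable only directly below) counts as
    resolvable with zero range.
    """
    _check_positive("d_max_cm", d_max_cm)
    _check_positive("height_cm", height_cm)
    if d_max_cm < height_cm:
        return VisibilityCone(resolvable_below=False, horizontal_range_cm=None)
    return VisibilityCone(
        resolvable_below=True,
        horizontal_range_cm=math.sqrt(d_max_cm**2 - height_cm**2),
    )


def card_max_dimension(width_cm: float, length_cm: float) -> float:
    """Diagonal of a rectangular card (cm): its maximal linear extent."""
    _check_positive("width_cm", width_cm)
    _check_positive("length_cm", length_cm)
    return math.hypot(width_cm, length_cm)


def classify_choice_design(
    trap_spacing_cm: float,
    card_width_cm: float,
    card_length_cm: float,
    vs: VisualSystem,
) -> tuple[str, SizeRange]:
    """Classify a multi-trap layout as ``"choice"`` or ``"no_choice"``.

    The layout is no-choice when the minimum resolvable size at the trap
    spacing — for the *finest* assumed eye — exceeds the whole card's
    diagonal, so no more than one trap can be resolved at a time.  Returns
    the resolvable-size range at the spacing for reporting.  The boundary
    (minimum resolvable size equal to the diagonal) counts as choice.
    """
    _check_positive("trap_spacing_cm", trap_spacing_cm)
    rng = size_range(trap_spacing_cm, vs)
    diagonal = card_max_dimension(card_width_cm, card_length_cm)
    label = "no_choice" if rng.r_min_cm > diagonal else "choice"
    return label, rng


def visibility_table(placements: Sequence[TrapPlacement]) -> pd.DataFrame:
    """One row per placement: height, element size, whether the pattern is
    resolvable from directly below, and the horizontal visible range."""
    if len(placements) == 0:
        raise ValueError("placements must be a nonempty sequence")
    rows = []
    for p in placements:
        if p.height_above_canopy_cm > 0:
            cone = horizontal_visible_range(
                p.element_resolvable_distance_cm, p.height_above_canopy_cm
            )
        else:  # card at canopy level: the cone degenerates to a disc of d_max
            cone = VisibilityCone(True, p.element_resolvable_distance_cm)
        size = p.element_size_cm
        if size is None and p.card is not None:
            elements = getattr(p.card, "elements", None)
            if elements:
                size = elements[0].size_cm
        rows.append(
            {
                "height_cm": p.height_above_canopy_cm,
                "size_cm": size,
                "resolvable_below": cone.resolvable_below,
                "horizontal_range_cm": cone.horizontal_range_cm
                if cone.resolvable_below
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
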