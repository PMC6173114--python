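"""Raster rendering of grid states.

Pointy-top hexagons in odd-r layout, drawn with Pillow. One component is
rendered at a time, its level picking a colour from a fixed palette (level 0
is white). Output bytes are deterministic for a given state.
"""

from __future__ import annotations

from PIL import Image, ImageDraw

from .epithelium import GridState
from .errors import ValidationError

__all__ = ["render_state", "PALETTE"]

#: colour per level; level 0 is white, levels beyond the palette reuse the last entry
PALETTE = [
    (255, 255, 255),
    (214, 39, 40),   # level 1: red
    (44, 160, 44),   # level 2: green
    (31, 119, 180),  # level 3: blue
    (255, 127, 14),  # level 4: orange
    (148, 103, 189), # level 5: purple
]

_OUTLINE = (120, 120, 120)

# pointy-top hexagon: sqrt(3) ~ horizontal pitch factor
_SQRT3 = 3.0 ** 0.5


def _hex_corners(cx: float, cy: float, size: float):
    # pointy-top: vertices at 30° offsets from vertical
    pts = []
    for i in range(6):
        ang = 3.14159265358979 * (60.0 * i - 30.0) / 180.0
        import math

        pts.append((cx + size * math.cos(ang), cy + size * math.sin(ang)))
    return pts


def render_state(
    state: GridState, component: str, path: str, size: int = 8
) -> None:
    """Render one component of ``state`` as a PNG at ``path``.

    ``size`` is the hexagon circumradius in pixels.
    """
    if component not in state.levels:
        raise ValidationError(f"unknown component {component!r}")
    w, h = state.width, state.height
    img_w = int(_SQRT3 * size * (w + 0.5)) + 2 * size
    img_h = int(1.5 * size * (h - 1)) + 4 * size
    img = Image.new("RGB", (img_w, img_h), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    arr = state.levels[component]
    for row in range(h):
        for col in range(w):
            cx = _SQRT3 * size * (col + 0.5 * (row % 2)) + size
            cy = 1.5 * size * row + 2 * size
            level = int(arr[row, col])
            colour = PALETTE[min(level, len(PALETTE) - 1)] if level >= 0 else PALETTE[0]
            draw.polygon(_hex_corners(cx, cy, size), fill=colour, outline=_OUTLINE)
    img.save(path, format="PNG")
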