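"""Deterministic static rendering of a layout.

Drawing conventions: nodes are horizontal line segments, one per row,
spanning the columns they touch; edges are vertical segments, one per
column, spanning their endpoint rows; both ends of an edge carry a small
endpoint square, and directed edges an arrowhead at the target row.  Node
and edge segments are colored from a repeating 32-color cycle keyed by row
and column respectively, with edges drawn darker than nodes so links float
in front despite the orthogonal crossings.  Optional node-zone shading
alternates pale blue and pale pink backgrounds behind consecutive zones.

Everything is laid on a fixed square grid: row pitch equals column pitch,
so boundary slopes of the rendered fabric are directly readable in degrees.

The palette is generated programmatically (32 evenly spaced hues; light and
dark lightness variants) and is not meant to match any other tool's colors.
"""

from __future__ import annotations

import colorsys
import io
from dataclasses import dataclass, field
from typing import Literal

from .columns import ColumnAssignment
from .model import Link, Network, NodeOrder, ValidationError

__all__ = ["Scene", "SceneOptions", "build_scene", "palette",
           "render_svg", "render_raster"]

PALETTE_SIZE = 32
SHADING_BLUE = "#E6EEF8"
SHADING_PINK = "#FAE6EE"

#: refuse rasters beyond this many pixels (no tile cache: one static image)
MAX_RASTER_PIXELS = 64_000_000


def _hex(rgb: tuple[float, float, float]) -> str:
    return "#%02X%02X%02X" % tuple(round(c * 255) for c in rgb)


def _build_palette() -> list[tuple[str, str]]:
    entries = []
    for i in range(PALETTE_SIZE):
        hue = i / PALETTE_SIZE
        light = colorsys.hls_to_rgb(hue, 0.70, 0.75)
        dark = colorsys.hls_to_rgb(hue, 0.32, 0.85)
        entries.append((_hex(light), _hex(dark)))
    return entries


_PALETTE = _build_palette()


def palette(index: int) -> tuple[str, str]:
    """(light, dark) hex pair for 1-based ``index``; cycle period is 32.

    Node segments use the light variant keyed by row, edge segments the
    dark variant keyed by column; the dark variant always has lower
    luminance.
    """
    if index < 1:
        raise ValidationError("palette index must be >= 1")
    return _PALETTE[(index - 1) % PALETTE_SIZE]


def luminance(hex_color: str) -> float:
    """Rec. 709 relative luminance of a #RRGGBB color, in [0, 1]."""
    r = int(hex_color[1:3], 16) / 255
    g = int(hex_color[3:5], 16) / 255
    b = int(hex_color[5:7], 16) / 255
    return 0.2126 * r + 0.7152 * g + 0.0722 * b


# ---------------------------------------------------------------------------
# Scene model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeSegment:
    row: int
    col_lo: float
    col_hi: float
    color: str


@dataclass(frozen=True)
class EdgeSegment:
    col: int
    row_lo: float
    row_hi: float
    color: str


@dataclass(frozen=True)
class EndpointSquare:
    row: float
    col: float
    color: str


@dataclass(frozen=True)
class Arrowhead:
    row: float
    col: float
    orientation: Literal["up", "down"]
    color: str


@dataclass(frozen=True)
class ZoneRect:
    col_lo: float
    col_hi: float
    color: str


@dataclass(frozen=True)
class LabelText:
    text: str
    row: int
    col: float


@dataclass(frozen=True)
class SceneOptions:
    cell_size: float = 10.0
    shading: bool = False
    labels: bool = True


@dataclass
class Scene:
    """Resolution-independent draw list on the square layout grid."""

    n_rows: int
    n_cols: int
    cell: float
    primitives: list = field(default_factory=list)

    @property
    def width_cells(self) -> float:
        # 1 cell margin each side; lone-node stubs sit in grid column 0
        return self.n_cols + 2

    @property
    def height_cells(self) -> float:
        return self.n_rows + 2


def build_scene(network: Network, order: NodeOrder, columns: ColumnAssignment,
                options: SceneOptions | None = None) -> Scene:
    """Turn a layout into an ordered primitive list (O(n + E) primitives).

    Draw order: zone shading, node segments, edge segments, endpoint
    squares, arrowheads, labels.
    """
    opts = options or SceneOptions()
    scene = Scene(n_rows=len(order.row_of), n_cols=columns.width,
                  cell=opts.cell_size)
    prims = scene.primitives

    if opts.shading:
        parity = 0
        for node in order.by_row():
            zone = columns.zone_of.get(node)
            if zone is None:
                continue
            color = SHADING_BLUE if parity % 2 == 0 else SHADING_PINK
            prims.append(ZoneRect(zone[0] - 0.5, zone[1] + 0.5, color))
            parity += 1

    for node in order.by_row():
        row = order[node]
        light, _dark = palette(row)
        extent = columns.extent_of.get(node)
        if extent is None:
            # lone node: one-cell stub left of column 1
            prims.append(NodeSegment(row, 0.0, 1.0, light))
        else:
            # pad 0.45 cell each side so single-column extents stay visible
            prims.append(NodeSegment(row, extent[0] - 0.45, extent[1] + 0.45,
                                     light))

    for link in columns.by_column():
        col = columns.column_of[link]
        _light, dark = palette(col)
        r_src, r_tgt = order[link.source], order[link.target]
        lo, hi = min(r_src, r_tgt), max(r_src, r_tgt)
        if link.is_self_loop:
            # stub: short vertical tick within the row band, one square
            prims.append(EdgeSegment(col, lo - 0.4, lo + 0.4, dark))
            prims.append(EndpointSquare(lo - 0.4, col, dark))
        else:
            prims.append(EdgeSegment(col, float(lo), float(hi), dark))
            prims.append(EndpointSquare(float(lo), col, dark))
            prims.append(EndpointSquare(float(hi), col, dark))
            if link.directed:
                orient = "down" if r_tgt > r_src else "up"
                prims.append(Arrowhead(float(r_tgt), col, orient, dark))

    if opts.labels:
        for node in order.by_row():
            row = order[node]
            extent = columns.extent_of.get(node)
            anchor = float(extent[1]) + 0.5 if extent else 1.2
            prims.append(LabelText(node, row, anchor))

    return scene


# ---------------------------------------------------------------------------
# SVG
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    s = f"{x:.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


def render_svg(scene: Scene) -> bytes:
    """SVG 1.1 document; byte-deterministic for identical scenes.

    Each scene primitive maps to exactly one SVG element inside the single
    top-level group.
    """
    if scene.n_rows == 0 or scene.cell <= 0:
        raise ValidationError("cannot render an empty scene")
    c = scene.cell
    width = scene.width_cells * c
    height = scene.height_cells * c

    def x(col: float) -> str:
        return _fmt((col + 0.5) * c)

    def y(row: float) -> str:
        return _fmt((row + 0.5) * c)

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>\n',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}" '
        f'style="background-color:#FFFFFF">\n<g>\n',
    ]
    sq = 0.25 * c  # endpoint square half-side = 0.5 cell total
    ah = 0.3 * c   # arrowhead half-width, 0.6 cell total
    for p in scene.primitives:
        if isinstance(p, ZoneRect):
            parts.append(
                f'<rect x="{x(p.col_lo)}" y="{_fmt(0.5 * c)}" '
                f'width="{_fmt((p.col_hi - p.col_lo) * c)}" '
                f'height="{_fmt((scene.height_cells - 1) * c)}" '
                f'fill="{p.color}"/>\n')
        elif isinstance(p, NodeSegment):
            parts.append(
                f'<line x1="{x(p.col_lo)}" y1="{y(p.row)}" '
                f'x2="{x(p.col_hi)}" y2="{y(p.row)}" '
                f'stroke="{p.color}" stroke-width="{_fmt(0.25 * c)}"/>\n')
        elif isinstance(p, EdgeSegment):
            parts.append(
                f'<line x1="{x(p.col)}" y1="{y(p.row_lo)}" '
                f'x2="{x(p.col)}" y2="{y(p.row_hi)}" '
                f'stroke="{p.color}" stroke-width="{_fmt(0.18 * c)}"/>\n')
        elif isinstance(p, EndpointSquare):
            parts.append(
                f'<rect x="{_fmt((p.col + 0.5) * c - sq)}" '
                f'y="{_fmt((p.row + 0.5) * c - sq)}" '
                f'width="{_fmt(2 * sq)}" height="{_fmt(2 * sq)}" '
                f'fill="{p.color}"/>\n')
        elif isinstance(p, Arrowhead):
            cx, cy = (p.col + 0.5) * c, (p.row + 0.5) * c
            tip = cy + ah if p.orientation == "down" else cy - ah
            base = cy - ah if p.orientation == "down" else cy + ah
            parts.append(
                f'<polygon points="{_fmt(cx - ah)},{_fmt(base)} '
                f'{_fmt(cx + ah)},{_fmt(base)} {_fmt(cx)},{_fmt(tip)}" '
                f'fill="{p.color}"/>\n')
        elif isinstance(p, LabelText):
            parts.append(
                f'<text x="{x(p.col)}" y="{_fmt((p.row + 0.5) * c - 0.15 * c)}" '
                f'font-size="{_fmt(0.8 * c)}" font-family="sans-serif" '
                f'text-anchor="start">{_escape(p.text)}</text>\n')
        else:  # pragma: no cover - scene model is closed
            raise ValidationError(f"unknown primitive {p!r}")
    parts.append("</g>\n</svg>\n")
    return "".join(parts).encode("utf-8")


def _escape(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;")
            .replace(">", "&gt;"))


# ---------------------------------------------------------------------------
# Raster
# ---------------------------------------------------------------------------

def render_raster(scene: Scene, dpi: int = 96) -> bytes:
    """PNG raster of the scene, antialiased by 2x supersampling.

    Raises when the output (at 2x) would exceed the pixel budget; giant
    fabrics should be rendered as SVG or in slices.
    """
    from PIL import Image, ImageDraw

    if scene.n_rows == 0 or scene.cell <= 0:
        raise ValidationError("cannot render an empty scene")
    scale = dpi / 96.0
    ss = 2  # supersampling factor
    c = scene.cell * scale * ss
    width = max(1, round(scene.width_cells * c))
    height = max(1, round(scene.height_cells * c))
    if width * height > MAX_RASTER_PIXELS:
        raise ValidationError(
            f"raster of {width}x{height} px exceeds the "
            f"{MAX_RASTER_PIXELS}-pixel budget; render SVG instead or "
            "reduce cell size / dpi")

    img = Image.new("RGB", (width, height), "#FFFFFF")
    draw = ImageDraw.Draw(img)

    def pt(col: float, row: float) -> tuple[float, float]:
        return ((col + 0.5) * c, (row + 0.5) * c)

    sq = 0.25 * c
    ah = 0.3 * c
    for p in scene.primitives:
        if isinstance(p, ZoneRect):
            x0, _ = pt(p.col_lo, 0)
            x1, _ = pt(p.col_hi, 0)
            draw.rectangle([x0, 0.5 * c, x1, height - 0.5 * c], fill=p.color)
        elif isinstance(p, NodeSegment):
            draw.line([pt(p.col_lo, p.row), pt(p.col_hi, p.row)],
                      fill=p.color, width=max(1, round(0.25 * c)))
        elif isinstance(p, EdgeSegment):
            draw.line([pt(p.col, p.row_lo), pt(p.col, p.row_hi)],
                      fill=p.color, width=max(1, round(0.18 * c)))
        elif isinstance(p, EndpointSquare):
            cx, cy = pt(p.col, p.row)
            draw.rectangle([cx - sq, cy - sq, cx + sq, cy + sq], fill=p.color)
        elif isinstance(p, Arrowhead):
            cx, cy = pt(p.col, p.row)
            tip = cy + ah if p.orientation == "down" else cy - ah
            base = cy - ah if p.orientation == "down" else cy + ah
            draw.polygon([(cx - ah, base), (cx + ah, base), (cx, tip)],
                         fill=p.color)
        elif isinstance(p, LabelText):
            cx, cy = pt(p.col, p.row)
            draw.text((cx, cy), p.text, fill="#000000", anchor="lm")

    img = img.resize((max(1, width // ss), max(1, height // ss)),
                     Image.Resampling.LANCZOS)
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()
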