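"""Visual-mapping attributes: node colour/size gradients and edge colours.

Nodes are mapped on a linear blue -> red gradient (#0000FF low, #FF0000
high) and a linear size ramp over the mapped quantity — mass, retention
time, or abundance in a chosen sample (absent abundance maps to 0, i.e.
bluest and smallest, which visually flags undetected features).  Edges are
coloured by transformation type class through a user palette, defaulting to
grey.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError
from .netbuild import MassDiffNetwork

DEFAULT_EDGE_COLOR = "#999999"


@dataclass
class VisualAttrs:
    """Per-node colour/size and per-edge colour assignments.

    Edge keys are (source_id, target_id, label) triples, matching the
    parallel-edge identity used throughout the package.
    """

    node_color: dict[str, str] = field(default_factory=dict)
    node_size: dict[str, float] = field(default_factory=dict)
    edge_color: dict[tuple[str, str, str], str] = field(default_factory=dict)


def _gradient_color(t: float) -> str:
    r = round(255 * t)
    b = round(255 * (1.0 - t))
    return f"#{r:02X}00{b:02X}"


def assign_node_attrs(
    net: MassDiffNetwork,
    by: str = "mass",
    sample: str | None = None,
    min_size: float = 10.0,
    max_size: float = 50.0,
    attrs: VisualAttrs | None = None,
) -> VisualAttrs:
    """Colour and size nodes by mass, rt, or per-sample intensity.

    Values are normalised linearly to [0, 1]; when all values coincide every
    node sits at the gradient midpoint (t = 0.5).
    """
    if by not in ("mass", "rt", "intensity"):
        raise ConfigurationError(f"mapping quantity must be mass, rt or intensity, got {by!r}")
    if by == "intensity" and sample is None:
        raise ConfigurationError("intensity mapping requires a sample label")
    if attrs is None:
        attrs = VisualAttrs()

    def value(p) -> float:
        if by == "mass":
            return p.mass
        if by == "rt":
            return p.rt if p.rt is not None else 0.0
        return p.abundances.get(sample, 0.0)

    vals = {p.peak_id: value(p) for p in net.peaks}
    if not vals:
        return attrs
    vmin, vmax = min(vals.values()), max(vals.values())
    span = vmax - vmin
    for pid, v in vals.items():
        t = 0.5 if span == 0 else (v - vmin) / span
        attrs.node_color[pid] = _gradient_color(t)
        attrs.node_size[pid] = min_size + t * (max_size - min_size)
    return attrs


def assign_edge_colors(
    net: MassDiffNetwork,
    palette: dict[str, str],
    attrs: VisualAttrs | None = None,
) -> VisualAttrs:
    """Colour edges by their transformation type class via ``palette``;
    edges without a class or without a palette entry get the default grey."""
    if attrs is None:
        attrs = VisualAttrs()
    for e in net.edges:
        color = DEFAULT_EDGE_COLOR
        if e.type_class is not None and e.type_class in palette:
            color = palette[e.type_class]
        attrs.edge_color[(e.source_id, e.target_id, e.label)] = color
    return attrs
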