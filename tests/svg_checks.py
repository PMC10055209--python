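"""Helpers for machine-checking rendered SVG output with lxml.

Mark elements live inside ``<g id="layer-*">`` groups: ground/fill/hex
marks are ``<path>`` children; symbol marks are ``<use>`` references (the
glyph path itself sits in a ``<defs>`` block and is not a mark).
"""

from __future__ import annotations

import re
from pathlib import Path

from lxml import etree

SVG_NS = {"s": "http://www.w3.org/2000/svg"}

_NUM = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def parse_svg(path):
    return etree.parse(str(path))


def layer_groups(tree, prefix="layer-"):
    """Mapping gid -> group element, document order preserved by dict."""
    out = {}
    for g in tree.iter("{http://www.w3.org/2000/svg}g"):
        gid = g.get("id")
        if gid and gid.startswith(prefix):
            out[gid] = g
    return out


def mark_elements(group):
    """The mark elements of one layer group (paths, or uses for symbols)."""
    uses = group.findall(".//s:use", SVG_NS)
    if uses:
        return uses
    return group.findall(".//s:path", SVG_NS)


def mark_count(tree, gid):
    groups = layer_groups(tree)
    return len(mark_elements(groups[gid])) if gid in groups else 0


def symbol_mark_count(tree):
    return sum(len(mark_elements(g)) for gid, g in layer_groups(tree).items()
               if gid.startswith("layer-symbol"))


def document_order(tree):
    """Layer gids in SVG document order."""
    return list(layer_groups(tree))


def style_value(element, key):
    """One property from an element's style attribute, e.g. 'fill'."""
    style = element.get("style", "")
    for part in style.split(";"):
        if ":" in part:
            k, v = part.split(":", 1)
            if k.strip() == key:
                return v.strip()
    return None


def path_bbox(element):
    """Bounding box (xmin, ymin, xmax, ymax) of a path's control polygon.

    For matplotlib's bezier circle approximation the control polygon's
    bbox equals the circle's bbox exactly, so widths give diameters in
    device units.
    """
    nums = [float(m) for m in _NUM.findall(element.get("d", ""))]
    xs, ys = nums[0::2], nums[1::2]
    return min(xs), min(ys), max(xs), max(ys)
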