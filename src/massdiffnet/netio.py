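"""Serialisation of networks to Cytoscape-loadable formats.

GraphML carries the full attribute set (node mass/rt/abundances and visual
attributes, edge label/kind/mass errors/colour) and round-trips through any
standard GraphML reader; SIF is the minimal `source  label  target` form;
TSV node/edge tables mirror every attribute for spreadsheet work.  Numbers
are serialised with ``repr`` so values survive a round trip bit-for-bit.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .netbuild import MassDiffNetwork
from .styling import VisualAttrs


def edge_key(source_id: str, label: str, target_id: str) -> str:
    """Stable parallel-edge identifier: ``source|label|target``."""
    return f"{source_id}|{label}|{target_id}"


def to_networkx(net: MassDiffNetwork, attrs: VisualAttrs | None = None) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    for p in net.peaks:
        node_attrs: dict = {"mass": p.mass}
        if p.rt is not None:
            node_attrs["rt"] = p.rt
        for s in net.samples:
            if s in p.abundances:
                node_attrs[s] = p.abundances[s]
        if attrs is not None:
            if p.peak_id in attrs.node_color:
                node_attrs["color"] = attrs.node_color[p.peak_id]
            if p.peak_id in attrs.node_size:
                node_attrs["size"] = attrs.node_size[p.peak_id]
        g.add_node(p.peak_id, **node_attrs)
    for e in net.edges:
        eattrs: dict = {
            "label": e.label,
            "kind": e.kind,
            "observed_delta": e.observed_delta,
            "expected_value": e.expected_value,
            "error_ppm": e.error_ppm,
        }
        if e.rt_delta is not None:
            eattrs["rt_delta"] = e.rt_delta
        if attrs is not None:
            key = (e.source_id, e.target_id, e.label)
            if key in attrs.edge_color:
                eattrs["color"] = attrs.edge_color[key]
        g.add_edge(
            e.source_id,
            e.target_id,
            key=edge_key(e.source_id, e.label, e.target_id),
            **eattrs,
        )
    return g


def write_graphml(
    net: MassDiffNetwork, path: str | Path, attrs: VisualAttrs | None = None
) -> None:
    """Write well-formed GraphML; parallel edges get distinct stable ids."""
    g = to_networkx(net, attrs)
    nx.write_graphml(g, str(path))


def write_sif(net: MassDiffNetwork, path: str | Path) -> None:
    """One line per edge ``source\\tlabel\\ttarget``; orphan nodes as bare ids."""
    used = {e.source_id for e in net.edges} | {e.target_id for e in net.edges}
    with open(path, "w", encoding="utf-8") as fh:
        for e in net.edges:
            fh.write(f"{e.source_id}\t{e.label}\t{e.target_id}\n")
        for p in net.peaks:
            if p.peak_id not in used:
                fh.write(f"{p.peak_id}\n")


def write_edge_table(net: MassDiffNetwork, path: str | Path) -> None:
    rows = []
    for e in net.edges:
        rows.append(
            {
                "source": e.source_id,
                "target": e.target_id,
                "kind": e.kind,
                "label": e.label,
                "observed_delta": repr(e.observed_delta),
                "expected_value": repr(e.expected_value),
                "error_ppm": repr(e.error_ppm),
                "rt_delta": repr(e.rt_delta) if e.rt_delta is not None else "",
                "type_class": e.type_class or "",
            }
        )
    cols = [
        "source",
        "target",
        "kind",
        "label",
        "observed_delta",
        "expected_value",
        "error_ppm",
        "rt_delta",
        "type_class",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_node_table(
    net: MassDiffNetwork, path: str | Path, attrs: VisualAttrs | None = None
) -> None:
    has_rt = any(p.rt is not None for p in net.peaks)
    rows = []
    for p in net.peaks:
        row: dict = {"id": p.peak_id, "mass": repr(p.mass)}
        if has_rt:
            row["rt"] = repr(p.rt) if p.rt is not None else ""
        for s in net.samples:
            row[s] = repr(p.abundances[s]) if s in p.abundances else ""
        if attrs is not None:
            row["color"] = attrs.node_color.get(p.peak_id, "")
            size = attrs.node_size.get(p.peak_id)
            row["size"] = repr(size) if size is not None else ""
        rows.append(row)
    cols = ["id", "mass"] + (["rt"] if has_rt else []) + list(net.samples)
    if attrs is not None:
        cols += ["color", "size"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
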