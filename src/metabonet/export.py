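"""GEXF 1.2 and GraphML export/import for estimated networks.

Both writers store, per edge, the positive ``weight`` (|Rp|, the scale a
layout engine expects), the signed ``rp`` and a ``sign`` flag, so a
round-trip through either format loses nothing.  Node attributes (e.g.
dimension, community, centralities) are written as typed attributes.
The matching readers parse exactly the dialect the writers emit.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

from .errors import MetabonetError
from .graph import SimpleGraph

_GEXF_NS = "http://www.gexf.net/1.2draft"
_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def _attr_type(value) -> str:
    if isinstance(value, bool):
        return "boolean"
    if isinstance(value, int):
        return "long"
    if isinstance(value, float):
        return "double"
    return "string"


def _parse_typed(value: str, typ: str):
    if typ in ("double", "float"):
        return float(value)
    if typ in ("long", "int", "integer"):
        return int(value)
    if typ == "boolean":
        return value == "true"
    return value


def _edge_attr_rows(graph: SimpleGraph):
    for u, v, rp in graph.edge_list():
        yield u, v, {"rp": float(rp), "sign": "+" if rp >= 0 else "-"}


# ---------------------------------------------------------------------------
# GEXF

def write_gexf(graph: SimpleGraph, path, node_attributes: dict | None = None) -> None:
    """Write an undirected GEXF 1.2 file with node/edge attributes."""
    node_attributes = node_attributes or {}
    attr_names = _collect_attr_names(graph, node_attributes)

    root = ET.Element("gexf", {"xmlns": _GEXF_NS, "version": "1.2"})
    g = ET.SubElement(root, "graph", {"defaultedgetype": "undirected", "mode": "static"})

    natts = ET.SubElement(g, "attributes", {"class": "node"})
    for idx, (name, typ) in enumerate(attr_names.items()):
        ET.SubElement(natts, "attribute", {"id": str(idx), "title": name, "type": typ})
    eatts = ET.SubElement(g, "attributes", {"class": "edge"})
    ET.SubElement(eatts, "attribute", {"id": "rp", "title": "rp", "type": "double"})
    ET.SubElement(eatts, "attribute", {"id": "sign", "title": "sign", "type": "string"})

    nodes_el = ET.SubElement(g, "nodes")
    name_to_id = {name: str(i) for i, name in enumerate(attr_names)}
    for u in graph.nodes:
        node_el = ET.SubElement(nodes_el, "node", {"id": str(u), "label": str(u)})
        attrs = node_attributes.get(u, {})
        if attrs:
            values = ET.SubElement(node_el, "attvalues")
            for name, value in attrs.items():
                ET.SubElement(values, "attvalue",
                              {"for": name_to_id[name], "value": _fmt(value)})
    edges_el = ET.SubElement(g, "edges")
    for k, (u, v, attrs) in enumerate(_edge_attr_rows(graph)):
        e = ET.SubElement(edges_el, "edge", {
            "id": str(k), "source": str(u), "target": str(v),
            "weight": _fmt(abs(attrs["rp"])),
        })
        values = ET.SubElement(e, "attvalues")
        ET.SubElement(values, "attvalue", {"for": "rp", "value": _fmt(attrs["rp"])})
        ET.SubElement(values, "attvalue", {"for": "sign", "value": attrs["sign"]})
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def read_gexf(path) -> tuple[SimpleGraph, dict]:
    """Read a GEXF file written by :func:`write_gexf`."""
    root = ET.parse(path).getroot()
    ns = {"g": _GEXF_NS}
    graph_el = root.find("g:graph", ns)
    if graph_el is None:
        raise MetabonetError(f"{path}: not a GEXF graph")
    attr_defs = {}
    for attrs_el in graph_el.findall("g:attributes", ns):
        if attrs_el.get("class") == "node":
            for a in attrs_el.findall("g:attribute", ns):
                attr_defs[a.get("id")] = (a.get("title"), a.get("type"))
    nodes, node_attributes = [], {}
    for node_el in graph_el.find("g:nodes", ns).findall("g:node", ns):
        u = node_el.get("id")
        nodes.append(u)
        attrs = {}
        values = node_el.find("g:attvalues", ns)
        if values is not None:
            for av in values.findall("g:attvalue", ns):
                name, typ = attr_defs[av.get("for")]
                attrs[name] = _parse_typed(av.get("value"), typ)
        node_attributes[u] = attrs
    edges = []
    for e in graph_el.find("g:edges", ns).findall("g:edge", ns):
        rp = None
        values = e.find("g:attvalues", ns)
        if values is not None:
            for av in values.findall("g:attvalue", ns):
                if av.get("for") == "rp":
                    rp = float(av.get("value"))
        weight = rp if rp is not None else float(e.get("weight", "1"))
        edges.append((e.get("source"), e.get("target"), weight))
    return SimpleGraph(nodes, edges), node_attributes


# ---------------------------------------------------------------------------
# GraphML

def write_graphml(graph: SimpleGraph, path, node_attributes: dict | None = None) -> None:
    """Write an undirected GraphML file with node/edge attributes."""
    node_attributes = node_attributes or {}
    attr_names = _collect_attr_names(graph, node_attributes)

    root = ET.Element("graphml", {"xmlns": _GRAPHML_NS})
    key_ids = {}
    for idx, (name, typ) in enumerate(attr_names.items()):
        kid = f"dn{idx}"
        key_ids[name] = kid
        ET.SubElement(root, "key", {"id": kid, "for": "node", "attr.name": name,
                                    "attr.type": typ})
    for kid, name, typ in (("de0", "weight", "double"), ("de1", "rp", "double"),
                           ("de2", "sign", "string")):
        ET.SubElement(root, "key", {"id": kid, "for": "edge", "attr.name": name,
                                    "attr.type": typ})
    g = ET.SubElement(root, "graph", {"id": "G", "edgedefault": "undirected"})
    for u in graph.nodes:
        node_el = ET.SubElement(g, "node", {"id": str(u)})
        for name, value in node_attributes.get(u, {}).items():
            d = ET.SubElement(node_el, "data", {"key": key_ids[name]})
            d.text = _fmt(value)
    for u, v, attrs in _edge_attr_rows(graph):
        e = ET.SubElement(g, "edge", {"source": str(u), "target": str(v)})
        for kid, value in (("de0", _fmt(abs(attrs["rp"]))),
                           ("de1", _fmt(attrs["rp"])), ("de2", attrs["sign"])):
            d = ET.SubElement(e, "data", {"key": kid})
            d.text = value
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def read_graphml(path) -> tuple[SimpleGraph, dict]:
    """Read a GraphML file written by :func:`write_graphml`."""
    root = ET.parse(path).getroot()
    ns = {"g": _GRAPHML_NS}
    keys = {}
    for k in root.findall("g:key", ns):
        keys[k.get("id")] = (k.get("attr.name"), k.get("attr.type"))
    g = root.find("g:graph", ns)
    if g is None:
        raise MetabonetError(f"{path}: not a GraphML graph")
    nodes, node_attributes = [], {}
    for node_el in g.findall("g:node", ns):
        u = node_el.get("id")
        nodes.append(u)
        attrs = {}
        for d in node_el.findall("g:data", ns):
            name, typ = keys[d.get("key")]
            attrs[name] = _parse_typed(d.text or "", typ)
        node_attributes[u] = attrs
    edges = []
    for e in g.findall("g:edge", ns):
        rp, weight = None, 1.0
        for d in e.findall("g:data", ns):
            name, _ = keys[d.get("key")]
            if name == "rp":
                rp = float(d.text)
            elif name == "weight":
                weight = float(d.text)
        edges.append((e.get("source"), e.get("target"), rp if rp is not None else weight))
    return SimpleGraph(nodes, edges), node_attributes


def _collect_attr_names(graph: SimpleGraph, node_attributes: dict) -> dict[str, str]:
    """Stable (insertion-ordered) attribute name -> XML type map."""
    names: dict[str, str] = {}
    for u in graph.nodes:
        for name, value in node_attributes.get(u, {}).items():
            typ = _attr_type(value)
            if names.setdefault(name, typ) != typ:
                # mixed int/float across nodes widens to double
                if {names[name], typ} == {"long", "double"}:
                    names[name] = "double"
                else:
                    names[name] = "string"
    return names


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)
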