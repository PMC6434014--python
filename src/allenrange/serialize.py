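"""Versioned on-disk index format shared by the three tree structures.

An index archive is a JSON document (gzip-compressed when the filename ends
in ``.gz``) holding one serialized tree per chromosome plus the structure
kind.  Trees are flattened to node lists with integer child references, so
loading reconstructs the exact node layout — FC arrays included — and a
loaded index answers every query bit-identically to the freshly built one.
"""

from __future__ import annotations

import gzip
import json
from typing import Any, Union

from .allen_core import GenomicInterval
from .interval_tree import BLACK, ITNode, IntervalTreeIndex
from .range_tree_2d import RT2DNode, YTree
from .rtfc import RTFCNode

__all__ = ["FORMAT_VERSION", "STRUCTURE_KINDS", "save_index", "load_index"]

FORMAT_MAGIC = "allenrange-index"
FORMAT_VERSION = 1
STRUCTURE_KINDS = ("rtfc", "rt2d", "it")


def _iv_to_obj(a: GenomicInterval) -> list:
    return [a.chrom, a.start, a.end, a.index]


def _iv_from_obj(o: list) -> GenomicInterval:
    return GenomicInterval(o[0], o[1], o[2], o[3])


# -- RTFC -----------------------------------------------------------------


def _rtfc_to_obj(root: RTFCNode) -> list[dict]:
    nodes: list[dict] = []
    order: list[RTFCNode] = []
    stack = [root]
    while stack:  # preorder; children referenced by position in `nodes`
        v = stack.pop()
        order.append(v)
        if not v.is_leaf:
            stack.append(v.rchild)
            stack.append(v.lchild)
    pos = {id(v): i for i, v in enumerate(order)}
    for v in order:
        d: dict[str, Any] = {"x": v.x_key, "ys": v.ys, "idx": v.idx}
        if v.is_leaf:
            d["leaf"] = _iv_to_obj(v.interval)
        else:
            d["lfc"] = v.lfc
            d["rfc"] = v.rfc
            d["l"] = pos[id(v.lchild)]
            d["r"] = pos[id(v.rchild)]
        nodes.append(d)
    return nodes


def _rtfc_from_obj(nodes: list[dict]) -> RTFCNode:
    built: list[RTFCNode] = [None] * len(nodes)  # type: ignore[list-item]
    for i in range(len(nodes) - 1, -1, -1):
        d = nodes[i]
        if "leaf" in d:
            built[i] = RTFCNode(
                x_key=d["x"], ys=list(d["ys"]), idx=list(d["idx"]),
                interval=_iv_from_obj(d["leaf"]),
            )
        else:
            built[i] = RTFCNode(
                x_key=d["x"], ys=list(d["ys"]), idx=list(d["idx"]),
                lfc=list(d["lfc"]), rfc=list(d["rfc"]),
                lchild=built[d["l"]], rchild=built[d["r"]],
            )
    return built[0]


# -- 2D-RT ----------------------------------------------------------------


def _rt2d_to_obj(root: RT2DNode) -> list[dict]:
    nodes: list[dict] = []
    order: list[RT2DNode] = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        if not v.is_leaf:
            stack.append(v.rchild)
            stack.append(v.lchild)
    pos = {id(v): i for i, v in enumerate(order)}
    for v in order:
        d: dict[str, Any] = {"x": v.x_key, "ys": v.ytree.ys, "idx": v.ytree.idx}
        if v.is_leaf:
            d["leaf"] = _iv_to_obj(v.interval)
        else:
            d["l"] = pos[id(v.lchild)]
            d["r"] = pos[id(v.rchild)]
        nodes.append(d)
    return nodes


def _rt2d_from_obj(nodes: list[dict]) -> RT2DNode:
    built: list[RT2DNode] = [None] * len(nodes)  # type: ignore[list-item]
    for i in range(len(nodes) - 1, -1, -1):
        d = nodes[i]
        ytree = YTree(list(d["ys"]), list(d["idx"]))
        if "leaf" in d:
            built[i] = RT2DNode(x_key=d["x"], ytree=ytree,
                                interval=_iv_from_obj(d["leaf"]))
        else:
            built[i] = RT2DNode(x_key=d["x"], ytree=ytree,
                                lchild=built[d["l"]], rchild=built[d["r"]])
    return built[0]


# -- IT -------------------------------------------------------------------


def _it_to_obj(tree: IntervalTreeIndex) -> list[dict]:
    nodes: list[dict] = []
    order: list[ITNode] = []
    stack = [tree.root]
    while stack:
        v = stack.pop()
        if v is tree.nil:
            continue
        order.append(v)
        stack.append(v.rchild)
        stack.append(v.lchild)
    pos = {id(v): i for i, v in enumerate(order)}
    pos[id(tree.nil)] = -1
    for v in order:
        nodes.append(
            {
                "iv": _iv_to_obj(v.interval),
                "c": v.color,
                "l": pos[id(v.lchild)],
                "r": pos[id(v.rchild)],
            }
        )
    return nodes


def _it_from_obj(nodes: list[dict]) -> IntervalTreeIndex:
    tree = IntervalTreeIndex()
    if not nodes:
        return tree
    built = [ITNode(_iv_from_obj(d["iv"]), d["c"]) for d in nodes]

    def resolve(i: int) -> ITNode:
        return tree.nil if i < 0 else built[i]

    for v, d in zip(built, nodes):
        v.lchild = resolve(d["l"])
        v.rchild = resolve(d["r"])
        for c in (v.lchild, v.rchild):
            if c is not tree.nil:
                c.parent = v
        v.max_end = v.interval.end  # recomputed below
    # recompute max_end bottom-up (reverse preorder visits children first)
    for v in reversed(built):
        v.max_end = max(v.interval.end, v.lchild.max_end, v.rchild.max_end)
    tree.root = built[0]
    tree.root.parent = tree.nil
    tree.size = len(built)
    return tree


# -- archive --------------------------------------------------------------

_TO_OBJ = {"rtfc": _rtfc_to_obj, "rt2d": _rt2d_to_obj, "it": _it_to_obj}
_FROM_OBJ = {"rtfc": _rtfc_from_obj, "rt2d": _rt2d_from_obj, "it": _it_from_obj}

Tree = Union[RTFCNode, RT2DNode, IntervalTreeIndex]


def save_index(path: str, trees: dict[str, Tree], kind: str) -> None:
    """Write one serialized tree per chromosome into a single JSON archive."""
    if kind not in STRUCTURE_KINDS:
        raise ValueError(f"unknown structure kind {kind!r}")
    doc = {
        "format": FORMAT_MAGIC,
        "version": FORMAT_VERSION,
        "kind": kind,
        "chromosomes": {c: _TO_OBJ[kind](t) for c, t in trees.items()},
    }
    payload = json.dumps(doc, separators=(",", ":"))
    if path.endswith(".gz"):
        with gzip.open(path, "wt", encoding="utf-8") as fh:
            fh.write(payload)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(payload)


def load_index(path: str) -> tuple[dict[str, Tree], str]:
    """Load an index archive; returns (chromosome → tree, structure kind)."""
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt", encoding="utf-8") as fh:  # type: ignore[operator]
        doc = json.load(fh)
    if doc.get("format") != FORMAT_MAGIC:
        raise ValueError(f"{path}: not an allenrange index archive")
    if doc.get("version") != FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported index format version {doc.get('version')!r}"
        )
    kind = doc["kind"]
    if kind not in STRUCTURE_KINDS:
        raise ValueError(f"{path}: unknown structure kind {kind!r}")
    trees = {c: _FROM_OBJ[kind](obj) for c, obj in doc["chromosomes"].items()}
    return trees, kind
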