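"""Support-label parsing, classification and low-support collapse.

Maximum-likelihood trees carry dual support labels per internal branch —
ultrafast bootstrap (UFB) and SH-aLRT (SHT) percentages written as
``ufb/sht`` — while coalescent species trees carry a single local posterior
probability (LPP, a fraction).  Branches are classified as:

* **strong** — UFB >= 95 and SHT >= 95, or LPP >= 0.95;
* **moderate** — UFB >= 95 and SHT >= 80, or LPP >= 0.85;
* **weak** — exactly one of UFB >= 95, SHT >= 80 holds;
* **none** — otherwise.

Branches with extremely low bootstrap support (UFB < 10) can be contracted
into polytomies, the standard preparation of gene trees for quartet-based
species-tree estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

__all__ = [
    "SupportValues",
    "SupportParseError",
    "parse_support",
    "classify_support",
    "collapse_low_support",
    "write_annotated",
    "CLASS_ORDER",
]

CLASS_ORDER = ("none", "weak", "moderate", "strong")


class SupportParseError(ValueError):
    pass


@dataclass
class SupportValues:
    ufb: float | None = None  # percent, 0-100
    sht: float | None = None  # percent, 0-100
    lpp: float | None = None  # fraction, 0-1

    def __post_init__(self) -> None:
        if self.ufb is None and self.sht is None and self.lpp is None:
            raise ValueError("at least one support value required")
        for v, hi, name in ((self.ufb, 100, "ufb"), (self.sht, 100, "sht"), (self.lpp, 1, "lpp")):
            if v is not None and not (0 <= v <= hi):
                raise ValueError(f"{name} value {v} out of range [0, {hi}]")

    def label(self, fmt: str) -> str:
        if fmt == "lpp":
            return f"{self.lpp:g}"
        first, second = fmt.split("-")
        vals = {"ufb": self.ufb, "sht": self.sht}
        return f"{vals[first]:g}/{vals[second]:g}"


def _node_path(node: dendropy.Node) -> str:
    leaves = sorted(l.taxon.label for l in node.leaf_iter() if l.taxon)
    return "{" + ",".join(leaves[:4]) + ("..." if len(leaves) > 4 else "") + "}"


def parse_support(newick: str, label_format: str = "ufb-sht") -> dendropy.Tree:
    """Parse a newick string and attach :class:`SupportValues` to every
    labelled internal node (as ``node.support``).

    *label_format* is ``ufb-sht`` (default IQ-TREE order), ``sht-ufb``, or
    ``lpp`` for single-value posterior labels.
    """
    if label_format not in ("ufb-sht", "sht-ufb", "lpp"):
        raise ValueError(f"unknown label format {label_format!r}")
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True
    )
    for node in tree.preorder_node_iter():
        node.support = None
        if node.is_leaf() or node.parent_node is None:
            continue
        if node.label is None or node.label == "":
            continue
        parts = node.label.split("/")
        try:
            if label_format == "lpp":
                if len(parts) != 1:
                    raise ValueError("expected a single LPP value")
                node.support = SupportValues(lpp=float(parts[0]))
            else:
                if len(parts) != 2:
                    raise ValueError(f"expected two '/'-separated values, got {len(parts)}")
                a, b = (float(x) for x in parts)
                if label_format == "ufb-sht":
                    node.support = SupportValues(ufb=a, sht=b)
                else:
                    node.support = SupportValues(ufb=b, sht=a)
        except ValueError as exc:
            raise SupportParseError(
                f"malformed support label {node.label!r} at node {_node_path(node)}: {exc}"
            ) from exc
    return tree


def classify_support(s: SupportValues) -> str:
    ufb_hi = s.ufb is not None and s.ufb >= 95
    sht_hi = s.sht is not None and s.sht >= 80
    sht_vhi = s.sht is not None and s.sht >= 95
    if (ufb_hi and sht_vhi) or (s.lpp is not None and s.lpp >= 0.95):
        return "strong"
    if (ufb_hi and sht_hi) or (s.lpp is not None and s.lpp >= 0.85):
        return "moderate"
    if ufb_hi != sht_hi and (ufb_hi or sht_hi):
        return "weak"
    return "none"


def three_class(cls: str) -> str:
    """Figure-style mapping: moderate folds into weak."""
    return "weak" if cls == "moderate" else cls


def collapse_low_support(
    tree: dendropy.Tree, threshold: float = 10.0, assume_supported: bool = False
) -> dendropy.Tree:
    """Contract internal edges with UFB below *threshold* into polytomies.

    Leaf edges and the root are never touched.  Unannotated internal edges
    raise unless *assume_supported* is set (they are then kept).
    """
    to_collapse = []
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        support = getattr(node, "support", None)
        if support is None or support.ufb is None:
            if assume_supported:
                continue
            raise ValueError(
                f"internal edge at {_node_path(node)} has no UFB annotation"
            )
        if support.ufb < threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return tree


def write_annotated(tree: dendropy.Tree, label_format: str = "ufb-sht") -> str:
    """Serialise to newick, regenerating support labels from annotations."""
    for node in tree.preorder_node_iter():
        support = getattr(node, "support", None)
        if support is not None and not node.is_leaf() and node.parent_node is not None:
            node.label = support.label(label_format)
    return tree.as_string(schema="newick", suppress_rooting=True).strip()
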