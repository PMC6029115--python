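"""Dated, rooted, fixed-topology trees and fossil-style node calibrations.

The central object is :class:`Timetree`: a rooted binary tree whose nodes
carry absolute ages in Ma (tips at 0), so that branch durations are simply
``age(parent) - age(child)``.  :func:`build_simulation_tree` constructs the
12-taxon mammal-like tree used throughout the simulation experiments: a
"placental" ingroup with crown origin at 80 Ma, two superordinal nodes at
66 Ma, four calibrated 33-Ma clades (tagged I-IV), and marsupial-like and
monotreme-like outgroup pairs, with the root at 200 Ma.

Trees round-trip through newick with branch lengths in Ma; calibrations are
written as ``[&B(min,max,tail)]`` node comments (an MCMCtree-style soft-bound
dialect, documented in :func:`write_newick`).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "Calibration",
    "Timetree",
    "SimulationTreeConfig",
    "build_simulation_tree",
    "parse_newick",
    "write_newick",
    "NewickParseError",
]


class NewickParseError(ValueError):
    """Raised when newick text cannot be parsed; names the offending position."""


@dataclass(frozen=True)
class Calibration:
    """Soft-bound age calibration on a named node.

    ``tail`` is the prior probability mass allowed on each side beyond the
    bounds (2.5% per side by default, i.e. 95% of the prior mass lies inside
    ``[min_age, max_age]``).  Ages are in Ma.
    """

    tag: str
    min_age: float
    max_age: float
    tail: float = 0.025

    def __post_init__(self) -> None:
        if not (0 < self.min_age < self.max_age):
            raise ValueError(
                f"calibration on {self.tag!r}: need 0 < min < max, "
                f"got ({self.min_age}, {self.max_age})"
            )
        if not (0 < self.tail < 0.5):
            raise ValueError(f"calibration on {self.tag!r}: tail mass must be in (0, 0.5)")

    @classmethod
    def symmetric(cls, tag: str, true_age: float, halfwidth: float, tail: float = 0.025) -> "Calibration":
        """Bounds equidistant from ``true_age`` by ``halfwidth`` Ma."""
        return cls(tag, true_age - halfwidth, true_age + halfwidth, tail)


class Timetree:
    """Rooted, dated, binary tree stored in flat arrays.

    Parameters
    ----------
    parent
        ``parent[i]`` is the index of node ``i``'s parent, ``-1`` for the root.
    ages
        Node ages in Ma; every tip must be 0 and every child strictly younger
        than its parent.
    labels
        One entry per node: tip name for tips, tag (or ``None``) for internal
        nodes.  Non-``None`` labels must be unique.
    calibrations
        Optional mapping tag -> :class:`Calibration` attached to tagged nodes.
    """

    def __init__(
        self,
        parent: np.ndarray,
        ages: np.ndarray,
        labels: list[str | None],
        calibrations: dict[str, Calibration] | None = None,
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.ages = np.asarray(ages, dtype=float)
        self.labels = list(labels)
        self.calibrations: dict[str, Calibration] = dict(calibrations or {})
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        n = len(self.parent)
        if not (len(self.ages) == n == len(self.labels)):
            raise ValueError("parent, ages and labels must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.n_nodes = n
        kids: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(i)
        self.children = [tuple(k) for k in kids]
        self.is_tip = np.array([len(k) == 0 for k in kids])
        if any(len(k) not in (0, 2) for k in kids):
            raise ValueError("tree must be strictly binary")
        self.n_tips = int(self.is_tip.sum())
        if np.any(self.ages[self.is_tip] != 0.0):
            raise ValueError("all tips must have age 0")
        for i, p in enumerate(self.parent):
            if p >= 0 and not self.ages[p] > self.ages[i]:
                raise ValueError(
                    f"node {self.labels[i] or i} (age {self.ages[i]}) must be "
                    f"strictly younger than its parent (age {self.ages[p]})"
                )
        named = [l for l in self.labels if l is not None]
        if len(named) != len(set(named)):
            raise ValueError("node labels/tags must be unique")
        self._tag_index = {l: i for i, l in enumerate(self.labels) if l is not None}
        for tag in self.calibrations:
            if tag not in self._tag_index:
                raise KeyError(f"calibration attached to unknown node tag {tag!r}")
        # postorder: children before parents
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        self.preorder = np.array(order)
        self.postorder = self.preorder[::-1].copy()

    # -- queries --------------------------------------------------------------

    def node(self, tag: str) -> int:
        """Index of the node carrying ``tag`` (tip name or internal tag)."""
        try:
            return self._tag_index[tag]
        except KeyError:
            raise KeyError(f"no node tagged {tag!r}") from None

    @property
    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def tip_names(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def branch_durations(self) -> np.ndarray:
        """Duration in Ma of the branch above each node (0 at the root)."""
        d = np.zeros(self.n_nodes)
        nz = self.parent >= 0
        d[nz] = self.ages[self.parent[nz]] - self.ages[nz]
        return d

    @property
    def branch_ids(self) -> np.ndarray:
        """Branches are identified by their child node; root excluded."""
        return np.flatnonzero(self.parent >= 0)

    def with_calibrations(self, calibrations: dict[str, Calibration]) -> "Timetree":
        return Timetree(self.parent.copy(), self.ages.copy(), list(self.labels), calibrations)

    def copy(self) -> "Timetree":
        return self.with_calibrations(dict(self.calibrations))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Timetree: {self.n_tips} tips, root age {self.ages[self.root]:g} Ma>"


# ---------------------------------------------------------------------------
# The simulation tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationTreeConfig:
    """Node ages (Ma) of the fixed 12-taxon simulation tree.

    The in-text ages are the placental crown (80), the two superorders (66),
    the four calibrated clades (33) and the root (200); the remaining interior
    ages are read off the published figure and kept configurable.
    """

    crown_age: float = 80.0
    superorder_age: float = 66.0
    clade_age: float = 33.0
    root_age: float = 200.0
    theria_age: float = 160.0
    marsupial_crown_age: float = 60.0
    monotreme_crown_age: float = 50.0
    low_rate_tags: tuple[str, ...] = ("I", "III")

    def __post_init__(self) -> None:
        ok = (
            0 < self.clade_age < self.superorder_age < self.crown_age
            < self.theria_age < self.root_age
            and 0 < self.marsupial_crown_age < self.theria_age
            and 0 < self.monotreme_crown_age < self.root_age
        )
        if not ok:
            raise ValueError("simulation tree ages violate the required ordering")


def build_simulation_tree(config: SimulationTreeConfig | None = None) -> Timetree:
    """Deterministically build the 12-taxon tree of the dating experiments.

    Topology (ages in Ma under the default config)::

        root 200 ─┬─ monotremes 50 ── mono1, mono2
                  └─ theria 160 ─┬─ marsupials 60 ── mar1, mar2
                                 └─ crown 80 ─┬─ V 66 ─┬─ I 33 ── A1, A2
                                              │        └─ II 33 ── B1, B2
                                              └─ VI 66 ─┬─ III 33 ── C1, C2
                                                        └─ IV 33 ── D1, D2

    Nodes I and III are the clades whose daughter branches are decelerated in
    the "mixed rates" scheme (configurable via ``low_rate_tags``).
    """
    c = config or SimulationTreeConfig()
    # (label, age, parent-tag) specification; parents listed before children
    spec = [
        ("root", c.root_age, None),
        ("monotremes", c.monotreme_crown_age, "root"),
        ("theria", c.theria_age, "root"),
        ("marsupials", c.marsupial_crown_age, "theria"),
        ("crown", c.crown_age, "theria"),
        ("V", c.superorder_age, "crown"),
        ("VI", c.superorder_age, "crown"),
        ("I", c.clade_age, "V"),
        ("II", c.clade_age, "V"),
        ("III", c.clade_age, "VI"),
        ("IV", c.clade_age, "VI"),
        ("mono1", 0.0, "monotremes"),
        ("mono2", 0.0, "monotremes"),
        ("mar1", 0.0, "marsupials"),
        ("mar2", 0.0, "marsupials"),
        ("A1", 0.0, "I"),
        ("A2", 0.0, "I"),
        ("B1", 0.0, "II"),
        ("B2", 0.0, "II"),
        ("C1", 0.0, "III"),
        ("C2", 0.0, "III"),
        ("D1", 0.0, "IV"),
        ("D2", 0.0, "IV"),
    ]
    idx = {label: i for i, (label, _, _) in enumerate(spec)}
    parent = np.array([-1 if p is None else idx[p] for _, _, p in spec])
    ages = np.array([a for _, a, _ in spec])
    labels = [label for label, _, _ in spec]
    return Timetree(parent, ages, labels)


# ---------------------------------------------------------------------------
# Newick IO
# ---------------------------------------------------------------------------


def write_newick(tree: Timetree, with_calibrations: bool = True) -> str:
    """Serialize to newick with branch lengths in Ma.

    Calibrations are emitted as node comments in the form
    ``[&B(min,max,tail)]`` placed between the node label and the branch
    length, e.g. ``(A1:33,A2:33)I[&B(29.7,36.3,0.025)]:33``; this mirrors
    MCMCtree's ``B(min,max)`` soft-bound notation.  ``parse_newick`` recovers
    them exactly.
    """
    cal_by_node = {}
    if with_calibrations:
        cal_by_node = {tree.node(c.tag): c for c in tree.calibrations.values()}
    dur = tree.branch_durations

    def fmt(x: float) -> str:
        return repr(float(x))

    def render(v: int) -> str:
        if tree.is_tip[v]:
            s = tree.labels[v]
        else:
            s = "(" + ",".join(render(k) for k in tree.children[v]) + ")"
            s += tree.labels[v] or ""
        if v in cal_by_node:
            c = cal_by_node[v]
            s += f"[&B({fmt(c.min_age)},{fmt(c.max_age)},{fmt(c.tail)})]"
        if v != tree.root:
            s += ":" + fmt(dur[v])
        return s

    return render(tree.root) + ";"


def _parse_calibration_comment(comment: str, tag: str) -> Calibration | None:
    body = comment.strip().lstrip("&")
    if not body.startswith("B(") or not body.endswith(")"):
        return None
    parts = body[2:-1].split(",")
    if len(parts) not in (2, 3):
        raise NewickParseError(f"malformed calibration comment [{comment}] on node {tag!r}")
    lo, hi = float(parts[0]), float(parts[1])
    tail = float(parts[2]) if len(parts) == 3 else 0.025
    return Calibration(tag, lo, hi, tail)


def parse_newick(text: str) -> Timetree:
    """Parse a newick string with branch lengths in Ma into a :class:`Timetree`.

    The tree must be rooted, binary and ultrametric (all tips equidistant from
    the root, within 1e-6 Ma); ``[&B(min,max[,tail])]`` comments become
    :class:`Calibration` objects attached to the commented node, which must be
    labelled.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )
    except Exception as e:  # dendropy raises several parse error types
        line = getattr(e, "line_num", None)
        col = getattr(e, "col_num", None)
        where = f" at line {line}, column {col}" if line is not None else ""
        raise NewickParseError(f"malformed newick{where}: {e}") from e

    dnodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    n = len(dnodes)
    parent = np.full(n, -1, dtype=np.int64)
    depth = np.zeros(n)
    labels: list[str | None] = [None] * n
    comments: list[list[str]] = [[] for _ in range(n)]
    for i, nd in enumerate(dnodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise NewickParseError("every non-root branch needs a length in Ma")
            depth[i] = depth[parent[i]] + nd.edge.length
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
        comments[i] = list(nd.comments)

    height = depth.max()
    is_tip = np.array([nd.is_leaf() for nd in dnodes])
    if np.any(np.abs(depth[is_tip] - height) > 1e-6):
        raise NewickParseError("tree is not ultrametric: tips are not equidistant from the root")
    ages = height - depth
    ages[is_tip] = 0.0

    calibrations: dict[str, Calibration] = {}
    for i, clist in enumerate(comments):
        for cmt in clist:
            tag = labels[i]
            if tag is None:
                raise NewickParseError("calibration comment on an unlabelled node")
            cal = _parse_calibration_comment(cmt, tag)
            if cal is not None:
                calibrations[tag] = cal
    return Timetree(parent, ages, labels, calibrations)
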