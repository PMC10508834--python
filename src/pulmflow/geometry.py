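"""Vascular geometry: the proximal artery/vein network and structured-tree beds.

The proximal domain is a fixed network of 15 large pulmonary arteries and 12
large pulmonary veins (two venous generations).  Terminal proximal arteries are
paired one-to-one with terminal proximal veins; each pair is closed by a
two-sided *structured tree* of distal vessels: a self-similar binary tree in
which the two daughters of a vessel of radius r have radii alpha*r (major) and
beta*r (minor), 0 < beta < alpha < 1.  A vessel indexed by the number of major
(i) and minor (j) steps from the tree root has

    r_ij = alpha**i * beta**j * r_root,      L_ij = r_ij * lrr

with lrr the side-specific length-to-radius ratio.  The arterial tree
terminates where it meets the venous tree: a node is terminal as soon as its
minor daughter would fall below the minimum radius ``r_min``, and at every
terminal node the arterial vessel joins the mirrored venous vessel.  The
venous tree mirrors the arterial (i, j) index set with radii rescaled by the
ratio of venous to arterial root radius.

Because any two nodes with equal (i, j) head identical subtrees, all
tree-level computations are memoized over the distinct (i, j) set rather than
the exponentially many physical branches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "Vessel",
    "ProximalNetwork",
    "StructuredTreeSpec",
    "TreeNode",
    "NetworkStructureError",
    "build_proximal_network",
    "load_reference_network",
    "generate_tree",
    "count_unique_subtrees",
    "total_branch_count",
]


class NetworkStructureError(ValueError):
    """Raised when a vessel table does not describe a valid network."""


@dataclass
class Vessel:
    name: str
    length: float  # cm
    radius: float  # cm, reference radius r0
    kind: str  # "artery" | "vein"
    daughters: list[str] = field(default_factory=list)
    paired_terminal: str | None = None
    parent: str | None = None

    @property
    def reference_area(self) -> float:
        """A0 = pi r0^2 (cm^2)."""
        return math.pi * self.radius**2

    @property
    def is_terminal(self) -> bool:
        return self.paired_terminal is not None


@dataclass
class ProximalNetwork:
    vessels: dict[str, Vessel]
    root_artery: str
    vein_roots: list[str]
    beds: list[tuple[str, str]]  # (terminal artery, terminal vein)

    @property
    def arteries(self) -> list[str]:
        return [n for n, v in self.vessels.items() if v.kind == "artery"]

    @property
    def veins(self) -> list[str]:
        return [n for n, v in self.vessels.items() if v.kind == "vein"]

    def __getitem__(self, name: str) -> Vessel:
        return self.vessels[name]


def build_proximal_network(table: pd.DataFrame) -> ProximalNetwork:
    """Build the proximal network from a vessel table.

    Expected columns: ``name, kind, length_cm, radius_cm, parent, daughters``
    with daughters ';'-separated.  For terminal rows the daughters column
    names the paired vessel on the other side of the microvascular bed
    (an artery's entry names a vein and vice versa).
    """
    names = list(table["name"])
    if len(set(names)) != len(names):
        dupes = {n for n in names if names.count(n) > 1}
        raise NetworkStructureError(f"duplicate vessel names: {sorted(dupes)}")

    vessels: dict[str, Vessel] = {}
    for row in table.itertuples(index=False):
        length = float(row.length_cm)
        radius = float(row.radius_cm)
        if length <= 0 or radius <= 0:
            raise NetworkStructureError(f"nonpositive geometry for {row.name}")
        parent = None if pd.isna(row.parent) or row.parent == "" else str(row.parent)
        vessels[row.name] = Vessel(
            name=row.name, length=length, radius=radius, kind=str(row.kind),
            parent=parent,
        )

    for row in table.itertuples(index=False):
        v = vessels[row.name]
        entries = [] if pd.isna(row.daughters) or row.daughters == "" else [
            d.strip() for d in str(row.daughters).split(";")
        ]
        for d in entries:
            if d not in vessels:
                raise NetworkStructureError(
                    f"{row.name} references unknown vessel {d!r}"
                )
        kinds = {vessels[d].kind for d in entries}
        if entries and kinds == {v.kind}:
            v.daughters = entries
        elif len(entries) == 1 and kinds != {v.kind}:
            v.paired_terminal = entries[0]
        elif entries:
            raise NetworkStructureError(
                f"{row.name}: daughters mix same- and cross-side vessels"
            )

    roots_a = [n for n, v in vessels.items() if v.kind == "artery" and v.parent is None]
    if len(roots_a) != 1:
        raise NetworkStructureError(f"expected one root artery, found {roots_a}")
    vein_roots = sorted(
        n for n, v in vessels.items() if v.kind == "vein" and v.parent is None
    )

    beds = sorted(
        (n, v.paired_terminal)
        for n, v in vessels.items()
        if v.kind == "artery" and v.paired_terminal is not None
    )
    for art, vein in beds:
        if vessels[vein].paired_terminal != art:
            raise NetworkStructureError(
                f"asymmetric bed pairing: {art} -> {vein} -> "
                f"{vessels[vein].paired_terminal}"
            )

    net = ProximalNetwork(
        vessels=vessels, root_artery=roots_a[0], vein_roots=vein_roots, beds=beds
    )
    _check_acyclic(net)
    for n, v in vessels.items():
        if v.daughters and len(v.daughters) > 2:
            raise NetworkStructureError(f"junction at {n} has >2 daughters")
    return net


def _check_acyclic(net: ProximalNetwork) -> None:
    for root in [net.root_artery, *net.vein_roots]:
        seen: set[str] = set()
        stack = [root]
        while stack:
            n = stack.pop()
            if n in seen:
                raise NetworkStructureError(f"cycle detected at {n}")
            seen.add(n)
            stack.extend(net.vessels[n].daughters)


def load_reference_network() -> ProximalNetwork:
    """Load the packaged 15-artery / 12-vein pulmonary network table."""
    with resources.files("pulmflow.data").joinpath("proximal_network.csv").open() as f:
        table = pd.read_csv(f)
    return build_proximal_network(table)


# ---------------------------------------------------------------------------
# Structured trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeNode:
    i: int
    j: int
    radius: float          # arterial-side radius, cm
    terminal: bool


@dataclass
class StructuredTreeSpec:
    root_radius_artery: float
    root_radius_vein: float
    alpha: float
    beta: float
    lrr_artery: float
    lrr_vein: float
    r_min: float
    nodes: dict[tuple[int, int], TreeNode]

    @property
    def vein_scale(self) -> float:
        """Radius rescaling from arterial to mirrored venous tree."""
        return self.root_radius_vein / self.root_radius_artery

    def radius(self, i: int, j: int, side: str = "artery") -> float:
        r = self.alpha**i * self.beta**j * self.root_radius_artery
        return r if side == "artery" else r * self.vein_scale

    def length(self, i: int, j: int, side: str = "artery") -> float:
        lrr = self.lrr_artery if side == "artery" else self.lrr_vein
        return self.radius(i, j, side) * lrr

    def alpha_path(self) -> list[tuple[int, int]]:
        """(i, 0) nodes along the major-daughter-only pathway."""
        path = [(0, 0)]
        while not self.nodes[path[-1]].terminal:
            path.append((path[-1][0] + 1, path[-1][1]))
        return path

    def beta_path(self) -> list[tuple[int, int]]:
        """(0, j) nodes along the minor-daughter-only pathway."""
        path = [(0, 0)]
        while not self.nodes[path[-1]].terminal:
            path.append((path[-1][0], path[-1][1] + 1))
        return path

    def to_records(self) -> pd.DataFrame:
        rows = [
            {
                "i": n.i, "j": n.j, "radius_cm": n.radius,
                "length_artery_cm": n.radius * self.lrr_artery,
                "radius_vein_cm": n.radius * self.vein_scale,
                "length_vein_cm": n.radius * self.vein_scale * self.lrr_vein,
                "terminal": n.terminal,
            }
            for n in self.nodes.values()
        ]
        return pd.DataFrame(rows).sort_values(["i", "j"]).reset_index(drop=True)


def generate_tree(
    root_radius: float,
    alpha: float,
    beta: float,
    lrr_artery: float,
    lrr_vein: float,
    r_min: float,
    root_radius_vein: float | None = None,
) -> StructuredTreeSpec:
    """Generate the distinct-(i, j) node set of a two-sided structured tree.

    A node is terminal as soon as its minor (beta) daughter would fall below
    ``r_min``; at terminal nodes the arterial tree crosses over into the
    mirrored venous tree.  If ``r_min >= root_radius`` the tree degenerates to
    a single terminal root vessel.
    """
    if root_radius <= 0:
        raise ValueError("root radius must be positive")
    if r_min <= 0:
        raise ValueError("r_min must be positive")
    if not (0 < beta < alpha < 1):
        raise ValueError(f"need 0 < beta < alpha < 1, got alpha={alpha}, beta={beta}")

    nodes: dict[tuple[int, int], TreeNode] = {}
    stack = [(0, 0)]
    while stack:
        i, j = stack.pop()
        if (i, j) in nodes:
            continue
        r = alpha**i * beta**j * root_radius
        terminal = beta * r < r_min
        nodes[(i, j)] = TreeNode(i=i, j=j, radius=r, terminal=terminal)
        if not terminal:
            stack.append((i + 1, j))
            stack.append((i, j + 1))

    return StructuredTreeSpec(
        root_radius_artery=root_radius,
        root_radius_vein=root_radius if root_radius_vein is None else root_radius_vein,
        alpha=alpha,
        beta=beta,
        lrr_artery=lrr_artery,
        lrr_vein=lrr_vein,
        r_min=r_min,
        nodes=nodes,
    )


def count_unique_subtrees(spec: StructuredTreeSpec) -> int:
    """Number of distinct (i, j) index pairs: the memoized-recursion work bound."""
    return len(spec.nodes)


def total_branch_count(spec: StructuredTreeSpec) -> int:
    """Number of physical branches per side of the full binary tree.

    A node (i, j) is reached by every root path through non-terminal ancestors,
    so its multiplicity follows the lattice recursion
    m(i, j) = m(i-1, j)*[ (i-1, j) non-terminal ] + m(i, j-1)*[ ... ].
    """
    mult: dict[tuple[int, int], int] = {}
    for (i, j) in sorted(spec.nodes, key=lambda ij: (ij[0] + ij[1], ij[0])):
        if (i, j) == (0, 0):
            mult[(i, j)] = 1
            continue
        m = 0
        for pi, pj in [(i - 1, j), (i, j - 1)]:
            parent = spec.nodes.get((pi, pj))
            if parent is not None and not parent.terminal:
                m += mult[(pi, pj)]
        mult[(i, j)] = m
    return sum(mult.values())
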