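"""Perfect-phylogeny reconstruction from binary haploid SNP matrices.

The male-specific region of the Y chromosome does not recombine, so its
genealogy is a single rooted tree and, under the infinite-sites model, every
biallelic SNP marks exactly one branch (the set of carriers of the derived
allele is a clade).  This module provides the shared containers
(:class:`GenotypeMatrix`, :class:`CladeTree`) and the tree operations:

* four-gamete compatibility testing,
* polarisation of ref/alt calls into ancestral/derived states,
* perfect-phylogeny construction from the compatible sites,
* small-parsimony (Sankoff) placement of the incompatible remainder, with
  classification into unique / recurrent / triallelic / unassigned-direction
  variants,
* midpoint rooting on mutation-count branch lengths,
* newick round-tripping (branch length = mutation count, internal labels =
  node ids).

Coordinates are 1-based genomic positions throughout this module; branch
lengths are integer mutation counts unless a tree carries explicit node times
(simulated genealogies, in years).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "Node",
    "CladeTree",
    "SiteClassification",
    "four_gamete_compatible",
    "polarize",
    "build_perfect_phylogeny",
    "map_incompatible_sites",
    "midpoint_root",
    "collapse_zero_mutation_branches",
    "to_newick",
    "from_newick",
]

MISSING = -1  # sentinel for a missing haploid call


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Binary (ancestral/derived/missing) haploid calls, samples x sites.

    ``calls[i, j]`` holds the state of sample ``samples[i]`` at 1-based
    position ``positions[j]``: 0 ancestral, 1 (or 2 for the second allele of a
    triallelic site) derived, -1 missing.
    """

    samples: list[str]
    positions: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.positions)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.positions)} sites"
            )
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if len(self.positions) and self.positions[0] < 1:
            raise ValueError("positions are 1-based and must be >= 1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def site_index(self, position: int) -> int:
        idx = int(np.searchsorted(self.positions, position))
        if idx >= self.n_sites or self.positions[idx] != position:
            raise KeyError(f"position {position} not in matrix")
        return idx

    def column(self, position: int) -> np.ndarray:
        return self.calls[:, self.site_index(position)]

    def carriers(self, position: int, allele: int = 1) -> frozenset[str]:
        """Samples carrying the given derived allele at ``position``."""
        col = self.column(position)
        return frozenset(s for s, c in zip(self.samples, col) if c == allele)

    def subset_sites(self, positions: Sequence[int]) -> "GenotypeMatrix":
        idx = [self.site_index(p) for p in sorted(positions)]
        return GenotypeMatrix(
            list(self.samples), self.positions[idx], self.calls[:, idx]
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# Tree container
# ---------------------------------------------------------------------------


class Node:
    """A node of a :class:`CladeTree`.

    The branch *above* the node carries either an explicit mutation list
    (``mutations``, 1-based site positions) or a bare integer length parsed
    from newick.  ``time_years`` is set on simulated genealogies only.
    """

    __slots__ = ("id", "parent", "children", "name", "mutations", "_length", "time_years")

    def __init__(
        self,
        name: str | None = None,
        mutations: Iterable[int] | None = None,
        length: float | None = None,
        time_years: float | None = None,
    ) -> None:
        self.id: int | None = None
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.name = name
        self.mutations: list[int] | None = (
            sorted(mutations) if mutations is not None else None
        )
        self._length = length
        self.time_years = time_years

    @property
    def length(self) -> float:
        """Branch length above this node (mutation count when mapped)."""
        if self.mutations is not None:
            return len(self.mutations)
        return self._length if self._length is not None else 0

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = self.name if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.id} {kind} l={self.length}>"


class CladeTree:
    """Rooted tree whose branches carry mutation lists and tips sample ids.

    Node ids are assigned deterministically in pre-order, with children at
    every node ordered by their smallest descendant sample id, so two
    structurally identical trees always receive identical ids.
    """

    def __init__(self, root: Node, renumber: bool = True) -> None:
        self.root = root
        if renumber:
            self.renumber()

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    def tip(self, name: str) -> Node:
        for node in self.preorder():
            if node.is_tip and node.name == name:
                return node
        raise KeyError(f"no tip named {name!r}")

    def node(self, node_id: int) -> Node:
        for node in self.preorder():
            if node.id == node_id:
                return node
        raise KeyError(f"no node with id {node_id}")

    # -- bookkeeping -------------------------------------------------------

    def renumber(self) -> None:
        """Sort children by smallest descendant sample id; assign pre-order ids."""
        min_tip: dict[int, str] = {}
        for node in self.postorder():
            if node.is_tip:
                min_tip[id(node)] = node.name or ""
            else:
                node.children.sort(key=lambda c: min_tip[id(c)])
                min_tip[id(node)] = min_tip[id(node.children[0])]
        for i, node in enumerate(self.preorder()):
            node.id = i

    def tip_counts(self) -> dict[int, int]:
        """node id -> number of descendant tips (a tip counts itself)."""
        counts: dict[int, int] = {}
        for node in self.postorder():
            counts[node.id] = 1 if node.is_tip else sum(
                counts[c.id] for c in node.children
            )
        return counts

    def clades(self) -> dict[int, frozenset[str]]:
        """node id -> set of descendant tip names."""
        out: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_tip:
                out[node.id] = frozenset([node.name])
            else:
                out[node.id] = frozenset().union(*(out[c.id] for c in node.children))
        return out

    def branch_assignment(self) -> dict[int, int]:
        """site position -> id of the node below the carrying branch."""
        out: dict[int, int] = {}
        for node in self.preorder():
            for pos in node.mutations or ():
                out[pos] = node.id
        return out

    def same_shape(self, other: "CladeTree") -> bool:
        """Structural equality: topology, tip names, ids and branch lengths."""

        def eq(a: Node, b: Node) -> bool:
            if a.name != b.name or a.id != b.id or a.length != b.length:
                return False
            if len(a.children) != len(b.children):
                return False
            return all(eq(x, y) for x, y in zip(a.children, b.children))

        return eq(self.root, other.root)

    def copy(self) -> "CladeTree":
        def rec(node: Node) -> Node:
            clone = Node(
                name=node.name,
                mutations=node.mutations,
                length=node._length,
                time_years=node.time_years,
            )
            clone.id = node.id
            for child in node.children:
                clone.add(rec(child))
            return clone

        return CladeTree(rec(self.root), renumber=False)


# ---------------------------------------------------------------------------
# Compatibility and polarisation
# ---------------------------------------------------------------------------


def four_gamete_compatible(site_a: np.ndarray, site_b: np.ndarray) -> bool:
    """Four-gamete test for two binary sites over the same sample vector.

    Returns False iff all four gametes (00, 01, 10, 11) are observed among
    samples non-missing at both sites; two such sites cannot lie on a single
    mutation each of the same tree.
    """
    a = np.asarray(site_a)
    b = np.asarray(site_b)
    if a.shape != b.shape:
        raise ValueError("site vectors must cover the same samples")
    keep = (a != MISSING) & (b != MISSING)
    gametes = {(int(x), int(y)) for x, y in zip(a[keep], b[keep])}
    return not {(0, 0), (0, 1), (1, 0), (1, 1)} <= gametes


def polarize(
    matrix: GenotypeMatrix, outgroup: str | None = None
) -> tuple[GenotypeMatrix, bool, list[int]]:
    """Recode a ref/alt matrix so state 0 is the ancestral allele.

    With an outgroup sample the ancestral state at each site is the
    outgroup's allele (majority state where the outgroup is missing) and the
    polarity is considered anchored, mirroring the use of basal A00/A0-T
    lineages to orient the Y tree.  Without an outgroup the majority state is
    taken as ancestral (ties resolved to the reference state 0) and the
    polarity of root-adjacent mutations remains formally unassignable.

    Returns ``(matrix, anchored, dropped)`` where ``dropped`` lists positions
    that became invariant (derived in every non-missing sample) and were
    removed.
    """
    calls = matrix.calls.copy()
    og_idx = matrix.samples.index(outgroup) if outgroup is not None else None
    keep: list[int] = []
    for j in range(matrix.n_sites):
        col = calls[:, j]
        observed = col[col != MISSING]
        if observed.size == 0:
            continue
        if og_idx is not None and col[og_idx] != MISSING:
            anc = int(col[og_idx])
        else:
            ones = int(np.sum(observed == 1))
            zeros = int(np.sum(observed == 0))
            anc = 1 if ones > zeros else 0
        if anc == 1:
            orig = col.copy()
            col[orig == 1] = 0
            col[orig == 0] = 1
        observed = col[col != MISSING]
        if np.all(observed == 1):  # invariant after polarisation: uninformative
            continue
        keep.append(j)
    dropped = [int(p) for p in np.delete(matrix.positions, keep)]
    out = GenotypeMatrix(
        list(matrix.samples), matrix.positions[keep], calls[:, keep]
    )
    return out, outgroup is not None, dropped


# ---------------------------------------------------------------------------
# Perfect phylogeny
# ---------------------------------------------------------------------------


def build_perfect_phylogeny(
    matrix: GenotypeMatrix,
) -> tuple[CladeTree, list[int]]:
    """Build the perfect phylogeny of the pairwise-compatible sites.

    Sites are grouped by their derived-carrier set (missing calls counted as
    ancestral, the conservative reading of a no-call), considered in order of
    decreasing carrier count (ties by position), and accepted while the
    family of carrier sets stays laminar (every pair nested or disjoint).
    Accepted sites map to exactly one branch each, identical carrier sets
    share a branch, and the remaining sites are returned for small-parsimony
    placement by :func:`map_incompatible_sites`.

    Raises ``ValueError`` if a site has no derived calls or no site can be
    accepted.
    """
    if matrix.n_sites == 0:
        raise ValueError("no compatible sites: matrix is empty")
    full = frozenset(matrix.samples)
    sets: dict[frozenset[str], list[int]] = {}
    for j, pos in enumerate(matrix.positions):
        col = matrix.calls[:, j]
        carriers = frozenset(
            s for s, c in zip(matrix.samples, col) if c == 1
        )
        if not carriers:
            raise ValueError(f"site {int(pos)} has zero derived calls")
        sets.setdefault(carriers, []).append(int(pos))

    ordered = sorted(sets, key=lambda s: (-len(s), min(sets[s])))
    accepted: list[frozenset[str]] = []
    deferred: list[int] = []
    for s in ordered:
        if s == full or all(s <= t or t <= s or not (s & t) for t in accepted):
            accepted.append(s)
        else:
            deferred.extend(sets[s])
    if not any(s != full for s in accepted) and matrix.n_sites:
        if deferred:
            raise ValueError("no compatible sites among input")

    root = Node(mutations=sets.get(full, []))
    node_for: dict[frozenset[str], Node] = {full: root}
    for s in sorted(accepted, key=lambda s: (-len(s), sorted(s))):
        if s == full:
            continue
        parent_set = min(
            (t for t in node_for if s < t), key=len
        )
        node = Node(
            name=next(iter(s)) if len(s) == 1 else None,
            mutations=sets[s],
        )
        node_for[parent_set].add(node)
        node_for[s] = node
    for sample in matrix.samples:
        single = frozenset([sample])
        if single in node_for:
            continue
        parent_set = min((t for t in node_for if sample in t), key=len)
        node_for[parent_set].add(Node(name=sample, mutations=[]))

    tree = CladeTree(root)
    return tree, sorted(deferred)


# ---------------------------------------------------------------------------
# Small parsimony placement of incompatible sites
# ---------------------------------------------------------------------------


@dataclass
class SiteClassification:
    """Per-site verdicts: unique / recurrent / triallelic / unassigned_direction."""

    verdicts: dict[int, str] = field(default_factory=dict)
    changes: dict[int, int] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in self.verdicts.values():
            out[v] = out.get(v, 0) + 1
        return out


_INF = 10**9


def _sankoff(
    tree: CladeTree,
    tip_state: Mapping[str, int | None],
    root_state: int | None = 0,
) -> tuple[int, list[int]]:
    """Exact unit-cost small parsimony of a binary character on a fixed tree.

    Handles multifurcations and missing tips (state ``None``).  Returns the
    minimal number of state changes and the ids of the nodes whose branch
    carries a change, under the deterministic resolution that prefers the
    parent's state on ties, then state 0.
    """
    cost: dict[int, list[int]] = {}
    for node in tree.postorder():
        if node.is_tip:
            s = tip_state.get(node.name)
            cost[node.id] = [0, 0] if s is None else [
                0 if s == 0 else _INF,
                0 if s == 1 else _INF,
            ]
        else:
            c0 = c1 = 0
            for child in node.children:
                cc = cost[child.id]
                c0 += min(cc[0], cc[1] + 1)
                c1 += min(cc[0] + 1, cc[1])
            cost[node.id] = [c0, c1]

    root_cost = cost[tree.root.id]
    if root_state is None:
        root_state = 0 if root_cost[0] <= root_cost[1] else 1
    changes = root_cost[root_state]
    if changes >= _INF:
        raise ValueError("tip states inconsistent with forced root state")

    assigned: dict[int, int] = {tree.root.id: root_state}
    changed: list[int] = []
    for node in tree.preorder():
        if node is tree.root:
            continue
        ps = assigned[node.parent.id]
        cc = cost[node.id]
        best = min(cc[0] + (ps != 0), cc[1] + (ps != 1))
        # tie-break: keep the parent's state, then state 0
        for s in (ps, 0, 1):
            if cc[s] + (ps != s) == best:
                assigned[node.id] = s
                break
        if assigned[node.id] != ps:
            changed.append(node.id)
    return changes, changed


def map_incompatible_sites(
    tree: CladeTree,
    matrix: GenotypeMatrix,
    polarity_anchored: bool = True,
) -> SiteClassification:
    """Place sites rejected by the perfect phylogeny onto the fixed topology.

    Each biallelic site is placed by exact small parsimony (minimal state
    changes): one change classifies it as ``unique``, two or more as
    ``recurrent``.  Sites with two derived alleles are ``triallelic`` and
    each allele is placed independently.  A single-change site whose mutation
    falls on a branch adjacent to a two-child root is ``unassigned_direction``
    when the polarity was not anchored by an outgroup (the event could belong
    to either side of the root).  Branch mutation lists are augmented in
    place with every inferred change.
    """
    result = SiteClassification()
    name_index = {s: i for i, s in enumerate(matrix.samples)}
    root_children = {c.id for c in tree.root.children}
    binary_root = len(tree.root.children) == 2

    def place(col: np.ndarray, allele: int) -> tuple[int, list[int]]:
        tip_state = {
            s: (None if col[name_index[s]] == MISSING else int(col[name_index[s]] == allele))
            for s in matrix.samples
        }
        return _sankoff(tree, tip_state, root_state=0)

    nodes_by_id = {n.id: n for n in tree.preorder()}
    for j, pos in enumerate(matrix.positions):
        pos = int(pos)
        col = matrix.calls[:, j]
        alleles = sorted({int(c) for c in col if c > 0})
        if not alleles:
            raise ValueError(f"site {pos} has zero derived calls")
        if len(alleles) > 1:
            result.verdicts[pos] = "triallelic"
            total = 0
            for allele in alleles:
                changes, changed = place(col, allele)
                total += changes
                for nid in changed:
                    node = nodes_by_id[nid]
                    node.mutations = sorted((node.mutations or []) + [pos])
            result.changes[pos] = total
            continue
        changes, changed = place(col, alleles[0])
        result.changes[pos] = changes
        if changes >= 2:
            result.verdicts[pos] = "recurrent"
        elif (
            not polarity_anchored
            and binary_root
            and changed
            and changed[0] in root_children
        ):
            result.verdicts[pos] = "unassigned_direction"
        else:
            result.verdicts[pos] = "unique"
        for nid in changed:
            node = nodes_by_id[nid]
            node.mutations = sorted((node.mutations or []) + [pos])
    return result


# ---------------------------------------------------------------------------
# Rooting and branch collapsing
# ---------------------------------------------------------------------------


def _tip_distances(tree: CladeTree, start: Node) -> dict[int, float]:
    """Path length (sum of branch lengths) from ``start`` to every node."""
    dist: dict[int, float] = {start.id: 0.0}
    stack = [start]
    while stack:
        node = stack.pop()
        d = dist[node.id]
        neigh: list[tuple[Node, float]] = [(c, c.length) for c in node.children]
        if node.parent is not None:
            neigh.append((node.parent, node.length))
        for other, w in neigh:
            if other.id not in dist:
                dist[other.id] = d + w
                stack.append(other)
    return dist


def _path(u: Node, v: Node) -> list[Node]:
    anc_u = []
    x = u
    while x is not None:
        anc_u.append(x)
        x = x.parent
    anc_set = {id(a) for a in anc_u}
    down = []
    x = v
    while id(x) not in anc_set:
        down.append(x)
        x = x.parent
    lca = x
    up = anc_u[: anc_u.index(lca) + 1]
    return up + list(reversed(down))


def _reroot_at_node(tree: CladeTree, new_root: Node) -> CladeTree:
    if new_root is tree.root:
        return tree
    chain: list[Node] = []
    x = new_root
    while x is not None:
        chain.append(x)
        x = x.parent
    # reverse every edge along the chain: the branch above chain[i] becomes
    # the branch above chain[i+1] in the new orientation
    for i in range(len(chain) - 1):
        child, parent = chain[i], chain[i + 1]
        parent.children.remove(child)
    prev = new_root
    prev_muts, prev_len = new_root.mutations, new_root._length
    new_root.parent = None
    new_root.mutations, new_root._length = None, None
    for nxt in chain[1:]:
        muts, ln = nxt.mutations, nxt._length
        prev.add(nxt)
        nxt.mutations, nxt._length = prev_muts, prev_len
        prev_muts, prev_len = muts, ln
        prev = nxt
    old_root = chain[-1]
    if len(old_root.children) == 1:  # old binary root becomes a unary node
        only = old_root.children[0]
        if only.mutations is not None or old_root.mutations is not None:
            only.mutations = sorted(
                (only.mutations or []) + (old_root.mutations or [])
            )
        else:
            only._length = (only._length or 0) + (old_root._length or 0)
        old_root.parent.children.remove(old_root)
        old_root.parent.add(only)
    for node in (tree.root, new_root):
        node.time_years = None
    return CladeTree(new_root)


def _reroot_on_edge(tree: CladeTree, child: Node, k_child: int) -> CladeTree:
    """Place the root on the branch above ``child``, keeping ``k_child``
    mutations (smallest positions first) on the child's side."""
    parent = child.parent
    has_muts = child.mutations is not None
    muts = sorted(child.mutations or [])
    ln = child._length
    parent.children.remove(child)
    child.parent = None
    rest = _reroot_at_node(CladeTree(tree.root, renumber=False), parent)
    new_root = Node()
    if has_muts:
        child.mutations = muts[:k_child]
        rest.root.mutations = muts[k_child:]
        rest.root._length = None
    else:
        child.mutations = None
        child._length = k_child
        rest.root._length = (ln or 0) - k_child
    top = rest.root
    if len(top.children) == 1:  # old binary root left unary after detaching child
        only = top.children[0]
        if only.mutations is not None or top.mutations is not None:
            only.mutations = sorted((only.mutations or []) + (top.mutations or []))
        else:
            only._length = (only._length or 0) + (top._length or 0)
        only.parent = None
        top = only
    new_root.add(child)
    new_root.add(top)
    return CladeTree(new_root)


def midpoint_root(tree: CladeTree) -> CladeTree:
    """Re-root at the midpoint of the longest tip-to-tip mutation path.

    Mirrors the default rooting used when the polarity of the deepest
    branches cannot be fixed.  Ties between equally long paths are broken by
    the lexicographically smallest pair of endpoint names; if the midpoint
    falls inside a branch, the branch's mutations are split by genomic
    position, the smaller positions staying on the nearer-endpoint side.

    Raises ``ValueError`` when every branch has length zero.
    """
    tips = tree.tips()
    if len(tips) < 2:
        raise ValueError("midpoint rooting needs at least two tips")
    best: tuple[float, tuple[str, str], Node, Node] | None = None
    for u in tips:
        dist = _tip_distances(tree, u)
        for v in tips:
            if v is u:
                continue
            d = dist[v.id]
            names = tuple(sorted((u.name or "", v.name or "")))
            key = (-d, names)
            if best is None or key < (-best[0], best[1]):
                a, b = (u, v) if (u.name or "") <= (v.name or "") else (v, u)
                best = (d, names, a, b)
    diameter, _, u, v = best
    if diameter == 0:
        raise ValueError("all branch lengths are zero; midpoint undefined")

    half = diameter / 2.0
    path = _path(u, v)
    cum = 0.0
    for i in range(len(path) - 1):
        a, b = path[i], path[i + 1]
        edge_child = a if a.parent is b else b  # the lower end of this edge
        step = edge_child.length
        if abs(cum + step - half) < 1e-9:
            # midpoint coincides with the far node of this edge
            if b is tree.root:
                return tree
            return _reroot_at_node(tree, b)
        if cum + step > half:
            # midpoint falls inside this edge; measure from the child end
            if edge_child is b:  # walking parent -> child, child end at cum+step
                offset_from_child = (cum + step) - half
            else:  # walking child -> parent, child end at cum
                offset_from_child = half - cum
            k_child = int(np.floor(offset_from_child + 1e-9))
            return _reroot_on_edge(tree, edge_child, k_child)
        cum += step
    return tree


def collapse_zero_mutation_branches(tree: CladeTree) -> CladeTree:
    """Contract internal branches carrying no mutations into multifurcations.

    The coalescent produces strictly binary genealogies; branches on which no
    mutation fell are unobservable in the SNP matrix, so collapsing them
    yields the topology a perfect phylogeny can actually recover (and the
    multifurcations the real tree displays, e.g. the main E-M2 one).
    """
    tree = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(tree.preorder()):
            if node.is_tip or node.parent is None:
                continue
            if node.length == 0:
                parent = node.parent
                parent.children.remove(node)
                for child in node.children:
                    parent.add(child)
                changed = True
    return CladeTree(tree.root)


# ---------------------------------------------------------------------------
# Newick i/o
# ---------------------------------------------------------------------------


def to_newick(tree: CladeTree, lengths: str = "mutations") -> str:
    """Serialise to newick: internal labels are node ids, branch lengths are
    mutation counts (``lengths='mutations'``) or node times in years
    (``lengths='years'``, for simulated genealogies)."""
    if tree.root is None or not tree.tips():
        raise ValueError("cannot serialise an empty tree")

    def branch_length(node: Node) -> float:
        if lengths == "years":
            return (node.parent.time_years or 0.0) - (node.time_years or 0.0)
        return node.length

    def fmt(x: float) -> str:
        return f"{int(x)}" if float(x).is_integer() else f"{x:.6f}"

    def rec(node: Node) -> str:
        if node.is_tip:
            core = node.name or f"n{node.id}"
        else:
            core = "(" + ",".join(rec(c) for c in node.children) + ")" + str(node.id)
        if node.parent is None:
            return core
        return f"{core}:{fmt(branch_length(node))}"

    return rec(tree.root) + ";"


def from_newick(text: str) -> CladeTree:
    """Parse a newick string produced by :func:`to_newick`.

    Internal labels become node ids, branch lengths become bare lengths
    (mutation positions are not recoverable from newick; use the
    branch-assignment table for those).  Malformed input raises
    ``ValueError`` with the parser's position information.
    """
    import dendropy

    if not text or not text.strip() or text.strip() == ";":
        raise ValueError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy reports the offending position
        raise ValueError(f"malformed newick: {exc}") from exc

    def rec(dnode) -> Node:
        if not dnode.child_nodes():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            node = Node(name=name, length=dnode.edge.length or 0)
        else:
            node = Node(length=dnode.edge.length or 0)
            if dnode.label is not None:
                try:
                    node.id = int(dnode.label)
                except ValueError:
                    pass
            for child in dnode.child_nodes():
                node.add(rec(child))
        return node

    root = rec(dtree.seed_node)
    tree = CladeTree(root, renumber=False)
    if any(n.id is None for n in tree.preorder()):
        tree.renumber()
    return tree
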