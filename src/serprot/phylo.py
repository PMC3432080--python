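"""Distance phylogenetics: progressive MSA, NJ, bootstrap, group extraction.

The workflow mirrors the classical characterization pipeline for protease
gene families: align the deduced proteins, compute pairwise distances under
pairwise deletion, build a Saitou-Nei neighbor-joining tree, attach bootstrap
supports by column resampling, and read off groups as the maximal clades
whose support clears a threshold (sequences under no such clade stay
"ungrouped").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._align import align_profiles, global_align

GAP = "-"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Msa:
    """Aligned protein block: equal-length gapped rows keyed by unique ids."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in MSA")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows differ in length")

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(ntaxa x ncol) byte matrix and the non-gap mask."""
        x = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8).reshape(len(self.rows), self.ncol)
        return x, x != ord(GAP)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class TreeNode:
    """Node of a (generally unrooted, trifurcating-root) phylogeny."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._newick() for c in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6g}"


def bipartitions(root: TreeNode) -> dict[frozenset[str], TreeNode]:
    """Canonical leaf-set bipartition keys for every internal edge.

    Each internal non-root node defines the split (its leaves | the rest); the
    key is the side *not* containing the alphabetically first leaf, so that a
    split has one representation regardless of rooting.
    """
    all_leaves = root.leaf_names()
    anchor = min(all_leaves)
    out: dict[frozenset[str], TreeNode] = {}
    for node in root.walk():
        if node is root or node.is_leaf:
            continue
        side = node.leaf_names()
        if len(side) < 2 or len(side) > len(all_leaves) - 2:
            continue  # trivial split
        key = frozenset(all_leaves - side) if anchor in side else side
        out[key] = node
    return out


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def pairwise_distance(m: Msa, model: str = "p_distance") -> DistanceMatrix:
    """Pairwise-deletion p-distance (or its Poisson correction -ln(1-p))."""
    if m.ncol < 1:
        raise ValueError("empty alignment")
    x, nongap = m.to_arrays()
    n = len(m.ids)
    d = np.zeros((n, n))
    for i in range(n):
        shared = nongap[i] & nongap[i + 1 :]
        nshared = shared.sum(axis=1)
        if np.any(nshared == 0):
            j = int(np.argmax(nshared == 0)) + i + 1
            raise ValueError(f"no shared non-gap columns between {m.ids[i]} and {m.ids[j]}")
        mism = ((x[i] != x[i + 1 :]) & shared).sum(axis=1)
        d[i, i + 1 :] = mism / nshared
    d = d + d.T
    if model == "poisson":
        # p -> 1 is outside the model's range; cap just below to stay finite
        d = -np.log1p(-np.minimum(d, 1.0 - 1e-12))
        np.fill_diagonal(d, 0.0)
    elif model != "p_distance":
        raise ValueError(f"unknown distance model {model!r}")
    return DistanceMatrix(list(m.ids), d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # negative branch length: clamp to 0, transfer the deficit to the sister
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei NJ; ties in the Q-criterion break to the smallest (i, j)."""
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=i) for i in dm.ids]
    d = dm.d.copy()
    active = list(range(n))
    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        iu = np.triu_indices(k, 1)
        flat = q[iu]
        best = int(np.argmin(flat))  # argmin returns the first = smallest (i, j)
        i_loc, j_loc = iu[0][best], iu[1][best]
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = dij / 2.0 + (r[i_loc] - r[j_loc]) / (2.0 * (k - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode(children=[replace_length(nodes[i], li), replace_length(nodes[j], lj)])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for m_loc, m_idx in enumerate(active):
            if m_idx in (i, j):
                continue
            new_row[m_idx] = max((d[i, m_idx] + d[j, m_idx] - dij) / 2.0, 0.0)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    a, b, c = active
    va = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    vb = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    vc = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    root = TreeNode(
        children=[
            replace_length(nodes[a], max(va, 0.0)),
            replace_length(nodes[b], max(vb, 0.0)),
            replace_length(nodes[c], max(vc, 0.0)),
        ]
    )
    return root


def replace_length(node: TreeNode, length: float) -> TreeNode:
    node.length = float(length)
    return node


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------


def progressive_msa(
    seqs: dict[str, str] | list[tuple[str, str]],
    *,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Msa:
    """Progressive alignment: NJ guide tree on pairwise NW p-distances, then
    profile-profile merges in guide-tree order.  Deterministic."""
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    ids = [i for i, _ in items]
    if len(items) < 2:
        raise ValueError("progressive MSA needs at least 2 sequences")
    if len(items) == 2:
        am = global_align(items[0][1], items[1][1], gap_open=gap_open, gap_extend=gap_extend)
        r0, r1 = [], []
        for q, r in am.pairs:
            r0.append(items[0][1][q] if q is not None else GAP)
            r1.append(items[1][1][r] if r is not None else GAP)
        return Msa(ids, ["".join(r0), "".join(r1)])

    n = len(items)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            am = global_align(items[i][1], items[j][1], gap_open=gap_open, gap_extend=gap_extend)
            shared = sum(1 for q, r in am.pairs if q is not None and r is not None)
            mism = sum(
                1 for q, r in am.pairs if q is not None and r is not None and items[i][1][q] != items[j][1][r]
            )
            d[i, j] = d[j, i] = mism / shared if shared else 1.0
    guide = neighbor_joining(DistanceMatrix(ids, d))
    seq_of = dict(items)

    def merge(node: TreeNode) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.name], [seq_of[node.name]]
        child_blocks = [merge(c) for c in node.children]
        ids_acc, rows_acc = child_blocks[0]
        for cid, crows in child_blocks[1:]:
            a, b, _ = align_profiles(rows_acc, crows, gap_open=gap_open, gap_extend=gap_extend)
            ids_acc, rows_acc = ids_acc + cid, a + b
        return ids_acc, rows_acc

    out_ids, out_rows = merge(guide)
    order = {name: k for k, name in enumerate(ids)}
    pairs = sorted(zip(out_ids, out_rows), key=lambda t: order[t[0]])
    return Msa([i for i, _ in pairs], [r for _, r in pairs])


# ---------------------------------------------------------------------------
# bootstrap and groups
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhyloConfig:
    distance_model: str = "p_distance"
    bootstrap_replicates: int = 5000
    support_threshold: float = 75.0
    seed: int = 0

    def __post_init__(self):
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap replicate count must be >= 1")
        if not 0 <= self.support_threshold <= 100:
            raise ValueError("support threshold must be a percentage")


def bootstrap_support(m: Msa, cfg: PhyloConfig) -> TreeNode:
    """NJ tree from the full alignment with bootstrap supports on its edges.

    Columns are resampled with replacement ``bootstrap_replicates`` times
    (replicate-indexed substreams of the seed); the support of an internal
    edge is the percentage of replicate trees containing the same bipartition.
    """
    if m.ncol < 2:
        raise ValueError("bootstrap needs at least 2 columns")
    tree = neighbor_joining(pairwise_distance(m, cfg.distance_model))
    splits = bipartitions(tree)
    counts = {key: 0 for key in splits}
    x, _ = m.to_arrays()
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.bootstrap_replicates)
    for ss in streams:
        rng = np.random.default_rng(ss)
        cols = rng.integers(0, m.ncol, m.ncol)
        rep = Msa(list(m.ids), [row.tobytes().decode() for row in x[:, cols]])
        rep_dm = pairwise_distance(rep, cfg.distance_model)
        assert np.allclose(rep_dm.d, rep_dm.d.T) and not np.any(np.diag(rep_dm.d))
        rep_tree = neighbor_joining(rep_dm)
        rep_splits = bipartitions(rep_tree)
        for key in counts:
            if key in rep_splits:
                counts[key] += 1
    for key, node in splits.items():
        node.support = 100.0 * counts[key] / cfg.bootstrap_replicates
    return tree


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Reroot at the midpoint of the longest leaf-to-leaf path.

    NJ trees are unrooted; the trifurcation produced by the final join is an
    artifact of join order, so clade extraction uses the midpoint rooting (the
    usual display convention).  Bipartition supports are preserved: they are
    properties of edges, which rerooting does not change.
    """
    # adjacency view of the unrooted tree
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str | None] = {}

    def build_adj(node: TreeNode):
        names[id(node)] = node.name
        adj.setdefault(id(node), [])
        for c in node.children:
            adj.setdefault(id(c), [])
            adj[id(node)].append((id(c), c.length))
            adj[id(c)].append((id(node), c.length))
            build_adj(c)

    build_adj(tree)
    leaves = [id(l) for l in tree.leaves()]

    def farthest_from(start: int) -> tuple[int, dict[int, float], dict[int, int]]:
        dist = {start: 0.0}
        prev: dict[int, int] = {}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    prev[v] = u
                    stack.append(v)
        end = max(leaves, key=lambda l: dist[l])
        return end, dist, prev

    u, _, _ = farthest_from(leaves[0])
    v, dist, prev = farthest_from(u)
    if u == v or dist[v] == 0:
        return tree  # zero diameter: nothing to reroot on
    half = dist[v] / 2.0
    # walk back from v toward u to find the edge containing the midpoint
    path = [v]
    while path[-1] != u:
        path.append(prev[path[-1]])
    path.reverse()  # u ... v
    acc = 0.0
    for a, b in zip(path, path[1:]):
        w = next(w for nb, w in adj[a] if nb == b)
        if acc + w >= half:
            t = half - acc  # distance from a toward b
            break
        acc += w
    else:  # pragma: no cover - float slack: root on the last edge
        t = w

    def subtree(node_id: int, parent_id: int, length: float) -> TreeNode:
        children = [subtree(nb, node_id, wl) for nb, wl in adj[node_id] if nb != parent_id]
        return TreeNode(name=names[node_id], length=length, children=children)

    old_supports = {key: node.support for key, node in bipartitions(tree).items()}
    root = TreeNode(children=[subtree(a, b, t), subtree(b, a, w - t)])
    all_leaves = root.leaf_names()
    anchor_leaf = min(all_leaves)
    for node in root.walk():
        if node is root or node.is_leaf:
            continue
        side = node.leaf_names()
        if len(side) < 2 or len(side) > len(all_leaves) - 2:
            continue
        key = frozenset(all_leaves - side) if anchor_leaf in side else side
        node.support = old_supports.get(key)
    return root


def extract_groups(tree: TreeNode, threshold: float = 75.0) -> dict[str, str]:
    """Leaf -> group assignment: maximal clades with support >= threshold.

    Groups are named G1, G2, ... in tree order; leaves under no supported
    clade are assigned "ungrouped".
    """
    supports = [n.support for n in tree.walk() if n is not tree and not n.is_leaf]
    if supports and all(s is None for s in supports):
        raise ValueError("tree carries no bootstrap supports; run bootstrap_support first")
    assignment = {leaf.name: "ungrouped" for leaf in tree.leaves()}
    counter = 0

    def visit(node: TreeNode):
        nonlocal counter
        if node is not tree and not node.is_leaf and node.support is not None and node.support >= threshold:
            counter += 1
            for leaf in node.leaves():
                assignment[leaf.name] = f"G{counter}"
            return
        for c in node.children:
            visit(c)

    visit(tree)
    return assignment
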