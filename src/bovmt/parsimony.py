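"""Maximum-parsimony haplotype trees over small sets of variant profiles.

Complete-genome haplotypes in this system differ by a handful of mutations,
so trees are built exactly: all unrooted topologies are enumerated for up to
seven distinct haplotypes (Fitch-scored per segregating site), and a simple
branch-and-bound stepwise insertion is used beyond that.  Identical profiles
collapse onto one tip with a multiplicity; haplotypes identical to an
inferred ancestral state sit on zero-length branches (sampled ancestors,
e.g. a clade's root haplotype observed in several animals).

The resulting :class:`CladeTree` is rooted (midpoint or outgroup), keeps the
absolute mutation state of every node relative to the reference, and
annotates each branch with the ordered mutations separating the node from
its parent; it is the substrate for rho/sigma dating.
"""

from __future__ import annotations


from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

from .mutation import Mutation, MutationSet
from .variants import VariantProfile

__all__ = [
    "TreeNode",
    "CladeTree",
    "build_parsimony_tree",
    "root_tree",
    "annotate_recurrences",
]


@dataclass
class TreeNode:
    """One node of a rooted clade tree.

    ``state`` is the node's absolute mutation set relative to the reference;
    ``branch`` holds the mutations on the edge to the parent (symmetric
    difference of the two states).  Sampled haplotypes carry their sample
    ids; internal inferred nodes carry none.
    """

    state: MutationSet
    branch: MutationSet = field(default_factory=MutationSet)
    branch_length: float = 0.0
    label: str | None = None
    samples: tuple[str, ...] = ()
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def multiplicity(self) -> int:
        return len(self.samples)


@dataclass
class CladeTree:
    """Rooted tree whose branches carry mutations; tips carry multiplicities."""

    root: TreeNode
    name: str = "clade"
    #: False for freshly built trees whose root placement is arbitrary;
    #: set by :func:`root_tree`
    rooted: bool = True

    def nodes(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def sample_nodes(self) -> list[TreeNode]:
        return [n for n in self.nodes() if n.samples]

    @property
    def n_samples(self) -> int:
        return sum(n.multiplicity for n in self.nodes())

    @property
    def parsimony_score(self) -> int:
        return sum(len(n.branch) for n in self.nodes() if n is not self.root)

    def validate(self) -> None:
        """Check the state-consistency invariant on every edge."""
        def walk(node: TreeNode) -> None:
            for child in node.children:
                if node.state.symmetric_difference(child.branch) != child.state:
                    raise AssertionError(
                        f"state of node {child.label!r} inconsistent with parent "
                        "XOR branch"
                    )
                walk(child)
        walk(self.root)

    def subtree_multiplicity(self, node: TreeNode) -> int:
        total = node.multiplicity
        for c in node.children:
            total += self.subtree_multiplicity(c)
        return total

    def newick(self, include_mutations: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            label = node.label or ""
            if node.children:
                inner = ",".join(fmt(c) for c in node.children)
                core = f"({inner}){label}"
            else:
                core = label
            length = node.branch_length if node.branch_length else float(len(node.branch))
            notes = []
            if include_mutations and node.branch:
                notes.append("muts=" + "|".join(m.token() for m in node.branch))
            if node.multiplicity > 1:
                notes.append(f"n={node.multiplicity}")
            comment = f"[&{','.join(notes)}]" if notes else ""
            return f"{core}:{length:g}{comment}"

        return fmt(self.root) + ";"

    def copy(self) -> "CladeTree":
        def cp(node: TreeNode) -> TreeNode:
            return TreeNode(
                state=node.state,
                branch=node.branch,
                branch_length=node.branch_length,
                label=node.label,
                samples=node.samples,
                children=[cp(c) for c in node.children],
            )
        return CladeTree(cp(self.root), self.name, self.rooted)


# ---------------------------------------------------------------------------
# haplotype collapsing

@dataclass(frozen=True)
class _Haplotype:
    label: str
    state: MutationSet
    samples: tuple[str, ...]


def _collapse(profiles: Iterable[VariantProfile]) -> list[_Haplotype]:
    seen_ids: set[str] = set()
    groups: dict[MutationSet, list[str]] = {}
    for p in profiles:
        if p.sample_id in seen_ids:
            raise ValueError(f"duplicate sample id {p.sample_id!r}")
        seen_ids.add(p.sample_id)
        groups.setdefault(p.mutations, []).append(p.sample_id)
    haps = [
        _Haplotype(label=min(ids), state=state, samples=tuple(sorted(ids)))
        for state, ids in groups.items()
    ]
    return sorted(haps, key=lambda h: h.label)


# ---------------------------------------------------------------------------
# topology enumeration and Fitch scoring (tips are integers 0..k-1,
# internal nodes are negative integers)

def _copy_adj(adj: dict[int, set[int]]) -> dict[int, set[int]]:
    return {u: set(vs) for u, vs in adj.items()}


def _edges(adj: dict[int, set[int]]) -> list[tuple[int, int]]:
    return sorted({tuple(sorted((u, v))) for u in adj for v in adj[u]})


def _insert_tip(adj: dict[int, set[int]], edge: tuple[int, int],
                tip: int, internal: int) -> dict[int, set[int]]:
    u, v = edge
    new = _copy_adj(adj)
    new[u].discard(v)
    new[v].discard(u)
    new[internal] = {u, v, tip}
    new[u].add(internal)
    new[v].add(internal)
    new[tip] = {internal}
    return new


def _all_topologies(k: int) -> Iterator[dict[int, set[int]]]:
    if k == 2:
        yield {0: {1}, 1: {0}}
        return
    base = {0: {-1}, 1: {-1}, 2: {-1}, -1: {0, 1, 2}}
    def expand(adj, next_tip, next_internal):
        if next_tip == k:
            yield adj
            return
        for edge in _edges(adj):
            yield from expand(
                _insert_tip(adj, edge, next_tip, next_internal),
                next_tip + 1, next_internal - 1,
            )
    yield from expand(base, 3, -2)


def _fitch_score(adj: dict[int, set[int]], tip_states: list[dict]) -> int:
    """Total Fitch parsimony score; ``tip_states[i]`` maps site -> 0/1."""
    sites = set()
    for st in tip_states:
        sites.update(st)
    if not sites:
        return 0
    # root at tip 0; post-order over the remaining tree
    order: list[tuple[int, int]] = []  # (node, parent)
    stack = [(0, None)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nb in sorted(adj[node]):
            if nb != parent:
                stack.append((nb, node))
    score = 0
    for site in sites:
        sets: dict[int, frozenset] = {}
        for node, parent in reversed(order):
            if node >= 0:
                sets[node] = frozenset({tip_states[node].get(site, 0)})
            else:
                acc = None
                for nb in adj[node]:
                    if nb == parent:
                        continue
                    s = sets[nb]
                    if acc is None:
                        acc = s
                    else:
                        inter = acc & s
                        if inter:
                            acc = inter
                        else:
                            acc = acc | s
                            score += 1
                sets[node] = acc
        # account for the edge to the artificial root (tip 0)
        root_child = next(iter(adj[0]))
        if root_child != 0 and sets[0] & sets[root_child] == frozenset():
            score += 1
    return score


def _canonical(adj: dict[int, set[int]], labels: list[str]) -> str:
    """Canonical string of an unrooted topology, for deterministic tie-breaks."""
    root = next(iter(adj[0])) if len(adj) > 1 else 0
    def fmt(node: int, parent: int | None) -> str:
        kids = [nb for nb in adj[node] if nb != parent]
        if node >= 0:
            if not kids or parent is not None:
                return labels[node]
        parts = sorted(fmt(nb, node) for nb in kids)
        if node >= 0:
            parts.append(labels[node])
            parts.sort()
        return "(" + ",".join(parts) + ")"
    return fmt(root, None)


def _best_topology(haps: list[_Haplotype]) -> dict[int, set[int]]:
    k = len(haps)
    site_keys = sorted({m.key for h in haps for m in h.state})
    tip_states = [
        {key: (1 if key in {m.key for m in h.state} else 0) for key in site_keys}
        for h in haps
    ]
    labels = [h.label for h in haps]
    if k <= 7:
        best = None
        for adj in _all_topologies(k):
            score = _fitch_score(adj, tip_states)
            key = (score, _canonical(adj, labels))
            if best is None or key < best[0]:
                best = (key, adj)
        return best[1]
    # branch and bound by stepwise insertion; the score of a partial tree is
    # a lower bound for any completion
    best_adj: dict[int, set[int]] | None = None
    best_key: tuple | None = None

    def recurse(adj, next_tip, next_internal):
        nonlocal best_adj, best_key
        score = _fitch_score(adj, tip_states)
        if best_key is not None and score > best_key[0]:
            return
        if next_tip == k:
            key = (score, _canonical(adj, labels))
            if best_key is None or key < best_key:
                best_key, best_adj = key, adj
            return
        for edge in _edges(adj):
            recurse(_insert_tip(adj, edge, next_tip, next_internal),
                    next_tip + 1, next_internal - 1)

    recurse({0: {-1}, 1: {-1}, 2: {-1}, -1: {0, 1, 2}}, 3, -2)
    return best_adj


# ---------------------------------------------------------------------------
# state assignment (Fitch down-pass + delayed-transformation up-pass)

def _assign_states(
    adj: dict[int, set[int]],
    haps: list[_Haplotype],
    root: int,
) -> dict[int, MutationSet]:
    site_keys = sorted({m.key for h in haps for m in h.state})
    exemplar = {}
    for h in haps:
        for m in h.state:
            exemplar.setdefault(
                m.key,
                replace(m, heteroplasmic=False, back_mutation=False, recurrent=False),
            )
    tip_has = [{m.key for m in h.state} for h in haps]

    order: list[tuple[int, int | None]] = []
    stack: list[tuple[int, int | None]] = [(root, None)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nb in sorted(adj[node]):
            if nb != parent:
                stack.append((nb, node))

    INF = float("inf")
    final: dict[int, dict] = {node: {} for node, _ in order}
    for site in site_keys:
        # exact small-parsimony DP (unit costs), valid for polytomies too
        cost: dict[int, tuple[float, float]] = {}
        for node, parent in reversed(order):
            if node >= 0:
                observed = 1 if site in tip_has[node] else 0
                cost[node] = (0.0, INF) if observed == 0 else (INF, 0.0)
            else:
                c0 = c1 = 0.0
                for nb in adj[node]:
                    if nb == parent:
                        continue
                    k0, k1 = cost[nb]
                    c0 += min(k0, k1 + 1)
                    c1 += min(k1, k0 + 1)
                cost[node] = (c0, c1)
        for node, parent in order:
            c0, c1 = cost[node]
            if parent is None:
                # ties resolve toward the reference-like (ancestral) state
                final[node][site] = 0 if c0 <= c1 else 1
            else:
                pstate = final[parent][site]
                other = 1 - pstate
                with_p = cost[node][pstate]
                with_other = cost[node][other] + 1
                # keep the parent state whenever it is optimal (delayed
                # transformation: changes sit as far from the root as possible)
                final[node][site] = pstate if with_p <= with_other else other
    return {
        node: MutationSet(tuple(exemplar[s] for s, v in st.items() if v == 1))
        for node, st in final.items()
    }


def _compose_tree(
    adj: dict[int, set[int]],
    states: dict[int, MutationSet],
    haps: list[_Haplotype],
    root: int,
    name: str = "clade",
) -> CladeTree:
    def build(node: int, parent: int | None) -> TreeNode:
        state = states[node]
        tn = TreeNode(state=state)
        if node >= 0:
            tn.label = haps[node].label
            tn.samples = haps[node].samples
        if parent is not None:
            tn.branch = states[parent].symmetric_difference(state)
            tn.branch_length = float(len(tn.branch))
        for nb in sorted(adj[node], key=lambda x: (x < 0, x)):
            if nb != parent:
                tn.children.append(build(nb, node))
        return tn

    tree = CladeTree(build(root, None), name, rooted=False)
    tree.validate()
    return tree


def build_parsimony_tree(
    profiles: Iterable[VariantProfile], name: str = "clade"
) -> CladeTree:
    """Most-parsimonious rooted tree over the distinct haplotypes.

    The output is rooted (arbitrarily, at the attachment node of the
    lexicographically first haplotype) and deterministic: among equally
    parsimonious topologies the one with the smallest canonical newick of
    haplotype labels is chosen.  Use :func:`root_tree` to re-root.
    """
    profiles = list(profiles)
    haps = _collapse(profiles)
    if len(haps) == 1:
        h = haps[0]
        return CladeTree(
            TreeNode(state=h.state, label=h.label, samples=h.samples), name
        )
    adj = _best_topology(haps)
    # root at the node adjacent to tip 0 (internal if one exists)
    root = next(iter(adj[0])) if len(adj) > 2 else 0
    states = _assign_states(adj, haps, root)
    return _compose_tree(adj, states, haps, root, name)


# ---------------------------------------------------------------------------
# re-rooting

def _decompose(tree: CladeTree):
    """Undirected view: node records plus edges with their mutation sets."""
    nodes: list[dict] = []
    edges: list[tuple[int, int, MutationSet, float]] = []

    def walk(node: TreeNode, parent_id: int | None) -> int:
        nid = len(nodes)
        nodes.append({"state": node.state, "label": node.label, "samples": node.samples})
        if parent_id is not None:
            edges.append((parent_id, nid, node.branch, node.branch_length))
        for c in node.children:
            walk(c, nid)
        return nid

    walk(tree.root, None)
    return nodes, edges


def _compose_from_edges(nodes, edges, root_id, name) -> CladeTree:
    adj: dict[int, list[tuple[int, MutationSet, float]]] = {i: [] for i in range(len(nodes))}
    for u, v, ms, ln in edges:
        adj[u].append((v, ms, ln))
        adj[v].append((u, ms, ln))

    def build(nid: int, parent: int | None, branch: MutationSet, length: float) -> TreeNode:
        rec = nodes[nid]
        tn = TreeNode(state=rec["state"], branch=branch, branch_length=length,
                      label=rec["label"], samples=rec["samples"])
        for nb, ms, ln in sorted(adj[nid], key=lambda t: t[0]):
            if nb != parent:
                tn.children.append(build(nb, nid, ms, ln))
        return tn

    tree = CladeTree(build(root_id, None, MutationSet(), 0.0), name, rooted=True)
    tree = _suppress_unary(tree)
    tree.validate()
    return tree


def _suppress_unary(tree: CladeTree) -> CladeTree:
    """Merge sample-free degree-2 nodes left behind by re-rooting."""
    def walk(node: TreeNode) -> TreeNode:
        node.children = [walk(c) for c in node.children]
        merged = []
        for c in node.children:
            if len(c.children) == 1 and not c.samples:
                g = c.children[0]
                g.branch = c.branch.union(g.branch)
                g.branch_length = c.branch_length + g.branch_length
                merged.append(g)
            else:
                merged.append(c)
        node.children = merged
        return node

    return CladeTree(walk(tree.root), tree.name, tree.rooted)


def root_tree(
    tree: CladeTree,
    method: str = "midpoint",
    outgroup: VariantProfile | str | None = None,
    drop_outgroup: bool = True,
) -> CladeTree:
    """Re-root a clade tree at the midpoint or on an outgroup attachment.

    Midpoint rooting places the root halfway along the longest tip-to-tip
    path in the mutation-count metric, splitting an edge if necessary (the
    two root branches then carry fractional lengths whose mutation sets
    partition the split edge).  Outgroup rooting places the root at the
    node where the outgroup tip attaches and, by default, removes the
    outgroup from the returned tree.
    """
    nodes, edges = _decompose(tree)
    if method == "outgroup":
        if outgroup is None:
            raise ValueError("outgroup rooting requires an outgroup")
        og_state = outgroup.mutations if isinstance(outgroup, VariantProfile) else None
        og_label = outgroup if isinstance(outgroup, str) else None
        target = None
        for i, rec in enumerate(nodes):
            if og_label is not None and rec["label"] == og_label:
                target = i
                break
            if og_state is not None and rec["samples"] and rec["state"] == og_state:
                target = i
                break
        if target is None:
            raise ValueError("outgroup not found among the tree's haplotypes")
        og_id = outgroup.sample_id if isinstance(outgroup, VariantProfile) else None
        kept_samples = tuple(s for s in nodes[target]["samples"] if s != og_id)
        if kept_samples:
            # the outgroup state coincides with a sampled ingroup haplotype
            # (sampled ancestor): the root *is* that node
            if drop_outgroup:
                nodes[target]["samples"] = kept_samples
                nodes[target]["label"] = min(kept_samples)
            return _compose_from_edges(nodes, edges, target, tree.name)
        neighbours = [
            (u if v == target else v)
            for (u, v, _, _) in edges if target in (u, v)
        ]
        if not neighbours:  # outgroup is the sole node
            raise ValueError("cannot root a single-node tree on its outgroup")
        root_id = neighbours[0]
        if drop_outgroup:
            edges = [e for e in edges if target not in e[:2]]
            nodes[target]["samples"] = ()
            nodes[target]["label"] = None
        return _compose_from_edges(nodes, edges, root_id, tree.name)

    if method != "midpoint":
        raise ValueError(f"unknown rooting method {method!r}")

    # midpoint: longest path between sample-bearing nodes
    adj: dict[int, list[tuple[int, int, MutationSet, float]]] = {i: [] for i in range(len(nodes))}
    for ei, (u, v, ms, ln) in enumerate(edges):
        adj[u].append((v, ei, ms, ln))
        adj[v].append((u, ei, ms, ln))

    payload = [i for i, rec in enumerate(nodes) if rec["samples"]]

    def distances(src: int) -> dict[int, tuple[float, list[int]]]:
        out = {src: (0.0, [])}
        stack = [src]
        while stack:
            u = stack.pop()
            d, path = out[u]
            for v, ei, ms, ln in adj[u]:
                if v not in out:
                    out[v] = (d + len(ms), path + [ei])
                    stack.append(v)
        return out

    best = (0.0, None, None, None)
    for a in payload:
        dmap = distances(a)
        for b in payload:
            if b <= a:
                continue
            d, path = dmap[b]
            if d > best[0]:
                best = (d, a, b, path)
    diameter, a, b, path = best
    if diameter == 0:
        raise ValueError("midpoint rooting undefined on a zero-length tree")
    half = diameter / 2.0
    acc = 0.0
    cur = a
    for ei in path:
        u, v, ms, ln = edges[ei]
        far = v if cur == u else u
        step = float(len(ms))
        if acc + step >= half:
            into = half - acc  # distance from `cur` into this edge
            if into == 0.0:
                return _compose_from_edges(nodes, edges, cur, tree.name)
            if into == step:
                return _compose_from_edges(nodes, edges, far, tree.name)
            ordered = sorted(ms, key=lambda m: (m.position, m.token()))
            k_cur = int(into)  # mutations assigned to the `cur` side
            cur_side = MutationSet(tuple(ordered[:k_cur]))
            far_side = MutationSet(tuple(ordered[k_cur:]))
            root_id = len(nodes)
            root_state = nodes[cur]["state"].symmetric_difference(cur_side)
            nodes.append({"state": root_state, "label": None, "samples": ()})
            edges = [e for i, e in enumerate(edges) if i != ei]
            edges.append((root_id, cur, cur_side, into))
            edges.append((root_id, far, far_side, step - into))
            return _compose_from_edges(nodes, edges, root_id, tree.name)
        acc += step
        cur = far
    raise AssertionError("midpoint not located on the longest path")


def annotate_recurrences(tree: CladeTree) -> CladeTree:
    """Flag recurrent and back mutations on a rooted tree's branches.

    A mutation occurring on more than one branch is flagged recurrent; a
    branch mutation that reverts a state already present on the root-to-node
    path (i.e. removes it) is flagged as a back mutation.
    """
    out = tree.copy()
    counts: dict = {}
    for n in out.nodes():
        if n is out.root:
            continue
        for m in n.branch:
            counts[m.key] = counts.get(m.key, 0) + 1

    def walk(node: TreeNode, parent_state: MutationSet | None) -> None:
        if parent_state is not None:
            new_branch = []
            for m in node.branch:
                recurrent = counts.get(m.key, 0) > 1
                back = m in parent_state  # present upstream, removed here
                new_branch.append(replace(m, recurrent=recurrent, back_mutation=back))
            node.branch = MutationSet(tuple(new_branch))
        for c in node.children:
            walk(c, node.state)

    walk(out.root, None)
    return out
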