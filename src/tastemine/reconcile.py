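"""Tree I/O, neighbor joining, LCA gene-tree/species-tree reconciliation and
gene-repertoire trajectories.

The reconciliation embeds a rooted binary gene tree into a rooted binary
species tree by the last-common-ancestor (LCA) mapping: a gene node whose
mapping equals the mapping of one of its children is a duplication; losses
are counted per gene-tree edge from the depth difference of the mappings
(path length minus one for speciations, path length for duplications) and
charged to the sibling species branches along the path.  The LCA mapping
simultaneously minimises the duplication and loss counts.

Repertoire trajectories place the summed per-branch gains (duplications)
and losses of a set of families on the species tree and propagate ancestral
copy numbers from the root, so that on every branch
``child = parent + gains - losses``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy

ROOT_BRANCH = "ROOT"


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------


def read_newick(text: str) -> dendropy.Tree:
    """Parse a newick string; raises ValueError on malformed input or
    duplicate leaf labels.  Non-binary trees are accepted and flagged via
    :func:`is_binary`."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed newick: {exc}") from exc
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in newick input")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def is_binary(tree: dendropy.Tree) -> bool:
    return all(
        len(n.child_nodes()) in (0, 2) for n in tree.preorder_node_iter()
    )


# ---------------------------------------------------------------------------
# neighbor joining (fallback when no externally built tree is supplied)
# ---------------------------------------------------------------------------


def nj_tree(distances) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance table.

    ``distances`` is a pandas DataFrame (index == columns == taxa) or a
    nested dict.  Taxa are ordered lexicographically so ties resolve
    deterministically.
    """
    import io as _io

    import pandas as pd

    df = pd.DataFrame(distances)
    df = df.loc[sorted(df.index), sorted(df.index)]
    if not (df.values.T == df.values).all():
        raise ValueError("distance table must be symmetric")
    csv = _io.StringIO(df.to_csv())
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(csv, delimiter=",")
    return pdm.nj_tree()


# ---------------------------------------------------------------------------
# internal light-weight rooted trees
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    name: str | None = None
    children: list = field(default_factory=list)
    parent: object = None
    depth: int = 0
    leafset: frozenset = frozenset()


def _from_dendropy(tree: dendropy.Tree) -> _Node:
    def conv(nd, parent):
        n = _Node(name=nd.taxon.label if nd.taxon else nd.label, parent=parent)
        n.children = [conv(c, n) for c in nd.child_nodes()]
        return n

    root = conv(tree.seed_node, None)
    _index(root)
    return root


def _index(root: _Node) -> None:
    def down(n, depth):
        n.depth = depth
        if not n.children:
            n.leafset = frozenset([n.name])
        else:
            for c in n.children:
                down(c, depth + 1)
            n.leafset = frozenset().union(*(c.leafset for c in n.children))

    down(root, 0)


def _postorder(n: _Node):
    for c in n.children:
        yield from _postorder(c)
    yield n


def branch_key(node: _Node) -> str:
    """Canonical branch id: sorted leaf names below the branch's child."""
    return ",".join(sorted(node.leafset))


def default_leaf_map(label: str) -> str:
    """Species name from a 'Species_gene' gene-tree leaf label."""
    return label.split("_")[0]


# ---------------------------------------------------------------------------
# LCA reconciliation
# ---------------------------------------------------------------------------


@dataclass
class ReconciliationResult:
    duplications: int
    losses: int
    events: dict  # gene branch_key -> SPECIATION | DUPLICATION | LEAF
    mapping: dict  # gene branch_key -> species branch_key
    dup_by_branch: dict  # species branch key -> duplication count
    loss_by_branch: dict  # species branch key -> loss count
    root_lineages: int = 1  # gene lineages crossing the species root


def _lca(a: _Node, b: _Node) -> _Node:
    while a is not b:
        if a.depth >= b.depth:
            a = a.parent
        else:
            b = b.parent
    return a


def lca_reconcile(
    gene_tree, species_tree, leaf_map=default_leaf_map
) -> ReconciliationResult:
    """Minimal duplication/loss reconciliation by the LCA mapping.

    Both trees must be rooted and binary; gene leaves map onto species
    leaves via ``leaf_map`` (callable or dict).
    """
    g_root = _as_node(gene_tree)
    s_root = _as_node(species_tree)
    for tree, what in ((g_root, "gene"), (s_root, "species")):
        if any(len(n.children) not in (0, 2) for n in _postorder(tree)):
            raise ValueError(f"{what} tree must be binary")
    species_by_name = {n.name: n for n in _postorder(s_root) if not n.children}
    mapper = leaf_map if callable(leaf_map) else leaf_map.get

    M: dict[int, _Node] = {}
    events: dict[str, str] = {}
    mapping: dict[str, str] = {}
    D = 0
    dup_by_branch: dict[str, int] = {}
    loss_by_branch: dict[str, int] = {}

    for g in _postorder(g_root):
        if not g.children:
            sp = mapper(g.name)
            if sp not in species_by_name:
                raise ValueError(
                    f"gene leaf {g.name!r} maps to unknown species {sp!r}"
                )
            M[id(g)] = species_by_name[sp]
            events[branch_key(g)] = "LEAF"
        else:
            m = _lca(M[id(g.children[0])], M[id(g.children[1])])
            M[id(g)] = m
            dup = any(M[id(c)] is m for c in g.children)
            events[branch_key(g)] = "DUPLICATION" if dup else "SPECIATION"
            if dup:
                D += 1
                key = ROOT_BRANCH if m.parent is None else branch_key(m)
                dup_by_branch[key] = dup_by_branch.get(key, 0) + 1
        mapping[branch_key(g)] = branch_key(M[id(g)])

    L = 0
    for g in _postorder(g_root):
        if not g.children:
            continue
        dup = events[branch_key(g)] == "DUPLICATION"
        for c in g.children:
            lo, hi = M[id(c)], M[id(g)]
            # walk up from the child's mapping; each species node passed
            # leaves a loss on the sibling branch not taken
            node = lo
            while node is not hi:
                sib = [x for x in node.parent.children if x is not node][0]
                if node.parent is hi and not dup:
                    break  # speciation: entry into this branch is the event
                key = branch_key(sib)
                loss_by_branch[key] = loss_by_branch.get(key, 0) + 1
                L += 1
                node = node.parent

    return ReconciliationResult(
        duplications=D,
        losses=L,
        events=events,
        mapping=mapping,
        dup_by_branch=dup_by_branch,
        loss_by_branch=loss_by_branch,
        root_lineages=1 + dup_by_branch.get(ROOT_BRANCH, 0),
    )


def _as_node(tree) -> _Node:
    if isinstance(tree, _Node):
        return tree
    if isinstance(tree, str):
        tree = read_newick(tree)
    return _from_dendropy(tree)


# ---------------------------------------------------------------------------
# exhaustive minimal-reconciliation oracle (brute force, small trees only)
# ---------------------------------------------------------------------------


def exhaustive_min_dl(gene_tree, species_tree, leaf_map=default_leaf_map):
    """(D, L) of a minimal reconciliation by exhaustive search over all
    mappings of gene nodes to species nodes.  Exponential; validation use
    only (the LCA algorithm is the production path)."""
    g_root = _as_node(gene_tree)
    s_root = _as_node(species_tree)
    species_by_name = {n.name: n for n in _postorder(s_root) if not n.children}
    mapper = leaf_map if callable(leaf_map) else leaf_map.get
    s_nodes = list(_postorder(s_root))
    gene_internal = [g for g in _postorder(g_root) if g.children]
    ancestors: dict[int, set] = {}
    for s in s_nodes:
        anc, node = set(), s
        while node is not None:
            anc.add(id(node))
            node = node.parent
        ancestors[id(s)] = anc

    fixed = {}
    for g in _postorder(g_root):
        if not g.children:
            fixed[id(g)] = species_by_name[mapper(g.name)]

    best = None
    for assignment in itertools.product(s_nodes, repeat=len(gene_internal)):
        M = dict(fixed)
        for g, s in zip(gene_internal, assignment):
            M[id(g)] = s
        ok = True
        D = L = 0
        for g in gene_internal:
            s = M[id(g)]
            kids = [M[id(c)] for c in g.children]
            if any(id(s) not in ancestors[id(k)] for k in kids):
                ok = False
                break
            dup = any(k is s for k in kids) or _lca(kids[0], kids[1]) is not s
            if dup:
                D += 1
                L += sum(k.depth - s.depth for k in kids)
            else:
                L += sum(k.depth - s.depth - 1 for k in kids)
        if not ok:
            continue
        cand = (D + L, D, L)
        if best is None or cand < best:
            best = cand
    return best[1], best[2]


# ---------------------------------------------------------------------------
# rooting by duplication-loss score
# ---------------------------------------------------------------------------


def root_by_dl(gene_tree, species_tree, leaf_map=default_leaf_map):
    """Root an unrooted gene tree on the branch minimising D+L.

    Every branch is evaluated as a root position; ties break by (D, then
    canonical branch order).  Returns (rooted dendropy tree, result).
    """
    if isinstance(gene_tree, str):
        gene_tree = read_newick(gene_tree)
    leaves = [l.taxon.label for l in gene_tree.leaf_node_iter()]
    if len(leaves) < 3:
        res = lca_reconcile(gene_tree, species_tree, leaf_map)
        return gene_tree, res
    best = None
    edges = []
    for edge in gene_tree.preorder_edge_iter():
        if edge.head_node is gene_tree.seed_node:
            continue
        key = ",".join(sorted(l.taxon.label for l in edge.head_node.leaf_iter()))
        edges.append((key, edge))
    edges.sort(key=lambda ke: ke[0])
    for key, edge in edges:
        t = gene_tree.clone(depth=1)
        # find the corresponding edge in the clone by its leafset
        target = None
        for e in t.preorder_edge_iter():
            if e.head_node is t.seed_node:
                continue
            k = ",".join(sorted(l.taxon.label for l in e.head_node.leaf_iter()))
            if k == key:
                target = e
                break
        t.reroot_at_edge(target, update_bipartitions=False)
        t.seed_node.parent_node = None
        if not is_binary(t):
            continue
        res = lca_reconcile(t, species_tree, leaf_map)
        cand = (res.duplications + res.losses, res.duplications, key)
        if best is None or cand < best[0]:
            best = (cand, t, res)
    if best is None:
        raise ValueError("no valid rooting found")
    return best[1], best[2]


# ---------------------------------------------------------------------------
# repertoire trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    counts: dict  # species branch key (node leafset) -> ancestral count
    gains: dict  # species branch key -> gains on the branch into the node
    losses: dict
    root_count: int


def trajectory_from_events(
    species_tree,
    root_count: int,
    gains: dict,
    losses: dict,
    observed_counts: dict | None = None,
) -> Trajectory:
    """Propagate ancestral counts from the root given per-branch events.

    ``gains``/``losses`` are keyed by branch (canonical child-leafset key or
    a leaf name for terminal branches).  Raises ValueError naming the
    branch if a propagated leaf count contradicts ``observed_counts``.
    """
    s_root = _as_node(species_tree)
    counts: dict[str, int] = {}

    def down(node: _Node, parent_count: int) -> None:
        key = branch_key(node)
        if node.parent is None:
            counts[key] = parent_count
        else:
            counts[key] = (
                parent_count + gains.get(key, 0) - losses.get(key, 0)
            )
        if not node.children:
            if (
                observed_counts is not None
                and node.name in observed_counts
                and observed_counts[node.name] != counts[key]
            ):
                raise ValueError(
                    f"branch {key}: propagated count {counts[key]} != "
                    f"observed {observed_counts[node.name]}"
                )
        for c in node.children:
            down(c, counts[key])

    down(s_root, root_count)
    return Trajectory(
        counts=counts,
        gains={branch_key(n): gains.get(branch_key(n), 0)
               for n in _postorder(s_root) if n.parent is not None},
        losses={branch_key(n): losses.get(branch_key(n), 0)
                for n in _postorder(s_root) if n.parent is not None},
        root_count=root_count,
    )


def ancestral_trajectory(
    results: list[ReconciliationResult],
    species_tree,
    observed_counts: dict | None = None,
) -> Trajectory:
    """Sum per-branch events over reconciled families and propagate counts."""
    gains: dict[str, int] = {}
    losses: dict[str, int] = {}
    root = 0
    for r in results:
        root += r.root_lineages
        for k, v in r.dup_by_branch.items():
            if k != ROOT_BRANCH:
                gains[k] = gains.get(k, 0) + v
        for k, v in r.loss_by_branch.items():
            losses[k] = losses.get(k, 0) + v
    return trajectory_from_events(
        species_tree, root, gains, losses, observed_counts
    )


def trajectory_to_tsv(traj: Trajectory) -> str:
    lines = ["branch\tancestral_count\tgains\tlosses"]
    for key in sorted(traj.counts):
        lines.append(
            f"{key}\t{traj.counts[key]}\t{traj.gains.get(key, 0)}\t"
            f"{traj.losses.get(key, 0)}"
        )
    return "\n".join(lines) + "\n"
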